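import numpy as np
import pytest

import rbedplan as rp
from rbedplan.phantom import tumour_centre
from rbedplan.physics import AttenuationTable, EnergySpectrum


@pytest.fixture(scope="session")
def attenuation_table():
    return AttenuationTable.bundled()


@pytest.fixture(scope="session")
def spectrum_6mv():
    return EnergySpectrum.bundled_6mv()


@pytest.fixture(scope="session")
def default_phantom_2mm():
    """The study phantom voxelised at 2 mm for desk-scale engine runs."""
    return rp.build_default_phantom({"spacing_mm": 2.0})


@pytest.fixture(scope="session")
def calibrated_runs(default_phantom_2mm, spectrum_6mv, attenuation_table):
    """Calibrated doped/undoped fraction doses on the default phantom."""
    phantom = default_phantom_2mm
    plan = rp.opposed_pair(tumour_centre())
    doses = {}
    for arm, ph in [("doped", phantom), ("undoped", phantom.with_concentrations(0.0))]:
        raw = rp.simulate_fraction(ph, plan, spectrum_6mv, attenuation_table)
        _, doses[arm] = rp.calibrate_to_min_region_dose(raw, phantom, [8, 9], 2.0)
    return phantom, doses


@pytest.fixture(scope="session")
def water_slab_2mm():
    """Homogeneous 60 mm water cube on a 2 mm lattice (vacuum outside)."""
    from rbedplan.phantom import RegionSpec, VoxelPhantom, voxelize

    labels, origin = voxelize([], 2.0, [[-30, 30]] * 3)
    labels[:] = 1
    return VoxelPhantom(
        labels,
        (2.0, 2.0, 2.0),
        origin,
        {
            0: RegionSpec(0, "background", "vacuum", 0.0),
            1: RegionSpec(1, "water_slab", "water", 0.0),
        },
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
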
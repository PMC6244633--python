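"""Phantom voxelisation: primitives, default anatomy, I/O round trips."""

import math

import numpy as np
import pytest

from rbedplan.materials import MATERIALS
from rbedplan.phantom import (
    DEFAULT_REGIONS,
    RegionSpec,
    ShapePrimitive,
    VoxelPhantom,
    build_default_phantom,
    export_phantom,
    import_phantom,
    region_volumes,
    voxelize,
)


def brute_force_sphere_count(radius, spacing, extent_half, centre=(0.0, 0.0, 0.0)):
    """Centre-inclusion voxel count by explicit scalar iteration."""
    n = int(round(2 * extent_half / spacing))
    count = 0
    for i in range(n):
        x = -extent_half + (i + 0.5) * spacing - centre[0]
        for j in range(n):
            y = -extent_half + (j + 0.5) * spacing - centre[1]
            for k in range(n):
                z = -extent_half + (k + 0.5) * spacing - centre[2]
                if x * x + y * y + z * z <= radius * radius:
                    count += 1
    return count


class TestVoxelize:
    # A generic (off-lattice) centre, as in the default phantom; lattice-
    # symmetric centres align the surface with voxel centres and carry a
    # larger systematic surface bias.
    CENTRE = (0.3, 0.2, 0.1)

    def test_sphere_volume_close_to_analytic_and_exact_vs_oracle(self):
        sphere = ShapePrimitive("sphere", self.CENTRE, {"radius": 8.0}, label=1, priority=1)
        labels, _ = voxelize([sphere], 1.0, [[-12, 12]] * 3)
        count = int((labels == 1).sum())
        assert count == brute_force_sphere_count(8.0, 1.0, 12.0, self.CENTRE)
        analytic = 4 / 3 * math.pi * 8**3  # 2144.66 mm³
        assert abs(count - analytic) / analytic < 0.01

    def test_shell_volume_close_to_analytic(self):
        shell = ShapePrimitive(
            "spherical-shell",
            self.CENTRE,
            {"outer_radius": 10.0, "inner_radius": 8.0},
            label=1,
            priority=1,
        )
        labels, _ = voxelize([shell], 1.0, [[-12, 12]] * 3)
        analytic = 4 / 3 * math.pi * (10**3 - 8**3)  # 2044.13 mm³
        assert abs(int((labels == 1).sum()) - analytic) / analytic < 0.02

    def test_tiny_sphere_single_voxel(self):
        sphere = ShapePrimitive(
            "sphere", (0.5, 0.5, 0.5), {"radius": 0.4}, label=1, priority=1
        )
        labels, _ = voxelize([sphere], 1.0, [[0, 4]] * 3)
        assert int((labels == 1).sum()) == 1

    def test_empty_shape_list_uniform_background(self):
        labels, origin = voxelize([], 1.0, [[0, 10]] * 3)
        assert labels.shape == (10, 10, 10)
        assert np.all(labels == 0)
        assert origin == (0.0, 0.0, 0.0)

    def test_priority_resolves_overlap(self):
        lo = ShapePrimitive("sphere", (0, 0, 0), {"radius": 5.0}, label=1, priority=1)
        hi = ShapePrimitive("sphere", (0, 0, 0), {"radius": 3.0}, label=2, priority=2)
        labels, _ = voxelize([lo, hi], 1.0, [[-6, 6]] * 3)
        assert labels[6, 6, 6] == 2
        assert (labels == 1).any()

    def test_convergence_to_analytic_volume(self):
        analytic = 4 / 3 * math.pi * 10**3
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            sphere = ShapePrimitive(
                "sphere", (0, 0, 0), {"radius": 10.0}, label=1, priority=1
            )
            labels, _ = voxelize([sphere], spacing, [[-12, 12]] * 3)
            vol = (labels == 1).sum() * spacing**3
            errors.append(abs(vol - analytic) / analytic)
        assert errors[-1] < errors[0]
        assert errors[-1] < 5e-3


class TestRegionVolumes:
    def test_all_background_grid(self):
        labels, origin = voxelize([], 1.0, [[0, 10]] * 3)
        ph = VoxelPhantom(
            labels, (1, 1, 1), origin, {0: RegionSpec(0, "background", "air")}
        )
        assert region_volumes(ph) == {0: 1000.0}

    def test_empty_label_reports_zero(self):
        labels, origin = voxelize([], 1.0, [[0, 5]] * 3)
        ph = VoxelPhantom(
            labels,
            (1, 1, 1),
            origin,
            {0: RegionSpec(0, "background", "air"), 3: RegionSpec(3, "ghost", "water")},
        )
        assert region_volumes(ph)[3] == 0.0


@pytest.fixture(scope="module")
def phantom_2mm():
    return build_default_phantom({"spacing_mm": 2.0})


class TestDefaultPhantom:
    def test_region_table_components(self, phantom_2mm):
        names = {s.name for s in phantom_2mm.regions.values()}
        assert names == {
            "background",
            "torso_bulk",
            "spine",
            "sternum",
            "ribs",
            "lung_wall",
            "heart",
            "breast",
            "tumour_inner",
            "tumour_wall",
        }
        present = set(np.unique(phantom_2mm.labels).tolist())
        assert present == set(range(10))

    def test_aunp_uptake_pattern(self, phantom_2mm):
        by_name = {s.name: s for s in phantom_2mm.regions.values()}
        assert by_name["tumour_wall"].concentration == 500.0
        assert by_name["tumour_inner"].concentration == 250.0
        assert by_name["breast"].concentration == 25.0
        for bone in ("ribs", "spine", "sternum"):
            assert by_name[bone].concentration == 0.0
            assert by_name[bone].material == "compact_bone"

    def test_tumour_compartment_volume_ratio(self, phantom_2mm):
        vols = region_volumes(phantom_2mm)
        ratio = vols[8] / vols[9]
        assert ratio == pytest.approx(4096 / 3904, rel=0.05)

    def test_mirror_symmetry(self, phantom_2mm):
        lab = phantom_2mm.labels
        refl = lab[::-1, :, :]
        breast_union = np.isin(lab, [7, 8, 9])
        assert np.array_equal(breast_union, np.isin(refl, [7, 8, 9]))
        assert np.array_equal(lab == 5, refl == 5)

    def test_tumour_outside_breast_rejected(self):
        with pytest.raises(ValueError, match="tumour"):
            build_default_phantom({"spacing_mm": 4.0, "tumour": {"offset": 80.0}})


def test_material_mass_fractions_normalised():
    for spec in DEFAULT_REGIONS.values():
        mat = MATERIALS[spec.material]
        if mat.composition:
            assert sum(mat.composition.values()) == pytest.approx(1.0, abs=1e-6)


class TestPhantomIO:
    def test_round_trip(self, tmp_path, phantom_2mm):
        path = tmp_path / "phantom.nii.gz"
        export_phantom(phantom_2mm, path)
        back = import_phantom(path)
        np.testing.assert_array_equal(back.labels, phantom_2mm.labels)
        assert back.spacing == phantom_2mm.spacing
        assert region_volumes(back) == region_volumes(phantom_2mm)

    def test_missing_sidecar(self, tmp_path, phantom_2mm):
        path = tmp_path / "phantom.nii.gz"
        export_phantom(phantom_2mm, path)
        (tmp_path / "phantom.regions.json").unlink()
        with pytest.raises(FileNotFoundError):
            import_phantom(path)

    def test_unknown_label_rejected(self, tmp_path):
        labels, origin = voxelize([], 1.0, [[0, 5]] * 3)
        labels[0, 0, 0] = 7  # not in the table below
        ph_path = tmp_path / "bad.nii.gz"
        good = VoxelPhantom(
            np.zeros_like(labels),
            (1, 1, 1),
            origin,
            {0: RegionSpec(0, "background", "air")},
        )
        export_phantom(good, ph_path)
        import nibabel as nib

        nib.save(nib.Nifti1Image(labels.astype(np.int16), np.eye(4)), ph_path)
        with pytest.raises(ValueError, match="missing from the region table"):
            import_phantom(ph_path)
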
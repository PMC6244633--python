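"""Tissue material compositions and nanoparticle doping.

Compositions are elemental mass fractions for the ICRU-style body tissues
used by the phantom (soft tissue, breast, inflated lung, skeletal muscle,
compact bone) plus water, air and vacuum. Gold doping at a volumetric
concentration C (μg/ml) adds Au at mass fraction (C × 1e-6 g/cm³) / ρ and
renormalises the host fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Material:
    """An elemental mixture with a bulk mass density.

    Parameters
    ----------
    name : str
        Identifier used in region tables.
    density : float
        Bulk density in g/cm³ (0 for vacuum).
    composition : dict
        Element symbol → mass fraction. Fractions must sum to 1 within
        1e-6 (empty for vacuum).
    """

    name: str
    density: float
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"negative density for {self.name!r}")
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"mass fractions of {self.name!r} sum to {total!r}, not 1"
                )
        if any(w < 0 for w in self.composition.values()):
            raise ValueError(f"negative mass fraction in {self.name!r}")


def _mat(name: str, density: float, **fractions: float) -> Material:
    total = sum(fractions.values())
    comp = {el: w / total for el, w in fractions.items()}
    return Material(name, density, comp)


#: Registry of base materials. ICRU-44 body-tissue recipes (adult), the
#: compact-bone recipe used by ICRU stopping-power tabulations, and
#: supporting media.
MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        _mat("water", 1.000, H=0.111894, O=0.888106),
        _mat(
            "air", 0.0012048, C=0.000124, N=0.755267, O=0.231781, Ar=0.012827
        ),
        Material("vacuum", 0.0, {}),
        _mat(
            "soft_tissue",
            1.03,
            H=0.102, C=0.143, N=0.034, O=0.708,
            Na=0.002, P=0.003, S=0.003, Cl=0.002, K=0.003,
        ),
        _mat(
            "breast_tissue",
            1.02,
            H=0.106, C=0.332, N=0.030, O=0.527,
            Na=0.001, P=0.001, S=0.002, Cl=0.001,
        ),
        _mat(
            "lung_tissue",
            0.26,
            H=0.103, C=0.105, N=0.031, O=0.749,
            Na=0.002, P=0.002, S=0.003, Cl=0.003, K=0.002,
        ),
        _mat(
            "muscle",
            1.05,
            H=0.102, C=0.143, N=0.034, O=0.710,
            Na=0.001, P=0.002, S=0.003, Cl=0.001, K=0.004,
        ),
        _mat(
            "compact_bone",
            1.85,
            H=0.064, C=0.278, N=0.027, O=0.410,
            Mg=0.002, P=0.070, S=0.002, Ca=0.147,
        ),
    ]
}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(MATERIALS)}"
        ) from None


def doped_composition(material: Material | str, concentration: float) -> Material:
    """Add gold nanoparticles at a volumetric concentration to a material.

    Parameters
    ----------
    material : Material or str
        Host material (or its registry name).
    concentration : float
        AuNP concentration in μg/ml (= μg/cm³ of tissue).

    Returns
    -------
    Material
        The host with gold at mass fraction (C·1e-6)/ρ and the remaining
        fractions renormalised. C = 0 returns the host unchanged. The bulk
        density is kept at the host value: at clinical concentrations
        (≤ 500 μg/ml) the density perturbation is ≤ 5e-4 and irrelevant
        next to the attenuation perturbation being modelled.
    """
    if isinstance(material, str):
        material = get_material(material)
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration == 0:
        return material
    if material.density <= 0:
        raise ValueError(f"cannot dope {material.name!r} (zero density)")
    w_au = concentration * 1e-6 / material.density
    if w_au >= 1.0:
        raise ValueError(
            f"gold mass fraction {w_au:.3g} ≥ 1 at C={concentration} μg/ml"
        )
    comp = {el: w * (1.0 - w_au) for el, w in material.composition.items()}
    comp["Au"] = comp.get("Au", 0.0) + w_au
    return Material(
        f"{material.name}+Au{concentration:g}", material.density, comp
    )
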
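"""Voxel phantom construction from analytic shape primitives.

The default phantom is a geometric adult-female torso: a soft-tissue
elliptical cylinder containing seven vertebrae, a sternum, seven rib
rings, two lungs and a skewed-ellipsoid heart, with two fused
cylinder-ellipsoid breasts contoured on the anterior surface, each rotated
20° away from the sternum. A two-compartment spherical tumour (20 mm outer
/ 16 mm inner diameter) sits 20 mm anterior of the left-breast centre.
Region materials and gold-nanoparticle concentrations follow the
tumour-uptake pattern 500 (tumour wall) / 250 (tumour inner) / 25 μg/ml
(soft tissues), with zero uptake in bone.

Coordinates are right-handed and in mm: z along the body axis, y anterior,
x to the patient's left; the sagittal plane is x = 0. Voxel (i, j, k)
spans the half-open box [origin + i·spacing, origin + (i+1)·spacing).
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .materials import get_material

_KINDS = {
    "sphere",
    "spherical-shell",
    "ellipsoid",
    "elliptical-cylinder",
    "elliptical-tube",
    "fused-cylinder-ellipsoid",
}


@dataclass(frozen=True)
class ShapePrimitive:
    """One analytic solid with a label and an overlap priority.

    ``rotation_deg`` rotates the shape about ``rotation_axis`` through its
    centre; ``mirror_x`` reflects the finished shape through the sagittal
    plane x = 0 (used to build exactly mirror-symmetric organ pairs).
    Higher ``priority`` wins where shapes overlap.
    """

    kind: str
    centre: tuple[float, float, float]
    params: dict
    label: int
    priority: int
    rotation_deg: float = 0.0
    rotation_axis: str = "z"
    mirror_x: bool = False

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if not -180.0 <= self.rotation_deg <= 180.0:
            raise ValueError("rotation must be within [-180, 180] degrees")
        if self.label <= 0:
            raise ValueError("shape label must be a positive integer")
        for v in self.params.values():
            if np.any(np.asarray(v, dtype=float) < 0) and self.kind != "fused-cylinder-ellipsoid":
                raise ValueError(f"negative dimension in {self.kind} params")

    # -- geometry ---------------------------------------------------------

    def _local_coords(self, xs, ys, zs):
        """Broadcastable local coordinates (q0, q1, q2) of grid points."""
        x = -xs if self.mirror_x else xs
        px = x.reshape(-1, 1, 1) - self.centre[0]
        py = ys.reshape(1, -1, 1) - self.centre[1]
        pz = zs.reshape(1, 1, -1) - self.centre[2]
        if self.rotation_deg == 0.0:
            return px, py, pz
        t = np.deg2rad(self.rotation_deg)
        c, s = np.cos(t), np.sin(t)
        if self.rotation_axis == "z":
            return c * px + s * py, -s * px + c * py, pz
        if self.rotation_axis == "y":
            return c * px - s * pz, py, s * px + c * pz
        if self.rotation_axis == "x":
            return px, c * py + s * pz, -s * py + c * pz
        raise ValueError(f"bad rotation axis {self.rotation_axis!r}")

    def contains(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        """Inclusion mask at the tensor grid xs × ys × zs (world mm)."""
        q0, q1, q2 = self._local_coords(
            np.asarray(xs, float), np.asarray(ys, float), np.asarray(zs, float)
        )
        p = self.params
        if self.kind == "sphere":
            r2 = q0 * q0 + q1 * q1 + q2 * q2
            return r2 <= p["radius"] ** 2
        if self.kind == "spherical-shell":
            r2 = q0 * q0 + q1 * q1 + q2 * q2
            return (r2 <= p["outer_radius"] ** 2) & (r2 > p["inner_radius"] ** 2)
        if self.kind == "ellipsoid":
            a, b, c = p["semi_axes"]
            return (q0 / a) ** 2 + (q1 / b) ** 2 + (q2 / c) ** 2 <= 1.0
        if self.kind == "elliptical-cylinder":
            a, b = p["semi_axes"]
            rad = (q0 / a) ** 2 + (q1 / b) ** 2 <= 1.0
            return rad & (np.abs(q2) <= p["half_height"])
        if self.kind == "elliptical-tube":
            ao, bo = p["outer_semi_axes"]
            ai, bi = p["inner_semi_axes"]
            outer = (q0 / ao) ** 2 + (q1 / bo) ** 2 <= 1.0
            inner = (q0 / ai) ** 2 + (q1 / bi) ** 2 <= 1.0
            return outer & ~inner & (np.abs(q2) <= p["half_height"])
        if self.kind == "fused-cylinder-ellipsoid":
            # Local axis is +y: a finite cylinder for s in [s_min, s_max]
            # fused with an ellipsoidal cap centred at s = s_max.
            r, s0, s1, h = p["radius"], p["s_min"], p["s_max"], p["cap_half_length"]
            lat2 = q0 * q0 + q2 * q2
            cyl = (lat2 <= r * r) & (q1 >= s0) & (q1 <= s1)
            cap = lat2 / (r * r) + ((q1 - s1) / h) ** 2 <= 1.0
            return cyl | cap
        raise AssertionError(self.kind)

    def bounding_radius(self) -> float:
        p = self.params
        if self.kind == "sphere":
            return p["radius"]
        if self.kind == "spherical-shell":
            return p["outer_radius"]
        if self.kind == "ellipsoid":
            return max(p["semi_axes"])
        if self.kind == "elliptical-cylinder":
            return float(np.hypot(max(p["semi_axes"]), p["half_height"]))
        if self.kind == "elliptical-tube":
            return float(np.hypot(max(p["outer_semi_axes"]), p["half_height"]))
        if self.kind == "fused-cylinder-ellipsoid":
            reach = max(abs(p["s_min"]), abs(p["s_max"]) + p["cap_half_length"])
            return float(np.hypot(p["radius"], reach))
        raise AssertionError(self.kind)

    def effective_centre(self) -> tuple[float, float, float]:
        cx, cy, cz = self.centre
        return (-cx, cy, cz) if self.mirror_x else (cx, cy, cz)


@dataclass(frozen=True)
class RegionSpec:
    """Label metadata: tissue material and AuNP concentration (μg/ml)."""

    label: int
    name: str
    material: str
    concentration: float = 0.0

    def __post_init__(self):
        if self.label < 0:
            raise ValueError("label must be non-negative")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        get_material(self.material)  # validate the reference


@dataclass
class VoxelPhantom:
    """Labelled voxel grid with a region table.

    ``labels`` is a 3-D integer array; ``spacing``/``origin`` are mm.
    Every label occurring in the grid must have a :class:`RegionSpec`.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    regions: dict[int, RegionSpec] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        missing = sorted(set(np.unique(self.labels).tolist()) - set(self.regions))
        if missing:
            raise ValueError(f"labels {missing} missing from the region table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """mm³ per voxel."""
        return float(np.prod(self.spacing))

    def mask(self, labels) -> np.ndarray:
        labs = np.atleast_1d(labels)
        return np.isin(self.labels, labs)

    def label_by_name(self, name: str) -> int:
        for lab, spec in self.regions.items():
            if spec.name == name:
                return lab
        raise KeyError(f"no region named {name!r}")

    def axis_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing[i]
            for i in range(3)
        )

    def with_concentrations(self, value: float = 0.0) -> "VoxelPhantom":
        """Copy of the phantom with every region concentration replaced."""
        regions = {
            lab: replace(spec, concentration=value)
            for lab, spec in self.regions.items()
        }
        return VoxelPhantom(self.labels, self.spacing, self.origin, regions)


def voxelize(
    shapes: list[ShapePrimitive],
    spacing,
    extent,
    background_label: int = 0,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Rasterise shapes onto a voxel lattice by centre inclusion.

    Parameters
    ----------
    shapes : list of ShapePrimitive
    spacing : float or 3-sequence, mm
    extent : ((x0, x1), (y0, y1), (z0, z1)) in mm; must enclose all shapes.

    Returns
    -------
    (labels, origin)
        Integer label grid (highest-priority shape containing each voxel
        centre; ``background_label`` elsewhere) and the grid origin.
    """
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    ext = np.asarray(extent, dtype=float)
    n = np.round((ext[:, 1] - ext[:, 0]) / sp).astype(int)
    if np.any(n <= 0):
        raise ValueError("extent must span at least one voxel per axis")
    origin = ext[:, 0]
    axes = [origin[i] + (np.arange(n[i]) + 0.5) * sp[i] for i in range(3)]

    labels = np.full(tuple(n), background_label, dtype=np.int16)
    prio = np.full(tuple(n), np.iinfo(np.int32).min, dtype=np.int32)
    for shape in sorted(shapes, key=lambda s: s.priority):
        c = shape.effective_centre()
        r = shape.bounding_radius()
        sl = []
        for i in range(3):
            lo = int(np.floor((c[i] - r - origin[i]) / sp[i]))
            hi = int(np.ceil((c[i] + r - origin[i]) / sp[i]))
            sl.append(slice(max(lo, 0), min(hi + 1, n[i])))
        if any(s.start >= s.stop for s in sl):
            continue
        sub = shape.contains(axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]])
        take = sub & (shape.priority > prio[tuple(sl)])
        labels[tuple(sl)][take] = shape.label
        prio[tuple(sl)][take] = shape.priority
    return labels, tuple(float(v) for v in origin)


def region_volumes(phantom: VoxelPhantom) -> dict[int, float]:
    """Voxel-count volume (mm³) of every region in the table."""
    counts = np.bincount(
        phantom.labels.ravel().astype(np.int64),
        minlength=max(phantom.regions) + 1,
    )
    return {
        lab: float(counts[lab] * phantom.voxel_volume) if lab < counts.size else 0.0
        for lab in phantom.regions
    }


# -- default phantom ------------------------------------------------------

#: Region table matching the phantom component list: nine tissue
#: components plus the air background.
DEFAULT_REGIONS: dict[int, RegionSpec] = {
    0: RegionSpec(0, "background", "air", 0.0),
    1: RegionSpec(1, "torso_bulk", "soft_tissue", 25.0),
    2: RegionSpec(2, "spine", "compact_bone", 0.0),
    3: RegionSpec(3, "sternum", "compact_bone", 0.0),
    4: RegionSpec(4, "ribs", "compact_bone", 0.0),
    5: RegionSpec(5, "lung_wall", "lung_tissue", 25.0),
    6: RegionSpec(6, "heart", "muscle", 25.0),
    7: RegionSpec(7, "breast", "breast_tissue", 25.0),
    8: RegionSpec(8, "tumour_inner", "breast_tissue", 250.0),
    9: RegionSpec(9, "tumour_wall", "breast_tissue", 500.0),
}

#: All lengths in mm, angles in degrees. Stated quantities (tumour
#: diameters, 20° rotations, 20 mm tumour offset, 1 mm voxels) come from
#: the study design; the remaining dimensions are plausible adult-female
#: defaults and freely overridable.
DEFAULT_CONFIG: dict = {
    "spacing_mm": 1.0,
    "extent_mm": [[-160.0, 160.0], [-100.0, 160.0], [0.0, 220.0]],
    "torso": {"semi_axes": [150.0, 90.0], "centre_z": 110.0, "half_height": 100.0},
    "spine": {
        "radius": 14.0,
        "centre_y": -65.0,
        "n_vertebrae": 7,
        "vertebra_height": 18.0,
        "gap": 4.0,
        "centre_z": 110.0,
    },
    "sternum": {"semi_axes": [14.0, 7.0], "centre": [0.0, 78.0, 128.0], "half_height": 42.0},
    "ribs": {
        "outer_semi_axes": [146.0, 86.0],
        "thickness": 10.0,
        "half_height": 4.0,
        "top_z": 150.0,
        "spacing_z": 15.0,
        "count": 7,
    },
    "lungs": {"semi_axes": [46.0, 58.0, 78.0], "centre": [68.0, -4.0, 118.0]},
    "heart": {"semi_axes": [44.0, 36.0, 42.0], "centre": [14.0, 14.0, 92.0], "skew_deg": 30.0},
    "breast": {
        "radius": 55.0,
        "s_min": -5.0,
        "s_max": 20.0,
        "cap_half_length": 38.0,
        "angle_deg": 20.0,
        "centre_radial": 85.0,
        "centre_z": 120.0,
    },
    "tumour": {"outer_diameter": 20.0, "inner_diameter": 16.0, "offset": 20.0},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def breast_axis(config: dict | None = None) -> np.ndarray:
    """Unit axis of the left breast (and of the treatment beam)."""
    cfg = _merge(DEFAULT_CONFIG, config)
    t = np.deg2rad(cfg["breast"]["angle_deg"])
    return np.array([np.sin(t), np.cos(t), 0.0])


def tumour_centre(config: dict | None = None) -> np.ndarray:
    cfg = _merge(DEFAULT_CONFIG, config)
    b = cfg["breast"]
    u = breast_axis(cfg)
    centre = u * b["centre_radial"]
    centre[2] = b["centre_z"]
    return centre + u * cfg["tumour"]["offset"]


def default_shapes(config: dict | None = None) -> list[ShapePrimitive]:
    """The shape list of the default phantom (priority-ordered overlap)."""
    cfg = _merge(DEFAULT_CONFIG, config)
    shapes: list[ShapePrimitive] = []

    t = cfg["torso"]
    shapes.append(
        ShapePrimitive(
            "elliptical-cylinder",
            (0.0, 0.0, t["centre_z"]),
            {"semi_axes": tuple(t["semi_axes"]), "half_height": t["half_height"]},
            label=1,
            priority=1,
        )
    )

    r = cfg["ribs"]
    inner = (r["outer_semi_axes"][0] - r["thickness"], r["outer_semi_axes"][1] - r["thickness"])
    for i in range(r["count"]):
        shapes.append(
            ShapePrimitive(
                "elliptical-tube",
                (0.0, 0.0, r["top_z"] - i * r["spacing_z"]),
                {
                    "outer_semi_axes": tuple(r["outer_semi_axes"]),
                    "inner_semi_axes": inner,
                    "half_height": r["half_height"],
                },
                label=4,
                priority=2,
            )
        )

    s = cfg["spine"]
    n = s["n_vertebrae"]
    span = n * s["vertebra_height"] + (n - 1) * s["gap"]
    z0 = s["centre_z"] - span / 2 + s["vertebra_height"] / 2
    for i in range(n):
        shapes.append(
            ShapePrimitive(
                "elliptical-cylinder",
                (0.0, s["centre_y"], z0 + i * (s["vertebra_height"] + s["gap"])),
                {
                    "semi_axes": (s["radius"], s["radius"]),
                    "half_height": s["vertebra_height"] / 2,
                },
                label=2,
                priority=3,
            )
        )

    st = cfg["sternum"]
    shapes.append(
        ShapePrimitive(
            "elliptical-cylinder",
            tuple(st["centre"]),
            {"semi_axes": tuple(st["semi_axes"]), "half_height": st["half_height"]},
            label=3,
            priority=3,
        )
    )

    h = cfg["heart"]
    shapes.append(
        ShapePrimitive(
            "ellipsoid",
            tuple(h["centre"]),
            {"semi_axes": tuple(h["semi_axes"])},
            label=6,
            priority=4,
            rotation_deg=h["skew_deg"],
        )
    )

    lg = cfg["lungs"]
    left_lung = ShapePrimitive(
        "ellipsoid",
        tuple(lg["centre"]),
        {"semi_axes": tuple(lg["semi_axes"])},
        label=5,
        priority=5,
    )
    shapes.append(left_lung)
    shapes.append(replace(left_lung, mirror_x=True))

    b = cfg["breast"]
    u = breast_axis(cfg)
    bc = u * b["centre_radial"]
    left_breast = ShapePrimitive(
        "fused-cylinder-ellipsoid",
        (bc[0], bc[1], b["centre_z"]),
        {
            "radius": b["radius"],
            "s_min": b["s_min"],
            "s_max": b["s_max"],
            "cap_half_length": b["cap_half_length"],
        },
        label=7,
        priority=6,
        rotation_deg=-b["angle_deg"],
    )
    shapes.append(left_breast)
    shapes.append(replace(left_breast, mirror_x=True))

    tu = cfg["tumour"]
    tc = tumour_centre(cfg)
    shapes.append(
        ShapePrimitive(
            "spherical-shell",
            tuple(tc),
            {
                "outer_radius": tu["outer_diameter"] / 2,
                "inner_radius": tu["inner_diameter"] / 2,
            },
            label=9,
            priority=7,
        )
    )
    shapes.append(
        ShapePrimitive(
            "sphere",
            tuple(tc),
            {"radius": tu["inner_diameter"] / 2},
            label=8,
            priority=8,
        )
    )
    return shapes


def build_default_phantom(config: dict | None = None) -> VoxelPhantom:
    """Voxelise the default phantom at the configured spacing.

    Raises
    ------
    ValueError
        If the two-compartment tumour is not fully contained in the left
        breast at the configured geometry.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    shapes = default_shapes(cfg)
    labels, origin = voxelize(shapes, cfg["spacing_mm"], cfg["extent_mm"])
    phantom = VoxelPhantom(labels, (cfg["spacing_mm"],) * 3, origin, dict(DEFAULT_REGIONS))

    breast = next(s for s in shapes if s.label == 7 and not s.mirror_x)
    tmask = phantom.mask([8, 9])
    if tmask.any():
        xs, ys, zs = phantom.axis_centres()
        inside = breast.contains(xs, ys, zs)
        if not np.all(inside[tmask]):
            raise ValueError("tumour is not fully inside the left breast")
    return phantom


# -- I/O ------------------------------------------------------------------

def _affine(phantom: VoxelPhantom) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(phantom.spacing)
    aff[:3, 3] = phantom.origin
    return aff


def export_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write the label grid as NIfTI plus a ``.regions.json`` sidecar."""
    path = Path(path)
    nib.save(
        nib.Nifti1Image(phantom.labels.astype(np.int16), _affine(phantom)), path
    )
    sidecar = {
        "spacing_mm": list(phantom.spacing),
        "origin_mm": list(phantom.origin),
        "regions": [
            {
                "label": s.label,
                "name": s.name,
                "material": s.material,
                "concentration_ug_per_ml": s.concentration,
            }
            for s in phantom.regions.values()
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".regions.json")
    return path.with_suffix(".regions.json")


def import_phantom(path: str | Path) -> VoxelPhantom:
    """Load a phantom written by :func:`export_phantom`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing region sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.int16)
    regions = {
        int(r["label"]): RegionSpec(
            int(r["label"]), r["name"], r["material"], float(r["concentration_ug_per_ml"])
        )
        for r in meta["regions"]
    }
    return VoxelPhantom(
        labels,
        tuple(meta["spacing_mm"]),
        tuple(meta["origin_mm"]),
        regions,
    )
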
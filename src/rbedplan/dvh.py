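"""Cumulative dose/RBED-volume histograms, region statistics, profiles.

A cumulative DVH reports, for each dose level d, the fraction of a
region's volume receiving at least d; the same machinery applied to an
RBED grid yields an RBED-volume histogram (RVH).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import VoxelPhantom


@dataclass(frozen=True)
class RegionHistogram:
    """Cumulative volume histogram of one labelled region.

    ``cumulative_volume_pct[i]`` is the percentage of the region's volume
    with value ≥ ``bin_edges[i]``; the curve is non-increasing and starts
    at 100% at 0 Gy.
    """

    label: int
    bin_edges: np.ndarray
    cumulative_volume_pct: np.ndarray
    min: float
    mean: float
    max: float

    def volume_fraction_at(self, dose: float) -> float:
        """V(d): % of region volume receiving at least ``dose`` Gy."""
        i = np.searchsorted(self.bin_edges, dose, side="right") - 1
        i = int(np.clip(i, 0, self.bin_edges.size - 1))
        return float(self.cumulative_volume_pct[i])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bin_edge_Gy", "volume_pct"])
            for e, v in zip(self.bin_edges, self.cumulative_volume_pct):
                w.writerow([f"{e:.6g}", f"{v:.8g}"])


@dataclass(frozen=True)
class AxisProfile:
    """Values sampled along a straight line through the grid."""

    positions_mm: np.ndarray
    values: np.ndarray
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self):
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("profile positions must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["position_mm", "value_Gy"])
            for p, v in zip(self.positions_mm, self.values):
                w.writerow([f"{p:.6g}", f"{v:.8g}"])


def region_stats(grid: np.ndarray, phantom: VoxelPhantom, labels) -> tuple[float, float, float]:
    """(min, mean, max) of a grid over one region (or a label union)."""
    mask = phantom.mask(labels)
    if not mask.any():
        raise ValueError(f"region {labels!r} is empty")
    vals = np.asarray(grid, dtype=float)[mask]
    return float(vals.min()), float(vals.mean()), float(vals.max())


def cumulative_histogram(
    grid: np.ndarray,
    phantom: VoxelPhantom,
    labels,
    bin_width_gy: float = 0.01,
) -> RegionHistogram:
    """Cumulative volume histogram V(d) of a region at fixed bin width."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    mask = phantom.mask(labels)
    if not mask.any():
        raise ValueError(f"region {labels!r} is empty")
    vals = np.asarray(grid, dtype=float)[mask]
    vmin, vmean, vmax = float(vals.min()), float(vals.mean()), float(vals.max())
    n_bins = int(np.ceil(vmax / bin_width_gy)) + 1
    if n_bins > 10_000_000:
        raise ValueError(
            f"{n_bins} bins for range [0, {vmax:g}] Gy at width {bin_width_gy} Gy; "
            "increase the bin width"
        )
    edges = np.arange(n_bins + 1) * bin_width_gy
    # V(edge) = fraction of voxels with value >= edge.
    counts, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    above = np.cumsum(counts[::-1])[::-1]
    pct = 100.0 * above / vals.size
    lab = int(np.atleast_1d(labels)[0])
    return RegionHistogram(lab, edges, pct, vmin, vmean, vmax)


def line_profile(
    grid: np.ndarray,
    phantom: VoxelPhantom,
    point_mm,
    direction,
    step_mm: float = 0.5,
    half_length_mm: float | None = None,
) -> AxisProfile:
    """Trilinear profile along ``point + t·direction``, t in mm.

    Samples are restricted to the part of the line inside the grid;
    positions are signed distances from ``point_mm``.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate direction vector")
    d = d / norm
    p0 = np.asarray(point_mm, dtype=float)
    sp = np.asarray(phantom.spacing, dtype=float)
    origin = np.asarray(phantom.origin, dtype=float)
    hi = origin + np.asarray(phantom.shape) * sp

    if half_length_mm is None:
        half_length_mm = float(np.linalg.norm(hi - origin))
    ts = np.arange(-half_length_mm, half_length_mm + step_mm / 2, step_mm)
    pts = p0 + ts[:, None] * d
    ok = np.all((pts >= origin) & (pts <= hi - 1e-9), axis=1)
    if not ok.any():
        raise ValueError("line does not intersect the grid")
    ts, pts = ts[ok], pts[ok]
    coords = ((pts - origin) / sp - 0.5).T  # voxel-centre index space
    vals = ndimage.map_coordinates(
        np.asarray(grid, dtype=float), coords, order=1, mode="nearest"
    )
    return AxisProfile(ts, vals, tuple(p0), tuple(d))


def region_stats_table(
    grid: np.ndarray, phantom: VoxelPhantom, unions: dict[str, list[int]] | None = None
) -> dict[str, dict[str, float]]:
    """Named min/mean/max for every region (plus optional label unions)."""
    out = {}
    for lab, spec in phantom.regions.items():
        if not (phantom.labels == lab).any():
            continue
        mn, me, mx = region_stats(grid, phantom, lab)
        out[spec.name] = {"min": mn, "mean": me, "max": mx}
    for name, labs in (unions or {}).items():
        if phantom.mask(labs).any():
            mn, me, mx = region_stats(grid, phantom, labs)
            out[name] = {"min": mn, "mean": me, "max": mx}
    return out
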
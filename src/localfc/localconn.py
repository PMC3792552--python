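"""Local functional connectivity statistics: regional homogeneity and degree.

Regional homogeneity (ReHo) scores each gray-matter voxel by Kendall's
coefficient of concordance W over the rank-transformed time series of the
voxel and its neighbors.  With K member series, n retained frames, frame
rank sums R_i and their mean Rbar::

    W = (sum_i R_i^2 - n Rbar^2) / ((1/12) K^2 (n^3 - n))

W ranges from 0 (no concordance) to 1 (identical rank orderings).  The
neighborhood is one of the standard lattice clusters — face-adjacent
(7 voxels), face+edge (19), the full 3x3x3 cube (27) — or all voxels whose
center lies strictly within a given radius.  At 3 mm isotropic the strict
6 mm sphere is exactly the 27-voxel cube and the strict 14 mm sphere has
437 members.

Connection density ("degree") counts, for each voxel, the neighbors
within a radius whose Pearson correlation with the center time series
exceeds a threshold (r > 0.25 by default).  Both maps are optionally
standardized to z-scores over the analysis mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core import Bold4D, DataError
from .motion import CensorMask

__all__ = [
    "NeighborhoodSpec",
    "KCCMap",
    "DegreeMap",
    "neighborhood_offsets",
    "kcc",
    "reho_map",
    "degree_map",
    "standardize_map",
]

NEIGHBORHOOD_KINDS = ("face7", "edge19", "cube27", "radius")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A named local neighborhood: lattice cluster or metric ball.

    ``face7``  — center + 6 face-adjacent voxels;
    ``edge19`` — face7 + 12 edge-adjacent;
    ``cube27`` — the full 3x3x3 cube;
    ``radius`` — every integer offset whose center-to-center Euclidean
    distance is strictly below ``radius_mm``.
    """

    kind: str
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in NEIGHBORHOOD_KINDS:
            raise DataError(f"unknown neighborhood kind {self.kind!r}")
        if self.kind == "radius" and (self.radius_mm is None or self.radius_mm <= 0):
            raise DataError("radius kind requires positive radius_mm")

    @classmethod
    def parse(cls, text: str) -> "NeighborhoodSpec":
        """Parse 'face7' | 'edge19' | 'cube27' | 'radius:<mm>'."""
        if text.startswith("radius:"):
            return cls("radius", float(text.split(":", 1)[1]))
        return cls(text)

    def __str__(self) -> str:
        if self.kind == "radius":
            return f"radius:{self.radius_mm:g}"
        return self.kind


def neighborhood_offsets(
    spec: NeighborhoodSpec, voxel_size_mm: float = 1.0
) -> np.ndarray:
    """Expand a neighborhood spec into integer voxel offsets (center included).

    The offset set always contains (0,0,0) and is symmetric under
    negation.  The radius kind uses strict center-to-center distance.
    """
    if voxel_size_mm <= 0:
        raise DataError("voxel_size_mm must be positive")
    if spec.kind == "radius":
        if spec.radius_mm < voxel_size_mm:
            raise DataError("radius must be at least one voxel size")
        reach = int(np.ceil(spec.radius_mm / voxel_size_mm))
        offsets = [
            (i, j, k)
            for i, j, k in itertools.product(range(-reach, reach + 1), repeat=3)
            if voxel_size_mm * np.sqrt(i * i + j * j + k * k) < spec.radius_mm
        ]
    elif spec.kind == "cube27":
        offsets = list(itertools.product((-1, 0, 1), repeat=3))
    else:
        offsets = [(0, 0, 0)]
        offsets += [
            off
            for off in itertools.product((-1, 0, 1), repeat=3)
            if sum(o != 0 for o in off) == 1
        ]
        if spec.kind == "edge19":
            offsets += [
                off
                for off in itertools.product((-1, 0, 1), repeat=3)
                if sum(o != 0 for o in off) == 2
            ]
    return np.array(sorted(offsets), dtype=int)


def kcc(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K series over n frames.

    Each row is rank-transformed over time (midranks for ties); rows with
    zero variance are excluded (K is decremented).  Returns NaN when
    fewer than 2 usable series remain.
    """
    series = np.atleast_2d(np.asarray(series_set, dtype=float))
    if series.shape[0] < 2:
        raise DataError("KCC requires at least 2 series")
    n = series.shape[1]
    if n < 3:
        raise DataError("KCC requires at least 3 frames")
    usable = np.ptp(series, axis=1) > 0
    series = series[usable]
    k = series.shape[0]
    if k < 2:
        return float("nan")
    ranks = stats.rankdata(series, axis=1)
    r_i = ranks.sum(axis=0)
    rbar = r_i.mean()
    numerator = (r_i**2).sum() - n * rbar**2
    return float(numerator / (k**2 * (n**3 - n) / 12.0))


@dataclass
class KCCMap:
    """Per-voxel W map with the effective cluster size actually used."""

    w: np.ndarray  # 3D, NaN where undefined / out of mask
    k_eff: np.ndarray  # 3D int, member series count per voxel
    n_frames: int
    spec: NeighborhoodSpec
    standardized: bool = False

    def replace_values(self, values: np.ndarray) -> "KCCMap":
        return replace(self, w=values, standardized=True)

    @property
    def values(self) -> np.ndarray:
        return self.w


@dataclass
class DegreeMap:
    """Per-voxel neighbor count above the correlation threshold."""

    degree: np.ndarray  # 3D float (int values; NaN where undefined)
    radius_mm: float
    r_threshold: float
    n_frames: int
    standardized: bool = False

    def replace_values(self, values: np.ndarray) -> "DegreeMap":
        return replace(self, degree=values, standardized=True)

    @property
    def values(self) -> np.ndarray:
        return self.degree


def _shifted(arr: np.ndarray, off, fill=0) -> np.ndarray:
    """arr sampled at position + off, zero-filled at the grid boundary.

    ``out[p] = arr[p + off]`` wherever ``p + off`` is on the grid.
    """
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for o, dim in zip(off, arr.shape[:3]):
        if o >= 0:
            src.append(slice(o, dim))
            dst.append(slice(0, dim - o))
        else:
            src.append(slice(0, dim + o))
            dst.append(slice(-o, dim))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _retained_data(bold: Bold4D, censor: CensorMask | None) -> np.ndarray:
    if censor is None:
        return np.asarray(bold.data, dtype=float)
    if censor.n_frames != bold.n_frames:
        raise DataError("censor mask length must equal BOLD frame count")
    return np.asarray(bold.data[..., censor.keep], dtype=float)


def reho_map(
    bold: Bold4D,
    mask: np.ndarray,
    spec: NeighborhoodSpec,
    censor: CensorMask | None = None,
) -> KCCMap:
    """Voxelwise Kendall's W over the given neighborhood, within a mask.

    Neighborhoods are clipped at the mask boundary and the effective
    member count K is recorded per voxel.  Member series with zero
    variance are dropped from their clusters; centers left with K < 2
    are undefined (NaN).  The temporal rank transform is computed once
    per voxel and reused by every neighborhood containing it, so the
    whole-map cost is one ranking pass plus one accumulation per offset.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_dims:
        raise DataError("mask shape must match BOLD grid")
    if not mask.any():
        raise DataError("empty analysis mask")
    data = _retained_data(bold, censor)
    n = data.shape[-1]
    if n < 3:
        raise DataError("need at least 3 retained frames")

    valid = mask & (np.ptp(data, axis=-1) > 0)
    ranks = np.zeros_like(data)
    ranks[valid] = stats.rankdata(data[valid], axis=-1)

    offsets = neighborhood_offsets(spec, bold.voxel_size_mm)
    rank_sum = np.zeros(data.shape, dtype=float)
    k_eff = np.zeros(mask.shape, dtype=np.int32)
    for off in offsets:
        rank_sum += _shifted(ranks, off)
        k_eff += _shifted(valid.astype(np.int32), off)

    w = np.full(mask.shape, np.nan)
    centers = mask & (k_eff >= 2)
    k = k_eff[centers].astype(float)
    # each series' ranks sum to n(n+1)/2, so Rbar = K (n+1) / 2 exactly
    rbar = k * (n + 1) / 2.0
    sum_sq = (rank_sum[centers] ** 2).sum(axis=-1)
    w[centers] = (sum_sq - n * rbar**2) / (k**2 * (n**3 - n) / 12.0)
    k_eff[~mask] = 0
    return KCCMap(w=w, k_eff=k_eff, n_frames=n, spec=spec)


def degree_map(
    bold: Bold4D,
    mask: np.ndarray,
    radius_mm: float,
    r_threshold: float = 0.25,
    censor: CensorMask | None = None,
) -> DegreeMap:
    """Voxelwise connection density within a strict metric radius.

    Counts in-mask neighbors (center excluded) whose Pearson correlation
    with the center series, over retained frames, strictly exceeds
    ``r_threshold``.  Zero-variance centers are undefined (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_dims:
        raise DataError("mask shape must match BOLD grid")
    if not mask.any():
        raise DataError("empty analysis mask")
    data = _retained_data(bold, censor)
    n = data.shape[-1]
    if n < 3:
        raise DataError("need at least 3 retained frames")

    valid = mask & (np.ptp(data, axis=-1) > 0)
    z = np.zeros_like(data)
    mean = data[valid].mean(axis=-1, keepdims=True)
    sd = data[valid].std(axis=-1, keepdims=True)
    z[valid] = (data[valid] - mean) / sd

    spec = NeighborhoodSpec("radius", radius_mm)
    offsets = neighborhood_offsets(spec, bold.voxel_size_mm)
    degree = np.zeros(mask.shape, dtype=np.int32)
    for off in offsets:
        if not np.any(off):
            continue  # "neighboring voxels": center excluded
        zn = _shifted(z, off)
        vn = _shifted(valid.astype(bool), off, fill=False)
        r = (z * zn).sum(axis=-1) / n
        degree += (r > r_threshold) & valid & vn

    out = np.asarray(degree, dtype=float)
    out[~mask] = np.nan
    out[mask & ~valid] = np.nan
    return DegreeMap(degree=out, radius_mm=radius_mm, r_threshold=r_threshold, n_frames=n)


def standardize_map(map_or_values, mask: np.ndarray):
    """Convert a voxel map to z-scores over the analysis mask.

    z = (value - in-mask mean) / in-mask SD, with the population-SD
    convention (ddof=0).  Undefined in-mask voxels (NaN) are ignored in
    the moments and stay NaN; out-of-mask voxels stay NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    values = map_or_values.values if hasattr(map_or_values, "values") else map_or_values
    values = np.asarray(values, dtype=float)
    if values.shape != mask.shape:
        raise DataError("map and mask shapes differ")
    defined = mask & np.isfinite(values)
    if defined.sum() < 2:
        raise DataError("need at least 2 defined in-mask voxels")
    mean = values[defined].mean()
    sd = values[defined].std()
    if sd == 0:
        raise DataError("cannot standardize a map constant over the mask")
    z = np.full(values.shape, np.nan)
    z[defined] = (values[defined] - mean) / sd
    if hasattr(map_or_values, "replace_values"):
        return map_or_values.replace_values(z)
    return z
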
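"""Head-motion quantification and frame censoring ("scrubbing").

Framewise displacement is the Euclidean norm of the change in the six
rigid-body realignment parameters between consecutive frames, with the
three rotations converted from degrees to millimetres of arc on a sphere
of configurable radius (default 50 mm, the usual head-radius convention).

Censoring applies three rules in sequence:

1. every step whose displacement exceeds the threshold censors the frame
   before the movement, the frame of the movement, and the following frame;
2. if two censored frames are separated by no more than ``merge_gap``
   retained frames, the run between them is censored as well;
3. subjects retaining fewer than ``min_retention`` of their frames are
   excluded from analysis (exactly the retention boundary is kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataError, load_motion

__all__ = [
    "CensorMask",
    "framewise_displacement",
    "censor",
    "exclusion_rule",
    "rmsd",
    "select_low_motion",
]

DEFAULT_ROT_RADIUS_MM = 50.0


@dataclass
class CensorMask:
    """Per-frame keep/censor vector (``True`` = retained)."""

    keep: np.ndarray
    threshold_mm: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def retention(self) -> float:
        return self.n_retained / self.n_frames

    @classmethod
    def all_retained(cls, n_frames: int) -> "CensorMask":
        return cls(np.ones(n_frames, dtype=bool), threshold_mm=np.inf)


def framewise_displacement(
    trace: np.ndarray, rot_radius_mm: float = DEFAULT_ROT_RADIUS_MM
) -> np.ndarray:
    """Euclidean displacement between consecutive frames.

    Parameters
    ----------
    trace : ndarray, shape (n_frames, 6)
        tx, ty, tz in mm; rx, ry, rz in degrees.
    rot_radius_mm : float
        Sphere radius used to convert rotation differences to mm of arc.

    Returns
    -------
    ndarray, shape (n_frames - 1,)
        ``out[j]`` is the displacement of the step between frames ``j``
        and ``j + 1``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise DataError("motion trace must have shape (n_frames, 6)")
    if trace.shape[0] < 2:
        raise DataError("need at least 2 frames to compute displacement")
    if not np.all(np.isfinite(trace)):
        raise DataError("motion trace contains non-finite values")
    d = np.diff(trace, axis=0)
    d[:, 3:] = np.deg2rad(d[:, 3:]) * rot_radius_mm
    return np.sqrt((d**2).sum(axis=1))


def censor(
    displacement: np.ndarray,
    threshold_mm: float,
    pad: int = 1,
    merge_gap: int = 10,
) -> CensorMask:
    """Apply the displacement threshold, padding and gap-merge rules.

    A step between frames ``j`` and ``j + 1`` exceeding the threshold
    censors frames ``j`` (preceding), ``j + 1`` (the movement) and
    ``j + 2`` (subsequent), clipped at the run bounds; ``pad`` widens the
    censored window symmetrically beyond that default of 1.  After
    padding, any two censored frames with at most ``merge_gap`` retained
    frames between them have the whole run between them censored.
    """
    displacement = np.asarray(displacement, dtype=float)
    if threshold_mm <= 0:
        raise DataError("threshold_mm must be positive")
    n = displacement.size + 1
    censored = np.zeros(n, dtype=bool)
    for j in np.nonzero(displacement > threshold_mm)[0]:
        lo = max(j + 1 - pad, 0)
        hi = min(j + 1 + pad, n - 1)
        censored[lo : hi + 1] = True

    censored = fill_gaps(censored, merge_gap)
    return CensorMask(~censored, threshold_mm=threshold_mm)


def fill_gaps(censored: np.ndarray, merge_gap: int) -> np.ndarray:
    """Censor any run of <= ``merge_gap`` retained frames between two
    censored frames.  Idempotent."""
    censored = np.asarray(censored, dtype=bool).copy()
    idx = np.nonzero(censored)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= merge_gap + 1:
            censored[a:b] = True
    return censored


def exclusion_rule(mask: CensorMask, min_retention: float = 0.8) -> bool:
    """Return ``True`` when the subject must be excluded.

    Exclusion is strict: retention exactly at the boundary is kept
    ("fewer than 80% of time points remaining" excludes).
    """
    return mask.retention < min_retention


def rmsd(displacement: np.ndarray) -> float:
    """Root-mean-square of per-step displacement (subject motion summary)."""
    displacement = np.asarray(displacement, dtype=float)
    if displacement.size == 0:
        raise DataError("rmsd of an empty displacement vector is undefined")
    return float(np.sqrt(np.mean(displacement**2)))


def motion_qc(
    trace: np.ndarray,
    threshold_mm: float,
    min_retention: float = 0.8,
    rot_radius_mm: float = DEFAULT_ROT_RADIUS_MM,
    pad: int = 1,
    merge_gap: int = 10,
) -> tuple[CensorMask, float, bool]:
    """Convenience: displacement -> censor mask, RMSD, exclusion decision.

    RMSD is computed on all steps, before censoring (configurable only by
    computing it separately on the retained steps).
    """
    disp = framewise_displacement(trace, rot_radius_mm=rot_radius_mm)
    mask = censor(disp, threshold_mm, pad=pad, merge_gap=merge_gap)
    return mask, rmsd(disp), exclusion_rule(mask, min_retention)


def select_low_motion(
    manifest: pd.DataFrame,
    root=None,
    strict_threshold_mm: float = 0.25,
    min_retention: float = 0.8,
    rot_radius_mm: float = DEFAULT_ROT_RADIUS_MM,
    n_discard: int = 0,
) -> pd.DataFrame:
    """Re-censor every subject at a conservative threshold and subsample.

    Parameters
    ----------
    manifest : DataFrame
        Cohort manifest with columns ``subject_id``, ``group`` and
        ``motion`` (path to the 6-column trace file, relative to *root*).
    root : path-like, optional
        Directory the manifest paths are relative to.
    n_discard : int
        Leading frames to drop from each trace before QC (to match the
        analysis frames of the BOLD run).

    Returns
    -------
    DataFrame
        One row per subject: subject_id, group, retention, rmsd, excluded.
        The low-motion subsample is the subset with ``~excluded``.
    """
    rows = []
    for rec in manifest.itertuples(index=False):
        path = Path(root) / rec.motion if root is not None else Path(rec.motion)
        if not path.exists():
            raise DataError(f"missing motion trace: {path}")
        trace = load_motion(path)[n_discard:]
        mask, subj_rmsd, excluded = motion_qc(
            trace,
            strict_threshold_mm,
            min_retention=min_retention,
            rot_radius_mm=rot_radius_mm,
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "retention": mask.retention,
                "rmsd": subj_rmsd,
                "excluded": excluded,
            }
        )
    columns = ["subject_id", "group", "retention", "rmsd", "excluded"]
    return pd.DataFrame(rows, columns=columns)
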
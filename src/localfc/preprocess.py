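"""Temporal filtering, nuisance regression and spatial-smoothness control.

The temporal pipeline isolates spontaneous low-frequency BOLD fluctuations
with a zero-phase second-order Butterworth band-pass (0.008-0.08 Hz by
default) and removes structured noise by voxelwise ordinary least squares
against 16 nuisance regressors (six rigid-body motion parameters, their
backward-difference derivatives, mean white-matter and ventricle signals
and their derivatives; optional global signal + derivative brings the
count to 18).  An intercept and a linear scanner-drift term are always in
the model but are not counted among the nuisance regressors.

Spatial smoothness is measured with the classical gradient-variance
estimator and, when a common smoothness across datasets is wanted,
equalized by iteratively applying small in-mask Gaussian increments until
the estimate reaches the target FWHM ("blur to FWHM").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import Bold4D, DataError
from .motion import CensorMask

__all__ = [
    "FilterSpec",
    "NuisanceDesign",
    "bandpass",
    "bandpass_array",
    "build_nuisance",
    "regress_nuisance",
    "extract_tissue_series",
    "estimate_fwhm",
    "blur_to_fwhm",
    "FwhmEstimate",
    "SmoothResult",
]

FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))  # 2.3548...


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (zero-phase application)."""

    low_hz: float = 0.008
    high_hz: float = 0.08
    order: int = 2

    def validate(self, tr_s: float) -> None:
        nyquist = 0.5 / tr_s
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise DataError(
                f"band ({self.low_hz}, {self.high_hz}) Hz invalid for "
                f"Nyquist {nyquist:.4f} Hz"
            )

    def sos(self, tr_s: float) -> np.ndarray:
        self.validate(tr_s)
        return signal.butter(
            self.order,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=1.0 / tr_s,
            output="sos",
        )


def bandpass_array(ts: np.ndarray, spec: FilterSpec, tr_s: float, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass along *axis*; the mean is removed first so a
    constant series maps exactly to zero."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[axis] < 20:
        raise DataError("need at least 20 frames to band-pass filter")
    if not np.all(np.isfinite(ts)):
        raise DataError("cannot filter non-finite data")
    sos = spec.sos(tr_s)
    demeaned = ts - ts.mean(axis=axis, keepdims=True)
    return signal.sosfiltfilt(sos, demeaned, axis=axis)


def bandpass(bold: Bold4D, spec: FilterSpec = FilterSpec()) -> Bold4D:
    """Band-pass every voxel time series of a 4D BOLD run."""
    return bold.copy_with(bandpass_array(bold.data, spec, bold.tr_s, axis=-1))


# ---------------------------------------------------------------------------
# Nuisance model
# ---------------------------------------------------------------------------

MOTION_LABELS = ("mot_tx", "mot_ty", "mot_tz", "mot_rx", "mot_ry", "mot_rz")


def backward_difference(x: np.ndarray) -> np.ndarray:
    """Backward difference along the first axis, leading element 0."""
    d = np.zeros_like(np.asarray(x, dtype=float))
    d[1:] = np.diff(np.asarray(x, dtype=float), axis=0)
    return d


@dataclass
class NuisanceDesign:
    """Labeled nuisance-regressor matrix (intercept/trend tracked apart).

    ``matrix`` holds only the labeled nuisance columns; the intercept and
    linear-trend columns are appended by :func:`regress_nuisance` and are
    deliberately not counted among the regressors.
    """

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.labels):
            raise DataError("label count must match column count")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def drop_null_columns(self) -> "NuisanceDesign":
        """Remove identically-zero columns (e.g. derivatives of a constant
        motion trace), which would otherwise make the model rank deficient."""
        nonzero = np.ptp(self.matrix, axis=0) > 0
        return NuisanceDesign(
            self.matrix[:, nonzero],
            [lab for lab, keep in zip(self.labels, nonzero) if keep],
        )


def build_nuisance(
    motion: np.ndarray,
    wm_ts: np.ndarray,
    vent_ts: np.ndarray,
    gsr: bool = False,
    global_ts: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
    tr_s: float | None = None,
) -> NuisanceDesign:
    """Assemble the standard nuisance model.

    Without GSR: 6 motion + 6 motion derivatives + white matter +
    ventricle + their 2 derivatives = 16 columns.  With ``gsr=True`` the
    global signal and its derivative are appended (18).  When a
    ``filter_spec`` (and ``tr_s``) is given, every column is band-passed
    with the same filter applied to the data.
    """
    motion = np.asarray(motion, dtype=float)
    wm_ts = np.asarray(wm_ts, dtype=float).ravel()
    vent_ts = np.asarray(vent_ts, dtype=float).ravel()
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError("motion must have shape (n_frames, 6)")
    n = motion.shape[0]
    if wm_ts.size != n or vent_ts.size != n:
        raise DataError("tissue series length must match motion frame count")
    if gsr:
        if global_ts is None:
            raise DataError("gsr=True requires global_ts")
        global_ts = np.asarray(global_ts, dtype=float).ravel()
        if global_ts.size != n:
            raise DataError("global series length must match frame count")

    cols = [motion, backward_difference(motion), wm_ts[:, None], vent_ts[:, None]]
    labels = list(MOTION_LABELS)
    labels += [f"{lab}_deriv" for lab in MOTION_LABELS]
    labels += ["wm", "vent"]
    cols.append(backward_difference(wm_ts)[:, None])
    cols.append(backward_difference(vent_ts)[:, None])
    labels += ["wm_deriv", "vent_deriv"]
    if gsr:
        cols.append(global_ts[:, None])
        cols.append(backward_difference(global_ts)[:, None])
        labels += ["global", "global_deriv"]

    matrix = np.hstack(cols)
    if filter_spec is not None:
        if tr_s is None:
            raise DataError("tr_s required to filter nuisance columns")
        matrix = bandpass_array(matrix, filter_spec, tr_s, axis=0)
    return NuisanceDesign(matrix, labels)


def _full_design(design: NuisanceDesign, n: int) -> tuple[np.ndarray, list[str]]:
    intercept = np.ones(n)
    trend = np.linspace(-1.0, 1.0, n)  # scanner drift
    X = np.column_stack([intercept, trend, design.matrix])
    return X, ["intercept", "trend", *design.labels]


def regress_nuisance(
    bold: Bold4D,
    design: NuisanceDesign,
    censor: CensorMask | None = None,
    drop_null_columns: bool = True,
) -> Bold4D:
    """Voxelwise OLS removal of intercept, linear trend and nuisance columns.

    The model is fitted on retained frames only; residuals for censored
    frames are evaluated from the fitted coefficients so frame indexing
    is preserved (censored frames are excluded again downstream).

    Raises
    ------
    DataError
        If the design is rank deficient; the message names the collinear
        columns.
    """
    n = bold.n_frames
    if design.n_frames != n:
        raise DataError("design rows must equal BOLD frame count")
    if censor is None:
        censor = CensorMask.all_retained(n)
    if censor.n_frames != n:
        raise DataError("censor mask length must equal BOLD frame count")
    if drop_null_columns:
        design = design.drop_null_columns()

    X, labels = _full_design(design, n)
    keep = censor.keep
    Xk = X[keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < X.shape[1]:
        # name the offending columns via near-perfect pairwise correlation
        culprits = set()
        norms = np.linalg.norm(Xk, axis=0)
        norms[norms == 0] = 1.0
        Xn = Xk / norms
        gram = Xn.T @ Xn
        p = X.shape[1]
        for i in range(p):
            for j in range(i + 1, p):
                if abs(gram[i, j]) > 1 - 1e-10:
                    culprits.update((labels[i], labels[j]))
        detail = ", ".join(sorted(culprits)) if culprits else "unidentified columns"
        raise DataError(f"rank-deficient nuisance design (collinear: {detail})")

    Y = bold.data.reshape(-1, n).T  # (n, V)
    beta, *_ = np.linalg.lstsq(Xk, Y[keep], rcond=None)
    resid = (Y - X @ beta).T.reshape(bold.data.shape)
    return bold.copy_with(resid)


def extract_tissue_series(
    bold: Bold4D, mask: np.ndarray, erode: int = 1
) -> np.ndarray:
    """Mean time series over an (optionally eroded) tissue mask.

    Erosion removes voxels with any 6-connected neighbor outside the mask
    and is repeated ``erode`` times, trimming the mask away from tissue
    boundaries to limit partial-volume contamination.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_dims:
        raise DataError("mask shape must match BOLD grid")
    if erode > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_erosion(mask, structure=structure, iterations=erode)
    if not mask.any():
        raise DataError("tissue mask is empty after erosion")
    return bold.data[mask].mean(axis=0)


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """6-connectivity binary erosion (exposed for mask QC)."""
    if iterations <= 0:
        return np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(
        np.asarray(mask, dtype=bool), structure=structure, iterations=iterations
    )


# ---------------------------------------------------------------------------
# Spatial smoothness
# ---------------------------------------------------------------------------


@dataclass
class FwhmEstimate:
    """Per-axis and combined smoothness estimate, mm."""

    per_axis_mm: np.ndarray
    mean_mm: float  # geometric mean over axes


def _fwhm_one_volume(vol, mask, voxel_sizes):
    vals = vol[mask]
    s2 = vals.var()
    if s2 == 0:
        raise DataError("cannot estimate smoothness of a constant volume")
    out = np.zeros(3)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if pair.sum() < 2:
            raise DataError(f"too few in-mask voxel pairs along axis {ax}")
        diffs = vol[tuple(sl_a)][pair] - vol[tuple(sl_b)][pair]
        ratio = diffs.var() / (2.0 * s2)
        if ratio >= 1.0:
            out[ax] = 0.0  # rougher than white noise: unsmoothed sentinel
        else:
            out[ax] = voxel_sizes[ax] * np.sqrt(
                -2.0 * np.log(2.0) / np.log1p(-ratio)
            )
    return out


def estimate_fwhm(
    data: np.ndarray | Bold4D,
    mask: np.ndarray,
    voxel_sizes_mm=None,
) -> FwhmEstimate:
    """Gradient-variance spatial-smoothness estimator.

    Per axis, with voxel spacing ``d``, in-mask first-difference variance
    ``s2_diff`` and voxel variance ``s2``::

        FWHM = d * sqrt(-2 ln 2 / ln(1 - s2_diff / (2 s2)))

    White noise gives ``s2_diff ~= 2 s2`` and an estimate near zero; data
    rougher than white noise report a 0 mm sentinel for that axis.  4D
    input averages the per-frame estimates.
    """
    if isinstance(data, Bold4D):
        voxel_sizes_mm = data.voxel_sizes_mm
        data = data.data
    if voxel_sizes_mm is None:
        raise DataError("voxel_sizes_mm required for array input")
    voxel_sizes = np.broadcast_to(np.asarray(voxel_sizes_mm, dtype=float), (3,))
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise DataError("mask shape must match volume grid")

    if data.ndim == 3:
        per_axis = _fwhm_one_volume(data, mask, voxel_sizes)
    elif data.ndim == 4:
        per_axis = np.mean(
            [_fwhm_one_volume(data[..., t], mask, voxel_sizes) for t in range(data.shape[3])],
            axis=0,
        )
    else:
        raise DataError("expected a 3D map or 4D run")
    mean = float(np.exp(np.log(np.maximum(per_axis, 1e-12)).mean()))
    if np.any(per_axis <= 1e-12):
        mean = 0.0
    return FwhmEstimate(per_axis, mean)


def masked_gaussian_smooth(
    data: np.ndarray, mask: np.ndarray, sigma_vox: float
) -> np.ndarray:
    """Normalized in-mask Gaussian smoothing (no bleed across the mask
    boundary); out-of-mask voxels pass through unchanged."""
    mask = np.asarray(mask, dtype=bool)
    m = mask.astype(float)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = np.array(data, dtype=float, copy=True)
    if data.ndim == 3:
        num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma_vox)
        out[mask] = num[mask] / den[mask]
    else:
        for t in range(data.shape[3]):
            num = ndimage.gaussian_filter(np.where(mask, data[..., t], 0.0), sigma_vox)
            out[..., t][mask] = num[mask] / den[mask]
    return out


@dataclass
class SmoothResult:
    data: np.ndarray
    achieved_fwhm_mm: float
    iterations: int
    no_op: bool = False  # input was already at/above the target


def blur_to_fwhm(
    data: np.ndarray | Bold4D,
    target_mm: float,
    mask: np.ndarray,
    voxel_sizes_mm=None,
    tol: float = 0.05,
    max_iter: int = 150,
    gain: float = 0.7,
) -> SmoothResult:
    """Iteratively smooth until the estimated FWHM reaches ``target_mm``.

    Each pass applies an in-mask Gaussian increment whose width is a
    fraction (``gain``) of the remaining quadrature deficit
    ``sqrt(target^2 - current^2)``, so smoothness increases monotonically
    and converges from below without overshooting the tolerance band.
    Input already smoother than the target is returned unchanged with
    ``no_op=True``.
    """
    is_bold = isinstance(data, Bold4D)
    if is_bold:
        voxel_sizes_mm = data.voxel_sizes_mm
        arr = np.asarray(data.data, dtype=float)
        bold = data
    else:
        arr = np.asarray(data, dtype=float)
        bold = None
    if voxel_sizes_mm is None:
        raise DataError("voxel_sizes_mm required for array input")
    voxel = float(np.mean(np.broadcast_to(np.asarray(voxel_sizes_mm, float), (3,))))
    if target_mm <= 0:
        raise DataError("target_mm must be positive")

    current = estimate_fwhm(arr, mask, voxel_sizes_mm).mean_mm
    if current >= target_mm * (1 - tol):
        no_op = current > target_mm * (1 + tol)
        result = arr
        if is_bold:
            result_obj = bold.copy_with(result)
        return SmoothResult(
            result_obj if is_bold else result, current, 0, no_op=no_op
        )

    out = arr
    # Trial steps with backtracking: discrete truncated kernels deliver
    # smoothing that tracks the nominal quadrature increment only loosely
    # (the truncation radius jumps at half-integer sigmas, and thin masks
    # can over-deliver), so each proposed increment is applied, measured,
    # and only accepted when it does not overshoot the tolerance band.
    # Accepted iterates are monotone non-decreasing in smoothness.
    lo, hi = target_mm * (1 - tol), target_mm * (1 + tol)
    for it in range(1, max_iter + 1):
        deficit_sq = target_mm**2 - current**2
        if deficit_sq <= 0:
            break
        sigma_vox = max(
            np.sqrt(gain * deficit_sq) / FWHM_PER_SIGMA / voxel, 0.3
        )
        accepted = False
        for _ in range(8):
            cand = masked_gaussian_smooth(out, mask, sigma_vox)
            new_current = estimate_fwhm(cand, mask, voxel_sizes_mm).mean_mm
            if new_current <= hi:
                out, current, accepted = cand, new_current, True
                break
            if sigma_vox <= 0.3:  # smallest effective kernel still too big
                break
            sigma_vox = max(sigma_vox / 1.6, 0.3)
        if not accepted:
            # the minimal lattice step jumps past the band; take it only
            # if it lands closer to the target than staying put would
            if abs(new_current - target_mm) < abs(current - target_mm):
                out, current = cand, new_current
            break
        if lo <= current <= hi:
            return SmoothResult(
                bold.copy_with(out) if is_bold else out, current, it
            )
    raise DataError(
        f"blur_to_fwhm did not reach {target_mm} mm within {max_iter} "
        f"iterations (achieved {current:.3f} mm)"
    )
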
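"""Synthetic two-group resting-state BOLD cohorts with planted local
connectivity structure.

The generator emulates the acquisition this pipeline targets — 185
volumes at TR 2 s (the first 5 later discarded), a 3 mm isotropic grid,
a nested set of brain/gray/white/ventricle masks, and two matched groups
— while keeping full control of the ground truth.  Background activity
is spatially autocorrelated, temporally band-limited noise; local
coherence is planted by mixing a region-shared band-limited signal into
member voxels with variance-preserving weights, so that the expected
pairwise correlation between two region voxels with independent noise
equals the coherence level exactly.  Nuisance structure (linear drift,
tissue signals, a global fluctuation) and motion (random-walk jitter
plus configurable spikes) are superimposed so the preprocessing and
scrubbing stages have real work to do.

All randomness flows from per-subject substreams derived from the design
seed, so a cohort is bit-reproducible and adding subjects does not
reshuffle existing ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Bold4D, DataError, save_mask, save_motion
from .preprocess import FWHM_PER_SIGMA, FilterSpec, bandpass_array

__all__ = [
    "EffectRegion",
    "MotionSpec",
    "NuisanceSpec",
    "SimulationDesign",
    "GroundTruth",
    "Masks",
    "Subject",
    "Cohort",
    "generate_masks",
    "generate_subject",
    "generate_cohort",
]

GROUP_LABELS = ("control", "case")


@dataclass(frozen=True)
class EffectRegion:
    """A planted local-coherence perturbation.

    The region is a sphere (fractional grid coordinates and radius)
    intersected with the gray-matter mask.  ``direction='increase'``
    plants elevated coherence in the case group, ``'decrease'`` in the
    control group (so the case group is relatively reduced).
    """

    center_frac: tuple[float, float, float]
    radius_frac: float
    direction: str
    coherence: float

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise DataError("direction must be 'increase' or 'decrease'")
        if not 0.0 <= self.coherence <= 1.0:
            raise DataError("coherence level must be in [0, 1]")


@dataclass(frozen=True)
class MotionSpec:
    """Motion-trace generation parameters.

    ``spikes`` maps subject index to explicit (frame, amplitude_mm)
    events; subjects not listed receive a Poisson(``spike_rate``) number
    of spikes with amplitudes uniform in ``spike_amp_mm``.
    """

    jitter_mm: float = 0.02
    spike_rate: float = 2.0
    spike_amp_mm: tuple[float, float] = (0.2, 1.5)
    spikes: tuple = ()  # ((subject_index, ((frame, amp_mm), ...)), ...)

    def explicit_spikes(self, subject_index: int):
        for idx, events in self.spikes:
            if idx == subject_index:
                return list(events)
        return None


@dataclass(frozen=True)
class NuisanceSpec:
    """Amplitudes (BOLD intensity units) of the planted nuisance terms."""

    drift_amp: float = 3.0
    tissue_amp: float = 2.0
    global_amp: float = 1.0


def _default_regions() -> tuple[EffectRegion, ...]:
    # ~100 gray voxels (~2700 ul at 3 mm) per region on the default grid,
    # the volume scale at which cluster-level effects are typically reported
    return (
        EffectRegion((0.875, 0.5, 0.5), 0.14, "increase", 0.5),
        EffectRegion((0.125, 0.5, 0.5), 0.14, "decrease", 0.5),
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a synthetic two-group cohort."""

    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_frames: int = 185
    tr_s: float = 2.0
    n_discard: int = 5
    group_sizes: tuple[int, int] = (29, 29)
    base_fwhm_mm: float = 6.0
    effect_regions: tuple[EffectRegion, ...] = field(default_factory=_default_regions)
    coherence_subject_sd: float = 0.1
    signal_amp: float = 5.0
    baseline: float = 1000.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    motion_spec: MotionSpec = field(default_factory=MotionSpec)
    nuisance_spec: NuisanceSpec = field(default_factory=NuisanceSpec)
    behavior_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) <= 0:
            raise DataError("group sizes must be positive")
        if not 0 <= self.n_discard < self.n_frames:
            raise DataError("n_discard must be < n_frames")
        if min(self.grid_dims) < 8:
            raise DataError("grid must be at least 8 voxels per axis")
        if not -1.0 <= self.behavior_corr <= 1.0:
            raise DataError("behavior_corr must be in [-1, 1]")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        center = (np.asarray(self.grid_dims) - 1) / 2.0
        aff[:3, 3] = -center * self.voxel_size_mm
        return aff

    def subject_seed(self, subject_index: int) -> int:
        """Stable per-subject substream seed (independent of cohort size)."""
        ss = np.random.SeedSequence([self.seed, subject_index])
        return int(ss.generate_state(1)[0])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class Masks:
    brain: np.ndarray
    gray: np.ndarray
    white: np.ndarray
    ventricle: np.ndarray


@dataclass
class GroundTruth:
    """Planted-effect label map (0 background, k for region k, 1-based)."""

    label_map: np.ndarray
    regions: tuple[EffectRegion, ...]

    def region_mask(self, k: int) -> np.ndarray:
        return self.label_map == k

    def sidecar(self) -> dict:
        return {
            "regions": [
                {
                    "label": k + 1,
                    "direction": r.direction,
                    "coherence": r.coherence,
                    "n_voxels": int((self.label_map == k + 1).sum()),
                }
                for k, r in enumerate(self.regions)
            ]
        }


@dataclass
class Subject:
    subject_id: str
    group: str
    bold: Bold4D
    motion: np.ndarray
    coherence: float  # mean planted coherence across regions, this subject


@dataclass
class Cohort:
    design: SimulationDesign
    subjects: list[Subject]
    masks: Masks
    truth: GroundTruth
    scores: pd.DataFrame  # subject_id, group, score


# ---------------------------------------------------------------------------
# Masks and ground truth
# ---------------------------------------------------------------------------


def _radius_grid(grid_dims) -> np.ndarray:
    center = (np.asarray(grid_dims) - 1) / 2.0
    coords = np.meshgrid(*[np.arange(d) for d in grid_dims], indexing="ij")
    return np.sqrt(sum((c - ctr) ** 2 for c, ctr in zip(coords, center)))


def generate_masks(design: SimulationDesign) -> Masks:
    """Concentric-shell head model: ventricle core, white shell, gray rind.

    gray is a strict subset of brain; white and ventricle are disjoint
    from gray (a gap shell separates white from gray, mimicking trimmed
    segmentation boundaries).
    """
    n = min(design.grid_dims)
    r = _radius_grid(design.grid_dims)
    brain = r <= 0.45 * n
    ventricle = r <= 0.14 * n
    white = (r > 0.14 * n) & (r <= 0.28 * n)
    gray = (r > 0.32 * n) & brain
    return Masks(brain=brain, gray=gray, white=white, ventricle=ventricle)


def region_voxel_mask(
    region: EffectRegion, design: SimulationDesign, gray: np.ndarray
) -> np.ndarray:
    """Expand a region spec to voxels (sphere intersected with gray)."""
    dims = np.asarray(design.grid_dims)
    center = region.center_frac * (dims - 1)
    if np.any(center < 0) or np.any(center > dims - 1):
        raise DataError("effect region center outside the grid")
    coords = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    dist = np.sqrt(sum((c - ctr) ** 2 for c, ctr in zip(coords, center)))
    sphere = dist <= region.radius_frac * min(dims)
    out = sphere & gray
    if not out.any():
        raise DataError("effect region does not intersect the gray mask")
    return out


def ground_truth(design: SimulationDesign, masks: Masks | None = None) -> GroundTruth:
    masks = masks or generate_masks(design)
    labels = np.zeros(design.grid_dims, dtype=np.int16)
    for k, region in enumerate(design.effect_regions, start=1):
        labels[region_voxel_mask(region, design, masks.gray)] = k
    return GroundTruth(label_map=labels, regions=tuple(design.effect_regions))


# ---------------------------------------------------------------------------
# Subject-level generation
# ---------------------------------------------------------------------------


def _band_limited(rng, shape, design) -> np.ndarray:
    """White noise band-limited to the low-frequency BOLD band, unit-ish
    variance along the last (time) axis."""
    spec = FilterSpec(design.band_hz[0], design.band_hz[1], order=2)
    x = bandpass_array(rng.standard_normal(shape), spec, design.tr_s, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _draw_coherences(design, group, rng) -> dict[int, float]:
    """Per-region planted coherence for one subject.

    The group named by the region direction gets the region's coherence
    level plus subject-level jitter; the other group gets zero.
    """
    out = {}
    for k, region in enumerate(design.effect_regions, start=1):
        affected = "case" if region.direction == "increase" else "control"
        if group == affected:
            c = region.coherence + design.coherence_subject_sd * rng.standard_normal()
            out[k] = float(np.clip(c, 0.0, 1.0))
        else:
            out[k] = 0.0
    return out


def _generate_motion(design, rng, subject_index=None) -> np.ndarray:
    spec = design.motion_spec
    n = design.n_frames
    steps = rng.normal(0.0, spec.jitter_mm, size=(n, 6))
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    explicit = (
        spec.explicit_spikes(subject_index) if subject_index is not None else None
    )
    if explicit is None:
        n_spikes = rng.poisson(spec.spike_rate)
        frames = rng.integers(1, n, size=n_spikes)
        amps = rng.uniform(*spec.spike_amp_mm, size=n_spikes)
        events = list(zip(frames, amps))
    else:
        events = explicit
    for frame, amp in events:
        if not 0 <= frame < n:
            raise DataError("motion spike frame outside the run")
        axis = rng.integers(0, 3)
        trace[int(frame), axis] += amp  # transient single-frame excursion
    return trace


def _generate_subject_arrays(design, group, subject_seed, masks, truth, subject_index=None):
    if group not in GROUP_LABELS:
        raise DataError(f"group must be one of {GROUP_LABELS}")
    rng = np.random.default_rng(subject_seed)
    coherences = _draw_coherences(design, group, rng)

    shape = tuple(design.grid_dims) + (design.n_frames,)
    bg = _band_limited(rng, shape, design)
    sigma_vox = design.base_fwhm_mm / FWHM_PER_SIGMA / design.voxel_size_mm
    if sigma_vox > 0:
        bg = ndimage.gaussian_filter(bg, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0))
    sd = bg.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    bg /= sd

    data = design.signal_amp * bg
    for k in range(1, len(design.effect_regions) + 1):
        rmask = truth.label_map == k
        c = coherences[k]
        if c == 0 or not rmask.any():
            continue
        shared = _band_limited(rng, (design.n_frames,), design)
        mix = np.sqrt(c) * shared + np.sqrt(1.0 - c) * bg[rmask]
        data[rmask] = design.signal_amp * mix

    nu = design.nuisance_spec
    n = design.n_frames
    drift = nu.drift_amp * (np.arange(n) / (n - 1) - 0.5)
    wm_sig = nu.tissue_amp * _band_limited(rng, (n,), design)
    vent_sig = nu.tissue_amp * _band_limited(rng, (n,), design)
    glob_sig = nu.global_amp * _band_limited(rng, (n,), design)
    data[masks.brain] += drift + glob_sig
    data[masks.white] += wm_sig
    data[masks.ventricle] += vent_sig
    data[masks.brain] += design.baseline

    motion = _generate_motion(design, rng, subject_index)
    bold = Bold4D(data, design.affine, design.tr_s)
    mean_coherence = float(np.mean(list(coherences.values()))) if coherences else 0.0
    return bold, motion, mean_coherence


def generate_subject(
    design: SimulationDesign, group: str, subject_seed: int
) -> tuple[Bold4D, np.ndarray]:
    """Generate one subject's BOLD run and motion trace.

    The run has the design's full (pre-discard) frame count; discarding
    the leading frames is the pipeline's job.
    """
    masks = generate_masks(design)
    truth = ground_truth(design, masks)
    bold, motion, _ = _generate_subject_arrays(design, group, subject_seed, masks, truth)
    return bold, motion


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------


def _behavior_scores(design, subjects, rng) -> pd.DataFrame:
    """Pseudo-severity scores correlated with each subject's planted
    coherence at the design's ``behavior_corr`` level (mean 10, SD 3)."""
    coh = np.array([s.coherence for s in subjects])
    sd = coh.std()
    z = (coh - coh.mean()) / sd if sd > 0 else np.zeros_like(coh)
    rho = design.behavior_corr
    noise = rng.standard_normal(len(subjects))
    latent = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "score": 10.0 + 3.0 * latent,
        }
    )


def generate_cohort(design: SimulationDesign, outdir=None) -> Cohort:
    """Generate the full two-group cohort; optionally write it to disk.

    When ``outdir`` is given the on-disk layout is::

        outdir/
          manifest.tsv                subject_id, group, bold, motion
          behavior.tsv                subject_id, group, score
          design.json
          masks/{brain,gray,white,ventricle}.nii.gz
          truth.nii.gz + truth.json
          sub-XXX/bold.nii.gz, sub-XXX/motion.txt
    """
    masks = generate_masks(design)
    truth = ground_truth(design, masks)
    subjects: list[Subject] = []
    index = 0
    for group, size in zip(GROUP_LABELS, design.group_sizes):
        for _ in range(size):
            seed = design.subject_seed(index)
            bold, motion, coh = _generate_subject_arrays(
                design, group, seed, masks, truth, subject_index=index
            )
            subjects.append(
                Subject(
                    subject_id=f"sub-{index:03d}",
                    group=group,
                    bold=bold,
                    motion=motion,
                    coherence=coh,
                )
            )
            index += 1

    score_rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, 1_000_003])
    )
    scores = _behavior_scores(design, subjects, score_rng)
    cohort = Cohort(
        design=design, subjects=subjects, masks=masks, truth=truth, scores=scores
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: Cohort, outdir) -> Path:
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create cohort directory {outdir}: {exc}") from exc
    design = cohort.design
    affine = design.affine

    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for name in ("brain", "gray", "white", "ventricle"):
        save_mask(getattr(cohort.masks, name), affine, mask_dir / f"{name}.nii.gz")
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(cohort.truth.label_map.astype(np.int16), affine),
        str(outdir / "truth.nii.gz"),
    )
    (outdir / "truth.json").write_text(json.dumps(cohort.truth.sidecar(), indent=2))
    (outdir / "design.json").write_text(design.to_json())

    rows = []
    for subj in cohort.subjects:
        sdir = outdir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        subj.bold.save(sdir / "bold.nii.gz")
        save_motion(subj.motion, sdir / "motion.txt")
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "bold": f"{subj.subject_id}/bold.nii.gz",
                "motion": f"{subj.subject_id}/motion.txt",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    cohort.scores.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    return outdir / "manifest.tsv"


def load_cohort(cohort_dir) -> Cohort:
    """Read a written cohort back into memory."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise DataError(f"no manifest.tsv in {cohort_dir}")
    design_raw = json.loads((cohort_dir / "design.json").read_text())
    design_raw["grid_dims"] = tuple(design_raw["grid_dims"])
    design_raw["group_sizes"] = tuple(design_raw["group_sizes"])
    design_raw["band_hz"] = tuple(design_raw["band_hz"])
    design_raw["effect_regions"] = tuple(
        EffectRegion(
            tuple(r["center_frac"]), r["radius_frac"], r["direction"], r["coherence"]
        )
        for r in design_raw["effect_regions"]
    )
    ms = design_raw["motion_spec"]
    design_raw["motion_spec"] = MotionSpec(
        ms["jitter_mm"],
        ms["spike_rate"],
        tuple(ms["spike_amp_mm"]),
        tuple((i, tuple(tuple(e) for e in ev)) for i, ev in ms["spikes"]),
    )
    design_raw["nuisance_spec"] = NuisanceSpec(**design_raw["nuisance_spec"])
    design = SimulationDesign(**design_raw)

    from .core import load_mask, load_motion

    masks = Masks(
        *[
            load_mask(cohort_dir / "masks" / f"{name}.nii.gz")[0]
            for name in ("brain", "gray", "white", "ventricle")
        ]
    )
    import nibabel as nib

    label_map = np.asanyarray(nib.load(str(cohort_dir / "truth.nii.gz")).dataobj)
    truth = GroundTruth(label_map=label_map.astype(np.int16), regions=design.effect_regions)

    manifest = pd.read_csv(manifest_path, sep="\t")
    scores = pd.read_csv(cohort_dir / "behavior.tsv", sep="\t")
    subjects = []
    for rec in manifest.itertuples(index=False):
        bold = Bold4D.load(cohort_dir / rec.bold, tr_s=design.tr_s)
        motion = load_motion(cohort_dir / rec.motion)
        subjects.append(
            Subject(
                subject_id=rec.subject_id,
                group=rec.group,
                bold=bold,
                motion=motion,
                coherence=float("nan"),
            )
        )
    return Cohort(design=design, subjects=subjects, masks=masks, truth=truth, scores=scores)
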
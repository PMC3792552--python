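"""Shared fixtures: synthetic cohorts processed through the full pipeline.

The two heavyweight session fixtures (a null cohort for calibration
checks and a set of planted-effect replicates) are computed once and
shared across the statistical tests that need them.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from localfc import groupstats, synthdata
from localfc.cli import DEFAULT_CONFIG, merge_config, process_subject

N_PLANTED_REPLICATES = 20


def pipeline_maps(cohort, cfg, name="reho_cube27"):
    """Run the subject-level pipeline; returns (maps, groups) for the
    subjects that survive motion exclusion."""
    maps, groups = [], []
    for subj in cohort.subjects:
        m, _, _, _, excluded = process_subject(
            subj.bold, subj.motion, cohort.masks, cfg, cohort.design.n_discard
        )
        if excluded:
            continue
        maps.append(m[name])
        groups.append(subj.group)
    return maps, groups


@pytest.fixture(scope="session")
def default_cfg():
    return merge_config(DEFAULT_CONFIG, {})


@pytest.fixture(scope="session")
def null_cohort_maps(default_cfg):
    """Standardized, smoothed ReHo27 maps for a no-effect 16^3 cohort
    of 8 + 8 subjects (180 analysis frames)."""
    design = synthdata.SimulationDesign(
        grid_dims=(16, 16, 16), group_sizes=(8, 8), effect_regions=(), seed=42
    )
    cohort = synthdata.generate_cohort(design)
    maps, groups = pipeline_maps(cohort, default_cfg)
    return SimpleNamespace(
        maps=maps, groups=groups, gray=cohort.masks.gray, design=design
    )


@pytest.fixture(scope="session")
def planted_replicates(default_cfg):
    """Group comparisons of standardized cube27 ReHo for replicate
    cohorts (8 + 8) with one planted coherence increase and one
    decrease region."""
    out = []
    for rep in range(N_PLANTED_REPLICATES):
        design = synthdata.SimulationDesign(group_sizes=(8, 8), seed=100 + rep)
        cohort = synthdata.generate_cohort(design)
        maps, groups = pipeline_maps(cohort, default_cfg)
        g1 = [m for m, g in zip(maps, groups) if g == "control"]
        g2 = [m for m, g in zip(maps, groups) if g == "case"]
        comp = groupstats.voxelwise_ttest(g1, g2, cohort.masks.gray)
        out.append(
            SimpleNamespace(
                comparison=comp,
                increase=cohort.truth.label_map == 1,
                decrease=cohort.truth.label_map == 2,
                affine=design.affine,
            )
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
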
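"""Cohort-level simulation: study-condition defaults and subject map generation.

The default ground truths encode the direction of the group effects the
analysis is built to detect: both adult groups carry stronger cross-language
pattern correlation than children in the speech-association region, control
adults carry the most stable trial-similarity structure across repetitions,
and children the least.

Two routes from ground truth to trial betas are provided. The full forward
route synthesizes 4D BOLD and estimates betas with the LSS GLM; it is exact
but costly, and is exercised by the GLM-level tests. For cohort-scale
experiments, :func:`simulate_trial_betas` draws betas directly as latent
pattern + Gaussian estimation noise, emulating the sampling distribution of
LSS estimates at a chosen beta-level signal-to-noise ratio (default 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ExperimentDesign, WORD_PHASES, generate_design
from .patterns import GroundTruth, PatternSet, generate_patterns

GROUPS = ("children", "control_adults", "singers")
REGION_NAME = "speech_assoc"

_DEFAULT_RHO_CL = {"children": 0.1, "control_adults": 0.5, "singers": 0.5}
_DEFAULT_RHO_REP = {"children": 0.3, "control_adults": 0.7, "singers": 0.55}


def default_region_mask(grid_shape=(20, 20, 20), side: int = 5) -> np.ndarray:
    """A cubic 'speech-association' region near the grid center (side**3 voxels)."""
    mask = np.zeros(grid_shape, dtype=bool)
    start = [max((s - side) // 2, 0) for s in grid_shape]
    sl = tuple(slice(a, a + side) for a in start)
    mask[sl] = True
    return mask


def default_ground_truth(
    group: str,
    grid_shape=(20, 20, 20),
    seed: int = 0,
    rho_cross_language: float | None = None,
    rho_repetition: float | None = None,
    region_mask: np.ndarray | None = None,
    **kwargs,
) -> GroundTruth:
    """Study-condition generative parameters for one subject of ``group``."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if region_mask is None:
        region_mask = default_region_mask(grid_shape)
    rho_cl = _DEFAULT_RHO_CL[group] if rho_cross_language is None else rho_cross_language
    rho_rep = _DEFAULT_RHO_REP[group] if rho_repetition is None else rho_repetition
    return GroundTruth(
        group=group,
        region_masks={REGION_NAME: region_mask},
        rho_cross_language={REGION_NAME: rho_cl},
        rho_repetition={REGION_NAME: rho_rep},
        seed=seed,
        **kwargs,
    )


def simulate_trial_betas(
    ground_truth: GroundTruth,
    design_cn: ExperimentDesign,
    design_es: ExperimentDesign,
    beta_noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    patterns: PatternSet | None = None,
    phases=WORD_PHASES,
    dtype=np.float64,
) -> dict:
    """Draw per-trial beta sets directly: amplitude * pattern + noise.

    Returns a dict keyed by (language, phase) of
    :class:`imitrsa.trial_betas.TrialBetaSet`. Trial order follows the
    design's word-event order; the mask is the full grid. ``phases`` limits
    generation to the phases actually analyzed.
    """
    from ..trial_betas import TrialBetaSet

    if rng is None:
        rng = np.random.default_rng(ground_truth.seed)
    if patterns is None:
        patterns = generate_patterns(ground_truth, design_cn, design_es, rng=rng)
    grid_shape = patterns.grid_shape
    n_vox = int(np.prod(grid_shape))
    mask = np.ones(grid_shape, dtype=bool)
    designs = {"chinese": design_cn, "spanish": design_es}
    out: dict = {}
    for lang, design in designs.items():
        affine = np.diag(list(design.voxel_size) + [1.0])
        for phase in phases:
            events = design.word_events(phase)
            betas = np.empty((len(events), n_vox), dtype=dtype)
            rows = []
            for i, ev in enumerate(events):
                pat = patterns.get(lang, phase, ev.word_id, ev.repetition)
                betas[i] = ground_truth.amplitude * pat
                rows.append(
                    {
                        "language": lang,
                        "word_id": ev.word_id,
                        "repetition": ev.repetition,
                        "phase": phase,
                    }
                )
            betas += beta_noise_sd * rng.standard_normal(betas.shape).astype(dtype)
            out[(lang, phase)] = TrialBetaSet(
                betas=betas, meta=pd.DataFrame(rows), mask=mask, affine=affine
            )
    return out


def _subject_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_subject_maps(
    measure: str,
    group: str,
    subject_seed: int,
    grid_shape=(20, 20, 20),
    k: int = 125,
    beta_noise_sd: float = 1.0,
    phase: str = "perception",
    language: str = "spanish",
    neighborhoods: list | None = None,
    **gt_kwargs,
) -> np.ndarray:
    """One subject's similarity z-map for one measure (3D array)."""
    from ..searchlight import run_searchlight

    gt = default_ground_truth(group, grid_shape=grid_shape, seed=subject_seed, **gt_kwargs)
    rng = np.random.default_rng(subject_seed)
    d_cn = generate_design(f"{group}_sim", "chinese", int(rng.integers(2**31 - 1)), grid_shape=grid_shape)
    d_es = generate_design(f"{group}_sim", "spanish", int(rng.integers(2**31 - 1)), grid_shape=grid_shape)
    betas = simulate_trial_betas(
        gt, d_cn, d_es, beta_noise_sd=beta_noise_sd, rng=rng, phases=(phase,), dtype=np.float32
    )
    mask = np.ones(grid_shape, dtype=bool)
    if measure == "cross_language":
        beta_arg = {"chinese": betas[("chinese", phase)], "spanish": betas[("spanish", phase)]}
    else:
        beta_arg = betas[(language, phase)]
    smap = run_searchlight(beta_arg, mask, measure, k=k, neighborhoods=neighborhoods)
    return smap.values


def simulate_similarity_maps(
    measure: str,
    n_per_group: int,
    seed: int,
    groups=GROUPS,
    grid_shape=(20, 20, 20),
    k: int = 125,
    beta_noise_sd: float = 1.0,
    phase: str = "perception",
    language: str = "spanish",
    **gt_kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one z-map per subject for a whole cohort.

    Returns (maps with shape (n_subjects, *grid_shape), group labels,
    region mask). Neighborhoods are built once and shared across subjects.
    """
    from ..searchlight import MEASURES, build_neighborhoods

    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    mask = np.ones(grid_shape, dtype=bool)
    neighborhoods = build_neighborhoods(mask, k=k)
    seeds = _subject_seeds(seed, n_per_group * len(groups))
    maps = []
    labels = []
    i = 0
    for group in groups:
        for _ in range(n_per_group):
            maps.append(
                simulate_subject_maps(
                    measure,
                    group,
                    seeds[i],
                    grid_shape=grid_shape,
                    k=k,
                    beta_noise_sd=beta_noise_sd,
                    phase=phase,
                    language=language,
                    neighborhoods=neighborhoods,
                    **gt_kwargs,
                )
            )
            labels.append(group)
            i += 1
    region = default_region_mask(grid_shape)
    return np.stack(maps), np.asarray(labels), region


def simulate_feature_set(
    n_per_group: int,
    seed: int,
    groups=("children", "control_adults"),
    grid_shape=(12, 12, 12),
    k: int = 125,
    beta_noise_sd: float = 1.0,
    **gt_kwargs,
):
    """Simulate the 12 repetition-similarity maps per subject for classification.

    Returns an :class:`imitrsa.mvpa.FeatureSet` over the full-grid mask plus
    the planted region mask.
    """
    from ..mvpa import FeatureSet
    from ..searchlight import build_neighborhoods, run_repetition_searchlights

    rep_measures = ("rep_t1t2", "rep_t2t3", "rep_t1t3")
    mask = np.ones(grid_shape, dtype=bool)
    neighborhoods = build_neighborhoods(mask, k=k)
    seeds = _subject_seeds(seed, n_per_group * len(groups))
    all_maps = []
    labels = []
    i = 0
    for group in groups:
        for _ in range(n_per_group):
            subject_seed = seeds[i]
            gt = default_ground_truth(group, grid_shape=grid_shape, seed=subject_seed, **gt_kwargs)
            rng = np.random.default_rng(subject_seed)
            d_cn = generate_design(f"{group}_sim", "chinese", int(rng.integers(2**31 - 1)), grid_shape=grid_shape)
            d_es = generate_design(f"{group}_sim", "spanish", int(rng.integers(2**31 - 1)), grid_shape=grid_shape)
            betas = simulate_trial_betas(
                gt, d_cn, d_es, beta_noise_sd=beta_noise_sd, rng=rng, dtype=np.float32
            )
            subject_maps = []
            for lang in ("chinese", "spanish"):
                for phase in WORD_PHASES:
                    smaps = run_repetition_searchlights(
                        betas[(lang, phase)], mask, measures=rep_measures,
                        k=k, neighborhoods=neighborhoods,
                    )
                    for measure in rep_measures:
                        subject_maps.append(smaps[measure].values[mask])
            all_maps.append(np.stack(subject_maps))
            labels.append(group)
            i += 1
    feature_set = FeatureSet(maps=np.stack(all_maps), labels=np.asarray(labels), mask=mask)
    return feature_set, default_region_mask(grid_shape)
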
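"""Latent word-by-repetition multivoxel patterns with controlled correlation structure.

Within each region, the pattern for (language L, repetition t, word w) is a
unit-variance mixture of independent standard-normal components

    p[L, t, w] = a * g[w]  +  s[t] * h[L, w]  +  q[t] * e[L, t, w]

so that the expected Pearson correlation between a word's Chinese and
Spanish patterns equals ``rho_cross_language`` (= a**2) and the expected
correlation between the same word's patterns at repetitions t_i, t_j within
a language equals ``rho_repetition[t_i, t_j]`` (= a**2 + s_i * s_j). The
language-shared word component g[w] itself mixes a word-nonspecific regional
response m (weight sqrt(word_common_frac)) with a word-specific vector, so
that all words of a region engage a common speech response, as all stimuli
of a real experiment engage the same network; this leaves the same-word
cross-language correlation at rho_cross_language and sets the
different-word cross-language correlation to rho_cross_language *
word_common_frac. Outside all region masks, patterns are independent noise
(expected correlations zero). Perception and production pattern sets are
generated from separate latents, optionally correlated at ``rho_phase``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ExperimentDesign, N_REPS, N_WORDS, REPETITIONS, WORD_PHASES

_PAIRS = (("t1", "t2"), ("t2", "t3"), ("t1", "t3"))


@dataclass
class GroundTruth:
    """Generative parameters for one subject's pattern structure."""

    group: str
    region_masks: dict[str, np.ndarray]
    rho_cross_language: dict[str, float]
    rho_repetition: dict[str, float | dict[tuple[str, str], float]]
    amplitude: float = 1.0
    noise_sd: float = 1.0
    word_common_frac: float = 0.5
    rho_phase: float = 0.0
    drift_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        flat_sum = None
        for name, mask in self.region_masks.items():
            mask = np.asarray(mask, dtype=bool)
            self.region_masks[name] = mask
            flat_sum = mask.astype(int) if flat_sum is None else flat_sum + mask
        if flat_sum is not None and (flat_sum > 1).any():
            raise ValueError("region masks must be disjoint")
        for name in self.region_masks:
            rho_cl = self.rho_cross_language.get(name, 0.0)
            if not -1.0 <= rho_cl <= 1.0:
                raise ValueError(f"rho_cross_language[{name}]={rho_cl} outside [-1, 1]")
            for r in _rep_rho_values(self.rho_repetition.get(name, 0.0)):
                if not -1.0 <= r <= 1.0:
                    raise ValueError(f"rho_repetition[{name}] value {r} outside [-1, 1]")
        if not 0.0 <= self.word_common_frac <= 1.0:
            raise ValueError("word_common_frac must lie in [0, 1]")
        if not -1.0 <= self.rho_phase <= 1.0:
            raise ValueError("rho_phase outside [-1, 1]")


@dataclass
class PatternSet:
    """Per-trial latent patterns: arrays of shape (n_words, n_reps, n_voxels)."""

    patterns: dict[tuple[str, str], np.ndarray]  # (language, phase) -> array
    word_ids: dict[str, list[str]]  # language -> ordered word list
    grid_shape: tuple[int, int, int]

    def get(self, language: str, phase: str, word_id: str, repetition: str) -> np.ndarray:
        arr = self.patterns[(language, phase)]
        w = self.word_ids[language].index(word_id)
        t = REPETITIONS.index(repetition)
        return arr[w, t]


def _rep_rho_values(rho) -> list[float]:
    if isinstance(rho, dict):
        return [float(v) for v in rho.values()]
    return [float(rho)]


def _rep_weights(rho_rep, rho_cl: float) -> np.ndarray:
    """Solve per-repetition loadings s_t with s_i*s_j = rho_rep(i,j) - rho_cl."""
    if isinstance(rho_rep, dict):
        d = {}
        for pair in _PAIRS:
            if pair in rho_rep:
                val = rho_rep[pair]
            elif (pair[1], pair[0]) in rho_rep:
                val = rho_rep[(pair[1], pair[0])]
            else:
                raise ValueError(f"rho_repetition missing pair {pair}")
            d[pair] = float(val) - rho_cl
        if any(v < 0 for v in d.values()):
            raise ValueError("rho_repetition must be >= rho_cross_language in each region")
        if all(v == 0 for v in d.values()):
            return np.zeros(N_REPS)
        d12, d23, d13 = d[_PAIRS[0]], d[_PAIRS[1]], d[_PAIRS[2]]
        if min(d12, d23, d13) <= 0:
            raise ValueError("pairwise rho_repetition values must all exceed rho_cross_language, or all equal it")
        s1 = np.sqrt(d12 * d13 / d23)
        s2 = d12 / s1
        s3 = d13 / s1
        s = np.array([s1, s2, s3])
    else:
        d = float(rho_rep) - rho_cl
        if d < 0:
            raise ValueError("rho_repetition must be >= rho_cross_language in each region")
        s = np.full(N_REPS, np.sqrt(d))
    if (s**2 + rho_cl > 1.0 + 1e-12).any():
        raise ValueError("repetition loadings exceed unit variance; lower rho_repetition")
    return s


def _mixed_normal(rng: np.random.Generator, shape, rho_phase: float, n_phases: int) -> list[np.ndarray]:
    """Independent standard-normal components per phase, correlated at rho_phase."""
    if rho_phase == 0.0:
        return [rng.standard_normal(shape) for _ in range(n_phases)]
    shared = rng.standard_normal(shape)
    a, b = np.sqrt(abs(rho_phase)), np.sqrt(1.0 - abs(rho_phase))
    sign = np.sign(rho_phase) if rho_phase else 1.0
    out = [a * shared + b * rng.standard_normal(shape)]
    for _ in range(n_phases - 1):
        out.append(sign * a * shared + b * rng.standard_normal(shape))
    return out


def generate_patterns(
    ground_truth: GroundTruth,
    design_cn: ExperimentDesign,
    design_es: ExperimentDesign,
    rng: np.random.Generator | None = None,
) -> PatternSet:
    """Draw one subject's latent patterns for both languages and phases."""
    if tuple(design_cn.grid_shape) != tuple(design_es.grid_shape):
        raise ValueError("designs must share grid_shape")
    grid_shape = tuple(design_cn.grid_shape)
    n_vox = int(np.prod(grid_shape))
    if rng is None:
        rng = np.random.default_rng(ground_truth.seed)

    designs = {"chinese": design_cn, "spanish": design_es}
    word_ids = {lang: d.word_ids for lang, d in designs.items()}
    langs = ("chinese", "spanish")
    phases = WORD_PHASES
    out = {(lang, ph): np.empty((N_WORDS, N_REPS, n_vox)) for lang in langs for ph in phases}

    # background voxels: all-independent patterns
    region_union = np.zeros(grid_shape, dtype=bool)
    for mask in ground_truth.region_masks.values():
        if mask.shape != grid_shape:
            raise ValueError("region mask shape does not match grid_shape")
        region_union |= mask
    regions = dict(ground_truth.region_masks)
    regions["__background__"] = ~region_union

    for name, mask in regions.items():
        vox = np.flatnonzero(mask.ravel())
        if vox.size == 0:
            continue
        nv = vox.size
        rho_cl = float(ground_truth.rho_cross_language.get(name, 0.0))
        if name == "__background__":
            rho_cl = 0.0
            s = np.zeros(N_REPS)
        else:
            s = _rep_weights(ground_truth.rho_repetition.get(name, rho_cl), rho_cl)
        a = np.sqrt(rho_cl) if rho_cl >= 0 else np.nan
        if rho_cl < 0:
            raise ValueError("negative rho_cross_language is not representable by this mixture")
        q = np.sqrt(1.0 - rho_cl - s**2)
        eta = ground_truth.word_common_frac

        m = _mixed_normal(rng, (nv,), ground_truth.rho_phase, len(phases))
        g = _mixed_normal(rng, (N_WORDS, nv), ground_truth.rho_phase, len(phases))
        h = _mixed_normal(rng, (2, N_WORDS, nv), ground_truth.rho_phase, len(phases))
        e = _mixed_normal(rng, (2, N_WORDS, N_REPS, nv), ground_truth.rho_phase, len(phases))

        for pi, ph in enumerate(phases):
            g_full = np.sqrt(eta) * m[pi][None, :] + np.sqrt(1.0 - eta) * g[pi]
            for li, lang in enumerate(langs):
                block = (
                    a * g_full[:, None, :]
                    + s[None, :, None] * h[pi][li][:, None, :]
                    + q[None, :, None] * e[pi][li]
                )
                out[(lang, ph)][:, :, vox] = block

    return PatternSet(patterns=out, word_ids=word_ids, grid_shape=grid_shape)
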
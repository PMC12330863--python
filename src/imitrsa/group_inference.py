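"""Group-level statistics on similarity maps.

Voxelwise mixed-design (split-plot) ANOVA with one between-subject factor
(group) and one within-subject factor (process, language, or imitation
order), computed from per-cell subject means with no sphericity correction;
minimum-statistic conjunctions of one-sided t contrasts at voxel p < .001;
cluster-extent correction by max-cluster-size permutation (a permutation
stand-in for random-field-theory cluster FWE, same control target);
first-principal-component composites of acoustic distance scores; and
brain-behavior partial correlation controlling for digit span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
DEFAULT_VOXEL_P = 0.001


@dataclass
class StatMap:
    statistic: np.ndarray
    dof: tuple
    contrast: str
    kind: str = "F"  # "F" or "t"
    threshold_meta: dict = field(default_factory=dict)


def _as_2d(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=float)
    return maps.reshape(maps.shape[0], -1)


def mixed_anova_maps(
    data: np.ndarray,
    groups,
    within_labels=None,
) -> dict[str, StatMap]:
    """Voxelwise mixed ANOVA from per-cell subject means.

    Parameters
    ----------
    data : (n_subjects, n_levels, n_voxels) array
        One value per subject and within-factor level (cell mean).
    groups : length n_subjects labels of the between factor.

    Returns
    -------
    dict with F maps "group", "within", "interaction".
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (n_subjects, n_levels, n_voxels)")
    groups = np.asarray(groups)
    n_subj, n_lev, n_vox = data.shape
    labels = pd.unique(groups)
    n_grp = len(labels)
    counts = np.array([(groups == g).sum() for g in labels])
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 subjects")

    grand = data.mean(axis=(0, 1))  # (V,)
    subj_mean = data.mean(axis=1)  # (S, V)
    lev_mean = data.mean(axis=0)  # (L, V)
    grp_mean = np.stack([data[groups == g].mean(axis=(0, 1)) for g in labels])  # (G, V)
    cell_mean = np.stack([data[groups == g].mean(axis=0) for g in labels])  # (G, L, V)

    ss_group = n_lev * (counts[:, None] * (grp_mean - grand) ** 2).sum(axis=0)
    ss_between_subj = n_lev * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_subj_within = ss_between_subj - ss_group

    ss_within_total = ((data - subj_mean[:, None, :]) ** 2).sum(axis=(0, 1))
    ss_level = n_subj * ((lev_mean - grand) ** 2).sum(axis=0)
    ss_cells = (
        counts[:, None, None]
        * (cell_mean - grp_mean[:, None, :] - lev_mean[None, :, :] + grand) ** 2
    ).sum(axis=(0, 1))
    ss_interaction = ss_cells
    ss_error_within = ss_within_total - ss_level - ss_interaction

    df_group = n_grp - 1
    df_subj = n_subj - n_grp
    df_level = n_lev - 1
    df_inter = df_group * df_level
    df_err_within = df_subj * df_level

    def f_map(ss_num, df_num, ss_den, df_den, name):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_num / df_num) / (ss_den / df_den)
        return StatMap(
            statistic=np.nan_to_num(f, nan=0.0, posinf=0.0),
            dof=(df_num, df_den),
            contrast=name,
            kind="F",
        )

    return {
        "group": f_map(ss_group, df_group, ss_subj_within, df_subj, "main effect of group"),
        "within": f_map(ss_level, df_level, ss_error_within, df_err_within, "main effect of within factor"),
        "interaction": f_map(
            ss_interaction, df_inter, ss_error_within, df_err_within, "group x within interaction"
        ),
    }


def two_sample_tmap(maps_a: np.ndarray, maps_b: np.ndarray) -> StatMap:
    """Voxelwise independent-samples t (a > b), pooled variance."""
    a, b = _as_2d(maps_a), _as_2d(maps_b)
    na, nb = a.shape[0], b.shape[0]
    dof = na + nb - 2
    sp2 = (((a - a.mean(0)) ** 2).sum(0) + ((b - b.mean(0)) ** 2).sum(0)) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(0) - b.mean(0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.nan_to_num(t, nan=0.0)
    shape = np.asarray(maps_a).shape[1:]
    return StatMap(statistic=t.reshape(shape), dof=(dof,), contrast="a > b", kind="t")


def conjunction(
    tmap_a: StatMap, tmap_b: StatMap, voxel_p: float = DEFAULT_VOXEL_P
) -> np.ndarray:
    """Minimum-statistic conjunction: both one-sided t maps supra-threshold."""
    if tmap_a.statistic.shape != tmap_b.statistic.shape:
        raise ValueError("t maps must share a grid")
    thr_a = stats.t.ppf(1.0 - voxel_p, tmap_a.dof[-1])
    thr_b = stats.t.ppf(1.0 - voxel_p, tmap_b.dof[-1])
    return (tmap_a.statistic > thr_a) & (tmap_b.statistic > thr_b)


def _max_cluster_size(supra: np.ndarray) -> int:
    labeled, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def cluster_threshold_permutation(
    maps: np.ndarray,
    group_labels,
    n_perm: int = 1000,
    voxel_p: float = DEFAULT_VOXEL_P,
    alpha: float = 0.05,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Cluster-extent FWE control by max-cluster-size permutation.

    Two-group contrast (first label > second): the observed one-sided t map
    is thresholded at ``voxel_p``; group labels are permuted ``n_perm``
    times and the maximum supra-threshold cluster size recorded; observed
    clusters larger than the (1 - alpha) percentile of that null survive.

    Returns (thresholded binary map, cluster table, null max sizes).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if (n_perm + 1) * alpha < 1:
        raise ValueError("n_perm too small for the requested alpha")
    maps = np.asarray(maps, dtype=float)
    group_labels = np.asarray(group_labels)
    labels = pd.unique(group_labels)
    if len(labels) != 2:
        raise ValueError("cluster permutation expects exactly two groups")
    idx_a = group_labels == labels[0]

    def tstat(sel_a: np.ndarray) -> np.ndarray:
        return two_sample_tmap(maps[sel_a], maps[~sel_a]).statistic

    dof = maps.shape[0] - 2
    thr = stats.t.ppf(1.0 - voxel_p, dof)
    observed_t = tstat(idx_a)
    supra = observed_t > thr

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    n_a = int(idx_a.sum())
    for i in range(n_perm):
        perm = np.zeros(maps.shape[0], dtype=bool)
        perm[rng.choice(maps.shape[0], size=n_a, replace=False)] = True
        null_max[i] = _max_cluster_size(tstat(perm) > thr)
    crit = np.quantile(null_max, 1.0 - alpha, method="higher")

    labeled, n_clusters = ndimage.label(supra, structure=CONNECTIVITY_26)
    keep = np.zeros_like(supra)
    rows = []
    for c in range(1, n_clusters + 1):
        in_c = labeled == c
        size = int(in_c.sum())
        peak_flat = np.flatnonzero(in_c.ravel())[np.argmax(observed_t[in_c])]
        peak = np.unravel_index(peak_flat, supra.shape)
        world = (
            (affine @ np.array([*peak, 1.0]))[:3] if affine is not None else np.asarray(peak, float)
        )
        survives = size > crit
        if survives:
            keep |= in_c
        rows.append(
            {
                "cluster": c,
                "size": size,
                "peak_x": world[0],
                "peak_y": world[1],
                "peak_z": world[2],
                "peak_stat": float(observed_t[in_c].max()),
                "survives": survives,
            }
        )
    table = pd.DataFrame(rows, columns=["cluster", "size", "peak_x", "peak_y", "peak_z", "peak_stat", "survives"])
    return keep, table, null_max


def pca_composite(distances: pd.DataFrame) -> tuple[pd.Series, pd.Series, float]:
    """First-principal-component score of standardized distance variables.

    Sign is fixed so that a larger score means a larger mean distance
    (worse imitation). Zero-variance variables are dropped with a warning.

    Returns (scores per subject, loadings, explained variance ratio).
    """
    if distances.shape[1] < 2:
        raise ValueError("need at least 2 distance variables")
    if distances.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sd = distances.std(ddof=1)
    dead = sd.index[sd == 0]
    if len(dead):
        warnings.warn(f"dropping zero-variance variables: {list(dead)}", RuntimeWarning)
        distances = distances.drop(columns=dead)
        sd = sd.drop(dead)
    z = (distances - distances.mean()) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    loadings = pd.Series(vt[0], index=distances.columns)
    scores = pd.Series(z.to_numpy() @ vt[0], index=distances.index)
    if np.corrcoef(scores, z.mean(axis=1))[0, 1] < 0:
        scores, loadings = -scores, -loadings
    explained = float(s[0] ** 2 / (s**2).sum())
    return scores, loadings, explained


def brain_behavior_partial(
    similarity_values: np.ndarray,
    behavior: np.ndarray,
    covariate: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial Pearson correlation per voxel, controlling the covariate.

    Both the similarity values and the behavior score are residualized on
    the covariate (with intercept); the residuals are correlated and a
    two-sided p computed from the t transform with n - 3 dof.
    """
    sims = _as_2d(similarity_values) if np.asarray(similarity_values).ndim > 1 else np.asarray(
        similarity_values, float
    ).reshape(-1, 1)
    behavior = np.asarray(behavior, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n = len(behavior)
    if sims.shape[0] != n or len(covariate) != n:
        raise ValueError("inputs must have equal length")
    if n < 5:
        raise ValueError("need at least 5 subjects")

    if np.ptp(covariate) == 0:
        warnings.warn("constant covariate; computing plain correlation", RuntimeWarning)
        res_s, res_b = sims - sims.mean(0), behavior - behavior.mean()
        dof = n - 2
    else:
        X = np.column_stack([np.ones(n), covariate])
        hat = X @ np.linalg.pinv(X)
        res_s = sims - hat @ sims
        res_b = behavior - hat @ behavior
        dof = n - 3
    num = res_s.T @ res_b
    ns = np.sqrt((res_s**2).sum(0))
    nb = np.sqrt((res_b**2).sum())
    # residuals that vanish (up to rounding) carry no partial association
    ok = (ns > 1e-10 * (np.sqrt((sims**2).sum(0)) + 1.0)) & (
        nb > 1e-10 * (np.sqrt((behavior**2).sum()) + 1.0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ok, num / (ns * nb), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    if np.asarray(similarity_values).ndim == 1:
        return float(r[0]), float(p[0])
    return r, p


def read_subjects_table(path) -> pd.DataFrame:
    """Read a tab-separated subjects table (subject_id, group, digit_span, ...)."""
    return pd.read_csv(path, sep="\t")


def write_cluster_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
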
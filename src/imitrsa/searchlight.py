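"""Searchlight similarity statistics over 125-voxel neighborhoods.

Two per-neighborhood measures are provided, each returning a Fisher
z-transformed statistic:

* cross-language similarity: the Pearson correlation between every trial
  pattern of one language and every trial pattern of the other (84 x 84 =
  7056 pairs) over the neighborhood's beta values, averaged, then
  z-transformed;
* between-repetition similarity: at each repetition, the 28 x 28 matrix of
  pairwise trial-pattern correlations ("DSM"); the Spearman rank correlation
  between the two repetitions' matrices over the strict upper triangle
  (378 entries), z-transformed.

The "sphere containing 125 voxels" is implemented count-based: the 125
nearest in-mask voxels by Euclidean distance in world coordinates, ties
broken by lexicographic voxel index. Degenerate zero-variance trial
patterns contribute correlation 0 (with a warning) so maps stay finite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .trial_betas import TrialBetaSet

MEASURES = ("cross_language", "rep_t1t2", "rep_t2t3", "rep_t1t3")
REP_PAIRS = {
    "rep_t1t2": ("t1", "t2"),
    "rep_t2t3": ("t2", "t3"),
    "rep_t1t3": ("t1", "t3"),
}
_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class Neighborhood:
    """Searchlight neighborhood: flat grid indices plus positions within the
    in-mask voxel ordering (C order)."""

    center: int
    members: np.ndarray
    positions: np.ndarray


@dataclass
class TrialSimilarityMatrix:
    values: np.ndarray  # 28 x 28 Pearson correlations, diagonal 1
    language: str
    repetition: str
    phase: str

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("trial-similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        if (np.abs(v) > 1 + 1e-9).any():
            raise ValueError("entries must lie in [-1, 1]")


@dataclass
class SimilarityMap:
    """Per-voxel Fisher-z similarity statistic for one measure/condition."""

    values: np.ndarray  # 3D, zero outside mask
    mask: np.ndarray
    measure: str
    phase: str
    language: str | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]

    def save(self, nii_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(self.values, self.affine), str(nii_path))
        if sidecar_path is not None:
            Path(sidecar_path).write_text(
                json.dumps(
                    {"measure": self.measure, "phase": self.phase, "language": self.language},
                    indent=1,
                )
            )


def fisher_z(r) -> np.ndarray | float:
    """atanh of a correlation, clipped to |r| <= 1 - 1e-12."""
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def build_neighborhoods(
    mask: np.ndarray,
    k: int = 125,
    voxel_size=(3.0, 3.0, 3.0),
    chunk: int = 256,
) -> list[Neighborhood]:
    """Nearest-k in-mask neighborhoods for every in-mask voxel.

    Distances are Euclidean in world (mm) coordinates; exact distance ties
    are broken by lexicographic voxel index. If the mask holds fewer than k
    voxels, every neighborhood uses all of them.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("mask is empty")
    flat = np.ravel_multi_index(coords.T, mask.shape)
    world = coords * np.asarray(voxel_size, dtype=float)
    n = coords.shape[0]
    kk = min(k, n)

    # Candidate pruning: a KD-tree shortlist (padded well beyond any
    # equal-distance shell multiplicity) followed by an exact re-sort, so the
    # selected members are identical to a full-distance sort. Small masks are
    # sorted exhaustively.
    slack = 256
    use_tree = n > kk + slack
    if use_tree:
        tree = cKDTree(world)
        _, cand = tree.query(world, k=kk + slack)

    out: list[Neighborhood] = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        if use_tree:
            # ascending candidate positions first, so the stable sort on the
            # recomputed distances breaks exact ties lexicographically
            cand_rows = np.sort(cand[start:stop], axis=1)
            d2 = ((world[cand_rows] - world[start:stop, None, :]) ** 2).sum(axis=-1)
            order = np.argsort(d2, axis=1, kind="stable")[:, :kk]
            sel = np.take_along_axis(cand_rows, order, axis=1)
        else:
            d2 = ((world[start:stop, None, :] - world[None, :, :]) ** 2).sum(axis=-1)
            # stable sort on distance keeps ascending in-mask order
            # (= lexicographic voxel index) among exact ties
            sel = np.argsort(d2, axis=1, kind="stable")[:, :kk]
        for i, row in enumerate(sel):
            out.append(
                Neighborhood(center=int(flat[start + i]), members=flat[row], positions=row)
            )
    return out


def _normalize_rows(x: np.ndarray, context: str) -> np.ndarray:
    """Center and unit-norm each row; zero-variance rows become zero (warned)."""
    x = x - x.mean(axis=-1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=-1, keepdims=True))
    n_zero = int((norms == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-variance trial pattern(s) in {context}; their correlations are set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)


def _member_values(betas: TrialBetaSet | np.ndarray, neighborhood: Neighborhood) -> np.ndarray:
    arr = betas.betas if isinstance(betas, TrialBetaSet) else np.asarray(betas, dtype=float)
    return arr[:, neighborhood.positions]


def cross_language_similarity(
    betas_cn: TrialBetaSet | np.ndarray,
    betas_es: TrialBetaSet | np.ndarray,
    neighborhood: Neighborhood,
) -> float:
    """Fisher z of the mean Pearson r over all cross-language trial pairs."""
    a = _normalize_rows(_member_values(betas_cn, neighborhood), "cross_language")
    b = _normalize_rows(_member_values(betas_es, neighborhood), "cross_language")
    mean_r = float(a.sum(axis=0) @ b.sum(axis=0)) / (a.shape[0] * b.shape[0])
    return float(fisher_z(mean_r))


def n_cross_language_pairs(betas_cn: TrialBetaSet, betas_es: TrialBetaSet) -> int:
    """Number of trial-pair correlations entering the cross-language mean."""
    return betas_cn.n_trials * betas_es.n_trials


def _rep_indices(betas: TrialBetaSet, repetition: str) -> np.ndarray:
    meta = betas.meta
    sel = meta.index[meta["repetition"] == repetition]
    if len(sel) == 0:
        raise ValueError(f"no trials with repetition {repetition}")
    order = meta.loc[sel, "word_id"].argsort(kind="stable")
    return sel.to_numpy()[order]


def trial_similarity_matrix(
    betas: TrialBetaSet, neighborhood: Neighborhood, repetition: str
) -> TrialSimilarityMatrix:
    """28 x 28 Pearson correlation matrix between same-repetition trials."""
    idx = _rep_indices(betas, repetition)
    z = _normalize_rows(betas.betas[np.ix_(idx, neighborhood.positions)], "trial_similarity_matrix")
    values = z @ z.T
    np.fill_diagonal(values, 1.0)
    lang = betas.meta["language"].iloc[0]
    phase = betas.meta["phase"].iloc[0]
    out = TrialSimilarityMatrix(values=values, language=lang, repetition=repetition, phase=phase)
    return out


def _pearson_rows(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation (zero when either row is constant)."""
    rx = rx - rx.mean(axis=-1, keepdims=True)
    ry = ry - ry.mean(axis=-1, keepdims=True)
    nx = np.sqrt((rx**2).sum(axis=-1))
    ny = np.sqrt((ry**2).sum(axis=-1))
    denom = nx * ny
    num = (rx * ry).sum(axis=-1)
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho (average ranks, Pearson on ranks)."""
    return _pearson_rows(rankdata(x, axis=-1), rankdata(y, axis=-1))


def repetition_similarity(
    betas: TrialBetaSet, neighborhood: Neighborhood, pair: tuple[str, str]
) -> float:
    """Fisher z of the Spearman correlation between two repetitions' DSMs
    over the strict upper triangle."""
    d1 = trial_similarity_matrix(betas, neighborhood, pair[0]).values
    d2 = trial_similarity_matrix(betas, neighborhood, pair[1]).values
    iu = np.triu_indices(d1.shape[0], k=1)
    rho = float(_spearman_rows(d1[iu], d2[iu]))
    return float(fisher_z(rho))


def run_searchlight(
    beta_sets: dict[str, TrialBetaSet] | TrialBetaSet,
    mask: np.ndarray,
    measure: str,
    k: int = 125,
    voxel_size=(3.0, 3.0, 3.0),
    neighborhoods: list[Neighborhood] | None = None,
    chunk: int = 512,
) -> SimilarityMap:
    """Evaluate a similarity measure at every in-mask voxel.

    For ``measure="cross_language"``, ``beta_sets`` is a dict with keys
    "chinese" and "spanish"; for repetition measures it is a single
    :class:`TrialBetaSet`.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    mask = np.asarray(mask, dtype=bool)
    if neighborhoods is None:
        neighborhoods = build_neighborhoods(mask, k=k, voxel_size=voxel_size)
    pos = np.stack([nb.positions for nb in neighborhoods])  # (n_centers, kk)
    centers = np.array([nb.center for nb in neighborhoods])

    if measure == "cross_language":
        a_set, b_set = beta_sets["chinese"], beta_sets["spanish"]
        if a_set.meta["phase"].iloc[0] != b_set.meta["phase"].iloc[0]:
            raise ValueError("both beta sets must come from the same phase")
        A, B = a_set.betas, b_set.betas
        phase = a_set.meta["phase"].iloc[0]
        language = None
        vals = np.empty(len(neighborhoods))
        for start in range(0, len(neighborhoods), chunk):
            p = pos[start : start + chunk]  # (C, kk)
            sa = _normalize_rows(A[:, p], "cross_language").sum(axis=0)  # (C, kk)
            sb = _normalize_rows(B[:, p], "cross_language").sum(axis=0)
            vals[start : start + chunk] = (sa * sb).sum(axis=1) / (A.shape[0] * B.shape[0])
        z = fisher_z(vals)
    else:
        betas = beta_sets
        if isinstance(betas, dict):
            raise ValueError("repetition measures take a single TrialBetaSet")
        return run_repetition_searchlights(
            betas, mask, measures=(measure,), k=k, voxel_size=voxel_size,
            neighborhoods=neighborhoods, chunk=chunk,
        )[measure]

    values = np.zeros(mask.shape)
    values.ravel()[centers] = z
    return SimilarityMap(
        values=values, mask=mask, measure=measure, phase=phase, language=language
    )


def run_repetition_searchlights(
    betas: TrialBetaSet,
    mask: np.ndarray,
    measures=("rep_t1t2", "rep_t2t3", "rep_t1t3"),
    k: int = 125,
    voxel_size=(3.0, 3.0, 3.0),
    neighborhoods: list[Neighborhood] | None = None,
    chunk: int = 512,
) -> dict[str, SimilarityMap]:
    """Between-repetition similarity maps for several repetition pairs at once.

    Each repetition's trial-similarity matrices (and their triangle ranks)
    are computed once per searchlight and shared across the requested pairs.
    """
    for m in measures:
        if m not in REP_PAIRS:
            raise ValueError(f"not a repetition measure: {m}")
    mask = np.asarray(mask, dtype=bool)
    if neighborhoods is None:
        neighborhoods = build_neighborhoods(mask, k=k, voxel_size=voxel_size)
    pos = np.stack([nb.positions for nb in neighborhoods])
    centers = np.array([nb.center for nb in neighborhoods])
    phase = betas.meta["phase"].iloc[0]
    language = betas.meta["language"].iloc[0]

    reps = sorted({r for m in measures for r in REP_PAIRS[m]})
    idx = {r: _rep_indices(betas, r) for r in reps}
    n = len(idx[reps[0]])
    iu = np.triu_indices(n, k=1)
    vals = {m: np.empty(len(neighborhoods)) for m in measures}
    for start in range(0, len(neighborhoods), chunk):
        p = pos[start : start + chunk]
        ranks = {}
        for r in reps:
            g = _normalize_rows(betas.betas[idx[r]][:, p].transpose(1, 0, 2), f"rep {r}")
            dsm = g @ g.transpose(0, 2, 1)  # (C, n, n)
            ranks[r] = rankdata(dsm[:, iu[0], iu[1]], axis=-1)
        for m in measures:
            ra, rb = REP_PAIRS[m]
            vals[m][start : start + chunk] = _pearson_rows(ranks[ra], ranks[rb])

    out = {}
    for m in measures:
        values = np.zeros(mask.shape)
        values.ravel()[centers] = fisher_z(vals[m])
        out[m] = SimilarityMap(
            values=values, mask=mask, measure=m, phase=phase, language=language
        )
    return out
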
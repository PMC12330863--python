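"""Single-trial response estimation with the Least-Squares-Separate (LSS) GLM.

For each word event, a separate ordinary-least-squares model is fit whose
columns are: the target event's HRF-convolved boxcar; one combined
regressor for all other events of the same phase; one combined regressor
for all events of the other phase; optional motion parameters; a
discrete-cosine drift set (cutoff 0.01 Hz, so only signals above 0.01 Hz
are kept); and an intercept. The target column's coefficient is the trial's
beta pattern. Perception and production epochs are modeled as separate
regressors because the two phases are analyzed separately downstream.
Baseline fixation epochs are left unmodeled (implicit baseline). No
autocorrelation model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import HIGH_PASS_HZ, cosine_drift, event_regressor
from .synth.design import Event, ExperimentDesign, WORD_PHASES


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when an LSS design matrix is rank deficient."""


@dataclass
class TrialBetaSet:
    """One beta vector per word event, with trial metadata.

    ``betas`` has shape (n_trials, n_mask_voxels); ``meta`` has one row per
    trial with columns language, word_id, repetition, phase.
    """

    betas: np.ndarray
    meta: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        if self.betas.shape[0] != len(self.meta):
            raise ValueError("betas and meta must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    def validate(self) -> None:
        if not np.isfinite(self.betas).all():
            raise ValueError("betas must be finite inside the mask")
        key = self.meta[["word_id", "repetition", "phase"]]
        if key.duplicated().any():
            raise ValueError("duplicate (word, repetition, phase) beta")


def _other_phase(phase: str) -> str:
    return WORD_PHASES[1 - WORD_PHASES.index(phase)]


def _event_key(e: Event) -> tuple:
    return (e.onset, e.phase, e.word_id, e.repetition)


def build_design_matrix(
    design: ExperimentDesign,
    target_event: Event,
    nuisance_motion: np.ndarray | None = None,
    regressors: dict | None = None,
) -> pd.DataFrame:
    """LSS design matrix for one target word event.

    ``regressors`` may carry precomputed per-event regressors (as returned
    by :func:`precompute_event_regressors`) to avoid re-convolving.
    """
    if target_event.phase not in WORD_PHASES:
        raise KeyError("target event must be a perception or production event")
    keys = [_event_key(e) for e in design.word_events(target_event.phase)]
    if _event_key(target_event) not in keys:
        raise KeyError("target event not found in design")

    if regressors is None:
        regressors = precompute_event_regressors(design)

    phase = target_event.phase
    other = _other_phase(phase)
    cols = {"target": regressors[_event_key(target_event)]}
    same_events = [
        e for e in design.word_events(phase) if _event_key(e) != _event_key(target_event)
    ]
    if same_events:
        cols[f"other_{phase}"] = sum(regressors[_event_key(e)] for e in same_events)
    other_events = design.word_events(other)
    if other_events:
        cols[f"all_{other}"] = sum(regressors[_event_key(e)] for e in other_events)
    if nuisance_motion is not None:
        nuisance_motion = np.asarray(nuisance_motion, dtype=float)
        if nuisance_motion.shape[0] != design.n_volumes:
            raise ValueError("motion regressors must have one row per volume")
        for j in range(nuisance_motion.shape[1]):
            cols[f"motion_{j + 1}"] = nuisance_motion[:, j]
    drift = cosine_drift(design.n_volumes, design.tr, HIGH_PASS_HZ)
    for j in range(drift.shape[1]):
        cols[f"drift_{j + 1}"] = drift[:, j]
    cols["intercept"] = np.ones(design.n_volumes)
    return pd.DataFrame(cols)


def precompute_event_regressors(design: ExperimentDesign) -> dict:
    """One HRF-convolved regressor per word event, keyed by event identity."""
    out = {}
    for phase in WORD_PHASES:
        for e in design.word_events(phase):
            out[_event_key(e)] = event_regressor(
                [e.onset], [e.duration], design.n_volumes, design.tr
            )
    return out


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise SingularDesignError(f"rank-deficient design matrix; offending columns: {bad}")


def estimate_lss(
    series: nib.Nifti1Image | np.ndarray,
    design: ExperimentDesign,
    phase: str,
    mask: np.ndarray | None = None,
    nuisance_motion: np.ndarray | None = None,
) -> TrialBetaSet:
    """Estimate one beta pattern per word event of ``phase``."""
    if phase not in WORD_PHASES:
        raise ValueError(f"phase must be one of {WORD_PHASES}")
    if isinstance(series, nib.Nifti1Image):
        data = np.asarray(series.dataobj, dtype=float)
        affine = series.affine
    else:
        data = np.asarray(series, dtype=float)
        affine = np.diag(list(design.voxel_size) + [1.0])
    if data.shape[:3] != tuple(design.grid_shape):
        raise ValueError("series grid does not match design grid_shape")
    if data.shape[3] != design.n_volumes:
        raise ValueError("series has wrong number of volumes for this design")
    if mask is None:
        mask = np.ones(design.grid_shape, dtype=bool)
    Y = data.reshape(-1, design.n_volumes)[mask.ravel()].T  # (T, V)

    regressors = precompute_event_regressors(design)
    events = design.word_events(phase)
    betas = np.empty((len(events), Y.shape[1]))
    rows = []
    for i, ev in enumerate(events):
        X = build_design_matrix(design, ev, nuisance_motion, regressors=regressors)
        _check_rank(X.to_numpy(), list(X.columns))
        pinv = np.linalg.pinv(X.to_numpy())
        betas[i] = pinv[0] @ Y  # column 0 is the target regressor
        rows.append(
            {
                "language": design.language,
                "word_id": ev.word_id,
                "repetition": ev.repetition,
                "phase": phase,
            }
        )
    out = TrialBetaSet(betas=betas, meta=pd.DataFrame(rows), mask=mask, affine=affine)
    out.validate()
    return out


def write_betas(beta_set: TrialBetaSet, nii_path: str | Path, meta_path: str | Path) -> None:
    """Write betas as a 4D NIfTI (trial as 4th axis) plus a TSV metadata table."""
    shape = beta_set.mask.shape
    vol = np.zeros((*shape, beta_set.n_trials))
    vol[beta_set.mask] = beta_set.betas.T
    nib.save(nib.Nifti1Image(vol, beta_set.affine), str(nii_path))
    beta_set.meta.to_csv(meta_path, sep="\t", index=False)


def read_betas(nii_path: str | Path, meta_path: str | Path, mask: np.ndarray | None = None) -> TrialBetaSet:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    betas = data[mask].T
    meta = pd.read_csv(meta_path, sep="\t")
    return TrialBetaSet(betas=betas, meta=meta, mask=mask, affine=img.affine)
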
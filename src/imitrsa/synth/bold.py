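"""Forward model from latent patterns to a 4D BOLD series.

Each word event contributes its latent pattern, scaled by the ground-truth
amplitude and modulated by the event's HRF-convolved boxcar. Additive
Gaussian noise and a slow cosine drift (all frequencies below the 0.01 Hz
high-pass cutoff) complete the series, so downstream estimation must honor
the high-pass contract to be unbiased.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from ..glm import HIGH_PASS_HZ, cosine_drift, event_regressor
from .design import ExperimentDesign, WORD_PHASES
from .patterns import GroundTruth, PatternSet


def _affine(design: ExperimentDesign) -> np.ndarray:
    aff = np.diag(list(design.voxel_size) + [1.0])
    return aff


def synthesize_bold(
    design: ExperimentDesign,
    patterns: PatternSet,
    ground_truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> nib.Nifti1Image:
    """Simulate the 4D series (X, Y, Z, T) for one run as a NIfTI-1 image."""
    if tuple(design.grid_shape) != tuple(patterns.grid_shape):
        raise ValueError("design and patterns disagree on grid_shape")
    if rng is None:
        rng = np.random.default_rng(ground_truth.seed)
    n_vox = int(np.prod(design.grid_shape))
    n_vol = design.n_volumes
    data = np.zeros((n_vol, n_vox))

    for phase in WORD_PHASES:
        for event in design.word_events(phase):
            pat = patterns.get(design.language, phase, event.word_id, event.repetition)
            reg = event_regressor([event.onset], [event.duration], n_vol, design.tr)
            data += np.outer(reg, ground_truth.amplitude * pat)

    drift_basis = cosine_drift(n_vol, design.tr, HIGH_PASS_HZ)
    if drift_basis.shape[1]:
        coefs = ground_truth.drift_sd * rng.standard_normal((drift_basis.shape[1], n_vox))
        data += drift_basis @ coefs
    if ground_truth.noise_sd > 0:
        data += ground_truth.noise_sd * rng.standard_normal((n_vol, n_vox))

    vol = np.moveaxis(data.reshape((n_vol, *design.grid_shape)), 0, -1)
    img = nib.Nifti1Image(vol.astype(np.float64), _affine(design))
    img.header.set_zooms((*design.voxel_size, design.tr))
    return img


def write_bold(img: nib.Nifti1Image, path: str | Path) -> None:
    """Write uncompressed NIfTI (.nii), byte-identical for identical data."""
    path = Path(path)
    if path.suffix == ".gz":
        raise ValueError("use uncompressed .nii for reproducible output")
    nib.save(img, str(path))
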
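"""Hemodynamic regressors and drift bases shared by the simulator and the GLM.

Event regressors are boxcars convolved with the SPM canonical double-gamma
HRF (response peak near 5-6 s, undershoot near 16 s, no derivatives),
evaluated on an oversampled grid and sampled at volume acquisition times.
Temporal high-pass filtering is expressed as discrete-cosine drift columns
inside the design matrix; only frequencies below the cutoff are spanned, so
including them as nuisance regressors keeps signals above the cutoff.
"""

from __future__ import annotations

import numpy as np
from nilearn.glm.first_level.hemodynamic_models import spm_hrf

DEFAULT_OVERSAMPLING = 20
HIGH_PASS_HZ = 0.01  # temporal filter cutoff: only signals above 0.01 Hz are kept


def canonical_hrf(dt: float) -> np.ndarray:
    """SPM canonical double-gamma HRF sampled every ``dt`` seconds (unit area)."""
    return spm_hrf(dt, oversampling=1)


def event_regressor(
    onsets,
    durations,
    n_volumes: int,
    tr: float,
    amplitudes=None,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume onsets.

    Parameters
    ----------
    onsets, durations : array-like, seconds
        Event timing. ``amplitudes`` scales each event's boxcar (default 1).
    n_volumes, tr : scan geometry.

    Returns
    -------
    (n_volumes,) float array.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if not (len(onsets) == len(durations) == len(amplitudes)):
        raise ValueError("onsets, durations and amplitudes must have equal length")

    dt = tr / oversampling
    n_fine = n_volumes * oversampling
    boxcar = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        if i0 >= n_fine:
            raise ValueError(f"event at {onset} s falls outside the run")
        boxcar[i0 : min(i1, n_fine)] += amp
    fine = np.convolve(boxcar, canonical_hrf(dt))[:n_fine]
    return fine[:: oversampling].copy()


def cosine_drift(n_volumes: int, tr: float, high_pass: float = HIGH_PASS_HZ) -> np.ndarray:
    """Discrete-cosine drift basis spanning frequencies strictly below ``high_pass``.

    Column ``k`` (1-based) has frequency k / (2 * n_volumes * tr) Hz; the
    number of columns is the largest k with frequency < high_pass. The
    constant term is excluded (the design matrix carries its own intercept).
    """
    run_length = n_volumes * tr
    n_basis = int(np.floor(2.0 * run_length * high_pass))
    if n_basis > 0 and n_basis / (2.0 * run_length) >= high_pass:
        n_basis -= 1
    frames = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (frames + 0.5) * k / n_volumes)
        for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def drift_frequencies(n_volumes: int, tr: float, high_pass: float = HIGH_PASS_HZ) -> np.ndarray:
    """Frequencies (Hz) of the columns returned by :func:`cosine_drift`."""
    n_basis = cosine_drift(n_volumes, tr, high_pass).shape[1]
    return np.arange(1, n_basis + 1) / (2.0 * n_volumes * tr)
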
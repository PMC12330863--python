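"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own vectorized code paths: plain
loops, numpy.corrcoef, scipy.stats.spearmanr, and direct discrete
convolution.
"""

import numpy as np
from scipy import stats


def convolve_boxcar_oracle(onset, duration, n_volumes, tr, hrf, oversampling):
    """Direct discrete convolution of a boxcar with a sampled HRF."""
    dt = tr / oversampling
    n_fine = n_volumes * oversampling
    boxcar = np.zeros(n_fine)
    i0 = int(round(onset / dt))
    i1 = int(round((onset + duration) / dt))
    boxcar[i0:i1] = 1.0
    fine = np.zeros(n_fine)
    for t in range(n_fine):
        lo = max(0, t - len(hrf) + 1)
        fine[t] = np.dot(boxcar[lo : t + 1], hrf[: t - lo + 1][::-1])
    return fine[::oversampling]


def cross_language_mean_r_oracle(a, b):
    """Nested-loop mean Pearson r over all cross-language trial pairs."""
    rs = []
    for x in a:
        for y in b:
            if x.std() == 0 or y.std() == 0:
                rs.append(0.0)
            else:
                rs.append(np.corrcoef(x, y)[0, 1])
    return float(np.mean(rs))


def dsm_oracle(trials):
    """Pairwise Pearson correlation matrix via numpy.corrcoef, diagonal 1."""
    n = trials.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if trials[i].std() == 0 or trials[j].std() == 0:
                r = 0.0
            else:
                r = np.corrcoef(trials[i], trials[j])[0, 1]
            out[i, j] = out[j, i] = r
    return out


def repetition_rho_oracle(trials_a, trials_b):
    """Spearman rho between the strict upper triangles of the two DSMs."""
    da = dsm_oracle(trials_a)
    db = dsm_oracle(trials_b)
    iu = np.triu_indices(da.shape[0], k=1)
    rho, _ = stats.spearmanr(da[iu], db[iu])
    return float(rho)


def fisher_z_oracle(r):
    return float(np.arctanh(np.clip(r, -(1 - 1e-12), 1 - 1e-12)))


def rep_trials(beta_set, repetition):
    """Trials of one repetition ordered by word id (matching the package)."""
    meta = beta_set.meta
    sel = meta.index[meta["repetition"] == repetition].to_numpy()
    order = np.argsort(meta.loc[sel, "word_id"].to_numpy(), kind="stable")
    return beta_set.betas[sel[order]]
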
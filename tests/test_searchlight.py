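import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracle_utils import (
    cross_language_mean_r_oracle,
    dsm_oracle,
    fisher_z_oracle,
    rep_trials,
    repetition_rho_oracle,
)

from imitrsa import searchlight as sl
from imitrsa.synth import generate_design
from imitrsa.synth.cohort import simulate_trial_betas
from imitrsa.synth.patterns import GroundTruth
from imitrsa.trial_betas import TrialBetaSet

GRID = (6, 6, 6)


def _beta_set(arr, repetitions=None, words=None, language="spanish", phase="perception"):
    n = arr.shape[0]
    meta = pd.DataFrame(
        {
            "language": language,
            "word_id": words if words is not None else [f"w{i:02d}" for i in range(n)],
            "repetition": repetitions if repetitions is not None else ["t1"] * n,
            "phase": phase,
        }
    )
    side = int(round(arr.shape[1] ** (1 / 3)))
    mask = np.ones((side, side, side), dtype=bool)
    return TrialBetaSet(betas=arr, meta=meta, mask=mask, affine=np.eye(4))


# ---------------------------------------------------------------- neighborhoods


def test_neighborhoods_match_brute_force_oracle():
    rng = np.random.default_rng(0)
    mask = rng.random((8, 8, 8)) > 0.25
    voxel_size = (1.7, 1.7, 3.0)
    nbs = sl.build_neighborhoods(mask, k=125, voxel_size=voxel_size)
    coords = np.argwhere(mask)
    world = coords * np.asarray(voxel_size)
    flat = np.ravel_multi_index(coords.T, mask.shape)
    for i in range(0, len(nbs), 17):
        d2 = ((world - world[i]) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")[:125]
        assert np.array_equal(nbs[i].members, flat[order])
        assert nbs[i].members[0] == nbs[i].center


def test_interior_neighborhood_has_125_members():
    mask = np.ones((10, 10, 10), dtype=bool)
    nbs = sl.build_neighborhoods(mask, k=125)
    assert all(len(nb.members) == 125 for nb in nbs)
    assert all(np.isin(nb.members, np.flatnonzero(mask.ravel())).all() for nb in nbs[:20])


def test_single_voxel_mask():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[2, 1, 3] = True
    nbs = sl.build_neighborhoods(mask, k=125)
    assert len(nbs) == 1
    assert len(nbs[0].members) == 1 and nbs[0].members[0] == nbs[0].center


def test_empty_mask_raises():
    with pytest.raises(ValueError):
        sl.build_neighborhoods(np.zeros((3, 3, 3), dtype=bool))


# ------------------------------------------------------- cross-language measure


def test_cross_language_pair_count(null_beta_sets):
    cn = null_beta_sets[("chinese", "perception")]
    es = null_beta_sets[("spanish", "perception")]
    assert sl.n_cross_language_pairs(cn, es) == 84 * 84 == 7056


def test_cross_language_matches_nested_loop_oracle(small_beta_sets):
    betas, _ = small_beta_sets
    cn = betas[("chinese", "perception")]
    es = betas[("spanish", "perception")]
    nb = sl.build_neighborhoods(cn.mask, k=125)[40]
    z = sl.cross_language_similarity(cn, es, nb)
    mean_r = cross_language_mean_r_oracle(cn.betas[:, nb.positions], es.betas[:, nb.positions])
    assert z == pytest.approx(fisher_z_oracle(mean_r), abs=1e-12)


def test_cross_language_identical_sets_equal_full_matrix_mean():
    rng = np.random.default_rng(4)
    arr = rng.normal(size=(12, 27))
    a = _beta_set(arr, language="chinese")
    b = _beta_set(arr.copy(), language="spanish")
    nb = sl.build_neighborhoods(np.ones((3, 3, 3), dtype=bool), k=27)[0]
    z = sl.cross_language_similarity(a, b, nb)
    full = np.corrcoef(arr)
    assert z == pytest.approx(fisher_z_oracle(full.mean()), abs=1e-12)


def test_orthogonal_zero_mean_patterns_give_zero():
    # rows orthogonal to each other and to the constant vector: QR columns
    # after the leading ones column are zero-sum and mutually orthogonal
    n = 8
    helm = np.linalg.qr(
        np.column_stack([np.ones(27), np.random.default_rng(6).normal(size=(27, n))])
    )[0][:, 1:].T
    a = _beta_set(helm[: n // 2], language="chinese")
    b = _beta_set(helm[n // 2 :], language="spanish")
    nb = sl.build_neighborhoods(np.ones((3, 3, 3), dtype=bool), k=27)[0]
    assert sl.cross_language_similarity(a, b, nb) == pytest.approx(0.0, abs=1e-12)


def test_cross_language_symmetry(small_beta_sets):
    betas, _ = small_beta_sets
    cn = betas[("chinese", "perception")]
    es = betas[("spanish", "perception")]
    nb = sl.build_neighborhoods(cn.mask, k=125)[100]
    assert sl.cross_language_similarity(cn, es, nb) == sl.cross_language_similarity(es, cn, nb)


def test_zero_variance_trial_counts_as_zero_correlation():
    rng = np.random.default_rng(7)
    a_arr = rng.normal(size=(6, 27))
    b_arr = rng.normal(size=(6, 27))
    a_arr[2] = 3.14  # constant pattern
    a = _beta_set(a_arr, language="chinese")
    b = _beta_set(b_arr, language="spanish")
    nb = sl.build_neighborhoods(np.ones((3, 3, 3), dtype=bool), k=27)[0]
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        z = sl.cross_language_similarity(a, b, nb)
    mean_r = cross_language_mean_r_oracle(a_arr, b_arr)
    assert z == pytest.approx(fisher_z_oracle(mean_r), abs=1e-12)


# --------------------------------------------------------- repetition measure


def test_trial_similarity_matrix_shape_and_invariants(small_beta_sets):
    betas, _ = small_beta_sets
    es = betas[("spanish", "perception")]
    nb = sl.build_neighborhoods(es.mask, k=125)[10]
    dsm = sl.trial_similarity_matrix(es, nb, "t2")
    assert dsm.values.shape == (28, 28)
    dsm.validate()
    oracle = dsm_oracle(rep_trials(es, "t2")[:, nb.positions])
    assert np.abs(dsm.values - oracle).max() < 1e-12


def test_identical_repetitions_give_perfect_spearman():
    rng = np.random.default_rng(8)
    arr = rng.normal(size=(28, 27))
    stacked = np.vstack([arr, arr, rng.normal(size=(28, 27))])
    reps = ["t1"] * 28 + ["t2"] * 28 + ["t3"] * 28
    words = [f"w{i:02d}" for i in range(28)] * 3
    bs = _beta_set(stacked, repetitions=reps, words=words)
    nb = sl.build_neighborhoods(np.ones((3, 3, 3), dtype=bool), k=27)[0]
    z = sl.repetition_similarity(bs, nb, ("t1", "t2"))
    assert z == pytest.approx(fisher_z_oracle(1.0))


def test_repetition_similarity_matches_rank_oracle(small_beta_sets):
    betas, _ = small_beta_sets
    es = betas[("spanish", "production")]
    nb = sl.build_neighborhoods(es.mask, k=125)[77]
    for pair in (("t1", "t2"), ("t2", "t3"), ("t1", "t3")):
        z = sl.repetition_similarity(es, nb, pair)
        rho = repetition_rho_oracle(
            rep_trials(es, pair[0])[:, nb.positions], rep_trials(es, pair[1])[:, nb.positions]
        )
        assert z == pytest.approx(fisher_z_oracle(rho), abs=1e-12)


def test_missing_repetition_raises():
    rng = np.random.default_rng(9)
    arr = rng.normal(size=(28, 27))
    bs = _beta_set(arr, repetitions=["t1"] * 28, words=[f"w{i}" for i in range(28)])
    nb = sl.build_neighborhoods(np.ones((3, 3, 3), dtype=bool), k=27)[0]
    with pytest.raises(ValueError):
        sl.repetition_similarity(bs, nb, ("t1", "t2"))


# -------------------------------------------------------------- whole searchlight


def test_searchlight_matches_per_voxel_oracle(small_beta_sets):
    """Vectorized maps equal naive per-voxel recomputation on a 6x6x6 grid."""
    betas, _ = small_beta_sets
    cn = betas[("chinese", "perception")]
    es = betas[("spanish", "perception")]
    mask = cn.mask
    nbs = sl.build_neighborhoods(mask, k=125)

    zmap = sl.run_searchlight({"chinese": cn, "spanish": es}, mask, "cross_language", neighborhoods=nbs)
    # independent oracle: numpy corrcoef over the stacked trials per voxel
    for nb in nbs[::23]:
        c = np.corrcoef(np.vstack([cn.betas[:, nb.positions], es.betas[:, nb.positions]]))
        mean_r = c[:84, 84:].mean()
        assert zmap.values.ravel()[nb.center] == pytest.approx(fisher_z_oracle(mean_r), abs=1e-10)

    rmap = sl.run_searchlight(es, mask, "rep_t1t3", neighborhoods=nbs)
    for nb in nbs[::23]:
        rho = repetition_rho_oracle(
            rep_trials(es, "t1")[:, nb.positions], rep_trials(es, "t3")[:, nb.positions]
        )
        assert rmap.values.ravel()[nb.center] == pytest.approx(fisher_z_oracle(rho), abs=1e-10)


def test_constant_trials_give_spatially_constant_map():
    rng = np.random.default_rng(10)
    pattern = rng.normal(size=216)
    arr = np.tile(pattern, (84, 1))
    reps = (["t1"] * 28 + ["t2"] * 28 + ["t3"] * 28)
    words = [f"w{i:02d}" for i in range(28)] * 3
    cn = _beta_set(arr, repetitions=reps, words=words, language="chinese")
    es = _beta_set(arr.copy(), repetitions=reps, words=words, language="spanish")
    mask = np.ones(GRID, dtype=bool)
    zmap = sl.run_searchlight({"chinese": cn, "spanish": es}, mask, "cross_language", k=27)
    assert np.ptp(zmap.values) == pytest.approx(0.0, abs=1e-9)
    assert zmap.values.ravel()[0] == pytest.approx(fisher_z_oracle(1.0))


def test_cross_language_invariant_to_trial_order(small_beta_sets):
    """The all-pairs cross-language mean does not depend on trial labels:
    every one of the 7056 pairs enters the average regardless of order."""
    betas, _ = small_beta_sets
    cn = betas[("chinese", "perception")]
    es = betas[("spanish", "perception")]
    nb = sl.build_neighborhoods(cn.mask, k=125)[40]
    z = sl.cross_language_similarity(cn, es, nb)
    perm = np.random.default_rng(11).permutation(es.betas.shape[0])
    shuffled = TrialBetaSet(betas=es.betas[perm], meta=es.meta, mask=es.mask, affine=es.affine)
    assert sl.cross_language_similarity(cn, shuffled, nb) == pytest.approx(z, abs=1e-10)


def test_word_shuffle_destroys_repetition_similarity(small_beta_sets):
    """Permutation null: breaking the word alignment between repetitions
    drives the DSM Spearman similarity to zero on average."""
    betas, _ = small_beta_sets
    es = betas[("spanish", "perception")]
    nb = sl.build_neighborhoods(es.mask, k=125)[40]
    observed = sl.repetition_similarity(es, nb, ("t1", "t2"))
    t1 = rep_trials(es, "t1")[:, nb.positions]
    t2 = rep_trials(es, "t2")[:, nb.positions]
    rng = np.random.default_rng(11)
    zs = []
    for _ in range(200):
        rho = repetition_rho_oracle(t1, t2[rng.permutation(28)])
        zs.append(fisher_z_oracle(rho))
    sem = np.std(zs) / np.sqrt(len(zs))
    assert abs(np.mean(zs)) < 3 * sem + 1e-3
    assert observed > np.mean(zs) + 2 * np.std(zs)


def test_recovered_z_monotone_in_generative_rho():
    """Mean region z increases strictly with the planted cross-language rho."""
    grid = (8, 8, 8)
    region = np.zeros(grid, dtype=bool)
    region[2:6, 2:6, 2:6] = True
    mask = np.ones(grid, dtype=bool)
    nbs = sl.build_neighborhoods(mask, k=125)
    d_cn = generate_design("s", "chinese", 1, grid_shape=grid)
    d_es = generate_design("s", "spanish", 2, grid_shape=grid)
    means = []
    for rho in (0.0, 0.3, 0.6, 0.9):
        vals = []
        for seed in range(10):
            gt = GroundTruth(
                group="x", region_masks={"r": region},
                rho_cross_language={"r": rho}, rho_repetition={"r": max(rho, 0.9)},
                seed=seed,
            )
            betas = simulate_trial_betas(
                gt, d_cn, d_es, rng=np.random.default_rng(1000 + seed),
                phases=("perception",), dtype=np.float32,
            )
            zmap = sl.run_searchlight(
                {"chinese": betas[("chinese", "perception")], "spanish": betas[("spanish", "perception")]},
                mask, "cross_language", neighborhoods=nbs,
            )
            vals.append(zmap.values[region].mean())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2] < means[3]


def test_searchlight_map_io(tmp_path, small_beta_sets):
    import json

    import nibabel as nib

    betas, _ = small_beta_sets
    es = betas[("spanish", "perception")]
    zmap = sl.run_searchlight(es, es.mask, "rep_t1t2", k=27)
    nii, sidecar = tmp_path / "z.nii", tmp_path / "z.json"
    zmap.save(nii, sidecar)
    back = np.asarray(nib.load(str(nii)).dataobj)
    assert np.allclose(back, zmap.values)
    meta = json.loads(sidecar.read_text())
    assert meta["measure"] == "rep_t1t2" and meta["language"] == "spanish"
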
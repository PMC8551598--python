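"""PLS regression, CV model selection, permutation and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes

from behconn import pls as P


def make_design(rng, n=80, p=36, n_groups=4, signal=0.0, with_cov=True):
    groups = np.repeat(np.arange(n_groups), n // n_groups)
    x = rng.standard_normal((n, p))
    if signal:
        for g in range(n_groups):
            x[groups == g, g % p] += signal * (g + 1)
    y = np.eye(n_groups)[groups]
    cov = rng.standard_normal((n, 4)) if with_cov else None
    return P.DesignMatrices(x=x, y=y, groups=groups,
                            group_names=[f"g{i}" for i in range(n_groups)],
                            covariates=cov,
                            feature_names=[f"f{i}" for i in range(p)])


# ---------------------------------------------------------------- design

def test_build_design_one_hot_and_preprocessing(rng):
    feats = pd.DataFrame(rng.standard_normal((40, 6)),
                         index=[f"S{i}" for i in range(40)],
                         columns=[f"f{i}" for i in range(6)])
    groups = pd.Series(np.repeat(["comparison", "C1", "C2", "C3"], 10),
                       index=feats.index)
    covs = pd.DataFrame(rng.standard_normal((40, 4)), index=feats.index,
                        columns=["age", "sex", "mean_fd", "mean_fc"])
    d = P.build_design(feats, groups, covs,
                       group_order=["comparison", "C1", "C2", "C3"])
    assert d.y.shape == (40, 4)
    assert np.allclose(d.y.sum(axis=1), 1.0)
    prep = P.Preprocessor().fit(d.x, d.covariates)
    xt = prep.transform(d.x, d.covariates)
    assert np.allclose(xt.mean(axis=0), 0, atol=1e-8)
    assert np.allclose(xt.std(axis=0), 1, atol=1e-8)
    # residualised columns orthogonal to every covariate
    assert np.abs((xt * prep.sd).T @ d.covariates).max() < 1e-8


def test_single_response_perfect_signal(rng):
    # uncorrelated zero-mean predictors: one component captures y = x0 exactly
    a = rng.standard_normal((30, 8))
    x, _ = np.linalg.qr(a - a.mean(axis=0))
    y = x[:, [0]].copy()
    m = P.fit_pls(x, y, 1)
    assert np.abs(m.predict(x) - y).max() < 1e-8


def test_full_rank_pls_equals_least_squares(rng):
    x = rng.standard_normal((30, 10))
    y = rng.standard_normal((30, 4))
    m = P.fit_pls(x, y, 10)
    z = np.column_stack([np.ones(30), x])
    ols = z @ np.linalg.lstsq(z, y, rcond=None)[0]
    assert np.abs(m.predict(x) - ols).max() < 1e-6


def test_score_orthogonality(rng):
    x = rng.standard_normal((30, 10))
    y = rng.standard_normal((30, 3))
    t = P.fit_pls(x, y, 5).x_scores
    gram = t.T @ t
    assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-8


def test_matches_sklearn_pls(rng):
    from sklearn.cross_decomposition import PLSRegression
    x = rng.standard_normal((50, 12))
    y = rng.standard_normal((50, 4))
    ours = P.fit_pls(x, y, 3).predict(x)
    theirs = PLSRegression(n_components=3, scale=False).fit(x, y).predict(x)
    assert np.abs(ours - theirs).max() < 1e-3


def test_k_beyond_rank_rejected(rng):
    x = rng.standard_normal((10, 4))
    y = rng.standard_normal((10, 2))
    with pytest.raises(ValueError):
        P.fit_pls(x, y, 8)


# ---------------------------------------------------------------- CV

def test_constant_predictor_casewise_rmse():
    assert P.constant_predictor_rmse(4) == pytest.approx(np.sqrt(0.1875))
    y = np.eye(4)
    pred = np.full((4, 4), 0.25)
    assert np.allclose(P.casewise_rmse(y, pred), np.sqrt(0.1875))


def test_cv_perfect_separation_low_rmse(rng):
    d = make_design(rng, n=80, signal=5.0)
    cv = P.cross_validate(d, k_max=4, repeats=2, seed=0)
    best = min(cv.values(), key=lambda c: c.mean_rmse)
    assert best.mean_rmse < 0.25
    assert best.mean_accuracy > 0.9


def test_cv_null_accuracy_near_chance(rng):
    accs = []
    for s in range(5):
        d = make_design(rng, n=80, signal=0.0)
        cv = P.cross_validate(d, k_max=2, repeats=2, seed=s)
        accs.append(cv[2].mean_accuracy)
    assert abs(np.mean(accs) - 0.25) < 0.08


def test_no_leakage_from_test_subjects(rng):
    d = make_design(rng, n=40, p=6)
    train = np.arange(30)
    prep = P.Preprocessor().fit(d.x[train], d.covariates[train])
    x2 = d.x.copy()
    x2[35] += 100.0  # perturb a held-out subject
    prep2 = P.Preprocessor().fit(x2[train], d.covariates[train])
    assert np.array_equal(prep.mean, prep2.mean)
    assert np.array_equal(prep.sd, prep2.sd)
    assert np.array_equal(prep.coef, prep2.coef)


# ---------------------------------------------------------------- selection

def test_one_se_rule_arithmetic():
    def cvres(k, rmse, sem):
        # two fold values with the requested mean and SEM
        d = sem * np.sqrt(2) / np.sqrt(2)  # sd = sem*sqrt(n), n=2
        vals = np.array([rmse - d, rmse + d])
        return P.CVResult(k=k, fold_rmse=vals, fold_accuracy=vals)

    cv = {1: cvres(1, 0.50, 0.02), 2: cvres(2, 0.466, 0.02),
          3: cvres(3, 0.465, 0.02)}
    assert P.select_components(cv) == 2
    flat = {k: cvres(k, 0.5, 0.001) for k in (1, 2, 3)}
    assert P.select_components(flat) == 1
    steep = {1: cvres(1, 0.9, 1e-6), 2: cvres(2, 0.5, 1e-6),
             3: cvres(3, 0.2, 1e-6)}
    assert P.select_components(steep) == 3


# ---------------------------------------------------------------- permutation

def test_permutation_extreme_signal_minimal_p(rng):
    d = make_design(rng, n=60, p=10, signal=6.0)
    res = P.permutation_test(d, 2, n_perm=19, repeats=1, seed=0)
    assert res.p == pytest.approx(1 / 20)
    assert res.observed < res.null.min()


def test_permutation_p_definition(rng):
    d = make_design(rng, n=40, p=8, signal=0.0)
    res = P.permutation_test(d, 1, n_perm=19, repeats=1, seed=1)
    expected = (1 + (res.null <= res.observed).sum()) / 20
    assert res.p == pytest.approx(expected)


def test_auc_permutation_variant(rng):
    designs = {c: make_design(np.random.default_rng(int(c * 100)), n=40, p=8,
                              signal=4.0) for c in (0.1, 0.2, 0.3)}
    res = P.permutation_test_auc(designs, 2, n_perm=9, repeats=1, seed=2)
    assert 0 < res.p <= 1
    assert res.observed < np.median(res.null)


# ---------------------------------------------------------------- bootstrap

def test_procrustes_identity_fixed_point(rng):
    ref = rng.standard_normal((10, 3))
    rot, _ = orthogonal_procrustes(ref, ref)
    assert np.allclose(rot, np.eye(3), atol=1e-10)


def test_procrustes_repairs_sign_flip_and_order():
    rng = np.random.default_rng(0)
    ref = rng.standard_normal((12, 3))
    flip = ref[:, [1, 0, 2]] * np.array([1, -1, 1])
    rot, _ = orthogonal_procrustes(flip, ref)
    assert np.allclose(flip @ rot, ref, atol=1e-10)


def test_procrustes_matches_grid_search_oracle(rng):
    ref = rng.standard_normal((8, 2))
    other = rng.standard_normal((8, 2))
    rot, _ = orthogonal_procrustes(other, ref)
    best, best_err = None, np.inf
    for theta in np.linspace(0, 2 * np.pi, 20001):
        c, s = np.cos(theta), np.sin(theta)
        for refl in (1, -1):
            r = np.array([[c, -s], [s, c]]) @ np.diag([1, refl])
            err = np.linalg.norm(other @ r - ref)
            if err < best_err:
                best, best_err = r, err
    assert np.linalg.norm(other @ rot - ref) <= best_err + 1e-6
    assert np.allclose(rot, best, atol=2e-3)


def test_bootstrap_loadings_stability_ordering(rng):
    # features 0..3 carry the group signal; 30..35 are pure noise
    d = make_design(rng, n=120, p=36, signal=3.0)
    boot = P.bootstrap_loadings(d, 2, n_boot=60, seed=3)
    r = np.nanmax(np.abs(boot.ratio), axis=1)
    assert np.median(r[:4]) > np.median(r[30:])
    top = boot.top_fraction(0.25, 0)
    assert len(top) == 9


def test_score_group_test_sign_antisymmetry(rng):
    scores = rng.standard_normal((40, 2))
    groups = np.repeat([0, 1], 20)
    a = P.score_group_test(scores, groups, n_perm=49, seed=4)
    b = P.score_group_test(scores, 1 - groups, n_perm=49, seed=4)
    assert np.allclose(a["mean_diff"], -b["mean_diff"])


def test_score_group_test_planted_shift(rng):
    scores = rng.standard_normal((60, 1))
    groups = np.repeat([0, 1], 30)
    scores[groups == 1] += 3.0
    res = P.score_group_test(scores, groups, n_perm=99, seed=5)
    assert res["p"].iloc[0] == pytest.approx(1 / 100)


def test_covariate_append_mode(rng):
    feats = pd.DataFrame(rng.standard_normal((20, 5)),
                         index=[f"S{i}" for i in range(20)],
                         columns=[f"f{i}" for i in range(5)])
    groups = pd.Series(np.repeat(["a", "b"], 10), index=feats.index)
    covs = pd.DataFrame(rng.standard_normal((20, 2)), index=feats.index,
                        columns=["age", "sex"])
    d = P.build_design(feats, groups, covs, covariate_mode="append")
    assert d.covariates is None
    assert d.x.shape == (20, 7)
    assert d.feature_names[-2:] == ["age", "sex"]
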
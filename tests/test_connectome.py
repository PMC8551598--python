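"""Connectome construction, motion/FC QC, thresholding, ICN block features."""

import numpy as np
import pandas as pd
import pytest

import oracles
from behconn import connectome as cn


def make_conn(mat, icn=None, sid="S1"):
    ids = [f"R{i:03d}" for i in range(mat.shape[0])]
    icn_map = None
    if icn is not None:
        icn_map = pd.Series(icn, index=ids)
    return cn.Connectome(matrix=np.asarray(mat, float), region_ids=ids,
                         icn_map=icn_map, subject_id=sid)


# ---------------------------------------------------------------- correlation

def test_duplicated_region_correlates_perfectly(rng):
    ts = rng.standard_normal((4, 60))
    ts[1] = ts[0]
    c = cn.correlation_connectome(ts)
    assert c.matrix[0, 1] == pytest.approx(1.0)
    assert np.all(np.diag(c.matrix) == 0)


def test_orthogonal_sine_cosine_uncorrelated():
    t = np.linspace(0, 2 * np.pi, 101)[:-1]
    ts = np.vstack([np.sin(t), np.cos(t), np.sin(2 * t)])
    c = cn.correlation_connectome(ts)
    assert abs(c.matrix[0, 1]) < 1e-8


def test_correlation_matches_two_pass_oracle(rng):
    ts = rng.standard_normal((10, 50))
    c = cn.correlation_connectome(ts)
    for i in range(10):
        for j in range(i + 1, 10):
            assert c.matrix[i, j] == pytest.approx(
                oracles.pearson(ts[i], ts[j]), abs=1e-12)


def test_constant_region_rejected(rng):
    ts = rng.standard_normal((5, 30))
    ts[2] = 3.14
    with pytest.raises(ValueError, match="R002"):
        cn.correlation_connectome(ts)


# ---------------------------------------------------------------- motion QC

def test_motion_filter_rules():
    traces = pd.DataFrame({
        "high_mean": np.full(100, 0.6),
        "spiky": np.r_[np.full(25, 0.6), np.full(75, 0.1)],  # mean .225, 25% spikes
        "clean": np.r_[np.full(5, 0.6), np.full(95, 0.18)],  # 5% spikes
    })
    qc = cn.motion_filter(traces)
    assert not qc.loc["high_mean", "included"]
    assert qc.loc["high_mean", "reason"] == "mean FD"
    assert not qc.loc["spiky", "included"]
    assert qc.loc["spiky", "reason"] == "spikes"
    assert qc.loc["clean", "included"]


# ---------------------------------------------------------------- thresholding

def test_group_threshold_counting_and_mask_identity(rng):
    n = 10  # E = 45 edges; cost 0.2 -> keep 9
    stack = {}
    base = rng.uniform(0.1, 1.0, size=(n, n))
    base = (base + base.T) / 2
    np.fill_diagonal(base, 0)
    for s in range(6):
        m = base + rng.normal(0, 0.01, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        stack[f"S{s}"] = make_conn(m, sid=f"S{s}")
    thr, mask = cn.group_threshold(stack, cost=0.2)
    iu = np.triu_indices(n, 1)
    assert mask[iu].sum() == 9
    nz = {sid: set(zip(*np.nonzero(c.matrix))) for sid, c in thr.items()}
    first = next(iter(nz.values()))
    assert all(v == first for v in nz.values())  # identical edge sets
    # the retained edges are the top-9 of the group mean
    mean = np.mean([c.matrix for c in stack.values()], axis=0)
    kept = np.sort(mean[iu][mask[iu]])
    dropped = mean[iu][~mask[iu]]
    assert kept.min() >= dropped.max()


def test_negative_surviving_edge_set_to_small_positive():
    a = np.array([[0, .9, .1], [.9, 0, -.2], [.1, -.2, 0]])
    b = np.array([[0, .9, .1], [.9, 0, .9], [.1, .9, 0]])
    thr, mask = cn.group_threshold(
        {"a": make_conn(a), "b": make_conn(b)}, cost=2 / 3)
    assert mask[1, 2]
    assert thr["a"].matrix[1, 2] == pytest.approx(0.001)
    assert thr["b"].matrix[1, 2] == pytest.approx(0.9)


def test_masks_nested_across_costs(rng):
    n = 20
    stack = {}
    for s in range(4):
        m = rng.normal(0.2, 0.4, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        stack[f"S{s}"] = make_conn(m, sid=f"S{s}")
    _, m5 = cn.group_threshold(stack, cost=0.05)
    _, m30 = cn.group_threshold(stack, cost=0.30)
    assert not (m5 & ~m30).any()  # mask(5%) subset of mask(30%)


def test_group_threshold_idempotent(rng):
    n = 12
    stack = {f"S{s}": make_conn(np.abs((lambda a: (a + a.T) / 2)(
        rng.uniform(0, 1, (n, n)))), sid=f"S{s}") for s in range(3)}
    for c in stack.values():
        np.fill_diagonal(c.matrix, 0)
    thr1, mask1 = cn.group_threshold(stack, cost=0.25)
    thr2, mask2 = cn.group_threshold(thr1, cost=0.25)
    assert np.array_equal(mask1, mask2)
    for sid in stack:
        assert np.allclose(thr1[sid].matrix, thr2[sid].matrix)


def test_infeasible_cost_rejected():
    neg = -np.ones((5, 5))
    np.fill_diagonal(neg, 0)
    with pytest.raises(ValueError, match="positive"):
        cn.group_threshold({"a": make_conn(neg)}, cost=0.5)


def test_individual_threshold_density_and_normalisation(rng):
    n = 16
    m = rng.normal(0.1, 0.5, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    c = cn.individual_threshold(make_conn(m), cost=0.25)
    iu = np.triu_indices(n, 1)
    assert (c.matrix[iu] > 0).sum() == int(0.25 * len(iu[0]))
    norm = cn.normalise_to_max(c)
    assert norm.matrix.max() == pytest.approx(1.0)
    doubled = cn.normalise_to_max(
        cn.Connectome(matrix=2 * c.matrix, region_ids=c.region_ids))
    assert np.allclose(norm.matrix, doubled.matrix)  # scale invariance


# ---------------------------------------------------------------- FC outliers

def test_fc_outlier_removed_and_order_invariant(rng):
    mats = {}
    for s in range(10):
        m = rng.normal(0.2, 0.02, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        mats[f"S{s}"] = make_conn(m, sid=f"S{s}")
    out = np.full((8, 8), 0.95)
    np.fill_diagonal(out, 0)
    mats["OUT"] = make_conn(out, sid="OUT")
    res = cn.fc_outlier_filter(mats)
    assert not res.loc["OUT", "included"]
    assert res["included"].drop("OUT").all()
    shuffled = dict(reversed(list(mats.items())))
    res2 = cn.fc_outlier_filter(shuffled)
    pd.testing.assert_frame_equal(res.sort_index(), res2.sort_index())


def test_fc_outlier_all_equal_none_removed():
    m = np.full((6, 6), 0.3)
    np.fill_diagonal(m, 0)
    mats = {f"S{s}": make_conn(m, sid=f"S{s}") for s in range(5)}
    assert cn.fc_outlier_filter(mats)["included"].all()


# ---------------------------------------------------------------- ICN features

def test_icn_features_count_and_uniform_weight(rng):
    labels = ["visual", "somatomotor", "dorsal_attention", "ventral_attention",
              "fronto_parietal", "default_mode", "limbic", "subcortical"]
    icn = [lab for lab in labels for _ in range(3)]
    w = np.full((24, 24), 0.5)
    np.fill_diagonal(w, 0)
    feats = cn.icn_features(make_conn(w, icn=icn), labels)
    assert len(feats) == 36  # 8 within + C(8,2) between
    assert np.allclose(feats, 0.5)


def test_icn_features_match_hand_computation():
    # 6 nodes, 2 ICNs (A: 0-2, B: 3-5)
    w = np.zeros((6, 6))
    w[0, 1] = w[1, 0] = 0.8
    w[0, 2] = w[2, 0] = 0.4          # within A: mean 0.6
    w[3, 4] = w[4, 3] = 0.2          # within B: mean 0.2
    w[2, 3] = w[3, 2] = 0.5
    w[1, 4] = w[4, 1] = 0.7          # between: mean 0.6
    feats = cn.icn_features(make_conn(w, icn=["A"] * 3 + ["B"] * 3), ["A", "B"])
    assert feats["within_A"] == pytest.approx(0.6)
    assert feats["within_B"] == pytest.approx(0.2)
    assert feats["between_A_B"] == pytest.approx(0.6)


def test_icn_empty_block_is_zero():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    feats = cn.icn_features(make_conn(w, icn=["A", "A", "B", "B"]), ["A", "B"])
    assert feats["within_B"] == 0.0
    assert feats["between_A_B"] == 0.0


def test_cost_basis_positive_subset(rng):
    n = 12
    m = rng.normal(0.0, 0.5, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    conn = make_conn(m)
    iu = np.triu_indices(n, 1)
    n_pos = int((m[iu] > 0).sum())
    c_all = cn.individual_threshold(conn, cost=0.25, cost_basis="all")
    c_pos = cn.individual_threshold(conn, cost=0.25, cost_basis="positive")
    assert (c_all.matrix[iu] > 0).sum() == int(0.25 * len(iu[0]))
    assert (c_pos.matrix[iu] > 0).sum() == int(0.25 * n_pos)
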
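"""Weighted graph metrics vs brute-force oracles; nulls; AUC."""

import numpy as np
import pytest

import oracles
from behconn import graphmetrics as gm


def test_star_graph_betweenness():
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    nm = gm.nodal_metrics(w, np.zeros(5, int))
    assert nm["betweenness"].iloc[0] == 6.0  # C(4,2) leaf pairs
    assert (nm["betweenness"].iloc[1:] == 0).all()


def test_chain_path_length():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    assert gm.global_metrics(w)["path_length"] == pytest.approx(4 / 3)


def test_complete_graph_unit_metrics():
    w = np.ones((5, 5))
    np.fill_diagonal(w, 0)
    g = gm.global_metrics(w)
    assert g["path_length"] == 1.0
    assert g["global_efficiency"] == 1.0
    assert g["clustering"] == 1.0


def test_participation_formula_limits():
    # node 0: all edges in own module -> 0; node 3: split across 2 modules -> .5
    w = np.zeros((6, 6))
    w[0, 1] = w[1, 0] = w[0, 2] = w[2, 0] = 1.0
    w[3, 2] = w[2, 3] = w[3, 4] = w[4, 3] = 1.0
    modules = np.array([0, 0, 0, 1, 1, 1])
    p = gm.participation_coefficient(w, modules)
    assert p[0] == 0.0
    assert p[3] == pytest.approx(0.5)
    m = len(np.unique(modules))
    assert np.all(p <= 1 - 1 / m + 1e-12)


def test_strength_partition_bookkeeping(rng):
    w = np.abs(rng.normal(size=(12, 12)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    modules = rng.integers(0, 3, size=12)
    from behconn.graphmetrics import _module_strengths
    ks = _module_strengths(w, modules)
    assert np.allclose(ks.sum(axis=1), w.sum(axis=1))


def test_assortativity_degenerate_is_nan():
    w = np.ones((4, 4))
    np.fill_diagonal(w, 0)
    with pytest.warns(UserWarning, match="assortativity"):
        assert np.isnan(gm.assortativity(w))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_metrics_match_bruteforce_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    w = oracles.random_connected_graph(7, rng)
    modules = rng.integers(0, 3, size=7)
    nm = gm.nodal_metrics(w, modules)
    assert np.allclose(nm["strength"], oracles.strength(w), atol=1e-9)
    assert np.allclose(nm["betweenness"], oracles.betweenness(w), atol=1e-9)
    assert np.allclose(nm["clustering"], oracles.onnela_clustering(w), atol=1e-9)
    assert np.allclose(nm["participation"], oracles.participation(w, modules),
                       atol=1e-9)
    assert np.allclose(nm["within_module_z"],
                       oracles.within_module_z(w, modules), atol=1e-9)
    assert np.allclose(nm["local_efficiency"],
                       oracles.local_efficiency_nodal(w), atol=1e-9)
    g = gm.global_metrics(w)
    assert g["path_length"] == pytest.approx(oracles.char_path_length(w), abs=1e-9)
    assert g["global_efficiency"] == pytest.approx(
        oracles.global_efficiency(w), abs=1e-9)
    assert g["assortativity"] == pytest.approx(oracles.assortativity(w), abs=1e-9)


def test_betweenness_invariant_to_weight_scaling(rng):
    w = oracles.random_connected_graph(8, rng)
    nm1 = gm.nodal_metrics(w, np.zeros(8, int))
    nm2 = gm.nodal_metrics(3.7 * w, np.zeros(8, int))
    assert np.allclose(nm1["betweenness"], nm2["betweenness"])


def test_rewiring_preserves_degree_and_weights(rng):
    w = oracles.random_connected_graph(30, rng, density=0.3)
    wn = gm.rewire_preserving(w, swaps_per_edge=10, seed=3)
    assert np.array_equal((wn > 0).sum(axis=0), (w > 0).sum(axis=0))
    iu = np.triu_indices(30, 1)
    assert np.allclose(np.sort(wn[iu][wn[iu] > 0]),
                       np.sort(w[iu][w[iu] > 0]))
    assert not np.array_equal(wn, w)  # actually rewired


def test_normalising_null_by_own_ensemble_near_one(rng):
    w = oracles.random_connected_graph(40, rng, density=0.25)
    nulls = gm.null_ensemble(w, n_nulls=20, seed=4)
    raw = gm.global_metrics(gm.rewire_preserving(w, seed=5))
    norm = gm.normalise_metrics(raw, nulls)
    assert norm["clustering"] == pytest.approx(1.0, rel=0.2)
    assert norm["path_length"] == pytest.approx(1.0, rel=0.1)


def test_normalised_smallworldness_identity(rng):
    w = oracles.random_connected_graph(25, rng, density=0.3)
    nulls = gm.null_ensemble(w, n_nulls=10, seed=6)
    norm = gm.normalise_metrics(gm.global_metrics(w), nulls)
    assert norm["small_worldness"] == pytest.approx(
        norm["clustering"] / norm["path_length"], abs=1e-12)
    assert norm["strength"] == norm["raw_strength"]  # not normalised
    assert norm["modularity"] == norm["raw_modularity"]


def test_lattice_clustering_above_random(rng):
    # ring lattice with neighbours 1, 2: high clustering vs rewired nulls
    n = 30
    w = np.zeros((n, n))
    for i in range(n):
        for d in (1, 2):
            w[i, (i + d) % n] = w[(i + d) % n, i] = 1.0 + 0.01 * ((i + d) % 7)
    nulls = gm.null_ensemble(w, n_nulls=10, seed=7)
    norm = gm.normalise_metrics(gm.global_metrics(w), nulls)
    assert norm["clustering"] > 1.0


def test_auc_over_costs_examples():
    costs = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
    assert gm.auc_over_costs(np.full(6, 2.0), costs) == pytest.approx(0.5)
    ramp = np.linspace(0, 1, 6)
    assert gm.auc_over_costs(ramp, costs) == pytest.approx(0.125)
    quad = 3 * costs**2 - costs + 0.2
    assert gm.auc_over_costs(quad, costs) == pytest.approx(
        oracles.trapezoid(quad, costs), abs=1e-12)
    with pytest.raises(ValueError):
        gm.auc_over_costs(np.ones(1), costs[:1])


def test_strength_preserving_null_tracks_strengths(rng):
    w = oracles.random_connected_graph(40, rng, density=0.3)
    w *= rng.uniform(0.5, 3.0, size=w.shape[0])[:, None]  # heterogeneous
    w = (w + w.T) / 2
    s = w.sum(axis=1)
    from behconn.graphmetrics import rewire_preserving, _reassign_weights_by_strength
    corr_deg, corr_str = [], []
    for seed in range(5):
        wn = rewire_preserving(w, seed=seed)
        ws = _reassign_weights_by_strength(wn, s)
        iu = np.triu_indices(40, 1)
        # weight multiset and degrees still exact
        assert np.allclose(np.sort(ws[iu][ws[iu] > 0]),
                           np.sort(w[iu][w[iu] > 0]))
        assert np.array_equal((ws > 0).sum(0), (w > 0).sum(0))
        corr_deg.append(np.corrcoef(s, wn.sum(axis=1))[0, 1])
        corr_str.append(np.corrcoef(s, ws.sum(axis=1))[0, 1])
    assert np.mean(corr_str) > np.mean(corr_deg)
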
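"""Cross-condition edge correlations, multilayer assembly, graph tests."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as cc_oracle

from statenet import (
    ContrastDesign,
    MultilayerGraph,
    MultilayerGroupContrast,
    MultilayerOneSampleTest,
    MultilinkMatrix,
    assemble_multilayer,
    between_block_node_degree,
    common_links,
    condition_mean_z,
    edge_condition_correlation,
    group_difference_graph_test,
    group_one_sample_graph_test,
    multilink_components,
)


def random_condition_net(rng, n, condition):
    m = rng.normal(size=(n, n))
    np.fill_diagonal(m, 0.0)
    return condition_mean_z([m], subject="s", condition=condition)


def test_identical_trials_give_unit_correlations(rng):
    trials = rng.normal(size=(20, 5, 5))
    for t in trials:
        np.fill_diagonal(t, 0.0)
    ml = edge_condition_correlation(trials, trials.copy(), pair=("a", "b"), alpha=0.05)
    off = ~np.eye(5, dtype=bool)
    assert np.allclose(ml.matrix[off], 1.0)
    assert np.all(np.diag(ml.matrix) == 0)


def test_correlation_calibration_under_independence(rng):
    """Fraction of retained entries matches the per-edge alpha level."""
    fracs = []
    for _ in range(50):
        a = rng.normal(size=(60, 20, 20))
        b = rng.normal(size=(60, 20, 20))
        ml = edge_condition_correlation(a, b, pair=("a", "b"), alpha=0.05)
        off = ~np.eye(20, dtype=bool)
        fracs.append((ml.matrix[off] != 0).mean())
    mean = np.mean(fracs)
    se = np.sqrt(0.05 * 0.95 / (50 * 380))
    assert abs(mean - 0.05) < 4 * se


def test_planted_shared_modulation_has_largest_correlations(rng):
    """Edges whose trial series share a latent modulation across conditions
    out-correlate independent edges."""
    n_trials, n = 60, 10
    planted = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]
    a = rng.normal(size=(n_trials, n, n))
    b = rng.normal(size=(n_trials, n, n))
    u = rng.normal(size=(n_trials, len(planted)))
    for k, (i, j) in enumerate(planted):
        a[:, i, j] += 2.0 * u[:, k]
        b[:, i, j] += 2.0 * u[:, k]
    ml = edge_condition_correlation(a, b, pair=("a", "b"), alpha=0.05)
    order = np.dstack(np.unravel_index(np.argsort(np.abs(ml.matrix), axis=None), ml.matrix.shape))[0]
    top5 = {tuple(map(int, e)) for e in order[-5:]}
    assert top5 == set(planted)


def test_correlation_input_validation(rng):
    a = rng.normal(size=(3, 4, 4))
    with pytest.raises(ValueError):
        edge_condition_correlation(a, a, alpha=0.05)  # too few trials
    b = rng.normal(size=(10, 4, 4))
    with pytest.raises(ValueError):
        edge_condition_correlation(b, b, alpha=1.5)
    with pytest.raises(ValueError):
        edge_condition_correlation(b, b, pairing="sorted")
    const = np.ones((10, 4, 4))
    with pytest.warns(RuntimeWarning):
        ml = edge_condition_correlation(const, const, alpha=0.05)
    assert np.all(ml.matrix == 0)


def test_random_pairing_is_seeded(rng):
    a = rng.normal(size=(12, 4, 4))
    b = rng.normal(size=(12, 4, 4))
    m1 = edge_condition_correlation(a, b, pairing="random", seed=5).matrix
    m2 = edge_condition_correlation(a, b, pairing="random", seed=5).matrix
    np.testing.assert_array_equal(m1, m2)


def test_assemble_structure_and_mirroring(rng):
    nets = [random_condition_net(rng, 3, c) for c in ("standard", "auditory")]
    pair = MultilinkMatrix(np.array([[0, 0.5, 0], [0, 0, -0.7], [0.2, 0, 0]]), ("standard", "auditory"), 0.05, 10)
    g = assemble_multilayer(nets, [pair], subject="s1")
    assert g.side == 6
    np.testing.assert_array_equal(g.block("standard", "auditory"), pair.matrix)
    np.testing.assert_array_equal(g.block("auditory", "standard"), pair.matrix)
    np.testing.assert_array_equal(g.block("standard", "standard"), nets[0].matrix)


def test_assemble_full_study_dimension(rng):
    conditions = ("standard", "audiovisual", "auditory", "visual")
    nets = [random_condition_net(rng, 360, c) for c in conditions]
    zeros = np.zeros((360, 360))
    pairs = [
        MultilinkMatrix(zeros, (a, b), 0.05, 10)
        for i, a in enumerate(conditions)
        for b in conditions[i + 1 :]
    ]
    g = assemble_multilayer(nets, pairs)
    assert g.matrix.shape == (1440, 1440)


def test_assemble_missing_pair_rejected(rng):
    nets = [random_condition_net(rng, 3, c) for c in ("a", "b", "c")]
    pair = MultilinkMatrix(np.zeros((3, 3)), ("a", "b"), 0.05, 10)
    with pytest.raises(ValueError, match="missing"):
        assemble_multilayer(nets, [pair])


def test_multilayer_roundtrip(tmp_path, rng):
    nets = [random_condition_net(rng, 4, c) for c in ("a", "b")]
    pair = MultilinkMatrix(np.zeros((4, 4)), ("a", "b"), 0.05, 12)
    g = assemble_multilayer(nets, [pair], subject="s7")
    g.write(tmp_path / "g")
    back = MultilayerGraph.read(tmp_path / "g")
    np.testing.assert_array_equal(back.matrix, g.matrix)
    assert back.states == g.states and back.subject == "s7"


def _graphs_from(matrices, states=("a", "b"), n=3):
    return [MultilayerGraph(m, states=states, n_nodes=n) for m in matrices]


def test_one_sample_graph_test_trivial_and_planted(rng):
    side = 6
    zeros = _graphs_from(np.zeros((5, side, side)))
    res = MultilayerOneSampleTest(zeros).fit(n_permutations=200, q=0.05, seed=0)
    assert res.n_edges == 0
    mats = rng.normal(size=(10, side, side)) * 0.3
    mats[:, 1, 4] += 3.0
    res = MultilayerOneSampleTest(_graphs_from(mats)).fit(n_permutations=1000, q=0.05, seed=0)
    assert (1, 4) in set(zip(res.edges["source"], res.edges["target"]))
    res2 = group_one_sample_graph_test(
        _graphs_from(mats), ContrastDesign(scheme="one_sample", n_permutations=1000, q=0.05, seed=0)
    )
    assert res.edges.equals(res2.edges)


def test_group_difference_split_by_sign(rng):
    side = 6
    a = rng.normal(size=(8, side, side)) * 0.2
    b = rng.normal(size=(8, side, side)) * 0.2
    a[:, 0, 4] += 3.0  # A > B
    b[:, 2, 5] += 3.0  # B > A
    res_ab, res_ba = MultilayerGroupContrast(_graphs_from(a), _graphs_from(b)).fit(
        n_permutations=1000, q=0.05, seed=1
    )
    assert (0, 4) in set(zip(res_ab.edges["source"], res_ab.edges["target"]))
    assert (2, 5) in set(zip(res_ba.edges["source"], res_ba.edges["target"]))
    # identical groups -> both contrasts empty
    e_ab, e_ba = group_difference_graph_test(
        _graphs_from(a), _graphs_from(a.copy()), ContrastDesign(scheme="two_sample", n_permutations=200, q=0.05)
    )
    assert e_ab.n_edges == 0 and e_ba.n_edges == 0


def test_between_block_node_degree(rng):
    side = 6
    mats = np.zeros((5, side, side))
    mats[:, 0, 4] = 5.0 + 0.1 * rng.normal(size=5)  # block (a, b), regions 0 -> 1
    res = MultilayerOneSampleTest(_graphs_from(mats)).fit(n_permutations=1000, q=0.05, seed=0)
    deg = between_block_node_degree(res, ("a", "b"))
    assert deg[0] == 1 and deg[1] == 1 and deg[2] == 0
    assert deg.sum() == 2 * 1
    with pytest.raises(KeyError):
        between_block_node_degree(res, ("a", "z"))


def test_multilink_components_against_sparse_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(3, 12))
        mask = rng.uniform(size=(n, n)) < 0.15
        np.fill_diagonal(mask, False)
        comps = multilink_components(mask)
        sym = mask | mask.T
        n_cc, labels = cc_oracle(coo_matrix(sym), directed=False)
        involved = sorted(np.nonzero(sym.any(axis=0) | sym.any(axis=1))[0])
        oracle_parts = {}
        for node in involved:
            oracle_parts.setdefault(labels[node], set()).add(node)
        assert sorted(map(sorted, (c[0] for c in comps))) == sorted(map(sorted, oracle_parts.values()))
    assert multilink_components(np.zeros((4, 4))) == []
    two = np.zeros((6, 6))
    two[1, 2] = 1.0
    two[3, 4] = -0.5
    assert len(multilink_components(two)) == 2


def test_common_links(rng):
    a = rng.uniform(size=(5, 5)) < 0.4
    b = rng.uniform(size=(5, 5)) < 0.4
    c = rng.uniform(size=(5, 5)) < 0.4
    out = common_links([a, b, c])
    np.testing.assert_array_equal(out, a & b & c)
    np.testing.assert_array_equal(common_links([a, a]), a)
    assert not common_links([a, ~a]).any()
    with pytest.raises(ValueError):
        common_links([a, np.zeros((4, 4))])
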
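"""Edge-wise statistics, permutation p-values, FDR, network summaries."""

import itertools

import numpy as np
import pytest

from statenet import (
    ContrastDesign,
    GroupInteractionContrast,
    PairedEdgeContrast,
    fdr_bh,
    interaction_edge_stats,
    paired_edge_stats,
    permutation_pvalues,
    significant_network,
)


def bh_oracle(pvals, q):
    """Literal step-up definition: largest i with p_(i) <= i*q/m."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = p.size
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    mask = np.zeros(m, bool)
    mask[order[:k]] = True
    return mask


def exhaustive_signflip_p(x):
    """Exact sign-flip p-values for a small (n, E) sample, centered null."""
    n, E = x.shape
    mean = x.mean(0)
    sd = x.std(0, ddof=1)
    t_obs = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    xc = x - mean
    count = np.zeros(E)
    total = 0
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        s = np.array(signs)[:, None] * xc
        m = s.mean(0)
        v = s.std(0, ddof=1)
        t = np.where(v > 0, m / (v / np.sqrt(n)), 0.0)
        count += np.abs(t) >= np.abs(t_obs) - 1e-12
        total += 1
    return count / total


def test_paired_stats_trivial_and_f_identity(rng):
    mats = rng.normal(size=(6, 5, 5))
    t, f = paired_edge_stats(mats, mats)
    assert np.all(t == 0)
    dev = mats + rng.normal(size=mats.shape)
    t, f = paired_edge_stats(mats, dev)
    np.testing.assert_allclose(f, t**2)


def test_paired_planted_shift_attains_max(rng):
    """A 1-SD mean shift on one edge is usually the strongest edge statistic
    (rate frozen from an oracle simulation of the same design)."""
    hits = 0
    n_sim = 100
    for _ in range(n_sim):
        std = np.zeros((13, 6, 6))
        diff = rng.normal(size=(13, 6, 6))
        diff[:, 1, 2] += 1.0
        t, _ = paired_edge_stats(std, std + diff)
        off = ~np.eye(6, dtype=bool)
        hits += np.abs(t[1, 2]) == np.abs(t[off]).max()
    assert hits / n_sim >= 0.70


def test_interaction_stats_properties(rng):
    a = rng.normal(size=(8, 4, 4))
    t_same, _ = interaction_edge_stats(a, a.copy())
    assert np.all(t_same == 0)
    b = rng.normal(size=(7, 4, 4))
    t_ab, f_ab = interaction_edge_stats(a, b)
    t_ba, f_ba = interaction_edge_stats(b, a)
    np.testing.assert_allclose(t_ab, -t_ba)
    np.testing.assert_allclose(f_ab, f_ba)


def test_interaction_planted_group_difference(rng):
    hits = 0
    for _ in range(100):
        a = rng.normal(size=(13, 6, 6))
        b = rng.normal(size=(12, 6, 6))
        a[:, 2, 3] += 1.5
        t, _ = interaction_edge_stats(a, b)
        off = ~np.eye(6, dtype=bool)
        hits += np.abs(t[2, 3]) == np.abs(t[off]).max()
    assert hits / 100 >= 0.70


def test_permutation_pvalues_bounds_and_determinism(rng):
    x = rng.normal(size=(10, 9))
    x[:, 0] += 50.0  # unbeatable effect
    design = ContrastDesign(scheme="one_sample", n_permutations=500, q=0.05, seed=3)
    t = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(10))
    p = permutation_pvalues(t, x, design)
    assert p[0] == pytest.approx(1.0 / 501.0)
    assert np.all((p > 0) & (p <= 1))
    p2 = permutation_pvalues(t, x, design)
    np.testing.assert_array_equal(p, p2)


def test_permutation_pvalues_invariant_to_subject_order(rng):
    x = rng.normal(size=(9, 12))
    t = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(9))
    design = ContrastDesign(scheme="one_sample", n_permutations=400, q=0.05, seed=11)
    p = permutation_pvalues(t, x, design)
    perm = rng.permutation(9)
    p_shuffled = permutation_pvalues(t, x[perm], design)
    np.testing.assert_array_equal(p, p_shuffled)


def test_permutation_pvalues_match_exhaustive_oracle(rng):
    x = rng.normal(size=(5, 6))
    x[:, 2] += 1.0
    exact = exhaustive_signflip_p(x)
    t = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(5))
    design = ContrastDesign(scheme="one_sample", n_permutations=10000, q=0.05, seed=0)
    approx = permutation_pvalues(t, x, design)
    # the +1 correction biases the sampled estimate upward by at most 1/(P+1)
    np.testing.assert_allclose(approx, exact, atol=0.02)


def test_permutation_rejects_unknown_scheme():
    with pytest.raises(ValueError):
        ContrastDesign(scheme="bootstrap")
    with pytest.raises(ValueError):
        ContrastDesign(n_permutations=50)


def test_fdr_bh_examples_and_oracle(rng):
    mask = fdr_bh(np.array([0.001, 0.02, 0.03, 0.04]), 0.05)
    assert mask.all()
    assert not fdr_bh(np.full(10, 0.9), 0.05).any()
    for _ in range(100):
        p = rng.uniform(size=rng.integers(3, 40))
        np.testing.assert_array_equal(fdr_bh(p, 0.05), bh_oracle(p, 0.05))
    with pytest.raises(ValueError):
        fdr_bh(np.array([0.5]), 1.5)
    with pytest.raises(ValueError):
        fdr_bh(np.array([1.5]), 0.05)


def test_significant_network_summaries(rng):
    n = 8
    stats = rng.normal(size=(n, n))
    pvals = rng.uniform(size=(n, n))
    empty = significant_network(stats, pvals, np.zeros((n, n), bool))
    assert empty.n_edges == 0 and empty.density == 0.0
    mask = rng.uniform(size=(n, n)) < 0.2
    net = significant_network(stats, pvals, mask)
    assert net.node_degree.sum() == 2 * net.n_edges
    assert net.density == pytest.approx(net.n_edges / (n * (n - 1)))
    dense = net.significant_matrix()
    assert np.count_nonzero(dense) == net.n_edges
    assert "edges" in net.summary()


def test_density_example_scaled():
    # 67 significant edges on a 360-node network
    stats = np.zeros((360, 360))
    pvals = np.ones((360, 360))
    mask = np.zeros((360, 360), bool)
    idx = np.random.default_rng(0).choice(360 * 359, 67, replace=False)
    src, tgt = np.divmod(idx, 359)
    tgt = tgt + (tgt >= src)
    stats[src, tgt] = 1.0
    mask[src, tgt] = True
    net = significant_network(stats, pvals, mask)
    assert net.n_edges == 67
    assert net.density == pytest.approx(67 / (360 * 359))


def test_paired_contrast_model_end_to_end(rng):
    std = rng.normal(size=(12, 8, 8))
    diff = rng.normal(size=(12, 8, 8)) * 0.5
    diff[:, 1, 5] += 4.0
    res = PairedEdgeContrast(std, std + diff).fit(n_permutations=2000, q=0.05, seed=1)
    found = set(zip(res.edges["source"], res.edges["target"]))
    assert (1, 5) in found
    res2 = PairedEdgeContrast(std, std + diff).fit(n_permutations=2000, q=0.05, seed=1)
    assert res.edges.equals(res2.edges)


def test_pipeline_power_recovers_planted_edges(rng):
    """Full paired chain recall of five 1.5-SD planted edges (level frozen
    from the oracle measurement of this exact design)."""
    recalls = []
    planted = [(1, 2), (4, 7), (9, 0), (13, 16), (18, 5)]
    for r in range(10):
        std = np.zeros((13, 20, 20))
        diff = rng.normal(size=(13, 20, 20))
        for e in planted:
            diff[:, e[0], e[1]] += 1.5
        res = PairedEdgeContrast(std, std + diff).fit(n_permutations=5000, q=0.05, seed=r)
        found = set(zip(res.edges["source"], res.edges["target"]))
        recalls.append(len(found & set(planted)) / 5)
    assert np.mean(recalls) >= 0.6


def test_zero_variance_edges_warn(rng):
    mats = np.zeros((5, 3, 3))
    dev = mats.copy()
    dev[:, 0, 1] = 1.0  # constant nonzero difference
    with pytest.warns(RuntimeWarning):
        t, _ = paired_edge_stats(mats, dev)
    assert t[0, 1] == 0.0


def test_plot_adjacency_smoke(rng):
    import matplotlib

    matplotlib.use("Agg")
    mask = rng.uniform(size=(5, 5)) < 0.3
    net = significant_network(rng.normal(size=(5, 5)), rng.uniform(size=(5, 5)), mask)
    ax = net.plot_adjacency()
    assert ax.figure is not None
    import matplotlib.pyplot as plt

    plt.close("all")


def test_group_interaction_model(rng):
    a = rng.normal(size=(10, 6, 6))
    b = rng.normal(size=(9, 6, 6))
    a[:, 3, 4] += 4.0
    res = GroupInteractionContrast(a, b).fit(n_permutations=2000, q=0.05, seed=2)
    assert (3, 4) in set(zip(res.edges["source"], res.edges["target"]))
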
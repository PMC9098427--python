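"""Multilayer task-state graphs from cross-condition edge correlations.

For each subject and each pair of conditions, the trial series of every
directed edge's PTE value in condition A is Pearson-correlated with the
same edge's series in condition B (trials paired by chronological index),
giving a "multilink" matrix whose entries survive only if the correlation
is significant.  The K z-scored condition networks (diagonal blocks) and
the K(K-1)/2 multilink matrices (mirrored off-diagonal blocks) assemble
into a (K N) x (K N) multilayer graph per subject; with the study's K = 4
conditions and N = 360 parcels this is the 1440 x 1440 graph.  Group-level
one-sample and between-group permutation tests on these graphs reuse the
edge-contrast machinery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats as sps

from .contrasts import ContrastDesign, StatNetworkResults, fdr_bh, permutation_pvalues, significant_network
from .contrasts import _one_sample_t, _two_sample_t
from .pte import ConditionNetwork

__all__ = [
    "MultilinkMatrix",
    "MultilayerGraph",
    "edge_condition_correlation",
    "assemble_multilayer",
    "MultilayerOneSampleTest",
    "MultilayerGroupContrast",
    "group_one_sample_graph_test",
    "group_difference_graph_test",
    "between_block_node_degree",
    "multilink_components",
    "common_links",
]


@dataclass
class MultilinkMatrix:
    """Thresholded cross-condition edge-to-edge correlations for one pair."""

    matrix: np.ndarray  # N x N, zero where the correlation test failed
    pair: tuple[str, str]
    alpha: float
    n_pairs: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("multilink matrix must be square")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    @property
    def mask(self) -> np.ndarray:
        return self.matrix != 0


def edge_condition_correlation(
    trials_a,
    trials_b,
    pair: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
    pairing: str = "chronological",
    seed: int | None = None,
) -> MultilinkMatrix:
    """Per-edge Pearson correlation of trial-wise PTE values across two conditions.

    Trials are paired by chronological index after truncation to the
    common count (``pairing="random"`` instead pairs by a seeded random
    permutation of condition B's trials).  Each directed edge (i, j) gets
    the correlation r over paired trials between its value in A and in B;
    entries whose two-sided t-test (t = r sqrt((n-2)/(1-r^2))) does not
    reject at ``alpha`` are set to zero.  Positive and negative r are both
    retained.
    """
    a = np.asarray(trials_a, dtype=float)
    b = np.asarray(trials_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("expected trials x N x N arrays with a common node set")
    n = min(a.shape[0], b.shape[0])
    if n < 4:
        raise ValueError("need at least 4 paired trials")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    a = a[:n]
    if pairing == "chronological":
        b = b[:n]
    elif pairing == "random":
        b = b[np.random.default_rng(seed).permutation(b.shape[0])[:n]]
    else:
        raise ValueError(f"unknown pairing scheme {pairing!r}")
    N = a.shape[1]
    av = a.reshape(n, -1)
    bv = b.reshape(n, -1)
    ac = av - av.mean(axis=0)
    bc = bv - bv.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    constant = denom == 0
    if constant.any():
        off = ~np.eye(N, dtype=bool).ravel()
        if (constant & off).any():
            warnings.warn("constant edge series; correlation undefined, entry set to 0", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(constant, 0.0, (ac * bc).sum(axis=0) / denom)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    out = np.where(p < alpha, r, 0.0).reshape(N, N)
    np.fill_diagonal(out, 0.0)
    return MultilinkMatrix(out, pair=tuple(pair), alpha=alpha, n_pairs=n)


@dataclass
class MultilayerGraph:
    """(K N) x (K N) block matrix of condition networks and multilinks."""

    matrix: np.ndarray
    states: tuple[str, ...]
    n_nodes: int
    subject: str = ""
    meta: dict | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        side = len(self.states) * self.n_nodes
        if m.shape != (side, side):
            raise ValueError(f"matrix must be {side} x {side} for {len(self.states)} states of {self.n_nodes} nodes")
        self.matrix = m

    @property
    def side(self) -> int:
        return self.matrix.shape[0]

    def block(self, a: str, b: str) -> np.ndarray:
        ia, ib = self.states.index(a), self.states.index(b)
        N = self.n_nodes
        return self.matrix[ia * N : (ia + 1) * N, ib * N : (ib + 1) * N]

    # ------------------------------------------------------------------ I/O
    def write(self, path: str | Path) -> Path:
        """Write the matrix as TSV plus a JSON sidecar; round-trips bit-exactly."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "multilayer.tsv", self.matrix, delimiter="\t", fmt="%.17g")
        sidecar = {
            "states": list(self.states),
            "n_nodes": self.n_nodes,
            "subject": self.subject,
            "meta": self.meta or {},
        }
        (path / "multilayer.json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "MultilayerGraph":
        path = Path(path)
        sidecar = json.loads((path / "multilayer.json").read_text())
        matrix = np.loadtxt(path / "multilayer.tsv", delimiter="\t", ndmin=2)
        return cls(
            matrix=matrix,
            states=tuple(sidecar["states"]),
            n_nodes=sidecar["n_nodes"],
            subject=sidecar.get("subject", ""),
            meta=sidecar.get("meta"),
        )


def assemble_multilayer(
    condition_nets: list[ConditionNetwork],
    pair_mats: list[MultilinkMatrix],
    subject: str = "",
) -> MultilayerGraph:
    """Block-assemble condition networks and multilink matrices.

    Diagonal blocks are the z-scored condition networks in their given
    order; block (a, b) and block (b, a) both carry the multilink matrix
    of the pair {a, b} (the edge-wise correlation is one number per edge,
    symmetric in condition order).
    """
    states = tuple(cn.condition for cn in condition_nets)
    if len(set(states)) != len(states):
        raise ValueError("condition networks must have distinct condition names")
    N = condition_nets[0].n_nodes
    if any(cn.n_nodes != N for cn in condition_nets):
        raise ValueError("condition networks disagree on the node count")
    K = len(states)
    lookup: dict[frozenset, MultilinkMatrix] = {}
    for mm in pair_mats:
        if mm.matrix.shape != (N, N):
            raise ValueError("multilink matrix shape mismatch")
        lookup[frozenset(mm.pair)] = mm
    needed = [frozenset((states[i], states[j])) for i in range(K) for j in range(i + 1, K)]
    missing = [set(k) for k in needed if k not in lookup]
    if missing:
        raise ValueError(f"missing multilink matrices for pairs: {missing}")
    side = K * N
    out = np.zeros((side, side))
    for i, cn in enumerate(condition_nets):
        out[i * N : (i + 1) * N, i * N : (i + 1) * N] = cn.matrix
    for i in range(K):
        for j in range(i + 1, K):
            m = lookup[frozenset((states[i], states[j]))].matrix
            out[i * N : (i + 1) * N, j * N : (j + 1) * N] = m
            out[j * N : (j + 1) * N, i * N : (i + 1) * N] = m
    meta = {
        pairs_key(states[i], states[j]): {"alpha": lookup[frozenset((states[i], states[j]))].alpha}
        for i in range(K)
        for j in range(i + 1, K)
    }
    return MultilayerGraph(out, states=states, n_nodes=N, subject=subject, meta=meta)


def pairs_key(a: str, b: str) -> str:
    return f"{a}|{b}"


def _graph_stack(graphs: list[MultilayerGraph]) -> tuple[np.ndarray, MultilayerGraph]:
    if len(graphs) < 3:
        raise ValueError("need at least 3 subjects")
    ref = graphs[0]
    for g in graphs[1:]:
        if g.states != ref.states or g.n_nodes != ref.n_nodes:
            raise ValueError("graphs disagree on states or node count")
    return np.stack([g.matrix for g in graphs]), ref


class MultilayerOneSampleTest:
    """One-sample permutation test of group multilayer graphs against zero."""

    def __init__(self, graphs: list[MultilayerGraph]):
        self.data, self.ref = _graph_stack(graphs)

    def fit(self, n_permutations: int = 10000, q: float = 0.001, seed: int | None = None) -> StatNetworkResults:
        design = ContrastDesign(scheme="one_sample", n_permutations=n_permutations, q=q, seed=seed)
        flat = self.data.reshape(self.data.shape[0], -1)
        t = _one_sample_t(flat).reshape(self.data.shape[1:])
        np.fill_diagonal(t, 0.0)
        p = permutation_pvalues(t, self.data, design)
        np.fill_diagonal(p, 1.0)
        mask = fdr_bh(p, q)
        meta = {"q": q, "n_permutations": n_permutations, "seed": seed, "correction": "fdr_bh",
                "states": list(self.ref.states), "n_nodes": self.ref.n_nodes}
        res = significant_network(t, p, mask, threshold_meta=meta)
        res.states = self.ref.states
        res.block_size = self.ref.n_nodes
        return res


class MultilayerGroupContrast:
    """Between-group permutation contrast; splits results by direction."""

    def __init__(self, graphs_a: list[MultilayerGraph], graphs_b: list[MultilayerGraph]):
        self.data_a, ref_a = _graph_stack(graphs_a)
        self.data_b, ref_b = _graph_stack(graphs_b)
        if ref_a.states != ref_b.states or ref_a.n_nodes != ref_b.n_nodes:
            raise ValueError("groups disagree on states or node count")
        self.ref = ref_a

    def fit(
        self, n_permutations: int = 10000, q: float = 0.001, seed: int | None = None
    ) -> tuple[StatNetworkResults, StatNetworkResults]:
        """Returns (A > B contrast, B > A contrast)."""
        design = ContrastDesign(scheme="two_sample", n_permutations=n_permutations, q=q, seed=seed)
        fa = self.data_a.reshape(self.data_a.shape[0], -1)
        fb = self.data_b.reshape(self.data_b.shape[0], -1)
        t = _two_sample_t(fa, fb).reshape(self.data_a.shape[1:])
        np.fill_diagonal(t, 0.0)
        p = permutation_pvalues(t, (self.data_a, self.data_b), design)
        np.fill_diagonal(p, 1.0)
        mask = fdr_bh(p, q)
        meta = {"q": q, "n_permutations": n_permutations, "seed": seed, "correction": "fdr_bh",
                "states": list(self.ref.states), "n_nodes": self.ref.n_nodes}
        results = []
        for sign in (1, -1):
            res = significant_network(t, p, mask & (np.sign(t) == sign), threshold_meta=meta)
            res.states = self.ref.states
            res.block_size = self.ref.n_nodes
            results.append(res)
        return tuple(results)


def group_one_sample_graph_test(graphs: list[MultilayerGraph], design: ContrastDesign) -> StatNetworkResults:
    return MultilayerOneSampleTest(graphs).fit(design.n_permutations, design.q, design.seed)


def group_difference_graph_test(
    graphs_a: list[MultilayerGraph], graphs_b: list[MultilayerGraph], design: ContrastDesign
) -> tuple[StatNetworkResults, StatNetworkResults]:
    return MultilayerGroupContrast(graphs_a, graphs_b).fit(design.n_permutations, design.q, design.seed)


def between_block_node_degree(sig: StatNetworkResults, pair: tuple[str, str]) -> np.ndarray:
    """Per-region multilink count within one between-condition block.

    For each region i, counts significant entries of block (a, b) whose
    row or column index is i.
    """
    states = getattr(sig, "states", None)
    N = getattr(sig, "block_size", None)
    if states is None or N is None:
        raise ValueError("results object carries no multilayer block structure")
    a, b = pair
    if a not in states or b not in states:
        raise KeyError(f"unknown condition pair {pair}; states are {states}")
    ia, ib = states.index(a), states.index(b)
    m = sig.significant_matrix()[ia * N : (ia + 1) * N, ib * N : (ib + 1) * N]
    rows, cols = np.nonzero(m)
    deg = np.zeros(N, dtype=int)
    for i, j in zip(rows, cols):
        deg[i] += 1
        if j != i:
            deg[j] += 1
    return deg


def multilink_components(block_mask: np.ndarray) -> list[tuple[set[int], list[tuple[int, int]]]]:
    """Connected components of the undirected graph induced by nonzero entries.

    Returns a list of (node set, entry list); isolated (all-zero) regions
    form no component.
    """
    mask = np.asarray(block_mask) != 0
    g = nx.Graph()
    rows, cols = np.nonzero(mask)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    out = []
    for comp in nx.connected_components(g):
        entries = [(int(i), int(j)) for i, j in zip(rows, cols) if i in comp or j in comp]
        out.append((set(map(int, comp)), entries))
    return out


def common_links(blocks: list[np.ndarray]) -> np.ndarray:
    """Mask of entries that are nonzero in every input block."""
    if not blocks:
        raise ValueError("need at least one block")
    shape = np.asarray(blocks[0]).shape
    out = np.ones(shape, dtype=bool)
    for b in blocks:
        b = np.asarray(b)
        if b.shape != shape:
            raise ValueError("blocks disagree in shape")
        out &= b != 0
    return out
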
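"""Edge-wise permutation contrasts on connectivity matrices (NBS-style GLM).

Every directed edge gets a mass-univariate statistic — a paired t across
subjects for within-group standard-vs-deviant contrasts, or a two-sample t
on per-subject difference matrices for the group x condition interaction —
with a permutation null (sign flips of subject differences, or reshuffles
of group labels) and Benjamini–Hochberg FDR control across edges.  The
retained edges form a :class:`StatNetworkResults` with node strength,
node degree and network density summaries, mirroring how significant
networks are typically reported for whole-cortex connectomes.

Models follow the statsmodels convention: construct from data, call
``fit()`` to obtain a results object with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastDesign",
    "StatNetworkResults",
    "PairedEdgeContrast",
    "GroupInteractionContrast",
    "paired_edge_stats",
    "interaction_edge_stats",
    "permutation_pvalues",
    "fdr_bh",
    "significant_network",
]


@dataclass(frozen=True)
class ContrastDesign:
    """Permutation-test settings for one contrast."""

    scheme: str = "paired_condition"
    n_permutations: int = 10000
    q: float = 0.001
    seed: int | None = None

    _SCHEMES = ("paired_condition", "group_interaction", "one_sample", "two_sample")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {self._SCHEMES}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must be in (0, 1)")


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _stack(mats, name: str) -> np.ndarray:
    arr = np.asarray(mats, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError(f"{name} must be a list of square matrices (subjects x N x N)")
    return arr


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t over axis 0; zero-variance columns give t = 0."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero & (mean != 0)):
        warnings.warn("zero-variance entries with nonzero mean set to statistic 0", RuntimeWarning, stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t (A minus B) over axis 0."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    zero = pooled == 0
    if np.any(zero):
        warnings.warn("zero pooled variance entries set to statistic 0", RuntimeWarning, stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled * (1.0 / na + 1.0 / nb)))
    return t


def paired_edge_stats(standard, deviant) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge paired t (deviant minus standard) across subjects, and F = t^2."""
    s = _stack(standard, "standard")
    d = _stack(deviant, "deviant")
    if s.shape != d.shape:
        raise ValueError("standard and deviant must hold the same subjects (matching shapes)")
    if s.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    t = _one_sample_t(d - s)
    np.fill_diagonal(t, 0.0)
    return t, t**2


def interaction_edge_stats(group_a_diffs, group_b_diffs) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge two-sample t between groups on (deviant - standard) differences."""
    a = _stack(group_a_diffs, "group_a_diffs")
    b = _stack(group_b_diffs, "group_b_diffs")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share the node set")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    t = _two_sample_t(a, b)
    np.fill_diagonal(t, 0.0)
    return t, t**2


def _canonical_rows(x: np.ndarray) -> np.ndarray:
    """Sort subject rows lexicographically so p-values do not depend on input order."""
    return x[np.lexsort(x.T[::-1])]


def _perm_one_sample(x: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null |t| distribution from sign flips of mean-centered values; x is (n, E).

    Centering each edge before flipping keeps the null free of any true
    location effect (a shift-invariant, Freedman–Lane-style null), which
    preserves power when effects are large; under the null the centering
    is asymptotically immaterial.
    """
    x = _canonical_rows(x)
    x = x - x.mean(axis=0)
    n = x.shape[0]
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    sums = signs @ x
    mean = sums / n
    ssq = (x**2).sum(axis=0)  # invariant under sign flips
    var = np.maximum(ssq - n * mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var == 0, 0.0, mean / np.sqrt(var / n))
    return np.abs(t)


def _perm_two_sample(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null |t| distribution from reshuffles of group labels; a, b are (n, E).

    Group means are removed before pooling (residual permutation), so the
    null is unaffected by a true group difference.
    """
    x = _canonical_rows(np.vstack([a - a.mean(axis=0), b - b.mean(axis=0)]))
    x2 = x**2
    n, na = x.shape[0], a.shape[0]
    nb = n - na
    tot = x.sum(axis=0)
    tot2 = x2.sum(axis=0)
    out = np.empty((n_perm, x.shape[1]))
    for p in range(n_perm):
        idx = rng.permutation(n)[:na]
        sa = x[idx].sum(axis=0)
        sa2 = x2[idx].sum(axis=0)
        ma, mb = sa / na, (tot - sa) / nb
        va = np.maximum(sa2 - na * ma**2, 0.0) / (na - 1)
        vb = np.maximum((tot2 - sa2) - nb * mb**2, 0.0) / (nb - 1)
        pooled = ((na - 1) * va + (nb - 1) * vb) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[p] = np.where(pooled == 0, 0.0, (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb)))
    return np.abs(out)


def permutation_pvalues(observed_stats: np.ndarray, data, design: ContrastDesign) -> np.ndarray:
    """Two-sided permutation p-values for per-edge statistics.

    ``data`` is a (subjects, ...) array of difference matrices (or raw
    values) for the sign-flip schemes ``paired_condition``/``one_sample``,
    or a ``(group_a, group_b)`` tuple for ``group_interaction``/
    ``two_sample``.  p = (1 + #{|t_perm| >= |t_obs|}) / (1 + P), so p is
    never zero.  Deterministic given ``design.seed``.
    """
    obs = np.abs(np.asarray(observed_stats, dtype=float))
    shape = obs.shape
    rng = np.random.default_rng(design.seed)
    if design.scheme in ("paired_condition", "one_sample"):
        x = np.asarray(data, dtype=float).reshape(len(data), -1)
        null = _perm_one_sample(x, design.n_permutations, rng)
    elif design.scheme in ("group_interaction", "two_sample"):
        a, b = data
        a = np.asarray(a, dtype=float).reshape(len(a), -1)
        b = np.asarray(b, dtype=float).reshape(len(b), -1)
        null = _perm_two_sample(a, b, design.n_permutations, rng)
    else:  # pragma: no cover - guarded by ContrastDesign
        raise ValueError(f"unknown scheme {design.scheme!r}")
    exceed = (null >= obs.reshape(1, -1) - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + design.n_permutations)
    return p.reshape(shape)


def fdr_bh(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up significance mask at FDR level q."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


@dataclass
class StatNetworkResults:
    """Significant directed network with graph summaries.

    ``edges`` holds one row per retained edge (source, target, statistic,
    p_value); node strength is the sum of |statistic| over incident
    significant edges, node degree the incident edge count (in + out),
    and density the fraction |edges| / (N (N - 1)).
    """

    edges: pd.DataFrame
    n_nodes: int
    node_strength: np.ndarray
    node_degree: np.ndarray
    density: float
    threshold_meta: dict
    node_labels: list[str] | None = None
    stat_matrix: np.ndarray | None = None
    p_matrix: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def significant_matrix(self) -> np.ndarray:
        """Dense N x N matrix holding the retained edge statistics."""
        m = np.zeros((self.n_nodes, self.n_nodes))
        if self.n_edges:
            m[self.edges["source"].to_numpy(), self.edges["target"].to_numpy()] = self.edges["statistic"].to_numpy()
        return m

    def summary(self) -> str:
        meta = self.threshold_meta
        lines = [
            "Significant network summary",
            "===========================",
            f"nodes: {self.n_nodes}   edges: {self.n_edges}   density: {self.density:.6g}",
            f"correction: {meta.get('correction', 'fdr_bh')} at q={meta.get('q')}   "
            f"permutations: {meta.get('n_permutations')}   seed: {meta.get('seed')}",
        ]
        if self.n_edges:
            top = self.edges.reindex(self.edges["statistic"].abs().sort_values(ascending=False).index).head(10)
            lines.append("top edges (|statistic|):")
            for _, r in top.iterrows():
                s = self._label(int(r["source"]))
                t = self._label(int(r["target"]))
                lines.append(f"  {s} -> {t}   stat={r['statistic']: .4f}   p={r['p_value']:.4g}")
            k = int(np.argmax(self.node_strength))
            lines.append(f"strongest node: {self._label(k)} (strength {self.node_strength[k]:.4f})")
        return "\n".join(lines)

    def _label(self, i: int) -> str:
        return self.node_labels[i] if self.node_labels else f"node{i:03d}"

    def to_edge_tsv(self, path) -> None:
        df = self.edges.copy()
        df.insert(0, "source_label", [self._label(i) for i in df["source"]])
        df.insert(1, "target_label", [self._label(i) for i in df["target"]])
        df.to_csv(path, sep="\t", index=False)

    def to_node_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "label": [self._label(i) for i in range(self.n_nodes)],
                "strength": self.node_strength,
                "degree": self.node_degree,
            }
        ).to_csv(path, sep="\t", index=False)

    def plot_adjacency(self, ax=None):
        """Heat map of the retained edge statistics."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.significant_matrix()
        vmax = np.abs(m).max() or 1.0
        im = ax.imshow(m, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("target node")
        ax.set_ylabel("source node")
        ax.figure.colorbar(im, ax=ax, label="statistic")
        return ax


def significant_network(
    stats: np.ndarray,
    pvals: np.ndarray,
    mask: np.ndarray,
    threshold_meta: dict | None = None,
    node_labels: list[str] | None = None,
) -> StatNetworkResults:
    """Assemble a :class:`StatNetworkResults` from masked edge statistics."""
    stats = np.asarray(stats, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stats.shape != pvals.shape or stats.shape != mask.shape:
        raise ValueError("stats, pvals and mask must share a shape")
    n = stats.shape[0]
    mask = mask & _offdiag_mask(n)
    src, tgt = np.nonzero(mask)
    edges = pd.DataFrame(
        {"source": src, "target": tgt, "statistic": stats[src, tgt], "p_value": pvals[src, tgt]}
    )
    strength = np.zeros(n)
    degree = np.zeros(n, dtype=int)
    for i, j, s in zip(src, tgt, np.abs(stats[src, tgt])):
        strength[i] += s
        strength[j] += s
        degree[i] += 1
        degree[j] += 1
    return StatNetworkResults(
        edges=edges,
        n_nodes=n,
        node_strength=strength,
        node_degree=degree,
        density=len(edges) / (n * (n - 1)),
        threshold_meta=threshold_meta or {},
        node_labels=node_labels,
        stat_matrix=stats,
        p_matrix=pvals,
    )


class _EdgeContrastBase:
    """Shared fit machinery for edge-wise permutation contrasts."""

    design_scheme: str = "paired_condition"

    def _observed(self) -> tuple[np.ndarray, object]:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, n_permutations: int = 10000, q: float = 0.001, seed: int | None = None) -> StatNetworkResults:
        design = ContrastDesign(scheme=self.design_scheme, n_permutations=n_permutations, q=q, seed=seed)
        t, data = self._observed()
        p = permutation_pvalues(t, data, design)
        np.fill_diagonal(p, 1.0)
        mask = fdr_bh(p, q)
        meta = {"q": q, "n_permutations": n_permutations, "seed": seed, "correction": "fdr_bh"}
        return significant_network(t, p, mask, threshold_meta=meta, node_labels=self.node_labels)


class PairedEdgeContrast(_EdgeContrastBase):
    """Within-group standard-vs-deviant contrast on per-subject edge matrices."""

    design_scheme = "paired_condition"

    def __init__(self, standard, deviant, node_labels: list[str] | None = None):
        self.standard = _stack(standard, "standard")
        self.deviant = _stack(deviant, "deviant")
        if self.standard.shape != self.deviant.shape:
            raise ValueError("standard and deviant must hold the same subjects")
        self.node_labels = node_labels

    def _observed(self):
        t, _ = paired_edge_stats(self.standard, self.deviant)
        return t, self.deviant - self.standard


class GroupInteractionContrast(_EdgeContrastBase):
    """Group x condition interaction on per-subject difference matrices."""

    design_scheme = "group_interaction"

    def __init__(self, group_a_diffs, group_b_diffs, node_labels: list[str] | None = None):
        self.group_a = _stack(group_a_diffs, "group_a_diffs")
        self.group_b = _stack(group_b_diffs, "group_b_diffs")
        self.node_labels = node_labels

    def _observed(self):
        t, _ = interaction_edge_stats(self.group_a, self.group_b)
        return t, (self.group_a, self.group_b)
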
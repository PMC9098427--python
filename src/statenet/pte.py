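"""Directed phase transfer entropy (PTE) between source-space signals.

PTE quantifies phase-based information flow from a source signal x to a
target signal y as the transfer entropy between their instantaneous phases:

    PTE(x -> y) = H(y_{t+d}, y_t) - H(y_t) - H(y_{t+d}, y_t, x_t) + H(y_t, x_t)

with prediction delay ``d`` in samples, target history of length 1, and
Shannon entropies (nats) estimated by plug-in from joint histograms of
binned phases.  Instantaneous phases come from a band-limited analytic
signal built in the frequency domain, so band restriction and the Hilbert
transform happen in a single step with no time-domain filtering.

The per-trial N x N adjacency matrices produced by :func:`pte_matrix` are
averaged across trials of one experimental condition and z-scored to give
one :class:`ConditionNetwork` per subject and condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PTEConfig",
    "ConditionNetwork",
    "analytic_phase",
    "scott_bins",
    "pte_pair",
    "pte_matrix",
    "condition_mean_z",
]


@dataclass(frozen=True)
class PTEConfig:
    """Estimator settings.

    Parameters
    ----------
    delay : int
        Prediction delay in samples (time from the past of source and
        target to the predicted target sample).
    embedding_k : int
        Length of the target history; only ``k=1`` is implemented.
    band : tuple of float
        Pass band in Hz used when extracting the analytic phase.
    bin_rule : str
        Rule for the number of phase histogram bins; ``"scott"`` applies
        the normal-reference bin width of Scott (as recommended by Nason
        and Scott for small samples).
    bins_override : int, optional
        Fixed bin count, bypassing the rule.
    """

    delay: int = 10
    embedding_k: int = 1
    band: tuple[float, float] = (2.0, 60.0)
    bin_rule: str = "scott"
    bins_override: int | None = None

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be a positive integer number of samples")
        if self.embedding_k != 1:
            raise NotImplementedError("only embedding length k=1 is supported")
        low, high = self.band
        if not (0.0 < low < high):
            raise ValueError(f"invalid band {self.band}")
        if self.bins_override is not None and self.bins_override < 2:
            raise ValueError("bins_override must be >= 2")


@dataclass
class ConditionNetwork:
    """Trial-averaged directed connectivity matrix for one subject x condition."""

    matrix: np.ndarray
    subject: str
    condition: str
    normalized: bool = False
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("ConditionNetwork matrix must be square")
        if not np.isfinite(m).all():
            raise ValueError("ConditionNetwork matrix contains non-finite values")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def analytic_phase(signal: np.ndarray, fs: float, band: tuple[float, float] = (2.0, 60.0)) -> np.ndarray:
    """Instantaneous phase of the band-limited analytic signal.

    The analytic signal is constructed in the frequency domain: Fourier
    coefficients outside ``band`` and at non-positive frequencies are
    zeroed, the retained positive-frequency coefficients are doubled, and
    the result is transformed back.  The phase is the complex argument,
    in (-pi, pi].

    Accepts a 1-D series or a 2-D ``(n_signals, n_samples)`` array
    (transformed along the last axis).
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if n < 64:
        raise ValueError("series too short for a stable analytic phase (need >= 64 samples)")
    if fs <= 0:
        raise ValueError("fs must be positive")
    low, high = band
    if not (0.0 < low < high <= fs / 2.0):
        raise ValueError(f"band {band} must lie inside (0, fs/2) = (0, {fs / 2.0})")
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    weight = np.where((freqs > 0) & (freqs >= low) & (freqs <= high), 2.0, 0.0)
    z = np.fft.ifft(np.fft.fft(x, axis=-1) * weight, axis=-1)
    power = np.abs(z).max(axis=-1)
    if np.any(power < 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0)))):
        raise ValueError("signal has no power inside the analysis band (constant input?)")
    return np.angle(z)


def scott_bins(phases: np.ndarray, m: int | None = None, bins_override: int | None = None) -> int:
    """Histogram bin count from Scott's normal-reference rule.

    The bin width is ``h = 3.49 * sigma * m**(-1/3)`` where ``sigma`` is
    the sample standard deviation of the pooled phases and ``m`` the
    number of observations entering each histogram; the phase axis
    [-pi, pi) is partitioned into ``ceil(2 pi / h)`` bins (minimum 2).
    """
    if bins_override is not None:
        if bins_override < 2:
            raise ValueError("bins_override must be >= 2")
        return int(bins_override)
    ph = np.asarray(phases, dtype=float).ravel()
    if m is None:
        m = ph.size
    if m < 2:
        raise ValueError("need at least 2 observations")
    sigma = float(np.std(ph, ddof=1))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise ValueError("degenerate phase sample (zero standard deviation)")
    h = 3.49 * sigma * m ** (-1.0 / 3.0)
    return max(2, math.ceil(2.0 * math.pi / h))


def _bin_phases(phases: np.ndarray, bins: int) -> np.ndarray:
    """Map phases in (-pi, pi] to integer bins 0..bins-1 partitioning [-pi, pi]."""
    idx = np.floor((np.asarray(phases) + np.pi) * (bins / (2.0 * np.pi))).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Plug-in entropy of each row of a count matrix."""
    c = counts.astype(float)
    totals = c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(c > 0, c * np.log(c / totals), 0.0)
    return -term.sum(axis=1) / totals[:, 0]


def pte_pair(phase_x: np.ndarray, phase_y: np.ndarray, cfg: PTEConfig = PTEConfig(), bins: int | None = None) -> float:
    """Plug-in phase transfer entropy from x to y (nats), given phase series."""
    px = np.asarray(phase_x, dtype=float)
    py = np.asarray(phase_y, dtype=float)
    if px.shape != py.shape or px.ndim != 1:
        raise ValueError("phase series must be 1-D and of equal length")
    T = px.size
    d = cfg.delay
    if T - d < 2:
        raise ValueError("series too short for the requested delay")
    if bins is None:
        bins = scott_bins(np.concatenate([px, py]), m=T - d, bins_override=cfg.bins_override)
    if T - d < 10 * bins:
        warnings.warn(
            f"only {T - d} samples for {bins} bins; PTE estimate may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    bx = _bin_phases(px, bins)
    by = _bin_phases(py, bins)
    y_fut = by[d:]
    y_past = by[:-d]
    x_past = bx[:-d]
    b = bins
    h_y = _entropy_from_counts(np.bincount(y_past, minlength=b))
    h_yy = _entropy_from_counts(np.bincount(y_fut * b + y_past, minlength=b * b))
    h_yx = _entropy_from_counts(np.bincount(y_past * b + x_past, minlength=b * b))
    h_yyx = _entropy_from_counts(np.bincount((y_fut * b + y_past) * b + x_past, minlength=b * b * b))
    return h_yy - h_y - h_yyx + h_yx


def pte_matrix(trial: np.ndarray, fs: float, cfg: PTEConfig = PTEConfig()) -> np.ndarray:
    """Directed N x N PTE adjacency matrix for one trial.

    Entry (i, j) is PTE from node i to node j.  Phases are extracted once
    per node and the bin count (shared by all histogram axes) is derived
    from the pooled phase sample of the whole trial with m = T - delay.
    """
    data = np.asarray(trial, dtype=float)
    if data.ndim != 2:
        raise ValueError("trial must be a 2-D (nodes x samples) array")
    n_nodes, T = data.shape
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    d = cfg.delay
    if T - d < 2:
        raise ValueError("epoch too short for the configured delay")
    try:
        phases = analytic_phase(data, fs, cfg.band)
    except ValueError as exc:
        raise ValueError(f"phase extraction failed for trial of shape {data.shape}: {exc}") from exc
    b = scott_bins(phases.ravel(), m=T - d, bins_override=cfg.bins_override)
    idx = _bin_phases(phases, b)
    fut = idx[:, d:]  # (N, T-d)
    past = idx[:, :-d]
    n_obs = T - d
    if n_obs < 10 * b:
        warnings.warn(
            f"only {n_obs} samples for {b} bins; PTE estimates may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )

    # target-only entropy terms
    h_y = np.empty(n_nodes)
    h_yy = np.empty(n_nodes)
    for j in range(n_nodes):
        h_y[j] = _entropy_from_counts(np.bincount(past[j], minlength=b))
        h_yy[j] = _entropy_from_counts(np.bincount(fut[j] * b + past[j], minlength=b * b))

    row_offset = np.arange(n_nodes)[:, None]
    out = np.zeros((n_nodes, n_nodes))
    for j in range(n_nodes):
        # joint histograms of (y_past_j, x_past_i) and (y_fut_j, y_past_j, x_past_i)
        # for all sources i at once, via offset-encoded bincounts
        code2 = past[j][None, :] * b + past  # (N, T-d)
        cnt2 = np.bincount((code2 + row_offset * b * b).ravel(), minlength=n_nodes * b * b)
        h2 = _entropy_rows(cnt2.reshape(n_nodes, b * b))
        code3 = (fut[j][None, :] * b + past[j][None, :]) * b + past
        cnt3 = np.bincount((code3 + row_offset * b * b * b).ravel(), minlength=n_nodes * b * b * b)
        h3 = _entropy_rows(cnt3.reshape(n_nodes, b * b * b))
        out[:, j] = h_yy[j] - h_y[j] - h3 + h2
        out[j, j] = 0.0
    return out


def condition_mean_z(
    trial_matrices: list[np.ndarray] | np.ndarray,
    subject: str = "",
    condition: str = "",
    node_labels: list[str] | None = None,
) -> ConditionNetwork:
    """Average trial adjacency matrices and z-score the off-diagonal entries.

    The z-score is taken within the averaged matrix, over its off-diagonal
    entries (sample SD, ddof=1); the diagonal stays exactly zero.
    """
    mats = np.asarray(trial_matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.ndim != 3 or mats.shape[0] == 0 or mats.shape[1] != mats.shape[2]:
        raise ValueError("expected a non-empty list of square matrices of common shape")
    mean = mats.mean(axis=0)
    n = mean.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = mean[off]
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across off-diagonal entries; cannot z-score")
    z = np.zeros_like(mean)
    z[off] = (vals - vals.mean()) / sd
    return ConditionNetwork(z, subject=subject, condition=condition, normalized=True, node_labels=node_labels)
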
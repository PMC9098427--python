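"""Synthetic source-space epochs from delayed-coupled phase oscillators.

The generator emulates the structure the downstream analysis assumes:
multi-subject, multi-condition sets of band-limited oscillatory signals in
which (i) directed phase coupling on a known edge set differs between the
standard and the deviant conditions, and (ii) the trial-to-trial coupling
strength of selected edges is co-modulated across a named condition pair
(ground-truth "multilinks").  Phases evolve by an Euler step of a
Kuramoto-type model with a transmission delay of ``sim_delay`` samples:

    theta_i[t+1] = theta_i[t] + 2 pi f_i / fs
                   + (1/fs) * sum_j kappa_ij^(trial) * sin(theta_j[t-d] - theta_i[t])
                   + process noise

and the observed signal is ``sin(theta_i[t])`` plus measurement noise.
Per-trial strengths are ``kappa^(trial) = kappa_bar * (1 + gamma * u)``
with ``u`` a standard-normal draw that is shared between trial k of the
two conditions of a multilink edge (paired by trial index) and drawn
independently otherwise.

A separate helper draws binomial 2AFC response counts per subject and
modality for the behavioral arm of the study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = ["GroundTruth", "make_ground_truth", "simulate_subject_epochs", "simulate_behavior"]

DEFAULT_CONDITIONS = ("standard", "audiovisual", "auditory", "visual")


@dataclass(frozen=True)
class GroundTruth:
    """Planted connectivity structure shared by all subjects of a simulated study.

    ``coupling`` maps each condition name to a dict of directed edges
    ``(source, target) -> mean strength kappa_bar`` in radians per second.
    ``multilink_edges`` lists the edges whose per-trial strength draw is
    shared across ``multilink_pair`` (co-modulation gain ``gamma``).
    """

    n_nodes: int
    conditions: tuple[str, ...]
    coupling: dict[str, dict[tuple[int, int], float]]
    multilink_edges: tuple[tuple[int, int], ...]
    multilink_pair: tuple[str, str]
    gamma: float = 2.0
    oscillator_band: tuple[float, float] = (8.0, 12.0)
    process_noise_sd: float = 0.4
    measurement_noise_sd: float = 0.05
    sim_delay: int = 10

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.sim_delay < 1:
            raise ValueError("sim_delay must be a positive integer")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.process_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        for cond, edges in self.coupling.items():
            for (i, j), k in edges.items():
                if i == j:
                    raise ValueError(f"self-edge ({i},{j}) in condition {cond!r}")
                if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                    raise ValueError(f"edge ({i},{j}) out of range for {self.n_nodes} nodes")
                if not np.isfinite(k):
                    raise ValueError(f"non-finite strength on edge ({i},{j})")
        a, b = self.multilink_pair
        allowed = set(self.coupling.get(a, {})) | set(self.coupling.get(b, {}))
        for e in self.multilink_edges:
            if e not in allowed:
                raise ValueError(f"multilink edge {e} is not a coupling edge of the pair {self.multilink_pair}")


def make_ground_truth(
    n_nodes: int,
    edges_per_condition: int,
    n_multilink: int,
    effect: float,
    seed: int,
    *,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    coupling_strength: tuple[float, float] = (80.0, 120.0),
    gamma: float = 2.0,
    multilink_pair: tuple[str, str] | None = None,
    oscillator_band: tuple[float, float] = (8.0, 12.0),
    process_noise_sd: float = 0.4,
    measurement_noise_sd: float = 0.05,
    sim_delay: int = 10,
) -> GroundTruth:
    """Draw a seeded :class:`GroundTruth`.

    One set of ``edges_per_condition`` directed edges (shared across
    conditions, so condition pairs always share the multilink edges) gets
    mean strengths uniform in ``coupling_strength``; every condition
    other than the first ("standard") differs from the standard by
    ``effect`` (radians/s) added to all of its edges.  ``n_multilink``
    edges are flagged as co-modulated across ``multilink_pair`` (default:
    the first two conditions).

    So that the planted co-modulation has a clean readout, multilink
    edges are placed on nodes not shared with any other coupling edge
    (falling back to shared nodes only when the graph is too dense for
    that), and they receive the top of the ``coupling_strength`` range.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if edges_per_condition < 1 or n_multilink < 0:
        raise ValueError("counts must be positive (n_multilink may be zero)")
    if n_multilink > edges_per_condition:
        raise ValueError("n_multilink cannot exceed edges_per_condition")
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    rng = np.random.default_rng(seed)
    if edges_per_condition > n_nodes * (n_nodes - 1):
        raise ValueError("more edges requested than ordered node pairs")

    multilink_edges_l: list[tuple[int, int]] = []
    if n_multilink:
        if 2 * n_multilink <= n_nodes:
            nodes = rng.permutation(n_nodes)
            multilink_edges_l = [
                (int(s), int(t)) for s, t in zip(nodes[n_multilink : 2 * n_multilink], nodes[:n_multilink])
            ]
        else:
            pick = rng.choice(n_nodes * (n_nodes - 1), size=n_multilink, replace=False)
            all_pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
            multilink_edges_l = [all_pairs[k] for k in pick]
    ml_nodes = {n for e in multilink_edges_l for n in e}
    pool = [
        (i, j)
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and i not in ml_nodes and j not in ml_nodes
    ]
    n_other = edges_per_condition - n_multilink
    if len(pool) < n_other:
        # dense request: allow other edges to touch multilink nodes
        pool = [
            (i, j)
            for i in range(n_nodes)
            for j in range(n_nodes)
            if i != j and (i, j) not in set(multilink_edges_l)
        ]
    pick = rng.choice(len(pool), size=n_other, replace=False) if n_other else []
    edges = multilink_edges_l + [pool[k] for k in pick]
    base = np.concatenate(
        [
            np.full(n_multilink, float(coupling_strength[1])),
            rng.uniform(*coupling_strength, size=n_other),
        ]
    )
    coupling: dict[str, dict[tuple[int, int], float]] = {}
    for c, cond in enumerate(conditions):
        shift = 0.0 if c == 0 else effect
        strengths = base + shift
        if np.any(strengths < 0):
            raise ValueError("effect drives a coupling strength negative")
        coupling[cond] = {e: float(s) for e, s in zip(edges, strengths)}
    multilink_edges = tuple(multilink_edges_l)
    pair = multilink_pair if multilink_pair is not None else (conditions[0], conditions[1])
    return GroundTruth(
        n_nodes=n_nodes,
        conditions=tuple(conditions),
        coupling=coupling,
        multilink_edges=multilink_edges,
        multilink_pair=tuple(pair),
        gamma=gamma,
        oscillator_band=oscillator_band,
        process_noise_sd=process_noise_sd,
        measurement_noise_sd=measurement_noise_sd,
        sim_delay=sim_delay,
    )


def _trial_strengths(gt: GroundTruth, n_trials: int, rng: np.random.Generator) -> dict[str, dict[tuple[int, int], np.ndarray]]:
    """Per-condition, per-edge arrays of kappa^(trial), honouring shared draws."""
    shared_u = {e: rng.standard_normal(n_trials) for e in gt.multilink_edges}
    out: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    for cond in gt.conditions:
        per_edge = {}
        for e, kbar in gt.coupling[cond].items():
            if e in shared_u and cond in gt.multilink_pair:
                u = shared_u[e]
            else:
                u = rng.standard_normal(n_trials)
            per_edge[e] = kbar * (1.0 + gt.gamma * u)
        out[cond] = per_edge
    return out


def simulate_subject_epochs(
    gt: GroundTruth,
    n_trials_per_condition: int,
    n_samples: int = 1921,
    fs: float = 1200.0,
    seed: int = 0,
    subject: str = "sub-01",
) -> EpochSet:
    """Simulate one subject's epochs for every condition of ``gt``.

    Returns an :class:`EpochSet` whose ``trial_strengths`` attribute keeps
    the realised per-trial coupling strengths (the recoverable ground
    truth for multilink analyses).  Deterministic given ``seed``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_samples <= gt.sim_delay + 2:
        raise ValueError("n_samples must exceed sim_delay + 2")
    if n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    rng = np.random.default_rng(seed)
    N, T, d = gt.n_nodes, n_samples, gt.sim_delay
    freqs = rng.uniform(*gt.oscillator_band, size=N)
    strengths = _trial_strengths(gt, n_trials_per_condition, rng)

    data = np.empty((len(gt.conditions) * n_trials_per_condition, N, T))
    labels: list[str] = []
    for c, cond in enumerate(gt.conditions):
        # coupling matrix per trial: K[trial, target, source]
        K = np.zeros((n_trials_per_condition, N, N))
        for (src, dst), kt in strengths[cond].items():
            K[:, dst, src] = kt
        theta = np.empty((n_trials_per_condition, N, T))
        theta[:, :, 0] = rng.uniform(-np.pi, np.pi, size=(n_trials_per_condition, N))
        step = 2.0 * np.pi * freqs / fs
        noise = (
            rng.normal(0.0, gt.process_noise_sd, size=(n_trials_per_condition, N, T - 1))
            if gt.process_noise_sd > 0
            else np.zeros((n_trials_per_condition, N, T - 1))
        )
        has_coupling = np.any(K != 0)
        with np.errstate(invalid="ignore", over="ignore"):
            for t in range(T - 1):
                drift = step[None, :]
                if has_coupling and t >= d:
                    delayed = theta[:, :, t - d]
                    s, cth = np.sin(delayed), np.cos(delayed)
                    cur_s, cur_c = np.sin(theta[:, :, t]), np.cos(theta[:, :, t])
                    # sin(theta_src[t-d] - theta_dst[t]) summed over sources, weighted by K
                    pull = (np.einsum("tij,tj->ti", K, s) * cur_c - np.einsum("tij,tj->ti", K, cth) * cur_s) / fs
                    drift = drift + pull
                theta[:, :, t + 1] = theta[:, :, t] + drift + noise[:, :, t]
            x = np.sin(theta)
        if gt.measurement_noise_sd > 0:
            x = x + rng.normal(0.0, gt.measurement_noise_sd, size=x.shape)
        if not np.isfinite(x).all():
            raise FloatingPointError("simulation diverged (non-finite output)")
        sl = slice(c * n_trials_per_condition, (c + 1) * n_trials_per_condition)
        data[sl] = x
        labels.extend([cond] * n_trials_per_condition)

    es = EpochSet(
        data=data,
        fs=fs,
        condition=np.array(labels),
        subject=subject,
        node_labels=[f"node{i:03d}" for i in range(N)],
        seed=seed,
    )
    es.trial_strengths = {c: {e: v.copy() for e, v in per.items()} for c, per in strengths.items()}
    es.ground_truth = gt
    return es


def simulate_behavior(
    accuracy_by_group_modality: dict[str, dict[str, float]],
    n_trials: int = 12,
    n_subjects_per_group: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial 2AFC correct-response counts per subject and modality.

    ``accuracy_by_group_modality`` maps group -> modality -> true accuracy
    in the open interval (0, 1).  Returns a tidy table with one row per
    subject x modality.  Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if n_subjects_per_group is None:
        n_subjects_per_group = {g: 12 for g in accuracy_by_group_modality}
    for g, mods in accuracy_by_group_modality.items():
        for m, p in mods.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"accuracy for {g}/{m} must be strictly inside (0, 1), got {p}")
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(accuracy_by_group_modality):
        mods = accuracy_by_group_modality[group]
        for s in range(n_subjects_per_group[group]):
            subject = f"{group}-{s + 1:02d}"
            for modality in sorted(mods):
                k = int(rng.binomial(n_trials, mods[modality]))
                rows.append(
                    {"subject": subject, "group": group, "modality": modality, "n_correct": k, "n_trials": n_trials}
                )
    return pd.DataFrame(rows)
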
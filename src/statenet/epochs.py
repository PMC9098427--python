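"""Container for source-space epoch data (trials x nodes x samples)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Epoched multichannel time series with condition labels.

    This is the pipeline entry point: real studies would populate it from
    source-reconstructed MEG epochs (e.g. 360 atlas parcels at 1200 Hz,
    1921 samples per epoch); the simulator produces the same structure.
    """

    data: np.ndarray  # (n_trials, n_nodes, n_samples)
    fs: float
    condition: np.ndarray  # (n_trials,) of str
    subject: str = ""
    node_labels: list[str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x nodes x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        self.condition = np.asarray(self.condition)
        if self.condition.shape != (self.data.shape[0],):
            raise ValueError("need exactly one condition label per trial")
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(self.data.shape[1])]
        if len(self.node_labels) != self.data.shape[1]:
            raise ValueError("node_labels length must match the node dimension")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition:
            if c not in seen:
                seen.append(str(c))
        return seen

    def select(self, condition: str) -> np.ndarray:
        """Trials of one condition, as a (n, nodes, samples) view."""
        mask = self.condition == condition
        if not mask.any():
            raise KeyError(f"no trials with condition {condition!r}")
        return self.data[mask]

    # ------------------------------------------------------------------ I/O
    def write_dir(self, path: str | Path) -> Path:
        """Write one TSV matrix (nodes x samples) per trial plus a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for k in range(self.n_trials):
            np.savetxt(path / f"trial{k:04d}.tsv", self.data[k], delimiter="\t", fmt="%.17g")
        sidecar: dict = {
            "fs": self.fs,
            "subject": self.subject,
            "condition": [str(c) for c in self.condition],
            "node_labels": self.node_labels,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "n_samples": self.n_samples,
        }
        gt = getattr(self, "ground_truth", None)
        if gt is not None:
            sidecar["ground_truth_edges"] = {
                cond: [[int(i), int(j), float(k)] for (i, j), k in edges.items()]
                for cond, edges in gt.coupling.items()
            }
            sidecar["multilink_edges"] = [list(map(int, e)) for e in gt.multilink_edges]
            sidecar["multilink_pair"] = list(gt.multilink_pair)
        ts = getattr(self, "trial_strengths", None)
        if ts is not None:
            sidecar["trial_strengths"] = {
                cond: {f"{i}->{j}": v.tolist() for (i, j), v in per.items()} for cond, per in ts.items()
            }
        (path / "epochs.json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def read_dir(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        sidecar = json.loads((path / "epochs.json").read_text())
        n_trials = sidecar["n_trials"]
        trials = []
        for k in range(n_trials):
            f = path / f"trial{k:04d}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"missing trial file {f}")
            try:
                trials.append(np.loadtxt(f, delimiter="\t", ndmin=2))
            except ValueError as exc:
                raise ValueError(f"corrupt trial file {f}: {exc}") from exc
        es = cls(
            data=np.stack(trials),
            fs=sidecar["fs"],
            condition=np.array(sidecar["condition"]),
            subject=sidecar.get("subject", ""),
            node_labels=sidecar.get("node_labels"),
            seed=sidecar.get("seed"),
        )
        if "trial_strengths" in sidecar:
            es.trial_strengths = {
                cond: {tuple(int(x) for x in key.split("->")): np.asarray(v) for key, v in per.items()}
                for cond, per in sidecar["trial_strengths"].items()
            }
        return es
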
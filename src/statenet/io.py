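"""Tab-separated matrix files, label tables and BrainNet-style exports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_brainnet",
    "load_node_labels",
    "write_manifest",
]


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, labels: list[str] | None = None) -> None:
    """Square matrix as TSV with a label header row and index column."""
    m = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = [f"node{i:03d}" for i in range(m.shape[0])]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree; not a square labelled matrix")
    return df.to_numpy(dtype=float), list(df.columns)


def write_brainnet(prefix: str | Path, results, coords: np.ndarray | None = None) -> None:
    """BrainNet Viewer text exports: ``<prefix>.node`` and ``<prefix>.edge``.

    ``coords`` are optional x/y/z node coordinates (defaults to a circle,
    since the atlas geometry is not shipped).
    """
    prefix = Path(prefix)
    n = results.n_nodes
    if coords is None:
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([70 * np.cos(ang), 70 * np.sin(ang), np.zeros(n)])
    node = pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "color": results.node_degree,
            "size": results.node_strength,
            "label": [results._label(i) for i in range(n)],
        }
    )
    node.to_csv(prefix.with_suffix(".node"), sep="\t", index=False, header=False)
    np.savetxt(prefix.with_suffix(".edge"), results.significant_matrix(), delimiter="\t", fmt="%.6g")


def load_node_labels(path: str | Path, n_nodes: int) -> list[str]:
    """Optional user-supplied label table (one label per line, or index<TAB>label)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    labels = [ln.split("\t")[-1] for ln in lines]
    if len(labels) != n_nodes:
        raise ValueError(f"label table has {len(labels)} entries but the data has {n_nodes} nodes")
    return labels


def write_manifest(path: str | Path, config: dict, seed: int | None) -> None:
    """Reproducibility manifest: config digest, seed, package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "statenet_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
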
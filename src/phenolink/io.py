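"""Plain-text persistence for matrices, annotations, and reports.

Matrices are stored as a dense whitespace-separated ``.tsv`` alongside a
``.meta.json`` header carrying the row identifiers, column vocabulary, a
raw/reduced/embedding kind tag, and the config fingerprint that produced the
artifact. Re-running a pipeline with a different configuration refuses to
overwrite an artifact whose recorded fingerprint disagrees.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "save_matrix",
    "load_matrix",
    "write_predictions_tsv",
    "write_annotation_tsv",
    "write_term_groups_json",
    "write_json",
    "FingerprintMismatchError",
]


class FingerprintMismatchError(RuntimeError):
    """An on-disk artifact was produced by a different configuration."""


def _meta_path(prefix: Path) -> Path:
    return prefix.with_suffix(prefix.suffix + ".meta.json")


def _tsv_path(prefix: Path) -> Path:
    return prefix.with_suffix(prefix.suffix + ".tsv")


def save_matrix(
    prefix: str | Path,
    M: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    kind: str,
    fingerprint: str | None = None,
) -> Path:
    """Persist a matrix as ``<prefix>.tsv`` + ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    M = np.asarray(M)
    if M.shape != (len(row_ids), len(col_ids)):
        raise ValueError("matrix shape does not match row/column ids")
    meta_path = _meta_path(prefix)
    if meta_path.exists() and fingerprint is not None:
        old = json.loads(meta_path.read_text())
        if old.get("fingerprint") not in (None, fingerprint):
            raise FingerprintMismatchError(
                f"{meta_path} was written by config {old['fingerprint']}, "
                f"refusing to overwrite with {fingerprint}"
            )
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(_tsv_path(prefix), M, delimiter="\t", fmt="%.12g")
    meta = {
        "rows": list(row_ids),
        "columns": list(col_ids),
        "kind": kind,
        "fingerprint": fingerprint,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return _tsv_path(prefix)


def load_matrix(prefix: str | Path) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Load a matrix written by :func:`save_matrix`."""
    prefix = Path(prefix)
    meta = json.loads(_meta_path(prefix).read_text())
    M = np.loadtxt(_tsv_path(prefix), delimiter="\t", ndmin=2)
    if M.shape != (len(meta["rows"]), len(meta["columns"])):
        raise ValueError(f"{prefix}: matrix shape disagrees with its header")
    return M, meta["rows"], meta["columns"], meta


def write_predictions_tsv(
    path: str | Path, P: np.ndarray, genes: Sequence[str], terms: Sequence[str]
) -> Path:
    """Write gene<TAB>term<TAB>score rows for every gene-term pair."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for i, g in enumerate(genes):
            for j, t in enumerate(terms):
                fh.write(f"{g}\t{t}\t{P[i, j]:.6g}\n")
    return path


def write_annotation_tsv(path: str | Path, assignments: dict) -> Path:
    """Write a two-column gene<TAB>term annotation file (sorted, stable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for gene in sorted(assignments):
            for term in sorted(assignments[gene]):
                fh.write(f"{gene}\t{term}\n")
    return path


def write_term_groups_json(path: str | Path, groups: dict) -> Path:
    return write_json(path, {"groups": dict(sorted(groups.items()))})


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path
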
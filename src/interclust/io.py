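"""Readers and writers for the pipeline's external text formats.

Formats
-------
* Plot x species table: delimited text (comma or tab, auto-detected), header
  row of species identifiers, first column of plot identifiers.
* Similarity matrix: the dense CLUTO-style text format — ``n + 1`` lines,
  the first holding the number of rows, each remaining line holding ``n``
  whitespace-separated similarity values.
* Labels: two-column TSV ``sample_id<TAB>cluster``.
* Reference classes: two-column delimited text ``class,species``.

Every reader/writer pair round-trips losslessly at its declared precision,
and readers never reorder: file order defines index order.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    ClusterSolution,
    CommunityMatrix,
    ReferenceClassification,
    SimilarityMatrix,
    warn,
)

__all__ = [
    "read_community_matrix",
    "write_community_matrix",
    "read_similarity_cluto",
    "write_similarity_cluto",
    "read_reference_classes",
    "read_labels",
    "write_labels",
]


def _detect_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_community_matrix(path: str, delimiter: str | None = None) -> CommunityMatrix:
    """Read a plot x species table.

    First row holds species identifiers, first column plot identifiers, body
    is numeric.  Delimiter is auto-detected (comma/tab) unless given.
    """
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed community matrix {path}: {exc}") from exc
    body = df.to_numpy()
    if body.dtype.kind not in "fiu":
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ValueError(f"non-numeric entries in columns: {list(bad)}")
    if np.any(np.isnan(body)):
        i, j = np.argwhere(np.isnan(body))[0]
        raise ValueError(f"missing value at plot {df.index[i]!r} (data line {i + 2})")
    if np.any(body < 0):
        raise ValueError("negative abundance values are not allowed")
    return CommunityMatrix(
        plot_ids=[str(x) for x in df.index],
        species_ids=[str(c) for c in df.columns],
        values=body.astype(float),
    )


def write_community_matrix(m: CommunityMatrix, path: str, delimiter: str = ",") -> None:
    df = pd.DataFrame(m.values, index=m.plot_ids, columns=m.species_ids)
    df.to_csv(path, sep=delimiter)


def read_similarity_cluto(path: str, sample_ids: list[str] | None = None) -> SimilarityMatrix:
    """Read a dense CLUTO-style similarity file.

    Line 1 is the row count ``n``; lines 2..n+1 each hold ``n`` values.
    The matrix must be symmetric to 1e-9 and lie in [0, 1]; a missing unit
    diagonal is coerced to 1 with a warning.
    """
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if not lines:
        raise ValueError(f"{path}: empty similarity file")
    try:
        n = int(lines[0])
    except ValueError as exc:
        raise ValueError(f"{path}: first line must be the row count") from exc
    if n < 1:
        raise ValueError(f"{path}: row count must be positive, got {n}")
    if len(lines) - 1 != n:
        raise ValueError(f"{path}: declared {n} rows but found {len(lines) - 1}")
    rows = []
    for k, ln in enumerate(lines[1:], start=2):
        vals = ln.split()
        if len(vals) != n:
            raise ValueError(f"{path}: line {k} has {len(vals)} values, expected {n}")
        rows.append([float(v) for v in vals])
    values = np.array(rows, dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError(f"{path}: similarity values outside [0, 1]")
    if np.max(np.abs(values - values.T)) > 1e-9:
        raise ValueError(f"{path}: similarity matrix is asymmetric beyond 1e-9")
    diag = np.diag(values)
    if not np.allclose(diag, 1.0, atol=1e-9):
        warn(f"{path}: coercing similarity diagonal to 1 (self-similarity is 1 by definition)")
        np.fill_diagonal(values, 1.0)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    return SimilarityMatrix(sample_ids=sample_ids, values=values)


def write_similarity_cluto(sim: SimilarityMatrix, path: str, decimals: int = 6) -> None:
    """Write the dense CLUTO-style format at fixed decimal precision."""
    if sim.n_samples == 0:
        raise ValueError("cannot write an empty similarity matrix")
    with open(path, "w") as fh:
        fh.write(f"{sim.n_samples}\n")
        fmt = f"%.{decimals}f"
        for row in sim.values:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_reference_classes(path: str, delimiter: str | None = None) -> ReferenceClassification:
    """Read a two-column (class, species) delimited text file."""
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    classes: dict[str, set] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split(delimiter)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            cls, sp = parts[0].strip(), parts[1].strip()
            if not cls or not sp:
                raise ValueError(f"{path}:{lineno}: empty class or species name")
            if cls not in classes:
                classes[cls] = set()
                order.append(cls)
            classes[cls].add(sp)
    if not classes:
        raise ValueError(f"{path}: no reference classes found")
    return ReferenceClassification(classes=classes, class_order=order)


def write_labels(solution: ClusterSolution, path: str) -> None:
    """Write labels as TSV ``sample_id<TAB>cluster``."""
    ids = solution.sample_ids
    if ids is None:
        ids = [str(i) for i in range(len(solution.labels))]
    with open(path, "w") as fh:
        for sid, lab in zip(ids, solution.labels):
            fh.write(f"{sid}\t{int(lab)}\n")


def read_labels(path: str, sample_ids: Iterable[str] | None = None) -> ClusterSolution:
    """Read a labels TSV; order in file defines index order.

    When ``sample_ids`` is given (e.g. from a community or similarity
    matrix), every id in the file must belong to it, and the labels are
    returned in the order of ``sample_ids``.
    """
    ids: list[str] = []
    labs: list[int] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample_id<TAB>cluster'")
            ids.append(parts[0])
            try:
                labs.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: cluster label must be an integer") from exc
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        known = set(sample_ids)
        unknown = [i for i in ids if i not in known]
        if unknown:
            raise ValueError(f"{path}: unknown sample ids: {unknown[:5]}")
        if set(ids) != known or len(ids) != len(sample_ids):
            raise ValueError(f"{path}: labels do not cover every sample exactly once")
        by_id = dict(zip(ids, labs))
        return ClusterSolution(
            labels=np.array([by_id[i] for i in sample_ids]), sample_ids=list(sample_ids)
        )
    return ClusterSolution(labels=np.array(labs), sample_ids=ids)
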
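"""Readers and writers for the package's plain-text interchange formats.

Everything is diffable text.  The canonical delimiter is TAB; commas are
accepted on read (sniffed from the header line).

* Expression series: header ``gene_id`` + decimal hour labels, one row per
  gene.  Round-trips are exact to 12 significant digits.
* Edge lists: columns ``predictor``, ``target`` and optional ``score``.
* Ground-truth edge lists: ``predictor``, ``target``, ``coefficient``.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .errors import FormatError
from .network import RegulatoryNetwork
from .synthetic import ExpressionSeries, GroundTruthModel

__all__ = [
    "read_series",
    "write_series",
    "read_edges",
    "write_edges",
    "write_truth_edges",
]

_FLOAT_FMT = "%.12g"


def _sniff_sep(path: str | os.PathLike) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_series(path: str | os.PathLike) -> ExpressionSeries:
    """Read a genes x time-points matrix (TSV or CSV).

    The header must start with ``gene_id`` followed by numeric hour
    labels; the body must be rectangular and numeric with unique gene IDs.
    """
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first header cell must be 'gene_id'")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least 2 time columns")
    try:
        labels = tuple(float(c) for c in df.columns[1:])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric time label in header") from exc
    gene_ids = tuple(df["gene_id"].astype(str))
    if len(set(gene_ids)) != len(gene_ids):
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    body = df.iloc[:, 1:]
    if body.isna().any().any():
        line = int(body.isna().any(axis=1).idxmax()) + 2
        raise FormatError(f"{path}: missing value near line {line}")
    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionSeries(gene_ids, labels, values)


def write_series(series: ExpressionSeries, path: str | os.PathLike) -> None:
    """Write a series as TSV (header ``gene_id`` + decimal hour labels)."""
    with open(path, "w", encoding="utf-8") as fh:
        labels = "\t".join(_FLOAT_FMT % t for t in series.time_labels_h)
        fh.write(f"gene_id\t{labels}\n")
        for gid, row in zip(series.gene_ids, series.values):
            cells = "\t".join(_FLOAT_FMT % v for v in row)
            fh.write(f"{gid}\t{cells}\n")


def read_edges(
    path: str | os.PathLike, gene_panel: Sequence[str]
) -> RegulatoryNetwork:
    """Read an edge list over a known gene panel.

    Unknown genes and duplicate edges are format errors — the panel is the
    contract that keeps downstream statistics (N0, K) well defined.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["predictor", "target"]:
        raise FormatError(f"{path}: expected columns 'predictor', 'target'")
    panel = set(gene_panel)
    edges: dict[tuple[str, str], float | None] = {}
    has_score = "score" in cols
    for k, row in enumerate(df.itertuples(index=False), start=2):
        pred, tgt = str(row.predictor), str(row.target)
        if pred not in panel or tgt not in panel:
            missing = pred if pred not in panel else tgt
            raise FormatError(f"{path}:{k}: gene {missing!r} not in panel")
        if (pred, tgt) in edges:
            raise FormatError(f"{path}:{k}: duplicate edge {pred!r} -> {tgt!r}")
        score = float(getattr(row, "score")) if has_score else None
        edges[(pred, tgt)] = score
    return RegulatoryNetwork(tuple(gene_panel), edges)


def write_edges(
    net: RegulatoryNetwork, path: str | os.PathLike, sif: bool = False
) -> None:
    """Write an edge list sorted by (predictor, target).

    ``sif=True`` writes the 3-column SIF-style variant
    (``predictor  regulates  target``) instead.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if sif:
            for pred, tgt, _ in net.sorted_edges():
                fh.write(f"{pred}\tregulates\t{tgt}\n")
            return
        fh.write("predictor\ttarget\tscore\n")
        for pred, tgt, score in net.sorted_edges():
            cell = "" if score is None else _FLOAT_FMT % score
            fh.write(f"{pred}\t{tgt}\t{cell}\n")


def write_truth_edges(model: GroundTruthModel, path: str | os.PathLike) -> None:
    """Write a ground truth's nonzero coefficients as a TSV edge list."""
    rows = []
    coeff = model.coefficients
    for i, tgt in enumerate(model.gene_ids):
        for j, pred in enumerate(model.gene_ids):
            if coeff[i, j] != 0.0:
                rows.append((pred, tgt, coeff[i, j]))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("predictor\ttarget\tcoefficient\n")
        for pred, tgt, c in rows:
            fh.write(f"{pred}\t{tgt}\t{_FLOAT_FMT % c}\n")
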
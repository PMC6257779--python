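"""Time-point-deletion experiments.

The design: starting from a series with T time points, build the reference
dataset G0 (nothing deleted), the T single-deletion datasets G1..GT (Gk
drops the k-th time point), and optionally adjacent-pair deletions labelled
``Ga_b``.  Each dataset is re-analysed with the same inference settings and
summarised with the statistics panel; per-statistic cross-network averages
and relative diversity scores quantify which statistics are robust to the
sampling design and which time points matter.

The relative diversity score of a statistic Q over networks k is

    d = sum_k |Q_k - ave| / ave,    ave = mean_k Q_k

— a scale-invariant total relative deviation; small d means the statistic
barely reacts to deleting time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ExperimentError,
    InsufficientDataError,
    ParameterError,
    UndefinedScoreError,
)
from .inference import infer_network
from .netstats import STATS_COLUMNS, StatsRow, network_summary
from .network import RegulatoryNetwork
from .synthetic import ExpressionSeries

__all__ = [
    "DeletionDesign",
    "ExperimentResult",
    "delete_timepoints",
    "standard_design",
    "diversity_score",
    "run_experiment",
]

#: Minimum retained time points for an entry to be inferable (4 transitions).
MIN_TIMEPOINTS = 5


@dataclass(frozen=True)
class DeletionDesign:
    """Ordered deletion plan: (label, deleted 1-based time indices) entries."""

    entries: tuple[tuple[str, frozenset[int]], ...]
    reference_label: str = "G0"

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ParameterError("duplicate design labels")
        if self.reference_label not in labels:
            raise ParameterError(f"reference entry {self.reference_label!r} missing")
        for lab, deleted in self.entries:
            if lab == self.reference_label and deleted:
                raise ParameterError("reference entry must delete nothing")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.entries)


def standard_design(
    T: int,
    pairs: Iterable[tuple[int, int]] = (),
) -> DeletionDesign:
    """The G0 + G1..GT single-deletion design, plus optional pair deletions.

    ``pairs`` entries are 1-based index pairs (a, b) producing labels
    ``Ga_b``; the classic adjacent pairs for an 11-point diurnal series are
    (2, 3) and (9, 10).
    """
    if T < 3:
        raise ParameterError("standard design needs T >= 3")
    entries: list[tuple[str, frozenset[int]]] = [("G0", frozenset())]
    entries += [(f"G{k}", frozenset({k})) for k in range(1, T + 1)]
    for a, b in pairs:
        if not (1 <= a <= T and 1 <= b <= T) or a == b:
            raise ParameterError(f"invalid deletion pair ({a}, {b}) for T={T}")
        entries.append((f"G{a}_{b}", frozenset({a, b})))
    return DeletionDesign(tuple(entries))


def delete_timepoints(
    series: ExpressionSeries, indices: Iterable[int]
) -> ExpressionSeries:
    """Drop the given 1-based time points, keeping the rest in order.

    Downstream inference treats the retained consecutive columns as
    unit-lag transitions — the deleted gap is collapsed, not interpolated.
    """
    drop = set(int(i) for i in indices)
    T = series.n_timepoints
    for i in drop:
        if not (1 <= i <= T):
            raise ParameterError(f"time index {i} outside 1..{T}")
    keep = [k for k in range(T) if (k + 1) not in drop]
    if len(keep) < 2:
        raise InsufficientDataError("deletion leaves fewer than 2 time points")
    return ExpressionSeries(
        series.gene_ids,
        tuple(series.time_labels_h[k] for k in keep),
        series.values[:, keep].copy(),
    )


def diversity_score(values: Sequence[float]) -> float:
    """Relative diversity d = sum |Q_k - ave| / ave (scale-invariant)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ParameterError("diversity score needs at least 2 values")
    ave = float(vals.mean())
    if ave == 0.0:
        raise UndefinedScoreError("diversity score undefined for zero-mean values")
    return float(np.sum(np.abs(vals - ave)) / ave)


@dataclass(frozen=True)
class ExperimentResult:
    """Networks, per-network stats and the summary table of one sweep.

    ``stats`` has one row per successful entry (index = label, columns =
    the statistics panel); ``table`` is ``stats`` with the ``ave`` and
    ``d_score`` rows appended (a statistic whose cross-network mean is
    zero gets a NaN d_score).  ``failed`` lists entries whose retained
    series was too short to infer.
    """

    design: DeletionDesign
    networks: Mapping[str, RegulatoryNetwork]
    stats_rows: Mapping[str, StatsRow]
    stats: pd.DataFrame
    table: pd.DataFrame
    failed: tuple[str, ...]

    @property
    def reference_network(self) -> RegulatoryNetwork:
        return self.networks[self.design.reference_label]


def summarize_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Append ``ave`` (column means) and ``d_score`` rows to a stats table."""
    ave = stats.mean(axis=0)
    d_row = {}
    for col in stats.columns:
        vals = stats[col].to_numpy(dtype=float)
        try:
            d_row[col] = diversity_score(vals)
        except (UndefinedScoreError, ParameterError):
            d_row[col] = np.nan
    out = stats.copy()
    out.loc["ave"] = ave
    out.loc["d_score"] = pd.Series(d_row)
    return out


def run_experiment(
    series: ExpressionSeries,
    design: DeletionDesign,
    alpha1: float = 0.5,
    alpha2: float = 0.05,
    exclude_self: bool = True,
) -> ExperimentResult:
    """Delete, re-infer and summarise every design entry.

    Entries whose retained series keeps fewer than 5 time points (4
    transitions) are recorded as failed rather than aborting the sweep;
    the run fails only if *no* entry is inferable.  Deterministic given
    (series, design, thresholds).
    """
    networks: dict[str, RegulatoryNetwork] = {}
    rows: dict[str, StatsRow] = {}
    failed: list[str] = []
    for label, deleted in design.entries:
        sub = delete_timepoints(series, deleted) if deleted else series
        if sub.n_timepoints < MIN_TIMEPOINTS:
            failed.append(label)
            continue
        net = infer_network(sub, alpha1=alpha1, alpha2=alpha2, exclude_self=exclude_self)
        networks[label] = net
        rows[label] = network_summary(net, label=label)
    if not networks:
        raise ExperimentError("every design entry left too few time points")
    stats = pd.DataFrame(
        {col: [getattr(rows[lab], col) for lab in rows] for col in STATS_COLUMNS},
        index=list(rows),
    )
    return ExperimentResult(
        design=design,
        networks=networks,
        stats_rows=rows,
        stats=stats,
        table=summarize_stats(stats),
        failed=tuple(failed),
    )
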
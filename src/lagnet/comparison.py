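"""Network-versus-network comparison and cross-collection edge overlap.

A perturbed network is scored against the reference network over the full
universe of admissible ordered gene pairs (self-pairs excluded by default,
consistent with the inference default): true positives are edges present
in both, and sensitivity / precision / F-measure follow the usual
confusion-matrix definitions over directed edge sets.

Edge-overlap analysis asks the complementary question: which individual
regulations persist across (almost) all networks in a collection, and how
fast does the shared edge set shrink as the required number of supporting
networks grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import AlignmentError, ParameterError
from .network import RegulatoryNetwork
from .perturbation import ExperimentResult

__all__ = [
    "ConfusionCounts",
    "ComparisonMetrics",
    "EdgeOccurrence",
    "edge_confusion",
    "classification_metrics",
    "compare_collection",
    "edge_overlap",
    "common_regulations",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN over the admissible ordered gene pairs."""

    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fp + self.n_fn + self.n_tn


@dataclass(frozen=True)
class ComparisonMetrics:
    """Sensitivity, precision and their harmonic mean (F-measure)."""

    sensitivity: float
    precision: float
    f_measure: float


@dataclass(frozen=True)
class EdgeOccurrence:
    """Per-edge membership across a labelled network collection.

    ``membership`` maps each edge to the sorted labels containing it;
    ``exact_m``/``at_least_m`` count edges occurring in exactly / at least
    m networks, for m = 1..#networks.
    """

    labels: tuple[str, ...]
    membership: Mapping[tuple[str, str], tuple[str, ...]]
    exact_m: Mapping[int, int]
    at_least_m: Mapping[int, int]


def _check_panels(nets: Sequence[RegulatoryNetwork]) -> tuple[str, ...]:
    panels = {net.gene_ids for net in nets}
    if len(panels) != 1:
        raise AlignmentError("networks use different gene panels")
    return nets[0].gene_ids


def edge_confusion(
    reference: RegulatoryNetwork,
    predicted: RegulatoryNetwork,
    include_self: bool = False,
) -> ConfusionCounts:
    """Confusion counts of ``predicted`` against ``reference``.

    The pair universe is every ordered gene pair (p(p-1), or p^2 when
    ``include_self``); mismatched panels raise rather than silently
    intersecting.
    """
    _check_panels([reference, predicted])
    p = reference.n_genes
    universe = p * p if include_self else p * (p - 1)
    ref, pred = reference.edge_set, predicted.edge_set
    if not include_self:
        ref = frozenset(e for e in ref if e[0] != e[1])
        pred = frozenset(e for e in pred if e[0] != e[1])
    tp = len(ref & pred)
    fp = len(pred - ref)
    fn = len(ref - pred)
    return ConfusionCounts(tp, fp, fn, universe - tp - fp - fn)


def classification_metrics(counts: ConfusionCounts) -> ComparisonMetrics:
    """Sensitivity, precision, F-measure with zero-denominator cases -> 0."""
    tp, fp, fn = counts.n_tp, counts.n_fp, counts.n_fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return ComparisonMetrics(sens, prec, f)


def compare_collection(
    result: ExperimentResult | Mapping[str, RegulatoryNetwork],
    reference_label: str | None = None,
) -> dict[str, ComparisonMetrics]:
    """Score every network in a sweep against the reference network.

    The reference compared with itself is (1, 1, 1) by construction.
    """
    if isinstance(result, ExperimentResult):
        networks: Mapping[str, RegulatoryNetwork] = result.networks
        reference_label = reference_label or result.design.reference_label
    else:
        networks = result
        if reference_label is None:
            raise ParameterError("reference_label required for a plain mapping")
    if reference_label not in networks:
        raise ParameterError(f"reference network {reference_label!r} missing")
    reference = networks[reference_label]
    return {
        label: classification_metrics(edge_confusion(reference, net))
        for label, net in networks.items()
    }


def edge_overlap(networks: Mapping[str, RegulatoryNetwork]) -> EdgeOccurrence:
    """Edge membership and occurrence-count curves across a collection."""
    if len(networks) < 2:
        raise ParameterError("overlap analysis needs at least 2 networks")
    _check_panels(list(networks.values()))
    labels = tuple(networks)
    membership: dict[tuple[str, str], tuple[str, ...]] = {}
    for label, net in networks.items():
        for edge in net.edge_set:
            membership.setdefault(edge, ())
            membership[edge] += (label,)
    membership = {e: tuple(sorted(labs)) for e, labs in membership.items()}
    n = len(labels)
    exact = {m: 0 for m in range(1, n + 1)}
    for labs in membership.values():
        exact[len(labs)] += 1
    at_least = {m: sum(exact[k] for k in range(m, n + 1)) for m in range(1, n + 1)}
    return EdgeOccurrence(labels, membership, exact, at_least)


def common_regulations(
    networks: Mapping[str, RegulatoryNetwork], m: int
) -> list[dict[str, object]]:
    """Edges occurring in exactly ``m`` networks, with member/absent labels.

    Returns table rows (predictor, target, networks_with, networks_without)
    sorted by (predictor, target) — the "common regulations" view used to
    flag regulations insensitive to the sampling design.
    """
    occ = edge_overlap(networks)
    if not (1 <= m <= len(occ.labels)):
        raise ParameterError(f"m={m} outside 1..{len(occ.labels)}")
    all_labels = set(occ.labels)
    rows = []
    for (pred, tgt), labs in sorted(occ.membership.items()):
        if len(labs) == m:
            rows.append(
                {
                    "predictor": pred,
                    "target": tgt,
                    "networks_with": labs,
                    "networks_without": tuple(sorted(all_labels - set(labs))),
                }
            )
    return rows
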
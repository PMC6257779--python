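"""Directed regulatory networks over a fixed gene panel.

A :class:`RegulatoryNetwork` is a directed graph whose node set is the
*full* gene panel — genes with no regulations stay in the graph, because
panel-level statistics (isolated-node count N0, average degree K) depend on
them.  Edges are ordered ``(predictor, target)`` pairs, optionally carrying
a real score (a p-value for inferred networks, a coefficient for ground
truths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import FormatError

__all__ = ["RegulatoryNetwork"]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed graph over gene identifiers with optional per-edge scores.

    Parameters
    ----------
    gene_ids
        Ordered gene panel; every edge endpoint must be a member.
    edges
        Mapping ``(predictor, target) -> score`` (score may be ``None``).
    """

    gene_ids: tuple[str, ...]
    edges: Mapping[tuple[str, str], Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers in panel")
        panel = set(self.gene_ids)
        for pred, tgt in self.edges:
            if pred not in panel or tgt not in panel:
                raise FormatError(
                    f"edge ({pred!r} -> {tgt!r}) references a gene outside the panel"
                )
        object.__setattr__(self, "edges", dict(self.edges))

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edge_list(
        cls,
        gene_ids: Iterable[str],
        edge_list: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]],
    ) -> "RegulatoryNetwork":
        """Build from ``(predictor, target)`` or ``(predictor, target, score)`` rows."""
        edges: dict[tuple[str, str], Optional[float]] = {}
        for row in edge_list:
            pred, tgt = row[0], row[1]
            score = float(row[2]) if len(row) > 2 else None  # type: ignore[misc]
            if (pred, tgt) in edges:
                raise FormatError(f"duplicate edge ({pred!r} -> {tgt!r})")
            edges[(pred, tgt)] = score
        return cls(tuple(gene_ids), edges)

    # -- views ----------------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        """networkx view with the full panel as node set."""
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        for (pred, tgt), score in self.edges.items():
            g.add_edge(pred, tgt, score=score)
        return g

    def sorted_edges(self) -> list[tuple[str, str, Optional[float]]]:
        """Edges sorted by (predictor, target) for stable output."""
        return [(p, t, self.edges[(p, t)]) for p, t in sorted(self.edges)]
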
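"""TF-centric regulatory structure from bound footprints: regulons,
co-regulation subnetworks, and feed-forward loops.

All constructs operate at gene-level resolution: a TF "binds" a gene when at
least one of its bound footprints is annotated to that gene's locus. The
regulon of a TF is its set of bound target genes; a co-regulation subnetwork
around a focal TF is a partner TF whose own gene is a focal target and whose
regulon shares targets with the focal regulon; a feed-forward loop is a
(focal, intermediate TF, target) triple where the focal TF binds both the
intermediate's gene and the target, and the intermediate binds the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .binding import TFBSRecord
from .differential_analysis import Signature

__all__ = [
    "RegulatoryEdge",
    "CoregulationSubnetwork",
    "regulon",
    "targets_of",
    "coregulation",
    "feed_forward_loops",
    "to_graph",
    "write_edges",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatoryEdge:
    """Aggregated binding of one TF to one target gene."""

    source_tf: str
    target_gene: str
    n_tfbs: int
    mean_diff: float
    direction: Optional[str] = None  # up | down | None when no signature given

    def __post_init__(self) -> None:
        if self.n_tfbs < 1:
            raise ValueError("an edge needs at least one supporting footprint")


@dataclass(frozen=True)
class CoregulationSubnetwork:
    """A focal-TF/partner-TF pair with the targets they co-bind."""

    focal_tf: str
    partner_tf: str
    shared_targets: frozenset


def targets_of(bound_tfbs: Iterable[TFBSRecord], tf: str) -> set[str]:
    """Genes with >=1 annotated bound footprint of the TF."""
    return {r.gene_id for r in bound_tfbs if r.tf == tf and r.gene_id is not None}


def regulon(
    bound_tfbs: Sequence[TFBSRecord], tf: str, signature: Optional[Signature] = None
) -> list[RegulatoryEdge]:
    """One edge per (tf, target gene) with support counts and mean binding change.

    When a signature is given each edge carries the target's expression
    direction; targets outside the signature get direction None. A TF absent
    from the table yields an empty regulon (with a logged warning).
    """
    records = [r for r in bound_tfbs if r.tf == tf and r.gene_id is not None]
    if not records:
        logger.warning("TF %s has no annotated bound footprints", tf)
        return []
    by_gene: dict[str, list[float]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec.diff)
    edges = []
    for gene in sorted(by_gene):
        direction = None
        if signature is not None:
            direction = "up" if gene in signature.up else "down" if gene in signature.down else None
        edges.append(
            RegulatoryEdge(
                source_tf=tf,
                target_gene=gene,
                n_tfbs=len(by_gene[gene]),
                mean_diff=float(np.mean(by_gene[gene])),
                direction=direction,
            )
        )
    return edges


def coregulation(
    bound_tfbs: Sequence[TFBSRecord], focal_tf: str, tf_gene_map: Mapping[str, str]
) -> tuple[list[CoregulationSubnetwork], list[str]]:
    """Co-regulation subnetworks around a focal TF.

    Partners are TFs whose own gene is bound by the focal TF and whose
    regulon intersects the focal regulon; the second return value lists
    bound-partner TFs with no shared targets. Raises if the focal TF has no
    annotated bound footprints.
    """
    focal_targets = targets_of(bound_tfbs, focal_tf)
    if not focal_targets:
        raise ValueError(f"focal TF {focal_tf} absent from the bound set")
    subnetworks = []
    no_shared = []
    for partner, partner_gene in sorted(tf_gene_map.items()):
        if partner == focal_tf or partner_gene not in focal_targets:
            continue
        shared = targets_of(bound_tfbs, partner) & focal_targets
        if shared:
            subnetworks.append(
                CoregulationSubnetwork(
                    focal_tf=focal_tf, partner_tf=partner, shared_targets=frozenset(shared)
                )
            )
        else:
            no_shared.append(partner)
    return subnetworks, no_shared


def feed_forward_loops(
    bound_tfbs: Sequence[TFBSRecord], focal_tf: str, tf_gene_map: Mapping[str, str]
) -> list[tuple[str, str, str]]:
    """(focal, intermediate TF, target) triples forming feed-forward loops.

    The focal TF binds the intermediate TF's gene, the intermediate binds the
    target, and the focal TF also binds the target directly.
    """
    focal_targets = targets_of(bound_tfbs, focal_tf)
    loops = []
    for intermediate, inter_gene in sorted(tf_gene_map.items()):
        if intermediate == focal_tf or inter_gene not in focal_targets:
            continue
        for target in sorted(targets_of(bound_tfbs, intermediate) & focal_targets):
            loops.append((focal_tf, intermediate, target))
    return loops


def to_graph(edges: Iterable[RegulatoryEdge]) -> nx.DiGraph:
    """Directed TF -> target graph for export (layout left to external tools)."""
    graph = nx.DiGraph()
    for edge in edges:
        graph.add_node(edge.source_tf, kind="tf")
        graph.add_node(edge.target_gene, kind="gene")
        graph.add_edge(
            edge.source_tf,
            edge.target_gene,
            n_tfbs=edge.n_tfbs,
            mean_diff=edge.mean_diff,
            direction=edge.direction or "",
        )
    return graph


def write_edges(path, edges: Sequence[RegulatoryEdge]) -> None:
    rows = [
        (e.source_tf, e.target_gene, e.n_tfbs, e.mean_diff, e.direction or "")
        for e in sorted(edges, key=lambda e: (e.source_tf, e.target_gene))
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "n_tfbs", "mean_diff", "target_direction"]
    ).to_csv(path, sep="\t", index=False)
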
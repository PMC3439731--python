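"""Gene-family clustering over the inter-genome similarity graph.

Significant reciprocal hits between the non-redundant model sets define an
adjacency graph on gene models; gene families are its connected components
(single linkage over thresholded edges, with its known chaining
behaviour).  Components are found with the greedy fixed-point scheme: every
node starts in its own cluster, and the algorithm sweeps the list of
matching pairs merging cluster labels until a complete pass connects no
new objects.  The resulting partition is independent of pair order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import IntegrityError
from .io_formats import HitRecord
from .similarity import DEFAULT_THRESHOLD, SimilarityThreshold


@dataclass
class AdjacencyPairs:
    """Thresholded similarity graph: ``nodes`` maps every retained gene ID
    to its genome tag; ``edges`` holds unordered inter-genome ID pairs
    stored as sorted tuples."""

    nodes: dict[str, str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise IntegrityError(f"self-loop on {a}")
            if a not in self.nodes or b not in self.nodes:
                raise IntegrityError(f"edge ({a},{b}) endpoint not in nodes")


@dataclass
class GeneFamily:
    """A cluster of gene models spanning one or more genomes."""

    members_by_genome: dict[str, tuple[str, ...]]
    name: str | None = None

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(
            gid for ids in self.members_by_genome.values() for gid in ids
        ))

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(self.members_by_genome)

    @property
    def size(self) -> int:
        return sum(len(ids) for ids in self.members_by_genome.values())


def build_adjacency(hits: Iterable[HitRecord], nodes: Mapping[str, str],
                    threshold: SimilarityThreshold = DEFAULT_THRESHOLD,
                    require_reciprocal: bool = True) -> AdjacencyPairs:
    """Turn directed hits into the undirected clustering graph.

    With ``require_reciprocal`` (default) an edge {a, b} needs a
    significant hit in both directions, the strict reading of reciprocal
    search; with it off one direction suffices.  Intra-genome pairs are
    never edges: within-genome redundancy was already resolved by the
    dedup stage, and the clustering graph connects genomes.

    Hits may come pre-filtered or raw; the threshold is re-applied here,
    which makes the operation idempotent and safe for externally produced
    tables.
    """
    directed: set[tuple[str, str]] = set()
    for h in hits:
        for gid in (h.qseqid, h.sseqid):
            if gid not in nodes:
                raise IntegrityError(
                    f"hit references ID {gid} absent from the retained set "
                    "(dedup/clustering input mismatch)"
                )
        if h.qseqid == h.sseqid:
            continue
        if nodes[h.qseqid] == nodes[h.sseqid]:
            continue
        if threshold.accepts(h.evalue):
            directed.add((h.qseqid, h.sseqid))

    edges: set[tuple[str, str]] = set()
    for q, s in directed:
        pair = (q, s) if q < s else (s, q)
        if pair in edges:
            continue
        if not require_reciprocal or (s, q) in directed:
            edges.add(pair)
    return AdjacencyPairs(nodes=dict(nodes), edges=edges)


def greedy_cluster(adj: AdjacencyPairs) -> list[GeneFamily]:
    """Partition the graph into families by iterated label merging.

    Each node is first its own cluster; repeated sweeps over the matching
    pairs assign both endpoints the smaller of their two labels, until a
    full sweep changes nothing.  The fixed point labels every node with
    the minimum ID of its connected component, so the partition does not
    depend on the order the pairs are visited in.  Isolated nodes remain
    singleton families.
    """
    label = {gid: gid for gid in adj.nodes}
    pairs = sorted(adj.edges)
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            la, lb = label[a], label[b]
            if la == lb:
                continue
            m = la if la < lb else lb
            label[a] = m
            label[b] = m
            changed = True

    clusters: dict[str, dict[str, list[str]]] = {}
    for gid in adj.nodes:
        clusters.setdefault(label[gid], {}).setdefault(adj.nodes[gid], []).append(gid)
    families = []
    for root in sorted(clusters):
        by_genome = {
            tag: tuple(sorted(ids)) for tag, ids in sorted(clusters[root].items())
        }
        families.append(GeneFamily(members_by_genome=by_genome))
    return families


def write_families(families: Iterable[GeneFamily], path) -> None:
    """Two-column TSV export: family name (or index), member ID."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, fam in enumerate(families):
            name = fam.name if fam.name is not None else str(i)
            for gid in fam.members:
                fh.write(f"{name}\t{gid}\n")
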
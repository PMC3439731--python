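"""Within-genome redundancy filtering.

Draft genomes predicted ab initio carry many truncated or fragmented
copies of the same gene.  Each genome's model set is compared against
itself; models connected by a significant self-hit are grouped, and within
each group only the longest sequence is retained (ties broken by
lexicographically smallest ID).  This collapses fragment stacks onto their
full-length representative and yields the non-redundant set used for
inter-genome comparison.

Redundancy is resolved per connected component rather than per hit pair:
pairwise greedy removal would depend on hit order, whereas the component
rule is deterministic and idempotent, and coincides with the pairwise rule
for the dominant real case (several fragments all hitting one full-length
model).  A one-directional significant hit suffices as an edge —
fragment-versus-full-length hits are often asymmetric in significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import IntegrityError
from .io_formats import GeneModel, HitRecord, write_gene_list
from .similarity import DEFAULT_THRESHOLD, SimilarityThreshold


@dataclass(frozen=True)
class DedupReport:
    """Outcome of one genome's redundancy filtering.

    ``kept`` and the keys of ``removed`` partition the input IDs; every
    removed ID maps to the retained representative of its redundancy
    group.  ``groups`` lists the non-trivial similarity-connected
    components (sorted, deterministic).
    """

    kept: frozenset[str]
    removed: dict[str, str]
    groups: tuple[tuple[str, ...], ...]


class _DisjointSet:
    def __init__(self, items: Iterable[str]):
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        parent = self._parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller ID becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self._parent[rb] = ra


def dedup_genome(models: Sequence[GeneModel], self_hits: Iterable[HitRecord],
                 threshold: SimilarityThreshold = DEFAULT_THRESHOLD) -> DedupReport:
    """Collapse a genome's model set to a non-redundant set.

    Builds an undirected graph with an edge for every significant
    self-comparison hit (self-pairs ignored), keeps the longest member of
    each connected component, and removes the rest.  The result is
    independent of model and hit order.
    """
    by_id = {m.id: m for m in models}
    if len(by_id) != len(models):
        raise IntegrityError("duplicate gene-model IDs within genome")
    dsu = _DisjointSet(by_id)
    linked: set[str] = set()
    for h in self_hits:
        for gid in (h.qseqid, h.sseqid):
            if gid not in by_id:
                raise IntegrityError(f"self-hit references unknown ID {gid}")
        if h.qseqid == h.sseqid:
            continue
        if threshold.accepts(h.evalue):
            dsu.union(h.qseqid, h.sseqid)
            linked.add(h.qseqid)
            linked.add(h.sseqid)

    components: dict[str, list[str]] = {}
    for gid in linked:
        components.setdefault(dsu.find(gid), []).append(gid)

    kept = set(by_id) - linked
    removed: dict[str, str] = {}
    groups: list[tuple[str, ...]] = []
    for members in components.values():
        # representative: longest sequence, ties to smallest ID
        rep = min(members, key=lambda g: (-by_id[g].length, g))
        kept.add(rep)
        for gid in members:
            if gid != rep:
                removed[gid] = rep
        groups.append(tuple(sorted(members)))
    groups.sort()
    return DedupReport(kept=frozenset(kept), removed=removed, groups=tuple(groups))


def kept_models(models: Sequence[GeneModel], report: DedupReport) -> list[GeneModel]:
    """The non-redundant models, original order preserved."""
    return [m for m in models if m.id in report.kept]


def write_report(report: DedupReport, removed_path: str | Path,
                 kept_path: str | Path | None = None) -> None:
    """Emit the removed→representative map as two-column TSV and,
    optionally, the kept-ID list (sorted for reproducibility)."""
    with open(removed_path, "w", encoding="utf-8", newline="\n") as fh:
        for rem in sorted(report.removed):
            fh.write(f"{rem}\t{report.removed[rem]}\n")
    if kept_path is not None:
        write_gene_list(sorted(report.kept), kept_path)
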
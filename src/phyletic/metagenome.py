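"""Assembly of the union gene catalog and its presence/absence matrix.

Clustering yields anonymous gene families; this module names them by the
first-appearance rule — genomes are processed in ascending tag order, so
each family is tagged by the ID of its alphabetically first member — and
lays them out as the families × genomes indicator matrix with a per-family
``sum`` column and derived boolean group columns (e.g. a "Bilateria"
column true for families present in any bilaterian genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import GeneFamily
from .errors import IntegrityError, PhyleticError
from .io_formats import GeneModel, GenomeSet
from . import queries


@dataclass
class MetagenomeMatrix:
    """Gene-family presence/absence matrix.

    ``presence``: int 0/1 DataFrame, rows = family names (ascending),
    columns = genome tags in processing order.  ``group_cols``: boolean
    DataFrame over the same rows, one column per derived genome group.
    The ``sum`` column is always recomputed from the presence rows, never
    stored, so the row-sum identity holds by construction.
    """

    presence: pd.DataFrame
    group_cols: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.group_cols.empty and len(self.group_cols.columns) == 0:
            self.group_cols = pd.DataFrame(index=self.presence.index)
        if not self.presence.index.is_unique:
            raise IntegrityError("duplicate family names in matrix")
        values = self.presence.to_numpy()
        if values.size and not ((values == 0) | (values == 1)).all():
            raise IntegrityError("presence cells must be 0 or 1")
        if values.size and (values.sum(axis=1) < 1).any():
            raise IntegrityError("every family must be present somewhere")
        order = self.presence.index.sort_values()
        self.presence = self.presence.loc[order].astype("int8")
        self.group_cols = self.group_cols.loc[order]

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self.presence.index)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(self.presence.columns)

    @property
    def sum_col(self) -> pd.Series:
        return self.presence.sum(axis=1)

    def equals(self, other: "MetagenomeMatrix") -> bool:
        return (
            self.presence.astype(int).equals(other.presence.astype(int))
            and self.group_cols.equals(other.group_cols)
        )


def name_families(families: Iterable[GeneFamily],
                  genome_order: Sequence[str]) -> list[GeneFamily]:
    """Assign first-appearance names.

    Members are ordered by (position of their genome in ``genome_order``,
    then ID lexicographically within a genome); the family takes the ID of
    its first member.  Returns new families sorted by name; names are
    unique because families partition unique IDs.
    """
    rank = {tag: i for i, tag in enumerate(genome_order)}
    named: list[GeneFamily] = []
    for fam in families:
        unknown = set(fam.members_by_genome) - set(rank)
        if unknown:
            raise IntegrityError(
                f"family member genome(s) {sorted(unknown)} not in genome order")
        first_tag = min(fam.members_by_genome, key=lambda t: rank[t])
        name = min(fam.members_by_genome[first_tag])
        named.append(GeneFamily(members_by_genome=dict(fam.members_by_genome),
                                name=name))
    named.sort(key=lambda f: f.name)
    return named


def build_matrix(named_families: Sequence[GeneFamily],
                 genome_set: GenomeSet) -> MetagenomeMatrix:
    """Lay the named families out as a presence/absence matrix.

    presence[f, t] = 1 iff family f has at least one member from genome t
    (binary occupancy; copy number stays in the family export).  Group
    columns are evaluated through the query layer from the genome set's
    group definitions.
    """
    tags = genome_set.tags
    names = []
    rows = []
    for fam in named_families:
        if fam.name is None:
            raise PhyleticError("families must be named before matrix assembly")
        names.append(fam.name)
        rows.append([1 if t in fam.members_by_genome else 0 for t in tags])
    presence = pd.DataFrame(rows, index=names, columns=list(tags), dtype="int8")
    matrix = MetagenomeMatrix(presence=presence)
    if genome_set.groups:
        cols = {}
        for gname in genome_set.groups:
            expr = queries.parse_expression(gname, genome_set)
            cols[gname] = queries.evaluate_expression(expr, matrix)
        matrix.group_cols = pd.DataFrame(cols, index=matrix.presence.index)
    return matrix


def extract_members(family_names: Iterable[str],
                    families: Sequence[GeneFamily],
                    models_by_genome: Mapping[str, Sequence[GeneModel]],
                    ) -> dict[str, list[GeneModel]]:
    """Pull the original gene models of the requested families, grouped by
    genome and ready for FASTA export."""
    by_name = {f.name: f for f in families}
    index: dict[str, dict[str, GeneModel]] = {
        tag: {m.id: m for m in models}
        for tag, models in models_by_genome.items()
    }
    out: dict[str, list[GeneModel]] = {}
    for name in family_names:
        fam = by_name.get(name)
        if fam is None:
            raise PhyleticError(f"unknown family name {name!r}")
        for tag, ids in fam.members_by_genome.items():
            pool = index.get(tag)
            if pool is None:
                raise IntegrityError(f"no models supplied for genome {tag!r}")
            for gid in ids:
                if gid not in pool:
                    raise IntegrityError(f"model {gid} missing from genome {tag}")
                out.setdefault(tag, []).append(pool[gid])
    return out
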
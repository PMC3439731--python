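"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* protein multi-FASTA, one file per genome (input);
* the 12-column tab-separated hit table, identical to NCBI BLAST+
  ``-outfmt 6`` / legacy ``-m 8`` (input and output);
* the tab-delimited gene-family presence/absence matrix, spreadsheet
  compatible (output and re-readable input);
* plain gene-ID lists, one ID per line.

All text output uses ``\\n`` line endings and UTF-8.  Gene-model IDs and
genome tags must be tab-free so the tab-separated dialects stay parseable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .metagenome import MetagenomeMatrix

# Residues accepted after normalization: the 20 standard amino acids plus
# ambiguity codes B/Z/X and selenocysteine U.  A stop ("*") is only legal
# as a trailing character and is stripped on input.
_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBZXU")
_TAG_RE = re.compile(r"^[a-z]{2,8}$")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One predicted protein model.

    ``id`` is the first whitespace-delimited token of the FASTA header,
    ``genome`` the short lowercase tag of the genome the model came from,
    and ``sequence`` the normalized (uppercase, stop-stripped) amino-acid
    string.
    """

    id: str
    genome: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or "\t" in self.id:
            raise FormatError(f"invalid gene-model ID {self.id!r}")
        if not self.sequence:
            raise FormatError(f"gene model {self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class GenomeEntry:
    tag: str
    name: str
    fasta: Path | None = None


@dataclass
class GenomeSet:
    """The genomes of a run, in processing order, plus named tag groups.

    Entries are kept in ascending lexicographic tag order: genome sets are
    added alphabetically so that every gene family is later named by the ID
    under which it first appears.
    """

    entries: list[GenomeEntry]
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not _TAG_RE.match(e.tag):
                raise FormatError(
                    f"genome tag {e.tag!r} is not 2-8 lowercase letters"
                )
        tags = [e.tag for e in self.entries]
        if len(set(tags)) != len(tags):
            raise FormatError("duplicate genome tags in genome set")
        self.entries = sorted(self.entries, key=lambda e: e.tag)
        tag_set = set(tags)
        for gname, members in self.groups.items():
            unknown = set(members) - tag_set
            if unknown:
                raise FormatError(
                    f"group {gname!r} references undeclared tags: "
                    f"{sorted(unknown)}"
                )
            self.groups[gname] = tuple(members)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(e.tag for e in self.entries)


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One directed query→subject local-alignment hit (BLAST outfmt-6 row)."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.qseqid}->{self.sseqid}: negative e-value")
        if not (1 <= self.qstart <= self.qend):
            raise FormatError(f"hit {self.qseqid}->{self.sseqid}: bad query coords")
        if not (1 <= self.sstart <= self.send):
            raise FormatError(f"hit {self.qseqid}->{self.sseqid}: bad subject coords")
        if not (0.0 <= self.pident <= 100.0):
            raise FormatError(f"hit {self.qseqid}->{self.sseqid}: pident out of range")


def normalize_sequence(raw: str, record_id: str = "?", *, permissive: bool = False) -> str:
    """Uppercase ``raw``, strip trailing stop codons, validate residues.

    An internal ``*`` usually flags a mis-translated gene model and is a
    hard error; with ``permissive=True`` it is replaced by ``X`` instead,
    which tolerates model sets contaminated by translated non-coding
    fragments.
    """
    seq = raw.upper()
    while seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        if permissive:
            seq = seq.replace("*", "X")
        else:
            raise FormatError(
                f"gene model {record_id}: internal stop codon "
                "(use permissive mode to mask with X)"
            )
    if not seq:
        raise FormatError(f"gene model {record_id}: empty sequence")
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise FormatError(
            f"gene model {record_id}: invalid residues {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, genome_tag: str, *, permissive: bool = False) -> list[GeneModel]:
    """Read one genome's protein models in file order.

    IDs are the first whitespace-delimited header token and must be unique
    within the file.
    """
    path = Path(path)
    models: list[GeneModel] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"{path}: duplicate ID {record.id}")
        seen.add(record.id)
        seq = normalize_sequence(str(record.seq), record.id, permissive=permissive)
        models.append(GeneModel(id=record.id, genome=genome_tag, sequence=seq))
    if not models:
        raise FormatError(f"{path}: no FASTA records")
    return models


def write_fasta(models: Iterable[GeneModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.id, description="") for m in models
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


_HIT_FIELDS = (
    ("qseqid", str), ("sseqid", str), ("pident", float), ("length", int),
    ("mismatch", int), ("gapopen", int), ("qstart", int), ("qend", int),
    ("sstart", int), ("send", int), ("evalue", float), ("bitscore", float),
)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file.

    Blank lines and lines starting with ``#`` are skipped.  Scientific
    notation e-values (``1e-30``) are accepted.
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            kwargs = {}
            for (name, conv), value in zip(_HIT_FIELDS, cols):
                try:
                    kwargs[name] = conv(value)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: cannot parse field {name}={value!r}"
                    ) from exc
            hits.append(HitRecord(**kwargs))
    return hits


def _fmt(value: object) -> str:
    # repr() gives the shortest float string that round-trips exactly.
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    _fmt(getattr(h, name)) for name, _ in _HIT_FIELDS
                )
                + "\n"
            )


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    """One ID per line, input order preserved."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_matrix(matrix: "MetagenomeMatrix", path: str | Path) -> None:
    """Serialize a presence/absence matrix to spreadsheet-ready text.

    Header: ``gene``, the genome tags in processing order, ``sum``, then one
    column per derived group.  Presence cells are ``1``/``0``; group cells
    are ``TRUE``/``FALSE``.  Rows are ordered by family name ascending.
    """
    presence = matrix.presence
    groups = matrix.group_cols
    sums = matrix.sum_col
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["gene", *presence.columns, "sum", *groups.columns]
        fh.write("\t".join(header) + "\n")
        for name in presence.index:
            cells = [name]
            cells += [str(int(v)) for v in presence.loc[name]]
            cells.append(str(int(sums.loc[name])))
            cells += ["TRUE" if v else "FALSE" for v in groups.loc[name]]
            fh.write("\t".join(cells) + "\n")


def read_matrix(path: str | Path) -> "MetagenomeMatrix":
    """Re-read a matrix written by :func:`write_matrix`.

    Columns left of ``sum`` are genome tags, columns right of it are
    derived boolean group columns.
    """
    import pandas as pd

    from .metagenome import MetagenomeMatrix

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene" or "sum" not in header:
            raise FormatError(f"{path}: not a presence/absence matrix file")
        sum_pos = header.index("sum")
        tags = header[1:sum_pos]
        group_names = header[sum_pos + 1 :]
        names: list[str] = []
        pres_rows: list[list[int]] = []
        group_rows: list[list[bool]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cols)}"
                )
            names.append(cols[0])
            try:
                row = [int(v) for v in cols[1 : sum_pos + 1]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer presence cell") from exc
            if row[-1] != sum(row[:-1]):
                raise FormatError(
                    f"{path}:{lineno}: sum column disagrees with row"
                )
            pres_rows.append(row[:-1])
            group_rows.append([v.upper() == "TRUE" for v in cols[sum_pos + 1 :]])
    presence = pd.DataFrame(pres_rows, index=names, columns=tags, dtype="int8")
    group_cols = pd.DataFrame(group_rows, index=names, columns=group_names, dtype=bool)
    return MetagenomeMatrix(presence=presence, group_cols=group_cols)
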
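"""Boolean phyletic-pattern queries over the presence/absence matrix.

A small expression language mirrors the spreadsheet-style queries the
matrix is designed for: atoms are genome tags (true for a family iff it is
present in that genome) or named genome groups (expanding to OR over their
tags), combined with AND, OR, NOT and parentheses.  Both function syntax
``OR(ho,sa,br,ur,da,lo)`` and infix syntax ``ho OR sa`` are accepted;
keywords are case-insensitive.

On top of the language sit the canned statistics of a gain/loss analysis:
universal families (present everywhere), families unique to one genome,
the exclusive pairwise-sharing count table, and lineage loss counts
(absent in a genome, present in at least ``min_support`` others).  All
query results are pure functions of the presence matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

import numpy as np
import pandas as pd

from .errors import PhyleticError, QuerySyntaxError
from .io_formats import GenomeSet

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .metagenome import MetagenomeMatrix


# ---------------------------------------------------------------- AST ----

@dataclass(frozen=True)
class TagAtom:
    tag: str

    def evaluate(self, presence: pd.DataFrame) -> np.ndarray:
        return presence[self.tag].to_numpy() != 0


@dataclass(frozen=True)
class Not:
    operand: "Expression"

    def evaluate(self, presence: pd.DataFrame) -> np.ndarray:
        return ~self.operand.evaluate(presence)


@dataclass(frozen=True)
class And:
    operands: tuple["Expression", ...]

    def evaluate(self, presence: pd.DataFrame) -> np.ndarray:
        out = self.operands[0].evaluate(presence)
        for op in self.operands[1:]:
            out = out & op.evaluate(presence)
        return out


@dataclass(frozen=True)
class Or:
    operands: tuple["Expression", ...]

    def evaluate(self, presence: pd.DataFrame) -> np.ndarray:
        out = self.operands[0].evaluate(presence)
        for op in self.operands[1:]:
            out = out | op.evaluate(presence)
        return out


Expression = Union[TagAtom, Not, And, Or]


# ------------------------------------------------------------- parser ----

_TOKEN_RE = re.compile(r"\s*(?:(?P<word>[A-Za-z_][\w.]*)|(?P<sym>[(),]))")


class _Parser:
    def __init__(self, text: str, genome_set: GenomeSet):
        self.text = text
        self.tags = set(genome_set.tags)
        self.groups = genome_set.groups
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                if text[pos:].strip():
                    raise QuerySyntaxError(
                        f"unexpected character {text[pos]!r}", pos)
                break
            self.tokens.append((m.group("word") or m.group("sym"), m.start()))
            pos = m.end()
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def expect(self, sym: str) -> None:
        tok, pos = self.next()
        if tok != sym:
            raise QuerySyntaxError(f"expected {sym!r}, got {tok!r}", pos)

    # grammar: expr := term (OR term)* ; term := factor (AND factor)* ;
    # factor := NOT factor | "(" expr ")" | FUNC "(" atomlist ")" | atom
    def parse(self) -> Expression:
        expr = self.expr()
        tok = self.peek()
        if tok is not None:
            raise QuerySyntaxError(f"trailing token {tok[0]!r}", tok[1])
        return expr

    def expr(self) -> Expression:
        terms = [self.term()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0].upper() == "OR" and not self._is_func():
                self.next()
                terms.append(self.term())
            else:
                break
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> Expression:
        factors = [self.factor()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0].upper() == "AND" and not self._is_func():
                self.next()
                factors.append(self.factor())
            else:
                break
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def _is_func(self) -> bool:
        # OR/AND immediately followed by "(" is function syntax, not infix
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
        return nxt is not None and nxt[0] == "("

    def factor(self) -> Expression:
        tok, pos = self.next()
        upper = tok.upper()
        if upper == "NOT":
            return Not(self.factor())
        if tok == "(":
            inner = self.expr()
            self.expect(")")
            return inner
        if upper in ("OR", "AND"):
            self.expect("(")
            atoms = [self.atom()]
            while True:
                t = self.peek()
                if t is not None and t[0] == ",":
                    self.next()
                    atoms.append(self.atom())
                else:
                    break
            self.expect(")")
            cls = Or if upper == "OR" else And
            return cls(tuple(atoms))
        if tok in (")", ","):
            raise QuerySyntaxError(f"unexpected {tok!r}", pos)
        return self.resolve_atom(tok, pos)

    def atom(self) -> Expression:
        tok, pos = self.next()
        if tok in ("(", ")", ","):
            raise QuerySyntaxError(f"expected atom, got {tok!r}", pos)
        return self.resolve_atom(tok, pos)

    def resolve_atom(self, tok: str, pos: int) -> Expression:
        if tok.lower() in self.tags:
            return TagAtom(tok.lower())
        if tok in self.groups:
            return Or(tuple(TagAtom(t) for t in self.groups[tok]))
        raise QuerySyntaxError(f"unknown genome tag or group {tok!r}", pos)


def parse_expression(text: str, genome_set: GenomeSet) -> Expression:
    """Parse a phyletic-pattern expression against declared tags/groups.

    Named groups are expanded at parse time into OR over their tags.
    """
    expr = _Parser(text, genome_set).parse()
    return expr


# -------------------------------------------------------- evaluation ----

def _presence(matrix) -> pd.DataFrame:
    return matrix if isinstance(matrix, pd.DataFrame) else matrix.presence


def evaluate_expression(expr: Expression, matrix) -> pd.Series:
    """Per-family truth value of ``expr``; an atom is true iff the family
    is present in that genome."""
    presence = _presence(matrix)
    return pd.Series(expr.evaluate(presence), index=presence.index)


def universal_families(matrix) -> set[str]:
    """Families present in every genome."""
    presence = _presence(matrix)
    mask = (presence != 0).all(axis=1)
    return set(presence.index[mask])


def unique_families(matrix, tag: str) -> set[str]:
    """Families present in ``tag`` and in no other genome."""
    presence = _presence(matrix)
    if tag not in presence.columns:
        raise PhyleticError(f"unknown genome tag {tag!r}")
    mask = (presence[tag] != 0) & (presence.sum(axis=1) == 1)
    return set(presence.index[mask])


def exclusive_pair_matrix(matrix) -> pd.DataFrame:
    """Symmetric tag × tag table counting families shared by exactly the
    two genomes of each cell; the diagonal is zero."""
    presence = _presence(matrix)
    two = presence[presence.sum(axis=1) == 2]
    counts = two.T.to_numpy() @ two.to_numpy()
    np.fill_diagonal(counts, 0)
    return pd.DataFrame(counts, index=presence.columns, columns=presence.columns)


def loss_count(matrix, tag: str, min_support: int) -> tuple[int, set[str]]:
    """Families absent in ``tag`` but present in at least ``min_support``
    other genomes — the operational definition of a loss in that lineage.

    ``min_support`` has no default on purpose: how much outside support a
    loss call needs is an analysis decision, and results should always be
    read against the support level that produced them.
    """
    presence = _presence(matrix)
    if tag not in presence.columns:
        raise PhyleticError(f"unknown genome tag {tag!r}")
    n_other = presence.shape[1] - 1
    if not (1 <= min_support <= n_other):
        raise PhyleticError(
            f"min_support must be in [1, {n_other}], got {min_support}")
    absent = presence[tag] == 0
    support = presence.drop(columns=tag).sum(axis=1)
    mask = absent & (support >= min_support)
    names = set(presence.index[mask])
    return len(names), names


@dataclass(frozen=True)
class SummaryStats:
    total: int
    universal: int
    unique_total: int
    shared_other: int

    @property
    def pct_universal(self) -> float:
        return 100.0 * self.universal / self.total if self.total else 0.0

    @property
    def pct_unique(self) -> float:
        return 100.0 * self.unique_total / self.total if self.total else 0.0


def summary_stats(matrix) -> SummaryStats:
    """Headline decomposition of the catalog: families present everywhere,
    families private to one genome, and the rest (shared by 2+ but not
    all genomes)."""
    presence = _presence(matrix)
    total = presence.shape[0]
    sums = presence.sum(axis=1)
    universal = int((sums == presence.shape[1]).sum()) if total else 0
    unique_total = int((sums == 1).sum()) if total else 0
    return SummaryStats(
        total=total,
        universal=universal,
        unique_total=unique_total,
        shared_other=total - universal - unique_total,
    )


def write_pair_matrix(table: pd.DataFrame, path) -> None:
    """Tab-separated exclusive-pair table with tag header row and column."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(table.columns) + "\n")
        for tag in table.index:
            fh.write(tag + "\t" + "\t".join(str(int(v)) for v in table.loc[tag]) + "\n")
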
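"""Expression language and canned phyletic-pattern statistics vs brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_genome_set
from phyletic.errors import PhyleticError, QuerySyntaxError
from phyletic.metagenome import MetagenomeMatrix
from phyletic.queries import (
    And,
    Or,
    TagAtom,
    evaluate_expression,
    exclusive_pair_matrix,
    loss_count,
    parse_expression,
    summary_stats,
    unique_families,
    universal_families,
)

TAGS12 = ("am", "ar", "br", "ca", "da", "ho", "lo", "mo", "ne", "sa", "tr", "ur")
GS12 = make_genome_set(TAGS12, groups={"Bilateria": ("ho", "sa", "br", "ur", "da", "lo")})


def matrix_from(rows: dict[str, list[int]], tags=TAGS12) -> MetagenomeMatrix:
    return MetagenomeMatrix(
        presence=pd.DataFrame.from_dict(rows, orient="index", columns=list(tags)))


def random_matrix(seed: int, n_rows=50, n_tags=6) -> MetagenomeMatrix:
    rng = np.random.default_rng(seed)
    tags = [f"g{chr(ord('a') + i)}" for i in range(n_tags)]
    pres = rng.integers(0, 2, size=(n_rows, n_tags))
    pres[pres.sum(axis=1) == 0, 0] = 1
    names = [f"f{i:03d}" for i in range(n_rows)]
    return MetagenomeMatrix(presence=pd.DataFrame(pres, index=names, columns=tags))


class TestParser:
    def test_function_syntax(self):
        expr = parse_expression("OR(ho,sa,br,ur,da,lo)", GS12)
        assert isinstance(expr, Or) and len(expr.operands) == 6
        assert all(isinstance(a, TagAtom) for a in expr.operands)

    def test_single_atom(self):
        assert parse_expression("am", GS12) == TagAtom("am")

    def test_named_group_expands(self):
        expr = parse_expression("Bilateria", GS12)
        assert isinstance(expr, Or)
        assert {a.tag for a in expr.operands} == {"ho", "sa", "br", "ur", "da", "lo"}

    def test_keywords_case_insensitive(self):
        assert parse_expression("am and not tr", GS12) == parse_expression(
            "am AND NOT tr", GS12)

    def test_unknown_atom_named_in_error(self):
        with pytest.raises(QuerySyntaxError, match="zz"):
            parse_expression("am AND zz", GS12)

    def test_syntax_error_reports_position(self):
        with pytest.raises(QuerySyntaxError, match="position"):
            parse_expression("am AND (tr", GS12)
        with pytest.raises(QuerySyntaxError):
            parse_expression("OR(am,)", GS12)

    def test_truth_table_oracle(self):
        # evaluate "NOT (am OR tr) AND ne" on every assignment of 3 genomes
        gs = make_genome_set(("am", "ne", "tr"))
        expr = parse_expression("NOT (am OR tr) AND ne", gs)
        rows = {f"r{i}": list(bits) for i, bits in
                enumerate(itertools.product([0, 1], repeat=3))}
        pres = pd.DataFrame.from_dict(rows, orient="index", columns=["am", "ne", "tr"])
        got = expr.evaluate(pres)
        for (name, (am, ne, tr)), value in zip(sorted(rows.items()), got):
            assert value == ((not (am or tr)) and bool(ne))

    def test_infix_precedence_and_over_or(self):
        gs = make_genome_set(("aa", "bb", "cc"))
        expr = parse_expression("aa OR bb AND cc", gs)
        pres = pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["x", "y"],
                            columns=["aa", "bb", "cc"])
        assert list(expr.evaluate(pres)) == [True, False]


class TestEvaluate:
    def test_present_only_in_br(self):
        m = matrix_from({"f1": [0, 0, 1] + [0] * 9})
        mask = evaluate_expression(parse_expression("br", GS12), m)
        assert bool(mask.loc["f1"]) is True

    def test_printed_row_bilateria_true_via_sa(self):
        # presence (am..ur) = 1,0,0,1,0,0,0,0,0,1,0,1
        m = matrix_from({"Aqu1.201795": [1, 0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 1]})
        expr = parse_expression("OR(ho,sa,br,ur,da,lo)", GS12)
        assert bool(evaluate_expression(expr, m).loc["Aqu1.201795"]) is True


class TestCannedStats:
    def test_universal_all_ones_and_one_zero(self):
        m = matrix_from({"f1": [1] * 12, "f2": [1] * 11 + [0]})
        assert universal_families(m) == {"f1"}

    def test_unique_identity_matrix(self):
        tags = ("aa", "bb", "cc")
        m = matrix_from({f"f{i}": [int(i == j) for j in range(3)] for i in range(3)},
                        tags=tags)
        for i, t in enumerate(tags):
            assert unique_families(m, t) == {f"f{i}"}

    def test_unknown_tag_errors(self):
        m = random_matrix(0)
        with pytest.raises(PhyleticError):
            unique_families(m, "zz")
        with pytest.raises(PhyleticError):
            loss_count(m, "zz", 1)

    def test_exclusive_pair_single_family(self):
        m = matrix_from({"f1": [0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0],  # ar, tr
                         "f2": [1] * 12})
        table = exclusive_pair_matrix(m)
        assert table.loc["ar", "tr"] == 1 and table.loc["tr", "ar"] == 1
        assert int(table.to_numpy().sum()) == 2  # one unordered pair, symmetric
        assert (np.diag(table.to_numpy()) == 0).all()

    def test_loss_count_example(self):
        m = matrix_from({"f1": [1] * 10 + [0, 1]})  # absent only in tr
        count, names = loss_count(m, "tr", 2)
        assert (count, names) == (1, {"f1"})
        assert loss_count(m, "am", 2) == (0, set())

    def test_loss_min_support_bounds(self):
        m = random_matrix(1)
        with pytest.raises(PhyleticError):
            loss_count(m, "ga", 0)
        with pytest.raises(PhyleticError):
            loss_count(m, "ga", 6)

    def test_summary_small_example(self):
        m = matrix_from({"f1": [1, 1, 1], "f2": [1, 0, 0], "f3": [1, 1, 0]},
                        tags=("aa", "bb", "cc"))
        s = summary_stats(m)
        assert (s.total, s.universal, s.unique_total, s.shared_other) == (3, 1, 1, 1)

    def test_summary_empty(self):
        m = MetagenomeMatrix(presence=pd.DataFrame(columns=["aa", "bb"]))
        s = summary_stats(m)
        assert (s.total, s.universal, s.unique_total, s.shared_other) == (0, 0, 0, 0)
        assert s.pct_universal == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_canned_stats_match_brute_force(seed):
    """All canned statistics agree with per-row python scans on random
    matrices, and the accounting identities hold."""
    m = random_matrix(seed)
    pres = m.presence
    tags = list(pres.columns)
    rows = {name: [int(v) for v in pres.loc[name]] for name in pres.index}

    bf_universal = {n for n, r in rows.items() if all(r)}
    assert universal_families(m) == bf_universal

    uniq_all = set()
    for i, t in enumerate(tags):
        bf = {n for n, r in rows.items() if r[i] == 1 and sum(r) == 1}
        got = unique_families(m, t)
        assert got == bf
        assert got.isdisjoint(bf_universal)
        assert got.isdisjoint(uniq_all)
        uniq_all |= got

    s = summary_stats(m)
    assert s.total == s.universal + s.unique_total + s.shared_other
    assert s.unique_total == len(uniq_all)
    assert s.shared_other >= 0

    table = exclusive_pair_matrix(m)
    n_pairrows = sum(1 for r in rows.values() if sum(r) == 2)
    assert int(np.triu(table.to_numpy()).sum()) == n_pairrows
    for i, a in enumerate(tags):
        for j, b in enumerate(tags):
            bf = sum(1 for r in rows.values()
                     if sum(r) == 2 and r[i] == 1 and r[j] == 1 and i != j)
            assert table.loc[a, b] == bf

    prev = None
    for support in range(1, len(tags)):
        count, names = loss_count(m, tags[0], support)
        bf = {n for n, r in rows.items()
              if r[0] == 0 and sum(r[1:]) >= support}
        assert names == bf and count == len(bf)
        if prev is not None:
            assert count <= prev
        prev = count
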
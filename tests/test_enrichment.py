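import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import hypergeom

from gemsig.enrichment import (
    GeneSetCollection,
    bh_adjust,
    hypergeom_upper_tail,
    read_gmt,
    run_ora,
    weighted_counts,
)
from gemsig.errors import FormatError
from gemsig.mapping import MappingResult, MetaboliteSignature, ResolvedSignature
from gemsig.specificity import MappedGene, WeightParams


def make_mapping(weights: dict[str, float]) -> MappingResult:
    sig = MetaboliteSignature("synthetic", ["m1"])
    genes = [
        MappedGene(
            gene_id=g, symbol=None, metabolites_in_signature=("m1",),
            A_i=2, a_i=1, s_i=0.5, w_i=w, n_reactions=1, rank=i + 1,
        )
        for i, (g, w) in enumerate(sorted(weights.items()))
    ]
    return MappingResult(
        rule="non-directional",
        mapped_genes=genes,
        resolved_signature=ResolvedSignature(sig, {"m1": {"m1"}}, []),
        params=WeightParams(),
    )


# -- GMT ------------------------------------------------------------------


def test_read_gmt(gmt_file):
    coll = read_gmt(gmt_file)
    assert len(coll) == 3
    assert coll.members("S1") == {"g1", "g2"}


def test_read_gmt_deduplicates(tmp_path):
    p = tmp_path / "dup.gmt"
    p.write_text("S1\tdesc\tg1\tg1\tg2\n")
    assert read_gmt(p).members("S1") == {"g1", "g2"}


def test_read_gmt_rejects_short_lines(tmp_path):
    p = tmp_path / "short.gmt"
    p.write_text("S1\tdesc-only\n")
    with pytest.raises(FormatError, match="line"):
        read_gmt(p)


def test_read_gmt_empty_file_warns(tmp_path):
    p = tmp_path / "empty.gmt"
    p.write_text("")
    with pytest.warns(UserWarning):
        coll = read_gmt(p)
    assert len(coll) == 0


# -- weighted counts and the tail ----------------------------------------


def test_weighted_counts_round_half_up():
    bg = {"g1", "g2", "g3"}
    n_w, k_w = weighted_counts({"g1": 0.6, "g2": 0.6}, {"g1", "g2"}, bg)
    assert (n_w, k_w) == (1, 1)  # floor(0.5 + 1.2) = 1, clamped k


def test_weighted_counts_unit_weights_reduce_to_raw():
    bg = {f"g{i}" for i in range(10)}
    w = {f"g{i}": 1.0 for i in range(4)}
    assert weighted_counts(w, {"g0", "g1", "g9"}, bg) == (4, 2)


def test_weighted_counts_below_half_vanish():
    n_w, k_w = weighted_counts({"g1": 0.49}, {"g1"}, {"g1", "g2"})
    assert (n_w, k_w) == (0, 0)


def test_zero_query_reports_p_one(gmt_file):
    mapping = make_mapping({"g1": 0.49})
    [report] = run_ora(mapping, read_gmt(gmt_file), background={"g1", "g2", "g3"})
    assert all(r.p == 1.0 for r in report.rows)


def test_upper_tail_worked_example():
    # draw 3 of 10; 4 marked; all three marked: C(4,3)/C(10,3)
    assert hypergeom_upper_tail(10, 4, 3, 3) == pytest.approx(4 / 120, abs=1e-15)


def test_upper_tail_trivial_cases():
    assert hypergeom_upper_tail(50, 8, 10, 0) == 1.0
    assert hypergeom_upper_tail(12, 12, 5, 5) == 1.0


def test_upper_tail_matches_enumeration_small():
    for N in range(1, 9):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                marked = set(range(K))
                for k in range(0, n + 1):
                    hits = sum(
                        1
                        for draw in combinations(range(N), n)
                        if len(marked & set(draw)) >= k
                    )
                    expect = hits / math.comb(N, n)
                    assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                        expect, abs=1e-12
                    )


def test_upper_tail_argument_validation():
    for bad in [(10, 11, 3, 1), (10, 4, 11, 1), (10, 4, 3, 4)]:
        with pytest.raises(ValueError):
            hypergeom_upper_tail(*bad)


# -- BH adjustment --------------------------------------------------------


def bh_oracle(pvals):
    """Independent step-up: q_(i) = min over j>=i of p_(j) * m / j, capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * m / rank)
        q[i] = prev
    return q


def test_bh_matches_independent_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 40)).tolist()
        assert bh_adjust(p) == pytest.approx(bh_oracle(p).tolist(), abs=1e-12)


def test_bh_monotone_in_p():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    q = bh_adjust(p)
    assert all(a <= b for a, b in zip(q, q[1:]))
    assert all(qi >= pi for qi, pi in zip(q, p))


# -- run_ora --------------------------------------------------------------


def test_unweighted_ora_equals_classical(gmt_file):
    mapping = make_mapping({"g1": 0.7, "g2": 0.3, "g4": 0.9})
    bg = {f"g{i}" for i in range(1, 11)}
    [report] = run_ora(mapping, read_gmt(gmt_file), background=bg, use_weights=False)
    for row in report.rows:
        assert row.n_w == row.n_raw == 3
        assert row.k_w == row.k_raw
        expect = hypergeom.sf(row.k_raw - 1, len(bg), row.K, row.n_raw)
        assert row.p == pytest.approx(expect, abs=1e-12)


def test_single_set_collection_bh_is_identity(tmp_path):
    p = tmp_path / "one.gmt"
    p.write_text("S1\td\tg1\tg2\n")
    mapping = make_mapping({"g1": 1.0, "g2": 1.0})
    [report] = run_ora(mapping, read_gmt(p), background={"g1", "g2", "g3", "g4"})
    assert report.rows[0].p_adj == pytest.approx(report.rows[0].p)


def test_down_weighting_never_increases_kw_or_decreases_p(gmt_file):
    bg = {f"g{i}" for i in range(1, 11)}
    coll = read_gmt(gmt_file)
    base_w = {"g1": 0.9, "g2": 0.8, "g3": 0.7}
    [base] = run_ora(make_mapping(base_w), coll, background=bg)
    base_rows = {r.set_name: r for r in base.rows}
    for gene in base_w:
        lowered = dict(base_w, **{gene: base_w[gene] - 0.5})
        [low] = run_ora(make_mapping(lowered), coll, background=bg)
        for row in low.rows:
            b = base_rows[row.set_name]
            assert row.k_w <= b.k_w
            in_set = gene in coll.members(row.set_name)
            if in_set and (row.n_w, row.k_w) != (b.n_w, b.k_w):
                assert row.p >= b.p


def test_degenerate_set_rows_kept_with_p_one(gmt_file):
    mapping = make_mapping({"g1": 1.0})
    # S3's only member g9 is outside the background: K = 0, row kept at p = 1
    [report] = run_ora(mapping, read_gmt(gmt_file), background={"g1", "g2", "g3"})
    row = next(r for r in report.rows if r.set_name == "S3")
    assert row.K == 0 and row.p == 1.0
    assert len(report.rows) == 3


def test_empty_background_rejected(gmt_file):
    with pytest.raises(ValueError):
        run_ora(make_mapping({"g1": 1.0}), read_gmt(gmt_file), background=set())


def test_empty_mapping_rejected(gmt_file):
    sig = MetaboliteSignature("s", ["x"])
    empty = MappingResult(
        "non-directional", [], ResolvedSignature(sig, {}, ["x"]), WeightParams()
    )
    with pytest.raises(ValueError):
        run_ora(empty, read_gmt(gmt_file), background={"g1"})


def test_planted_enrichment_attains_minimum_p(tmp_path):
    """A set containing exactly the high-weight mapped genes must beat every
    other set, verified against brute-force scoring of all sets."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(40)]
    mapped = {g: 0.95 for g in genes[:6]}
    mapped.update({g: 0.2 for g in genes[6:10]})
    sets = {"PLANTED": ("d", frozenset(genes[:6]))}
    for j in range(12):
        members = rng.choice(genes[5:], size=8, replace=False)
        sets[f"R{j}"] = ("d", frozenset(members.tolist()))
    coll = GeneSetCollection("fixture", sets)
    [report] = run_ora(make_mapping(mapped), coll, background=set(genes))
    brute = {
        name: hypergeom_upper_tail(
            40,
            len(coll.members(name)),
            *weighted_counts(mapped, coll.members(name), set(genes)),
        )
        for name in sets
    }
    assert report.rows[0].set_name == "PLANTED"
    assert report.rows[0].p == pytest.approx(min(brute.values()))
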
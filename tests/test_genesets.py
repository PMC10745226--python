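"""Gene-list algebra and binomial pathway overrepresentation."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from adaredit.calling import EditingEvent
from adaredit.genesets import (
    GeneSet,
    PathwayUniverse,
    edited_gene_lists,
    enrich,
    genes_of_significance,
    intersect,
    load_gene_list,
    load_gmt,
    union_unique,
)


def exact_binom_upper_tail(k: int, n: int, p: float) -> float:
    """Independent oracle: P(X >= k) summed exactly over rationals."""
    pf = Fraction(p)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def gs(*genes, name="s"):
    return GeneSet(name=name, genes=frozenset(genes))


class TestLists:
    def test_load_deduplicates(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("gene_id\ng1\ng2\ng2\n")
        s = load_gene_list(p)
        assert s.genes == {"g1", "g2"}

    def test_version_suffix_stripped(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("gene_id\nENSG00000001.5\nENSG00000001.7\n")
        assert load_gene_list(p).genes == {"ENSG00000001"}

    def test_empty_column_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("gene_id\n\n")
        with pytest.raises(ValueError):
            load_gene_list(p)

    def test_intersection_and_union(self):
        a, b = gs("g1", "g2", "g3"), gs("g2", "g3", "g4")
        assert intersect(a, b).genes == {"g2", "g3"}
        assert union_unique(a, b).genes == {"g1", "g2", "g3", "g4"}
        assert intersect(a, a).genes == a.genes

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.frozensets(st.integers(0, 30), max_size=20),
        b=st.frozensets(st.integers(0, 30), max_size=20),
    )
    def test_inclusion_exclusion(self, a, b):
        sa, sb = gs(*map(str, a)), gs(*map(str, b))
        assert len(union_unique(sa, sb)) == len(sa) + len(sb) - len(intersect(sa, sb))

    def test_genes_of_significance_partition(self):
        pre, post = gs("a", "b", "c"), gs("b", "c", "d")
        parts = genes_of_significance(pre, post)
        assert parts["shared"].genes == {"b", "c"}
        assert parts["unique_pre"].genes == {"a"}
        assert parts["unique_post"].genes == {"d"}
        assert len(parts["combined"]) == 4
        # identity and disjoint degenerate cases
        same = genes_of_significance(pre, pre)
        assert not same["unique_pre"].genes and same["combined"].genes == pre.genes


class TestEditedGeneLists:
    def _ev(self, sample, gene, impact="HIGH"):
        return EditingEvent(
            sample_id=sample, chrom="1", pos=1, ref="A", alt="G",
            gene_id=gene, transcript_id="T", impact=impact,
        )

    GROUPS = {"S1": "g", "S2": "h"}

    def test_unique_genes_per_group(self):
        events = [self._ev("S1", "g1"), self._ev("S1", "g1"), self._ev("S1", "g2")]
        out = edited_gene_lists(events, self.GROUPS)
        assert out["g"].genes == {"g1", "g2"}

    def test_impact_filter(self):
        events = [self._ev("S1", "g1", impact="MODIFIER")]
        assert edited_gene_lists(events, self.GROUPS) == {}

    def test_restriction_to_reference_list(self):
        events = [self._ev("S1", "g1"), self._ev("S1", "g2")]
        out = edited_gene_lists(events, self.GROUPS, restrict_to=gs("g2"))
        assert out["g"].genes == {"g2"}

    def test_matches_truth_table_recount(self, small_cohort, cohort_records, cohort_groups):
        from adaredit.calling import filter_editing_candidates, recurrence_filter

        _, _, truth = small_cohort
        events = []
        for recs in cohort_records.values():
            events.extend(filter_editing_candidates(recs))
        events = recurrence_filter(events, cohort_groups)
        observed = {
            g: s.genes for g, s in edited_gene_lists(events, cohort_groups).items()
        }
        assert observed == truth.expected_gene_sets(min_samples=2)


def _universe(n_extra=400):
    """200-gene pathway P plus a sea of background genes."""
    pw = frozenset(f"p{i}" for i in range(200))
    other = frozenset(f"x{i}" for i in range(n_extra))
    return PathwayUniverse(
        pathways={"P": pw, "Q": frozenset(list(other)[:100])},
        universe=pw | other,
    )


class TestEnrich:
    def test_upper_tail_matches_exact_summation(self):
        """n=20, K/N=0.1, k=8: p equals the brute-force binomial sum."""
        uni = PathwayUniverse(
            pathways={"P": frozenset(f"p{i}" for i in range(10))},
            universe=frozenset(f"p{i}" for i in range(10)) | frozenset(f"x{i}" for i in range(90)),
        )
        query = gs(*[f"p{i}" for i in range(8)], *[f"x{i}" for i in range(12)])
        res = enrich(query, uni, min_genes=1, min_fraction=0.0)
        row = res[res["pathway"] == "P"].iloc[0]
        assert row["k"] == 8 and row["n"] == 20
        assert row["p_value"] == pytest.approx(exact_binom_upper_tail(8, 20, 0.1), abs=1e-12)

    def test_zero_overlap_pathways_not_tested(self):
        uni = _universe()
        res = enrich(gs(*[f"p{i}" for i in range(15)]), uni, min_genes=1, min_fraction=0.0)
        assert set(res["pathway"]) == {"P"}  # no query gene falls in Q

    def test_genes_absent_from_universe_dropped(self):
        uni = _universe()
        res = enrich(gs("p0", "p1", "NOT_THERE"), uni, min_genes=1, min_fraction=0.0)
        assert (res["n"] == 2).all()

    def test_empty_effective_list_rejected(self):
        with pytest.raises(ValueError):
            enrich(gs("nope"), _universe())

    def test_invariant_to_duplicates_and_order(self, tmp_path):
        p1 = tmp_path / "a.tsv"
        p1.write_text("gene_id\np0\np1\np2\n")
        p2 = tmp_path / "b.tsv"
        p2.write_text("gene_id\np2\np0\np1\np1\n")
        uni = _universe()
        r1 = enrich(load_gene_list(p1), uni, min_genes=1, min_fraction=0.0)
        r2 = enrich(load_gene_list(p2), uni, min_genes=1, min_fraction=0.0)
        assert r1["p_value"].tolist() == r2["p_value"].tolist()

    def test_bh_monotone_and_bounded(self):
        uni = PathwayUniverse(
            pathways={
                f"P{i}": frozenset(f"g{j}" for j in range(i * 5, i * 5 + 20))
                for i in range(8)
            },
            universe=frozenset(f"g{j}" for j in range(500)),
        )
        query = gs(*[f"g{j}" for j in range(30)])
        res = enrich(query, uni, min_genes=1, min_fraction=0.0)
        by_p = res.sort_values("p_value")
        assert by_p["fdr"].is_monotonic_increasing
        assert (res["fdr"] <= 1).all()
        assert (res["fdr"] >= res["p_value"]).all()

    def test_reporting_filters_each_violated_in_isolation(self):
        """k >= 10 AND k/n >= 0.10 AND fdr < alpha; break one at a time."""
        uni = _universe(n_extra=1800)  # pathway P is 10% of the universe
        # passes all three: k=15 of n=20 in P, strong enrichment
        strong = gs(*[f"p{i}" for i in range(15)], *[f"x{i}" for i in range(5)])
        res = enrich(strong, uni)
        assert bool(res[res["pathway"] == "P"]["reported"].iloc[0])
        # k=9 < 10 but still >10% of list and significant
        few = gs(*[f"p{i}" for i in range(9)], *[f"x{i}" for i in range(11)])
        res = enrich(few, uni)
        row = res[res["pathway"] == "P"].iloc[0]
        assert row["fdr"] < 0.05 and row["pct_of_list"] > 0.10 and not row["reported"]
        # k=10, 1/3 of the list, but composition matches the background
        # proportion of a small universe: no enrichment signal
        null_uni = _universe(n_extra=400)
        null_query = gs(*[f"p{i}" for i in range(10)], *[f"x{i}" for i in range(20)])
        res = enrich(null_query, null_uni)
        row = res[res["pathway"] == "P"].iloc[0]
        assert row["k"] >= 10 and row["pct_of_list"] >= 0.10
        assert row["fdr"] >= 0.05 and not row["reported"]


def test_gmt_round_trip(tmp_path):
    p = tmp_path / "p.gmt"
    p.write_text("A\tdesc\tg1\tg2\nB\tdesc\tg2\tg3\tg4\n")
    uni = load_gmt(p)
    assert uni.pathways["A"] == {"g1", "g2"}
    assert uni.universe == {"g1", "g2", "g3", "g4"}
    assert load_gmt(p, background=["g1", "g2", "g3", "g4", "g5"]).n_genes == 5
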
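"""Group statistics validated against closed-form and enumeration oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adaredit.calling import EditingEvent
from adaredit.stats import (
    TwoByTwoTable,
    build_contingency,
    chi2_test,
    kruskal_wallis,
    mann_whitney,
    summarize_groups,
)


def chi2_closed_form(a, b, c, d):
    """Independent oracle: N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    N = a + b + c + d
    return N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def mw_enumeration(xs, ys):
    """Independent oracle: exact two-tailed p by enumerating every assignment
    of pooled ranks to group x (tie-free data only)."""
    nx, ny = len(xs), len(ys)
    pooled = sorted(xs + ys)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank for v in xs for rank in [ranks[v]]) - nx * (nx + 1) / 2
    us = []
    for subset in combinations(range(1, nx + ny + 1), nx):
        us.append(sum(subset) - nx * (nx + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def _ev(sample, impact="MODERATE", pc=False, nmd=False, pos=1):
    return EditingEvent(
        sample_id=sample, chrom="1", pos=pos, ref="A", alt="G",
        gene_id="G", transcript_id="T", impact=impact,
        is_protein_coding=pc, is_nmd=nmd,
    )


class TestChi2:
    def test_equal_proportions_zero_statistic(self):
        stat, p, dof = chi2_test(TwoByTwoTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0 and dof == 1

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, _, _ = chi2_test(TwoByTwoTable(int(a), int(b), int(c), int(d)))
            assert stat == pytest.approx(chi2_closed_form(a, b, c, d), abs=1e-9)

    def test_extreme_table(self):
        stat, _, _ = chi2_test(TwoByTwoTable(0, 10, 10, 0))
        assert stat == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_test(TwoByTwoTable(0, 0, 5, 5))

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_invariance_under_row_and_column_swap(self, t):
        a, b, c, d = t
        s0, _, _ = chi2_test(TwoByTwoTable(a, b, c, d))
        s_rows, _, _ = chi2_test(TwoByTwoTable(c, d, a, b))
        s_cols, _, _ = chi2_test(TwoByTwoTable(b, a, d, c))
        assert s0 == pytest.approx(s_rows) == pytest.approx(s_cols)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)


class TestMannWhitney:
    def test_disjoint_groups_textbook_case(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2/20 over all C(6,3) assignments

    def test_identical_multisets_symmetric_u(self):
        U, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert U == pytest.approx(4.5)  # nA*nB/2 with ties at every value

    def test_u_sum_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            xs = list(rng.normal(size=rng.integers(2, 10)))
            ys = list(rng.normal(size=rng.integers(2, 10)))
            Ux, _ = mann_whitney(xs, ys)
            Uy, _ = mann_whitney(ys, xs)
            assert Ux + Uy == pytest.approx(len(xs) * len(ys))

    def test_exact_p_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(2)
        for nx in (2, 3, 5):
            for ny in (2, 4, 6):
                xs = list(rng.permutation(100)[: nx + ny])
                ys = [float(v) for v in xs[nx:]]
                xs = [float(v) for v in xs[:nx]]
                u_oracle, p_oracle = mw_enumeration(xs, ys)
                U, p = mann_whitney(xs, ys)
                assert U == pytest.approx(u_oracle)
                assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_constants_degenerate(self):
        H, p, degenerate = kruskal_wallis({"a": [5, 5], "b": [5, 5, 5]})
        assert H == 0.0 and p == 1.0 and degenerate

    def test_two_group_hand_computation(self):
        # ranks 1..6; H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 27/7
        H, p, _ = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert H == pytest.approx(27 / 7)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1, 2]})


class TestContingency:
    def test_direct_counting(self):
        ea = [_ev("S1", "HIGH")] * 3 + [_ev("S1", "LOW")] * 7
        eb = [_ev("S2", "HIGH")] * 5 + [_ev("S2", "LOW")] * 5
        t = build_contingency(ea, eb, lambda e: e.impact in ("HIGH", "MODERATE"))
        assert (t.a, t.b, t.c, t.d) == (3, 7, 5, 5)

    def test_predicate_matching_nothing(self):
        ea, eb = [_ev("S1")] * 4, [_ev("S2")] * 6
        t = build_contingency(ea, eb, lambda e: e.impact == "HIGH")
        assert (t.a, t.b, t.c, t.d) == (0, 4, 0, 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([], [_ev("S2")], lambda e: True)


class TestCalibrationAndPower:
    def test_chi2_type_i_error_near_alpha(self):
        """Null 2x2 tables (both groups drawn from the same proportion):
        rejection rate at alpha=0.05 within the binomial 99% CI."""
        from adaredit.simulate import null_contingency_tables

        tables = null_contingency_tables(2000, 2000, 0.12, 500, seed=13)
        rejections = 0
        for t in tables:
            _, p, _ = chi2_test(TwoByTwoTable(*t.ravel().tolist()))
            rejections += p < 0.05
        rate = rejections / 500
        half = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_chi2_power_on_planted_shift(self):
        """A 5-percentage-point shift at 2000 events per group is detected
        in >90% of replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.binomial(2000, 0.10)
            c = rng.binomial(2000, 0.15)
            _, p, _ = chi2_test(TwoByTwoTable(int(a), 2000 - int(a), int(c), 2000 - int(c)))
            rejections += p < 0.05
        assert rejections / n_rep > 0.90


class TestSummarize:
    def test_report_blocks_and_hand_means(self):
        events = (
            [_ev("S1", pos=p) for p in range(4)]
            + [_ev("S2", pos=p) for p in range(6)]
            + [_ev("S3", pos=p) for p in range(5)]
            + [_ev("S4", pos=p) for p in range(5)]
        )
        groups = {"S1": "g", "S2": "g", "S3": "h", "S4": "h"}
        expr = pd.DataFrame(
            {"S1": [1.0], "S2": [2.0], "S3": [3.0], "S4": [4.0]}, index=["ADAR"]
        )
        rep = summarize_groups(events, groups, expression=expr)
        per_group = {r["group"]: r for r in rep["per_group"]}
        assert per_group["g"]["mean"] == 5.0 and per_group["g"]["sem"] == pytest.approx(1.0)
        assert rep["mann_whitney"] and rep["kruskal_wallis"]
        assert {r["gene"] for r in rep["kruskal_wallis"]} == {"ADAR"}

    def test_missing_group_comparison_skipped(self):
        events = [_ev("S1", pos=p) for p in range(3)] + [_ev("S2", pos=p) for p in range(3)]
        groups = {"S1": "OlderMales", "S2": "PDMales"}
        rep = summarize_groups(events, groups)
        pairs = {(r["group_a"], r["group_b"]) for r in rep["mann_whitney"]}
        assert pairs == {("OlderMales", "PDMales")}
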
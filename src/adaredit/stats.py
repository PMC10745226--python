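"""Between-group statistics on editing events and expression.

Categorical event counts (high/moderate vs other, protein-coding vs not,
NMD vs not, deleterious vs tolerated) are compared with a Pearson chi-square
on the 2x2 table, without continuity correction by default.  Per-sample event
totals are compared with the Mann-Whitney U test (exact when tie-free and
enumerable), and per-gene expression across groups with the Kruskal-Wallis
test.  Bare p-values from any particular cohort are not reproduction targets;
the tests are validated against enumeration/closed-form oracles and by
type-I-error calibration on synthetic nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import EditingEvent, count_events_per_sample

__all__ = [
    "TwoByTwoTable",
    "build_contingency",
    "chi2_test",
    "mann_whitney",
    "kruskal_wallis",
    "summarize_groups",
    "STANDARD_COMPARISONS",
]

# the four standard pairwise comparisons when the five standard groups exist
STANDARD_COMPARISONS = (
    ("OlderMales", "PDMales"),
    ("OlderMales", "YoungerMales"),
    ("PDMales", "PostTrainingPD"),
    ("PreTrainingPD", "PostTrainingPD"),
)

EXACT_ENUM_LIMIT = 20_000


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts: rows = groups, columns = in-category vs complement."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_contingency(
    events_a: Iterable[EditingEvent],
    events_b: Iterable[EditingEvent],
    predicate: Callable[[EditingEvent], bool],
) -> TwoByTwoTable:
    """2x2 table of events satisfying ``predicate`` vs complement in each
    group; the counting unit is the event (sample-site-transcript)."""
    ea, eb = list(events_a), list(events_b)
    if not ea or not eb:
        raise ValueError("both groups must contain events")
    a = sum(1 for e in ea if predicate(e))
    c = sum(1 for e in eb if predicate(e))
    return TwoByTwoTable(a=a, b=len(ea) - a, c=c, d=len(eb) - c)


def chi2_test(
    table: TwoByTwoTable, correction: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-square on a 2x2 table; (statistic, two-tailed p, df=1).

    No Yates continuity correction unless requested.  A zero row or column
    margin makes expected counts undefined and is rejected.
    """
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def mann_whitney(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U for independent samples; returns (U_x, p).

    Uses the exact null distribution when there are no ties and the number of
    rank assignments C(nx+ny, nx) is enumerable (<= 20,000); otherwise the
    tie-corrected normal approximation.  U_x + U_y = nx * ny always.
    """
    xs, ys = list(xs), list(ys)
    if not xs or not ys:
        raise ValueError("both groups must be nonempty")
    pooled = xs + ys
    no_ties = len(set(pooled)) == len(pooled)
    exact = no_ties and comb(len(xs) + len(ys), len(xs)) <= EXACT_ENUM_LIMIT
    res = stats.mannwhitneyu(
        xs, ys, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]]
) -> tuple[float, float, bool]:
    """Tie-corrected Kruskal-Wallis H across >=2 groups; (H, p, degenerate).

    When every value in every group is identical the statistic is 0 by
    convention and p = 1, flagged degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, True
    H, p = stats.kruskal(*arrays)
    return float(H), float(p), False


def _category_predicates() -> dict[str, Callable[[EditingEvent], bool]]:
    return {
        "high_moderate": lambda e: e.impact in ("HIGH", "MODERATE"),
        "protein_coding": lambda e: bool(e.is_protein_coding),
        "nmd": lambda e: bool(e.is_nmd),
    }


def summarize_groups(
    events: Iterable[EditingEvent],
    groups: Mapping[str, str],
    expression: pd.DataFrame | None = None,
    expression_genes: Sequence[str] = ("ADAR", "ADARB1", "ADARB2"),
    comparisons: Sequence[tuple[str, str]] | None = None,
    categories: Mapping[str, Callable[[EditingEvent], bool]] | None = None,
) -> dict:
    """Cohort report: per-group event means +/- SEM, pairwise Mann-Whitney on
    per-sample totals, per-category chi-square comparisons, and per-gene
    Kruskal-Wallis on expression.

    ``comparisons`` defaults to the standard pairs present in the cohort, or
    all pairs when none of the standard group labels are used.  Missing groups
    are skipped, not errors.
    """
    events = list(events)
    per_sample, per_group = count_events_per_sample(events, groups)
    group_names = sorted(set(groups.values()))
    if comparisons is None:
        comparisons = [
            c for c in STANDARD_COMPARISONS
            if c[0] in group_names and c[1] in group_names
        ] or [
            (a, b)
            for i, a in enumerate(group_names)
            for b in group_names[i + 1 :]
        ]
    by_group: dict[str, list[EditingEvent]] = {g: [] for g in group_names}
    for ev in events:
        by_group[groups[ev.sample_id]].append(ev)

    mw_rows = []
    for ga, gb in comparisons:
        if ga not in group_names or gb not in group_names:
            continue
        xs = [per_sample[s] for s, g in groups.items() if g == ga]
        ys = [per_sample[s] for s, g in groups.items() if g == gb]
        U, p = mann_whitney(xs, ys)
        mw_rows.append({"group_a": ga, "group_b": gb, "U": U, "p_value": p})

    preds = dict(categories) if categories is not None else _category_predicates()
    chi_rows = []
    for ga, gb in comparisons:
        for cat, pred in preds.items():
            ea, eb = by_group.get(ga, []), by_group.get(gb, [])
            if not ea or not eb:
                continue
            table = build_contingency(ea, eb, pred)
            try:
                stat, p, dof = chi2_test(table)
            except ValueError:
                continue  # zero-margin tables are not comparable
            chi_rows.append(
                {
                    "group_a": ga, "group_b": gb, "category": cat,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "chi2": stat, "p_value": p,
                }
            )

    kw_rows = []
    if expression is not None:
        sample_groups: dict[str, list[str]] = {}
        for s, g in groups.items():
            if s in expression.columns:
                sample_groups.setdefault(g, []).append(s)
        for gene in expression_genes:
            if gene not in expression.index:
                continue
            vals = {
                g: expression.loc[gene, ss].to_numpy()
                for g, ss in sample_groups.items()
            }
            H, p, degenerate = kruskal_wallis(vals)
            kw_rows.append({"gene": gene, "H": H, "p_value": p, "degenerate": degenerate})

    return {
        "per_sample_totals": per_sample.to_dict(),
        "per_group": per_group.to_dict(orient="records"),
        "mann_whitney": mw_rows,
        "chi_square": chi_rows,
        "kruskal_wallis": kw_rows,
    }
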
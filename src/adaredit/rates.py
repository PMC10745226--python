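"""Per-site editing-level quantification and group-wise comparison.

The editing level at a site is the fraction of reads supporting the edited
base (G reads at an A reference, C reads at a T reference) over the total
aligned depth at that site.  Only sites with at least 100 reads (default) are
considered, and the shared-site matrix keeps a site only when it has a
depth-passing entry in every sample, which is what makes unweighted group
means comparable across sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calling import EDITING_PAIRS, VariantRecord

__all__ = [
    "EditingRateEntry",
    "SharedSiteMatrix",
    "compute_rate",
    "rate_entries",
    "shared_sites",
    "group_rate_differences",
]

DEFAULT_MIN_DEPTH = 100


@dataclass(frozen=True)
class EditingRateEntry:
    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    edited_reads: int
    total_reads: int
    min_depth: int = DEFAULT_MIN_DEPTH

    @property
    def rate(self) -> float:
        if self.total_reads == 0:
            return float("nan")
        return self.edited_reads / self.total_reads

    @property
    def passes_depth(self) -> bool:
        return self.total_reads >= self.min_depth

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def compute_rate(
    edited_reads: int,
    total_reads: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    *,
    chrom: str = "",
    pos: int = 1,
    ref: str = "A",
    alt: str = "G",
    sample_id: str = "",
) -> EditingRateEntry:
    """Editing level = edited / total, with the depth-threshold flag."""
    if edited_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be nonnegative")
    if edited_reads > total_reads:
        raise ValueError(
            f"edited reads ({edited_reads}) exceed total reads ({total_reads})"
        )
    return EditingRateEntry(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        sample_id=sample_id,
        edited_reads=edited_reads,
        total_reads=total_reads,
        min_depth=min_depth,
    )


def rate_entries(
    records_by_sample: Mapping[str, Iterable[VariantRecord]],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[EditingRateEntry]:
    """Editing-rate entries from per-sample variant records.

    Only A>G / T>C records without a dbSNP rsID contribute; the edited count
    is the alt allelic depth, the total is DP when present, else ref+alt AD.
    Records lacking allelic depths cannot yield a rate and are skipped.
    """
    out: list[EditingRateEntry] = []
    for sample_id, records in records_by_sample.items():
        for rec in records:
            if (rec.ref, rec.alt) not in EDITING_PAIRS or rec.rsid_present:
                continue
            if rec.ad_alt is None:
                continue
            total = rec.dp if rec.dp is not None else (rec.ad_ref or 0) + rec.ad_alt
            if total <= 0:
                continue
            edited = min(rec.ad_alt, total)
            out.append(
                compute_rate(
                    edited,
                    total,
                    min_depth,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alt,
                    sample_id=sample_id,
                )
            )
    return out


@dataclass
class SharedSiteMatrix:
    """Sites x samples editing-level matrix over sites that pass the depth
    threshold in every sample; rows indexed by (chrom, pos, ref, alt)."""

    rates: pd.DataFrame
    groups: Mapping[str, str]

    @property
    def n_sites(self) -> int:
        return len(self.rates)

    def group_means(self) -> pd.DataFrame:
        """Unweighted per-group mean of per-sample rates (samples are the
        replication unit); one column per group."""
        cols = {}
        by_group: dict[str, list[str]] = {}
        for sample, group in self.groups.items():
            if sample in self.rates.columns:
                by_group.setdefault(group, []).append(sample)
        for group, samples in by_group.items():
            cols[group] = self.rates[samples].mean(axis=1)
        return pd.DataFrame(cols)


def shared_sites(
    entries: Iterable[EditingRateEntry],
    groups: Mapping[str, str],
) -> SharedSiteMatrix:
    """Build the shared-site matrix: a site is kept iff a depth-passing entry
    exists for it in every sample of ``groups``."""
    samples = sorted(groups)
    if len(samples) < 2:
        raise ValueError("shared-site analysis needs at least 2 samples")
    passing: dict[tuple, dict[str, float]] = {}
    for e in entries:
        if not e.passes_depth:
            continue
        passing.setdefault(e.site, {})[e.sample_id] = e.rate
    rows = {
        site: vals for site, vals in passing.items() if set(vals) >= set(samples)
    }
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=None)
    if not mat.empty:
        mat = mat[samples].sort_index()
        mat.index = pd.MultiIndex.from_tuples(mat.index, names=["chrom", "pos", "ref", "alt"])
    return SharedSiteMatrix(rates=mat, groups=dict(groups))


def group_rate_differences(
    matrix: SharedSiteMatrix,
    group_a: str,
    group_b: str,
    cutoff: float = 0.20,
) -> pd.DataFrame:
    """Per-site mean editing levels for two groups, their difference, and a
    flag for |delta| at or above ``cutoff`` (percentage points on the [0,1]
    scale, default 20).  Columns are scatter-ready: x = group_b (baseline)
    mean, y = group_a mean."""
    means = matrix.group_means()
    for g in (group_a, group_b):
        if g not in means.columns:
            raise KeyError(f"unknown group label {g!r}")
    out = pd.DataFrame(
        {
            "mean_a": means[group_a],
            "mean_b": means[group_b],
        }
    )
    out["delta"] = out["mean_a"] - out["mean_b"]
    out["flagged"] = out["delta"].abs() >= cutoff
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    out.attrs["cutoff"] = cutoff
    return out
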
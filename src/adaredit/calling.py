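"""Calling putative A-to-I editing events from annotated VCFs.

The caller applies the inclusion rules used for inferring ADAR editing from
RNA-seq variant calls: keep single-nucleotide A>G or T>C substitutions (the
two strand orientations of the same A-to-I change), drop any record carrying a
dbSNP rsID (likely germline), and finally require each (transcript, site) key
to recur in at least two samples of a group to suppress stochastic calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "Annotation",
    "VariantRecord",
    "EditingEvent",
    "load_vcf",
    "filter_editing_candidates",
    "recurrence_filter",
    "count_events_per_sample",
    "events_to_frame",
]

EDITING_PAIRS = {("A", "G"), ("T", "C")}
_IMPACT_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}


@dataclass(frozen=True)
class Annotation:
    """One SnpEff ANN entry attached to a variant allele."""

    gene_id: str | None
    gene_name: str | None
    transcript_id: str | None
    effect_terms: tuple[str, ...]
    impact: str


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV candidate in one sample (multi-allelics pre-split)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    rsid_present: bool
    ad_ref: int | None
    ad_alt: int | None
    dp: int | None
    annotations: tuple[Annotation, ...] = ()
    sample_id: str = ""

    @property
    def has_depth_support(self) -> bool:
        return self.ad_alt is not None or self.dp is not None


@dataclass(frozen=True)
class EditingEvent:
    """A putative A-to-I editing event in one sample, per transcript annotation."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    transcript_id: str | None
    impact: str
    effect_terms: tuple[str, ...] = ()
    is_protein_coding: bool | None = None
    is_nmd: bool | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None
    dp: int | None = None

    canonical_class: str = "A-to-I"

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _parse_ann(raw: str | None, alt: str) -> tuple[Annotation, ...]:
    if not raw:
        return ()
    out = []
    for entry in raw.split(","):
        fields = entry.split("|")
        if len(fields) < 7 or fields[0] != alt:
            continue
        out.append(
            Annotation(
                gene_id=fields[4] or None,
                gene_name=fields[3] or None,
                transcript_id=fields[6] or None,
                effect_terms=tuple(t for t in fields[1].split("&") if t),
                impact=fields[2] or "MODIFIER",
            )
        )
    return tuple(out)


def load_vcf(path: str | Path, sample_id: str) -> list[VariantRecord]:
    """Read one sample's VCF into variant records.

    Multi-allelic lines are split into per-ALT biallelic candidates; non-SNV
    alleles (indels, MNVs, symbolic) are dropped with a logged count.  Records
    lacking both AD and DP are retained but flagged depth-less (they join
    event calling but never rate computation).
    """
    path = str(path)
    vcf = VCF(path)
    records: list[VariantRecord] = []
    n_dropped = 0
    for v in vcf:
        ref = v.REF
        raw_ann = v.INFO.get("ANN")
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        dp_arr = None
        try:
            dp_arr = v.format("DP")
        except KeyError:
            pass
        dp = None
        if dp_arr is not None and dp_arr.size:
            dp_val = int(np.asarray(dp_arr).ravel()[0])
            dp = dp_val if dp_val >= 0 else None
        for i, alt in enumerate(v.ALT):
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                n_dropped += 1
                continue
            ad_ref = ad_alt = None
            if ad is not None:
                row = np.asarray(ad).ravel()
                if row.size > i + 1:
                    r, a = int(row[0]), int(row[i + 1])
                    ad_ref = r if r >= 0 else None
                    ad_alt = a if a >= 0 else None
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=ref,
                    alt=alt,
                    rsid_present=v.ID is not None and v.ID != ".",
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    dp=dp,
                    annotations=_parse_ann(raw_ann, alt),
                    sample_id=sample_id,
                )
            )
    if n_dropped:
        logger.info("%s: dropped %d non-SNV alleles", sample_id, n_dropped)
    return records


def filter_editing_candidates(records: Iterable[VariantRecord]) -> list[EditingEvent]:
    """Retain A>G / T>C SNVs without a dbSNP rsID, one event per transcript
    annotation.

    When a record carries several annotations for the same transcript, only
    the highest-impact one is kept (HIGH > MODERATE > LOW > MODIFIER) so a
    variant is never double-counted in category tables.  Unannotated records
    yield a single event with null gene/transcript and MODIFIER impact.
    """
    events: list[EditingEvent] = []
    for rec in records:
        if (rec.ref, rec.alt) not in EDITING_PAIRS or rec.rsid_present:
            continue
        by_tx: dict[str | None, Annotation] = {}
        for ann in rec.annotations:
            prev = by_tx.get(ann.transcript_id)
            if prev is None or _IMPACT_RANK.get(ann.impact, 3) < _IMPACT_RANK.get(prev.impact, 3):
                by_tx[ann.transcript_id] = ann
        anns: Sequence[Annotation] = list(by_tx.values()) or [
            Annotation(None, None, None, (), "MODIFIER")
        ]
        for ann in anns:
            events.append(
                EditingEvent(
                    sample_id=rec.sample_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alt,
                    gene_id=ann.gene_id,
                    transcript_id=ann.transcript_id,
                    impact=ann.impact,
                    effect_terms=ann.effect_terms,
                    ad_ref=rec.ad_ref,
                    ad_alt=rec.ad_alt,
                    dp=rec.dp,
                )
            )
    return events


def _recurrence_key(event: EditingEvent, include_transcript: bool) -> tuple:
    if include_transcript:
        return (event.transcript_id, event.chrom, event.pos, event.ref, event.alt)
    return (event.chrom, event.pos, event.ref, event.alt)


def recurrence_filter(
    events: Iterable[EditingEvent],
    groups: Mapping[str, str],
    min_samples: int = 2,
    include_transcript: bool = True,
    per_group: bool = True,
) -> list[EditingEvent]:
    """Drop keyed events supported by fewer than ``min_samples`` distinct
    samples.

    The key is (transcript, site) by default; scope is within each sample
    group (``per_group=False`` applies the rule cohort-wide).  Idempotent and
    never grows the event set.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    events = list(events)
    support: dict[tuple, set[str]] = {}
    for ev in events:
        scope = groups[ev.sample_id] if per_group else "__all__"
        key = (scope, _recurrence_key(ev, include_transcript))
        support.setdefault(key, set()).add(ev.sample_id)
    kept = []
    for ev in events:
        scope = groups[ev.sample_id] if per_group else "__all__"
        key = (scope, _recurrence_key(ev, include_transcript))
        if len(support[key]) >= min_samples:
            kept.append(ev)
    return kept


def count_events_per_sample(
    events: Iterable[EditingEvent], groups: Mapping[str, str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample totals of unique (sample, site, transcript) events, and
    per-group mean with SEM (sd with n-1 denominator over sqrt(n); NaN when
    a group has a single sample)."""
    seen = {(ev.sample_id, ev.chrom, ev.pos, ev.ref, ev.alt, ev.transcript_id) for ev in events}
    counts: dict[str, int] = {s: 0 for s in groups}
    for s, *_ in seen:
        counts[s] = counts.get(s, 0) + 1
    per_sample = pd.Series(counts, name="n_events").sort_index()
    rows = []
    frame = per_sample.rename_axis("sample_id").reset_index()
    frame["group"] = frame["sample_id"].map(groups)
    for group, sub in frame.groupby("group"):
        n = len(sub)
        mean = float(sub["n_events"].mean())
        sem = float(sub["n_events"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"group": group, "n_samples": n, "mean": mean, "sem": sem})
    return per_sample, pd.DataFrame(rows)


def events_to_frame(events: Iterable[EditingEvent], groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "sample": ev.sample_id,
                "group": groups.get(ev.sample_id) if groups else None,
                "chrom": ev.chrom,
                "pos": ev.pos,
                "ref": ev.ref,
                "alt": ev.alt,
                "gene_id": ev.gene_id,
                "transcript_id": ev.transcript_id,
                "impact": ev.impact,
                "effect": "&".join(ev.effect_terms),
                "protein_coding": ev.is_protein_coding,
                "nmd": ev.is_nmd,
                "ad_ref": ev.ad_ref,
                "ad_alt": ev.ad_alt,
                "dp": ev.dp,
            }
        )
    return pd.DataFrame(rows)
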
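"""Functional stratification of editing events.

Two orthogonal classifications are supported: the four-level SnpEff impact
(HIGH / MODERATE / LOW / MODIFIER, with HIGH and MODERATE treated as the
functionally consequential stratum) and the SIFT deleterious/tolerated call
(score <= 0.05 is deleterious, inclusive at the boundary).  Effect terms are
Sequence Ontology terms as emitted in the ANN field; the term -> flag mapping
ships as an editable YAML table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .calling import EditingEvent

__all__ = [
    "ImpactCategory",
    "SiftCall",
    "SIFT_THRESHOLD",
    "classify_impact",
    "classify_sift",
    "flag_consequences",
    "annotate_events",
    "load_term_map",
    "load_sift_table",
    "join_sift",
]

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
SIFT_THRESHOLD = 0.05


@dataclass(frozen=True)
class ImpactCategory:
    value: str

    @property
    def is_high_or_moderate(self) -> bool:
        return self.value in ("HIGH", "MODERATE")


@dataclass(frozen=True)
class SiftCall:
    score: float
    call: str  # "deleterious" | "tolerated"
    threshold: float = SIFT_THRESHOLD


def classify_impact(token: str | EditingEvent) -> ImpactCategory:
    """Map an ANN impact token (or an event's impact) to the four-level
    category; unknown tokens fall back to MODIFIER with a warning."""
    if isinstance(token, EditingEvent):
        token = token.impact
    token = (token or "").upper()
    if token not in IMPACT_LEVELS:
        warnings.warn(f"unknown impact token {token!r}; treating as MODIFIER")
        token = "MODIFIER"
    return ImpactCategory(token)


def classify_sift(score: float, threshold: float = SIFT_THRESHOLD) -> SiftCall:
    """Deleterious iff score <= threshold (boundary inclusive)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    call = "deleterious" if score <= threshold else "tolerated"
    return SiftCall(score=float(score), call=call, threshold=threshold)


def load_term_map(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load the effect-term mapping (keys ``protein_coding`` and ``nmd``)."""
    if path is None:
        text = resources.files("adaredit.data").joinpath("consequence_terms.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {
        "protein_coding": frozenset(raw.get("protein_coding", ())),
        "nmd": frozenset(raw.get("nmd", ())),
    }


def flag_consequences(
    event: EditingEvent | Sequence[str],
    term_map: dict[str, frozenset[str]] | None = None,
) -> tuple[bool, bool]:
    """(is_protein_coding, is_nmd) from an event's effect terms."""
    terms = event.effect_terms if isinstance(event, EditingEvent) else tuple(event)
    tm = term_map or load_term_map()
    is_pc = any(t in tm["protein_coding"] for t in terms)
    is_nmd = any(t in tm["nmd"] for t in terms)
    return is_pc, is_nmd


def annotate_events(
    events: Iterable[EditingEvent],
    term_map: dict[str, frozenset[str]] | None = None,
) -> list[EditingEvent]:
    """Return events with protein-coding / NMD flags filled in."""
    tm = term_map or load_term_map()
    out = []
    for ev in events:
        is_pc, is_nmd = flag_consequences(ev, tm)
        out.append(replace(ev, is_protein_coding=is_pc, is_nmd=is_nmd))
    return out


def load_sift_table(path: str | Path) -> pd.DataFrame:
    """SIFT scores keyed by (chrom, pos, ref, alt, transcript_id); TSV with a
    ``sift_score`` column (SNPNexus-export compatible)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "transcript_id", "sift_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SIFT table missing columns: {sorted(missing)}")
    return df


def join_sift(
    events: Iterable[EditingEvent],
    sift: pd.DataFrame,
    threshold: float = SIFT_THRESHOLD,
) -> pd.DataFrame:
    """Join filtered events to SIFT scores per (site, transcript) and call
    deleterious/tolerated.  Events with no matching score are left out (SIFT
    scores only nonsynonymous coding changes)."""
    from .calling import events_to_frame

    ev = events_to_frame(events)
    if ev.empty:
        return pd.DataFrame(
            columns=["sample", "chrom", "pos", "ref", "alt", "transcript_id", "sift_score", "sift_call"]
        )
    ev["chrom"] = ev["chrom"].astype(str)
    merged = ev.merge(
        sift, on=["chrom", "pos", "ref", "alt", "transcript_id"], how="inner"
    )
    merged["sift_call"] = [
        classify_sift(s, threshold).call for s in merged["sift_score"]
    ]
    return merged
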
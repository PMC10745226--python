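"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages in order — ingest, event calling,
consequence annotation, editing rates, gene sets, pathway enrichment, group
statistics — writing each stage's tables under the output directory plus a
machine-readable ``summary.json`` and a ``manifest.json`` recording the
thresholds, seed and inputs so a run is fully re-creatable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import calling, consequences, genesets, rates, stats

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    ``samples`` maps sample_id -> {"group": ..., "vcf": path}.  Optional
    inputs: gene lists (name -> {"path", "id_column", "sheet"}), a GMT
    pathway file, a SIFT score TSV, and an expression TSV (genes x samples).
    Thresholds default to the study's stated cut-offs.
    """

    samples: Mapping[str, Mapping[str, str]]
    gene_lists: Mapping[str, Mapping[str, object]] = field(default_factory=dict)
    gmt_path: str | None = None
    sift_path: str | None = None
    expression_path: str | None = None
    term_map_path: str | None = None
    min_samples: int = 2
    min_depth: int = 100
    sift_cutoff: float = 0.05
    enrich_min_genes: int = 10
    enrich_min_fraction: float = 0.10
    enrich_alpha: float = 0.05
    delta_cutoff: float = 0.20
    recurrence_per_group: bool = True
    recurrence_by_transcript: bool = True
    out_dir: str = "adaredit_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("samples: at least one sample is required")
        if self.min_samples < 1:
            raise ValueError("min_samples: must be >= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth: must be >= 1")
        if not 0 <= self.sift_cutoff <= 1:
            raise ValueError("sift_cutoff: must lie in [0, 1]")
        if not 0 < self.enrich_alpha < 1:
            raise ValueError("enrich_alpha: must lie in (0, 1)")
        for sid, info in self.samples.items():
            if "group" not in info or "vcf" not in info:
                raise ValueError(f"samples[{sid!r}]: needs 'group' and 'vcf'")

    @property
    def groups(self) -> dict[str, str]:
        return {sid: str(info["group"]) for sid, info in self.samples.items()}


class _stage:
    """Context manager renaming any stage failure after the stage; partial
    outputs written before the failure are left in place for debugging."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = config.groups
    summary: dict = {}

    # ingest ---------------------------------------------------------------
    with _stage("ingest"):
        records_by_sample = {}
        for sid, info in config.samples.items():
            records_by_sample[sid] = calling.load_vcf(info["vcf"], sid)
        summary["ingest"] = {
            "n_samples": len(records_by_sample),
            "records_per_sample": {s: len(r) for s, r in records_by_sample.items()},
        }

    # call -----------------------------------------------------------------
    with _stage("call"):
        all_events = []
        for sid, recs in records_by_sample.items():
            all_events.extend(calling.filter_editing_candidates(recs))
        n_candidates = len(all_events)
        events = calling.recurrence_filter(
            all_events,
            groups,
            min_samples=config.min_samples,
            include_transcript=config.recurrence_by_transcript,
            per_group=config.recurrence_per_group,
        )
        summary["call"] = {
            "n_candidate_events": n_candidates,
            "n_recurrent_events": len(events),
        }

    # consequences ----------------------------------------------------------
    with _stage("consequences"):
        term_map = consequences.load_term_map(config.term_map_path)
        events = consequences.annotate_events(events, term_map)
        calling.events_to_frame(events, groups).to_csv(
            out / "events.tsv", sep="\t", index=False
        )
        impact_counts: dict[str, int] = {}
        for ev in events:
            impact_counts[ev.impact] = impact_counts.get(ev.impact, 0) + 1
        sift_block = {}
        if config.sift_path:
            sift_df = consequences.load_sift_table(config.sift_path)
            joined = consequences.join_sift(events, sift_df, config.sift_cutoff)
            joined.to_csv(out / "sift_calls.tsv", sep="\t", index=False)
            sift_block = {
                "n_scored": int(len(joined)),
                "n_deleterious": int((joined["sift_call"] == "deleterious").sum())
                if len(joined)
                else 0,
            }
        summary["consequences"] = {"impact_counts": impact_counts, "sift": sift_block}

    # rates ------------------------------------------------------------------
    with _stage("rates"):
        entries = rates.rate_entries(records_by_sample, config.min_depth)
        matrix = rates.shared_sites(entries, groups) if len(groups) >= 2 else None
        rates_block = {"n_rate_entries": len(entries)}
        if matrix is not None:
            matrix.rates.to_csv(out / "shared_site_rates.tsv", sep="\t")
            rates_block["n_shared_sites"] = matrix.n_sites
            group_names = sorted(set(groups.values()))
            diff_frames = []
            for i, ga in enumerate(group_names):
                for gb in group_names[i + 1 :]:
                    if matrix.n_sites == 0:
                        continue
                    d = rates.group_rate_differences(matrix, ga, gb, config.delta_cutoff)
                    d = d.assign(group_a=ga, group_b=gb)
                    diff_frames.append(d)
            if diff_frames:
                pd.concat(diff_frames).to_csv(out / "group_rate_differences.tsv", sep="\t")
        summary["rates"] = rates_block

    # gene sets --------------------------------------------------------------
    with _stage("genesets"):
        loaded_lists: dict[str, genesets.GeneSet] = {}
        for name, spec in config.gene_lists.items():
            loaded_lists[name] = genesets.load_gene_list(
                spec["path"],
                id_column=str(spec.get("id_column", "gene_id")),
                sheet=spec.get("sheet"),
                name=name,
            )
        edited = genesets.edited_gene_lists(events, groups)
        genesets_block = {
            "loaded_list_sizes": {n: len(s) for n, s in loaded_lists.items()},
            "edited_genes_per_group": {g: len(s) for g, s in edited.items()},
        }
        summary["genesets"] = genesets_block

    # enrichment --------------------------------------------------------------
    with _stage("enrichment"):
        enrichment_block = {}
        if config.gmt_path:
            universe = genesets.load_gmt(config.gmt_path)
            for group, gs in edited.items():
                try:
                    res = genesets.enrich(
                        gs,
                        universe,
                        min_genes=config.enrich_min_genes,
                        min_fraction=config.enrich_min_fraction,
                        alpha=config.enrich_alpha,
                    )
                except ValueError:
                    enrichment_block[group] = {"n_tested": 0, "n_reported": 0}
                    continue
                res.to_csv(out / f"enrichment_{group}.tsv", sep="\t", index=False)
                enrichment_block[group] = {
                    "n_tested": int(len(res)),
                    "n_reported": int(res["reported"].sum()) if len(res) else 0,
                }
        summary["enrichment"] = enrichment_block

    # group stats --------------------------------------------------------------
    with _stage("group_stats"):
        expression = None
        if config.expression_path:
            expression = pd.read_csv(config.expression_path, sep="\t", index_col=0)
        summary["group_stats"] = stats.summarize_groups(events, groups, expression)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    manifest = asdict(config)
    manifest["stages"] = list(summary)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return summary
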
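"""Synthetic multi-sample RNA-seq variant-call cohorts with known editing ground truth.

The generator emulates the output of an upstream alignment + haplotype-calling
pipeline at the point where editing inference begins: per-sample VCF files whose
records are (a) planted A-to-I editing sites (A>G on plus-strand genes, T>C on
minus-strand genes) with read support drawn binomially from a per-group true
editing rate, (b) dbSNP-annotated germline contaminant variants at roughly
heterozygous or homozygous allele fractions, and (c) substitution records of
non-editing classes.  Every record carries SnpEff-dialect ``ANN`` annotations
over a synthetic gene/transcript/pathway universe and ``AD``/``DP`` FORMAT
fields, so the downstream caller, consequence, rate and enrichment stages all
run unmodified on simulated data.

A :class:`TruthTable` records everything that was planted, which lets tests
recompute expected downstream results by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthModel",
    "AnnotationUniverse",
    "SimulationConfig",
    "TruthTable",
    "simulate_cohort",
    "simulate_expression",
    "null_contingency_tables",
    "write_synthetic_s1_workbook",
]

ADAR_GENES = ("ADAR", "ADARB1", "ADARB2")

_IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_EFFECT_BY_IMPACT = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intron_variant",
}
# non-editing substitution classes emitted as background noise
_OTHER_CLASSES = (("C", "T"), ("G", "A"), ("C", "A"), ("G", "T"), ("A", "C"), ("T", "G"))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class DepthModel:
    """Per-site read-depth distribution.

    Negative binomial parameterized by mean and dispersion (the gamma shape of
    the mixing distribution); ``dispersion=None`` degenerates to Poisson.
    Overdispersion is the norm for RNA-seq coverage, hence the default.
    """

    mean: float = 500.0
    dispersion: float | None = 5.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.dispersion is None:
            return rng.poisson(self.mean, size=size)
        # NB as gamma-Poisson mixture: shape=dispersion, mean preserved
        lam = rng.gamma(self.dispersion, self.mean / self.dispersion, size=size)
        return rng.poisson(lam)


@dataclass(frozen=True)
class AnnotationUniverse:
    """Synthetic gene/transcript/pathway universe used for ANN annotations.

    genes: gene_id -> (gene_name, chrom, strand, transcript_ids)
    pathways: pathway name -> member gene_ids (GMT-compatible)
    """

    genes: Mapping[str, tuple[str, str, str, tuple[str, ...]]]
    pathways: Mapping[str, tuple[str, ...]]

    @classmethod
    def default(
        cls,
        n_genes: int = 60,
        n_pathways: int = 6,
        seed: int = 0,
    ) -> "AnnotationUniverse":
        rng = np.random.default_rng(seed)
        genes: dict[str, tuple[str, str, str, tuple[str, ...]]] = {}
        for i in range(n_genes):
            gid = f"SYNG{i:05d}"
            name = f"GENE{i}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(1, 4))
            txs = tuple(f"SYNT{i:05d}.{j}" for j in range(1, n_tx + 1))
            genes[gid] = (name, "1", strand, txs)
        # ADAR family always present so expression simulation can target it
        for j, sym in enumerate(ADAR_GENES):
            gid = f"SYNG_ADAR{j}"
            genes[gid] = (sym, "1", "+", (f"SYNT_ADAR{j}.1",))
        gene_ids = [g for g in genes if not g.startswith("SYNG_ADAR")]
        pathways: dict[str, tuple[str, ...]] = {}
        for p in range(n_pathways):
            size = int(rng.integers(max(3, n_genes // 10), max(4, n_genes // 3)))
            members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
            pathways[f"SYNPATH_{p}"] = tuple(sorted(members))
        return cls(genes=genes, pathways=pathways)

    def gene_strand(self, gene_id: str) -> str:
        return self.genes[gene_id][2]

    def all_gene_ids(self) -> list[str]:
        return list(self.genes)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort.

    ``group_rates`` gives each group's default true editing rate at every
    planted site; ``site_group_rates`` overrides the rate for individual sites
    (site index -> group -> rate).  ``expression_tpm`` gives per-group mean TPM
    for selected genes (others default to ``baseline_tpm``); ``tpm_cv`` is the
    coefficient of variation of the gamma noise around those means (0 gives
    exactly constant tables).
    """

    groups: tuple[tuple[str, int], ...] = (("Control", 4), ("Case", 4))
    n_sites: int = 100
    group_rates: Mapping[str, float] = field(
        default_factory=lambda: {"Control": 0.2, "Case": 0.2}
    )
    site_group_rates: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    depth_model: DepthModel = field(default_factory=DepthModel)
    snp_contam_n: int = 20
    other_subst_n: int = 20
    impact_weights: Mapping[str, float] = field(
        default_factory=lambda: {"HIGH": 0.05, "MODERATE": 0.15, "LOW": 0.3, "MODIFIER": 0.5}
    )
    nmd_fraction: float = 0.25  # fraction of HIGH-impact sites also flagged NMD
    universe: AnnotationUniverse | None = None
    expression_tpm: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_tpm: float = 10.0
    tpm_cv: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigurationError("groups: at least one group is required")
        for name, n in self.groups:
            if n < 1:
                raise ConfigurationError(f"groups: sample count for {name!r} must be >= 1")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites: must be >= 1")
        if self.depth_model.mean <= 0:
            raise ConfigurationError("depth_model.mean: must be > 0")
        if self.depth_model.dispersion is not None and self.depth_model.dispersion <= 0:
            raise ConfigurationError("depth_model.dispersion: must be > 0 or None")
        group_names = {g for g, _ in self.groups}
        for g in group_names:
            if g not in self.group_rates:
                raise ConfigurationError(f"group_rates: missing rate for group {g!r}")
        for g, r in self.group_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"group_rates[{g!r}]: rate {r} outside [0, 1]")
        for s, per_group in self.site_group_rates.items():
            for g, r in per_group.items():
                if not 0.0 <= r <= 1.0:
                    raise ConfigurationError(
                        f"site_group_rates[{s}][{g!r}]: rate {r} outside [0, 1]"
                    )
        if self.snp_contam_n < 0:
            raise ConfigurationError("snp_contam_n: must be >= 0")
        if self.other_subst_n < 0:
            raise ConfigurationError("other_subst_n: must be >= 0")
        w = sum(self.impact_weights.get(k, 0.0) for k in _IMPACT_LEVELS)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError("impact_weights: weights must sum to 1")
        if self.tpm_cv < 0:
            raise ConfigurationError("tpm_cv: must be >= 0")

    @property
    def sample_table(self) -> pd.DataFrame:
        rows = []
        for gname, n in self.groups:
            for i in range(1, n + 1):
                rows.append({"sample_id": f"{gname}_{i:02d}", "group": gname})
        return pd.DataFrame(rows)

    def rate(self, site_index: int, group: str) -> float:
        override = self.site_group_rates.get(site_index, {})
        return float(override.get(group, self.group_rates[group]))


@dataclass
class TruthTable:
    """Everything planted by :func:`simulate_cohort`, for brute-force recounts.

    sites:    one row per planted site with locus, gene/transcript, impact, effect.
    rates:    true rate per (site_id, group).
    counts:   simulated depth and edited-read count per (site_id, sample_id).
    contaminants: germline-like loci with rsIDs, shared by all samples.
    samples:  sample_id -> group.
    """

    sites: pd.DataFrame
    rates: pd.DataFrame
    counts: pd.DataFrame
    contaminants: pd.DataFrame
    samples: pd.DataFrame

    def expected_recurrent_keys(self, min_samples: int = 2) -> set[tuple]:
        """Brute-force (group, transcript_id, chrom, pos) keys surviving the
        >=min_samples recurrence rule, counting a sample as supporting a site
        iff it observed at least one edited read there."""
        obs = self.counts[self.counts["edited"] > 0].merge(self.samples, on="sample_id")
        obs = obs.merge(
            self.sites[["site_id", "chrom", "pos", "transcript_id"]], on="site_id"
        )
        keys: set[tuple] = set()
        grouped = obs.groupby(["group", "transcript_id", "chrom", "pos"])["sample_id"].nunique()
        for key, n in grouped.items():
            if n >= min_samples:
                keys.add(key)
        return keys

    def expected_gene_sets(
        self, min_samples: int = 2, impacts: Sequence[str] = ("HIGH", "MODERATE")
    ) -> dict[str, set[str]]:
        """Brute-force per-group unique-gene sets for sites of given impacts
        passing the recurrence rule."""
        keys = self.expected_recurrent_keys(min_samples)
        site_info = self.sites.set_index(["transcript_id", "chrom", "pos"])
        out: dict[str, set[str]] = {}
        for group, tx, chrom, pos in keys:
            row = site_info.loc[(tx, chrom, pos)]
            if row["impact"] in impacts:
                out.setdefault(group, set()).add(row["gene_id"])
        return out


def _site_catalogue(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    universe = config.universe or AnnotationUniverse.default(seed=config.seed)
    gene_ids = [g for g in universe.all_gene_ids() if not g.startswith("SYNG_ADAR")]
    rows = []
    for s in range(config.n_sites):
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        name, chrom, strand, txs = universe.genes[gid]
        tx = txs[int(rng.integers(0, len(txs)))]
        ref, alt = ("A", "G") if strand == "+" else ("T", "C")
        impact = rng.choice(_IMPACT_LEVELS, p=[config.impact_weights.get(k, 0.0) for k in _IMPACT_LEVELS])
        effect = _EFFECT_BY_IMPACT[str(impact)]
        if impact == "HIGH" and rng.random() < config.nmd_fraction:
            effect = effect + "&NMD_transcript_variant"
        rows.append(
            {
                "site_id": s,
                "chrom": chrom,
                # positions spaced so loci never collide across record classes
                "pos": 1_000 + s * 100,
                "ref": ref,
                "alt": alt,
                "gene_id": gid,
                "gene_name": name,
                "transcript_id": tx,
                "strand": strand,
                "impact": str(impact),
                "effect": effect,
            }
        )
    return pd.DataFrame(rows)


def _contaminant_catalogue(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Germline-like loci shared across samples; A>G / T>C so that only the
    rsID (dbSNP) filter can remove them downstream."""
    rows = []
    base = 1_000 + config.n_sites * 100 + 10_000
    for i in range(config.snp_contam_n):
        ref, alt = ("A", "G") if rng.random() < 0.5 else ("T", "C")
        af = 0.5 if rng.random() < 0.7 else 1.0
        rows.append(
            {
                "chrom": "1",
                "pos": base + i * 50,
                "ref": ref,
                "alt": alt,
                "rsid": f"rs{9_000_000 + i}",
                "allele_fraction": af,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "rsid", "allele_fraction"]
    )


def _ann_field(alt: str, effect: str, impact: str, gene_name: str, gene_id: str, tx: str) -> str:
    return (
        f"{alt}|{effect}|{impact}|{gene_name}|{gene_id}|transcript|{tx}"
        f"|protein_coding|||||||"
    )


def _vcf_line(chrom, pos, rsid, ref, alt, info, ad_ref, ad_alt, dp) -> str:
    if ad_alt == 0:
        gt = "0/0"
    elif ad_ref == 0:
        gt = "1/1"
    else:
        gt = "0/1"
    return (
        f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t100\tPASS\t{info}"
        f"\tGT:AD:DP\t{gt}:{ad_ref},{ad_alt}:{dp}"
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000000>
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos | CDS.pos | AA.pos | Distance'">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> tuple[dict[str, Path], TruthTable]:
    """Generate per-sample annotated VCFs plus the matching truth table.

    Returns (sample_id -> VCF path, TruthTable).  Identical config and seed
    produce byte-identical VCFs.  A planted site is emitted in a sample's VCF
    only when at least one edited read was drawn there (a caller emits no
    record without alternate-allele support); the truth table records depth
    and edited count for every (site, sample) regardless.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    universe = config.universe or AnnotationUniverse.default(seed=config.seed)

    master = np.random.default_rng(config.seed)
    sites = _site_catalogue(config, master)
    contaminants = _contaminant_catalogue(config, master)
    samples = config.sample_table

    rate_rows = []
    for s in range(config.n_sites):
        for gname, _ in config.groups:
            rate_rows.append({"site_id": s, "group": gname, "rate": config.rate(s, gname)})
    rates = pd.DataFrame(rate_rows)

    paths: dict[str, Path] = {}
    count_rows = []
    gene_ids = [g for g in universe.all_gene_ids() if not g.startswith("SYNG_ADAR")]

    for idx, row in samples.iterrows():
        sample_id, group = row["sample_id"], row["group"]
        rng = np.random.default_rng([config.seed, int(idx)])
        depths = config.depth_model.sample(rng, config.n_sites)
        site_rates = np.array([config.rate(s, group) for s in range(config.n_sites)])
        edited = rng.binomial(depths, site_rates)
        records: list[tuple[int, str]] = []
        for s in range(config.n_sites):
            d, e = int(depths[s]), int(edited[s])
            count_rows.append(
                {"site_id": s, "sample_id": sample_id, "depth": d, "edited": e}
            )
            if e < 1:
                continue
            site = sites.iloc[s]
            info = "ANN=" + _ann_field(
                site["alt"], site["effect"], site["impact"],
                site["gene_name"], site["gene_id"], site["transcript_id"],
            )
            records.append(
                (
                    int(site["pos"]),
                    _vcf_line(site["chrom"], site["pos"], ".", site["ref"], site["alt"], info, d - e, e, d),
                )
            )
        for _, c in contaminants.iterrows():
            d = max(1, int(config.depth_model.sample(rng, 1)[0]))
            a = int(rng.binomial(d, min(0.98, c["allele_fraction"])))
            if a < 1:
                a = 1  # germline variants always show alt support
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            name, chrom, _, txs = universe.genes[gid]
            info = "ANN=" + _ann_field(c["alt"], "missense_variant", "MODERATE", name, gid, txs[0])
            records.append(
                (int(c["pos"]), _vcf_line(c["chrom"], c["pos"], c["rsid"], c["ref"], c["alt"], info, d - a, a, d))
            )
        other_base = 1_000 + config.n_sites * 100 + 10_000 + config.snp_contam_n * 50 + 10_000
        for j in range(config.other_subst_n):
            ref, alt = _OTHER_CLASSES[int(rng.integers(0, len(_OTHER_CLASSES)))]
            pos = other_base + j * 50
            d = max(1, int(config.depth_model.sample(rng, 1)[0]))
            a = max(1, int(rng.binomial(d, 0.5)))
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            name, chrom, _, txs = universe.genes[gid]
            info = "ANN=" + _ann_field(alt, "missense_variant", "MODERATE", name, gid, txs[0])
            records.append((pos, _vcf_line("1", pos, ".", ref, alt, info, d - a, a, d)))
        records.sort(key=lambda r: r[0])
        path = out_dir / f"{sample_id}.vcf"
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER.format(sample=sample_id))
            for _, line in records:
                fh.write(line + "\n")
        paths[sample_id] = path

    truth = TruthTable(
        sites=sites,
        rates=rates,
        counts=pd.DataFrame(count_rows),
        contaminants=contaminants,
        samples=samples,
    )
    return paths, truth


def write_truth(truth: TruthTable, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.sites.to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
    truth.rates.to_csv(out_dir / "truth_rates.tsv", sep="\t", index=False)
    truth.counts.to_csv(out_dir / "truth_counts.tsv", sep="\t", index=False)
    truth.contaminants.to_csv(out_dir / "truth_contaminants.tsv", sep="\t", index=False)
    truth.samples.to_csv(out_dir / "truth_samples.tsv", sep="\t", index=False)


def write_universe_gmt(universe: AnnotationUniverse, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in universe.pathways.items():
            fh.write(name + "\tsynthetic\t" + "\t".join(members) + "\n")


def simulate_expression(config: SimulationConfig) -> pd.DataFrame:
    """Gene x sample TPM table over the annotation universe.

    Per-group means come from ``config.expression_tpm`` (gene symbol or id ->
    group -> mean TPM), defaulting to ``baseline_tpm``.  Values are gamma-drawn
    around the mean with coefficient of variation ``tpm_cv`` (0 = exact means).
    """
    config.validate()
    universe = config.universe or AnnotationUniverse.default(seed=config.seed)
    samples = config.sample_table
    known = {gid for gid in universe.genes} | {v[0] for v in universe.genes.values()}
    for gene in config.expression_tpm:
        if gene not in known:
            raise KeyError(f"unknown gene id {gene!r} in expression_tpm")
    rng = np.random.default_rng([config.seed, 777])
    rows = {}
    for gid, (symbol, *_rest) in universe.genes.items():
        spec = config.expression_tpm.get(symbol, config.expression_tpm.get(gid, {}))
        vals = []
        for _, srow in samples.iterrows():
            mean = float(spec.get(srow["group"], config.baseline_tpm))
            if config.tpm_cv == 0 or mean == 0:
                vals.append(mean)
            else:
                shape = 1.0 / config.tpm_cv**2
                vals.append(float(rng.gamma(shape, mean / shape)))
        rows[symbol] = vals
    return pd.DataFrame(rows, index=samples["sample_id"]).T


def null_contingency_tables(
    n_events_a: int,
    n_events_b: int,
    p_category: float,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Replicate 2x2 tables under the no-group-difference null.

    Both groups draw their in-category event counts binomially from the same
    proportion; used for type-I-error calibration of the chi-square comparison.
    Returns an array of shape (n_replicates, 2, 2).
    """
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_events_a, p_category, size=n_replicates)
    c = rng.binomial(n_events_b, p_category, size=n_replicates)
    tables = np.stack(
        [np.stack([a, n_events_a - a], axis=1), np.stack([c, n_events_b - c], axis=1)],
        axis=1,
    )
    return tables


def write_synthetic_s1_workbook(
    path: str | Path,
    n_pd_genes: int = 737,
    n_pd_transcripts: int = 7827,
    n_up: int = 302,
    n_down: int = 402,
    n_overlap: int = 38,
) -> Path:
    """Write a synthetic stand-in for the study's supplementary gene-list
    workbook (XLSX) with the published list sizes and overlap structure.

    Sheets: "NCBI PD Gene List" (gene_id, transcript_id; the stated numbers of
    unique genes and transcripts), "Lavin Up" and "Lavin Down" (disjoint
    differentially-expressed gene lists), with exactly ``n_overlap`` of the
    up/down genes also present in the PD list.  Gene identities are synthetic
    (SSG-prefixed); only the arithmetic of the lists is meaningful.
    """
    if n_overlap > n_up + n_down:
        raise ValueError("overlap cannot exceed the DE list size")
    pd_genes = [f"SSG{i:06d}" for i in range(n_pd_genes)]
    # distribute transcripts as evenly as possible across genes
    base, extra = divmod(n_pd_transcripts, n_pd_genes)
    rows = []
    t = 0
    for i, g in enumerate(pd_genes):
        n_tx = base + (1 if i < extra else 0)
        for _ in range(n_tx):
            rows.append({"gene_id": g, "transcript_id": f"SST{t:06d}"})
            t += 1
    pd_sheet = pd.DataFrame(rows)

    n_ov_up = min(n_overlap // 2, n_up)
    n_ov_down = n_overlap - n_ov_up
    up = pd_genes[:n_ov_up] + [f"SSGU{i:06d}" for i in range(n_up - n_ov_up)]
    down = pd_genes[n_ov_up : n_ov_up + n_ov_down] + [
        f"SSGD{i:06d}" for i in range(n_down - n_ov_down)
    ]
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        pd_sheet.to_excel(writer, sheet_name="NCBI PD Gene List", index=False)
        pd.DataFrame({"gene_id": up}).to_excel(writer, sheet_name="Lavin Up", index=False)
        pd.DataFrame({"gene_id": down}).to_excel(writer, sheet_name="Lavin Down", index=False)
    return path
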
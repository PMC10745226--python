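"""Shared fixtures: a small seeded synthetic cohort used across modules."""

from __future__ import annotations

import pytest

from adaredit import calling
from adaredit.simulate import DepthModel, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Two groups of four samples, 60 planted sites, contaminants and
    non-editing substitutions included; returns (config, paths, truth)."""
    config = SimulationConfig(
        groups=(("Control", 4), ("Case", 4)),
        n_sites=60,
        group_rates={"Control": 0.2, "Case": 0.4},
        depth_model=DepthModel(mean=300.0, dispersion=5.0),
        snp_contam_n=15,
        other_subst_n=15,
        seed=11,
    )
    out = tmp_path_factory.mktemp("cohort")
    paths, truth = simulate_cohort(config, out)
    return config, paths, truth


@pytest.fixture(scope="session")
def cohort_records(small_cohort):
    """Parsed VCF records per sample for the small cohort."""
    _, paths, _ = small_cohort
    return {sid: calling.load_vcf(p, sid) for sid, p in paths.items()}


@pytest.fixture(scope="session")
def cohort_groups(small_cohort):
    _, _, truth = small_cohort
    return dict(zip(truth.samples["sample_id"], truth.samples["group"]))


def write_vcf(path, lines, sample="S1"):
    """Write a minimal VCF with the given record lines (helper for fixtures)."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1,length=100000000>\n'
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    )
    path.write_text(header + "".join(line + "\n" for line in lines))
    return path
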
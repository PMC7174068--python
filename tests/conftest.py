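import textwrap

import pytest

from tmbcompare import (
    CodingExon,
    GeneModel,
    PanelSpec,
    SimulationConfig,
    Transcript,
    TumorTypeSpec,
    simulate_study,
)

TINY_GTF = textwrap.dedent("""\
    chr1\tsrc\tCDS\t11\t20\t.\t+\t0\tgene_id "A"; gene_name "A"; transcript_id "T1";
    chr1\tsrc\tCDS\t31\t40\t.\t+\t0\tgene_id "A"; gene_name "A"; transcript_id "T1";
    chr1\tsrc\tCDS\t101\t160\t.\t+\t0\tgene_id "B"; gene_name "B"; transcript_id "T2";
    chr1\tsrc\tCDS\t101\t130\t.\t+\t0\tgene_id "B"; gene_name "B"; transcript_id "T3";
    """)


@pytest.fixture
def tiny_gtf_text():
    return TINY_GTF


@pytest.fixture
def tiny_models():
    """Two genes on chr1: A (one 20 bp transcript), B (60 bp and 30 bp)."""
    a = GeneModel("A", [Transcript("T1", "A", [CodingExon("chr1", 10, 20), CodingExon("chr1", 30, 40)])])
    b = GeneModel(
        "B",
        [
            Transcript("T2", "B", [CodingExon("chr1", 100, 160)]),
            Transcript("T3", "B", [CodingExon("chr1", 100, 130)]),
        ],
    )
    return {"A": a, "B": b}


def small_config(seed=0, **kw):
    """A cut-down but structurally complete study configuration."""
    defaults = dict(
        seed=seed,
        n_genes=400,
        n_samples=40,
        panel_gene_pool=200,
        panels=(PanelSpec("P1", 60), PanelSpec("P2", 120)),
        tumor_types=(TumorTypeSpec("TTA", 2.0, 40.0), TumorTypeSpec("TTB", 5.0, 80.0)),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A written small study: genome/, vcf/, clinical.tsv, manifest.json."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = small_config()
    genome, cohort, clinical = simulate_study(cfg, outdir)
    return {
        "cfg": cfg,
        "dir": outdir,
        "genome": genome,
        "cohort": cohort,
        "clinical": clinical,
    }
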
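"""Synthetic study inputs: genome annotation, panels, somatic VCFs, clinical data.

The generator emulates the statistical structure of a large pan-cancer
somatic-variant cohort so the whole pipeline is testable without any
download: per-tumor mutation rates spanning several orders of magnitude
(log-uniform within tumor type), Poisson variant placement uniform over
each gene's coding footprint, consequences drawn either mechanistically
(random sense codon + random substitution, classified by the standard
genetic code, so the ~25% synonymous fraction *emerges* from the code) or
with a fixed synonymous probability for sharp targeted tests, and overall
survival whose hazard is log-linear in log(TMB+1).

Everything is deterministic given the config seed: the same config writes
byte-identical GTF, panel lists, VCFs and clinical tables.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome_model import (
    CodingExon,
    GeneModel,
    PanelDefinition,
    Transcript,
    longest_transcript,
)
from .variant_processing import VariantRecord, classify_consequence

logger = logging.getLogger(__name__)

__all__ = [
    "TumorTypeSpec",
    "PanelSpec",
    "SimulationConfig",
    "SyntheticGenome",
    "SyntheticCohort",
    "simulate_genome",
    "simulate_cohort",
    "simulate_survival",
    "simulate_study",
    "genetic_code_synonymous_fraction",
    "write_gtf",
    "write_panel_lists",
    "write_vcfs",
    "write_clinical",
]

_BASES = np.array(["A", "C", "G", "T"])
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)

# Lookup over (sense codon, codon position, alternate-base choice): the
# substitution's ref base, alt base and consequence under the standard code.
_SNV_REF = np.empty((61, 3, 3), dtype="U1")
_SNV_ALT = np.empty((61, 3, 3), dtype="U1")
_SNV_CSQ = np.empty((61, 3, 3), dtype="U16")
for _ci, _codon in enumerate(_SENSE_CODONS):
    for _p in range(3):
        _alts = [b for b in "ACGT" if b != _codon[_p]]
        for _ai, _alt in enumerate(_alts):
            _SNV_REF[_ci, _p, _ai] = _codon[_p]
            _SNV_ALT[_ci, _p, _ai] = _alt
            _SNV_CSQ[_ci, _p, _ai] = classify_consequence(_codon, _p, _alt)


def genetic_code_synonymous_fraction() -> float:
    """Exact probability that a uniform substitution in a uniform sense
    codon is synonymous (the code-determined constant, about one quarter)."""
    return float(np.mean(_SNV_CSQ == "synonymous"))


@dataclass(frozen=True)
class TumorTypeSpec:
    """A tumor type's per-Mb mutation-rate range.

    Rates are drawn log-uniformly in [rate_low, rate_high]; a degenerate
    range (low == high, possibly 0) fixes the rate for targeted tests.
    """

    name: str
    rate_low: float
    rate_high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.rate_low <= self.rate_high):
            raise ValueError("need 0 <= rate_low <= rate_high")
        if self.rate_low == 0 and self.rate_high > 0:
            raise ValueError("log-uniform range cannot start at 0; use a positive rate_low")


@dataclass(frozen=True)
class PanelSpec:
    """A panel drawn from the gene universe: either an explicit gene tuple
    or a size to sample from the shared cancer-gene pool."""

    name: str
    n_genes: int | None = None
    genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if (self.n_genes is None) == (self.genes is None):
            raise ValueError("specify exactly one of n_genes or genes")


# Default panels mirror the gene counts of six widely used clinical assays.
DEFAULT_PANELS = (
    PanelSpec("TsT170", 170),
    PanelSpec("FM", 324),
    PanelSpec("STMP", 397),
    PanelSpec("MSK", 468),
    PanelSpec("TsT500", 500),
    PanelSpec("TempusXT", 596),
)

# Rate ranges loosely graded from low-burden (glioma-like) to high-burden
# (melanoma-like) tumor types; together they span ~2.5 orders of magnitude.
DEFAULT_TUMOR_TYPES = (
    TumorTypeSpec("GBM", 0.5, 5.0),
    TumorTypeSpec("BRCA", 0.5, 10.0),
    TumorTypeSpec("BLCA", 1.0, 30.0),
    TumorTypeSpec("LUAD", 1.0, 60.0),
    TumorTypeSpec("SKCM", 2.0, 100.0),
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Gene coding lengths are log-normal with a ~1.5 kb mean; per-tumor
    mutation rates are log-uniform within tumor type; ``rate_multipliers``
    scales the per-base rate inside the genes of named panels (a gene in
    several multiplied panels gets the product), which is how the
    panels-sample-atypical-regions scenario is generated.
    """

    seed: int = 0
    # genome
    n_genes: int = 20_000
    gene_length_meanlog: float = float(np.log(1500.0) - 0.5 * 0.6**2)
    gene_length_sdlog: float = 0.6
    min_coding_length: int = 150
    max_exons: int = 20
    n_chromosomes: int = 22
    panel_gene_pool: int = 800
    panels: tuple[PanelSpec, ...] = DEFAULT_PANELS
    # cohort
    n_samples: int = 500
    tumor_types: tuple[TumorTypeSpec, ...] = DEFAULT_TUMOR_TYPES
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    consequence_model: str = "genetic_code"
    synonymous_fraction: float = 0.25
    indel_fraction: float = 0.1
    # survival
    baseline_hazard: float = 1.0 / 1500.0  # events per day at TMB 0
    beta_logtmb: float = 0.35  # log-hazard per unit log(TMB+1)
    censoring_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.consequence_model not in ("genetic_code", "fixed_fraction"):
            raise ValueError(f"unknown consequence_model {self.consequence_model!r}")
        if not 0 <= self.synonymous_fraction <= 1:
            raise ValueError("synonymous_fraction must be in [0, 1]")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        max_panel = max(
            (p.n_genes or len(p.genes or ())) for p in self.panels
        ) if self.panels else 0
        if max_panel > self.n_genes:
            raise ValueError("panel larger than gene universe")
        if self.panels and max_panel > self.panel_gene_pool:
            raise ValueError("panel larger than the panel gene pool")


@dataclass
class SyntheticGenome:
    """Gene models plus panel definitions, with a placement index.

    The placement index flattens every gene's coding footprint (its longest
    transcript, which by construction contains all other transcripts) into
    a single coding coordinate axis so variants can be placed uniformly per
    base in O(log n_exons).
    """

    gene_models: dict[str, GeneModel]
    panels: list[PanelDefinition]
    chrom_names: list[str]
    # flattened exon index
    exon_cum: np.ndarray  # cumulative coding-length start of each exon
    exon_gstart: np.ndarray
    exon_chrom: np.ndarray  # chrom index per exon
    exon_gene: np.ndarray  # gene index per exon
    gene_names: list[str]
    gene_offsets: np.ndarray  # first flattened-exon row per gene
    total_bases: int

    @property
    def total_mb(self) -> float:
        return self.total_bases / 1e6

    def gene_multipliers(self, rate_multipliers: Mapping[str, float]) -> np.ndarray:
        """Per-gene relative mutation rate from panel multipliers."""
        mult = np.ones(len(self.gene_names))
        if rate_multipliers:
            index = {g: i for i, g in enumerate(self.gene_names)}
            for panel in self.panels:
                m = rate_multipliers.get(panel.name)
                if m is None or m == 1.0:
                    continue
                for g in panel.genes:
                    mult[index[g]] *= m
        return mult


def simulate_genome(cfg: SimulationConfig) -> SyntheticGenome:
    """Draw the synthetic exome and panel gene lists (deterministic in seed)."""
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_genes
    gene_names = [f"SG{i + 1:05d}" for i in range(n)]
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]

    lengths = rng.lognormal(cfg.gene_length_meanlog, cfg.gene_length_sdlog, size=n)
    lengths = np.maximum(cfg.min_coding_length, (np.rint(lengths / 3) * 3)).astype(int)

    models: dict[str, GeneModel] = {}
    cursors = {c: 10_000 for c in chrom_names}
    cum_rows: list[int] = []
    gstart_rows: list[int] = []
    chrom_rows: list[int] = []
    gene_rows: list[int] = []
    gene_offsets = np.zeros(n, dtype=np.int64)
    cum = 0
    for i, (gname, L) in enumerate(zip(gene_names, lengths)):
        chrom_idx = i * cfg.n_chromosomes // n
        chrom = chrom_names[chrom_idx]
        n_codons = L // 3
        n_exons = int(rng.integers(1, min(cfg.max_exons, n_codons) + 1))
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, n_codons), size=n_exons - 1, replace=False))
            codon_counts = np.diff(np.concatenate([[0], cuts, [n_codons]]))
        else:
            codon_counts = np.array([n_codons])
        exon_lens = codon_counts * 3

        pos = cursors[chrom]
        exons: list[CodingExon] = []
        gene_offsets[i] = len(cum_rows)
        for el in exon_lens:
            exons.append(CodingExon(chrom, pos, pos + int(el)))
            cum_rows.append(cum)
            gstart_rows.append(pos)
            chrom_rows.append(chrom_idx)
            gene_rows.append(i)
            cum += int(el)
            pos += int(el) + int(rng.integers(200, 2001))
        cursors[chrom] = pos + int(rng.integers(1000, 10_001))

        n_tx = int(rng.integers(1, 4))
        transcripts = [Transcript(f"{gname}.t1", gname, list(exons))]
        for k in range(2, n_tx + 1):
            keep = int(rng.integers(1, n_exons + 1))
            transcripts.append(Transcript(f"{gname}.t{k}", gname, list(exons[:keep])))
        models[gname] = GeneModel(gname, transcripts)

    pool = sorted(rng.choice(gene_names, size=min(cfg.panel_gene_pool, n), replace=False))
    panels: list[PanelDefinition] = []
    for spec in cfg.panels:
        if spec.genes is not None:
            genes = frozenset(spec.genes)
            if not genes <= set(gene_names):
                raise ValueError(f"panel {spec.name} names genes outside the universe")
        else:
            genes = frozenset(rng.choice(pool, size=spec.n_genes, replace=False))
        panels.append(PanelDefinition(spec.name, genes))

    return SyntheticGenome(
        gene_models=models,
        panels=panels,
        chrom_names=chrom_names,
        exon_cum=np.asarray(cum_rows, dtype=np.int64),
        exon_gstart=np.asarray(gstart_rows, dtype=np.int64),
        exon_chrom=np.asarray(chrom_rows, dtype=np.int64),
        exon_gene=np.asarray(gene_rows, dtype=np.int64),
        gene_names=gene_names,
        gene_offsets=gene_offsets,
        total_bases=cum,
    )


@dataclass
class SyntheticCohort:
    samples: list[str]
    tumor_type: dict[str, str]
    rate_per_mb: dict[str, float]
    records: dict[str, list[VariantRecord]]

    @property
    def n_variants(self) -> int:
        return sum(len(v) for v in self.records.values())


def _draw_snv_alleles(
    rng: np.random.Generator, n: int, model: str, syn_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (ref, alt, consequence) for n coding SNVs."""
    if model == "genetic_code":
        ci = rng.integers(0, 61, size=n)
        p = rng.integers(0, 3, size=n)
        a = rng.integers(0, 3, size=n)
        return _SNV_REF[ci, p, a], _SNV_ALT[ci, p, a], _SNV_CSQ[ci, p, a]
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    csq = np.where(rng.random(n) < syn_fraction, "synonymous", "missense")
    return _BASES[ref_i], _BASES[alt_i], csq


def _draw_indel_alleles(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (ref, alt, consequence) for n coding indels (1-6 bp)."""
    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    csq = np.empty(n, dtype=object)
    is_ins = rng.random(n) < 0.5
    sizes = rng.integers(1, 7, size=n)
    anchor = _BASES[rng.integers(0, 4, size=n)]
    for i in range(n):
        extra = "".join(_BASES[rng.integers(0, 4, size=int(sizes[i]))])
        if is_ins[i]:
            refs[i], alts[i] = anchor[i], anchor[i] + extra
        else:
            refs[i], alts[i] = anchor[i] + extra, anchor[i]
        csq[i] = "frameshift" if sizes[i] % 3 else "inframe_indel"
    return refs, alts, csq


def simulate_cohort(cfg: SimulationConfig, genome: SyntheticGenome) -> SyntheticCohort:
    """Draw per-sample somatic variant lists.

    Per sample: a tumor type, then a per-Mb rate log-uniform in that type's
    range; variant counts are Poisson with per-gene intensity rate x gene
    footprint x multiplier, positions uniform over the gene's coding bases.
    Exact duplicate events (same position and alleles) within a sample are
    dropped so a written VCF round-trips to the same variant count.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    mult = genome.gene_multipliers(cfg.rate_multipliers)
    # group flattened exons by multiplier class for stratified placement
    exon_mult = mult[genome.exon_gene]
    classes: list[tuple[float, np.ndarray, np.ndarray, int]] = []
    for m in np.unique(exon_mult):
        rows = np.where(exon_mult == m)[0]
        exon_len = np.diff(
            np.append(genome.exon_cum, genome.total_bases)
        )[rows]
        cum = np.concatenate([[0], np.cumsum(exon_len)])
        classes.append((float(m), rows, cum, int(cum[-1])))

    weights = np.array([t.weight for t in cfg.tumor_types], dtype=float)
    weights /= weights.sum()

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    tumor_type: dict[str, str] = {}
    rate_per_mb: dict[str, float] = {}
    records: dict[str, list[VariantRecord]] = {}
    for sid in samples:
        tt = cfg.tumor_types[rng.choice(len(cfg.tumor_types), p=weights)]
        if tt.rate_low == tt.rate_high:
            rate = float(tt.rate_low)
        else:
            rate = float(np.exp(rng.uniform(np.log(tt.rate_low), np.log(tt.rate_high))))
        tumor_type[sid] = tt.name
        rate_per_mb[sid] = rate

        chroms: list[np.ndarray] = []
        pos0s: list[np.ndarray] = []
        genes: list[np.ndarray] = []
        for m, rows, cum, class_bases in classes:
            lam = rate / 1e6 * class_bases * m
            k = int(rng.poisson(lam))
            if k == 0:
                continue
            off = rng.integers(0, class_bases, size=k)
            j = np.searchsorted(cum, off, side="right") - 1
            row = rows[j]
            pos0s.append(genome.exon_gstart[row] + (off - cum[j]))
            chroms.append(genome.exon_chrom[row])
            genes.append(genome.exon_gene[row])
        recs: list[VariantRecord] = []
        if pos0s:
            chrom_i = np.concatenate(chroms)
            pos0 = np.concatenate(pos0s)
            gene_i = np.concatenate(genes)
            order = np.lexsort((pos0, chrom_i))
            chrom_i, pos0, gene_i = chrom_i[order], pos0[order], gene_i[order]
            k = len(pos0)
            is_indel = rng.random(k) < cfg.indel_fraction
            ref = np.empty(k, dtype=object)
            alt = np.empty(k, dtype=object)
            csq = np.empty(k, dtype=object)
            n_snv = int((~is_indel).sum())
            if n_snv:
                r, a, c = _draw_snv_alleles(
                    rng, n_snv, cfg.consequence_model, cfg.synonymous_fraction
                )
                ref[~is_indel], alt[~is_indel], csq[~is_indel] = r, a, c
            n_ind = k - n_snv
            if n_ind:
                r, a, c = _draw_indel_alleles(rng, n_ind)
                ref[is_indel], alt[is_indel], csq[is_indel] = r, a, c
            seen: set[tuple[int, int, str, str]] = set()
            for i in range(k):
                key = (int(chrom_i[i]), int(pos0[i]), ref[i], alt[i])
                if key in seen:
                    continue
                seen.add(key)
                recs.append(
                    VariantRecord(
                        sample_id=sid,
                        chrom=genome.chrom_names[chrom_i[i]],
                        pos=int(pos0[i]) + 1,
                        ref=str(ref[i]),
                        alt=str(alt[i]),
                        consequence=str(csq[i]),
                        gene_symbol=genome.gene_names[gene_i[i]],
                    )
                )
        records[sid] = recs
    return SyntheticCohort(samples, tumor_type, rate_per_mb, records)


def simulate_survival(
    cfg: SimulationConfig,
    tmb_by_sample: Mapping[str, float],
    tumor_type_by_sample: Mapping[str, str],
) -> pd.DataFrame:
    """Draw overall-survival times with hazard h0*exp(beta*log(TMB+1)).

    Censoring is an independent exponential whose rate is solved so the
    expected censored fraction equals ``cfg.censoring_fraction``.  Returns
    the clinical table (sample_id, tumor_type, os_days, event).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    samples = list(tmb_by_sample)
    missing = [s for s in samples if s not in tumor_type_by_sample]
    if missing:
        raise ValueError(f"tumor type missing for {len(missing)} samples")
    tmb = np.array([tmb_by_sample[s] for s in samples], dtype=float)
    hazard = cfg.baseline_hazard * np.exp(cfg.beta_logtmb * np.log1p(tmb))
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_fraction > 0:
        def censored_frac(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean(c / (c + hazard))) - cfg.censoring_fraction

        log_c = brentq(censored_frac, np.log(hazard.min()) - 20, np.log(hazard.max()) + 20)
        t_cens = rng.exponential(np.exp(-log_c), size=len(samples))
    else:
        t_cens = np.full(len(samples), np.inf)
    os_days = np.maximum(1, np.ceil(np.minimum(t_event, t_cens))).astype(int)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "tumor_type": [tumor_type_by_sample[s] for s in samples],
            "os_days": os_days,
            "event": event,
        }
    )


def simulate_study(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> tuple[SyntheticGenome, SyntheticCohort, pd.DataFrame]:
    """Genome + cohort + clinical table; optionally written to ``outdir``.

    The survival stage needs a TMB value per sample; the generative hazard
    uses each sample's *true* simulated mutation rate per Mb (the noiseless
    quantity every TMB method estimates), so no counting method is
    privileged.
    """
    genome = simulate_genome(cfg)
    cohort = simulate_cohort(cfg, genome)
    clinical = simulate_survival(cfg, cohort.rate_per_mb, cohort.tumor_type)
    if outdir is not None:
        outdir = Path(outdir)
        write_gtf(genome, outdir / "genome" / "annotation.gtf")
        write_panel_lists(genome, outdir / "genome" / "panels")
        write_vcfs(cohort, genome, outdir / "vcf")
        write_clinical(clinical, outdir / "clinical.tsv")
        manifest = {
            "config": dataclasses.asdict(cfg),
            "n_variants": cohort.n_variants,
            "exome_total_bases": genome.total_bases,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return genome, cohort, clinical


# ---------------------------------------------------------------------------
# writers (plain-text, byte-deterministic)

def write_gtf(genome: SyntheticGenome, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    for gname in genome.gene_names:
        model = genome.gene_models[gname]
        for tx in model.transcripts:
            for e in tx.exons:
                attrs = (
                    f'gene_id "{gname}"; gene_name "{gname}"; '
                    f'transcript_id "{tx.transcript_id}";'
                )
                lines.append(
                    f"{e.chrom}\tsynth\tCDS\t{e.start + 1}\t{e.end}\t.\t+\t0\t{attrs}"
                )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_panel_lists(genome: SyntheticGenome, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for panel in genome.panels:
        p = outdir / f"{panel.name}.txt"
        p.write_text("\n".join(sorted(panel.genes)) + "\n")
        paths.append(p)
    return paths


def _vcf_header(genome: SyntheticGenome) -> str:
    contig_end = {}
    for gname in genome.gene_names:
        tx = longest_transcript(genome.gene_models[gname])
        for e in tx.exons:
            contig_end[e.chrom] = max(contig_end.get(e.chrom, 0), e.end)
    lines = ["##fileformat=VCFv4.2"]
    for c in genome.chrom_names:
        if c in contig_end:
            lines.append(f"##contig=<ID={c},length={contig_end[c] + 10_000}>")
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append(
        '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines)


def write_vcfs(cohort: SyntheticCohort, genome: SyntheticGenome, outdir: str | Path) -> list[Path]:
    """One VCF v4.2 per sample (the one-file-per-tumor layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _vcf_header(genome)
    chrom_rank = {c: i for i, c in enumerate(genome.chrom_names)}
    paths = []
    for sid in cohort.samples:
        recs = sorted(cohort.records[sid], key=lambda r: (chrom_rank[r.chrom], r.pos, r.ref, r.alt))
        body = [
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
            f"GENE={r.gene_symbol};CSQ_CLASS={r.consequence}"
            for r in recs
        ]
        p = outdir / f"{sid}.vcf"
        content = header + "\n" + "\n".join(body) + "\n" if body else header + "\n"
        p.write_text(content)
        paths.append(p)
    return paths


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(path, sep="\t", index=False)
    return path
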
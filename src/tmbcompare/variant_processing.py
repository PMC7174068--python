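"""Somatic variant ingestion, consequence classification and inclusion policies.

A TMB method is a *policy*: which variant classes count (SNV / insertion /
deletion), whether synonymous substitutions count, and which genomic region
the variant must fall in (a panel footprint or the whole coding exome).
This module reads annotated VCFs (or a flat TSV dialect), classifies codon
substitutions with the standard genetic code, and applies policies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio.Data import CodonTable

from .genome_model import PanelFootprint

logger = logging.getLogger(__name__)

__all__ = [
    "SNV",
    "INSERTION",
    "DELETION",
    "CODING_CONSEQUENCES",
    "VariantRecord",
    "InclusionPolicy",
    "ReadStats",
    "read_variants",
    "read_variants_tsv",
    "classify_consequence",
    "in_region",
    "filter_variants",
]

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
VARIANT_CLASSES = frozenset({SNV, INSERTION, DELETION})

#: Consequences that place a variant in the coding sequence.  ``noncoding``
#: and ``unknown`` never count toward TMB (the definition requires a variant
#: "within a coding exon").
CODING_CONSEQUENCES = frozenset(
    {"synonymous", "missense", "nonsense", "frameshift", "inframe_indel", "splice"}
)
CONSEQUENCES = CODING_CONSEQUENCES | {"noncoding", "unknown"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = frozenset("ACGT")


def variant_class_of(ref: str, alt: str) -> str:
    """SNV for equal-length alleles, else insertion/deletion by length."""
    if len(ref) == len(alt):
        return SNV
    return INSERTION if len(alt) > len(ref) else DELETION


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant event (one per record x alternate allele)."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    consequence: str = "unknown"
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def variant_class(self) -> str:
        return variant_class_of(self.ref, self.alt)

    @property
    def anchor0(self) -> int:
        """0-based leftmost reference base affected — the region-membership
        anchor (for insertions, the base before the inserted sequence)."""
        return self.pos - 1


@dataclass(frozen=True)
class InclusionPolicy:
    """A variant-counting rule: class filter, synonymous toggle, region.

    ``include_splice`` keeps annotated splice variants among the
    non-synonymous coding events (default on; configurable because usage
    varies between clinical assays).
    """

    region: PanelFootprint
    include_synonymous: bool = False
    variant_classes: frozenset[str] = VARIANT_CLASSES
    include_splice: bool = True

    def __post_init__(self) -> None:
        if not self.variant_classes:
            raise ValueError("variant_classes must be non-empty")
        unknown = self.variant_classes - VARIANT_CLASSES
        if unknown:
            raise ValueError(f"unknown variant classes: {sorted(unknown)}")

    @property
    def counted_consequences(self) -> frozenset[str]:
        counted = set(CODING_CONSEQUENCES)
        if not self.include_synonymous:
            counted.discard("synonymous")
        if not self.include_splice:
            counted.discard("splice")
        return frozenset(counted)


@dataclass
class ReadStats:
    """Per-file ingestion accounting (reported in run summaries)."""

    n_records: int = 0
    n_kept: int = 0
    n_filter_dropped: int = 0
    n_duplicates: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_variants(
    vcf_path: str | Path,
    sample_id: str | None = None,
    gene_key: str = "GENE",
    consequence_key: str = "CSQ_CLASS",
    stats: ReadStats | None = None,
) -> list[VariantRecord]:
    """Read one sample's somatic variants from an annotated VCF.

    One :class:`VariantRecord` is produced per (record x alternate allele).
    Records whose FILTER is anything other than PASS or ``.`` are dropped
    and counted.  Exact duplicates (same chrom/pos/ref/alt) are collapsed
    to one event, counted.  Missing gene/consequence annotations yield
    ``gene_symbol=""`` and ``consequence="unknown"``.

    ``sample_id`` defaults to the VCF file's stem, matching a
    one-file-per-tumor layout.
    """
    path = Path(vcf_path)
    sid = sample_id if sample_id is not None else path.stem.removesuffix(".vcf")
    stats = stats if stats is not None else ReadStats()
    records: list[VariantRecord] = []
    seen: set[tuple[str, int, str, str]] = set()
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            stats.n_records += 1
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                stats.n_filter_dropped += 1
                continue
            gene = rec.info.get(gene_key, "")
            csq = rec.info.get(consequence_key, "unknown")
            if isinstance(gene, tuple):
                gene = gene[0] if gene else ""
            if isinstance(csq, tuple):
                csq = csq[0] if csq else "unknown"
            if csq not in CONSEQUENCES:
                csq = "unknown"
            for alt in rec.alts or ():
                key = (rec.chrom, rec.pos, rec.ref, alt)
                if key in seen:
                    stats.n_duplicates += 1
                    continue
                seen.add(key)
                records.append(
                    VariantRecord(
                        sample_id=sid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        consequence=str(csq),
                        gene_symbol=str(gene or ""),
                    )
                )
                stats.n_kept += 1
    if stats.n_filter_dropped or stats.n_duplicates:
        logger.info(
            "%s: dropped %d non-PASS records, collapsed %d duplicates",
            path.name,
            stats.n_filter_dropped,
            stats.n_duplicates,
        )
    return records


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read the flat TSV dialect: columns sample_id, chrom, pos, ref, alt,
    gene, consequence (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    required = {"sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].fillna("")
    return [
        VariantRecord(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            consequence=str(r.consequence) if str(r.consequence) in CONSEQUENCES else "unknown",
            gene_symbol=str(r.gene),
        )
        for r in df.itertuples()
    ]


def variants_to_tsv(records: list[VariantRecord], path: str | Path) -> Path:
    """Write records (e.g. a filtered list) in the flat TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "gene": [r.gene_symbol for r in records],
            "consequence": [r.consequence for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def classify_consequence(ref_codon: str, codon_pos: int, alt_base: str) -> str:
    """Classify a single-base codon substitution with the standard genetic code.

    Returns ``synonymous`` if the amino acid is unchanged, ``nonsense`` if
    the mutant codon is a stop, ``missense`` otherwise.
    """
    ref_codon = ref_codon.upper()
    alt_base = alt_base.upper()
    if len(ref_codon) != 3 or set(ref_codon) - _BASES:
        raise ValueError(f"invalid codon {ref_codon!r}")
    if alt_base not in _BASES:
        raise ValueError(f"invalid base {alt_base!r}")
    if codon_pos not in (0, 1, 2):
        raise ValueError("codon_pos must be 0, 1 or 2")
    if ref_codon in _STANDARD_TABLE.stop_codons:
        raise ValueError("reference codon is a stop codon")
    if alt_base == ref_codon[codon_pos]:
        raise ValueError("alternate base equals the reference base")
    alt_codon = ref_codon[:codon_pos] + alt_base + ref_codon[codon_pos + 1 :]
    if alt_codon in _STANDARD_TABLE.stop_codons:
        return "nonsense"
    ref_aa = _STANDARD_TABLE.forward_table[ref_codon]
    alt_aa = _STANDARD_TABLE.forward_table[alt_codon]
    return "synonymous" if ref_aa == alt_aa else "missense"


def in_region(v: VariantRecord, fp: PanelFootprint) -> bool:
    """True iff the variant's anchor base falls in the footprint's merged
    interval set (0-based half-open, so an interval's end base is outside)."""
    return fp.contains(v.chrom, v.anchor0)


def filter_variants(
    records: list[VariantRecord], policy: InclusionPolicy
) -> list[VariantRecord]:
    """Apply an inclusion policy; order-preserving and idempotent.

    A record is kept iff its variant class is in the policy, its anchor lies
    inside the policy region, and its consequence is one the policy counts.
    ``noncoding`` and ``unknown`` consequences never count.
    """
    counted = policy.counted_consequences
    classes = policy.variant_classes
    region = policy.region
    return [
        r
        for r in records
        if r.variant_class in classes
        and r.consequence in counted
        and region.contains(r.chrom, r.anchor0)
    ]
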
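"""Gene models, representative-transcript selection and coding footprints.

Tumor mutation burden is a density: qualifying variants divided by the
megabases of coding sequence interrogated.  This module builds the
denominator.  A targeted panel's footprint is the merged set of coding
exons of the *longest* transcript of each panel gene; the whole-exome
footprint is the union of *all* coding exons of *all* transcripts.  The
asymmetry is deliberate: a panel captures one representative transcript
per gene, while exome capture tiles every annotated coding exon.

Coordinates are 1-based inclusive on the GTF side and 0-based half-open
internally, so interval arithmetic never needs ±1 adjustments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "CodingExon",
    "Transcript",
    "GeneModel",
    "PanelDefinition",
    "PanelFootprint",
    "AnnotationFormatError",
    "load_gene_models",
    "longest_transcript",
    "panel_footprint",
    "exome_footprint",
    "footprint_report",
]


class AnnotationFormatError(ValueError):
    """Raised when a gene-annotation stream cannot be parsed."""


@dataclass(frozen=True)
class CodingExon:
    """One coding exon, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A transcript's coding exons, normalized to sorted, non-overlapping."""

    transcript_id: str
    gene_symbol: str
    exons: list[CodingExon]

    def __post_init__(self) -> None:
        self.exons = _normalize_exons(self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no coding exons")

    @property
    def coding_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class GeneModel:
    gene_symbol: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_symbol} has no transcripts")


@dataclass(frozen=True)
class PanelDefinition:
    """A named list of gene symbols targeted by an assay."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name} is empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "PanelDefinition":
        """Read a plain-text gene list (one symbol per line, ``#`` comments).

        Symbols are whitespace-trimmed and matched case-sensitively; duplicate
        lines are collapsed with a logged count.
        """
        path = Path(path)
        symbols: list[str] = []
        for line in path.read_text().splitlines():
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            symbols.append(sym)
        uniq = frozenset(symbols)
        if len(uniq) < len(symbols):
            logger.warning(
                "panel %s: %d duplicate symbols collapsed", path.name, len(symbols) - len(uniq)
            )
        return cls(name=name or path.stem, genes=uniq)


def _normalize_exons(exons: Iterable[CodingExon]) -> list[CodingExon]:
    """Sort by (chrom, start) and merge overlapping/adjacent exons per chrom."""
    by_chrom: dict[str, list[CodingExon]] = {}
    for e in exons:
        by_chrom.setdefault(e.chrom, []).append(e)
    out: list[CodingExon] = []
    for chrom in sorted(by_chrom):
        merged: list[list[int]] = []
        for e in sorted(by_chrom[chrom], key=lambda x: (x.start, x.end)):
            if merged and e.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e.end)
            else:
                merged.append([e.start, e.end])
        out.extend(CodingExon(chrom, s, t) for s, t in merged)
    return out


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge (chrom, start, end) triples into sorted disjoint arrays per chrom."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return {c: out[c] for c in sorted(out)}


@dataclass
class PanelFootprint:
    """Merged coding-interval set of a panel; the TMB denominator.

    ``intervals`` maps chromosome -> (starts, ends) as sorted disjoint
    0-based half-open numpy arrays.  ``total_mb`` is ``total_bases / 1e6``.
    """

    panel_name: str
    selected_transcripts: dict[str, str]
    intervals: dict[str, tuple[np.ndarray, np.ndarray]]
    total_bases: int
    missing_genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def total_mb(self) -> float:
        return self.total_bases / 1e6

    @property
    def n_genes(self) -> int:
        return len(self.selected_transcripts)

    def contains(self, chrom: str, pos0: int) -> bool:
        """True iff the 0-based position lies inside the merged interval set."""
        ivs = self.intervals.get(chrom)
        if ivs is None:
            return False
        starts, ends = ivs
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def contains_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an array of 0-based positions."""
        ivs = self.intervals.get(chrom)
        if ivs is None:
            return np.zeros(len(pos0), dtype=bool)
        starts, ends = ivs
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < ends[idx[ok]]
        return out

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom, (starts, ends) in self.intervals.items():
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e


def load_gene_models(annotation: str | Path | IO[str]) -> dict[str, GeneModel]:
    """Parse CDS features from a GTF-style stream into gene models.

    Accepts a path or an open text stream.  GTF coordinates (1-based,
    inclusive) are converted to the internal 0-based half-open convention.
    Features without a recognizable gene symbol (``gene_name`` falling back
    to ``gene_id``) or ``transcript_id`` are skipped with a logged count.

    Returns a mapping gene_symbol -> :class:`GeneModel`.

    Raises
    ------
    AnnotationFormatError
        On the first structurally unparseable line, naming its line number.
    """
    if isinstance(annotation, (str, Path)):
        with open(annotation) as fh:
            return load_gene_models(fh)

    exons: dict[tuple[str, str], list[CodingExon]] = {}
    n_skipped = 0
    for lineno, line in enumerate(annotation, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationFormatError(
                f"unparseable annotation at line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise AnnotationFormatError(f"unparseable annotation at line {lineno}: {exc}") from exc
        if feat.featuretype != "CDS":
            continue
        attrs = feat.attributes
        gene = (attrs.get("gene_name") or attrs.get("gene_id") or [None])[0]
        tx = (attrs.get("transcript_id") or [None])[0]
        if not gene or not tx:
            n_skipped += 1
            continue
        # GTF is 1-based inclusive; internal is 0-based half-open.
        exons.setdefault((gene.strip(), tx), []).append(
            CodingExon(feat.seqid, feat.start - 1, feat.end)
        )
    if n_skipped:
        logger.warning("skipped %d CDS features lacking gene or transcript attributes", n_skipped)

    genes: dict[str, list[Transcript]] = {}
    for (gene, tx), exon_list in exons.items():
        genes.setdefault(gene, []).append(Transcript(tx, gene, exon_list))
    return {g: GeneModel(g, txs) for g, txs in genes.items()}


def longest_transcript(gene: GeneModel) -> Transcript:
    """The transcript with maximal coding length.

    Ties are broken by lexicographically smallest ``transcript_id`` so that
    footprints are reproducible across runs and input orderings.
    """
    best_len = max(t.coding_length for t in gene.transcripts)
    candidates = [t for t in gene.transcripts if t.coding_length == best_len]
    return min(candidates, key=lambda t: t.transcript_id)


def panel_footprint(
    panel: PanelDefinition, models: Mapping[str, GeneModel]
) -> PanelFootprint:
    """Coding footprint of a panel: merged longest-transcript exons.

    Exon overlaps between panel genes are counted once toward
    ``total_bases`` (the denominator is sequence acquired, not a sum of
    per-gene lengths).  Panel genes absent from the annotation land in
    ``missing_genes`` and contribute nothing; if *every* gene is missing
    the footprint would be empty and a :class:`ValueError` is raised.
    """
    selected: dict[str, str] = {}
    triples: list[tuple[str, int, int]] = []
    missing: set[str] = set()
    for sym in sorted(panel.genes):
        model = models.get(sym)
        if model is None:
            missing.add(sym)
            continue
        tx = longest_transcript(model)
        selected[sym] = tx.transcript_id
        triples.extend((e.chrom, e.start, e.end) for e in tx.exons)
    if not selected:
        raise ValueError(f"empty footprint: no panel genes of {panel.name!r} found in annotation")
    if missing:
        logger.warning("panel %s: %d genes absent from annotation", panel.name, len(missing))
    merged = _merge_intervals(triples)
    total = int(sum((e - s).sum() for s, e in merged.values()))
    return PanelFootprint(
        panel_name=panel.name,
        selected_transcripts=selected,
        intervals=merged,
        total_bases=total,
        missing_genes=frozenset(missing),
    )


def exome_footprint(models: Mapping[str, GeneModel]) -> PanelFootprint:
    """Whole-exome coding footprint: union of all coding exons of all
    transcripts of all genes, merged.  Reported under the name ``WES``."""
    if not models:
        raise ValueError("no gene models supplied")
    triples: list[tuple[str, int, int]] = []
    selected: dict[str, str] = {}
    for sym in sorted(models):
        model = models[sym]
        selected[sym] = longest_transcript(model).transcript_id
        for tx in model.transcripts:
            triples.extend((e.chrom, e.start, e.end) for e in tx.exons)
    merged = _merge_intervals(triples)
    total = int(sum((e - s).sum() for s, e in merged.values()))
    return PanelFootprint(
        panel_name="WES",
        selected_transcripts=selected,
        intervals=merged,
        total_bases=total,
    )


def footprint_report(footprints: Iterable[PanelFootprint]) -> pd.DataFrame:
    """Tabulate footprints: panel, n_genes, n_missing, total_bases, total_mb."""
    rows = [
        {
            "panel": fp.panel_name,
            "n_genes": fp.n_genes,
            "n_missing": len(fp.missing_genes),
            "total_bases": fp.total_bases,
            "total_mb": fp.total_mb,
        }
        for fp in footprints
    ]
    return pd.DataFrame(rows, columns=["panel", "n_genes", "n_missing", "total_bases", "total_mb"])
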
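"""TMB computation: qualifying variants per megabase, per sample per method.

TMB = variant_count / footprint_mb, with the footprint fixed by the method
(a panel's merged longest-transcript exons, or the whole coding exome).
Values are kept at full floating precision; any display rounding belongs to
the report layer, so samples near clinical cut-offs are never misclassified
by formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import PanelFootprint
from .variant_processing import (
    InclusionPolicy,
    VariantRecord,
    filter_variants,
)

__all__ = ["TMBResult", "TMBMatrix", "TMBMethod", "compute_tmb", "tmb_matrix"]


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    method_label: str
    variant_count: int
    footprint_mb: float

    @property
    def tmb(self) -> float:
        return self.variant_count / self.footprint_mb


@dataclass(frozen=True)
class TMBMethod:
    """A named counting method: an inclusion policy over a footprint."""

    label: str
    policy: InclusionPolicy

    @property
    def footprint(self) -> PanelFootprint:
        return self.policy.region


@dataclass
class TMBMatrix:
    """Cohort TMB grid: samples x methods, with parallel variant counts.

    ``tmb`` and ``counts`` are DataFrames indexed by sample with one column
    per method label; ``footprint_mb`` maps labels to denominators.
    """

    tmb: pd.DataFrame
    counts: pd.DataFrame
    footprint_mb: dict[str, float]

    @property
    def samples(self) -> list[str]:
        return list(self.tmb.index)

    @property
    def methods(self) -> list[str]:
        return list(self.tmb.columns)

    def column(self, label: str) -> pd.Series:
        return self.tmb[label]

    def to_long(self) -> pd.DataFrame:
        """Long-format table: sample_id, method_label, variant_count,
        footprint_mb, tmb."""
        rows = []
        for sample in self.tmb.index:
            for method in self.tmb.columns:
                rows.append(
                    {
                        "sample_id": sample,
                        "method_label": method,
                        "variant_count": int(self.counts.at[sample, method]),
                        "footprint_mb": self.footprint_mb[method],
                        "tmb": float(self.tmb.at[sample, method]),
                    }
                )
        return pd.DataFrame(rows)


def compute_tmb(
    records: Iterable[VariantRecord],
    policy: InclusionPolicy,
    fp: PanelFootprint,
    sample_id: str,
    method_label: str | None = None,
) -> TMBResult:
    """TMB of one sample under one policy/footprint pair.

    The denominator must be positive: a zero footprint raises rather than
    returning 0 or infinity.
    """
    if fp.total_mb <= 0:
        raise ValueError(f"footprint {fp.panel_name!r} has zero size")
    kept = [r for r in filter_variants(list(records), policy) if r.sample_id == sample_id]
    return TMBResult(
        sample_id=sample_id,
        method_label=method_label or fp.panel_name,
        variant_count=len(kept),
        footprint_mb=fp.total_mb,
    )


def _records_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "chrom": [r.chrom for r in records],
            "anchor0": np.fromiter((r.anchor0 for r in records), dtype=np.int64, count=len(records)),
            "variant_class": [r.variant_class for r in records],
            "consequence": [r.consequence for r in records],
        }
    )


def tmb_matrix(
    cohort_records: Mapping[str, Sequence[VariantRecord]] | Sequence[VariantRecord],
    methods: Sequence[TMBMethod],
    samples: Sequence[str] | None = None,
) -> TMBMatrix:
    """Compute the full sample x method TMB grid.

    ``cohort_records`` is either a mapping sample_id -> records or a flat
    record list.  Samples listed in ``samples`` (or as mapping keys) with no
    variants get explicit zero counts rather than missing cells.  Region,
    class and consequence filters are applied vectorized; results agree
    with per-record :func:`compute_tmb` (tested both ways).
    """
    if not methods:
        raise ValueError("at least one method required")
    labels = [m.label for m in methods]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate method labels")

    if isinstance(cohort_records, Mapping):
        flat: list[VariantRecord] = [r for recs in cohort_records.values() for r in recs]
        sample_list = list(samples) if samples is not None else list(cohort_records)
    else:
        flat = list(cohort_records)
        sample_list = (
            list(samples) if samples is not None else sorted({r.sample_id for r in flat})
        )
    if not sample_list:
        raise ValueError("no samples")

    counts = pd.DataFrame(0, index=pd.Index(sample_list, name="sample_id"), columns=labels)
    if flat:
        df = _records_frame(flat)
        df = df[df["sample_id"].isin(set(sample_list))].reset_index(drop=True)
        sample_codes = pd.Categorical(df["sample_id"], categories=sample_list).codes
        for method in methods:
            pol = method.policy
            mask = df["variant_class"].isin(pol.variant_classes).to_numpy()
            mask &= df["consequence"].isin(pol.counted_consequences).to_numpy()
            region_ok = np.zeros(len(df), dtype=bool)
            for chrom, sub in df.groupby("chrom", sort=False):
                region_ok[sub.index.to_numpy()] = pol.region.contains_many(
                    chrom, sub["anchor0"].to_numpy()
                )
            mask &= region_ok
            per_sample = np.bincount(sample_codes[mask], minlength=len(sample_list))
            counts[method.label] = per_sample

    fp_mb = {m.label: m.footprint.total_mb for m in methods}
    for label, mb in fp_mb.items():
        if mb <= 0:
            raise ValueError(f"footprint for method {label!r} has zero size")
    tmb = counts.astype(float) / pd.Series(fp_mb)
    return TMBMatrix(tmb=tmb, counts=counts, footprint_mb=fp_mb)
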
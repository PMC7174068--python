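"""Pre-registered in-silico study designs built from the pipeline stages.

Each function runs one complete experiment end to end — simulate a cohort,
count variants under the relevant policies, and compute the comparison
statistic — and returns plain dictionaries of results.  They are what the
reproduction script and the acceptance-style tests execute; problem sizes
are chosen so each experiment runs in seconds to a couple of minutes on a
single core.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd

from .concordance import deming_fit, pearson
from .genome_model import exome_footprint, panel_footprint
from .survival import assign_quartiles, cox_quartile_hr
from .synthetic_data import (
    SimulationConfig,
    TumorTypeSpec,
    simulate_cohort,
    simulate_genome,
    simulate_survival,
)
from .tmb import TMBMethod, tmb_matrix
from .variant_processing import InclusionPolicy

__all__ = [
    "synonymous_toggle_experiment",
    "panel_concordance_experiment",
    "multiplier_recovery_experiment",
    "hr_direction_experiment",
    "cox_coverage_experiment",
]


def synonymous_toggle_experiment(
    seed: int, n_samples: int = 500, n_genes: int = 4000
) -> dict:
    """Impact of counting synonymous variants on whole-exome TMB.

    Simulates tumors whose coding-SNV counts are log-uniform between 10 and
    10,000, with consequences drawn mechanistically from the standard
    genetic code, then Deming-regresses all-coding WES TMB (y) on
    non-synonymous WES TMB (x).  The slope estimates 1/(1 - f_syn), the
    reciprocal non-synonymous fraction of the code.
    """
    base = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        n_samples=n_samples,
        panels=(),
        consequence_model="genetic_code",
        indel_fraction=0.0,
    )
    genome = simulate_genome(base)
    f_mb = genome.total_mb
    cfg = replace(base, tumor_types=(TumorTypeSpec("PAN", 10.0 / f_mb, 10_000.0 / f_mb),))
    cohort = simulate_cohort(cfg, genome)
    wes = exome_footprint(genome.gene_models)
    matrix = tmb_matrix(
        cohort.records,
        [
            TMBMethod("WES.allcoding", InclusionPolicy(region=wes, include_synonymous=True)),
            TMBMethod("WES.nonsyn", InclusionPolicy(region=wes, include_synonymous=False)),
        ],
        samples=cohort.samples,
    )
    x = matrix.tmb["WES.nonsyn"].to_numpy()
    y = matrix.tmb["WES.allcoding"].to_numpy()
    fit = deming_fit(x, y, lam=1.0)
    return {
        "slope": fit.slope,
        "slope_ci": fit.slope_ci,
        "intercept": fit.intercept,
        "pearson_r": fit.pearson_r,
        "n": n_samples,
        "tmb": matrix.tmb,
    }


def panel_concordance_experiment(
    seed: int, n_samples: int = 500, n_genes: int = 20_000
) -> dict:
    """Panel-vs-WES and panel-vs-panel TMB agreement at uniform mutation rate.

    A 20,000-gene exome carries six panels (170-596 genes, drawn with
    partial overlap from a shared cancer-gene pool); per-tumor rates are
    log-uniform over 0.5-100 /Mb.  All TMB methods use the non-synonymous
    policy.  Deming fits between panels orient the larger-footprint panel
    as x.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        n_samples=n_samples,
        tumor_types=(TumorTypeSpec("PAN", 0.5, 100.0),),
    )
    genome = simulate_genome(cfg)
    cohort = simulate_cohort(cfg, genome)
    wes = exome_footprint(genome.gene_models)
    fps = {p.name: panel_footprint(p, genome.gene_models) for p in genome.panels}
    methods = [TMBMethod("WES", InclusionPolicy(region=wes))] + [
        TMBMethod(name, InclusionPolicy(region=fp)) for name, fp in fps.items()
    ]
    matrix = tmb_matrix(cohort.records, methods, samples=cohort.samples)

    panel_names = [p.name for p in genome.panels]
    stmp_wes_r = pearson(matrix.tmb["WES"].to_numpy(), matrix.tmb["STMP"].to_numpy())
    stmp_wes_slope = deming_fit(
        matrix.tmb["WES"].to_numpy(), matrix.tmb["STMP"].to_numpy(), ci=False
    ).slope

    pair_rows = []
    for a, b in itertools.combinations(panel_names, 2):
        xm, ym = (a, b) if fps[a].total_mb >= fps[b].total_mb else (b, a)
        fit = deming_fit(matrix.tmb[xm].to_numpy(), matrix.tmb[ym].to_numpy(), ci=False)
        pair_rows.append(
            {"x_method": xm, "y_method": ym, "slope": fit.slope, "pearson_r": fit.pearson_r}
        )
    pairs = pd.DataFrame(pair_rows)
    return {
        "stmp_wes_r": stmp_wes_r,
        "stmp_wes_slope": stmp_wes_slope,
        "min_panel_pair_r": float(pairs["pearson_r"].min()),
        "min_panel_pair_slope": float(pairs["slope"].min()),
        "pairs": pairs,
        "n": n_samples,
        "tmb": matrix.tmb,
        "footprints": {**{n: fp.total_mb for n, fp in fps.items()}, "WES": wes.total_mb},
    }


def multiplier_recovery_experiment(
    seed: int, multiplier: float, n_samples: int = 500, n_genes: int = 8000
) -> float:
    """Recover a panel-region mutation-rate multiplier as a Deming slope.

    Panel genes mutate at ``multiplier`` times the exome-wide per-base rate;
    the panel-vs-WES (non-synonymous) Deming slope estimates the multiplier,
    reproducing the mechanism by which a panel sampling atypically mutating
    regions yields proportionally biased TMB.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        n_samples=n_samples,
        tumor_types=(TumorTypeSpec("PAN", 0.5, 100.0),),
        rate_multipliers={"STMP": multiplier},
    )
    genome = simulate_genome(cfg)
    cohort = simulate_cohort(cfg, genome)
    wes = exome_footprint(genome.gene_models)
    stmp = panel_footprint(next(p for p in genome.panels if p.name == "STMP"), genome.gene_models)
    matrix = tmb_matrix(
        cohort.records,
        [
            TMBMethod("WES", InclusionPolicy(region=wes)),
            TMBMethod("STMP", InclusionPolicy(region=stmp)),
        ],
        samples=cohort.samples,
    )
    return deming_fit(matrix.tmb["WES"].to_numpy(), matrix.tmb["STMP"].to_numpy(), ci=False).slope


def hr_direction_experiment(
    seed: int, n_samples: int = 400, n_genes: int = 8000, beta_logtmb: float = 0.35
) -> dict[str, float]:
    """Q4-vs-Q1 hazard ratio per TMB method on one survival cohort.

    Survival depends on the tumor's true mutation rate through
    ``beta_logtmb``; returns the fitted pan-cohort Q4-vs-Q1 HR for WES and
    each of the six panels (seven methods), to check that every counting
    method recovers the same direction of the TMB-survival association.
    """
    cfg = SimulationConfig(
        seed=seed, n_genes=n_genes, n_samples=n_samples, beta_logtmb=beta_logtmb
    )
    genome = simulate_genome(cfg)
    cohort = simulate_cohort(cfg, genome)
    clinical = simulate_survival(cfg, cohort.rate_per_mb, cohort.tumor_type)
    wes = exome_footprint(genome.gene_models)
    methods = [TMBMethod("WES", InclusionPolicy(region=wes))] + [
        TMBMethod(p.name, InclusionPolicy(region=panel_footprint(p, genome.gene_models)))
        for p in genome.panels
    ]
    matrix = tmb_matrix(cohort.records, methods, samples=cohort.samples)
    out: dict[str, float] = {}
    for label in matrix.methods:
        qa = assign_quartiles(matrix.tmb[label], clinical, mode="pan_cohort")
        res = {r.contrast: r for r in cox_quartile_hr(clinical, qa)}
        out[label] = res["Q4 vs Q1"].hr
    return out


def cox_coverage_experiment(
    seed: int,
    n_reps: int = 200,
    n: int = 800,
    beta_step: float = 0.3,
    baseline_hazard: float = 1e-3,
    censor_rate: float = 8e-4,
) -> float:
    """Wald-CI coverage of the Cox quartile model under a known hazard.

    Each replicate draws ``n`` subjects in four equal quartile groups with
    exponential survival (log-hazard ``beta_step`` per quartile step) and
    independent exponential censoring, fits the quartile model, and checks
    whether the Q4-vs-Q1 95% CI covers the true HR exp(3*beta_step).
    Returns the covered fraction.
    """
    rng = np.random.default_rng([seed, 3])
    true_hr = float(np.exp(3 * beta_step))
    covered = 0
    ids = [f"S{i}" for i in range(n)]
    for _ in range(n_reps):
        tmb_vals = rng.lognormal(1.5, 1.0, n)
        clinical = pd.DataFrame({"sample_id": ids, "tumor_type": "X"})
        qa = assign_quartiles(pd.Series(tmb_vals, index=ids), clinical)
        step = qa.groups.map({"Q1": 0, "Q2": 1, "Q3": 2, "Q4": 3}).loc[ids].to_numpy()
        hazard = baseline_hazard * np.exp(beta_step * step)
        t_event = rng.exponential(1 / hazard)
        t_cens = rng.exponential(1 / censor_rate, n)
        clinical["os_days"] = np.minimum(t_event, t_cens)
        clinical["event"] = (t_event <= t_cens).astype(int)
        res = {r.contrast: r for r in cox_quartile_hr(clinical, qa)}
        r4 = res["Q4 vs Q1"]
        if r4.ci_low <= true_hr <= r4.ci_high:
            covered += 1
    return covered / n_reps
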
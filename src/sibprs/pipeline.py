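"""End-to-end study drivers: simulate -> train -> score -> validate -> report.

Two studies are provided.  The case/control study produces the sibling and
random-pair call-rate tables, high-risk identification tables, the swept
high-risk curve, prevalence-versus-threshold curves (general and ASP
cohorts, with the two-Gaussian prediction), and the all-vs-ASP AUC table.
The quantitative study produces pairwise-difference correlations,
rank-order call fractions, and gap-thresholded rank calling.  All outputs
are plain CSV tables with a seed/config-hash provenance header plus a JSON
run summary.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohorts, validate_cc, validate_qt
from .datatypes import SimConfig
from .io import config_hash, write_table
from .simulate import Cohort, simulate_cohort
from .train import PredictorEnsemble, ScoreTable, TrainConfig, compute_scores, train_ensemble

logger = logging.getLogger("sibprs")

__all__ = ["ValidationConfig", "RunConfig", "run_case_control_study", "run_quantitative_study", "save_study", "run_pipeline"]


@dataclass
class ValidationConfig:
    """Grids and thresholds of the validation battery.

    Defaults: high-risk thresholds +1.5/+2.0/+2.5 SD with normal risk
    < +1 SD; sweep from +1 to +3 SD in 0.1 steps; prevalence thresholds
    from -3 to +3 SD in 0.25 steps; phenotype-gap thresholds 0.5/1.0/1.5 SD.
    """

    hi_thresholds: tuple = (1.5, 2.0, 2.5)
    normal_z: float = 1.0
    sweep_lo: float = 1.0
    sweep_hi: float = 3.0
    sweep_step: float = 0.1
    prev_lo: float = -3.0
    prev_hi: float = 3.0
    prev_step: float = 0.25
    gap_thresholds: tuple = (0.5, 1.0, 1.5)
    gap_grid_hi: float = 2.0
    gap_grid_step: float = 0.1

    def sweep_grid(self) -> np.ndarray:
        return np.round(np.arange(self.sweep_lo, self.sweep_hi + 1e-9, self.sweep_step), 10)

    def prevalence_grid(self) -> np.ndarray:
        return np.round(np.arange(self.prev_lo, self.prev_hi + 1e-9, self.prev_step), 10)

    def gap_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, self.gap_grid_hi + 1e-9, self.gap_grid_step), 10)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, a single seeded unit."""

    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    val: ValidationConfig = field(default_factory=ValidationConfig)
    out_dir: str = "results/run"
    seed: int = 0


def _frac_row(label: str, f) -> dict:
    if f is None:
        return {
            "cohort": label, "n": 0, "fraction": np.nan, "ensemble_sd": np.nan,
            "wald_sd": np.nan, "cp_halfwidth": np.nan, "combined_err": np.nan,
            "low_stats": True,
        }
    return {
        "cohort": label,
        "n": f.n,
        "fraction": f.fraction,
        "ensemble_sd": f.ensemble_sd,
        "wald_sd": f.wald_sd,
        "cp_halfwidth": f.sampling_err,
        "combined_err": f.combined_err,
        "low_stats": f.low_stats,
    }


def run_case_control_study(
    cohort: Cohort,
    val: ValidationConfig | None = None,
    train_cfg: TrainConfig | None = None,
    ensemble: PredictorEnsemble | None = None,
    seed: int = 0,
):
    """Run the full case/control validation battery on one cohort.

    Returns ``(tables, scores, ensemble)`` where ``tables`` maps file stems
    (table1, table2, table3, table4, fig2_curve, prevalence_*) to
    DataFrames plus a ``summary`` dict.
    """
    val = val or ValidationConfig()
    t0 = time.time()
    if ensemble is None:
        train_cfg = train_cfg or TrainConfig()
        ensemble = train_ensemble(cohort.genotypes, cohort.phenotypes, cohort.pedigree, "binary", train_cfg)
    sib_ids = cohort.pedigree.sib_ids()
    if len(sib_ids) == 0:
        raise ValueError("cohort has no sibling pairs to validate on")
    scores_all = compute_scores(cohort.genotypes, ensemble, reference_ids=sib_ids)
    scores = scores_all.subset(sib_ids)
    status = cohort.phenotypes.values
    z = scores.ensemble_mean()

    sib_pairs = cohorts.extract_sib_pairs(cohort.pedigree)
    sc_pairs = cohorts.single_case_pairs(sib_pairs, status)
    if sc_pairs.empty:
        raise ValueError("no status-discordant sibling pairs")
    family_of = cohort.pedigree.family_of(sib_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    rand_pairs = cohorts.random_pairs(sib_ids, status, len(sc_pairs), rng, family_of)

    # Table 1: call rates on all discordant pairs
    table1 = pd.DataFrame(
        [
            _frac_row("sibling", validate_cc.sibling_call_rate(sc_pairs, scores)),
            _frac_row("random", validate_cc.sibling_call_rate(rand_pairs, scores)),
        ]
    )

    # Tables 2-3: high-risk outlier identification
    def _hi_table(pairs):
        rows = []
        for t in val.hi_thresholds:
            sub = cohorts.highrisk_normal_pairs(pairs, z, hi_z=t, normal_z=val.normal_z)
            r = _frac_row(f"hi_z={t}", validate_cc.highrisk_call_rate(sub))
            r["hi_z"] = t
            r["n"] = len(sub)
            rows.append(r)
        return pd.DataFrame(rows)

    table2 = _hi_table(sc_pairs)
    table3 = _hi_table(rand_pairs)

    # Fig 2: swept threshold, sibling vs random
    sweep_s = validate_cc.threshold_sweep(sc_pairs, scores, val.sweep_grid(), val.normal_z)
    sweep_s["kind"] = "sibling"
    sweep_r = validate_cc.threshold_sweep(rand_pairs, scores, val.sweep_grid(), val.normal_z)
    sweep_r["kind"] = "random"
    fig2 = pd.concat([sweep_s, sweep_r], ignore_index=True)

    # Table 4: AUC all vs ASP
    table4 = validate_cc.auc_report(scores, status, cohort.pedigree)

    # Prevalence curves, general + ASP, both directions, with mixture overlay
    prev_tables = {}
    grid = val.prevalence_grid()
    mix = validate_cc.estimate_mixture(z, status)
    for direction in ("below", "above"):
        cur = validate_cc.prevalence_by_threshold(z, status, grid, direction)
        pred = validate_cc.gaussian_mixture_prevalence(mix, grid, direction)
        cur = cur.merge(pred, on="threshold")
        cur["overall_prevalence"] = cur.attrs.get("overall_prevalence", np.nan)
        prev_tables[f"prevalence_all_{direction}"] = cur
        asp = validate_cc.asp_prevalence(z, status, cohort.pedigree, grid, direction)
        asp["overall_prevalence"] = asp.attrs.get("overall_prevalence", np.nan)
        prev_tables[f"prevalence_asp_{direction}"] = asp

    tables = {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "table4": table4,
        "fig2_curve": fig2,
        **prev_tables,
    }

    trios = cohorts.extract_trios(cohort.pedigree)
    if not trios.empty:
        tr = validate_cc.trio_call_rate(trios, scores, status)
        tables["trio_call"] = pd.DataFrame([_frac_row("sibling_trios", tr)])

    summary = {
        "trait": cohort.phenotypes.trait,
        "trait_kind": "binary",
        "n_sib_test": int(len(sib_ids)),
        "n_single_case_pairs": int(len(sc_pairs)),
        "prevalence_sib": float(status.reindex(sib_ids).mean()),
        "validation_metric_mean": ensemble.metric_mean,
        "validation_metric_sd": ensemble.metric_sd,
        "auc_all": float(table4.loc[table4["cohort"] == "all", "auc"].iloc[0]),
        "auc_asp": float(table4.loc[table4["cohort"] == "asp", "auc"].iloc[0]),
        "seconds": round(time.time() - t0, 2),
    }
    tables["summary"] = summary
    logger.info("case/control study done in %.1fs", summary["seconds"])
    return tables, scores, ensemble


def run_quantitative_study(
    cohort: Cohort,
    val: ValidationConfig | None = None,
    train_cfg: TrainConfig | None = None,
    ensemble: PredictorEnsemble | None = None,
    seed: int = 0,
):
    """Run the quantitative-trait validation battery on one cohort."""
    val = val or ValidationConfig()
    t0 = time.time()
    if ensemble is None:
        train_cfg = train_cfg or TrainConfig()
        ensemble = train_ensemble(
            cohort.genotypes, cohort.phenotypes, cohort.pedigree, "quantitative", train_cfg
        )
    sib_ids = cohort.pedigree.sib_ids()
    if len(sib_ids) == 0:
        raise ValueError("cohort has no sibling pairs to validate on")
    scores_all = compute_scores(cohort.genotypes, ensemble, reference_ids=sib_ids)
    scores = scores_all.subset(sib_ids)
    phen = cohort.phenotypes

    sib_pairs = cohorts.extract_sib_pairs(cohort.pedigree)
    family_of = cohort.pedigree.family_of(sib_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    rand_pairs = cohorts.random_pairs_quantitative(sib_ids, len(sib_pairs), rng, family_of)
    order_rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))

    diff_s = validate_qt.pair_differences(sib_pairs, scores, phen, rng=order_rng)
    diff_r = validate_qt.pair_differences(rand_pairs, scores, phen, rng=order_rng)
    table5 = pd.DataFrame(
        [
            {
                "cohort": "sibling", "n_pairs": diff_s.n_pairs,
                "rho": diff_s.rho_mean, "ensemble_sd": diff_s.rho_sd,
            },
            {
                "cohort": "random", "n_pairs": diff_r.n_pairs,
                "rho": diff_r.rho_mean, "ensemble_sd": diff_r.rho_sd,
            },
        ]
    )

    rc_s = validate_qt.rank_call_fraction(sib_pairs, scores, phen, rng=np.random.default_rng(np.random.SeedSequence([seed, 13])))
    rc_r = validate_qt.rank_call_fraction(rand_pairs, scores, phen, rng=np.random.default_rng(np.random.SeedSequence([seed, 13])))
    table6 = pd.DataFrame([_frac_row("sibling", rc_s), _frac_row("random", rc_r)])

    gaps = list(val.gap_thresholds)
    table7 = validate_qt.rank_call_by_gap(sib_pairs, scores, phen, gaps, rng=np.random.default_rng(np.random.SeedSequence([seed, 13])))
    table8 = validate_qt.rank_call_by_gap(rand_pairs, scores, phen, gaps, rng=np.random.default_rng(np.random.SeedSequence([seed, 13])))
    g8 = validate_qt.rank_call_by_gap(sib_pairs, scores, phen, val.gap_grid(), rng=np.random.default_rng(np.random.SeedSequence([seed, 13])))
    g8["kind"] = "sibling"
    g8r = validate_qt.rank_call_by_gap(rand_pairs, scores, phen, val.gap_grid(), rng=np.random.default_rng(np.random.SeedSequence([seed, 13])))
    g8r["kind"] = "random"
    fig8 = pd.concat([g8, g8r], ignore_index=True)

    tables = {
        "table5": table5,
        "table6": table6,
        "table7": table7,
        "table8": table8,
        "fig8_curve": fig8,
    }

    trios = cohorts.extract_trios(cohort.pedigree)
    if not trios.empty:
        tables["trio_rank"] = pd.DataFrame(
            [_frac_row("sibling_trios", validate_qt.trio_rank_call(trios, scores, phen))]
        )

    summary = {
        "trait": phen.trait,
        "trait_kind": "quantitative",
        "n_sib_test": int(len(sib_ids)),
        "n_sib_pairs": int(len(sib_pairs)),
        "validation_metric_mean": ensemble.metric_mean,
        "validation_metric_sd": ensemble.metric_sd,
        "rho_sibling": diff_s.rho_mean,
        "rho_random": diff_r.rho_mean,
        "rank_call_sibling": rc_s.fraction,
        "rank_call_random": rc_r.fraction,
        "seconds": round(time.time() - t0, 2),
    }
    tables["summary"] = summary
    logger.info("quantitative study done in %.1fs", summary["seconds"])
    return tables, scores, ensemble


def save_study(tables: dict, out_dir, seed: int, cfg) -> None:
    """Write every table as commented CSV plus summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    for name, obj in tables.items():
        if name == "summary":
            payload = dict(obj)
            payload["seed"] = seed
            payload["config_hash"] = h
            (out / "summary.json").write_text(json.dumps(payload, indent=1, default=float))
        else:
            write_table(obj, out / f"{name}.csv", seed, h)


def run_pipeline(config: RunConfig):
    """simulate -> train -> score -> validate -> write; returns the tables.

    The study kind follows ``config.sim.trait_kind``.  Deterministic for a
    fixed config: the same seed reproduces every CSV byte for byte.
    """
    logger.info("simulating cohort (%s)", config.sim.trait_kind)
    cohort = simulate_cohort(config.sim)
    runner = run_case_control_study if config.sim.trait_kind == "binary" else run_quantitative_study
    try:
        tables, scores, ensemble = runner(
            cohort, val=config.val, train_cfg=config.train, seed=config.seed
        )
    except ValueError as e:
        raise ValueError(f"validation stage failed: {e}") from e
    save_study(tables, config.out_dir, config.seed, asdict(config.sim))
    return tables, scores, ensemble, cohort
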
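"""Simulate -> fit -> compare workflow over a whole cohort.

Mirrors the two-stage design of the study: secretion parameters are
first estimated per subject from the raw concentration profiles, then
only the fitted parameters and the clinical covariates enter the
statistical stage (the compare stage never reads raw concentrations).
Subjects whose secretion curve is not bell-shaped are excluded from all
statistics, with the exclusion reason recorded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cst
from . import fitting, simulate

log = logging.getLogger("melrhythm")

__all__ = [
    "PipelineConfig",
    "CohortReport",
    "load_config",
    "run_fit_stage",
    "run_compare_stage",
    "run_end_to_end",
]

PARAM_NAMES = ("b1", "b2", "b3", "b4", "b_max")
LOGIT_PREDICTORS = ("b1", "b2", "b3", "b4")  # b_max excluded: collinear by definition
EG_FEATURES = (
    "age",
    "iq_quotient",
    "avg_seizures_per_day",
    "seizures_day_before",
    "seizures_sampling_day",
    "n_aeds",
    "disease_duration",
    "hours_since_last_seizure",
)
CG_FEATURES = ("age", "iq_quotient")
BINARY_OUTCOMES = ("sleep_disorder", "sleep_associated_seizures", "generalized_seizures")


@dataclass(frozen=True)
class PipelineConfig:
    generator: simulate.GeneratorConfig = field(default_factory=simulate.GeneratorConfig)
    max_iter: int = 200
    tol: float = 1e-10
    holm: bool = False  # optional family-wise adjustment of report p-values


@dataclass(frozen=True)
class CohortReport:
    group_comparisons: list
    correlations_eg: list
    correlations_cg: list
    logit_summaries: list
    exclusions: list  # (subject_id, reason)
    fit_quality_summary: dict


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; all keys optional, defaults embedded."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = dict(raw.get("generator", {}))
    for key, cls in (("eg", simulate.GroupParams), ("cg", simulate.GroupParams),
                     ("effects", simulate.CovariateEffects)):
        if key in gen_raw and isinstance(gen_raw[key], dict):
            gen_raw[key] = cls(**gen_raw[key])
    if "sampling_times" in gen_raw:
        gen_raw["sampling_times"] = tuple(gen_raw["sampling_times"])
    gen = simulate.GeneratorConfig(**gen_raw)
    fit_raw = raw.get("fitter", {})
    stats_raw = raw.get("stats", {})
    return PipelineConfig(
        generator=gen,
        max_iter=int(fit_raw.get("max_iter", 200)),
        tol=float(fit_raw.get("tol", 1e-10)),
        holm=bool(stats_raw.get("holm", False)),
    )


def run_fit_stage(profiles_path, output_path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Fit every subject in a profile table; write one diagnostics row each."""
    config = config or PipelineConfig()
    profiles = fitting.read_profiles(profiles_path)
    fits = []
    for prof in profiles:
        res = fitting.fit_profile(prof, max_iter=config.max_iter, tol=config.tol)
        log.info(
            "fit %s: converged=%s iter=%d ev=%.4f bell=%s",
            prof.subject_id, res.converged, res.n_iterations,
            res.explained_variance, res.bell_shaped,
        )
        fits.append(res)
    frame = fitting.fits_to_frame(fits)
    if output_path is not None:
        frame.to_csv(output_path, index=False)
    return frame


def _correlation_block(df: pd.DataFrame, features) -> list:
    entries = []
    for feat in features:
        for par in PARAM_NAMES:
            x = df[feat].to_numpy(dtype=float)
            y = df[par].to_numpy(dtype=float)
            try:
                rho, p = cst.spearman_rho(x, y)
            except ValueError as err:  # constant covariate in a small group
                log.warning("correlation %s vs %s undefined: %s", feat, par, err)
                rho, p = float("nan"), float("nan")
            entries.append(cst.CorrelationEntry(feat, par, rho, p, len(df)))
    return entries


def run_compare_stage(fits_path, clinical_path, output_dir, config: PipelineConfig | None = None) -> CohortReport:
    """Group comparison, correlation screens and logit regressions.

    Reads the fitted-parameter and clinical tables, drops non-bell-shaped
    subjects, and emits the three report tables plus logit summaries.
    Disease-associated covariates are analyzed for the EG group only;
    the derived maximum concentration is excluded from the logit
    predictors because it is the sum of baseline and amplitude.
    """
    config = config or PipelineConfig()
    fits = pd.read_csv(fits_path)
    clin = pd.read_csv(clinical_path)
    orphan_fits = sorted(set(fits["subject_id"]) - set(clin["subject_id"]))
    orphan_clin = sorted(set(clin["subject_id"]) - set(fits["subject_id"]))
    if orphan_fits or orphan_clin:
        raise ValueError(
            "subject id mismatch between fit and clinical tables; "
            f"fits-only={orphan_fits}, clinical-only={orphan_clin}"
        )
    df = fits.merge(clin, on="subject_id", validate="one_to_one")

    exclusions = [
        (row.subject_id, "not bell shaped")
        for row in df.itertuples()
        if not row.bell_shaped
    ]
    analyzed = df[df["bell_shaped"].astype(bool)].copy()
    log.info("compare stage: %d analyzed, %d excluded", len(analyzed), len(exclusions))

    eg = analyzed[analyzed["group"] == "EG"]
    cg = analyzed[analyzed["group"] == "CG"]
    if min(len(eg), len(cg)) < 5:
        warnings.warn(
            "very small analyzed group; exact Mann-Whitney null enumeration "
            "engages once the combined sample size drops to 12",
            stacklevel=2,
        )

    comparisons = []
    for par in PARAM_NAMES:
        u, p, (med_eg, med_cg) = cst.mann_whitney_u(eg[par], cg[par])
        comparisons.append(cst.GroupComparison(par, med_eg, med_cg, u, p))

    corr_eg = _correlation_block(eg, EG_FEATURES)
    corr_cg = _correlation_block(cg, CG_FEATURES)

    logits = []
    for outcome in BINARY_OUTCOMES:
        if outcome not in eg.columns:
            continue
        y = eg[outcome].to_numpy(dtype=float)
        X = eg[list(LOGIT_PREDICTORS)].to_numpy(dtype=float)
        try:
            logits.append(cst.logit_fit(X, y, predictor_names=LOGIT_PREDICTORS, outcome_name=outcome))
        except ValueError as err:
            log.warning("logit %s skipped: %s", outcome, err)

    quality = {
        "n_input": int(len(df)),
        "n_analyzed": int(len(analyzed)),
        "n_excluded": int(len(exclusions)),
        "n_quality_pass": int(df["quality_pass"].astype(bool).sum()),
        "explained_variance_median": float(df["explained_variance"].median()),
        "explained_variance_q10": float(df["explained_variance"].quantile(0.10)),
    }

    report = CohortReport(comparisons, corr_eg, corr_cg, logits, exclusions, quality)
    if output_dir is not None:
        _write_report(report, Path(output_dir), holm=config.holm)
    return report


def _write_report(report: CohortReport, out: Path, holm: bool = False) -> None:
    out.mkdir(parents=True, exist_ok=True)
    grp = pd.DataFrame(
        [
            {
                "parameter": c.parameter_name,
                "median_eg": c.median_a,
                "median_cg": c.median_b,
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in report.group_comparisons
        ]
    )
    if holm and len(grp):
        grp["p_holm"] = cst.holm_adjust(grp["p_value"].to_numpy())
    grp.to_csv(out / "report_group.csv", index=False)

    for name, entries in (("report_corr_eg.csv", report.correlations_eg),
                          ("report_corr_cg.csv", report.correlations_cg)):
        corr = pd.DataFrame(
            [
                {
                    "feature": e.feature,
                    "parameter": e.parameter_name,
                    "rho": e.rho,
                    "p_value": e.p_value,
                    "n": e.n,
                    "significant": e.significant,
                }
                for e in entries
            ]
        )
        if holm and len(corr):
            corr["p_holm"] = cst.holm_adjust(corr["p_value"].to_numpy())
        corr.to_csv(out / name, index=False)

    rows = []
    for s in report.logit_summaries:
        if s.separation_detected or s.coefficients is None:
            rows.append({"outcome": s.outcome, "term": "", "coefficient": "",
                         "std_error": "", "p_value": "", "converged": s.converged,
                         "separation_detected": s.separation_detected, "n": s.n})
            continue
        for name, coef, se, p in zip(s.predictor_names, s.coefficients, s.standard_errors, s.p_values):
            rows.append({"outcome": s.outcome, "term": name, "coefficient": coef,
                         "std_error": se, "p_value": p, "converged": s.converged,
                         "separation_detected": False, "n": s.n})
    pd.DataFrame(rows).to_csv(out / "report_logit.csv", index=False)

    pd.DataFrame(report.exclusions, columns=["subject_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False
    )
    with open(out / "fit_quality_summary.json", "w") as fh:
        json.dump(report.fit_quality_summary, fh, indent=2)


def run_end_to_end(config, out_dir, seed: int | None = None) -> CohortReport:
    """simulate -> fit -> compare under a single seed, with a run manifest.

    ``config`` may be a :class:`PipelineConfig` or a path to a YAML file;
    ``seed`` overrides the generator seed when given.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    if seed is not None:
        config = dataclasses.replace(
            config, generator=dataclasses.replace(config.generator, seed=int(seed))
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        profiles, records, _ = simulate.generate_cohort(config.generator)
        paths = simulate.write_cohort(profiles, records, config.generator, out)
    except Exception as err:
        raise RuntimeError(f"simulate stage failed: {err}") from err
    try:
        run_fit_stage(paths["profiles"], out / "fits.csv", config)
    except Exception as err:
        raise RuntimeError(f"fit stage failed: {err}") from err
    try:
        report = run_compare_stage(out / "fits.csv", paths["clinical"], out, config)
    except Exception as err:
        raise RuntimeError(f"compare stage failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "generator": config.generator.to_dict(),
                "fitter": {"max_iter": config.max_iter, "tol": config.tol},
                "stats": {"holm": config.holm},
            },
            fh,
            indent=2,
            default=str,
        )
    return report
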
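"""Synthetic cohort generator emulating the study design.

Builds an epilepsy group (EG) and a comparison group (CG) of children
with 3-hourly melatonin sampling over one day.  Each subject receives
secretion parameters drawn from group-specific distributions whose
central values sit at the observed group medians (baseline ~6 pg/mL,
amplitudes ~118 vs ~143 pg/mL, peak times 2.39 vs 1.48 h, sleep duration
~7.2 h), and clinical covariates whose signed effects on the latent
parameters reproduce the direction of the reported feature-parameter
correlations: amplitude falls with age and disease duration and rises
with recent seizure load; the peak time is delayed by seizure frequency
and drug count in EG and by age in CG, and advanced by a long
seizure-free interval.  Baseline concentration, sleep duration and the
intellectual-development quotient carry no configured effects (null
rows).

Distributional choices: log-normal for the two concentration parameters
(positive, right-skewed), wrapped normal for the circular peak time, and
a truncated normal on (0, 12) for the width.  Measurement noise is
multiplicative Gaussian with a 5% coefficient of variation, a generic
immunoassay error scale, floored at zero.  A small fraction of EG
subjects can be generated with non-bell-shaped profiles (flat or
double-peaked) to exercise the downstream exclusion path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import SamplingProfile
from .model import SecretionParams, evaluate_model

__all__ = [
    "ClinicalRecord",
    "CovariateEffects",
    "GroupParams",
    "GeneratorConfig",
    "draw_subject_params",
    "synthesize_profile",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical covariates of one subject; seizure fields are EG-only."""

    subject_id: str
    group: str  # "EG" | "CG"
    age: float  # years
    iq_quotient: float
    avg_seizures_per_day: int | None = None
    seizures_day_before: int | None = None
    seizures_sampling_day: int | None = None
    n_aeds: int | None = None
    disease_duration: float | None = None  # months
    hours_since_last_seizure: float | None = None
    sleep_disorder: int = 0
    sleep_associated_seizures: int = 0
    generalized_seizures: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("EG", "CG"):
            raise ValueError(f"group must be 'EG' or 'CG', got {self.group!r}")
        eg_fields = (
            self.avg_seizures_per_day,
            self.seizures_day_before,
            self.seizures_sampling_day,
            self.n_aeds,
            self.disease_duration,
            self.hours_since_last_seizure,
        )
        if self.group == "CG" and any(v is not None for v in eg_fields):
            raise ValueError("CG records must leave seizure/AED/duration fields empty")
        if self.group == "EG" and any(v is None for v in eg_fields):
            raise ValueError("EG records require all seizure/AED/duration fields")


@dataclass(frozen=True)
class GroupParams:
    """Location/scale of the latent parameter distributions for one group."""

    b1_median: float
    b2_median: float
    b3_loc: float
    b4_loc: float
    b1_log_sd: float = 0.5
    b2_log_sd: float = 0.35
    b3_sd: float = 0.7
    b4_sd: float = 0.9


@dataclass(frozen=True)
class CovariateEffects:
    """Signed covariate coefficients on the latent parameter scales.

    Log-scale coefficients act on ln(b2); hour-scale coefficients act on
    the peak time b3.  Covariates enter centered at their generative
    means, so group medians are unchanged by the effects.
    """

    age_on_log_b2: float = -0.07  # both groups: amplitude falls with age
    age_on_b3_cg: float = 0.12  # CG only: later release with age
    seizures_per_day_on_log_b2: float = 0.17
    seizures_day_before_on_log_b2: float = 0.35
    seizures_sampling_day_on_log_b2: float = 0.35
    duration_on_log_b2: float = -0.003  # per month of disease
    hours_since_on_log_b2: float = -0.019
    seizures_per_day_on_b3: float = 0.40
    seizures_day_before_on_b3: float = 0.80
    seizures_sampling_day_on_b3: float = 0.85
    n_aeds_on_b3: float = 0.45
    hours_since_on_b3: float = -0.045


# covariate centers used when applying effects (generative means)
_CENTERS = {
    "age": 6.8,
    "avg_seizures_per_day": 2.0,
    "seizures_day_before": 1.25,
    "seizures_sampling_day": 1.2,
    "n_aeds": 2.0,
    "disease_duration": 105.5,
    "hours_since_last_seizure": 12.5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort structure, sampling design, noise and effect sizes."""

    n_eg: int = 52
    n_cg: int = 30
    sampling_times: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    noise_cv: float = 0.05
    seed: int = 0
    eg: GroupParams = field(
        default_factory=lambda: GroupParams(
            b1_median=5.9933, b2_median=117.9186, b3_loc=2.3851, b4_loc=7.2894
        )
    )
    cg: GroupParams = field(
        default_factory=lambda: GroupParams(
            b1_median=6.4645, b2_median=142.7516, b3_loc=1.4843, b4_loc=7.1835
        )
    )
    effects: CovariateEffects = field(default_factory=CovariateEffects)
    frac_non_bell: float = 0.05  # EG fraction given flat/double-peak profiles

    def __post_init__(self) -> None:
        if self.n_eg <= 0 or self.n_cg <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= self.frac_non_bell < 1:
            raise ValueError("frac_non_bell must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trunc_normal(rng: np.random.Generator, loc: float, sd: float, lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal; deterministic under a fixed rng."""
    for _ in range(1000):
        x = rng.normal(loc, sd)
        if lo < x < hi:
            return x
    return float(np.clip(loc, lo + 1e-6, hi - 1e-6))


def _draw_record(i: int, group: str, rng: np.random.Generator) -> ClinicalRecord:
    sid = f"{group}{i + 1:03d}"
    age = _trunc_normal(rng, _CENTERS["age"], 2.5, 1.0, 17.0)
    iq = round(_trunc_normal(rng, 90.0, 15.0, 40.0, 140.0))
    if group == "CG":
        return ClinicalRecord(sid, "CG", age, iq)
    return ClinicalRecord(
        sid,
        "EG",
        age,
        iq,
        avg_seizures_per_day=int(min(1 + rng.poisson(1.0), 9)),
        seizures_day_before=int(min(1 + rng.poisson(0.25), 3)),
        seizures_sampling_day=int(min(1 + rng.poisson(0.2), 3)),
        n_aeds=int(1 + rng.binomial(3, 1.0 / 3.0)),
        disease_duration=float(rng.integers(11, 201)),
        hours_since_last_seizure=float(
            np.clip(rng.lognormal(np.log(11.0), 0.7), 1.0, 42.0)
        ),
        sleep_disorder=int(rng.random() < 0.35),
        sleep_associated_seizures=int(rng.random() < 0.40),
        generalized_seizures=int(rng.random() < 0.50),
    )


def draw_subject_params(
    record: ClinicalRecord, config: GeneratorConfig, rng: np.random.Generator
) -> SecretionParams:
    """Draw one subject's secretion parameters from the group model.

    Log-normal baseline and amplitude, wrapped-normal peak time and
    truncated-normal width, with the configured linear covariate effects
    applied on the latent (log or hour) scale to centered covariates.
    """
    gp = config.eg if record.group == "EG" else config.cg
    eff = config.effects

    b1 = gp.b1_median * np.exp(rng.normal(0.0, gp.b1_log_sd))

    log_b2 = np.log(gp.b2_median) + rng.normal(0.0, gp.b2_log_sd)
    log_b2 += eff.age_on_log_b2 * (record.age - _CENTERS["age"])
    b3 = gp.b3_loc + rng.normal(0.0, gp.b3_sd)
    if record.group == "CG":
        b3 += eff.age_on_b3_cg * (record.age - _CENTERS["age"])
    else:
        log_b2 += eff.seizures_per_day_on_log_b2 * (
            record.avg_seizures_per_day - _CENTERS["avg_seizures_per_day"]
        )
        log_b2 += eff.seizures_day_before_on_log_b2 * (
            record.seizures_day_before - _CENTERS["seizures_day_before"]
        )
        log_b2 += eff.seizures_sampling_day_on_log_b2 * (
            record.seizures_sampling_day - _CENTERS["seizures_sampling_day"]
        )
        log_b2 += eff.duration_on_log_b2 * (
            record.disease_duration - _CENTERS["disease_duration"]
        )
        log_b2 += eff.hours_since_on_log_b2 * (
            record.hours_since_last_seizure - _CENTERS["hours_since_last_seizure"]
        )
        b3 += eff.seizures_per_day_on_b3 * (
            record.avg_seizures_per_day - _CENTERS["avg_seizures_per_day"]
        )
        b3 += eff.seizures_day_before_on_b3 * (
            record.seizures_day_before - _CENTERS["seizures_day_before"]
        )
        b3 += eff.seizures_sampling_day_on_b3 * (
            record.seizures_sampling_day - _CENTERS["seizures_sampling_day"]
        )
        b3 += eff.n_aeds_on_b3 * (record.n_aeds - _CENTERS["n_aeds"])
        b3 += eff.hours_since_on_b3 * (
            record.hours_since_last_seizure - _CENTERS["hours_since_last_seizure"]
        )
    b2 = float(np.exp(np.clip(log_b2, np.log(1e-3), np.log(1e4))))
    b4 = _trunc_normal(rng, gp.b4_loc, gp.b4_sd, 0.5, 11.5)
    return SecretionParams.wrapped(float(b1), b2, float(b3), float(b4))


def synthesize_profile(
    params: SecretionParams,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "S000",
    kind: str = "bell",
) -> SamplingProfile:
    """Sample a noisy profile from the model at the configured times.

    ``kind`` selects the curve family: ``"bell"`` (the secretion model),
    ``"flat"`` (amplitude suppressed to near the baseline) or
    ``"double"`` (two equal peaks 12 h apart), the latter two emulating
    physiologically disturbed, non-bell-shaped secretion.
    """
    t = np.asarray(config.sampling_times, dtype=float)
    if kind == "bell":
        clean = np.asarray(evaluate_model(params, t))
    elif kind == "flat":
        flat = SecretionParams(params.b1, 0.05 * max(params.b1, 1.0), params.b3, params.b4)
        clean = np.asarray(evaluate_model(flat, t))
    elif kind == "double":
        p1 = SecretionParams(params.b1, params.b2 / 2.0, params.b3, params.b4)
        p2 = SecretionParams.wrapped(0.0, params.b2 / 2.0, params.b3 + 12.0, params.b4)
        clean = np.asarray(evaluate_model(p1, t)) + np.asarray(evaluate_model(p2, t))
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    eps = rng.normal(0.0, config.noise_cv, size=len(t)) if config.noise_cv > 0 else 0.0
    noisy = np.maximum(clean * (1.0 + eps), 0.0)
    return SamplingProfile(subject_id=subject_id, times=t, concentrations=noisy)


def generate_cohort(config: GeneratorConfig):
    """Generate the full two-group cohort; reproducible from the seed.

    Returns ``(profiles, records, true_params)`` where ``true_params``
    maps subject id to the generating :class:`SecretionParams` (ground
    truth for recovery studies; not part of the observable data).
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[SamplingProfile] = []
    records: list[ClinicalRecord] = []
    truth: dict[str, SecretionParams] = {}
    n_non_bell = int(round(config.frac_non_bell * config.n_eg))
    for group, n in (("EG", config.n_eg), ("CG", config.n_cg)):
        for i in range(n):
            rec = _draw_record(i, group, rng)
            params = draw_subject_params(rec, config, rng)
            if group == "EG" and i < n_non_bell:
                kind = "flat" if i % 2 == 0 else "double"
            else:
                kind = "bell"
            prof = synthesize_profile(params, config, rng, subject_id=rec.subject_id, kind=kind)
            profiles.append(prof)
            records.append(rec)
            truth[rec.subject_id] = params
    return profiles, records, truth


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = [
        {"subject_id": p.subject_id, "time_h": t, "melatonin_pg_ml": c}
        for p in profiles
        for t, c in zip(p.times, p.concentrations)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "time_h", "melatonin_pg_ml"])


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_cohort(profiles, records, config: GeneratorConfig, out_dir) -> dict:
    """Write profiles.csv, clinical.csv and a manifest; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "clinical": out / "clinical.csv",
        "manifest": out / "manifest.json",
    }
    profiles_to_frame(profiles).to_csv(paths["profiles"], index=False, float_format="%.6f")
    records_to_frame(records).to_csv(paths["clinical"], index=False, float_format="%.4f")
    with open(paths["manifest"], "w") as fh:
        json.dump({"generator": config.to_dict()}, fh, indent=2, default=str)
    return paths
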
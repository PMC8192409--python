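"""Synthetic cohorts of runners for testing the estimation pipeline.

Each simulated runner has true parameters (CS, d') drawn from
truncated-at-zero normal distributions whose moments default to cohort
statistics typical of trained male runners (CS 4.39 +/- 0.41 m/s,
d' 226 +/- 57 m).  The incremental-test peak speed PS is anchored so
that the true time to exhaustion at 100% PS lands near the physiological
range (~6 min): PS = CS + d'/t100 with t100 drawn around 356 s.  This
guarantees every configured trial intensity (fractions of PS, default
90/100/110/120%) lies strictly above CS.

Observed times to exhaustion are heteroscedastic: Var(t) is proportional
to t, the noise law that motivates inverse-time WLS weights.  The
proportionality constant is parameterised so that ``noise_cv`` is the
coefficient of variation of the 100%-PS trial; variance at other
intensities follows from Var(t) = noise_cv**2 * t100 * t_true.  The
noise family is gamma by default (positive support), with a
moment-matched lognormal alternative.  Distances are always derived as
speed x observed time — speed itself carries no error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CSParameters, SubjectTrials, TrialObservation

__all__ = [
    "CohortConfig",
    "SimulatedSubject",
    "SimulatedCohort",
    "sample_subject",
    "generate_trials",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

_REQUIRED_COLUMNS = ("subject_id", "trial_index", "pct_ps", "time_s")
_TRUTH_COLUMNS = ("true_cs_mps", "true_dprime_m")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the reference protocol: 16 runners, four trials at
    90--120% of peak speed, times to exhaustion with Var(t) ~ t noise at
    a 5% coefficient of variation on the ~6-minute 100%-PS trial.
    """

    n_subjects: int = 16
    cs_mean: float = 4.39  # m/s
    cs_sd: float = 0.41
    dprime_mean: float = 226.0  # m
    dprime_sd: float = 57.0
    pct_ps: tuple[float, ...] = (0.9, 1.0, 1.1, 1.2)
    t100_mean: float = 356.0  # s, true time at 100% PS
    t100_sd: float = 72.0
    noise_cv: float = 0.05
    noise_family: str = "gamma"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need n_subjects >= 2")
        if min(self.cs_sd, self.dprime_sd, self.t100_sd) < 0 or self.noise_cv < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.noise_family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        if min(self.pct_ps) <= 0:
            raise ValueError("trial intensities must be positive fractions of PS")


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    params: CSParameters  # the generating truth
    peak_speed: float  # m/s
    t100: float  # s, true time to exhaustion at 100% PS


@dataclass(frozen=True)
class SimulatedCohort:
    subjects: tuple[SubjectTrials, ...]
    truth: pd.DataFrame  # subject_id, true_cs_mps, true_dprime_m, peak_speed_mps
    config: CohortConfig


def _trunc_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw redrawn until positive (degenerate sd=0 returns mean)."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate draw with non-positive mean")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("truncated-normal sampling failed to produce a positive draw")


def sample_subject(
    config: CohortConfig, rng: np.random.Generator, subject_id: str = "S00"
) -> SimulatedSubject:
    """Draw one runner's true (CS, d') and a feasible peak speed.

    PS is anchored via the 100%-PS time: PS = CS + d'/t100.  Draws for
    which any configured trial intensity would fall at or below CS are
    rejected and resampled (capped), so every generated trial has a
    finite true time to exhaustion.
    """
    min_pct = min(config.pct_ps)
    for _ in range(1000):
        cs = _trunc_positive_normal(rng, config.cs_mean, config.cs_sd)
        dp = _trunc_positive_normal(rng, config.dprime_mean, config.dprime_sd)
        t100 = _trunc_positive_normal(rng, config.t100_mean, config.t100_sd)
        ps = cs + dp / t100
        if min_pct * ps > cs:
            return SimulatedSubject(
                subject_id=subject_id,
                params=CSParameters(cs=cs, d_prime=dp),
                peak_speed=ps,
                t100=t100,
            )
    raise RuntimeError(
        "could not sample a subject whose trial speeds all exceed CS; "
        "check pct_ps and t100 configuration"
    )


def generate_trials(
    subject: SimulatedSubject, config: CohortConfig, rng: np.random.Generator
) -> SubjectTrials:
    """Simulate the subject's exhaustive trials at the configured %PS.

    True times follow the hyperbolic model; observed times are drawn
    with mean t_true and variance noise_cv**2 * t100 * t_true from the
    configured positive-support family.  noise_cv = 0 reproduces the
    true times exactly.
    """
    cs, dp = subject.params.cs, subject.params.d_prime
    c = config.noise_cv**2 * subject.t100  # Var(t) = c * t_true
    trials = []
    for pct in config.pct_ps:
        s = pct * subject.peak_speed
        if s <= cs:
            raise ValueError(
                f"trial intensity {pct:.0%} PS gives speed {s:.3f} <= CS {cs:.3f}"
            )
        t_true = dp / (s - cs)
        if c == 0:
            t_obs = t_true
        elif config.noise_family == "gamma":
            # shape*scale = t_true, shape*scale^2 = c*t_true
            t_obs = rng.gamma(shape=t_true / c, scale=c)
        else:  # lognormal, moment-matched
            sigma2 = np.log1p(c / t_true)
            mu = np.log(t_true) - sigma2 / 2.0
            t_obs = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
        trials.append(TrialObservation(speed=s, time_to_exhaustion=float(t_obs)))
    return SubjectTrials(
        subject_id=subject.subject_id,
        trials=tuple(trials),
        peak_speed=subject.peak_speed,
    )


def generate_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Generate a full cohort; all randomness flows from one generator."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    subjects, truth_rows = [], []
    width = max(2, len(str(config.n_subjects)))
    for i in range(config.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        subj = sample_subject(config, rng, subject_id=sid)
        subjects.append(generate_trials(subj, config, rng))
        truth_rows.append(
            {
                "subject_id": sid,
                "true_cs_mps": subj.params.cs,
                "true_dprime_m": subj.params.d_prime,
                "peak_speed_mps": subj.peak_speed,
            }
        )
    return SimulatedCohort(
        subjects=tuple(subjects), truth=pd.DataFrame(truth_rows), config=config
    )


def _cohort_frame(cohort: SimulatedCohort, include_truth: bool) -> pd.DataFrame:
    truth = cohort.truth.set_index("subject_id")
    rows = []
    for subj in cohort.subjects:
        ps = subj.peak_speed
        for j, tr in enumerate(subj.trials):
            row = {
                "subject_id": subj.subject_id,
                "trial_index": j,
                "pct_ps": tr.speed / ps if ps else np.nan,
                "speed_mps": tr.speed,
                "time_s": tr.time_to_exhaustion,
            }
            if include_truth:
                row["true_cs_mps"] = truth.loc[subj.subject_id, "true_cs_mps"]
                row["true_dprime_m"] = truth.loc[subj.subject_id, "true_dprime_m"]
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: SimulatedCohort, path, include_truth: bool = True) -> None:
    """Write a cohort to delimited text, full float precision.

    Truth columns (suffixed ``true_``) are only present for simulated
    data so that recovery tests can never leak into real-data workflows.
    """
    frame = _cohort_frame(cohort, include_truth)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> tuple[list[SubjectTrials], pd.DataFrame | None]:
    """Read a cohort table back into per-subject trial sets.

    Speeds are taken from a ``speed_mps`` column, or from ``speed_kmh``
    (converted) when only that is present.  Returns the subjects and, if
    truth columns exist, the truth table; ``None`` otherwise.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = set(frame.columns)
    missing = [c for c in _REQUIRED_COLUMNS if c not in cols]
    if "speed_mps" not in cols and "speed_kmh" not in cols:
        missing.append("speed_mps (or speed_kmh)")
    if missing:
        raise ValueError(f"cohort file {path}: missing columns {missing}")
    if "speed_mps" in cols:
        speeds = frame["speed_mps"].to_numpy(dtype=float)
    else:
        speeds = frame["speed_kmh"].to_numpy(dtype=float) / 3.6

    times = frame["time_s"].to_numpy(dtype=float)
    for i, (s, t) in enumerate(zip(speeds, times)):
        if not s > 0:
            raise ValueError(f"cohort file {path}: row {i}, column speed: {s} not > 0")
        if not t > 0:
            raise ValueError(f"cohort file {path}: row {i}, column time_s: {t} not > 0")

    subjects = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        idx = grp.index.to_numpy()
        order = np.argsort(grp["trial_index"].to_numpy())
        trs = tuple(
            TrialObservation(speed=float(speeds[i]), time_to_exhaustion=float(times[i]))
            for i in idx[order]
        )
        subjects.append(SubjectTrials(subject_id=str(sid), trials=trs))

    truth = None
    if all(c in cols for c in _TRUTH_COLUMNS):
        truth = (
            frame.groupby("subject_id", sort=False)[list(_TRUTH_COLUMNS)]
            .first()
            .reset_index()
        )
    return subjects, truth
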
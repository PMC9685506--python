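"""Multi-year synthetic inpatient cohort simulator.

Generates yearly cohorts of hospital encounters whose statistical
structure mimics the drift phenomena that degrade deployed clinical
prediction models: declining AKI prevalence, an aging population,
covariate shift (numeric feature means move year over year), concept
drift (the true risk coefficients rotate year over year), and
feature-space growth (labs that only start being recorded in later
years).  Every AKI encounter carries a serum-creatinine trajectory
constructed so that the KDIGO labeler recovers the designated maximum
stage at the designated onset day; the generator and labeler round-trip
by construction.

The outcome model is logistic: each encounter has a latent risk
``expit(a_y + beta_y . z + eps)`` where ``z`` collects standardized
encounter-level covariates, ``beta_y`` is the base coefficient vector
rotated by ``concept_drift_rate`` radians per elapsed year in
consecutive coordinate planes (so zero drift leaves it untouched and
the vector norm — hence the attainable discrimination — is preserved),
``eps`` is Gaussian residual noise, and the intercept ``a_y`` is solved
each year so the cohort-mean risk equals the scheduled prevalence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "AGE_BANDS",
    "CohortConfig",
    "DriftParams",
    "EncounterTimeline",
    "generate_cohort",
    "true_risk",
    "risk_coefficients",
    "write_cohort",
    "read_cohort",
    "study_config",
    "drift_scenario",
]

AGE_BANDS = ("18-25", "26-35", "36-45", "46-55", "56-65", ">65")

_SEXES = ("male", "female")
_RACES = (
    "american_indian",
    "asian",
    "african_american",
    "native_hawaiian",
    "white",
    "multiple",
    "other",
)
_RACE_PROBS = (0.004, 0.008, 0.153, 0.001, 0.729, 0.002, 0.103)

# Demographic table of the emulated eight-year study cohort: per year,
# encounter count, any-AKI fraction, and the age-band distribution.
_STUDY_YEARS = (2010, 2011, 2012, 2013, 2014, 2015, 2016, 2017)
_STUDY_N = {
    2010: 14946, 2011: 15422, 2012: 16682, 2013: 17450,
    2014: 18701, 2015: 20094, 2016: 20399, 2017: 18002,
}
_STUDY_PREV = {
    2010: 0.169, 2011: 0.161, 2012: 0.155, 2013: 0.133,
    2014: 0.136, 2015: 0.132, 2016: 0.134, 2017: 0.128,
}
_STUDY_AGE = {
    2010: (5.8, 8.6, 11.0, 20.2, 22.6, 31.7),
    2011: (5.7, 8.3, 11.2, 19.4, 23.7, 31.6),
    2012: (5.5, 8.7, 10.2, 19.2, 23.7, 32.6),
    2013: (5.3, 9.0, 10.7, 19.0, 23.8, 33.3),
    2014: (5.8, 9.7, 9.7, 16.8, 24.4, 34.1),
    2015: (5.4, 9.0, 10.6, 17.3, 24.4, 33.3),
    2016: (5.3, 8.9, 10.8, 16.0, 23.7, 35.3),
    2017: (5.6, 9.2, 10.7, 15.3, 22.7, 36.5),
}

_VITALS = ("sbp", "dbp", "hr")
_VITAL_LOC = {"sbp": 122.0, "dbp": 76.0, "hr": 82.0}
_VITAL_SCALE = {"sbp": 14.0, "dbp": 9.0, "hr": 11.0}

_LONG_COLUMNS = ("encounter_id", "year", "day", "kind", "code", "value")


@dataclass(frozen=True)
class DriftParams:
    """Rates of year-over-year distribution change.

    covariate_shift_rate
        Per-year displacement (in within-year standard deviations) of
        each numeric feature's latent mean, in a fixed per-feature
        direction.
    concept_drift_rate
        Per-year rotation angle (radians) applied to the true risk
        coefficient vector in consecutive coordinate planes.  Zero
        means the outcome-given-features relationship is stationary;
        pi/2 over one step makes the new coefficients orthogonal to the
        old (a complete concept change).
    noise_sd
        Standard deviation of the Gaussian residual added to the latent
        linear predictor.
    rerandomize_from_year
        If set, every year at or after this one uses a freshly drawn
        coefficient vector (same norm) instead of the rotated base
        vector — an abrupt, complete concept change, as opposed to the
        gradual rotation of ``concept_drift_rate``.
    """

    covariate_shift_rate: float = 0.0
    concept_drift_rate: float = 0.0
    noise_sd: float = 0.3
    rerandomize_from_year: int | None = None

    def __post_init__(self) -> None:
        for name in ("covariate_shift_rate", "concept_drift_rate", "noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a multi-year synthetic cohort."""

    years: tuple[int, ...]
    n_encounters_per_year: Mapping[int, int]
    prevalence_schedule: Mapping[int, float]
    demographic_schedule: Mapping[int, tuple[float, ...]]
    stage_mix: tuple[float, float, float] = (0.86, 0.08, 0.06)
    n_numeric_features: int = 12
    n_categorical_features: int = 3
    n_medications: int = 4
    feature_birth_year: Mapping[str, int] = field(default_factory=dict)
    drift: DriftParams = field(default_factory=DriftParams)
    los_mean: float = 6.0
    los_dispersion: float = 2.0
    rrt_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("years must be nonempty")
        for y in self.years:
            n = self.n_encounters_per_year.get(y)
            if n is None or n <= 0:
                raise ValueError(f"n_encounters_per_year missing/non-positive for {y}")
            p = self.prevalence_schedule.get(y)
            if p is None or not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {y} must lie strictly in (0,1)")
            dem = self.demographic_schedule.get(y)
            if dem is None or len(dem) != len(AGE_BANDS):
                raise ValueError(f"demographic_schedule for {y} needs {len(AGE_BANDS)} bands")
        if abs(sum(self.stage_mix) - 1.0) > 1e-6:
            raise ValueError("stage_mix must sum to 1")
        for feat, born in self.feature_birth_year.items():
            if born not in self.years:
                raise ValueError(f"birth year {born} of feature {feat!r} not in years")
        for n in (self.n_numeric_features, self.n_categorical_features, self.n_medications):
            if n < 0:
                raise ValueError("feature counts must be nonnegative")

    @property
    def numeric_codes(self) -> tuple[str, ...]:
        return tuple(f"lab_{i:02d}" for i in range(self.n_numeric_features))

    @property
    def categorical_codes(self) -> tuple[str, ...]:
        return tuple(f"dx_{i}" for i in range(self.n_categorical_features))

    @property
    def medication_codes(self) -> tuple[str, ...]:
        return tuple(f"med_{i}" for i in range(self.n_medications))


@dataclass
class EncounterTimeline:
    """One hospital encounter's per-day synthetic record."""

    encounter_id: str
    year: int
    los: int
    demographics: dict[str, str]
    numeric_obs: dict[str, tuple[tuple[int, float], ...]]
    categorical_obs: dict[str, tuple[tuple[int, str], ...]]
    medication_days: dict[str, tuple[int, ...]]
    scr_series: tuple[tuple[int, float], ...]
    rrt_days: frozenset[int]
    aki: bool
    designated_stage: int
    designated_onset: int | None
    latent: dict

    def to_records(self) -> pd.DataFrame:
        """Long-format clinical records (no simulator ground truth)."""
        rows: list[tuple] = []
        eid, yr = self.encounter_id, self.year
        for code, label in self.demographics.items():
            rows.append((eid, yr, 0, "demographic", code, label))
        for code, obs in self.numeric_obs.items():
            kind = "vital" if code in _VITALS else "lab"
            for day, val in obs:
                rows.append((eid, yr, day, kind, code, repr(float(val))))
        for day, val in self.scr_series:
            rows.append((eid, yr, day, "lab", "scr", repr(float(val))))
        for code, obs in self.categorical_obs.items():
            for day, cat in obs:
                rows.append((eid, yr, day, "diagnosis", code, cat))
        for code, days in self.medication_days.items():
            for day in days:
                rows.append((eid, yr, day, "medication", code, "1"))
        for day in sorted(self.rrt_days):
            rows.append((eid, yr, day, "procedure", "rrt", "1"))
        return pd.DataFrame(rows, columns=_LONG_COLUMNS)


# ---------------------------------------------------------------------------
# structural randomness (fixed per config, shared across years)


def _structure(config: CohortConfig) -> dict:
    rng = np.random.default_rng([config.seed, 1_000_003])
    n_num = config.n_numeric_features
    n_risk = min(10, n_num)
    struct = {
        "n_risk": n_risk,
        # display location/scale per lab (cosmetic, fixed over years)
        "lab_loc": rng.uniform(2.0, 150.0, size=n_num),
        "lab_scale": rng.uniform(0.5, 20.0, size=n_num),
        # unit direction of the per-year covariate mean shift
        "shift_sign": rng.choice([-1.0, 1.0], size=n_num),
        "cat_logits": rng.normal(0.0, 0.7, size=(config.n_categorical_features, 3)),
        "cat_shift_dir": rng.normal(0.0, 1.0, size=(config.n_categorical_features, 3)),
    }
    # base risk coefficients over [risk labs..., age, med_0 exposure]
    beta = rng.normal(0.0, 1.0, size=n_risk + 2)
    beta *= 1.6 / np.linalg.norm(beta)
    struct["beta_base"] = beta
    # independent same-norm vector used when a concept re-randomization
    # year is configured
    rng2 = np.random.default_rng([config.seed, 2_000_003])
    beta2 = rng2.normal(0.0, 1.0, size=n_risk + 2)
    beta2 *= 1.6 / np.linalg.norm(beta2)
    struct["beta_rerand"] = beta2
    return struct


def _rotate(beta: np.ndarray, angle: float) -> np.ndarray:
    """Rotate consecutive coordinate pairs of ``beta`` by ``angle``."""
    out = beta.astype(float).copy()
    c, s = math.cos(angle), math.sin(angle)
    for j in range(0, len(out) - 1, 2):
        a, b = out[j], out[j + 1]
        out[j], out[j + 1] = c * a - s * b, c * b + s * a
    return out


def _effective_beta(
    beta_base: np.ndarray,
    beta_rerand: np.ndarray,
    drift: DriftParams,
    year: int,
    year0: int,
) -> np.ndarray:
    if drift.rerandomize_from_year is not None and year >= drift.rerandomize_from_year:
        return np.asarray(beta_rerand, dtype=float)
    return _rotate(np.asarray(beta_base, dtype=float), drift.concept_drift_rate * (year - year0))


def risk_coefficients(config: CohortConfig, year: int) -> np.ndarray:
    """True risk coefficients in effect for ``year``."""
    if year not in config.years:
        raise ValueError(f"unknown year {year}")
    struct = _structure(config)
    return _effective_beta(
        struct["beta_base"], struct["beta_rerand"], config.drift, year, config.years[0]
    )


# ---------------------------------------------------------------------------
# SCr trajectory synthesis

#: ladder of intermediate baseline ratios passed through on the days
#: before a stage-2 or stage-3 onset, so lower stages onset first
_LADDER = {1: (), 2: (1.6,), 3: (1.6, 2.4)}
# drawn strictly inside each band so 4-decimal rounding of the stored
# values can never move a peak across a staging threshold
_PEAK_RATIO = {1: (1.55, 1.85), 2: (2.05, 2.85), 3: (3.05, 3.45)}


def _scr_trajectory(
    rng: np.random.Generator,
    baseline: float,
    los: int,
    stage: int,
    onset: int | None,
    rrt: bool,
) -> tuple[tuple[tuple[int, float], ...], frozenset[int]]:
    """SCr series (day, mg/dL) and RRT days for one encounter.

    Non-AKI series fluctuate within +-10% of baseline (with baseline
    <= 1.3 mg/dL the 48-hour rise stays below 0.3 and the ratio below
    1.5, so no KDIGO branch can fire).  AKI series climb a piecewise-
    linear ladder reaching the designated stage's ratio band exactly on
    the onset day, then decay.  RRT stage-3 encounters peak in the
    stage-2 band and qualify for stage 3 through the RRT day instead.
    """
    values = {0: baseline}
    safe = lambda: baseline * rng.uniform(0.9, 1.1)  # noqa: E731
    if stage == 0 or onset is None:
        for d in range(1, los + 1):
            values[d] = safe()
        return tuple(sorted((d, round(v, 4)) for d, v in values.items())), frozenset()

    ladder = _LADDER[stage]
    peak_ratio = (
        rng.uniform(2.05, 2.85) if (stage == 3 and rrt) else rng.uniform(*_PEAK_RATIO[stage])
    )
    rise_days = {onset: peak_ratio * baseline}
    for k, ratio in enumerate(reversed(ladder), start=1):
        if onset - k >= 1:
            rise_days[onset - k] = ratio * baseline
    for d in range(1, los + 1):
        if d in rise_days:
            values[d] = rise_days[d]
        elif d < onset:
            values[d] = safe()
        else:  # post-onset: linear decay toward baseline over ~5 days
            frac = max(0.0, 1.0 - (d - onset) / 5.0)
            values[d] = baseline + frac * (peak_ratio - 1.0) * baseline
    rrt_days = frozenset({onset}) if (stage == 3 and rrt) else frozenset()
    return tuple(sorted((d, round(v, 4)) for d, v in values.items())), rrt_days


def _sample_los(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """Zero-truncated negative binomial lengths of stay."""
    r = dispersion
    p = r / (r + mean - 0.5)  # untruncated mean just under `mean`
    out = rng.negative_binomial(r, p, size=n)
    while (zero := out == 0).any():
        out[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    return out


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    config: CohortConfig, year: int, seed: int | None = None
) -> list[EncounterTimeline]:
    """Generate one year's encounters.

    Deterministic given ``(config, year, seed)``; ``seed`` defaults to
    ``config.seed``.  The fraction of AKI encounters converges to
    ``prevalence_schedule[year]`` because the latent-risk intercept is
    solved so the cohort-mean risk equals the scheduled prevalence.
    """
    if year not in config.years:
        raise ValueError(f"unknown year {year}; config covers {config.years}")
    n = int(config.n_encounters_per_year[year])
    if n <= 0:
        raise ValueError("number of encounters must be positive")
    prevalence = float(config.prevalence_schedule[year])
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly in (0,1)")
    base_seed = config.seed if seed is None else int(seed)
    struct = _structure(config)
    n_risk = struct["n_risk"]
    dy = year - config.years[0]
    drift = config.drift

    rng = np.random.default_rng([base_seed, year, 7])

    # --- encounter-level draws (vectorized) -------------------------------
    age_probs = np.asarray(config.demographic_schedule[year], dtype=float)
    age_probs = age_probs / age_probs.sum()
    age_idx = rng.choice(len(AGE_BANDS), size=n, p=age_probs)
    sex_idx = rng.choice(2, size=n)
    race_idx = rng.choice(len(_RACES), size=n, p=np.asarray(_RACE_PROBS) / sum(_RACE_PROBS))

    n_num = config.n_numeric_features
    mu = drift.covariate_shift_rate * dy * struct["shift_sign"]
    z_lab = rng.normal(0.0, 1.0, size=(n, n_num)) + mu

    cat_levels = ("A", "B", "C")
    cat_idx = np.zeros((n, config.n_categorical_features), dtype=int)
    for j in range(config.n_categorical_features):
        logits = struct["cat_logits"][j] + drift.covariate_shift_rate * dy * struct["cat_shift_dir"][j]
        pj = np.exp(logits - logits.max())
        cat_idx[:, j] = rng.choice(3, size=n, p=pj / pj.sum())

    med_used = rng.random((n, config.n_medications)) < 0.3

    # latent risk
    z = np.column_stack(
        [
            z_lab[:, :n_risk],
            (age_idx - 2.5) / 1.7,
            ((med_used[:, 0].astype(float) - 0.3) / math.sqrt(0.21))
            if config.n_medications
            else np.zeros(n),
        ]
    )
    beta = _effective_beta(
        struct["beta_base"], struct["beta_rerand"], drift, year, config.years[0]
    )
    noise = rng.normal(0.0, drift.noise_sd, size=n)
    eta = z @ beta + noise
    intercept = brentq(lambda a: expit(eta + a).mean() - prevalence, -40.0, 40.0)
    risk = expit(eta + intercept)
    aki = rng.random(n) < risk

    los = _sample_los(rng, n, config.los_mean, config.los_dispersion)
    stage_draw = rng.choice([1, 2, 3], size=n, p=np.asarray(config.stage_mix))
    onset_frac = rng.random(n)
    rrt_draw = rng.random(n) < config.rrt_fraction
    baseline = rng.uniform(0.6, 1.3, size=n)
    birth = config.feature_birth_year

    timelines: list[EncounterTimeline] = []
    numeric_codes = config.numeric_codes
    for i in range(n):
        l = int(los[i])
        is_aki = bool(aki[i])
        stage = int(stage_draw[i]) if is_aki else 0
        onset = None
        if is_aki:
            onset = 1 + int(onset_frac[i] * min(l, 10))
            onset = min(onset, l)
        scr, rrt_days = _scr_trajectory(
            rng, float(baseline[i]), l, stage, onset, bool(rrt_draw[i])
        )

        numeric_obs: dict[str, tuple[tuple[int, float], ...]] = {}
        # labs: observed day 0 w.p. 0.9, later days w.p. 0.5
        live = [
            (j, code)
            for j, code in enumerate(numeric_codes)
            if birth.get(code, config.years[0]) <= year
        ]
        if live:
            obs_mask = rng.random((l + 1, len(live)))
            obs_noise = rng.normal(0.0, 0.5, size=(l + 1, len(live)))
            thresh = np.full(l + 1, 0.5)
            thresh[0] = 0.9
            for col, (j, code) in enumerate(live):
                days = np.nonzero(obs_mask[:, col] < thresh)[0]
                if days.size == 0:
                    continue
                vals = struct["lab_loc"][j] + struct["lab_scale"][j] * (
                    z_lab[i, j] + obs_noise[days, col]
                )
                numeric_obs[code] = tuple(
                    (int(d), round(float(v), 4)) for d, v in zip(days, vals)
                )
        # vitals: daily
        vit = rng.normal(0.0, 1.0, size=(l + 1, len(_VITALS)))
        for k, vcode in enumerate(_VITALS):
            numeric_obs[vcode] = tuple(
                (d, round(float(_VITAL_LOC[vcode] + _VITAL_SCALE[vcode] * vit[d, k]), 2))
                for d in range(l + 1)
            )
        # BUN: a renal marker that the feature pipeline must exclude
        bun_days = np.nonzero(rng.random(l + 1) < 0.7)[0]
        bun_vals = np.clip(rng.normal(16.0, 6.0, size=bun_days.size), 2.0, None)
        numeric_obs["bun"] = tuple(
            (int(d), round(float(v), 2)) for d, v in zip(bun_days, bun_vals)
        )

        categorical_obs = {
            code: ((0, cat_levels[cat_idx[i, j]]),)
            for j, code in enumerate(config.categorical_codes)
        }
        medication_days = {}
        for j, mcode in enumerate(config.medication_codes):
            if med_used[i, j]:
                days = np.nonzero(rng.random(l + 1) < 0.5)[0]
                if days.size == 0:
                    days = np.array([0])
                medication_days[mcode] = tuple(int(d) for d in days)

        timelines.append(
            EncounterTimeline(
                encounter_id=f"{year}-{i:06d}",
                year=year,
                los=l,
                demographics={
                    "age_band": AGE_BANDS[age_idx[i]],
                    "sex": _SEXES[sex_idx[i]],
                    "race": _RACES[race_idx[i]],
                },
                numeric_obs=numeric_obs,
                categorical_obs=categorical_obs,
                medication_days=medication_days,
                scr_series=scr,
                rrt_days=rrt_days,
                aki=is_aki,
                designated_stage=stage,
                designated_onset=onset,
                latent={
                    "z": [float(v) for v in z[i]],
                    "noise": float(noise[i]),
                    "intercept": float(intercept),
                    "beta_base": [float(v) for v in struct["beta_base"]],
                    "beta_rerand": [float(v) for v in struct["beta_rerand"]],
                    "year0": int(config.years[0]),
                },
            )
        )
    return timelines


def true_risk(timeline: EncounterTimeline, drift: DriftParams, year: int) -> float:
    """Ground-truth AKI probability used to assign the outcome.

    Recomputes ``expit(a_y + beta_y . z + eps)`` from the timeline's
    latent covariates and the coefficients in effect for ``year`` under
    ``drift``; exposed so tests can score any model against the truth.
    """
    lat = timeline.latent
    beta = _effective_beta(
        np.asarray(lat["beta_base"], dtype=float),
        np.asarray(lat.get("beta_rerand", lat["beta_base"]), dtype=float),
        drift,
        year,
        lat["year0"],
    )
    eta = float(np.dot(beta, np.asarray(lat["z"], dtype=float)))
    return float(expit(lat["intercept"] + eta + lat["noise"]))


# ---------------------------------------------------------------------------
# file I/O (long format, CSV and Parquet)


def _meta_rows(t: EncounterTimeline) -> list[tuple]:
    eid, yr = t.encounter_id, t.year
    return [
        (eid, yr, 0, "meta", "los", str(t.los)),
        (eid, yr, 0, "meta", "aki", "1" if t.aki else "0"),
        (eid, yr, 0, "meta", "designated_stage", str(t.designated_stage)),
        (
            eid, yr, 0, "meta", "designated_onset",
            "" if t.designated_onset is None else str(t.designated_onset),
        ),
        (eid, yr, 0, "meta", "latent", json.dumps(t.latent)),
    ]


def write_cohort(cohort: Sequence[EncounterTimeline], path: str | Path) -> Path:
    """Write a cohort to one long-format file (.csv or .parquet)."""
    path = Path(path)
    frames = []
    for t in cohort:
        frames.append(t.to_records())
        frames.append(pd.DataFrame(_meta_rows(t), columns=_LONG_COLUMNS))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_LONG_COLUMNS)
    df = df.astype({"encounter_id": str, "year": "int64" if len(df) else "int64",
                    "day": "int64", "kind": str, "code": str, "value": str})
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported cohort file suffix {path.suffix!r}")
    return path


def _parse_float(s: str, row: int) -> float:
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"malformed numeric value {s!r} at row {row}") from exc


def read_cohort(path: str | Path) -> list[EncounterTimeline]:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    elif path.suffix == ".csv":
        df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    else:
        raise ValueError(f"unsupported cohort file suffix {path.suffix!r}")
    missing = set(_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns {sorted(missing)}")

    out: list[EncounterTimeline] = []
    for eid, grp in df.groupby("encounter_id", sort=False):
        year = int(grp["year"].iloc[0])
        demographics: dict[str, str] = {}
        numeric: dict[str, list[tuple[int, float]]] = {}
        categorical: dict[str, list[tuple[int, str]]] = {}
        meds: dict[str, list[int]] = {}
        scr: list[tuple[int, float]] = []
        rrt: set[int] = set()
        meta: dict[str, str] = {}
        for row in grp.itertuples():
            day, kind, code, value = int(row.day), row.kind, row.code, row.value
            if kind == "demographic":
                demographics[code] = value
            elif kind in ("lab", "vital"):
                v = _parse_float(value, row.Index)
                if code == "scr":
                    scr.append((day, v))
                else:
                    numeric.setdefault(code, []).append((day, v))
            elif kind == "diagnosis":
                categorical.setdefault(code, []).append((day, value))
            elif kind == "medication":
                meds.setdefault(code, []).append(day)
            elif kind == "procedure" and code == "rrt":
                rrt.add(day)
            elif kind == "meta":
                meta[code] = value
            else:
                raise ValueError(f"malformed row {row.Index}: unknown kind {kind!r}")
        if "los" not in meta:
            raise ValueError(f"encounter {eid!r} missing meta/los row")
        onset = meta.get("designated_onset", "")
        out.append(
            EncounterTimeline(
                encounter_id=str(eid),
                year=year,
                los=int(meta["los"]),
                demographics=demographics,
                numeric_obs={c: tuple(v) for c, v in numeric.items()},
                categorical_obs={c: tuple(v) for c, v in categorical.items()},
                medication_days={c: tuple(v) for c, v in meds.items()},
                scr_series=tuple(scr),
                rrt_days=frozenset(rrt),
                aki=meta.get("aki", "0") == "1",
                designated_stage=int(meta.get("designated_stage", "0")),
                designated_onset=None if onset == "" else int(onset),
                latent=json.loads(meta["latent"]) if meta.get("latent") else {},
            )
        )
    return out


# ---------------------------------------------------------------------------
# packaged configurations


def study_config(
    seed: int = 0,
    n_scale: float = 1.0,
    drift: DriftParams | None = None,
) -> CohortConfig:
    """The packaged eight-year study cohort configuration.

    Yearly sizes, any-AKI prevalences and age-band distributions follow
    the emulated study's demographic table (prevalence declining from
    16.9% in 2010 to 12.8% in 2017; elderly fraction rising from 31.7%
    to 36.5%).  ``n_scale`` shrinks every year's cohort proportionally
    for desk-scale experiments.
    """
    if drift is None:
        drift = DriftParams(covariate_shift_rate=0.05, concept_drift_rate=0.15, noise_sd=0.3)
    return CohortConfig(
        years=_STUDY_YEARS,
        n_encounters_per_year={y: max(1, int(round(_STUDY_N[y] * n_scale))) for y in _STUDY_YEARS},
        prevalence_schedule=dict(_STUDY_PREV),
        demographic_schedule={y: _STUDY_AGE[y] for y in _STUDY_YEARS},
        feature_birth_year={"lab_10": 2014, "lab_11": 2014},
        drift=drift,
        seed=seed,
    )


def drift_scenario(
    n_per_year: int = 3000,
    years: tuple[int, ...] = _STUDY_YEARS,
    covariate_shift_rate: float = 0.05,
    concept_drift_rate: float = 0.15,
    noise_sd: float = 0.3,
    rerandomize_from_year: int | None = None,
    seed: int = 0,
) -> CohortConfig:
    """Moderate-drift scenario: study-shaped schedules at a chosen size.

    ``years`` must be drawn from the study range 2010-2017 (prevalence
    and demographics follow the packaged schedule for those years).
    """
    unknown = set(years) - set(_STUDY_YEARS)
    if unknown:
        raise ValueError(f"years {sorted(unknown)} outside the packaged 2010-2017 schedule")
    # late-born labs snap to the first included year >= their nominal birth
    birth = {}
    for feat, nominal in (("lab_10", 2014), ("lab_11", 2014)):
        later = [y for y in years if y >= nominal]
        if later:
            birth[feat] = min(later)
    return CohortConfig(
        years=tuple(years),
        n_encounters_per_year={y: n_per_year for y in years},
        prevalence_schedule={y: _STUDY_PREV[y] for y in years},
        demographic_schedule={y: _STUDY_AGE[y] for y in years},
        feature_birth_year=birth,
        drift=DriftParams(
            covariate_shift_rate=covariate_shift_rate,
            concept_drift_rate=concept_drift_rate,
            noise_sd=noise_sd,
            rerandomize_from_year=rerandomize_from_year,
        ),
        seed=seed,
    )
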
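"""Transferable EHR feature engineering.

A :class:`FeatureScheme` is fitted on development records and then
applied — unchanged — to any later data, so that a model trained on an
old era can be fed identically-constructed inputs from a new era.  The
preprocessing steps are: winsorization of numeric values outside the
fitted 1st/99th percentiles (values are *removed*, i.e. set missing,
not clipped — the GBM learner handles missingness natively);
one-hot coding of categorical variables; cumulative-exposure-day
encoding of medications; most-recent-record deduplication within a
day; sample-and-hold (last observation carried forward) for missing
numeric values; derived features (daily blood-pressure trend, length
of stay so far); and exclusion of all serum-creatinine and blood urea
nitrogen forms, which are disqualified as predictors because they
define the AKI outcome itself.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureScheme",
    "FeatureSplit",
    "fit_scheme",
    "apply_scheme",
    "apply_scheme_multi",
    "split_features",
    "project_to_common",
    "project_frame_to_common",
]

SCHEME_VERSION = 1

#: outcome-defining renal markers excluded from the predictor roster:
#: all serum-creatinine and blood-urea-nitrogen forms, plus renal
#: replacement therapy (RRT initiation is itself a stage-3 criterion)
_RENAL_RE = re.compile(
    r"(^|_)(scr|creatinine|bun|blood_urea_nitrogen|rrt|dialysis)(_|$)", re.IGNORECASE
)

NUMERIC_KINDS = ("lab", "vital")
CATEGORICAL_KINDS = ("diagnosis", "demographic")


def is_renal_marker(code: str) -> bool:
    return bool(_RENAL_RE.search(code))


@dataclass(frozen=True)
class FeatureScheme:
    """Fitted, serializable feature-engineering state."""

    numeric_cutpoints: dict[str, tuple[float, float]]
    categorical_vocab: dict[str, tuple[str, ...]]
    medications: tuple[str, ...]
    procedures: tuple[str, ...]
    excluded: tuple[str, ...]
    winsorize: bool = True
    hold_horizon: int | None = None  # days; None = unlimited carry-forward
    version: int = SCHEME_VERSION

    def __post_init__(self) -> None:
        for code, (lo, hi) in self.numeric_cutpoints.items():
            if lo > hi:
                raise ValueError(f"cutpoints inverted for {code!r}")
        for code in self.excluded:
            if code in self.numeric_cutpoints:
                raise ValueError(f"excluded feature {code!r} present in cutpoints")

    @property
    def roster(self) -> tuple[str, ...]:
        """Ordered names of every emitted feature."""
        names: list[str] = sorted(self.numeric_cutpoints)
        for code in sorted(self.categorical_vocab):
            names.extend(f"{code}={cat}" for cat in self.categorical_vocab[code])
        names.extend(f"{code}__cumdays" for code in sorted(self.medications))
        names.extend(f"{code}__any" for code in sorted(self.procedures))
        names.extend(["bp_trend", "los_so_far"])
        return tuple(names)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "winsorize": self.winsorize,
                "hold_horizon": self.hold_horizon,
                "numeric_cutpoints": {k: list(v) for k, v in self.numeric_cutpoints.items()},
                "categorical_vocab": {k: list(v) for k, v in self.categorical_vocab.items()},
                "medications": list(self.medications),
                "procedures": list(self.procedures),
                "excluded": list(self.excluded),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureScheme":
        d = json.loads(text)
        return cls(
            numeric_cutpoints={k: (float(a), float(b)) for k, (a, b) in d["numeric_cutpoints"].items()},
            categorical_vocab={k: tuple(v) for k, v in d["categorical_vocab"].items()},
            medications=tuple(d["medications"]),
            procedures=tuple(d["procedures"]),
            excluded=tuple(d["excluded"]),
            winsorize=bool(d["winsorize"]),
            hold_horizon=d["hold_horizon"],
            version=int(d["version"]),
        )


@dataclass(frozen=True)
class FeatureSplit:
    """Source/target roster set arithmetic for transfer modeling."""

    common: tuple[str, ...]
    unique_source: tuple[str, ...]
    unique_target: tuple[str, ...]
    source_roster: tuple[str, ...]
    target_roster: tuple[str, ...]


def fit_scheme(
    records: pd.DataFrame,
    winsorize: bool = True,
    hold_horizon: int | None = None,
) -> FeatureScheme:
    """Learn cutpoints, vocabularies and rosters from development records.

    ``records`` is long-format with columns (encounter_id, day, kind,
    code, value).  Order-independent: percentiles pool all records of a
    code; vocabularies are sorted.
    """
    if records is None or len(records) == 0:
        raise ValueError("cannot fit a feature scheme on empty records")
    excluded: set[str] = set()
    numeric: dict[str, tuple[float, float]] = {}
    vocab: dict[str, tuple[str, ...]] = {}
    meds: set[str] = set()
    procs: set[str] = set()
    for (kind, code), grp in records.groupby(["kind", "code"], sort=True):
        if kind == "meta":
            continue
        if is_renal_marker(code):
            excluded.add(code)
            continue
        if kind in NUMERIC_KINDS:
            vals = pd.to_numeric(grp["value"], errors="coerce").dropna().to_numpy(float)
            if vals.size == 0:
                continue
            lo, hi = np.percentile(vals, [1.0, 99.0])
            numeric[code] = (float(lo), float(hi))
        elif kind in CATEGORICAL_KINDS:
            vocab[code] = tuple(sorted(set(grp["value"].astype(str))))
        elif kind == "medication":
            meds.add(code)
        elif kind == "procedure":
            procs.add(code)
    return FeatureScheme(
        numeric_cutpoints=numeric,
        categorical_vocab=vocab,
        medications=tuple(sorted(meds)),
        procedures=tuple(sorted(procs)),
        excluded=tuple(sorted(excluded)),
        winsorize=winsorize,
        hold_horizon=hold_horizon,
    )


def _slope_last3(days: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope through the last <=3 daily values."""
    if len(days) >= 3:
        d, v = days[-3:].astype(float), values[-3:]
        return float(np.polyfit(d, v, 1)[0])
    if len(days) == 2:
        dd = float(days[-1] - days[-2])
        return float((values[-1] - values[-2]) / dd) if dd else 0.0
    return 0.0


def _index_records(scheme: FeatureScheme, records: pd.DataFrame):
    """Pre-index one encounter's records into per-code day/value arrays.

    Within a day the most recent (last) record of a code wins; winsorized
    numeric values are removed here so sample-and-hold later falls back
    to the last earlier valid value.
    """
    numeric_series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    cat_series: dict[str, tuple[np.ndarray, list[str]]] = {}
    med_days: dict[str, np.ndarray] = {}
    proc_days: dict[str, np.ndarray] = {}
    if len(records) == 0:
        return numeric_series, cat_series, med_days, proc_days
    order = np.argsort(records["day"].to_numpy(), kind="stable")
    days_a = records["day"].to_numpy()[order]
    kinds_a = records["kind"].to_numpy()[order]
    codes_a = records["code"].to_numpy()[order]
    values_a = records["value"].to_numpy()[order]

    num_acc: dict[str, dict[int, float]] = {}
    cat_acc: dict[str, dict[int, str]] = {}
    med_acc: dict[str, set[int]] = {}
    proc_acc: dict[str, set[int]] = {}
    for day, kind, code, value in zip(days_a, kinds_a, codes_a, values_a):
        day = int(day)
        if kind in NUMERIC_KINDS and code in scheme.numeric_cutpoints:
            try:
                num_acc.setdefault(code, {})[day] = float(value)
            except (TypeError, ValueError):
                num_acc.setdefault(code, {})[day] = float("nan")
        elif kind in CATEGORICAL_KINDS and code in scheme.categorical_vocab:
            cat_acc.setdefault(code, {})[day] = str(value)
        elif kind == "medication" and code in scheme.medications:
            med_acc.setdefault(code, set()).add(day)
        elif kind == "procedure" and code in scheme.procedures:
            proc_acc.setdefault(code, set()).add(day)

    for code, by_day in num_acc.items():
        days = np.fromiter(by_day.keys(), dtype=int)
        vals = np.fromiter(by_day.values(), dtype=float)
        order = np.argsort(days)
        days, vals = days[order], vals[order]
        if scheme.winsorize:
            lo, hi = scheme.numeric_cutpoints[code]
            vals = np.where((vals < lo) | (vals > hi), np.nan, vals)
        ok = ~np.isnan(vals)
        numeric_series[code] = (days[ok], vals[ok])
    for code, by_day in cat_acc.items():
        days = np.fromiter(by_day.keys(), dtype=int)
        order = np.argsort(days)
        labels = list(by_day.values())
        cat_series[code] = (days[order], [labels[i] for i in order])
    for code, dayset in med_acc.items():
        med_days[code] = np.fromiter(sorted(dayset), dtype=int)
    for code, dayset in proc_acc.items():
        proc_days[code] = np.fromiter(sorted(dayset), dtype=int)
    return numeric_series, cat_series, med_days, proc_days


def apply_scheme_matrix(
    scheme: FeatureScheme,
    records: pd.DataFrame,
    cutoff_days: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for one encounter at several cutoff days.

    Only records with ``day <= cutoff`` are ever read for a given
    cutoff (the no-leakage contract shared with the discrete-time
    sampler).  Returns ``(matrix, consumed_day)`` where row ``i`` is
    the roster-ordered vector at ``cutoff_days[i]`` and
    ``consumed_day[i]`` is the latest record day that contributed to
    it, so callers can hard-assert the no-leakage contract.
    """
    for c in cutoff_days:
        if c < 0:
            raise ValueError(f"cutoff_day must be >= 0, got {c}")
    numeric_series, cat_series, med_days, proc_days = _index_records(scheme, records)
    roster = scheme.roster
    n_feat = len(roster)
    out = np.empty((len(cutoff_days), n_feat))
    consumed = np.full(len(cutoff_days), -1, dtype=int)
    for i, cutoff in enumerate(cutoff_days):
        vec = np.empty(n_feat)
        k = 0
        latest = -1
        for code in sorted(scheme.numeric_cutpoints):
            val = np.nan
            entry = numeric_series.get(code)
            if entry is not None:
                days, vals = entry
                idx = int(np.searchsorted(days, cutoff, side="right")) - 1
                if idx >= 0:
                    d = int(days[idx])
                    if scheme.hold_horizon is None or cutoff - d <= scheme.hold_horizon:
                        val = vals[idx]
                        latest = max(latest, d)
            vec[k] = val
            k += 1
        for code in sorted(scheme.categorical_vocab):
            cats = scheme.categorical_vocab[code]
            current = None
            entry = cat_series.get(code)
            if entry is not None:
                days, labels = entry
                idx = int(np.searchsorted(days, cutoff, side="right")) - 1
                if idx >= 0:
                    current = labels[idx]
                    latest = max(latest, int(days[idx]))
            for cat in cats:
                vec[k] = 1.0 if current == cat else 0.0
                k += 1
        for code in sorted(scheme.medications):
            days = med_days.get(code)
            n_days = int(np.searchsorted(days, cutoff, side="right")) if days is not None else 0
            if n_days:
                latest = max(latest, int(days[n_days - 1]))
            vec[k] = float(n_days)
            k += 1
        for code in sorted(scheme.procedures):
            days = proc_days.get(code)
            n_days = int(np.searchsorted(days, cutoff, side="right")) if days is not None else 0
            if n_days:
                latest = max(latest, int(days[n_days - 1]))
            vec[k] = 1.0 if n_days else 0.0
            k += 1
        sbp = numeric_series.get("sbp")
        if sbp is not None:
            j = int(np.searchsorted(sbp[0], cutoff, side="right"))
            vec[k] = _slope_last3(sbp[0][:j], sbp[1][:j])
        else:
            vec[k] = 0.0
        vec[k + 1] = float(cutoff)
        out[i] = vec
        consumed[i] = latest
    return out, consumed


def apply_scheme_multi(
    scheme: FeatureScheme,
    records: pd.DataFrame,
    cutoff_days: Sequence[int],
) -> list[pd.Series]:
    """Feature vectors (roster-indexed Series) at several cutoff days."""
    matrix, _ = apply_scheme_matrix(scheme, records, cutoff_days)
    roster = list(scheme.roster)
    return [pd.Series(row, index=roster, dtype=float) for row in matrix]


def apply_scheme(
    scheme: FeatureScheme, records: pd.DataFrame, cutoff_day: int
) -> pd.Series:
    """Feature vector for one encounter at one cutoff day."""
    return apply_scheme_multi(scheme, records, [cutoff_day])[0]


def split_features(source_scheme: FeatureScheme, target_scheme: FeatureScheme) -> FeatureSplit:
    """Common / unique-source / unique-target roster arithmetic."""
    src, tgt = source_scheme.roster, target_scheme.roster
    src_set, tgt_set = set(src), set(tgt)
    return FeatureSplit(
        common=tuple(n for n in src if n in tgt_set),
        unique_source=tuple(n for n in src if n not in tgt_set),
        unique_target=tuple(n for n in tgt if n not in src_set),
        source_roster=src,
        target_roster=tgt,
    )


def project_to_common(vector: pd.Series, split: FeatureSplit) -> pd.Series:
    """Project a target-roster vector into the source input space.

    Keeps common features and injects explicit missing values for every
    source-only feature, ordered per the source roster — the
    representation consumed by the source and adapted models.
    """
    if tuple(vector.index) != split.target_roster:
        raise ValueError("vector does not conform to the target roster")
    out = pd.Series(np.nan, index=list(split.source_roster), dtype=float)
    common = list(split.common)
    out[common] = vector[common].astype(float)
    return out


def project_frame_to_common(X: pd.DataFrame, split: FeatureSplit) -> pd.DataFrame:
    """Vectorized :func:`project_to_common` over a design matrix."""
    if tuple(X.columns) != split.target_roster:
        raise ValueError("frame does not conform to the target roster")
    out = pd.DataFrame(np.nan, index=X.index, columns=list(split.source_roster), dtype=float)
    common = list(split.common)
    out[common] = X[common].astype(float)
    return out
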
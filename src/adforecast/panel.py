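"""Longitudinal ordinal panel data: containers, I/O, filters and diagnostics.

The central object is :class:`PanelDataset`, a thin validated wrapper around a
long-format :class:`pandas.DataFrame` with one row per patient-day.  Each row
carries six ordinal atopic-dermatitis sign scores (0 = none ... 4 = severe),
a binary topical-corticosteroid (TCS) usage flag and seven environmental
covariates (weather and air-pollutant series, typically city-level and hence
shared across patients).

Missing cells are represented as NaN and are preserved by all operations;
nothing here imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The six AD sign names, in canonical order.
SIGNS = ("dryness", "oedema", "itching", "oozing", "redness", "sleep")

#: Environmental covariate columns (city-level daily series).
ENV_COVARIATES = ("temp", "rh", "rainfall", "dtr", "pm10", "no2", "o3")

#: Everything that may enter a model's linear predictor as a covariate.
COVARIATES = ENV_COVARIATES + ("tcs",)

#: Covariates that are continuous and therefore standardized before fitting.
CONTINUOUS_COVARIATES = ENV_COVARIATES

_REQUIRED = ("patient_id", "day") + SIGNS


class PanelValidationError(ValueError):
    """A panel file or frame violates the schema (range, type or ordering)."""


@dataclass(frozen=True)
class TransitionPair:
    """One training/test unit: consecutive-day score pair for one sign.

    ``covariates`` holds the covariate values observed on day ``day`` (the
    predictor day); the outcome ``s_next`` is the score on ``day + 1``.
    """

    patient: object
    day: int
    s_t: int
    s_next: int
    covariates: tuple = ()


@dataclass
class CovariateStats:
    """Per-covariate mean/SD fitted on a training window, for z-scoring.

    Binary covariates (TCS) are passed through untouched and carry
    mean 0 / SD 1 entries so that transform/inverse are uniform.
    """

    names: tuple
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean


class PanelDataset:
    """Patients x days table of sign scores, TCS flag and environment.

    Parameters
    ----------
    data:
        Long-format frame with columns ``patient_id``, ``day``, the six
        signs, and optionally ``tcs`` and the seven environmental columns.
        NaN encodes missing.  Rows are sorted by (patient, day) on
        construction; days must be unique and strictly increasing within a
        patient.
    """

    def __init__(self, data: pd.DataFrame):
        missing_cols = [c for c in _REQUIRED if c not in data.columns]
        if missing_cols:
            raise PanelValidationError(f"missing required columns: {missing_cols}")
        df = data.copy()
        df["day"] = pd.to_numeric(df["day"], errors="raise")
        if not np.all(np.asarray(df["day"]) == np.asarray(df["day"], dtype=int)):
            raise PanelValidationError("day indices must be integers")
        df["day"] = df["day"].astype(int)
        df = df.sort_values(["patient_id", "day"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["patient_id", "day"]).any():
            dup = df[df.duplicated(["patient_id", "day"])].iloc[0]
            raise PanelValidationError(
                f"duplicate patient-day row: patient {dup['patient_id']} day {dup['day']}"
            )
        for sign in SIGNS:
            col = pd.to_numeric(df[sign], errors="coerce")
            bad_parse = df[sign].notna() & col.isna()
            if bad_parse.any():
                i = int(np.flatnonzero(bad_parse)[0])
                raise PanelValidationError(
                    f"non-numeric score in column '{sign}', row {i}: {df[sign].iloc[i]!r}"
                )
            observed = col.dropna()
            if len(observed) and not (
                np.all(observed == observed.astype(int))
                and observed.min() >= 0
                and observed.max() <= 4
            ):
                bad = observed[(observed < 0) | (observed > 4) | (observed != observed.astype(int))]
                i = bad.index[0]
                raise PanelValidationError(
                    f"score out of range {{0..4}} in column '{sign}', row {i}: {bad.iloc[0]}"
                )
            df[sign] = col.astype(float)
        if "tcs" in df.columns:
            tcs = pd.to_numeric(df["tcs"], errors="coerce")
            obs = tcs.dropna()
            if len(obs) and not set(np.unique(obs)).issubset({0.0, 1.0}):
                raise PanelValidationError("tcs must be 0/1 where present")
            df["tcs"] = tcs.astype(float)
        for cov in ENV_COVARIATES:
            if cov in df.columns:
                df[cov] = pd.to_numeric(df[cov], errors="coerce").astype(float)
        self.data = df

    # -- basic accessors ---------------------------------------------------

    @property
    def patients(self) -> list:
        return list(pd.unique(self.data["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_frame(self, patient) -> pd.DataFrame:
        return self.data[self.data["patient_id"] == patient]

    def covariate_columns(self) -> list:
        return [c for c in COVARIATES if c in self.data.columns]

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_panel(path, schema: Mapping[str, str] | None = None) -> PanelDataset:
    """Read a long-format panel CSV into a validated :class:`PanelDataset`.

    ``schema`` optionally maps canonical column names (``patient_id``,
    ``day``, sign and covariate names) to the names used in the file.
    Empty cells are read as missing.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelValidationError(f"could not parse {path}: {exc}") from exc
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        df = df.rename(columns=rename)
    return PanelDataset(df)


def filter_min_observations(ds: PanelDataset, min_days: int) -> PanelDataset:
    """Drop patients with fewer than ``min_days`` observed days.

    An observed day is a patient-day row with at least one non-missing sign
    score.  The study protocol this mirrors removes patients with fewer than
    10 daily observations.  Idempotent; preserves row order.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    df = ds.data
    any_sign = df[list(SIGNS)].notna().any(axis=1)
    counts = any_sign.groupby(df["patient_id"]).sum()
    keep = counts[counts >= min_days].index
    return PanelDataset(df[df["patient_id"].isin(keep)])


def derive_symptom_state(scores: Mapping[str, float]) -> int:
    """Binary AD symptom state from six non-missing sign scores.

    The state is 1 iff itching + sleep disturbance >= 2 *and* at least two of
    redness, dryness, oedema, oozing are non-zero; 0 otherwise.  Raises if any
    of the six scores is missing — missingness must be handled upstream.
    """
    vals = {}
    for sign in SIGNS:
        v = scores[sign]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"sign '{sign}' is missing; state undefined")
        vals[sign] = int(v)
    cond_a = vals["itching"] + vals["sleep"] >= 2
    cond_b = sum(vals[s] > 0 for s in ("redness", "dryness", "oedema", "oozing")) >= 2
    return int(cond_a and cond_b)


def symptom_state_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized symptom state over a panel frame; NaN where any sign missing."""
    complete = df[list(SIGNS)].notna().all(axis=1)
    a = (df["itching"] + df["sleep"]) >= 2
    b = (df[["redness", "dryness", "oedema", "oozing"]] > 0).sum(axis=1) >= 2
    out = (a & b).astype(float)
    out[~complete] = np.nan
    return out


def extract_transition_pairs(
    ds: PanelDataset,
    sign: str,
    covariate_set: Sequence[str] = (),
) -> list[TransitionPair]:
    """All consecutive-day (t, t+1) score pairs for one sign.

    A pair exists when days t and t+1 are both present with the sign observed
    on both, and — when ``covariate_set`` is non-empty — every requested
    covariate is observed on day t (covariates enter at day t to predict the
    day t+1 score).  Pairs with any required value missing are dropped, never
    imputed.  Output is sorted by patient then day.
    """
    if sign not in SIGNS:
        raise ValueError(f"unknown sign {sign!r}; expected one of {SIGNS}")
    for cov in covariate_set:
        if cov not in COVARIATES:
            raise ValueError(f"unknown covariate {cov!r}; expected one of {COVARIATES}")
        if cov not in ds.data.columns:
            raise ValueError(f"covariate {cov!r} not present in dataset")
    df = ds.data
    pid = df["patient_id"].to_numpy()
    day = df["day"].to_numpy()
    score = df[sign].to_numpy()
    cov_mat = df[list(covariate_set)].to_numpy(dtype=float) if covariate_set else None

    # rows are sorted by (patient, day); a pair is two adjacent rows of the
    # same patient on consecutive calendar days
    same = pid[:-1] == pid[1:]
    consecutive = day[1:] == day[:-1] + 1
    ok = same & consecutive & ~np.isnan(score[:-1]) & ~np.isnan(score[1:])
    if cov_mat is not None and cov_mat.shape[1]:
        ok &= ~np.isnan(cov_mat[:-1]).any(axis=1)
    idx = np.flatnonzero(ok)
    return [
        TransitionPair(
            patient=pid[i],
            day=int(day[i]),
            s_t=int(score[i]),
            s_next=int(score[i + 1]),
            covariates=tuple(cov_mat[i]) if cov_mat is not None else (),
        )
        for i in idx
    ]


def standardize_covariates(
    pairs: Iterable[TransitionPair],
    covariate_set: Sequence[str],
    stats: CovariateStats | None = None,
) -> tuple[list[TransitionPair], CovariateStats]:
    """Z-score continuous covariates across pairs; pass binary TCS through.

    When ``stats`` is None the mean/SD (population convention, ddof=0) are
    fitted from the pairs themselves and returned for reuse on test data —
    test-time covariates must be scaled with training-window statistics.
    """
    pairs = list(pairs)
    names = tuple(covariate_set)
    if stats is None:
        if pairs:
            mat = np.array([p.covariates for p in pairs], dtype=float)
        else:
            mat = np.zeros((0, len(names)))
        mean = np.zeros(len(names))
        sd = np.ones(len(names))
        for j, name in enumerate(names):
            if name in CONTINUOUS_COVARIATES:
                col = mat[:, j]
                m, s = float(np.mean(col)), float(np.std(col))
                if s == 0 or not np.isfinite(s):
                    raise ValueError(f"covariate {name!r} has zero variance in fitting window")
                mean[j], sd[j] = m, s
        stats = CovariateStats(names=names, mean=mean, sd=sd)
    elif stats.names != names:
        raise ValueError(f"stats fitted for {stats.names}, requested {names}")
    out = [
        TransitionPair(
            patient=p.patient,
            day=p.day,
            s_t=p.s_t,
            s_next=p.s_next,
            covariates=tuple(stats.transform(np.asarray(p.covariates, dtype=float))),
        )
        for p in pairs
    ]
    return out, stats


def cross_correlogram(
    ds: PanelDataset, sign: str, covariate: str, max_lag: int
) -> pd.DataFrame:
    """Pearson correlation between covariate at day t-lag and sign score at t.

    The sign series is mean-centered within each patient before pooling, so
    that between-patient baseline differences do not masquerade as
    covariate-score correlation.  Lags with fewer than 3 jointly observed
    (t-lag, t) pairs are reported as NaN.  This is the lag-selection
    diagnostic used to justify a first-order autoregressive structure.
    """
    if sign not in SIGNS:
        raise ValueError(f"unknown sign {sign!r}")
    if covariate not in ds.data.columns:
        raise ValueError(f"covariate {covariate!r} not present in dataset")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    rows = []
    centered_all: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    df = ds.data
    per_patient = []
    for patient, sub in df.groupby("patient_id", sort=False):
        day = sub["day"].to_numpy()
        s = sub[sign].to_numpy(dtype=float)
        x = sub[covariate].to_numpy(dtype=float)
        obs = ~np.isnan(s)
        if obs.sum() == 0:
            continue
        s_cent = s - np.nanmean(s)
        # dense day-indexed arrays so lagging is calendar-true across row gaps
        lo, hi = int(day.min()), int(day.max())
        dense_s = np.full(hi - lo + 1, np.nan)
        dense_x = np.full(hi - lo + 1, np.nan)
        dense_s[day - lo] = s_cent
        dense_x[day - lo] = x
        per_patient.append((dense_s, dense_x))
    for lag in range(max_lag + 1):
        ys, xs = [], []
        for dense_s, dense_x in per_patient:
            if lag >= len(dense_s):
                continue
            y = dense_s[lag:] if lag else dense_s
            x = dense_x[: len(dense_x) - lag] if lag else dense_x
            ok = ~np.isnan(y) & ~np.isnan(x)
            ys.append(y[ok])
            xs.append(x[ok])
        y = np.concatenate(ys) if ys else np.array([])
        x = np.concatenate(xs) if xs else np.array([])
        if len(y) < 3 or np.std(y) == 0 or np.std(x) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"lag": lag, "correlation": r, "n": len(y)})
    return pd.DataFrame(rows)
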
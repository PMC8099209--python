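"""Forward-chaining validation, proper scoring rules and ablation summaries.

The validation scheme is rolling-origin: for every test day T the models are
trained on all transition pairs whose outcome falls strictly before T and
scored on the day-T outcomes, so training data always precede the test day.
Sign-score forecasts are scored with the ranked probability score (RPS,
normalized by K-1 = 4 so it lies in [0, 1]); binary symptom-state forecasts
with the Brier score.  Covariate ablation is summarized as matched paired
RPS differences (positive = covariate model better) and as the fitted
single-covariate coefficients with standard errors.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .benchmarks import historical_forecast, uniform_forecast
from .model import (
    FitOptions,
    FittedSignModel,
    ModelSpec,
    OrderedLogisticParams,
    _fit_arrays,
    _PairData,
    _unpack,
    encode_previous_score,
)
from .panel import (
    CONTINUOUS_COVARIATES,
    SIGNS,
    CovariateStats,
    PanelDataset,
)
from .state import state_probability

K = 5


def rps(forecast, outcome: int) -> float:
    """Ranked probability score of one ordinal forecast, in [0, 1].

    Mean over the K-1 inner thresholds of the squared difference between the
    forecast CDF and the outcome step function; 0 for a point forecast on
    the realized outcome, 1 for a point forecast at the opposite extreme.
    """
    pmf = np.asarray(forecast, dtype=float)
    if pmf.shape != (K,) or np.any(pmf < -1e-12) or abs(pmf.sum() - 1.0) > 1e-6:
        raise ValueError(f"invalid forecast pmf: {pmf}")
    if not 0 <= int(outcome) <= 4:
        raise ValueError(f"outcome must be in 0..4, got {outcome}")
    F = np.cumsum(pmf)[:-1]
    O = (np.arange(K - 1) >= int(outcome)).astype(float)
    return float(np.mean((F - O) ** 2))


def brier(prob: float, outcome: int) -> float:
    """Brier score (prob - outcome)^2 of a binary probabilistic forecast."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must be in [0, 1]")
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    return float((prob - outcome) ** 2)


def _rps_rows(pmf_rows: np.ndarray, outcomes: np.ndarray) -> np.ndarray:
    F = np.cumsum(pmf_rows, axis=1)[:, :-1]
    O = (np.arange(K - 1)[None, :] >= outcomes[:, None]).astype(float)
    return np.mean((F - O) ** 2, axis=1)


@dataclass
class ScoreTable:
    """Per-prediction score records plus run metadata.

    ``records`` columns: patient_id, test_day, sign (one of the six or
    "state"), model_variant, score_type (RPS | Brier), score_value.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = ["patient_id", "test_day", "sign", "model_variant", "score_type"]
        if self.records.duplicated(keys).any():
            raise ValueError("duplicate score-record keys")

    def select(self, **conditions) -> pd.DataFrame:
        df = self.records
        for col, val in conditions.items():
            df = df[df[col] == val]
        return df

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, metadata=None) -> "ScoreTable":
        return cls(pd.read_csv(path), metadata or {})


# ---------------------------------------------------------------------------
# forward chaining
# ---------------------------------------------------------------------------


def _panel_tensors(ds: PanelDataset, covariates: Sequence[str]):
    """Dense (patient x day) tensors for scores and covariates."""
    df = ds.data
    patients = list(pd.unique(df["patient_id"]))
    code = {p: i for i, p in enumerate(patients)}
    d_max = int(df["day"].max())
    rows = df["patient_id"].map(code).to_numpy()
    cols = df["day"].to_numpy() - 1
    S = {}
    for s in SIGNS:
        mat = np.full((len(patients), d_max), np.nan)
        mat[rows, cols] = df[s].to_numpy(dtype=float)
        S[s] = mat
    C = np.full((len(patients), d_max, len(covariates)), np.nan)
    for j, cov in enumerate(covariates):
        if cov in df.columns:
            C[rows, cols, j] = df[cov].to_numpy(dtype=float)
    return patients, S, C, d_max


def _make_pairdata(patients, k_idx, s_t, s_next, X) -> _PairData:
    row_starts = np.flatnonzero(np.r_[True, k_idx[1:] != k_idx[:-1]])
    used = np.unique(k_idx)
    return _PairData(
        patients=[patients[i] for i in used],
        pat_idx=np.searchsorted(used, k_idx),
        row_starts=row_starts,
        s_t=s_t.astype(np.intp),
        s_next=s_next.astype(np.intp),
        X=X,
    )


class _VariantState:
    """Mutable per-(sign, variant) fitting state during forward chaining."""

    def __init__(self, spec: ModelSpec, cov_idx: np.ndarray):
        self.spec = spec
        self.cov_idx = cov_idx
        self.theta = None
        self.model_params = None  # (beta, gamma, cutpoints, alpha_by_code)
        self.stats = None


def forward_chaining(
    ds: PanelDataset,
    specs: Sequence[ModelSpec],
    refit_stride: int = 1,
    min_train_days: int = 1,
    fit_options: FitOptions | None = None,
    include_benchmarks: bool = True,
    score_state: bool = True,
) -> ScoreTable:
    """Rolling-origin validation of model variants against the benchmarks.

    For each test day T from ``min_train_days + 1`` to the last day, each
    variant is fitted on all pairs whose outcome day is < T (refitting every
    ``refit_stride`` days and reusing the last fit in between, warm-started)
    and scored on every patient with the sign observed on both T-1 and T.
    Benchmarks are scored on the same patient-days without any covariate
    requirement.  Symptom-state Brier records are added for variants that
    cover all six signs, on days where all six signs are observed at T-1 and
    T.  Failed fits are recorded as flagged gaps in the metadata, never
    silently dropped.
    """
    if refit_stride < 1:
        raise ValueError("refit_stride must be >= 1")
    fit_options = fit_options or FitOptions()
    all_covs = sorted({c for sp in specs for c in sp.covariate_set})
    patients, S, C, d_max = _panel_tensors(ds, all_covs)
    n_pat = len(patients)
    code = {p: i for i, p in enumerate(patients)}

    states: dict[tuple, _VariantState] = {}
    for sp in specs:
        idx = np.array([all_covs.index(c) for c in sp.covariate_set], dtype=int)
        states[(sp.sign, sp.variant)] = _VariantState(sp, idx)

    variants = sorted({sp.variant for sp in specs})
    state_variants = [
        v for v in variants
        if {sp.sign for sp in specs if sp.variant == v} == set(SIGNS)
    ]

    # per-sign validity of (d-1 -> d) transitions, 1-based predictor day d
    valid = {s: ~np.isnan(S[s][:, :-1]) & ~np.isnan(S[s][:, 1:]) for s in SIGNS}

    hist_counts = {s: np.zeros((n_pat, K)) for s in SIGNS}
    hist_last_day = 0  # last day already folded into the histories

    recs: dict[str, list] = {c: [] for c in
                             ("patient_id", "test_day", "sign", "model_variant",
                              "score_type", "score_value")}
    gaps: list[dict] = []

    def emit(pat_codes, T, sign, variant, stype, values):
        recs["patient_id"].extend(patients[k] for k in pat_codes)
        recs["test_day"].extend([T] * len(pat_codes))
        recs["sign"].extend([sign] * len(pat_codes))
        recs["model_variant"].extend([variant] * len(pat_codes))
        recs["score_type"].extend([stype] * len(pat_codes))
        recs["score_value"].extend(np.asarray(values, dtype=float))

    uniform_pmf = uniform_forecast()
    uniform_state_p = state_probability({s: uniform_pmf for s in SIGNS})

    first_T = min_train_days + 1
    for T in range(first_T, d_max + 1):
        # fold every day strictly before T into the patient histories
        for d in range(hist_last_day + 1, T):
            for s in SIGNS:
                col = S[s][:, d - 1]
                obs = ~np.isnan(col)
                hist_counts[s][obs, col[obs].astype(int)] += 1.0
        hist_last_day = T - 1

        scheduled_refit = (T - first_T) % refit_stride == 0
        test_codes: dict[str, np.ndarray] = {}
        model_pmfs: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

        for s in SIGNS:
            if not any(sp.sign == s for sp in specs) and not include_benchmarks:
                continue
            tc = np.flatnonzero(valid[s][:, T - 2])  # predictor day T-1
            test_codes[s] = tc

        for (sign, variant), vs in states.items():
            sp = vs.spec
            # refit on schedule; also retry daily while no usable fit exists
            if scheduled_refit or vs.model_params is None:
                vs.model_params = None
                mask = valid[sign][:, : max(T - 2, 0)]
                k_idx, t_idx = np.nonzero(mask)
                if k_idx.size:
                    X = C[k_idx, t_idx, :][:, vs.cov_idx] if len(vs.cov_idx) else \
                        np.zeros((k_idx.size, 0))
                    ok = ~np.isnan(X).any(axis=1)
                    k_idx, t_idx, X = k_idx[ok], t_idx[ok], X[ok]
                s_t = S[sign][k_idx, t_idx]
                s_next = S[sign][k_idx, t_idx + 1]
                if k_idx.size == 0 or len(np.unique(s_next)) < 2:
                    gaps.append({"test_day": T, "sign": sign, "variant": variant,
                                 "reason": "insufficient training data"})
                else:
                    try:
                        mean = np.zeros(X.shape[1])
                        sd = np.ones(X.shape[1])
                        for j, cov in enumerate(sp.covariate_set):
                            if cov in CONTINUOUS_COVARIATES:
                                m, v = X[:, j].mean(), X[:, j].std()
                                if v == 0:
                                    raise ValueError(f"zero variance: {cov}")
                                mean[j], sd[j] = m, v
                        Xz = (X - mean) / sd
                        data = _make_pairdata(patients, k_idx, s_t, s_next, Xz)
                        theta, alpha, ll, trace, conv = _fit_arrays(
                            data, fit_options, theta0=vs.theta
                        )
                        vs.theta = theta
                        beta, gamma, c, _, sigma = _unpack(theta, len(vs.cov_idx))
                        alpha_by_code = np.zeros(n_pat)
                        for pat, a in zip(data.patients, alpha):
                            alpha_by_code[code[pat]] = a
                        vs.stats = (mean, sd)
                        vs.model_params = (beta, gamma, c, alpha_by_code)
                        if not conv:
                            gaps.append({"test_day": T, "sign": sign,
                                         "variant": variant, "reason": "non-convergence"})
                    except Exception as exc:
                        gaps.append({"test_day": T, "sign": sign, "variant": variant,
                                     "reason": f"fit failed: {exc}"})
            if vs.model_params is None:
                continue
            tc = test_codes.get(sign, np.array([], dtype=int))
            if len(vs.cov_idx):
                x_test = C[tc, T - 2, :][:, vs.cov_idx]
                cov_ok = ~np.isnan(x_test).any(axis=1)
                tc, x_test = tc[cov_ok], x_test[cov_ok]
            else:
                x_test = np.zeros((len(tc), 0))
            if tc.size == 0:
                continue
            beta, gamma, c, alpha_by_code = vs.model_params
            s_prev = S[sign][tc, T - 2].astype(int)
            beta_ext = np.concatenate([beta, [0.0]])
            eta = alpha_by_code[tc] + beta_ext[s_prev]
            if len(vs.cov_idx):
                mean, sd = vs.stats
                eta = eta + ((x_test - mean) / sd) @ gamma
            cdf = expit(np.asarray(c)[None, :] - eta[:, None])
            pmf_rows = np.diff(
                np.concatenate([np.zeros((len(tc), 1)), cdf, np.ones((len(tc), 1))], axis=1),
                axis=1,
            )
            outcomes = S[sign][tc, T - 1].astype(int)
            emit(tc, T, sign, variant, "RPS", _rps_rows(pmf_rows, outcomes))
            model_pmfs[(sign, variant)] = (tc, pmf_rows)

        if include_benchmarks:
            for s in SIGNS:
                tc = test_codes.get(s, np.array([], dtype=int))
                if tc.size == 0:
                    continue
                outcomes = S[s][tc, T - 1].astype(int)
                u_rows = np.tile(uniform_pmf, (len(tc), 1))
                emit(tc, T, s, "uniform", "RPS", _rps_rows(u_rows, outcomes))
                counts = hist_counts[s][tc]
                totals = counts.sum(axis=1, keepdims=True)
                h_rows = np.where(totals > 0, counts / np.maximum(totals, 1.0), uniform_pmf)
                emit(tc, T, s, "historical", "RPS", _rps_rows(h_rows, outcomes))
                model_pmfs[(s, "historical")] = (tc, h_rows)

        if score_state:
            state_codes = None
            for s in SIGNS:
                tc = test_codes.get(s, np.array([], dtype=int))
                state_codes = set(tc) if state_codes is None else state_codes & set(tc)
            state_codes = sorted(state_codes or ())
            if state_codes:
                realized = {}
                for k in state_codes:
                    sc = {s: S[s][k, T - 1] for s in SIGNS}
                    a = sc["itching"] + sc["sleep"] >= 2
                    b = sum(sc[s] > 0 for s in ("redness", "dryness", "oedema", "oozing")) >= 2
                    realized[k] = int(a and b)
                for variant in (state_variants
                                + (["uniform", "historical"] if include_benchmarks else [])):
                    if variant == "uniform":
                        vals = [brier(uniform_state_p, realized[k]) for k in state_codes]
                        emit(state_codes, T, "state", "uniform", "Brier", vals)
                        continue
                    per_sign = {}
                    complete = True
                    for s in SIGNS:
                        key = (s, variant)
                        if key not in model_pmfs:
                            complete = False
                            break
                        tc, pmf_rows = model_pmfs[key]
                        per_sign[s] = dict(zip(tc, pmf_rows))
                    if not complete:
                        continue
                    codes_here = [k for k in state_codes
                                  if all(k in per_sign[s] for s in SIGNS)]
                    vals = [
                        brier(state_probability({s: per_sign[s][k] for s in SIGNS}),
                              realized[k])
                        for k in codes_here
                    ]
                    emit(codes_here, T, "state", variant, "Brier", vals)

    table = pd.DataFrame(recs)
    meta = {
        "refit_stride": refit_stride,
        "min_train_days": min_train_days,
        "quad_order": fit_options.quad_order,
        "gaps": gaps,
        "config_hash": hashlib.sha256(
            f"{refit_stride}|{min_train_days}|{sorted(str(sp) for sp in specs)}".encode()
        ).hexdigest()[:12],
    }
    return ScoreTable(table, meta)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def learning_curve(
    table: ScoreTable,
    model_variant: str,
    sign: str,
    smoothing_fraction: float = 0.3,
    score_type: str | None = None,
) -> pd.DataFrame:
    """Daily mean score with a LOWESS-smoothed curve and +-1.96 SE band.

    The mean and its standard error (SD/sqrt(n)) are taken across patients
    within each test day; the band is the smoothed mean +-1.96 SE.  Days
    with a single patient get an undefined (NaN) band.
    """
    stype = score_type or ("Brier" if sign == "state" else "RPS")
    df = table.select(model_variant=model_variant, sign=sign, score_type=stype)
    if df.empty:
        return pd.DataFrame(columns=["test_day", "mean", "se", "smoothed", "lo", "hi"])
    g = df.groupby("test_day")["score_value"]
    out = pd.DataFrame({"test_day": sorted(g.groups), "mean": g.mean().values,
                        "se": (g.std(ddof=1) / np.sqrt(g.count())).values})
    if len(out) >= 3:
        sm = lowess(out["mean"], out["test_day"], frac=smoothing_fraction,
                    return_sorted=False)
    else:
        sm = out["mean"].to_numpy()
    out["smoothed"] = sm
    out["lo"] = out["smoothed"] - 1.96 * out["se"]
    out["hi"] = out["smoothed"] + 1.96 * out["se"]
    return out


def paired_score_difference(
    table_a: ScoreTable, table_b: ScoreTable,
    variant_a: str | None = None, variant_b: str | None = None,
    score_type: str = "RPS",
) -> pd.DataFrame:
    """Per-sign mean of matched paired score differences (A - B), +-1.96 SE.

    Records are matched on (patient, test_day, sign); a key present in one
    table but not the other is an error, never a silent drop.  With A the
    no-covariate model and B a covariate variant, positive values mean the
    covariate model predicts better.
    """
    def pick(t, variant):
        df = t.records[t.records["score_type"] == score_type]
        df = df[df["sign"] != "state"]
        if variant is not None:
            df = df[df["model_variant"] == variant]
        if df["model_variant"].nunique() != 1:
            raise ValueError("each side must contain exactly one model variant; "
                             f"got {sorted(df['model_variant'].unique())}")
        return df

    a = pick(table_a, variant_a)
    b = pick(table_b, variant_b)
    keys = ["patient_id", "test_day", "sign"]
    merged = a.merge(b, on=keys, how="outer", suffixes=("_a", "_b"), indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        sample = unmatched[keys].head(5).to_dict("records")
        raise ValueError(f"{len(unmatched)} unmatched prediction keys, e.g. {sample}")
    merged["diff"] = merged["score_value_a"] - merged["score_value_b"]
    rows = []
    for sign, sub in merged.groupby("sign"):
        d = sub["diff"].to_numpy()
        se = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
        m = float(d.mean())
        rows.append({"sign": sign, "mean_diff": m, "se": se, "n": len(d),
                     "lo": m - 1.96 * se, "hi": m + 1.96 * se})
    return pd.DataFrame(rows)


def coefficient_table(models: Sequence[FittedSignModel]) -> pd.DataFrame:
    """Fitted covariate coefficients +-SE across single-covariate models.

    Positive coefficients mean an increase in the covariate is associated
    with a higher probability of more severe outcomes.  Models without
    standard errors are excluded with a warning.
    """
    rows = []
    for m in models:
        if len(m.spec.covariate_set) != 1:
            raise ValueError("coefficient_table expects single-covariate models")
        if m.gamma_se is None:
            warnings.warn(f"model for {m.spec.sign}/{m.spec.covariate_set[0]} "
                          "has no standard errors; excluded")
            continue
        rows.append({
            "sign": m.spec.sign,
            "covariate": m.spec.covariate_set[0],
            "coefficient": float(m.gamma[0]),
            "se": float(m.gamma_se[0]),
        })
    return pd.DataFrame(rows)
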
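"""Hierarchical linear model over nested dyads.

Each speaker contributes one articulation-space value; speakers are nested
in same-sex pairs, so observations within a pair share a random intercept:

    area_ij = X_ij beta + b_j + e_ij,   b_j ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with fixed effects for gender, country, age, speech duration, closeness
rating (CR) and autistic traits (AQ), estimated by restricted maximum
likelihood (REML).  Inference on the fixed effects uses t statistics with
Satterthwaite approximate denominator degrees of freedom, computed from the
REML information matrix of the two variance components.

Contrast coding defaults to *simple* coding — factor contrasts are
level-vs-reference but centered, and covariates are grand-mean centered —
so that the intercept estimates the grand mean rather than a reference
cell.  Treatment (reference-cell) coding is available via
``ModelConfig(coding="treatment")``; the coding used is always recorded in
``fit_meta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ModelConfig
from .errors import FitError, IntegrityError

__all__ = [
    "GENDER_LEVELS",
    "COUNTRY_LEVELS",
    "HLMResult",
    "build_design",
    "assemble_dataset",
    "fit_hlm",
    "descriptives",
]

GENDER_LEVELS = ("female", "male")  # gender 1 = female, gender 2 = male
COUNTRY_LEVELS = ("Italy", "India", "UK")  # Italy is the contrast reference
COVARIATES = ("age", "duration", "cr", "aq")

#: fixed-effect names in fit order, with the contrast label shown in reports
EFFECT_LABELS = {
    "(Intercept)": "(Intercept)",
    "gender": "2-1",
    "country_india": "India-Italy",
    "country_uk": "UK-Italy",
    "age": "Age",
    "duration": "Duration",
    "cr": "CR",
    "aq": "AQ",
}


@dataclass
class HLMResult:
    """Fixed-effect table plus variance components and fit metadata."""

    fixed_effects: pd.DataFrame  # name, effect, estimate, se, ci_lo, ci_hi, df, t, p
    var_pair: float
    var_resid: float
    n_obs: int
    n_pairs: int
    fit_meta: dict = field(default_factory=dict)


def build_design(
    df: pd.DataFrame, coding: str = "simple", center: bool = True
) -> tuple[np.ndarray, list[str], dict]:
    """Coded fixed-effects design matrix.

    Simple coding: gender male = +1/2, female = -1/2; country columns are
    indicator-minus-1/3 contrasts against Italy (so each coefficient is a
    level difference while the intercept sits at the unweighted grand
    mean); covariates centered at their sample means.  Treatment coding:
    plain 0/1 indicators with Italy/female reference and uncentered
    covariates.
    """
    if coding not in ("simple", "treatment"):
        raise ValueError("coding must be 'simple' or 'treatment'")
    n = len(df)
    gender = df["gender"].astype(str)
    country = df["country"].astype(str)
    bad_gender = set(gender) - set(GENDER_LEVELS)
    bad_country = set(country) - set(COUNTRY_LEVELS)
    if bad_gender or bad_country:
        raise IntegrityError(f"unknown factor levels: {bad_gender | bad_country}")
    male = (gender == "male").to_numpy(float)
    india = (country == "India").to_numpy(float)
    uk = (country == "UK").to_numpy(float)
    if coding == "simple":
        g = male - 0.5
        c_india = india - 1.0 / 3.0
        c_uk = uk - 1.0 / 3.0
    else:
        g, c_india, c_uk = male, india, uk
    cols = [np.ones(n), g, c_india, c_uk]
    means: dict[str, float] = {}
    for name in COVARIATES:
        x = df[name].to_numpy(float)
        mu = float(np.mean(x)) if (center and coding == "simple") else 0.0
        means[name] = mu
        cols.append(x - mu)
    X = np.column_stack(cols)
    names = ["(Intercept)", "gender", "country_india", "country_uk", *COVARIATES]
    return X, names, means


def assemble_dataset(features: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Join per-participant features onto the manifest and validate the
    dyadic design.

    Requires exactly one feature row per manifest row, unique participant
    ids, and pairs of exactly two members sharing gender and country.  Rows
    with missing AQ are kept (flagged ``aq_missing``); deletion happens only
    at fit time.
    """
    for frame, label in ((features, "features"), (manifest, "manifest")):
        if frame["participant_id"].duplicated().any():
            dups = frame.loc[frame["participant_id"].duplicated(), "participant_id"]
            raise IntegrityError(f"duplicate participant_id in {label}: {sorted(set(dups))}")
    missing = set(manifest["participant_id"]) - set(features["participant_id"])
    if missing:
        raise IntegrityError(f"manifest rows without feature rows: {sorted(missing)}")
    feat_cols = [c for c in features.columns if c == "participant_id" or c not in manifest.columns]
    df = manifest.merge(features[feat_cols], on="participant_id", how="inner")
    for pair_id, grp in df.groupby("pair_id"):
        if len(grp) != 2:
            raise IntegrityError(f"pair {pair_id} has {len(grp)} members, expected 2")
        if grp["gender"].nunique() != 1:
            raise IntegrityError(f"pair {pair_id} mixes genders")
        if grp["country"].nunique() != 1:
            raise IntegrityError(f"pair {pair_id} spans countries")
    df = df.copy()
    df["aq_missing"] = df["aq"].isna()
    return df


def _pair_indicator(pair_codes: np.ndarray) -> np.ndarray:
    """ZZ' for a random intercept per pair: 1 where two rows share a pair."""
    return (pair_codes[:, None] == pair_codes[None, :]).astype(float)


def _profile_sigma2(X: np.ndarray, pair_codes: np.ndarray, y: np.ndarray, tau2: float) -> float:
    """REML estimate of the residual variance with the pair variance held
    fixed.  At tau2 = 0 this is the exact OLS residual variance; otherwise a
    1-D REML profile is minimized numerically."""
    n, p = X.shape
    if tau2 == 0.0:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid) / (n - p)
    from scipy.optimize import minimize_scalar

    zzt = _pair_indicator(pair_codes)

    def nll(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        V = s2 * np.eye(n) + tau2 * zzt
        sign, logdet = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        return 0.5 * (logdet + np.linalg.slogdet(XtViX)[1] + r @ Vi @ r)

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s2_ols = float(resid @ resid) / (n - p)
    res = minimize_scalar(
        nll, bracket=(np.log(s2_ols) - 2, np.log(s2_ols) + 1), method="brent"
    )
    return float(np.exp(res.x))


def _satterthwaite(
    X: np.ndarray,
    pair_codes: np.ndarray,
    y: np.ndarray,
    tau2: float,
    sigma2: float,
    tau2_free: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS fixed effects at the REML variance estimates, their standard
    errors, and Satterthwaite degrees of freedom.

    For each coefficient, df = 2 g^2 / (grad' A grad) where g = Var(beta_j)
    as a function of the free variance components, grad its gradient, and A
    their asymptotic covariance (inverse REML information).  With the pair
    variance fixed (``tau2_free=False``) only sigma^2 varies and the formula
    reduces to the exact n - p when tau2 = 0.
    """
    n, p = X.shape
    zzt = _pair_indicator(pair_codes)
    V = sigma2 * np.eye(n) + tau2 * zzt
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    C = np.linalg.inv(XtVi @ X)  # Var(beta_hat)
    beta = C @ (XtVi @ y)
    se = np.sqrt(np.diag(C))
    P = Vi - XtVi.T @ C @ XtVi
    parts = (zzt, np.eye(n)) if tau2_free else (np.eye(n),)
    k = len(parts)
    info = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            info[a, b] = 0.5 * np.trace(P @ parts[a] @ P @ parts[b])
    try:
        acov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        acov = np.linalg.pinv(info)
    df = np.empty(p)
    for j in range(p):
        grads = np.empty(k)
        for a in range(k):
            M = C @ XtVi @ parts[a] @ XtVi.T @ C
            grads[a] = M[j, j]
        denom = float(grads @ acov @ grads)
        df[j] = 2.0 * C[j, j] ** 2 / denom if denom > 0 else float(n - p)
        if not np.isfinite(df[j]) or df[j] <= 0:
            df[j] = float(n - p)
    return beta, se, df


def fit_hlm(records: pd.DataFrame, config: ModelConfig | None = None) -> HLMResult:
    """REML fit of area_px ~ gender + country + age + duration + cr + aq
    with a random intercept per pair.

    Rows with any missing model variable are dropped listwise (the count is
    logged in ``fit_meta``).  Raises FitError for singular designs or
    non-convergence.
    """
    config = config or ModelConfig()
    model_cols = ["area_px", "pair_id", "gender", "country", *COVARIATES]
    data = records.dropna(subset=[c for c in model_cols if c in records.columns])
    n_dropped = len(records) - len(data)
    if data["pair_id"].nunique() < 3:
        raise FitError(f"need >= 3 pairs to fit, have {data['pair_id'].nunique()}")
    X, names, means = build_design(data, coding=config.coding)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise FitError(f"singular design; collinear columns: {bad}")
    y = data["area_px"].to_numpy(float)
    pair_codes = pd.factorize(data["pair_id"])[0]

    converged = True
    if config.var_pair is not None:
        tau2 = float(config.var_pair)
        sigma2 = _profile_sigma2(X, pair_codes, y, tau2)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=pair_codes)
            try:
                res = model.fit(reml=True)
            except Exception:
                try:
                    res = model.fit(reml=True, method="powell")
                except Exception as exc:
                    raise FitError(f"mixed model failed to fit: {exc}") from exc
        if not res.converged:
            raise FitError("REML estimation did not converge")
        converged = bool(res.converged)
        tau2 = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
        sigma2 = float(res.scale)

    beta, se, df = _satterthwaite(
        X, pair_codes, y, tau2, sigma2, tau2_free=config.var_pair is None
    )
    from scipy import stats

    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = stats.t.ppf(0.5 + config.ci_level / 2.0, df)
    table = pd.DataFrame(
        {
            "name": names,
            "effect": [EFFECT_LABELS[n] for n in names],
            "estimate": beta,
            "se": se,
            "ci_lo": beta - q * se,
            "ci_hi": beta + q * se,
            "df": df,
            "t": t,
            "p": p,
        }
    )
    return HLMResult(
        fixed_effects=table,
        var_pair=tau2,
        var_resid=sigma2,
        n_obs=len(data),
        n_pairs=int(data["pair_id"].nunique()),
        fit_meta={
            "method": "REML",
            "coding": config.coding,
            "ci_level": config.ci_level,
            "covariate_centers": means,
            "n_dropped_missing": n_dropped,
            "converged": converged,
            "var_pair_fixed": config.var_pair,
        },
    )


def descriptives(records: pd.DataFrame) -> pd.DataFrame:
    """N / mean / SD of CR, AQ and articulation space by country and gender,
    with per-country totals.  Missing values are excluded cell-wise, so AQ
    Ns reflect availability; an SD over a single observation is reported as
    missing."""
    if len(records) == 0:
        raise ValueError("descriptives requires a nonempty table")
    measures = {"cr": "CR", "aq": "AQ", "area_px": "Articulation space"}
    rows = []
    for country in sorted(records["country"].unique()):
        sub_c = records[records["country"] == country]
        groups = [(g, sub_c[sub_c["gender"] == g]) for g in GENDER_LEVELS]
        groups.append(("total", sub_c))
        for group_name, sub in groups:
            for col, label in measures.items():
                vals = sub[col].dropna().to_numpy(float)
                rows.append(
                    {
                        "country": country,
                        "group": group_name,
                        "measure": label,
                        "n": len(vals),
                        "mean": float(np.mean(vals)) if len(vals) else np.nan,
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
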
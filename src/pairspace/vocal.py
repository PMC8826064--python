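"""State-conditional calling: rates per age class and adult-female levels.

Call rates (calls/h per age class) are modelled per 10-min bin with a
negative-binomial (log link, quadratic mean-variance) random-intercept
model and a log offset of exposure in decimal hours, so the estimates are
rates regardless of bin length. Adult-female received levels — a proxy for
source level given consistent tag placement — are modelled with a Gaussian
linear mixed model fitted by REML. Both report least-squares state means
and the travelling-minus-resting contrast; calf rates carry an
``is_minimum`` flag because calls from a distant calf can be missed by the
tag on the female.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import MixedGLM, MixedGLMResults, NegativeBinomial, lsmeans, pairwise_contrasts
from .io import RunConfig
from .states import RESTING_MILLING, TRAVELLING

__all__ = [
    "RateModelResult",
    "LevelModelResult",
    "bin_call_counts",
    "compute_call_rates",
    "fit_rate_model",
    "fit_level_model",
    "state_contrast",
]

AGE_CLASSES = ("adult_female", "calf")
STATE_ORDER = (RESTING_MILLING, TRAVELLING)


@dataclass
class RateModelResult:
    """Negative-binomial mixed model of per-bin call counts for one class."""

    age_class: str
    lsmeans: pd.DataFrame        # level, estimate (log calls/h), se, response (calls/h)
    contrast: pd.DataFrame       # travelling - resting on the log scale, Wald z
    theta: float
    random_intercept_variance: float
    is_minimum: bool
    flags: list[str]
    results: MixedGLMResults


@dataclass
class LevelModelResult:
    """REML linear mixed model of adult-female received level (dB)."""

    lsmeans: pd.DataFrame
    contrast: pd.DataFrame       # t with df = n_groups - 1
    residual_variance: float
    random_intercept_variance: float
    flags: list[str]
    results: object


def bin_call_counts(
    calls: pd.DataFrame,
    states: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Count calls per (tag, bin, age class) over state-labelled bins.

    ``states`` needs tag_id, bin_index, t_start_s and state. Calls on a bin
    boundary follow the half-open bin rule. Bins with no calls contribute
    zero counts; every labelled bin appears for every age class, with
    exposure equal to the bin length in decimal hours.
    """
    config = config or RunConfig()
    bl = config.bin_length_s
    labelled = states.dropna(subset=["state"])
    rows = []
    for _, b in labelled.iterrows():
        t0 = b["t_start_s"]
        sel = calls[
            (calls["tag_id"].astype(str) == str(b["tag_id"]))
            & (calls["t_s"] >= t0)
            & (calls["t_s"] < t0 + bl)
        ]
        for ac in AGE_CLASSES:
            rows.append(
                {
                    "tag_id": b["tag_id"],
                    "bin_index": b["bin_index"],
                    "age_class": ac,
                    "state": b["state"],
                    "count": int((sel["age_class"] == ac).sum()),
                    "exposure_h": bl / 3600.0,
                }
            )
    return pd.DataFrame(rows)


def compute_call_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Empirical calls/h per (age class, state): total calls / total hours.

    States with zero exposure get a missing rate and an ``undefined`` flag.
    Calf rows are flagged ``is_minimum`` (distant calf calls can be missed
    by the tag on the female, so calf rates are floor estimates).
    """
    rows = []
    for ac in AGE_CLASSES:
        for st in STATE_ORDER:
            sel = counts[(counts["age_class"] == ac) & (counts["state"] == st)]
            hours = sel["exposure_h"].sum()
            n = sel["count"].sum()
            rows.append(
                {
                    "age_class": ac,
                    "state": st,
                    "n_calls": int(n),
                    "hours": float(hours),
                    "rate_per_h": (n / hours) if hours > 0 else np.nan,
                    "undefined": hours <= 0,
                    "is_minimum": ac == "calf",
                }
            )
    return pd.DataFrame(rows)


def fit_rate_model(
    counts: pd.DataFrame, age_class: str, n_quad: int = 32
) -> RateModelResult:
    """Fit the state call-rate model for one age class.

    Negative-binomial (Var = mu + mu^2/theta) log-link mixed model with a
    random intercept per tag and log-exposure offset. Least-squares means
    are back-transformed to calls/h; the contrast (travelling - resting) is
    reported on the log scale with Wald-z inference.
    """
    df = counts[counts["age_class"] == age_class].copy()
    zero_exp = df["exposure_h"] <= 0
    if zero_exp.any():
        import warnings

        warnings.warn(f"dropping {int(zero_exp.sum())} rows with zero exposure")
        df = df[~zero_exp]
    y = df["count"].to_numpy(float)
    travel = (df["state"] == TRAVELLING).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), travel])
    offset = np.log(df["exposure_h"].to_numpy(float))
    fit = MixedGLM(
        y, X, df["tag_id"].to_numpy(), NegativeBinomial(), offset=offset,
        exog_names=["intercept", "state_travelling"],
    ).fit(n_quad=n_quad)
    flags = list(fit.flags)
    if y.sum() == 0:
        flags.append("all-zero counts: boundary fit")
    design = np.array([[1.0, 0.0], [1.0, 1.0]])
    fe_cov = fit.cov_params[:2, :2]
    lsm = lsmeans(fit.fe_params, fe_cov, design, list(STATE_ORDER), backtransform=True)
    lsm = lsm.rename(columns={"response": "rate_per_h", "response_se": "rate_se"})
    con = pairwise_contrasts(fit.fe_params, fe_cov, design, list(STATE_ORDER), df=np.inf)
    theta = float(np.exp(fit.params[2]))
    return RateModelResult(
        age_class=age_class,
        lsmeans=lsm,
        contrast=con,
        theta=theta,
        random_intercept_variance=fit.random_effect_var,
        is_minimum=(age_class == "calf"),
        flags=flags,
        results=fit,
    )


def fit_level_model(calls_with_state: pd.DataFrame) -> LevelModelResult:
    """REML linear mixed model of adult-female received level vs state.

    Only adult-female calls enter (calf received levels confound source
    level with the unknown female-calf separation). The contrast uses a t
    reference with ``n_groups - 1`` degrees of freedom.
    """
    df = calls_with_state[
        (calls_with_state["age_class"] == "adult_female")
        & calls_with_state["state"].notna()
    ].copy()
    flags: list[str] = []
    present = [s for s in STATE_ORDER if (df["state"] == s).any()]
    if len(present) < 2:
        flags.append("a state has no adult-female calls: contrast undefined")
    y = df["received_level_db"].to_numpy(float)
    two_states = len(present) == 2
    if two_states:
        travel = (df["state"] == TRAVELLING).to_numpy(float)
        X = np.column_stack([np.ones(len(df)), travel])
        design = np.array([[1.0, 0.0], [1.0, 1.0]])
        labels = list(STATE_ORDER)
    else:
        X = np.ones((len(df), 1))  # single state: intercept-only mean
        design = np.array([[1.0]])
        labels = present
    groups = df["tag_id"].to_numpy()
    md = sm.MixedLM(y, X, groups=groups)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary RE variance retries are benign
        fit = md.fit(reml=True)
    fe = np.asarray(fit.fe_params, float)
    fe_cov = np.asarray(fit.cov_params())[: X.shape[1], : X.shape[1]]
    n_groups = len(np.unique(groups))
    lsm = lsmeans(fe, fe_cov, design, labels, backtransform=False)
    if two_states:
        con = pairwise_contrasts(fe, fe_cov, design, labels,
                                 df=float(n_groups - 1))
    else:
        con = pd.DataFrame()
    return LevelModelResult(
        lsmeans=lsm,
        contrast=con,
        residual_variance=float(fit.scale),
        random_intercept_variance=float(np.asarray(fit.cov_re)[0, 0]),
        flags=flags,
        results=fit,
    )


def state_contrast(
    fe_params: np.ndarray,
    fe_cov: np.ndarray,
    design_rows: np.ndarray,
    labels: list[str],
    df: float = np.inf,
) -> pd.DataFrame:
    """Adjusted pairwise comparisons of factor-level least-squares means.

    Thin facade over :func:`pairspace.glmm.pairwise_contrasts`: all
    pairwise contrasts with the multivariate-t equicoordinate adjustment;
    with exactly one contrast the adjusted p equals the unadjusted p.
    """
    return pairwise_contrasts(fe_params, fe_cov, design_rows, labels, df=df)


def rate_tables(models: list[RateModelResult]) -> pd.DataFrame:
    """One row per (age class, state) plus contrast columns, Table-style."""
    rows = []
    for m in models:
        by_level = {r["level"]: r for _, r in m.lsmeans.iterrows()}
        c = m.contrast.iloc[0]
        rows.append(
            {
                "age_class": m.age_class,
                "rate_resting": by_level[RESTING_MILLING]["rate_per_h"],
                "rate_resting_se": by_level[RESTING_MILLING]["rate_se"],
                "rate_travelling": by_level[TRAVELLING]["rate_per_h"],
                "rate_travelling_se": by_level[TRAVELLING]["rate_se"],
                "contrast_log": c["estimate"],
                "contrast_se": c["se"],
                "z": c["stat"],
                "p": c["p_adjusted"],
                "theta": m.theta,
                "is_minimum": m.is_minimum,
            }
        )
    return pd.DataFrame(rows)
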
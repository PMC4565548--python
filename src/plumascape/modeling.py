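"""OLS candidate models, AICc ranking, Akaike weights, term importance.

The response (feather δ²H, ‰) is regressed on subsets of
{ALT, PREC_TOT, SI, ABS_LAT (+ ABS_LAT²), REGION}.  The candidate set
is all-subsets under two structural rules: the quadratic latitude term
never appears without the linear one (marginality), and REGION enters
as an all-or-nothing block of dummy weights for regions 2..R against
region 1 (it is a factor).  With four free blocks and three latitude
states this yields 2⁴ × 3 = 48 candidates, including intercept-only.

Model comparison uses the small-sample-corrected Akaike criterion

    AICc = AIC + 2k(k+1)/(n − k − 1),   AIC = −2·logL + 2k,

with the Gaussian maximum-likelihood logL and ``k`` counting intercept,
slopes **and** the residual variance — the usual convention for
Gaussian OLS.  Akaike weights are exp(−Δᵢ/2) normalised over the
candidate set; the "supported set" is ΔAICc < 2; a term's relative
importance is the summed weight of the models containing it.

Because membership weights sum to 1, region dummies here are the fuzzy
weights w_2..w_R themselves: for a sample entirely inside region r the
dummy equals the classical 0/1 indicator, and fuzzy samples blend the
regional offsets linearly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelingError",
    "CollinearityError",
    "FULL_MODEL",
    "design_matrix",
    "fit_ols",
    "aicc_from_loglik",
    "enumerate_candidates",
    "rank_models",
    "relative_importance",
    "supported_set",
]

SUPPORTED_DELTA = 2.0  # ΔAICc defining the supported set


class ModelingError(ValueError):
    pass


class CollinearityError(ModelingError):
    """The design matrix is rank-deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which covariate blocks enter.

    ``lat_state``: 0 = no latitude, 1 = ABS_LAT, 2 = ABS_LAT + ABS_LAT².
    The intercept is always included.
    """

    alt: bool = False
    prec_tot: bool = False
    si: bool = False
    lat_state: int = 0
    region: bool = False

    def __post_init__(self) -> None:
        if self.lat_state not in (0, 1, 2):
            raise ModelingError("lat_state must be 0, 1 or 2")

    def terms(self, n_regions: int = 6) -> tuple[str, ...]:
        out: list[str] = []
        if self.lat_state >= 1:
            out.append("ABS_LAT")
        if self.lat_state == 2:
            out.append("ABS_LAT2")
        if self.alt:
            out.append("ALT")
        if self.prec_tot:
            out.append("PREC_TOT")
        if self.si:
            out.append("SI")
        if self.region:
            out.extend(f"w_{r}" for r in range(2, n_regions + 1))
        return tuple(out)

    def blocks(self) -> tuple[str, ...]:
        """Term blocks for importance bookkeeping (REGION is one block)."""
        out: list[str] = []
        if self.lat_state >= 1:
            out.append("ABS_LAT")
        if self.lat_state == 2:
            out.append("ABS_LAT2")
        if self.alt:
            out.append("ALT")
        if self.prec_tot:
            out.append("PREC_TOT")
        if self.si:
            out.append("SI")
        if self.region:
            out.append("REGION")
        return tuple(out)

    def label(self) -> str:
        return " + ".join(self.blocks()) or "intercept-only"


FULL_MODEL = ModelSpec(alt=True, prec_tot=True, si=True, lat_state=2, region=True)


def design_matrix(
    spec: ModelSpec, table: pd.DataFrame, n_regions: int = 6
) -> pd.DataFrame:
    """Design matrix with intercept for a candidate model.

    ABS_LAT² is derived from ABS_LAT; region columns are the fuzzy
    weights w_2..w_R (region 1 is the baseline and contributes only to
    the intercept).
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(table))}
    for term in spec.terms(n_regions):
        if term == "ABS_LAT2":
            cols[term] = table["ABS_LAT"].to_numpy(dtype=float) ** 2
        else:
            if term not in table.columns:
                raise ModelingError(f"covariate table lacks column {term!r}")
            cols[term] = table[term].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.index)


def aicc_from_loglik(loglik: float, n: int, k: int) -> float:
    """AICc with k counting all estimated parameters incl. σ²."""
    if n - k - 1 <= 0:
        raise ModelingError(f"AICc undefined: n={n} too small for k={k}")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelFit:
    """A fitted candidate model with selection statistics."""

    spec: ModelSpec
    n: int
    k: int  # estimated parameters: intercept + slopes + residual variance
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (t-based, 95% default)
    r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    f_pvalue: float
    loglik: float
    aic: float
    aicc: float
    sigma2_mle: float
    delta_aicc: float = np.nan  # filled by rank_models
    weight: float = np.nan  # filled by rank_models
    notes: list[str] = field(default_factory=list)

    def predict(self, table: pd.DataFrame, n_regions: int = 6) -> np.ndarray:
        X = design_matrix(self.spec, table, n_regions)
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()


def fit_ols(
    spec: ModelSpec,
    table: pd.DataFrame,
    response: str = "d2h",
    n_regions: int = 6,
    ci_level: float = 0.95,
) -> ModelFit:
    """Fit one candidate by ordinary least squares.

    Reports coefficient estimates with standard errors, t statistics
    and t-based confidence intervals; R², the overall F test against
    the intercept-only model; and AIC/AICc on the Gaussian likelihood.
    Raises :class:`CollinearityError` for rank-deficient designs.
    """
    y = table[response].to_numpy(dtype=float)
    X = design_matrix(spec, table, n_regions)
    n, p = X.shape
    if n <= p + 1:
        raise ModelingError(f"n = {n} too small for {p} mean parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        raise CollinearityError(
            f"rank-deficient design ({rank} < {p}) for terms {list(X.columns)}"
        )
    res = sm.OLS(y, X).fit()
    k = p + 1  # + residual variance
    notes = []
    if np.isclose(res.resid.var(ddof=0) if p < n else 0.0, 0.0):
        notes.append("zero-variance residuals: response fit exactly")
    ci = res.conf_int(alpha=1.0 - ci_level)
    ci.columns = ["lower", "upper"]
    return ModelFit(
        spec=spec,
        n=n,
        k=k,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=ci,
        r_squared=float(res.rsquared) if p > 1 else 0.0,
        f_statistic=float(res.fvalue) if p > 1 else np.nan,
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue) if p > 1 else np.nan,
        loglik=float(res.llf),
        aic=-2.0 * float(res.llf) + 2.0 * k,
        aicc=aicc_from_loglik(float(res.llf), n, k),
        sigma2_mle=float(np.mean(res.resid**2)),
        notes=notes,
    )


def enumerate_candidates(n_regions: int = 6) -> list[ModelSpec]:
    """All-subsets candidate list: 2⁴ binary blocks × 3 latitude states.

    Marginality (no ABS_LAT² without ABS_LAT) and the REGION block rule
    are built into :class:`ModelSpec`, so the enumeration is exhaustive
    and contains exactly 48 models, including intercept-only.
    """
    out = []
    for alt, prec, si, region in itertools.product((False, True), repeat=4):
        for lat_state in (0, 1, 2):
            out.append(
                ModelSpec(alt=alt, prec_tot=prec, si=si, lat_state=lat_state, region=region)
            )
    return out


def rank_models(fits: list[ModelFit]) -> list[ModelFit]:
    """Sort by AICc and attach ΔAICc and Akaike weights.

    All fits must be on the same data (same n); weights are
    exp(−Δᵢ/2) / Σⱼ exp(−Δⱼ/2).
    """
    if not fits:
        raise ModelingError("no fitted models to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ModelingError(f"models fitted on differing sample sizes: {sorted(ns)}")
    ranked = sorted(fits, key=lambda f: f.aicc)
    best = ranked[0].aicc
    rel = np.array([np.exp(-(f.aicc - best) / 2.0) for f in ranked])
    weights = rel / rel.sum()
    for f, w in zip(ranked, weights):
        f.delta_aicc = f.aicc - best
        f.weight = float(w)
    return ranked


def relative_importance(ranked: list[ModelFit]) -> dict[str, float]:
    """Per-block summed Akaike weight over the models containing it."""
    if any(np.isnan(f.weight) for f in ranked):
        raise ModelingError("rank_models must be applied before importances")
    importance: dict[str, float] = {}
    for f in ranked:
        for block in f.spec.blocks():
            importance[block] = importance.get(block, 0.0) + f.weight
    return importance


def supported_set(ranked: list[ModelFit], delta: float = SUPPORTED_DELTA) -> list[ModelFit]:
    """Models within ``delta`` AICc of the best one."""
    return [f for f in ranked if f.delta_aicc < delta]
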
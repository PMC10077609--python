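"""Multivariate logistic closure model with selection and diagnostics.

Fits the closure model (closed-by-follow-up ~ ownership + pediatrics +
teaching + population density + fertility rate + live births + nearest-
competitor travel time), screens multicollinearity (generalized variance
inflation factors) and linearity of the logit (Box–Tidwell), selects the
final model by backward stepwise AIC, adjusts Wald p-values by
Benjamini–Hochberg, and produces stratified LOWESS closure-probability
curves over annual live births.

Maximum likelihood is computed by Newton iteration (statsmodels Logit); the
fit contract is that the score (gradient of the log-likelihood) at the
solution has max-norm below 1e-8. Wald standard errors come from the observed
information; 95% CIs are exp(coef ± 1.96·SE). Reference levels: private
ownership, no pediatrics, non-teaching, low population density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile

SCORE_TOL = 1e-8
MAX_ITER = 100


class LogisticFitError(RuntimeError):
    """Raised when the closure model cannot be fitted (separation, rank loss)."""


@dataclass(frozen=True)
class Term:
    """One model term: a covariate that may expand to several indicator columns."""

    name: str
    kind: str  # "continuous" | "categorical"
    reference: str | None = None
    levels: tuple[str, ...] | None = None  # non-reference levels, display order

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical term {self.name!r} needs a reference level")


@dataclass(frozen=True)
class RegressionSpec:
    """Response, ordered terms, significance level, and GVIF cutoff."""

    response: str = "closed_by_followup"
    terms: tuple[Term, ...] = (
        Term("ownership", "categorical", reference="private", levels=("nonprofit", "public")),
        Term("has_pediatrics", "categorical", reference="False", levels=("True",)),
        Term("teaching", "categorical", reference="no", levels=("yes",)),
        Term("density_category", "categorical", reference="low", levels=("medium", "high")),
        Term("fertility_rate", "continuous"),
        Term("live_births", "continuous"),
        Term("min_interfacility_time", "continuous"),
    )
    alpha: float = 0.05
    # Fox–Monette scaled rule: remove a term when GVIF^(1/(2·df)) > sqrt(10).
    gvif_threshold: float = math.sqrt(10.0)

    def drop_term(self, name: str) -> "RegressionSpec":
        return RegressionSpec(
            response=self.response,
            terms=tuple(t for t in self.terms if t.name != name),
            alpha=self.alpha,
            gvif_threshold=self.gvif_threshold,
        )


@dataclass
class RegressionResult:
    """Coefficient table, per-term GVIFs, and model-fit statistics."""

    table: pd.DataFrame  # term, level, coef, se, odds_ratio, ci_low, ci_high, p_raw, p_bh
    gvif: dict[str, float]
    term_df: dict[str, int]
    log_likelihood: float
    null_log_likelihood: float
    null_deviance: float
    deviance: float
    aic: float
    bic: float
    mcfadden_adjusted_r2: float
    n_obs: int
    n_params: int
    spec: RegressionSpec
    params: pd.Series = field(repr=False, default=None)
    cov_params: pd.DataFrame = field(repr=False, default=None)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.spec.terms]


def build_design(cohort: pd.DataFrame, spec: RegressionSpec) -> tuple[pd.DataFrame, np.ndarray, dict[str, list[str]]]:
    """Design matrix with intercept, response vector, and term → columns map."""
    y = cohort[spec.response].astype(int).to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError(f"response {spec.response!r} must be binary")
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(cohort))}
    term_cols: dict[str, list[str]] = {}
    for term in spec.terms:
        if term.name not in cohort.columns:
            raise ValueError(f"covariate {term.name!r} missing from cohort")
        if term.kind == "continuous":
            cols[term.name] = cohort[term.name].to_numpy(float)
            term_cols[term.name] = [term.name]
        else:
            values = cohort[term.name].astype(str).to_numpy()
            observed = [lv for lv in pd.unique(values) if lv != term.reference]
            levels = list(term.levels) if term.levels is not None else sorted(observed)
            names = []
            for lv in levels:
                col = f"{term.name}[{lv}]"
                cols[col] = (values == lv).astype(float)
                names.append(col)
            term_cols[term.name] = names
    X = pd.DataFrame(cols, index=cohort.index)
    return X, y, term_cols


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise LogisticFitError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _separation_diagnostic(X: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in X.columns:
        if col == "(Intercept)":
            continue
        x = X[col].to_numpy(float)
        x1, x0 = x[y == 1], x[y == 0]
        if len(x1) == 0 or len(x0) == 0:
            continue
        if x1.min() > x0.max() or x0.min() > x1.max():
            return col
    return None


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_logistic(cohort: pd.DataFrame, spec: RegressionSpec) -> RegressionResult:
    """Maximum-likelihood logistic fit with Wald inference and BH adjustment.

    Raises :class:`LogisticFitError` on rank deficiency or (quasi-)complete
    separation, naming the offending columns.
    """
    X, y, term_cols = build_design(cohort, spec)
    _check_rank(X)
    if len(np.unique(y)) < 2:
        raise LogisticFitError("response has a single level; model not estimable")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            fit = model.fit(method="newton", maxiter=MAX_ITER, tol=1e-12, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        sep = _separation_diagnostic(X, y)
        hint = f"; separating covariate: {sep}" if sep else ""
        raise LogisticFitError(f"logistic fit failed: {exc}{hint}") from exc

    score = model.score(fit.params.to_numpy())
    if np.max(np.abs(score)) >= SCORE_TOL:
        sep = _separation_diagnostic(X, y)
        hint = f"; separating covariate: {sep}" if sep else ""
        raise LogisticFitError(
            f"score max-norm {np.max(np.abs(score)):.3g} above tolerance{hint}"
        )

    params = fit.params
    se = fit.bse
    pvals = fit.pvalues
    non_intercept = [c for c in X.columns if c != "(Intercept)"]
    adj = pd.Series(np.nan, index=X.columns)
    if non_intercept:
        adj[non_intercept] = bh_adjust(pvals[non_intercept].to_numpy())

    col_term = {c: t for t, cs in term_cols.items() for c in cs}
    rows = []
    for col in X.columns:
        coef = float(params[col])
        # near-separated fits can have huge Wald bounds; +-inf is the honest
        # report, not an overflow
        with np.errstate(over="ignore"):
            rows.append(
            {
                "term": col_term.get(col, col),
                "column": col,
                "coef": coef,
                "se": float(se[col]),
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - Z_95 * float(se[col]))),
                "ci_high": float(np.exp(coef + Z_95 * float(se[col]))),
                "p_raw": float(pvals[col]),
                "p_bh": float(adj[col]) if col != "(Intercept)" else math.nan,
            }
        )
    table = pd.DataFrame(rows)

    llf = float(fit.llf)
    n = len(y)
    k_total = X.shape[1]
    p_bar = y.mean()
    ll_null = float(n * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log1p(-p_bar))) if 0 < p_bar < 1 else 0.0
    gvifs, term_df = _gvif_all(X, term_cols)
    result = RegressionResult(
        table=table,
        gvif=gvifs,
        term_df=term_df,
        log_likelihood=llf,
        null_log_likelihood=ll_null,
        null_deviance=-2.0 * ll_null,
        deviance=-2.0 * llf,
        aic=2.0 * k_total - 2.0 * llf,
        bic=k_total * math.log(n) - 2.0 * llf,
        mcfadden_adjusted_r2=1.0 - (llf - (k_total - 1)) / ll_null,
        n_obs=n,
        n_params=k_total,
        spec=spec,
        params=params,
        cov_params=fit.cov_params(),
    )
    return result


def _gvif_all(X: pd.DataFrame, term_cols: Mapping[str, list[str]]) -> tuple[dict[str, float], dict[str, int]]:
    predictors = [c for cs in term_cols.values() for c in cs]
    gvifs: dict[str, float] = {}
    dfs: dict[str, int] = {t: len(cs) for t, cs in term_cols.items()}
    if len(term_cols) < 2:
        for t in term_cols:
            gvifs[t] = 1.0
        return gvifs, dfs
    arr = X[predictors].to_numpy(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    if np.any(~np.isfinite(corr)):
        raise LogisticFitError("constant predictor column; correlation matrix undefined")
    det_all = np.linalg.det(corr)
    if abs(det_all) < 1e-14:
        raise LogisticFitError("singular predictor correlation matrix; GVIF undefined")
    index = {c: i for i, c in enumerate(predictors)}
    for term, cs in term_cols.items():
        idx = [index[c] for c in cs]
        rest = [i for i in range(len(predictors)) if i not in idx]
        det_term = np.linalg.det(corr[np.ix_(idx, idx)])
        det_rest = np.linalg.det(corr[np.ix_(rest, rest)]) if rest else 1.0
        gvifs[term] = float(det_term * det_rest / det_all)
    return gvifs, dfs


def gvif(result: RegressionResult, term: str) -> float:
    """Generalized variance inflation factor of one model term.

    Determinant-ratio definition over the predictor correlation matrix;
    reduces to the classical VIF for single-column terms, and to 1 for a
    single-term model.
    """
    if term not in result.gvif:
        raise KeyError(f"unknown term {term!r}")
    return result.gvif[term]


def screen_multicollinearity(
    result: RegressionResult,
) -> list[str]:
    """Terms whose scaled GVIF, GVIF^(1/(2·df)), exceeds the spec threshold."""
    flagged = []
    for term, g in result.gvif.items():
        df = result.term_df[term]
        if g ** (1.0 / (2.0 * df)) > result.spec.gvif_threshold:
            flagged.append(term)
    return flagged


@dataclass
class LinearityDiagnostic:
    term: str
    statistic: float
    p_value: float
    passed: bool
    shift: float  # added to the covariate before taking logs, 0 if unneeded


def check_logit_linearity(
    cohort: pd.DataFrame, continuous_term: str, response: str = "closed_by_followup", alpha: float = 0.05
) -> LinearityDiagnostic:
    """Box–Tidwell check: Wald test of the x·log(x) interaction term.

    Non-positive covariate values are shifted to a minimum of 1 before the
    logarithm; the shift is reported in the diagnostic.
    """
    x = cohort[continuous_term].to_numpy(float)
    if len(np.unique(x)) <= 10:
        raise ValueError(f"{continuous_term!r} has too few distinct values for the check")
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - x.min()
        x = x + shift
    xlogx = x * np.log(x)
    X = pd.DataFrame({"(Intercept)": 1.0, "x": x, "x_log_x": xlogx})
    y = cohort[response].astype(int).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(method="newton", maxiter=MAX_ITER, tol=1e-12, disp=False)
    z = float(fit.params["x_log_x"] / fit.bse["x_log_x"])
    p = float(fit.pvalues["x_log_x"])
    return LinearityDiagnostic(
        term=continuous_term, statistic=z, p_value=p, passed=p > alpha, shift=shift
    )


def model_fit_stats(result: RegressionResult) -> dict[str, float]:
    """AIC, BIC, and McFadden adjusted pseudo-R² of a fitted model.

    McFadden adjusted R² = 1 − (LL_model − k)/LL_null with k the number of
    parameters excluding the intercept; AIC/BIC count all parameters.
    """
    return {
        "AIC": result.aic,
        "BIC": result.bic,
        "mcfadden_adjusted_r2": result.mcfadden_adjusted_r2,
    }


def backward_stepwise_aic(
    cohort: pd.DataFrame, spec: RegressionSpec
) -> tuple[RegressionResult, list[dict]]:
    """Backward elimination by AIC over whole terms.

    At each step the term whose removal yields the lowest AIC is dropped,
    as long as some removal lowers the AIC; categorical terms leave as
    complete indicator blocks. AIC ties are broken by dropping the term
    listed later in the spec. Returns the final fit and the elimination
    trace [(step, dropped term, AIC after drop), ...].
    """
    current_spec = spec
    current = fit_logistic(cohort, current_spec)
    trace: list[dict] = [{"step": 0, "dropped": None, "aic": current.aic}]
    step = 0
    while len(current_spec.terms) > 0:
        candidates = []
        for pos, term in enumerate(current_spec.terms):
            cand_spec = current_spec.drop_term(term.name)
            cand = fit_logistic(cohort, cand_spec)
            candidates.append((cand.aic, pos, term.name, cand, cand_spec))
        # Lowest AIC wins; among ties prefer the larger position (later term).
        best = min(candidates, key=lambda c: (round(c[0], 10), -c[1]))
        if best[0] < current.aic:
            step += 1
            current, current_spec = best[3], best[4]
            trace.append({"step": step, "dropped": best[2], "aic": best[0]})
        else:
            break
    return current, trace


@dataclass
class SmoothCurve:
    """LOWESS closure-probability curve for one pediatrics stratum."""

    x: np.ndarray
    y: np.ndarray
    span: float
    stratum: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.y)):
            raise ValueError("smoothed curve contains non-finite values")


def lowess_curve(
    cohort: pd.DataFrame,
    stratify_by_pediatrics: bool = True,
    span: float = 2.0 / 3.0,
    grid: np.ndarray | None = None,
    response: str = "closed_by_followup",
    x_var: str = "live_births",
    min_stratum_size: int = 20,
) -> dict[str, SmoothCurve]:
    """Locally weighted linear smooth of the closure indicator on live births.

    Returns one deterministic curve per stratum ("pediatrics" /
    "no_pediatrics", or "all"), evaluated on ``grid`` (default: 200 points
    spanning the stratum's observed range). Strata below the minimum size are
    skipped with a warning.
    """
    if stratify_by_pediatrics:
        groups = {
            "pediatrics": cohort[cohort["has_pediatrics"].astype(bool)],
            "no_pediatrics": cohort[~cohort["has_pediatrics"].astype(bool)],
        }
    else:
        groups = {"all": cohort}
    curves: dict[str, SmoothCurve] = {}
    for name, sub in groups.items():
        if len(sub) < min_stratum_size:
            warnings.warn(
                f"stratum {name!r} has {len(sub)} < {min_stratum_size} observations; skipped",
                stacklevel=2,
            )
            continue
        x = sub[x_var].to_numpy(float)
        y = sub[response].astype(float).to_numpy()
        g = grid if grid is not None else np.linspace(x.min(), x.max(), 200)
        smoothed = _sm_lowess(y, x, frac=span, it=0, xvals=np.asarray(g, float))
        curves[name] = SmoothCurve(x=np.asarray(g, float), y=smoothed, span=span, stratum=name)
    return curves
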
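"""Poisson regression with offset, SIR/SIRR estimation and the study tests.

Three nested exposure-response models are fitted to the analysis cells
(municipality x birth period), each with ``ln(E)`` as offset so that
coefficients are log rate ratios relative to the standardized expectation:

categorical
    one dummy per exposure category, no intercept; ``exp(delta_k)`` is the
    SIR of category ``k`` (equal to ``O_k / E_k`` when unadjusted).
semiquantitative
    intercept plus the births-weighted mean density of the cell's category
    (``Y_k``), in units of 10 percentage points.
continuous
    intercept plus the cell's own density, in units of 10 percentage
    points, so ``exp(beta')`` is the SIRR per 10-point density increase.
null
    intercept only.

Likelihood-ratio tests compare categorical vs null (heterogeneity of the
category SIRs, df = K - 1) and categorical vs semiquantitative (departure
from log-linearity, df = K - 2); both use the chi-square upper tail.  The
slope of the continuous model is tested one-sided (H0: beta' <= 0 against
H1: beta' > 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "sir_wald",
    "fit_poisson",
    "adjusted_fit",
    "category_sir_table",
    "heterogeneity_test",
    "departure_from_loglinearity",
    "sirr_per_10pct",
    "FitResult",
    "TestResult",
    "SirrEstimate",
]

MODELS = ("categorical", "semiquantitative", "continuous", "null")

#: Covariate name -> (cells column, value coded 1, design column name)
_COVARIATE_CODING = {
    "urban_unit": ("urban_unit_class", "paris_uu", "paris_uu"),
    "uv": ("uv_class", "high", "uv_high"),
    "deprivation": ("deprivation_class", "Q5_most_deprived", "deprived_q5"),
}


def sir_wald(
    observed: float, expected: float, alpha: float = 0.05
) -> tuple[float, float, float]:
    """SIR with a log-scale Wald confidence interval.

    ``SIR = O / E``; for ``O > 0`` the interval is
    ``SIR * exp(-+ z_{1-alpha/2} / sqrt(O))`` (the standard error of
    ``log SIR`` in the saturated Poisson model is ``1 / sqrt(O)``).  For
    ``O = 0`` the SIR is 0 and the interval is unavailable (NaN bounds).
    """
    if expected <= 0:
        raise ValidationError("expected count must be > 0 for a SIR")
    if observed < 0:
        raise ValidationError("observed count must be >= 0")
    sir = observed / expected
    if observed == 0:
        return 0.0, float("nan"), float("nan")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z / math.sqrt(observed)
    return sir, sir * math.exp(-half), sir * math.exp(half)


@dataclass
class FitResult:
    """A fitted Poisson model.

    ``params``/``cov`` are indexed by design column names; ``exposure_terms``
    names the columns that carry the exposure (category dummies or the
    density term), as opposed to intercept and adjustment columns.
    """

    model: str
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_params: int
    n_cells: int
    n_dropped: int
    exposure_terms: tuple[str, ...]

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


@dataclass
class TestResult:
    test: str
    statistic: float
    df: int
    p_value: float
    sidedness: str


@dataclass
class SirrEstimate:
    """SIRR per 10-percentage-point density increase with CI and one-sided p."""

    sirr: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    beta: float
    se: float


def _design_matrix(
    cells: pd.DataFrame, model: str, categories=None, adjust: tuple[str, ...] = ()
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    cols: dict[str, np.ndarray] = {}
    exposure: list[str] = []
    if model == "categorical":
        if "category" not in cells:
            raise UsageError("categorical model requires a 'category' cell column")
        for k in sorted(cells["category"].dropna().unique()):
            name = f"cat_{int(k)}"
            cols[name] = (cells["category"] == k).to_numpy(dtype=float)
            exposure.append(name)
    elif model == "semiquantitative":
        if categories is None:
            raise UsageError("semiquantitative model requires the category system")
        cols["intercept"] = np.ones(len(cells))
        y = cells["category"].map(categories.category_weighted_mean)
        if y.isna().any():
            raise UsageError("cells contain categories unknown to the category system")
        cols["y10"] = y.to_numpy(dtype=float) / 10.0
        exposure.append("y10")
    elif model == "continuous":
        if "density_pct" not in cells:
            raise UsageError("continuous model requires a 'density_pct' cell column")
        cols["intercept"] = np.ones(len(cells))
        cols["y10"] = cells["density_pct"].to_numpy(dtype=float) / 10.0
        exposure.append("y10")
    elif model == "null":
        cols["intercept"] = np.ones(len(cells))
    else:
        raise UsageError(f"unknown model {model!r}")

    for cov in adjust:
        if cov not in _COVARIATE_CODING:
            raise UsageError(f"unknown adjustment covariate {cov!r}")
        column, one_value, name = _COVARIATE_CODING[cov]
        if column not in cells:
            raise UsageError(f"cells lack covariate column {column!r}")
        cols[name] = (cells[column] == one_value).to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=cells.index)
    return X, tuple(exposure)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # locate dependent columns via the QR diagonal
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] <= tol]
        raise FitError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_poisson(
    cells: pd.DataFrame,
    model: str,
    categories=None,
    adjust: tuple[str, ...] = (),
    tol: float = 1e-10,
    maxiter: int = 100,
) -> FitResult:
    """Maximum-likelihood Poisson fit with ``ln(E)`` offset.

    Cells with ``E <= 0`` (no person-time) carry no information under the
    offset parameterisation and are dropped, with the count logged.  The
    fit is deterministic: IRLS from the default start, tolerance ``tol`` on
    the relative deviance change.
    """
    usable = cells[cells["expected"] > 0]
    n_dropped = len(cells) - len(usable)
    if n_dropped:
        logger.info("fit_poisson(%s): dropped %d cells with E = 0", model, n_dropped)
    if not len(usable):
        raise FitError("no cells with positive expected count")

    X, exposure = _design_matrix(usable, model, categories, adjust)
    _check_rank(X)
    offset = np.log(usable["expected"].to_numpy(dtype=float))
    y = usable["observed"].to_numpy(dtype=float)

    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = glm.fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        raise FitError(
            f"Poisson fit ({model}) did not converge in {maxiter} iterations; "
            f"deviance trace: {getattr(res, 'fit_history', {}).get('deviance', [])}"
        )
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return FitResult(
        model=model,
        params=params,
        cov=cov,
        llf=float(res.llf),
        n_params=X.shape[1],
        n_cells=len(usable),
        n_dropped=n_dropped,
        exposure_terms=exposure,
    )


def adjusted_fit(
    cells: pd.DataFrame,
    model: str,
    covariates: tuple[str, ...],
    categories=None,
) -> FitResult:
    """Convenience wrapper: :func:`fit_poisson` with adjustment covariates."""
    return fit_poisson(cells, model, categories=categories, adjust=tuple(covariates))


def category_sir_table(cells: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-category observed, expected, SIR and Wald CI (unadjusted).

    This is the closed form of the unadjusted categorical model:
    ``exp(delta_k) = O_k / E_k``.  A category with ``O = 0`` has SIR 0 and
    NaN CI bounds.
    """
    if "category" not in cells:
        raise UsageError("cells lack a 'category' column")
    grouped = cells.groupby("category").agg(
        O=("observed", "sum"), E=("expected", "sum")
    )
    rows = []
    for k, row in grouped.iterrows():
        if row["E"] > 0:
            sir, lo, hi = sir_wald(row["O"], row["E"], alpha)
        else:
            sir, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "category": int(k),
                "O": int(row["O"]),
                "E": float(row["E"]),
                "SIR": sir,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).sort_values("category", ignore_index=True)


def _likelihood_ratio(
    richer: FitResult, smaller: FitResult, name: str
) -> TestResult:
    df = richer.n_params - smaller.n_params
    if df <= 0:
        raise UsageError(
            f"{name}: models are not nested ({richer.model} has "
            f"{richer.n_params} parameters, {smaller.model} has {smaller.n_params})"
        )
    if richer.n_cells != smaller.n_cells:
        raise UsageError(f"{name}: fits do not share the same cells")
    statistic = 2.0 * (richer.llf - smaller.llf)
    if statistic < -1e-6:
        raise UsageError(
            f"{name}: richer model has lower likelihood; models are not nested"
        )
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(name, statistic, df, p, "two_sided")


def heterogeneity_test(fit_categorical: FitResult, fit_null: FitResult) -> TestResult:
    """LR test of SIR heterogeneity: categorical model vs intercept-only null."""
    if fit_categorical.model != "categorical" or fit_null.model != "null":
        raise UsageError("heterogeneity test needs a categorical and a null fit")
    return _likelihood_ratio(fit_categorical, fit_null, "heterogeneity")


def departure_from_loglinearity(
    fit_categorical: FitResult, fit_semiquantitative: FitResult
) -> TestResult:
    """LR test of the categorical model against the log-linear-in-``Y_k`` model."""
    if (
        fit_categorical.model != "categorical"
        or fit_semiquantitative.model != "semiquantitative"
    ):
        raise UsageError(
            "departure test needs a categorical and a semiquantitative fit"
        )
    return _likelihood_ratio(
        fit_categorical, fit_semiquantitative, "departure_from_loglinearity"
    )


def sirr_per_10pct(
    fit: FitResult, alpha: float = 0.05, term: str = "y10"
) -> SirrEstimate:
    """SIRR per 10-point density increase from a continuous (or Eq. 2) fit.

    The one-sided p-value tests H0: beta' <= 0 against H1: beta' > 0 (upper
    normal tail of the Wald z statistic).
    """
    if term not in fit.params.index:
        raise UsageError(f"fit has no term {term!r}")
    beta = float(fit.params[term])
    se = fit.se(term)
    z = stats.norm.ppf(1 - alpha / 2)
    p_one = float(stats.norm.sf(beta / se)) if se > 0 else float("nan")
    return SirrEstimate(
        sirr=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_one_sided=p_one,
        beta=beta,
        se=se,
    )


def covariate_sirr(fit: FitResult, covariate: str, alpha: float = 0.05) -> SirrEstimate:
    """Rate ratio of an adjustment covariate (e.g. Paris urban unit vs other)."""
    if covariate not in _COVARIATE_CODING:
        raise UsageError(f"unknown covariate {covariate!r}")
    term = _COVARIATE_CODING[covariate][2]
    if term not in fit.params.index:
        raise UsageError(f"fit was not adjusted for {covariate!r}")
    beta = float(fit.params[term])
    se = fit.se(term)
    z = stats.norm.ppf(1 - alpha / 2)
    return SirrEstimate(
        sirr=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_one_sided=float(stats.norm.sf(beta / se)) if se > 0 else float("nan"),
        beta=beta,
        se=se,
    )
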
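"""The study's statistical battery.

Normality screening (Kolmogorov-Smirnov with estimated parameters and a
seeded Monte-Carlo null), two-sample Student's t (pooled by default, Welch
by flag, raw samples or published mean/SD/n summaries), Pearson/Spearman
correlation, 2x2 categorical tests (Pearson chi-square, Yates, Fisher
exact), and multivariable linear/logistic regression with per-0.1
odds-ratio rescaling for the ALPS predictor.

Conventions: two-sided p throughout; alpha = 0.05; no multiple-testing
correction. Regression fits are delegated to statsmodels (OLS / Logit
maximum likelihood via IRLS) behind this module's result types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SummaryGroup",
    "TestResult",
    "CorrelationResult",
    "LogisticFit",
    "LinearFit",
    "lilliefors_statistic",
    "ks_normality",
    "ttest_two_sample",
    "correlation",
    "categorical_2x2",
    "logistic_fit",
    "linear_fit",
    "covariate_screen",
]


@dataclass(frozen=True)
class SummaryGroup:
    """Published group summary: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd <= 0:
            raise ValueError("SD must be positive")

    @classmethod
    def from_sample(cls, x) -> "SummaryGroup":
        x = np.asarray(x, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    method: str


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression summary.

    ``or_ci`` rows are (OR, low, high) per predictor; ``rescale`` maps a
    predictor name to the unit for which the OR is additionally reported
    (e.g. {"ipsilateral_alps": 0.1} gives OR per 0.1 increase via
    exp(0.1 * beta)).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    or_ci: pd.DataFrame
    converged: bool
    n_iter: int
    rescaled_or: dict[str, tuple[float, float, float]] = field(default_factory=dict)


@dataclass
class LinearFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    residuals: np.ndarray


# ---------------------------------------------------------------------------
# normality


def lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal fitted to the sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(ecdf_hi - cdf, cdf - ecdf_lo)))


def simulate_lilliefors_null(n: int, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the estimated-parameter KS statistic at size n.

    The statistic is computed on standardized samples, so the null does not
    depend on the true mean/SD; one table serves any normal sample of size n.
    """
    samples = rng.standard_normal((n_sims, n))
    samples.sort(axis=1)
    z = (samples - samples.mean(axis=1, keepdims=True)) / samples.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf(z)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return np.max(np.maximum(hi - cdf, cdf - lo), axis=1)


def ks_normality(x, n_monte_carlo: int = 1000, seed: int = 0) -> TestResult:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    The naive KS null is anticonservative when mean/SD are estimated from
    the sample, so the p-value comes from a seeded Monte-Carlo null
    (Lilliefors-style): p = (1 + #{null stats >= observed}) / (n_sims + 1).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    null = simulate_lilliefors_null(x.size, n_monte_carlo, rng)
    p = (1 + int(np.sum(null >= stat))) / (n_monte_carlo + 1)
    return TestResult(statistic=stat, p=p, method=f"ks_normality_mc(seed={seed})")


# ---------------------------------------------------------------------------
# two-sample t


def ttest_two_sample(a, b, pooled: bool = True) -> TestResult:
    """Two-sample t-test on raw samples or :class:`SummaryGroup` pairs.

    Pooled-variance Student's t by default; ``pooled=False`` gives Welch.
    Summary and raw forms agree exactly when the summaries are the raw
    moments.
    """
    ga = a if isinstance(a, SummaryGroup) else SummaryGroup.from_sample(a)
    gb = b if isinstance(b, SummaryGroup) else SummaryGroup.from_sample(b)
    if pooled:
        sp2 = ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / (ga.n + gb.n - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        se = np.sqrt(sp2 * (1 / ga.n + 1 / gb.n))
        df = ga.n + gb.n - 2
        method = "student_t_pooled"
    else:
        va, vb = ga.sd**2 / ga.n, gb.sd**2 / gb.n
        se = np.sqrt(va + vb)
        if se == 0:
            raise ValueError("zero variance in both groups")
        df = (va + vb) ** 2 / (va**2 / (ga.n - 1) + vb**2 / (gb.n - 1))
        method = "welch_t"
    t = (ga.mean - gb.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p=float(p), method=method, df=float(df))


# ---------------------------------------------------------------------------
# correlation


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson r (t-based p) or Spearman rho (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p), method=method)


# ---------------------------------------------------------------------------
# categorical


def categorical_2x2(a: int, b: int, c: int, d: int, method: str = "auto") -> TestResult:
    """Association test on the 2x2 table [[a, b], [c, d]].

    Methods: ``pearson`` (uncorrected chi-square), ``yates`` (continuity
    corrected), ``fisher`` (exact, two-sided by the point-probability rule),
    or ``auto`` — Fisher when any expected cell count is below 5, else
    Pearson, the usual applied-statistics convention.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("cells must be non-negative integers")
    if table.sum() == 0:
        raise ValueError("all cells are zero")
    if method == "auto":
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        method = "fisher" if np.any(expected < 5) else "pearson"
    if method == "fisher":
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return TestResult(statistic=float("nan"), p=float(p), method="fisher_exact")
    if method in ("pearson", "yates"):
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise ValueError("degenerate table: a zero margin")
        chi2, p, df, _ = sps.chi2_contingency(table, correction=(method == "yates"))
        return TestResult(statistic=float(chi2), p=float(p), method=f"chi2_{method}", df=float(df))
    raise ValueError("method must be 'pearson', 'yates', 'fisher' or 'auto'")


# ---------------------------------------------------------------------------
# regression


def _as_design(X, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if X.columns.dtype.kind in "iu":
        X.columns = [f"x{i}" for i in X.columns]
    const = X.std(ddof=0) == 0
    if const.any() and not (add_intercept is False):
        raise ValueError(f"constant predictor(s): {list(X.columns[const])}")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    return X

def logistic_fit(
    X,
    y,
    add_intercept: bool = True,
    rescale: Optional[dict[str, float]] = None,
    max_iter: int = 100,
) -> LogisticFit:
    """Binary logistic regression by maximum likelihood.

    Wald standard errors come from the observed information; odds ratios
    are exp(beta) with 95% CIs, plus optional per-unit rescaling
    OR_u = exp(u * beta) for the predictors named in ``rescale``. Perfect
    separation and singular designs are reported as errors naming the
    problem.
    """
    Xd = _as_design(X, add_intercept)
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(y) <= Xd.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(Xd.values) < Xd.shape[1]:
        raise ValueError("singular design matrix")
    model = sm.Logit(y, Xd)
    try:
        res = model.fit(disp=0, maxiter=max_iter)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if np.any(np.abs(res.params) > 50):
        worst = res.params.abs().idxmax()
        raise ValueError(f"perfect separation suspected: diverging coefficient for {worst!r}")
    ci = res.conf_int()
    or_ci = pd.DataFrame(
        {
            "OR": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
        }
    )
    rescaled = {}
    for name, unit in (rescale or {}).items():
        if name not in res.params.index:
            raise KeyError(f"no predictor named {name!r}")
        beta, se = res.params[name], res.bse[name]
        z = sps.norm.ppf(0.975)
        rescaled[name] = (
            float(np.exp(unit * beta)),
            float(np.exp(unit * (beta - z * se))),
            float(np.exp(unit * (beta + z * se))),
        )
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        or_ci=or_ci,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        rescaled_or=rescaled,
    )


def linear_fit(X, y, add_intercept: bool = True) -> LinearFit:
    """Ordinary least squares with t-based per-coefficient p-values."""
    Xd = _as_design(X, add_intercept)
    y = np.asarray(y, dtype=float).ravel()
    if np.linalg.matrix_rank(Xd.values) < Xd.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, Xd).fit()
    return LinearFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
    )


# ---------------------------------------------------------------------------
# covariate screening


def covariate_screen(
    candidates: pd.DataFrame,
    outcome,
    threshold: float = 0.1,
    always_include: Sequence[str] = ("age", "sex", "baseline_nihss"),
) -> list[str]:
    """Univariate screen for multivariable model building.

    Each candidate column is tested against the binary outcome: binary
    candidates by a 2x2 test, continuous ones by a two-sample t-test across
    outcome groups. Candidates with p < ``threshold`` are selected; the
    ``always_include`` names (established adjusters) are kept regardless
    when present in the table.
    """
    y = np.asarray(outcome).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary for screening")
    selected: list[str] = []
    for col in candidates.columns:
        x = candidates[col]
        if col in always_include:
            continue
        vals = x.dropna()
        x0 = x[y == 0].dropna().to_numpy(dtype=float)
        x1 = x[y == 1].dropna().to_numpy(dtype=float)
        if len(x0) < 2 or len(x1) < 2:
            continue
        if set(np.unique(vals)) <= {0, 1}:
            res = categorical_2x2(
                int((x1 == 1).sum()), int((x1 == 0).sum()),
                int((x0 == 1).sum()), int((x0 == 0).sum()),
            )
        else:
            try:
                res = ttest_two_sample(x1, x0)
            except ValueError:
                continue
        if res.p < threshold:
            selected.append(col)
    kept = [c for c in always_include if c in candidates.columns]
    return kept + selected
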
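"""Synthetic per-subject cohort tables for the statistics stage.

Subjects come in two groups: acute spontaneous intracerebral hemorrhage
(sICH) patients and healthy controls (HC). Continuous variables are drawn
from a Gaussian copula whose latent correlations are calibrated (by
Gauss-Hermite quadrature and root finding) so the OUTPUT Pearson
correlations match the configured targets despite non-normal marginals.
Marginals are normal (ALPS, age), zero-truncated normal moment-matched to
the configured mean/SD (NIHSS, disease duration), or moment-matched
lognormal (volumes, whose SD ~ mean indicates right skew a zero-truncated
normal cannot reach).

The 90-day outcome (modified Rankin Scale <= 2, "favorable") follows a
logistic model on the lesion-side ALPS index; the slope encodes the
configured odds ratio per 0.1 ALPS and the intercept is calibrated by
bisection so the expected favorable fraction matches its target.

The relative edema ratio is computed from the simulated volumes, never
drawn independently, preserving its definitional identity; its correlation
with ALPS is therefore emergent rather than enforced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "Marginal",
    "CohortParams",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "REQUIRED_COLUMNS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "subject_id", "group", "age", "female",
    "hypertension", "diabetes", "hyperlipemia", "smoking",
    "hemorrhage_side", "ipsilateral_alps", "contralateral_alps", "average_alps",
    "hemorrhage_ml", "edema_ml", "relative_edema_ratio",
    "baseline_nihss", "duration_days", "mrs_90d",
]


# ---------------------------------------------------------------------------
# marginal distributions


@dataclass(frozen=True)
class Marginal:
    """A continuous marginal with configured mean/SD and a distribution family.

    ``family``: 'normal', 'truncnorm' (zero-truncated, moment-matched so the
    truncated distribution reproduces mean/SD), or 'lognormal'
    (moment-matched).
    """

    mean: float
    sd: float
    family: str = "normal"
    lower: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SD must be positive")
        if self.family not in ("normal", "truncnorm", "lognormal"):
            raise ValueError(f"unknown marginal family {self.family!r}")

    def frozen(self):
        if self.family == "normal":
            return sps.norm(loc=self.mean, scale=self.sd)
        if self.family == "lognormal":
            s2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - s2 / 2
            return sps.lognorm(s=np.sqrt(s2), scale=np.exp(mu))
        mu, sigma = _truncnorm_match(self.mean - self.lower, self.sd)
        p_trunc = sps.norm.cdf(-mu / sigma)
        if p_trunc > 1e-6:
            logger.info(
                "truncnorm marginal (mean=%.3g, sd=%.3g): %.1f%% of the underlying "
                "normal mass truncated at %.3g", self.mean, self.sd, 100 * p_trunc, self.lower,
            )
        return sps.truncnorm(a=-mu / sigma, b=np.inf, loc=self.lower + mu, scale=sigma)

    def ppf(self, u):
        return self.frozen().ppf(u)


@lru_cache(maxsize=64)
def _truncnorm_match(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so the [0, inf)-truncated normal has the
    requested mean and SD. Feasible only for SD/mean < 1 (exponential limit)."""
    ratio = target_sd / target_mean
    if ratio >= 0.999:
        raise ValueError(
            f"truncated normal cannot reach SD/mean = {ratio:.3f} (limit 1); "
            "use the lognormal family"
        )

    # X = mu + sigma * Z with Z standard normal truncated to [alpha, inf) and
    # mu = -alpha * sigma, so X >= 0 with mean sigma * (E[Z] - alpha); the
    # coefficient of variation sqrt(Var Z) / (E[Z] - alpha) rises monotonically
    # from 0 (alpha -> -inf) to 1 (exponential tail limit, alpha -> +inf)
    def cv(alpha: float) -> float:
        m, v = sps.truncnorm.stats(alpha, np.inf, moments="mv")
        return float(np.sqrt(v) / (m - alpha)) - ratio

    alpha = optimize.brentq(cv, -38.0, 38.0, xtol=1e-12)
    m_std, v_std = sps.truncnorm.stats(alpha, np.inf, moments="mv")
    sigma = target_sd / float(np.sqrt(v_std))
    mu = -alpha * sigma
    assert abs(sigma * (float(m_std) - alpha) - target_mean) < 1e-6 * max(1.0, target_mean)
    return mu, sigma


# ---------------------------------------------------------------------------
# latent-correlation calibration

_GH_NODES = 64


def _gh_grid():
    z, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w = w / w.sum()
    return z, w


def _safe_cdf(z):
    # extreme quadrature nodes round norm.cdf to exactly 0/1, whose ppf is
    # infinite; their Gauss-Hermite weights are ~1e-25, so clipping is lossless
    return np.clip(sps.norm.cdf(z), 1e-13, 1 - 1e-13)


def _output_corr(marg_i: Marginal, marg_j: Marginal, rho: float) -> float:
    """Pearson correlation of the transformed pair under latent corr rho."""
    z, w = _gh_grid()
    gi = marg_i.ppf(_safe_cdf(z))
    gj = marg_j.ppf(_safe_cdf(z))
    mi, mj = float(gi @ w), float(gj @ w)
    si = float(np.sqrt((gi - mi) ** 2 @ w))
    sj = float(np.sqrt((gj - mj) ** 2 @ w))
    # z_j | z_i ~ N(rho z_i, 1 - rho^2); integrate over the 2-D grid
    zz = rho * z[:, None] + np.sqrt(max(0.0, 1 - rho**2)) * z[None, :]
    gj2 = marg_j.ppf(_safe_cdf(zz))
    cov = float((w[:, None] * w[None, :] * (gi[:, None] - mi) * (gj2 - mj)).sum())
    return cov / (si * sj)


@lru_cache(maxsize=256)
def latent_correlation(marg_i: Marginal, marg_j: Marginal, target_r: float) -> float:
    """Latent Gaussian correlation producing the target output Pearson r."""
    if target_r == 0.0:
        return 0.0
    if abs(target_r) >= 1:
        raise ValueError("|r| must be < 1")

    def f(rho):
        return _output_corr(marg_i, marg_j, rho) - target_r

    try:
        return optimize.brentq(f, -0.999, 0.999, xtol=1e-6)
    except ValueError as exc:
        raise ValueError(
            f"target correlation {target_r} is unreachable for these marginals"
        ) from exc


# ---------------------------------------------------------------------------
# parameters


def _default_marginals() -> dict[str, Marginal]:
    return {
        "ipsilateral_alps": Marginal(1.34, 0.24, "normal"),
        "contralateral_alps": Marginal(1.48, 0.21, "normal"),
        "hc_alps": Marginal(1.46, 0.22, "normal"),
        "hemorrhage_ml": Marginal(22.1, 20.1, "lognormal"),
        "edema_ml": Marginal(24.2, 26.2, "lognormal"),
        "age_sich": Marginal(58.0, 15.0, "normal"),
        "age_hc": Marginal(58.0, 7.0, "normal"),
        "baseline_nihss": Marginal(5.6, 5.2, "truncnorm"),
        "duration_days": Marginal(5.3, 3.1, "truncnorm"),
    }


def _default_correlations() -> dict[tuple[str, str], float]:
    return {
        ("ipsilateral_alps", "hemorrhage_ml"): -0.426,
        ("ipsilateral_alps", "edema_ml"): -0.592,
        ("ipsilateral_alps", "contralateral_alps"): 0.30,
        ("hemorrhage_ml", "edema_ml"): 0.70,
    }


def _default_prevalence() -> dict[str, dict[str, float]]:
    return {
        "sich": {"female": 14 / 55, "hypertension": 40 / 55, "diabetes": 7 / 55,
                 "hyperlipemia": 5 / 55, "smoking": 14 / 55},
        "hc": {"female": 25 / 97, "hypertension": 64 / 97, "diabetes": 17 / 97,
               "hyperlipemia": 22 / 97, "smoking": 25 / 97},
    }


@dataclass
class CohortParams:
    """Generator configuration; defaults reproduce the study's summary
    distributions (group sizes, means/SDs, correlation targets, outcome
    model with OR = 1.686 per 0.1 ALPS and a ~70.9% favorable fraction)."""

    n_sich: int = 55
    n_hc: int = 97
    n_subtentorial: int = 9
    marginals: dict[str, Marginal] = field(default_factory=_default_marginals)
    correlations: dict[tuple[str, str], float] = field(default_factory=_default_correlations)
    alps_ratio_target_r: float = -0.489  # emergent (ratio is computed, not drawn)
    prevalence: dict[str, dict[str, float]] = field(default_factory=_default_prevalence)
    or_per_01_alps: float = 1.686
    favorable_fraction: float = 39 / 55
    beta_age: float = 0.0
    beta_nihss: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_sich, self.n_hc) < 2:
            raise ValueError("group sizes must be >= 2")
        if not (0 <= self.n_subtentorial <= self.n_sich):
            raise ValueError("n_subtentorial must lie in [0, n_sich]")
        for pair, r in self.correlations.items():
            if abs(r) >= 1:
                raise ValueError(f"|r| must be < 1 for pair {pair}")

    @property
    def beta_alps(self) -> float:
        """Logistic slope per unit ALPS implied by the per-0.1 odds ratio."""
        return float(np.log(self.or_per_01_alps) / 0.1)


def calibrate_intercept(params: CohortParams) -> float:
    """Bisection for the logistic intercept.

    Solves E[expit(b0 + eta)] = favorable fraction, where the linear
    predictor eta = beta_alps * ALPS + beta_age * age + beta_nihss * NIHSS is
    treated as Gaussian with moments implied by the marginals (exact for the
    default model, where only the normal ALPS term enters).
    """
    m_alps = params.marginals["ipsilateral_alps"]
    m_age = params.marginals["age_sich"]
    m_nihss = params.marginals["baseline_nihss"]
    mean_eta = (params.beta_alps * m_alps.mean + params.beta_age * m_age.mean
                + params.beta_nihss * m_nihss.mean)
    var_eta = ((params.beta_alps * m_alps.sd) ** 2 + (params.beta_age * m_age.sd) ** 2
               + (params.beta_nihss * m_nihss.sd) ** 2)
    z, w = _gh_grid()
    eta = mean_eta + np.sqrt(var_eta) * z

    def frac(b0: float) -> float:
        return float(expit(b0 + eta) @ w) - params.favorable_fraction

    return optimize.brentq(frac, -60.0, 60.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# simulation


def _correlated_normals(n: int, names: list[str], latent: dict[tuple[str, str], float],
                        rng: np.random.Generator) -> pd.DataFrame:
    k = len(names)
    R = np.eye(k)
    for (a, b), rho in latent.items():
        ia, ib = names.index(a), names.index(b)
        R[ia, ib] = R[ib, ia] = rho
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin <= 0:
        worst = max(latent.items(), key=lambda kv: abs(kv[1]))
        raise ValueError(
            f"correlation matrix is not positive definite (min eigenvalue "
            f"{eigmin:.3g}); check the pair {worst[0]} (latent r = {worst[1]:.3f})"
        )
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, k)) @ L.T
    return pd.DataFrame(Z, columns=names)


def simulate_cohort(params: CohortParams, seed: int = 0) -> pd.DataFrame:
    """Draw a full cohort table, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    marg = params.marginals

    # latent correlations matched so output Pearson r hits the targets
    latent = {
        pair: latent_correlation(marg[pair[0]], marg[pair[1]], r)
        for pair, r in params.correlations.items()
    }

    sich_vars = ["ipsilateral_alps", "contralateral_alps", "hemorrhage_ml",
                 "edema_ml", "age_sich", "baseline_nihss", "duration_days"]
    Z = _correlated_normals(params.n_sich, sich_vars, latent, rng)
    U = pd.DataFrame(sps.norm.cdf(Z), columns=sich_vars)
    sich = pd.DataFrame({v: marg[v].ppf(U[v].to_numpy()) for v in sich_vars})
    sich = sich.rename(columns={"age_sich": "age"})

    n_sub = params.n_subtentorial
    sides = np.concatenate([
        rng.choice(["left", "right"], size=params.n_sich - n_sub),
        np.repeat("subtentorial", n_sub),
    ])
    rng.shuffle(sides)
    sich["hemorrhage_side"] = sides
    subtentorial = sich["hemorrhage_side"] == "subtentorial"
    sich["average_alps"] = (sich["ipsilateral_alps"] + sich["contralateral_alps"]) / 2
    sich["relative_edema_ratio"] = sich["edema_ml"] / sich["hemorrhage_ml"]

    # outcome: logistic on the lesion-side index (average for subtentorial)
    b0 = calibrate_intercept(params)
    driver = np.where(subtentorial, sich["average_alps"], sich["ipsilateral_alps"])
    eta = (b0 + params.beta_alps * driver + params.beta_age * sich["age"]
           + params.beta_nihss * sich["baseline_nihss"])
    favorable = rng.random(params.n_sich) < expit(eta)
    sich["mrs_90d"] = np.where(favorable, rng.integers(0, 3, params.n_sich),
                               rng.integers(3, 7, params.n_sich))

    # ipsi/contra undefined for subtentorial lesions
    sich.loc[subtentorial, ["ipsilateral_alps", "contralateral_alps"]] = np.nan

    for flag, p in params.prevalence["sich"].items():
        sich[flag] = (rng.random(params.n_sich) < p).astype(int)
    sich["group"] = "sICH"

    hc = pd.DataFrame({
        "age": marg["age_hc"].ppf(rng.random(params.n_hc)),
        "average_alps": marg["hc_alps"].ppf(rng.random(params.n_hc)),
    })
    for flag, p in params.prevalence["hc"].items():
        hc[flag] = (rng.random(params.n_hc) < p).astype(int)
    hc["group"] = "HC"
    hc["hemorrhage_side"] = "none"

    table = pd.concat([sich, hc], ignore_index=True)
    table["subject_id"] = [f"S{i:05d}" for i in range(len(table))]
    table = table.reindex(columns=REQUIRED_COLUMNS)
    validate_cohort(table)
    return table


# ---------------------------------------------------------------------------
# IO and validation


def validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing mandatory column(s): {missing}")
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    mrs = table["mrs_90d"].dropna()
    if not mrs.isin(range(7)).all():
        bad = sorted(set(mrs) - set(range(7)))
        raise ValueError(f"mrs_90d outside 0..6: {bad}")
    for col in ("hemorrhage_ml", "edema_ml"):
        if (table[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")
    for col in ("ipsilateral_alps", "contralateral_alps", "average_alps"):
        if (table[col].dropna() <= 0).any():
            raise ValueError(f"non-positive ALPS values in {col}")
    hc = table[table["group"] == "HC"]
    lesion_cols = ["hemorrhage_ml", "edema_ml", "relative_edema_ratio",
                   "ipsilateral_alps", "contralateral_alps"]
    if hc[lesion_cols].notna().any().any():
        raise ValueError("HC records must not carry lesion fields")


def write_cohort(table: pd.DataFrame, path) -> None:
    """CSV with full float precision so the round trip is lossless."""
    validate_cohort(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort file") from exc
    validate_cohort(table)
    return table
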
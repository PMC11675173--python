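"""Brain–behavior statistics: partial correlations, permutation-based
family-wise error correction, and hierarchical regression.

Partial correlation residualizes both variables on the covariates plus
an intercept and correlates the residuals; its p-value uses the t
distribution with n − k − 2 degrees of freedom.  Family-wise error over
a family of (metric, score) tests is controlled with a Freedman–Lane
max-|r| permutation scheme: score residuals are permuted, refitted onto
the covariates, and the familywise maximum |partial r| across tests
forms the null distribution.  The hierarchical regression ladder fits
nested OLS models block by block and tests each ΔR² with the F-change
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_N_PERMUTATIONS = 10_000

#: Reading scores standardized by age (standard scores) versus not.
AGE_STANDARDIZED_SCORES = frozenset({"swe_std", "pde_std", "pc_std"})
RAW_SCORES = frozenset({"ran_items_per_sec"})

STANDARD_COVARIATES = ("sex", "mean_fa", "handedness")
RAN_COVARIATES = ("age_years", "sex", "mean_fa", "handedness")


class CollinearityError(ValueError):
    """Covariate/design matrix is rank deficient."""


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class StatTestResult:
    metric: str
    score: str
    r: float
    p_uncorrected: float
    p_fwe: float
    n: int
    covariates: tuple[str, ...]


@dataclass(frozen=True)
class StatReport:
    tests: tuple[StatTestResult, ...]
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": t.metric,
                    "score": t.score,
                    "partial_r": t.r,
                    "p_uncorrected": t.p_uncorrected,
                    "p_fwe": t.p_fwe,
                    "n": t.n,
                    "covariates": "+".join(t.covariates),
                }
                for t in self.tests
            ]
        )


@dataclass(frozen=True)
class RegressionModelFit:
    block: tuple[str, ...]
    predictors: tuple[str, ...]
    r_squared: float
    delta_r_squared: float
    f_change: float
    p_change: float
    n: int


@dataclass(frozen=True)
class RegressionLadder:
    models: tuple[RegressionModelFit, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": k + 1,
                    "block": "+".join(m.block),
                    "r_squared": m.r_squared,
                    "delta_r_squared": m.delta_r_squared,
                    "f_change": m.f_change,
                    "p_change": m.p_change,
                    "n": m.n,
                }
                for k, m in enumerate(self.models)
            ]
        )


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

def _design(covariates: np.ndarray | None, n: int,
            names: tuple[str, ...] = ()) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    Z = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        # name the offending columns if names were given
        bad = []
        for j in range(covariates.shape[1]):
            sub = np.column_stack([np.ones(n), np.delete(covariates, j, axis=1)])
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(Z):
                bad.append(names[j] if j < len(names) else f"column {j}")
        raise CollinearityError(
            f"collinear covariate columns: {bad or 'unknown'}"
        )
    return Z


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after projecting out covariates.

    p-value from t = r·sqrt(df/(1−r²)) with df = n − k − 2 (k covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    cov = None
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match x length")
        k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations for {k} covariates")
    Z = _design(cov, n, covariate_names)
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance; cannot correlate")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r, p, n, tuple(covariate_names))


def covariate_set(score_name: str, cohort: pd.DataFrame | None = None,
                  ran_includes_only_age: bool = False) -> tuple[str, ...]:
    """Covariate list for a reading score.

    Age-standardized scores: sex, mean FA, handedness.  RAN (raw
    items/second, not age-normed) additionally includes age; setting
    ``ran_includes_only_age`` reduces the RAN set to age alone.
    Constant columns in ``cohort`` (e.g. all right-handed) are dropped
    with a warning.
    """
    if score_name in AGE_STANDARDIZED_SCORES:
        covs = list(STANDARD_COVARIATES)
    elif score_name in RAW_SCORES:
        covs = ["age_years"] if ran_includes_only_age else list(RAN_COVARIATES)
    else:
        raise ValueError(f"unknown score {score_name!r}")
    if cohort is not None:
        kept = []
        for c in covs:
            if c in cohort.columns and cohort[c].nunique() <= 1:
                warnings.warn(f"covariate {c!r} is constant; dropped")
            else:
                kept.append(c)
        covs = kept
    return tuple(covs)


# ---------------------------------------------------------------------------
# Permutation FWE (Freedman–Lane, max statistic)
# ---------------------------------------------------------------------------

def permutation_fwe(
    tests: list[tuple[str, str]],
    cohort: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    ran_includes_only_age: bool = False,
) -> StatReport:
    """Permutation-corrected partial correlations for a family of
    (metric, score) tests.

    For every permutation the score residuals (after covariate
    projection) are shuffled with a shared index permutation, refitted
    onto the covariates (Freedman–Lane), and the familywise max |r|
    recorded; corrected p = (1 + #{perm max ≥ |r_obs|}) / (1 + n_perm).
    """
    if not tests:
        raise ValueError("empty test family")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    prepared = []
    for metric, score in tests:
        covs = covariate_set(score, cohort, ran_includes_only_age)
        Z = _design(cohort[list(covs)].to_numpy(dtype=float) if covs else None,
                    n, covs)
        x = cohort[metric].to_numpy(dtype=float)
        y = cohort[score].to_numpy(dtype=float)
        rx = _residualize(x, Z)
        H = Z @ np.linalg.pinv(Z)
        ry = y - H @ y
        denom_x = np.sqrt(rx @ rx)
        if denom_x == 0 or (ry @ ry) == 0:
            raise ValueError(f"zero variance in test ({metric}, {score})")
        r_obs = float((rx @ ry) / (denom_x * np.sqrt(ry @ ry)))
        prepared.append((metric, score, covs, rx, ry, H, r_obs, len(covs)))

    # familywise max |r| per permutation
    max_r = np.zeros(n_perm)
    for metric, score, covs, rx, ry, H, r_obs, k in prepared:
        E = ry[perms]                      # (n_perm, n) permuted residuals
        R = E - E @ H.T                    # re-residualize on covariates
        num = R @ rx
        den = np.sqrt((R * R).sum(axis=1)) * np.sqrt(rx @ rx)
        r_perm = np.abs(num / den)
        np.maximum(max_r, r_perm, out=max_r)

    results = []
    for metric, score, covs, rx, ry, H, r_obs, k in prepared:
        df = n - k - 2
        if abs(r_obs) >= 1.0:
            p_unc = 0.0
        else:
            t = r_obs * np.sqrt(df / (1.0 - r_obs**2))
            p_unc = float(2 * stats.t.sf(abs(t), df))
        p_fwe = float((1 + np.sum(max_r >= abs(r_obs) - 1e-15)) / (1 + n_perm))
        # corrected p can never undercut the single-test p
        p_fwe = max(p_fwe, p_unc)
        results.append(StatTestResult(metric, score, r_obs, p_unc, p_fwe,
                                      n, covs))
    return StatReport(tuple(results), n_perm, seed)


# ---------------------------------------------------------------------------
# Hierarchical regression
# ---------------------------------------------------------------------------

def hierarchical_regression(
    y: np.ndarray,
    blocks: list[tuple[tuple[str, ...], np.ndarray]],
) -> RegressionLadder:
    """Nested OLS ladder with ΔR² F-change tests.

    ``blocks`` is an ordered list of (names, columns) predictor blocks;
    model k regresses y on the first k blocks plus an intercept.
    F-change for block k (size q):
    F = (ΔR²/q) / ((1 − R²_k) / (n − p_k − 1)).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not blocks:
        raise ValueError("need at least one predictor block")
    names_seen: set[str] = set()
    fits = []
    X = np.ones((n, 1))
    r2_prev = 0.0
    all_names: list[str] = []
    for block_names, cols in blocks:
        cols = np.atleast_2d(np.asarray(cols, dtype=float))
        if cols.shape[0] != n:
            cols = cols.T
        if cols.shape[0] != n:
            raise ValueError(f"block {block_names} rows do not match y")
        overlap = names_seen & set(block_names)
        if overlap:
            raise ValueError(f"blocks overlap on predictors {sorted(overlap)}")
        names_seen |= set(block_names)
        all_names.extend(block_names)
        X = np.column_stack([X, cols])
        p_full = X.shape[1] - 1
        if p_full >= n - 1:
            raise ValueError("cumulative predictors must be < n - 2")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CollinearityError(
                f"design became rank deficient after adding block {block_names}"
            )
        fit = sm.OLS(y, X).fit()
        r2 = float(fit.rsquared)
        q = cols.shape[1]
        dr2 = r2 - r2_prev
        df_resid = n - p_full - 1
        if 1.0 - r2 <= 0:
            f_change, p_change = np.inf, 0.0
        else:
            f_change = (dr2 / q) / ((1.0 - r2) / df_resid)
            p_change = float(stats.f.sf(f_change, q, df_resid))
        fits.append(RegressionModelFit(
            block=tuple(block_names),
            predictors=tuple(all_names),
            r_squared=r2,
            delta_r_squared=dr2,
            f_change=float(f_change),
            p_change=p_change,
            n=n,
        ))
        r2_prev = r2
    return RegressionLadder(tuple(fits))
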
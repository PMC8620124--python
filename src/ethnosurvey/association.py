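"""Statistical harness: proportion tests, independence tests with a
small-expected-count fallback, and Poisson / quasi-Poisson count regression.

The independence test mirrors common survey practice: a Pearson chi-square
(no continuity correction) when every expected cell count reaches 5, and
Fisher's exact test otherwise — exact for 2x2 tables, Monte-Carlo over
Patefield-sampled tables with fixed margins for larger ones.

Counts (e.g. trees owned) are modelled by a log-link Poisson GLM; when the
Pearson dispersion statistic exceeds a threshold the standard errors are
rescaled by sqrt(dispersion), i.e. the quasi-Poisson working model.  Point
estimates are identical under both families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "CountModelFit",
    "equal_proportions_test",
    "independence_test",
    "fit_count_model",
    "dispersion_check",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str
    note: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def equal_proportions_test(counts) -> TestResult:
    """Chi-square goodness of fit of k category counts against equal shares."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if counts.sum() <= 0:
        raise ValueError("total count must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    stat, p = stats.chisquare(counts)
    return TestResult(float(stat), float(counts.size - 1), float(p),
                      "chi-square equal proportions")


def _log_table_probability(table: np.ndarray) -> float:
    """Log conditional probability of an r x c table given its margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def independence_test(table, seed: int = 0, n_mc: int = 100_000) -> TestResult:
    """Chi-square or Fisher's exact test of independence on an r x c table.

    Pearson chi-square (uncorrected) when all expected counts are >= 5;
    otherwise Fisher's exact test — exact for 2x2, Monte-Carlo with ``n_mc``
    Patefield table draws and the given seed for larger tables.  Rows or
    columns with a zero margin are dropped (noted in the result).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("table entries must be non-negative integers")
    note = ""
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        note = "zero-margin rows/columns dropped"
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")

    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(rows, cols) / n
    if np.all(expected >= 5):
        stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return TestResult(float(stat), float(dof), float(p), "chi-square", note)

    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table.astype(int))
        return TestResult(float("nan"), None, float(p), "fisher-exact",
                          (note + "; " if note else "") + "expected count < 5")
    # Monte-Carlo Fisher: p = share of margin-preserving tables no more
    # probable than the observed one (add-one correction keeps p in (0, 1])
    rng = np.random.default_rng(seed)
    log_obs = _log_table_probability(table)
    dist = stats.random_table(rows.astype(int), cols.astype(int))
    samples = dist.rvs(size=n_mc, random_state=rng)
    log_p = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
             - gammaln(n + 1) - gammaln(samples + 1).sum(axis=(1, 2)))
    hits = int(np.sum(log_p <= log_obs + 1e-9))
    p = (hits + 1) / (n_mc + 1)
    return TestResult(float("nan"), None, float(p), "fisher-monte-carlo",
                      (note + "; " if note else "") + "expected count < 5")


# ---------------------------------------------------------------------------
# Count regression
# ---------------------------------------------------------------------------

@dataclass
class CountModelFit:
    """Result of a log-link count regression.

    ``coefficients`` are on the log scale; ``dispersion`` is the Pearson
    statistic sum(pearson residual^2)/(n - p); ``family_used`` records
    whether quasi-Poisson SE scaling was applied.  ``deviance_trace`` holds
    the IRLS deviance sequence (non-increasing after the first step).
    """

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    dispersion: float
    family_used: str
    fitted_means: np.ndarray
    deviance: float
    df_resid: int
    deviance_trace: list[float] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for term, est in self.coefficients.items():
            se = self.std_errors[term]
            t = est / se if se > 0 else np.inf
            if self.family_used == "quasipoisson":
                p = 2 * stats.t.sf(abs(t), self.df_resid)
            else:
                p = 2 * stats.norm.sf(abs(t))
            rows.append({"term": term, "estimate": est, "std_error": se,
                         "t_value": t, "p_value": p})
        return pd.DataFrame(rows).set_index("term")


class FitError(RuntimeError):
    pass


def _design_matrix(design, n_obs: int) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix from a factor table (or vector).

    ``None`` or a constant factor yields the intercept-only design."""
    if design is None:
        return np.ones((n_obs, 1)), ["Intercept"]
    if isinstance(design, pd.Series):
        design = design.to_frame()
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame({"factor": list(design)})
    design = design.reset_index(drop=True)
    X = pd.DataFrame({"Intercept": np.ones(len(design))})
    names = ["Intercept"]
    for col in design.columns:
        series = design[col]
        if pd.api.types.is_numeric_dtype(series):
            X[col] = series.to_numpy(dtype=float)
            names.append(str(col))
            continue
        levels = sorted(series.astype(str).unique())
        for level in levels[1:]:  # first level is the reference
            name = f"{col}[{level}]"
            X[name] = (series.astype(str) == level).astype(float)
            names.append(name)
    return X.to_numpy(dtype=float), names


def fit_count_model(counts, design=None, dispersion_threshold: float = 1.5,
                    tol: float = 1e-8, maxiter: int = 100) -> CountModelFit:
    """Fit a log-link Poisson GLM of counts on categorical/numeric factors.

    Fitting is by iteratively reweighted least squares to relative tolerance
    ``tol``.  If the Pearson dispersion exceeds ``dispersion_threshold`` the
    standard errors are scaled by sqrt(dispersion) and ``family_used``
    switches to ``"quasipoisson"``; point estimates are unchanged.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if y.sum() == 0:
        raise ValueError("all-zero response: model mean is degenerate")
    X, names = _design_matrix(design, y.size)
    if X.shape[0] != y.size:
        raise ValueError("response and design sizes differ")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        import warnings

        with warnings.catch_warnings():
            # saturated fixtures legitimately fit perfectly
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, tol=tol, tol_criterion="params",
                            full_output=True)
    except Exception as exc:  # pragma: no cover - numeric failure path
        raise FitError(f"IRLS failed: {exc}") from exc
    # the first two history entries are initialisation placeholders (inf and
    # the deviance at the data-dependent starting mu), not coefficient iterates
    trace = [float(d) for d in res.fit_history.get("deviance", [])][2:]
    if not res.converged:
        raise FitError(
            f"IRLS did not converge in {maxiter} iterations; deviance trace: "
            f"{trace}")
    mu = np.asarray(res.fittedvalues)
    df_resid = int(res.df_resid)
    pearson = float(np.sum((y - mu) ** 2 / mu) / df_resid) if df_resid > 0 else 0.0
    se = np.asarray(res.bse)
    family = "poisson"
    if pearson > dispersion_threshold:
        family = "quasipoisson"
        se = se * np.sqrt(pearson)
    return CountModelFit(
        coefficients=dict(zip(names, map(float, res.params))),
        std_errors=dict(zip(names, map(float, se))),
        dispersion=pearson,
        family_used=family,
        fitted_means=mu,
        deviance=float(res.deviance),
        df_resid=df_resid,
        deviance_trace=trace,
    )


def dispersion_check(fit: CountModelFit) -> float:
    """Pearson dispersion statistic of a fitted count model."""
    return fit.dispersion
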
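"""Statistical pipeline: factorial GLM, regressions, one-tailed tests, gating.

The reporter analyses ask which population parameters the mating-pathway
response actually tracks.  A normal-family, identity-link GLM (ordinary
least squares) is fitted with the two printed model forms —
``Y ~ 1 + ρ_α + ρ_a + ρ_α·ρ_a`` and ``Y ~ 1 + θ_α + ρ_T`` — and each term
is assessed with an F statistic on (1, df_residual) degrees of freedom,
computed as the squared coefficient t (a Wald test, not sequential sums of
squares).  Regression of aggregation/mating fractions on the sex ratio is
through the origin (a zero sex ratio means no possible partners), with the
R² convention based on the uncentered total sum of squares.  Group
comparisons use pooled-variance one-tailed t-tests with Bonferroni
correction, or one-tailed Mann–Whitney U tests (exact by enumeration for
small samples, normal approximation with tie correction otherwise).
Flow-cytometry arithmetic — FSC normalization and two-colour gating with
the aggregated fraction pairs/(pairs + free MATa) — completes the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, t as t_dist

__all__ = [
    "GLMResult",
    "RegressionResult",
    "TTestResult",
    "MannWhitneyResult",
    "GateResult",
    "SingularDesignError",
    "fit_glm",
    "regression_through_origin",
    "linear_regression",
    "one_tailed_t_test",
    "bonferroni_adjust",
    "mann_whitney_u",
    "gate_events",
    "normalize_fluorescence",
]


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""


@dataclass
class GLMResult:
    """Per-term Wald F-tests from a normal/identity GLM fit."""

    terms: list
    coef: dict
    fvalues: dict  # F on (1, df_resid) per term
    pvalues: dict
    df_resid: int
    rss: float
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": pd.Series(self.coef),
                "F": pd.Series(self.fvalues),
                "p": pd.Series(self.pvalues),
            }
        )


def _design_matrix(table: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(table))]
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            col = np.ones(len(table))
            for p in parts:
                col = col * table[p].to_numpy(dtype=float)
        else:
            col = table[term].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def fit_glm(table: pd.DataFrame, terms, response: str = "reporter") -> GLMResult:
    """Fit ``response ~ 1 + terms`` by OLS and test each term with F = t².

    ``terms`` is an ordered list of column names; an interaction is written
    ``"a:b"`` (elementwise product).  With n observations and p parameters
    (intercept included) the residual degrees of freedom are n − p, so the
    printed factorial analyses (72 observations) give d.f. 68 for the
    four-parameter interaction model and 69 for the three-parameter one.
    """
    terms = list(terms)
    y = table[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains missing or non-finite values")
    X = _design_matrix(table, terms)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for {p} parameters, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify which term(s) are linearly dependent on the rest
        bad = []
        for j, term in enumerate(terms, start=1):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(term)
        raise SingularDesignError(
            f"design is rank deficient; collinear terms: {bad or terms}"
        )
    model = sm.OLS(y, X).fit()
    names = ["Intercept"] + terms
    coef = dict(zip(names, model.params))
    fvals = dict(zip(names, np.asarray(model.tvalues) ** 2))
    pvals = {}
    for name, f in fvals.items():
        # F(1, df) tail == two-sided t tail; keep p in (0, 1]
        tval = math.sqrt(f)
        pvals[name] = max(2.0 * t_dist.sf(tval, model.df_resid), 5e-324)
    return GLMResult(
        terms=names,
        coef=coef,
        fvalues=fvals,
        pvalues=pvals,
        df_resid=int(model.df_resid),
        rss=float(model.ssr),
        n_obs=n,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float | None
    r_squared: float
    se_regression: float
    slope_se: float
    intercept_se: float | None = None
    n_obs: int = 0


def regression_through_origin(x, y) -> RegressionResult:
    """Least-squares line forced through the origin: slope = Σxy/Σx².

    R² uses the uncentered total sum of squares Σy² (conventions differ for
    no-intercept models; this one makes R² the fraction of raw response
    variation captured, and equals MATLAB's for through-origin fits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("degenerate design: all x values are zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    rss = float(resid @ resid)
    tss = float(y @ y)
    df = x.size - 1
    ser = math.sqrt(rss / df)
    return RegressionResult(
        slope=slope,
        intercept=None,
        r_squared=1.0 - rss / tss if tss > 0 else 0.0,
        se_regression=ser,
        slope_se=ser / math.sqrt(sxx),
        n_obs=x.size,
    )


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    X = sm.add_constant(x)
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated n=2 fits
        model = sm.OLS(y, X).fit()
        intercept, slope = model.params
        ses = model.bse
        ser = math.sqrt(model.ssr / model.df_resid) if model.df_resid > 0 else 0.0
        r2 = float(model.rsquared) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        se_regression=ser,
        slope_se=float(ses[1]),
        intercept_se=float(ses[0]),
        n_obs=x.size,
    )


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def one_tailed_t_test(sample1, sample2, direction: str = "greater",
                      pooled: bool = True) -> TTestResult:
    """Two-sample one-tailed t-test (pooled variance by default).

    ``direction="greater"`` tests the alternative mean(sample1) >
    mean(sample2); ``"less"`` the reverse.  If both samples have zero
    variance and equal means the statistic is undefined and the
    conventional p = 0.5 is returned with the degenerate flag set.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, p=0.5, degenerate=True)
        sign = 1.0 if diff > 0 else -1.0
        p = 0.0 if (sign > 0) == (direction == "greater") else 1.0
        return TTestResult(t=sign * math.inf, p=p, degenerate=True)
    n1, n2 = a.size, b.size
    if pooled:
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:  # Welch
        se = math.sqrt(va / n1 + vb / n2)
        df = (va / n1 + vb / n2) ** 2 / (
            (va / n1) ** 2 / (n1 - 1) + (vb / n2) ** 2 / (n2 - 1)
        )
    tstat = diff / se
    p = t_dist.sf(tstat, df) if direction == "greater" else t_dist.cdf(tstat, df)
    return TTestResult(t=float(tstat), p=float(p))


def bonferroni_adjust(p_values, m: int | None = None):
    """Multiply each p-value by the number of comparisons, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(p * m, 1.0)


class MannWhitneyResult(NamedTuple):
    U: float
    p: float
    method: str


def mann_whitney_u(sample1, sample2, direction: str = "greater") -> MannWhitneyResult:
    """One-tailed Mann–Whitney U test.

    The statistic U counts pairs (x, y) with x > y (ties count 1/2).  For
    combined sample sizes up to 16 the p-value is exact, by enumerating all
    C(n1+n2, n1) assignments of the pooled values to the first group (valid
    with ties); larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = a.size, b.size
    U = _u_statistic(a, b)
    if n1 + n2 <= 16:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        total = 0
        extreme = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if direction == "greater":
                extreme += u >= U - 1e-12
            else:
                extreme += u <= U + 1e-12
        return MannWhitneyResult(U=float(U), p=extreme / total, method="exact")
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    sigma = math.sqrt(sigma2)
    if sigma == 0.0:
        return MannWhitneyResult(U=float(U), p=0.5, method="approx")
    if direction == "greater":
        z = (U - mu - 0.5) / sigma
        p = float(norm.sf(z))
    else:
        z = (U - mu + 0.5) / sigma
        p = float(norm.cdf(z))
    return MannWhitneyResult(U=float(U), p=p, method="approx")


def _u_statistic(a, b) -> float:
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


@dataclass
class GateResult:
    """Counts and aggregated fraction from two-colour gating."""

    n_pair: int
    n_a_only: int
    n_alpha_only: int
    n_ungated: int
    fraction_aggregated: float
    accuracy: float | None = None  # agreement with truth labels, if present
    confusion: pd.DataFrame | None = field(default=None, repr=False)


def gate_events(
    events: pd.DataFrame, green_threshold: float, red_threshold: float
) -> GateResult:
    """Classify events by channel thresholds and compute the mated fraction.

    Pairs carry both colours; the aggregated fraction is
    pairs / (pairs + free MATa), i.e. events in the MATa/MATα gate divided
    by all MATa-containing events.  If the table has a ``true_class``
    column the classification is scored against it.
    """
    if green_threshold <= 0 or red_threshold <= 0:
        raise ValueError("thresholds must be positive")
    green = events["green"].to_numpy(dtype=float)
    red = events["red"].to_numpy(dtype=float)
    hi_g = green > green_threshold
    hi_r = red > red_threshold
    called = np.where(
        hi_g & hi_r, "pair",
        np.where(hi_g, "a_only", np.where(hi_r, "alpha_only", "ungated")),
    )
    n_pair = int((called == "pair").sum())
    n_a = int((called == "a_only").sum())
    n_alpha = int((called == "alpha_only").sum())
    n_un = int((called == "ungated").sum())
    if n_pair + n_a == 0:
        raise ValueError("no MATa-containing events in the gates")
    if n_pair == len(events):
        warnings.warn(
            "every event falls in the pair gate; thresholds are likely below "
            "background",
            UserWarning,
            stacklevel=2,
        )
    frac = n_pair / (n_pair + n_a)
    accuracy = None
    confusion = None
    if "true_class" in events.columns:
        truth = events["true_class"].to_numpy()
        accuracy = float(np.mean(called == truth))
        confusion = pd.crosstab(
            pd.Series(truth, name="true"), pd.Series(called, name="called")
        )
    return GateResult(
        n_pair=n_pair,
        n_a_only=n_a,
        n_alpha_only=n_alpha,
        n_ungated=n_un,
        fraction_aggregated=frac,
        accuracy=accuracy,
        confusion=confusion,
    )


def normalize_fluorescence(raw, forward_scatter, background: float = 0.0):
    """Per-event FSC normalization: (raw − background)/FSC, floored at 0."""
    raw = np.asarray(raw, dtype=float)
    fsc = np.asarray(forward_scatter, dtype=float)
    if np.any(fsc <= 0):
        raise ValueError("forward scatter must be positive")
    out = np.maximum((raw - background) / fsc, 0.0)
    return float(out) if out.ndim == 0 else out
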
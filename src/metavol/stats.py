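"""Survival and small-sample statistics toolkit.

Thin, convention-pinning wrappers around the established implementations
(lifelines for Kaplan-Meier and log-rank, statsmodels for logistic
regression and the Lilliefors normality test, scipy for chi-square /
Fisher / Mann-Whitney, scikit-learn for ROC areas), plus the few pieces
where the exact convention matters and is computed here:

* restricted mean survival (area under the KM curve up to the largest
  observed time) with its classic large-sample standard error,
* Youden-index cutoff selection over score midpoints with a deterministic
  tie-break,
* Wald odds-ratio confidence intervals from 2x2 tables.

All 95% intervals use z = 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "SurvivalSample",
    "SurvivalCurve",
    "MeanSurvival",
    "ROCResult",
    "LogisticFit",
    "Table2x2",
    "ZeroCellError",
    "km_estimator",
    "mean_survival",
    "logrank_test",
    "roc_with_youden",
    "logistic_fit",
    "or_ci_from_table",
    "pearson_chi2",
    "fisher_exact",
    "mann_whitney_u",
    "ks_normality",
]

Z95 = 1.96


@dataclass(frozen=True)
class SurvivalSample:
    """Follow-up times (months, > 0) and event indicators (True = observed)."""

    time_months: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_months, dtype=float)
        e = np.asarray(self.event, dtype=bool)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("survival sample is empty")
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise ValueError("survival times must be positive and finite")
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "event", e)

    def __len__(self) -> int:
        return self.time_months.size


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with Greenwood variances at the event times."""

    event_times: np.ndarray      # distinct times with >= 1 event
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # number at risk just before each event time
    n_events: np.ndarray         # events at each event time
    greenwood_var: np.ndarray    # Greenwood variance of S at each event time
    max_observed_time: float     # largest follow-up time, event or censored
    n: int                       # sample size


class MeanSurvival(NamedTuple):
    mean_months: float
    se_months: float
    ci_95: tuple[float, float]


def km_estimator(sample: SurvivalSample) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator (censored-after-event at ties)."""
    kmf = KaplanMeierFitter()
    kmf.fit(sample.time_months, sample.event)
    table = kmf.event_table  # index: event_at, cols: observed, at_risk, ...
    observed = table["observed"].to_numpy()
    at_risk = table["at_risk"].to_numpy()
    times = table.index.to_numpy(dtype=float)
    has_event = observed > 0
    d = observed[has_event].astype(float)
    n_at = at_risk[has_event].astype(float)
    event_times = times[has_event]
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at > d, d / (n_at * (n_at - d)), np.inf)
    greenwood = surv**2 * np.cumsum(terms)
    return SurvivalCurve(
        event_times=event_times,
        survival=surv,
        at_risk=n_at.astype(int),
        n_events=d.astype(int),
        greenwood_var=greenwood,
        max_observed_time=float(sample.time_months.max()),
        n=len(sample),
    )


def mean_survival(curve: SurvivalCurve) -> MeanSurvival:
    """Restricted mean survival time with large-sample SE and 95% CI.

    The mean is the area under the KM step function from 0 to the largest
    observed time tau (S = 1 before the first event). The variance is the
    classic sum over event times j of A_j^2 * d_j / (n_j (n_j - d_j)),
    where A_j is the remaining area under the curve after t_j; terms with
    A_j = 0 contribute nothing even when n_j = d_j.
    """
    tau = curve.max_observed_time
    t = curve.event_times
    s = curve.survival
    if t.size == 0:
        return MeanSurvival(tau, 0.0, (tau, tau))
    # segment areas: S is 1 on [0, t_1), s_j on [t_j, t_{j+1})
    knots = np.concatenate([[0.0], t, [tau]])
    heights = np.concatenate([[1.0], s])
    widths = np.diff(knots)
    mean = float(np.sum(heights * widths))
    # A_j = area under the curve on (t_j, tau]
    areas_after = np.concatenate(
        [np.cumsum((heights[1:] * widths[1:])[::-1])[::-1], [0.0]]
    )[: t.size]
    d = curve.n_events.astype(float)
    n_at = curve.at_risk.astype(float)
    var = 0.0
    for a, dj, nj in zip(areas_after, d, n_at):
        if a == 0.0:
            continue
        if nj <= dj:
            var = np.inf
            break
        var += a**2 * dj / (nj * (nj - dj))
    se = float(np.sqrt(var))
    return MeanSurvival(mean, se, (mean - Z95 * se, mean + Z95 * se))


def logrank_test(groups: Sequence[SurvivalSample]) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across k groups: (chi-square, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    times = np.concatenate([g.time_months for g in groups])
    events = np.concatenate([g.event for g in groups])
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    df = len(groups) - 1
    stat = float(res.test_statistic)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray    # candidate cutoffs, original score scale
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    best_sens: float
    best_spec: float
    direction: str

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_with_youden(
    score: Sequence[float],
    label: Sequence[bool],
    direction: str = "high_positive",
) -> ROCResult:
    """Empirical ROC with the Youden-index optimal cutoff.

    Candidate cutoffs are the midpoints between consecutive distinct score
    values (plus open ends). With direction ``high_positive`` a subject is
    called positive when score >= cutoff; ``low_positive`` negates the
    scores first, supporting markers where *low* values predict the event
    (the returned cutoff is then read as "positive when score <= cutoff").
    Ties on the Youden index break toward the cutoff that classifies fewer
    subjects positive. The AUC is the trapezoidal area of the empirical
    curve (equivalently the concordance probability).
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("score and label must be 1-D arrays of equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for a ROC curve")
    if direction not in ("high_positive", "low_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "high_positive" else -1.0
    z = sign * s

    uniq = np.unique(z)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pos = z[y]
    neg = z[~y]
    sens = np.array([(pos >= c).mean() for c in cuts])
    spec = np.array([(neg < c).mean() for c in cuts])
    auc = float(roc_auc_score(y, z))

    j = sens + spec - 1.0
    best_j = j.max()
    # fewer positives == larger internal cutoff; pick the last argmax
    best_idx = int(np.flatnonzero(np.isclose(j, best_j)).max())
    return ROCResult(
        thresholds=sign * cuts,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_cutoff=float(sign * cuts[best_idx]),
        best_sens=float(sens[best_idx]),
        best_spec=float(spec[best_idx]),
        direction=direction,
    )


@dataclass(frozen=True)
class LogisticFit:
    coefficients: np.ndarray
    std_errors: np.ndarray
    odds_ratios: np.ndarray
    wald_ci_95: np.ndarray  # (k, 2) on the odds-ratio scale
    p_values: np.ndarray
    converged: bool
    n_iterations: int


def logistic_fit(
    design: np.ndarray,
    outcome: Sequence[bool],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``design`` must include its intercept column. Complete separation is
    reported via ``converged=False`` (with NaN inference where the MLE
    does not exist) instead of returning arbitrarily huge finite odds
    ratios.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design must be (n, k) matching the outcome length")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than columns ({k})")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=0, warn_convergence=False
            )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        nan = np.full(k, np.nan)
        return LogisticFit(nan, nan, nan, np.full((k, 2), np.nan), nan, False, max_iter)

    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    # separation heuristic: exploding coefficients or standard errors
    if np.any(np.abs(beta) > 15) or np.any(~np.isfinite(se)) or np.any(se > 1e3):
        converged = False
    with np.errstate(over="ignore"):
        odds = np.exp(beta)
        ci = np.column_stack([np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)])
    pvals = np.asarray(res.pvalues, dtype=float)  # Wald z-tests
    return LogisticFit(
        coefficients=beta,
        std_errors=se,
        odds_ratios=odds,
        wald_ci_95=ci,
        p_values=pvals,
        converged=converged,
        n_iterations=int(res.mle_retvals.get("iterations", max_iter)),
    )


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table; (a, b) first row, (c, d) second row."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; the Wald odds ratio is undefined (no correction applied)."""


def or_ci_from_table(t: Table2x2) -> tuple[float, tuple[float, float], float]:
    """Cross-product odds ratio with log-scale Wald 95% CI and Wald p."""
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ZeroCellError(
            "zero cell in 2x2 table; Wald odds ratio undefined (no Haldane correction)"
        )
    odds = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo, hi = np.exp(np.log(odds) - Z95 * se), np.exp(np.log(odds) + Z95 * se)
    z = abs(np.log(odds)) / se
    p = 2.0 * sps.norm.sf(z)
    return float(odds), (float(lo), float(hi)), float(p)


def pearson_chi2(t: Table2x2) -> tuple[float, float]:
    """Pearson chi-square (df 1, no continuity correction) on a 2x2 table."""
    arr = t.as_array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("2x2 table has an empty margin")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(t: Table2x2) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    arr = t.as_array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("2x2 table has an empty margin")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U of x vs y with mid-ranks for ties.

    Exact enumeration when n1 + n2 <= 12 and there are no ties; otherwise
    the normal approximation with tie correction and without continuity
    correction (SPSS convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


class KSNormality(NamedTuple):
    stat: float
    p: float
    is_normal: bool       # p > 0.05: treat as normal downstream
    degenerate: bool      # constant sample, routed nonparametric


def ks_normality(x: Sequence[float], alpha: float = 0.05) -> KSNormality:
    """Lilliefors Kolmogorov-Smirnov test against a fitted normal.

    Used to route continuous group comparisons: non-normal (or degenerate
    constant) samples go to the Mann-Whitney U test.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 observations for the normality test")
    if np.ptp(x) == 0.0:
        return KSNormality(float("nan"), 0.0, False, True)
    stat, p = lilliefors(x, dist="norm")
    return KSNormality(float(stat), float(p), bool(p > alpha), False)
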
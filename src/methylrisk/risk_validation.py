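"""Score independent cohorts with a signature and evaluate it.

Risk score = signature coefficients dotted with the cohort's
(training-standardized) methylation profile; discrimination is measured
through Somers' Dxy rank correlation (AUC = (Dxy + 1)/2) with a DeLong
variance for the confidence interval and a one-sided p-value against
AUC = 0.5.  Scores are dichotomized at their arithmetic mean for
Kaplan-Meier / log-rank / Cox survival contrasts, and epidemiological
factors are screened with two-sided Fisher's exact (categorical) or
Welch's t (continuous summary) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .methio import BetaMatrix, Signature

__all__ = [
    "RiskScoreTable",
    "AUCReport",
    "SurvivalReport",
    "score_samples",
    "somers_auc",
    "dichotomize_scores",
    "km_logrank",
    "cox_binary_hr",
    "fisher_exact_2x2",
    "welch_t",
]

_FISHER_SLACK = 1e-7  # relative slack for the point-probability rule


@dataclass
class RiskScoreTable:
    """Per-sample linear risk scores plus CpG-coverage bookkeeping."""

    scores: pd.Series
    n_cpgs_used: int
    n_cpgs_missing: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("scores must be finite")


@dataclass
class AUCReport:
    """Somers'-Dxy discrimination report for one cohort."""

    dxy: float
    auc: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if abs(self.auc - (self.dxy + 1.0) / 2.0) > 1e-12:
            raise ValueError("auc must equal (dxy + 1) / 2")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must contain the AUC")


@dataclass
class SurvivalReport:
    """High-vs-low score survival contrast."""

    hr: float
    hr_ci: tuple[float, float]
    logrank_p: float
    km_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    monotone: bool = False  # events confined to one group; HR non-estimable

    def __post_init__(self) -> None:
        if not self.monotone:
            if not self.hr > 0:
                raise ValueError("hazard ratio must be positive")
            if not self.hr_ci[0] <= self.hr <= self.hr_ci[1]:
                raise ValueError("CI must contain the HR")


# ---------------------------------------------------------------------------
# scoring


def score_samples(matrix: BetaMatrix, sig: Signature,
                  missing_policy: str = "intersect") -> RiskScoreTable:
    """Linear risk score of every sample in ``matrix``.

    score = sum over signature CpGs present in the matrix of
    coefficient * (beta - training mean) / training scale.  CpGs absent
    from the matrix are dropped without renormalisation (the
    ``intersect`` policy — a 27k-derived signature applied to a 450k
    array simply uses the probes both platforms share); missing beta
    values contribute the training mean, i.e. zero.
    """
    if missing_policy != "intersect":
        raise ValueError("only the 'intersect' missing policy is supported")
    common = sig.cpg_ids.intersection(matrix.cpg_ids)
    if len(common) == 0:
        raise ValueError(
            f"no overlap between signature ({len(sig)} CpGs) and matrix "
            f"({matrix.shape[0]} CpGs)")
    coef = sig.coefficients.loc[common].to_numpy()
    means = sig.means.loc[common].to_numpy()
    scales = sig.scales.loc[common].to_numpy()
    B = matrix.values.loc[common].to_numpy(dtype=float)  # cpgs x samples
    Z = (B - means[:, None]) / scales[:, None]
    Z = np.where(np.isnan(Z), 0.0, Z)
    scores = coef @ Z
    return RiskScoreTable(
        scores=pd.Series(scores, index=matrix.sample_ids, name="score"),
        n_cpgs_used=len(common),
        n_cpgs_missing=len(sig) - len(common),
    )


# ---------------------------------------------------------------------------
# discrimination


def somers_auc(scores, outcome) -> AUCReport:
    """AUC via Somers' Dxy with a DeLong variance.

    AUC = (concordant + 0.5 * tied) / (n1 * n0) over all case-control
    pairs, computed by midranks; Dxy = 2 AUC - 1.  The 95% CI uses the
    DeLong placement-variance estimator and the p-value is one-sided for
    the directional hypothesis AUC > 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcome must be matching 1-d vectors")
    if s.size < 4:
        raise ValueError("need at least 4 samples")
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    cases, controls = s[y == 1], s[y == 0]
    n1, n0 = cases.size, controls.size

    all_ranks = stats.rankdata(s)
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    # DeLong placements: V10_i = P(score_case_i beats a random control)
    v10 = (all_ranks[y == 1] - case_ranks) / n0
    v01 = 1.0 - (all_ranks[y == 0] - control_ranks) / n1
    auc = float(v10.mean())
    var = 0.0
    if n1 > 1:
        var += float(np.var(v10, ddof=1)) / n1
    if n0 > 1:
        var += float(np.var(v01, ddof=1)) / n0
    sd = np.sqrt(var)
    if sd > 0:
        ci_low = max(0.0, auc - 1.96 * sd)
        ci_high = min(1.0, auc + 1.96 * sd)
        p = float(stats.norm.sf((auc - 0.5) / sd))
    else:
        ci_low = ci_high = auc
        p = 0.5 if auc == 0.5 else (0.0 if auc > 0.5 else 1.0)
    return AUCReport(dxy=2.0 * auc - 1.0, auc=auc,
                     ci_low=ci_low, ci_high=ci_high, p_value=p)


def dichotomize_scores(scores) -> np.ndarray:
    """1 for scores strictly above the group's arithmetic mean, else 0."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    return (s > s.mean()).astype(int)


# ---------------------------------------------------------------------------
# survival


def km_logrank(time, event, group):
    """Kaplan-Meier curves per group plus the two-group log-rank p.

    Returns ``(km_curves, logrank_p)`` where ``km_curves`` maps group
    label ('low'/'high') to (times, survival) step arrays.  With zero
    events in both groups the curves are still valid (constant at 1) but
    the log-rank statistic is undefined: p is NaN with a warning.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    curves = {}
    for label, mask in (("low", g == 0), ("high", g == 1)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        curves[label] = (sf.index.to_numpy(dtype=float),
                         sf.iloc[:, 0].to_numpy(dtype=float))
    if e.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined",
                      RuntimeWarning)
        return curves, float("nan")
    res = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
    return curves, float(res.p_value)


def _breslow_loglik_terms(time, event, group):
    """Per-event-time sufficient statistics for the binary-covariate
    Breslow partial likelihood: (d_k, s_k, n1_k, n0_k)."""
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], group[order]
    out = []
    event_times = np.unique(t[e == 1])
    for tk in event_times:
        at_risk = t >= tk
        deaths = (t == tk) & (e == 1)
        out.append((int(deaths.sum()), int((deaths & (g == 1)).sum()),
                    int((at_risk & (g == 1)).sum()),
                    int((at_risk & (g == 0)).sum())))
    return out


def cox_binary_hr(time, event, group, logrank: bool = True) -> SurvivalReport:
    """Cox proportional-hazards fit for a single binary covariate.

    Breslow tie handling; Newton-Raphson on the partial likelihood to a
    gradient below 1e-8.  HR = exp(beta) with a Wald 95% CI.  When every
    event falls in one group the partial likelihood is monotone and the
    HR is reported as non-estimable (``monotone=True``).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group, dtype=int)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    curves, lr_p = km_logrank(t, e, g) if logrank else ({}, float("nan"))
    s_total = int((e[g == 1]).sum())
    if s_total == 0 or s_total == int(e.sum()):
        return SurvivalReport(hr=float("nan"), hr_ci=(float("nan"), float("nan")),
                              logrank_p=lr_p, km_curves=curves, monotone=True)

    terms = _breslow_loglik_terms(t, e, g)
    beta = 0.0
    for _ in range(100):
        grad = hess = 0.0
        for d, s, n1, n0 in terms:
            eb = np.exp(beta)
            denom = n1 * eb + n0
            grad += s - d * n1 * eb / denom
            hess -= d * n1 * n0 * eb / denom**2
        if abs(grad) < 1e-8:
            break
        if hess == 0.0 or abs(beta) > 20:
            return SurvivalReport(hr=float("nan"),
                                  hr_ci=(float("nan"), float("nan")),
                                  logrank_p=lr_p, km_curves=curves,
                                  monotone=True)
        beta -= grad / hess
    se = float(1.0 / np.sqrt(-hess))
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return SurvivalReport(hr=hr, hr_ci=ci, logrank_p=lr_p, km_curves=curves)


# ---------------------------------------------------------------------------
# factor association tests


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Point-probability rule: sum hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed
    the observed one (1 + 1e-7 relative slack), the convention of the
    standard statistical environments.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.floor(tab)):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    N, r1, c1 = a + b + c + d, a + b, a + c
    if r1 + c1 == 0 or (b + d) + (c + d) == 0:
        raise ValueError("both margins must be positive")
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, N, r1, c1)
    p_obs = stats.hypergeom.pmf(a, N, r1, c1)
    include = pmf <= p_obs * (1.0 + _FISHER_SLACK)
    if include.all():
        return 1.0  # observed table at the mode: all tables as extreme
    return float(min(pmf[include].sum(), 1.0))


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> float:
    """Two-sided Welch unequal-variance t-test from summary statistics
    (Satterthwaite degrees of freedom); lets printed mean (SD) tables be
    checked without the underlying data."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0.0:
        if mean1 == mean2:
            return 1.0
        warnings.warn("zero variance with unequal means; degenerate p = 0",
                      RuntimeWarning)
        return 0.0
    tstat = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(2.0 * stats.t.sf(abs(tstat), df))
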
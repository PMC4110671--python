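"""Per-CpG covariate-adjusted differential methylation scan.

For each CpG a logistic regression of carrier/group status on the CpG's
beta value plus covariates (age, batch indicators, cancer status) is
fitted by maximum likelihood; the beta-term Wald test gives the per-CpG
p-value.  Multiple testing is handled by Storey q-values (pi0 estimated
on a lambda grid with a cubic smoother), candidates are selected at a
relaxed FDR threshold, and the hypermethylated/hypomethylated direction
split is tested against a 50:50 null with an exact binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .methio import BetaMatrix, SampleSheet

__all__ = [
    "DiffMethTable",
    "CandidateSet",
    "cpg_logistic_scan",
    "storey_qvalues",
    "select_candidates",
    "binomial_skew_test",
]

# a fit whose predicted probabilities all sit within this distance of
# their observed 0/1 outcome has a monotone likelihood (perfect separation)
_SEPARATION_TOL = 1e-6


@dataclass
class DiffMethTable:
    """Per-CpG scan results: coefficient, SE, Wald z, p, q, direction."""

    data: pd.DataFrame  # index cpg_id; columns coefficient, se, wald_z,
    #                     p_value, q_value, direction, flagged
    n_flagged: int = 0

    def __post_init__(self) -> None:
        required = {"coefficient", "se", "wald_z", "p_value", "q_value",
                    "direction", "flagged"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DiffMethTable missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CandidateSet:
    """CpGs passing the FDR threshold, with their directions."""

    cpg_ids: pd.Index
    direction: pd.Series
    fdr_threshold: float

    @property
    def n_hyper(self) -> int:
        return int((self.direction > 0).sum())

    @property
    def n_hypo(self) -> int:
        return int((self.direction < 0).sum())

    def __len__(self) -> int:
        return len(self.cpg_ids)


def _design_covariates(sheet: SampleSheet, covariates: list[str]) -> np.ndarray:
    """Covariate block: numeric columns as-is, categoricals as indicator
    contrasts dropping the first level."""
    cols: list[np.ndarray] = []
    for name in covariates:
        if name not in sheet.data.columns:
            raise ValueError(f"covariate {name!r} not in sample sheet")
        col = sheet.data[name]
        if col.dtype.kind in "biufc":
            if col.nunique(dropna=True) <= 1:
                continue  # constant covariate: collinear with the intercept
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
    if not cols:
        return np.empty((len(sheet.data), 0))
    return np.column_stack(cols)


def cpg_logistic_scan(matrix: BetaMatrix, sheet: SampleSheet,
                      covariates: list[str] | None = None) -> DiffMethTable:
    """Scan every CpG: logistic regression of group on (beta, covariates).

    Reports the beta-term coefficient (log-odds of carrier status per
    unit beta), its standard error, Wald z and two-sided p.  CpGs where
    the fit does not converge or the likelihood is monotone (perfect
    separation) are flagged and assigned p = 1 with the direction taken
    from the carrier-vs-rest mean difference; q-values are filled in
    over the scanned set.  All-missing CpG rows are excluded.
    """
    if covariates is None:
        covariates = ["age", "batch", "cancer_status"]
    if not matrix.sample_ids.equals(sheet.sample_ids):
        sheet = SampleSheet(sheet.data.loc[matrix.sample_ids])
    y = sheet.group.astype(float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples in each outcome class")
    Z = _design_covariates(sheet, covariates)
    betas = matrix.values.to_numpy(dtype=float)

    n_cpgs = betas.shape[0]
    coef = np.full(n_cpgs, np.nan)
    se = np.full(n_cpgs, np.nan)
    pvals = np.full(n_cpgs, np.nan)
    flagged = np.zeros(n_cpgs, dtype=bool)
    keep = np.ones(n_cpgs, dtype=bool)
    n_flagged = 0

    for i in range(n_cpgs):
        b = betas[i]
        ok = ~np.isnan(b)
        if not ok.any():
            keep[i] = False
            continue
        X = np.column_stack([np.ones(ok.sum()), b[ok], Z[ok]])
        converged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y[ok], X).fit(disp=0, maxiter=100)
            separated = np.max(np.abs(y[ok] - fit.predict())) < _SEPARATION_TOL
            converged = (fit.mle_retvals.get("converged", False)
                         and not separated
                         and np.isfinite(fit.bse[1]))
        except Exception:
            fit = None
        if converged:
            coef[i] = fit.params[1]
            se[i] = fit.bse[1]
            pvals[i] = fit.pvalues[1]
        else:
            flagged[i] = True
            n_flagged += 1
            # direction from the raw group contrast; test is uninformative
            diff = np.nanmean(b[ok][y[ok] == 1]) - np.nanmean(b[ok][y[ok] == 0])
            coef[i] = np.sign(diff) if diff != 0 else 1.0
            se[i] = np.inf
            pvals[i] = 1.0
    if n_flagged:
        warnings.warn(f"{n_flagged} CpG(s) flagged (non-convergence or "
                      "separation); assigned p = 1", RuntimeWarning)

    idx = matrix.cpg_ids[keep]
    coef, se, pvals, flagged = coef[keep], se[keep], pvals[keep], flagged[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_z = np.where(np.isfinite(se) & (se > 0), coef / se, 0.0)
    qvals = storey_qvalues(pvals)
    direction = np.where(coef >= 0, 1, -1)
    table = pd.DataFrame({
        "coefficient": coef, "se": se, "wald_z": wald_z,
        "p_value": pvals, "q_value": qvals,
        "direction": direction, "flagged": flagged,
    }, index=idx)
    return DiffMethTable(table, n_flagged=n_flagged)


def estimate_pi0(p_values: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """Proportion of true nulls, estimated by the lambda-grid smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid
    0.05, 0.10, ..., 0.95; a cubic polynomial smoother is evaluated at
    the grid's right end (lambda -> 1) and clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coefs = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coefs, lambdas[-1]))
    return float(np.clip(pi0, 1e-8, 1.0))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """q-values under the pi0-adjusted step-up procedure.

    q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank_j, which with
    pi0 = 1 reduces exactly to Benjamini-Hochberg.  ``pi0=None``
    estimates pi0 from the data via :func:`estimate_pi0`.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_candidates(table: DiffMethTable,
                      fdr_threshold: float = 0.3) -> CandidateSet:
    """CpGs with q-value strictly below the FDR threshold."""
    if len(table) == 0:
        raise ValueError("empty differential-methylation table")
    mask = table.data["q_value"] < fdr_threshold
    sel = table.data.loc[mask]
    return CandidateSet(cpg_ids=sel.index,
                        direction=sel["direction"].astype(int),
                        fdr_threshold=fdr_threshold)


def binomial_skew_test(n_hyper: int, n_total: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test for the hyper/hypo direction split.

    Two-sided by the point-probability rule: sum P(X = k) over all k
    whose probability does not exceed that of the observed count (with a
    1 + 1e-7 relative slack against float ordering artifacts).
    """
    if not 0 <= n_hyper <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_hyper <= n_total, n_total >= 1")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    k = np.arange(n_total + 1)
    pmf = stats.binom.pmf(k, n_total, p0)
    include = pmf <= pmf[n_hyper] * (1.0 + 1e-7)
    if include.all():
        return 1.0  # observed count at the mode: every table is as extreme
    return float(min(pmf[include].sum(), 1.0))
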
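"""Kaplan-Meier estimation, log-rank testing, optimal-cutoff scan and Cox models.

The Kaplan-Meier estimator and the two-group log-rank statistic are
implemented directly in numpy (the cutoff scan evaluates thousands of
log-rank tests, so the hot path must be cheap); Cox proportional-hazards
fitting delegates to statsmodels' partial-likelihood implementation with
Breslow tie handling and Wald intervals.

The optimal-cutoff scan dichotomises a continuous score at every distinct
observed value that leaves at least ``min_group_frac`` of the cohort in each
arm, takes the best (smallest) raw log-rank p, and Bonferroni-adjusts it by
the number of candidate cutoffs tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def km_estimate(times, events, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns, per group, a step-function table (time, n_at_risk, n_events,
    survival) over the distinct event times; survival starts at 1 and is
    non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    groups = np.zeros_like(events) if groups is None else np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        t, e = times[mask], events[mask]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        rows = [(0.0, len(t), 0, 1.0)]
        surv = 1.0
        for ti in np.unique(t[e == 1]):
            at_risk = int(np.sum(t >= ti))
            d = int(np.sum((t == ti) & (e == 1)))
            surv *= 1.0 - d / at_risk
            rows.append((float(ti), at_risk, d, surv))
        out[g] = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                             "survival"])
    return out


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic df=1, p-value).

    Observed-minus-expected events in group 1 with the hypergeometric
    variance at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    lev = pd.unique(groups)
    if len(lev) != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    g1 = groups == lev[0]
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        raise ValueError("no events: log-rank statistic undefined")
    O = E = V = 0.0
    for ti in event_times:
        at = times >= ti
        n = at.sum()
        n1 = (at & g1).sum()
        dead = (times == ti) & (events == 1)
        d = dead.sum()
        d1 = (dead & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        raise ValueError("log-rank variance is zero (degenerate risk sets)")
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CutoffScanResult:
    cutoffs: np.ndarray
    statistics: np.ndarray
    raw_p: np.ndarray
    best_cutoff: float
    p_min: float
    n_tested: int
    adjusted_p: float


def scan_cutoff(score, times, events,
                min_group_frac: float = 0.1) -> CutoffScanResult:
    """Optimal-cutoff log-rank scan with Bonferroni correction.

    Candidates are the distinct score values whose high/low split (high =
    score > cutoff) leaves >= ``min_group_frac`` of the cohort in each arm.
    The adjusted p is ``min(1, p_min * n_candidates)``.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(score)
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    candidates = [c for c in np.unique(score)
                  if min_n <= np.sum(score > c) <= n - min_n]
    if not candidates:
        raise ValueError("no cutoff satisfies the group-size constraint")
    stats_, ps = [], []
    for c in candidates:
        chi2, p = logrank(times, events, score > c)
        stats_.append(chi2)
        ps.append(p)
    ps = np.asarray(ps)
    best = int(np.argmin(ps))
    m = len(candidates)
    return CutoffScanResult(cutoffs=np.asarray(candidates),
                            statistics=np.asarray(stats_), raw_p=ps,
                            best_cutoff=float(candidates[best]),
                            p_min=float(ps[best]), n_tested=m,
                            adjusted_p=float(min(1.0, ps[best] * m)))


@dataclass
class CoxResult:
    table: pd.DataFrame   # predictor, HR, ci_low, ci_high, p
    mode: str
    converged: bool


def _design(cohort: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    cols = []
    for p in predictors:
        s = cohort[p]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(pd.get_dummies(s, prefix=p, drop_first=True, dtype=float))
        else:
            cols.append(s.astype(float).rename(p))
    return pd.concat(cols, axis=1)


def cox_fit(cohort: pd.DataFrame, predictors: list[str],
            mode: str = "multivariate", time_col: str = "time",
            event_col: str = "event") -> CoxResult:
    """Cox proportional-hazards fit (Breslow ties, Wald CI and p).

    ``mode="univariate"`` fits each predictor in its own model;
    ``mode="multivariate"`` fits all jointly.  Categorical predictors are
    one-hot encoded with the first level as reference.  Constant predictors
    get HR 1 with an unbounded-flagged CI.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    groups = [[p] for p in predictors] if mode == "univariate" else [predictors]
    rows = []
    converged = True
    for grp in groups:
        X = _design(cohort, grp)
        keep = X.columns[X.std(ddof=0) > 0]
        for dropped in set(X.columns) - set(keep):
            rows.append({"predictor": dropped, "HR": 1.0, "ci_low": np.nan,
                         "ci_high": np.nan, "p": 1.0})
        if len(keep) == 0:
            continue
        X = X[keep]
        if int(cohort[event_col].sum()) < X.shape[1]:
            raise ValueError("fewer events than parameters")
        model = sm.PHReg(cohort[time_col].to_numpy(dtype=float),
                         X.to_numpy(dtype=float),
                         status=cohort[event_col].to_numpy(dtype=int),
                         ties="breslow")
        try:
            fit = model.fit(disp=False)
        except Exception:
            converged = False
            continue
        beta = fit.params
        se = fit.bse
        if np.any(~np.isfinite(se)) or np.any(np.abs(beta) > 20):
            converged = False  # monotone likelihood / separation
        zcrit = stats.norm.ppf(0.975)
        for name, b, s in zip(X.columns, beta, se):
            rows.append({"predictor": name, "HR": float(np.exp(b)),
                         "ci_low": float(np.exp(b - zcrit * s)),
                         "ci_high": float(np.exp(b + zcrit * s)),
                         "p": float(2 * stats.norm.sf(abs(b / s)))})
    return CoxResult(table=pd.DataFrame(rows), mode=mode, converged=converged)
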
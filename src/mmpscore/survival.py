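"""Survival analysis: Kaplan-Meier, k-sample log-rank, univariate Cox, and
time-dependent AUC at fixed horizons.

KM estimation goes through lifelines (product-limit estimator).  The Cox fit
is a direct Newton-Raphson maximization of the Breslow-ties partial
likelihood — the tie convention adopted throughout — and the k-sample
log-rank test is computed from the observed/expected event counts and their
hypergeometric covariance so that per-group O and E are part of the result.
The time-dependent AUC is the cumulative-case / dynamic-control estimator
with inverse-probability-of-censoring weights from the Kaplan-Meier estimate
of the censoring distribution; tied marker values get half credit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger("mmpscore")

DEFAULT_HORIZONS = (12.0, 24.0, 36.0, 48.0, 60.0)


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    if (t < 0).any():
        raise ValueError("negative survival time")
    return t, e.astype(int)


@dataclass
class KMCurve:
    """Product-limit curve: distinct times with at-risk/event counts and S(t)."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    endpoint: str = "OS"

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t); S = 1 before the first time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "at_risk": self.at_risk,
            "events": self.events, "survival": self.survival,
        })


def km_estimate(times, events, endpoint: str = "OS") -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censoring tied with an event time is handled after the event (the
    standard convention).
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    tab = tab[tab.index > 0] if 0 not in t else tab
    surv = kmf.survival_function_["KM_estimate"]
    times_out = tab.index.to_numpy(dtype=float)
    return KMCurve(
        times=times_out,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
        survival=surv.reindex(tab.index).to_numpy(dtype=float),
        endpoint=endpoint,
    )


@dataclass
class LogRankResult:
    """k-sample log-rank test with per-group observed/expected events."""

    chi2: float
    df: int
    p: float
    observed: dict
    expected: dict

    def __post_init__(self) -> None:
        tot_o = sum(self.observed.values())
        tot_e = sum(self.expected.values())
        assert abs(tot_o - tot_e) < 1e-9, "sum(O) must equal sum(E)"


def logrank_test(times, events, groups) -> LogRankResult:
    """Standard k-sample log-rank chi-square test (k-1 degrees of freedom).

    At each distinct event time the per-group event counts are compared with
    their conditional (hypergeometric) expectation; the quadratic form uses
    the summed covariance matrix with one group dropped (pseudo-inverse for
    safety in degenerate layouts).
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must align with times")
    levels = list(pd.unique(g))
    k = len(levels)
    if k < 2:
        raise ValueError("log-rank test needs >=2 groups")
    level_index = {lv: i for i, lv in enumerate(levels)}
    gi = np.array([level_index[x] for x in g])

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for tau in event_times:
        at_risk = t >= tau
        n_j = at_risk.sum()
        if n_j < 1:
            continue
        d_j = int(((t == tau) & (e == 1)).sum())
        n_gj = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gi[(t == tau) & (e == 1)], minlength=k).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            scale = d_j * (n_j - d_j) / (n_j - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(
        chi2=chi2, df=df, p=p,
        observed={lv: float(o) for lv, o in zip(levels, O)},
        expected={lv: float(x) for lv, x in zip(levels, E)},
    )


@dataclass
class CoxResult:
    """Univariate Cox fit; ``flagged`` marks non-convergence / no-information fits."""

    beta: float
    se: float
    p: float
    flagged: bool = False
    note: str = ""

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))


def _breslow_score_info(beta: float, t: np.ndarray, e: np.ndarray,
                        x: np.ndarray) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, score and information at ``beta``."""
    ll = score = info = 0.0
    for tau in np.unique(t[e == 1]):
        d_idx = (t == tau) & (e == 1)
        risk = t >= tau
        d = int(d_idx.sum())
        w = np.exp(beta * x[risk])
        s0 = float(w.sum())
        s1 = float((w * x[risk]).sum())
        s2 = float((w * x[risk] ** 2).sum())
        ll += beta * x[d_idx].sum() - d * np.log(s0)
        score += x[d_idx].sum() - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, score, info


def cox_univariate(times, events, covariate, tol: float = 1e-8,
                   max_iter: int = 50) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Newton-Raphson, Breslow ties).

    Iterates until ``|delta beta| < tol`` or ``max_iter`` steps.  Constant
    covariates carry no information and return ``beta = 0`` with an infinite
    standard error, flagged; monotone-likelihood / complete-separation runs
    (beta diverging) are flagged rather than silently returned.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    if e.sum() < 1:
        raise ValueError("Cox regression needs >=1 event")
    if np.all(x == x[0]):
        return CoxResult(beta=0.0, se=np.inf, p=1.0, flagged=True,
                         note="constant covariate: no information")
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, score, info = _breslow_score_info(beta, t, e, x)
        if info <= 0:
            return CoxResult(beta=beta, se=np.inf, p=1.0, flagged=True,
                             note="singular information")
        step = score / info
        step = float(np.clip(step, -5.0, 5.0))  # damp early overshoot
        beta += step
        if abs(beta) > 50:
            return CoxResult(beta=beta, se=np.inf, p=1.0, flagged=True,
                             note="monotone likelihood (complete separation?)")
        if abs(step) < tol:
            converged = True
            break
    _, _, info = _breslow_score_info(beta, t, e, x)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if not converged:
        return CoxResult(beta=beta, se=se, p=p, flagged=True,
                         note=f"no convergence in {max_iter} iterations")
    return CoxResult(beta=float(beta), se=se, p=p)


def breslow_partial_loglik(beta: float, times, events, covariate) -> float:
    """Breslow partial log-likelihood at a given beta (used as a brute-force
    cross-check of the Newton fit)."""
    t, e = _as_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    ll = 0.0
    for tau in np.unique(t[e == 1]):
        d_idx = (t == tau) & (e == 1)
        risk = t >= tau
        d = int(d_idx.sum())
        ll += beta * x[d_idx].sum() - d * np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


@dataclass
class TimeAUC:
    """Cumulative/dynamic AUC at fixed horizons (months)."""

    horizons: tuple
    auc: dict
    method: str = "ipcw-cumulative-dynamic"

    def as_series(self) -> pd.Series:
        return pd.Series({h: self.auc[h] for h in self.horizons}, name="auc")


def _censoring_km(t: np.ndarray, e: np.ndarray):
    """KM estimate of the censoring survival G(t) (events = censorings)."""
    kmf = KaplanMeierFitter()
    kmf.fit(t, 1 - e)
    sf = kmf.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)

    def G(q: np.ndarray, before: bool = False) -> np.ndarray:
        side = "left" if before else "right"
        idx = np.searchsorted(grid, q, side=side) - 1
        idx = np.clip(idx, -1, len(vals) - 1)
        out = np.where(idx < 0, 1.0, vals[np.maximum(idx, 0)])
        return out

    return G


def time_dependent_auc(times, events, marker, horizons=DEFAULT_HORIZONS) -> TimeAUC:
    """IPCW cumulative-case / dynamic-control AUC at each horizon.

    Cases at horizon tau are subjects with an observed event by tau
    (weight 1/G(T-)); controls are subjects still under observation beyond
    tau (weight 1/G(tau)).  Higher marker values are treated as higher risk;
    tied markers get half credit, so a constant marker scores exactly 0.5.
    Horizons with no cases or no controls yield NaN with a warning.
    """
    t, e = _as_arrays(times, events)
    m = np.asarray(marker, dtype=float)
    G = _censoring_km(t, e)
    auc: dict = {}
    for tau in horizons:
        cases = (t <= tau) & (e == 1)
        controls = t > tau
        if cases.sum() == 0 or controls.sum() == 0:
            logger.warning("time_dependent_auc: no cases or controls at t=%s", tau)
            auc[tau] = float("nan")
            continue
        g_case = G(t[cases], before=True)
        g_ctrl = float(G(np.array([tau]))[0])
        g_case = np.where(g_case <= 0, np.nan, g_case)
        w_case = 1.0 / g_case
        w_case = np.nan_to_num(w_case, nan=0.0)
        if g_ctrl <= 0:
            logger.warning("time_dependent_auc: censoring survival 0 at t=%s", tau)
            auc[tau] = float("nan")
            continue
        w_ctrl = np.full(int(controls.sum()), 1.0 / g_ctrl)
        mc, mk = m[cases], m[controls]
        greater = (mc[:, None] > mk[None, :]).astype(float)
        ties = (mc[:, None] == mk[None, :]).astype(float)
        W = np.outer(w_case, w_ctrl)
        num = float((W * (greater + 0.5 * ties)).sum())
        den = float(W.sum())
        auc[tau] = num / den if den > 0 else float("nan")
    return TimeAUC(horizons=tuple(horizons), auc=auc)
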
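"""Prognosis metrics: Harrell's C, time-dependent AUC, Kaplan-Meier
stratification, and binary Cox hazard ratios with subgroup tables.

Conventions: the time-dependent AUC is the cumulative/dynamic variant with
inverse-probability-of-censoring weights from the Kaplan-Meier estimate of
the censoring distribution (so with zero censoring it reduces exactly to the
empirical pair-counting AUC); the binary Cox model uses the Breslow tie
approximation with Wald 95% confidence intervals on the log scale; the
median split assigns scores <= median to the low group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve on the observed event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class HRResult:
    """Hazard ratio of group 1 vs group 0 with Wald 95% CI."""

    hr: float
    ci_low: float
    ci_high: float
    se_log_hr: float
    p_value: float
    n_group0: int
    n_group1: int


def harrell_c(scores, times, events) -> float:
    """Harrell's concordance: P(higher score fails earlier) among comparable pairs.

    A pair is comparable when the shorter time is an observed event; score
    ties count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    shorter = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = shorter.sum()
    if n_comp == 0:
        raise ValueError("no comparable pair for the concordance index")
    conc = np.sum(shorter & (s[:, None] > s[None, :]))
    tied = np.sum(shorter & (s[:, None] == s[None, :]))
    return float((conc + 0.5 * tied) / n_comp)


def _censoring_km(times, events):
    """KM of the censoring distribution G(t); returns a left-limit evaluator."""
    t = np.asarray(times, dtype=float)
    c = 1 - np.asarray(events, dtype=int)          # censoring is the "event"
    grid = np.unique(t[c == 1])
    if grid.size == 0:
        return lambda u: np.ones(np.size(u))
    n_j = (t[:, None] >= grid[None, :]).sum(axis=0).astype(float)
    d_j = ((t[:, None] == grid[None, :]) & (c[:, None] == 1)).sum(axis=0)
    surv = np.cumprod(1.0 - d_j / n_j)

    def g_minus(u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        idx = np.searchsorted(grid, u, side="left") - 1   # strictly-before steps
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out

    return g_minus


def auc_t(scores, times, events, t: float) -> float:
    """Cumulative/dynamic AUC at horizon t with KM-based IPCW.

    Cases are subjects with an observed event by t; controls are those still
    at risk beyond t.  Case i is weighted 1/G(t_i-), controls 1/G(t), with G
    the censoring-survival KM.  Score ties count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    tt = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cases = (tt <= t) & (e == 1)
    controls = tt > t
    if not cases.any() or not controls.any():
        raise ValueError(f"no cases or no controls at horizon t={t}")
    g = _censoring_km(tt, e)
    w_case = 1.0 / g(tt[cases])
    w_ctrl = np.full(controls.sum(), 1.0 / g(np.array([t]))[0])
    sc, sn = s[cases], s[controls]
    greater = (sc[:, None] > sn[None, :]).astype(float)
    tied = (sc[:, None] == sn[None, :]).astype(float)
    w = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(w * (greater + 0.5 * tied)) / np.sum(w))


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter().fit(t, e)
    grid = np.unique(t[e == 1])
    if grid.size == 0:
        grid = np.array([t.max()])
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = (t[:, None] >= grid[None, :]).sum(axis=0)
    return KMCurve(grid, surv, at_risk)


def logrank_test(times1, events1, times2, events2) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square, p)."""
    if len(times1) == 0 or len(times2) == 0:
        raise ValueError("empty group in log-rank test")
    res = _ll_logrank(times1, times2, event_observed_A=events1, event_observed_B=events2)
    return float(res.test_statistic), float(res.p_value)


def median_split(scores) -> np.ndarray:
    """Label scores <= median as 'low', > median as 'high'."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores to stratify")
    med = float(np.median(s))
    labels = np.where(s <= med, "low", "high")
    if (labels == "low").all() or (labels == "high").all():
        raise ValueError("degenerate stratification: all scores identical")
    return labels


def cox_hr_binary(group, times, events, max_iter: int = 50,
                  tol: float = 1e-10) -> HRResult:
    """One-covariate Cox model for a binary group (1 vs 0), Breslow ties.

    Newton-maximized partial likelihood; HR = exp(beta), 95% CI
    exp(beta +/- 1.96 SE).  Raises on monotone likelihood (complete
    separation of the event order), where the finite MLE does not exist.
    """
    x = np.asarray(group)
    if x.dtype.kind in "UO":
        x = (x == "high").astype(int)
    x = np.asarray(x, dtype=int)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n0, n1 = int((x == 0).sum()), int((x == 1).sum())
    if e[x == 0].sum() == 0 or e[x == 1].sum() == 0:
        raise ValueError("each group needs at least one event")

    et = np.unique(t[e == 1])
    d_j = ((t[:, None] == et[None, :]) & (e[:, None] == 1)).sum(axis=0).astype(float)
    d1_j = ((t[:, None] == et[None, :]) & (e[:, None] == 1) & (x[:, None] == 1)).sum(
        axis=0
    ).astype(float)
    r1_j = ((t[:, None] >= et[None, :]) & (x[:, None] == 1)).sum(axis=0).astype(float)
    r0_j = (t[:, None] >= et[None, :]).sum(axis=0).astype(float) - r1_j

    beta = 0.0
    for _ in range(max_iter):
        eb = math.exp(beta)
        s0 = r0_j + r1_j * eb
        mean1 = r1_j * eb / s0
        u = float(np.sum(d1_j - d_j * mean1))
        info = float(np.sum(d_j * mean1 * (1 - mean1)))
        if info <= 0:
            raise ValueError(
                "monotone partial likelihood (complete separation); "
                "use an exact or penalized method"
            )
        step = u / info
        beta += step
        if abs(beta) > 15:
            raise ValueError(
                "monotone partial likelihood (complete separation); "
                "use an exact or penalized method"
            )
        if abs(step) < tol:
            break
    eb = math.exp(beta)
    s0 = r0_j + r1_j * eb
    mean1 = r1_j * eb / s0
    info = float(np.sum(d_j * mean1 * (1 - mean1)))
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2.0 * sps.norm.sf(abs(z))
    return HRResult(
        hr=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        se_log_hr=se,
        p_value=float(p),
        n_group0=n0,
        n_group1=n1,
    )


def subgroup_hr(scores, times, events, subgroups: dict[str, np.ndarray]) -> pd.DataFrame:
    """High-vs-low HR within each subgroup.

    The median split is computed once on the full cohort; each subgroup then
    gets its own Cox fit.  Subgroups failing the fit preconditions are
    reported as NA with the reason.
    """
    labels = median_split(scores)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    rows = []
    for name, sel in subgroups.items():
        sel = np.asarray(sel, dtype=bool)
        try:
            if sel.sum() == 0:
                raise ValueError("empty subgroup")
            res = cox_hr_binary(labels[sel], t[sel], e[sel])
            rows.append({
                "subgroup": name, "hr": res.hr, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p_value": res.p_value,
                "n_low": res.n_group0, "n_high": res.n_group1, "note": "",
            })
        except ValueError as exc:
            rows.append({
                "subgroup": name, "hr": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p_value": np.nan,
                "n_low": int((labels[sel] == "low").sum()) if sel.any() else 0,
                "n_high": int((labels[sel] == "high").sum()) if sel.any() else 0,
                "note": str(exc),
            })
    return pd.DataFrame(rows)
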
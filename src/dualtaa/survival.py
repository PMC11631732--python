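"""Survival stratification by dual-marker expression.

Advanced-stage (III/IV) patients are grouped by whether their expression of
two target genes is high: ``dual-high`` (high on both), ``dual-low`` (low on
both), else ``mixed``. "High" is defined either by the per-gene median within
the stage-filtered cohort (default) or by calibrated RNA thresholds. Groups
are compared with the Kaplan-Meier product-limit estimator and the log-rank
test; a univariate Cox proportional-hazards model provides hazard ratios.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMEstimate",
    "group_by_dual_expression",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_score_test",
]


def _collapse_stage(stage: str) -> str:
    """Collapse sub-stages: 'IIIA' -> 'III', 'Stage IV' -> 'IV'."""
    s = str(stage).upper().replace("STAGE", "").strip()
    m = re.match(r"(IV|III|II|I)", s)
    return m.group(1) if m else s


def group_by_dual_expression(
    records: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    rule: str = "median",
    thresholds: dict[str, float] | None = None,
    stage_filter: set[str] | None = frozenset({"III", "IV"}),
    stage_col: str = "stage",
) -> pd.DataFrame:
    """Label stage-filtered patients dual-high / mixed / dual-low.

    ``rule='median'`` splits each gene at its median within the filtered
    cohort (values strictly above the median are high); ``rule='threshold'``
    uses calibrated cut-offs with a closed boundary (>= theta is high).
    """
    df = records.copy()
    if stage_filter is not None:
        collapsed = df[stage_col].map(_collapse_stage)
        df = df[collapsed.isin(stage_filter)].copy()
    if df.empty:
        raise ValueError("no patients remain after stage filtering")
    for g in (gene_a, gene_b):
        if g not in df.columns:
            raise KeyError(f"expression column {g!r} missing")

    if rule == "median":
        high = {g: df[g] > df[g].median() for g in (gene_a, gene_b)}
    elif rule == "threshold":
        if not thresholds:
            raise ValueError("rule='threshold' requires thresholds")
        high = {g: df[g] >= thresholds[g] for g in (gene_a, gene_b)}
    else:
        raise ValueError(f"unknown rule {rule!r}")

    both = high[gene_a] & high[gene_b]
    neither = ~high[gene_a] & ~high[gene_b]
    df["group"] = np.select([both, neither], ["dual-high", "dual-low"], "mixed")
    df.attrs["rule"] = rule
    return df


@dataclass
class KMEstimate:
    """Product-limit survival estimate with a risk table."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_times(times: np.ndarray) -> None:
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    S drops only at event times by the factor (1 - d_i / n_i); censored
    subjects leave the risk set without a drop. With no events S(t) = 1
    everywhere.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _check_times(times)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    n = len(times)
    surv, at_risk, d_counts = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMEstimate(
        times=event_times,
        survival=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(d_counts, dtype=int),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk set;
    chi2 = (sum(O - E))^2 / sum(V). Symmetric in group order and invariant to
    positive rescaling of time. Requires at least one event overall.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    _check_times(ta)
    _check_times(tb)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    event_times = np.unique(
        np.concatenate([ta[ea == 1], tb[eb == 1]])
    )
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        n = n1 + n2
        d1 = np.sum((ta == t) & (ea == 1))
        d2 = np.sum((tb == t) & (eb == 1))
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class CoxResult:
    hazard_ratio: float
    coef: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int
    converged: bool


def cox_univariate(
    records: pd.DataFrame,
    covariate: str,
    time_col: str = "time",
    event_col: str = "event",
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow tie handling).

    Returns the hazard ratio exp(beta) with its Wald 95% CI. Non-convergence
    or a monotone likelihood is flagged (``converged=False``) rather than
    raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = records[[time_col, event_col, covariate]].dropna()
    if df[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    cph = CoxPHFitter()
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError:
        return CoxResult(
            hazard_ratio=float("nan"), coef=float("nan"),
            ci_lower=float("nan"), ci_upper=float("nan"), p_value=float("nan"),
            n=len(df), n_events=int(df[event_col].sum()), converged=False,
        )
    coef = float(cph.params_[covariate])
    se = float(cph.standard_errors_[covariate])
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        coef=coef,
        ci_lower=float(np.exp(coef - 1.959963984540054 * se)),
        ci_upper=float(np.exp(coef + 1.959963984540054 * se)),
        p_value=float(cph.summary.loc[covariate, "p"]),
        n=len(df),
        n_events=int(df[event_col].sum()),
        converged=True,
    )


def cox_score_test(times, events, x) -> float:
    """Cox partial-likelihood score chi-square at beta = 0 (Breslow ties).

    For a binary covariate without tied event times this statistic equals the
    log-rank chi-square — the classical equivalence used as a cross-check.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    _check_times(times)
    u = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        risk = times >= t
        xr = x[risk]
        d_mask = (times == t) & (events == 1)
        d = int(d_mask.sum())
        mean = xr.mean()
        u += x[d_mask].sum() - d * mean
        v += d * (np.mean(xr**2) - mean**2)
    if v == 0:
        return 0.0
    return float(u**2 / v)
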
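"""Kaplan-Meier estimation, weighted two-sample tests and cutoff scanning.

Patients are dichotomised on a gene's expression or a signature score
("high" strictly above the cutoff), compared with the logrank and the
Gehan-Breslow-Wilcoxon test (a weighted logrank whose weights are the
number at risk at each event time, emphasising early events), and — when
the cutoff is not given a priori — stratified by a minimum-p scan over all
admissible inter-sample cutoffs.  The scan's naive minimum p is
anti-conservative by construction, so a permutation-adjusted p accompanies
it and the full scan table is returned to make the multiple-testing
exposure visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "GroupingRule",
    "km_estimate",
    "logrank_test",
    "gehan_breslow_wilcoxon_test",
    "scan_cutoff",
    "survival_association",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: event times, survival probabilities and the
    size of the risk set entering each time."""

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    endpoint: str = "OS"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "surv": self.surv, "at_risk": self.at_risk}
        )


@dataclass(frozen=True)
class GroupingRule:
    """Dichotomisation rule: high = value > cutoff (strict), low otherwise."""

    variable: str
    cutoff: float

    def assign(self, values: pd.Series) -> pd.Series:
        return pd.Series(
            np.where(values > self.cutoff, "high", "low"), index=values.index
        )


def _check_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return t, e


def km_estimate(time, event, endpoint: str = "OS") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Censored subjects shrink the risk set without producing a step; tied
    event times form a single step of the tied multiplicity.
    """
    t, e = _check_surv(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(t >= et).sum() for et in event_times])
    return SurvivalCurve(times=event_times, surv=surv, at_risk=at_risk, endpoint=endpoint)


def _weighted_logrank(
    time: np.ndarray, event: np.ndarray, in_g1: np.ndarray, gbw: bool
) -> tuple[float, float]:
    """Weighted logrank chi-square (1 df): weights 1 (logrank) or the total
    number at risk at each event time (Gehan-Breslow-Wilcoxon)."""
    order = np.argsort(time, kind="stable")
    t, e, g1 = time[order], event[order], in_g1[order].astype(float)
    n_total = t.size

    # distinct event times with the risk-set composition entering each
    et, start_idx = np.unique(t, return_index=True)
    # subjects at risk just before each distinct time
    n_at = n_total - start_idx
    csum_g1 = np.concatenate([[0.0], np.cumsum(g1)])
    n1_at = g1.sum() - csum_g1[start_idx]
    # events at each distinct time, per group
    d_tot = np.zeros(et.size)
    d_g1 = np.zeros(et.size)
    idx = np.searchsorted(et, t)
    np.add.at(d_tot, idx, e)
    np.add.at(d_g1, idx, e * g1)

    has_event = d_tot > 0
    if not has_event.any():
        logger.warning("no events in either group: p set to 1")
        return 0.0, 1.0
    n, n1, d, d1 = n_at[has_event], n1_at[has_event], d_tot[has_event], d_g1[has_event]
    exp1 = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var1 = d * (n1 / n) * (1 - n1 / n) * (n - d) / np.maximum(n - 1, 1)
    w = n if gbw else np.ones_like(n, dtype=float)
    num = float((w * (d1 - exp1)).sum())
    den = float((w**2 * var1).sum())
    if den == 0:
        return 0.0, 1.0
    chi2 = num**2 / den
    return chi2, float(stats.chi2.sf(chi2, df=1))


def logrank_test(time1, event1, time2, event2) -> tuple[float, float]:
    """Two-sample logrank test (O-E with hypergeometric variance, 1 df)."""
    t1, e1 = _check_surv(time1, event1)
    t2, e2 = _check_surv(time2, event2)
    time = np.concatenate([t1, t2])
    event = np.concatenate([e1, e2])
    in_g1 = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])
    return _weighted_logrank(time, event, in_g1, gbw=False)


def gehan_breslow_wilcoxon_test(time1, event1, time2, event2) -> tuple[float, float]:
    """Gehan-Breslow-Wilcoxon test: logrank machinery weighted by the
    number at risk, giving early events more influence."""
    t1, e1 = _check_surv(time1, event1)
    t2, e2 = _check_surv(time2, event2)
    time = np.concatenate([t1, t2])
    event = np.concatenate([e1, e2])
    in_g1 = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])
    return _weighted_logrank(time, event, in_g1, gbw=True)


def scan_cutoff(
    values,
    time,
    event,
    min_group_frac: float = 0.1,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[float, float, float, pd.DataFrame]:
    """Minimum-p logrank scan over all admissible inter-sample cutoffs.

    Every midpoint between consecutive distinct values is evaluated,
    keeping both groups at least ``min_group_frac`` of the cohort.  Returns
    ``(best_cutoff, p_at_best, p_adjusted, scan_table)`` where
    ``p_adjusted`` corrects the naive minimum p for the scan's multiple
    testing by permuting the value-to-outcome linkage ``n_permutations``
    times and ranking the observed minimum among permuted minima.
    """
    v = np.asarray(values, dtype=float)
    t, e = _check_surv(time, event)
    if v.size != t.size:
        raise ValueError("values and survival data must align")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("constant values admit no cutoff")
    mids = (distinct[:-1] + distinct[1:]) / 2
    min_n = max(int(np.ceil(min_group_frac * v.size)), 1)
    admissible = [c for c in mids if min_n <= (v > c).sum() <= v.size - min_n]
    if not admissible:
        raise ValueError("no cutoff keeps both groups large enough")

    def _min_scan(vals: np.ndarray) -> tuple[float, float]:
        best_p, best_c = np.inf, np.nan
        for c in admissible:
            chi2, p = _weighted_logrank(t, e, vals > c, gbw=False)
            if p < best_p:
                best_p, best_c = p, c
        return best_c, best_p

    rows = []
    for c in admissible:
        chi2, p = _weighted_logrank(t, e, v > c, gbw=False)
        rows.append({"cutoff": c, "n_high": int((v > c).sum()), "chi2": chi2, "p": p})
    table = pd.DataFrame(rows)
    best_idx = int(table["p"].idxmin())
    best_cutoff = float(table.loc[best_idx, "cutoff"])
    p_best = float(table.loc[best_idx, "p"])

    rng = np.random.default_rng(seed)
    perm_min = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_min[i] = _min_scan(rng.permutation(v))[1]
    p_adj = (1.0 + (perm_min <= p_best).sum()) / (n_permutations + 1.0)
    return best_cutoff, p_best, float(p_adj), table


def survival_association(
    clinical: pd.DataFrame,
    values: pd.Series,
    rule: GroupingRule | None = None,
    endpoints: tuple[str, ...] = ("OS", "EFS"),
    subgroup: pd.Series | None = None,
    scan_seed: int = 0,
) -> dict:
    """KM curves per group plus logrank and GBW tests for each endpoint.

    ``clinical`` carries per-endpoint columns ``{endpoint}_time`` and
    ``{endpoint}_event``.  ``subgroup`` (boolean mask, e.g. no-MNA) filters
    the cohort before stratification.  Without an explicit ``rule``, a
    minimum-p cutoff scan on the first endpoint chooses the cutoff.
    """
    df = clinical.copy()
    vals = values.reindex(df.index)
    if subgroup is not None:
        keep = subgroup.reindex(df.index).fillna(False).astype(bool)
        df, vals = df.loc[keep], vals.loc[keep]
        if df.empty:
            raise ValueError("subgroup filter removed every sample")

    out: dict = {"endpoints": {}}
    if rule is None:
        ep0 = endpoints[0]
        cutoff, p_naive, p_adj, table = scan_cutoff(
            vals.to_numpy(),
            df[f"{ep0}_time"].to_numpy(),
            df[f"{ep0}_event"].to_numpy(),
            seed=scan_seed,
        )
        rule = GroupingRule(variable=str(values.name), cutoff=cutoff)
        out["scan"] = {"p_naive": p_naive, "p_adjusted": p_adj, "table": table}
    out["rule"] = rule

    groups = rule.assign(vals)
    if groups.nunique() < 2:
        raise ValueError("cutoff yields a single group")
    for ep in endpoints:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol not in df.columns:
            continue
        hi = groups == "high"
        t_hi, e_hi = df.loc[hi, tcol], df.loc[hi, ecol]
        t_lo, e_lo = df.loc[~hi, tcol], df.loc[~hi, ecol]
        chi2_lr, p_lr = logrank_test(t_hi, e_hi, t_lo, e_lo)
        chi2_gbw, p_gbw = gehan_breslow_wilcoxon_test(t_hi, e_hi, t_lo, e_lo)
        out["endpoints"][ep] = {
            "curves": {
                "high": km_estimate(t_hi, e_hi, endpoint=ep),
                "low": km_estimate(t_lo, e_lo, endpoint=ep),
            },
            "logrank": {"chi2": chi2_lr, "p": p_lr},
            "gbw": {"chi2": chi2_gbw, "p": p_gbw},
            "n_high": int(hi.sum()),
            "n_low": int((~hi).sum()),
        }
    return out
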
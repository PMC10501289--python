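"""Survival analysis: Kaplan–Meier, log-rank, optimal cutoff, Cox PH, C-index.

Kaplan–Meier estimation, the cross-group log-rank test and Cox proportional
hazards (Efron ties, Newton–Raphson) are provided by ``lifelines``;
Harrell's concordance comes from ``scikit-survival``. The maximally-selected
cutoff search and the time-dependent (truncated-pair) concordance curve are
implemented here, including a fast standardized two-group log-rank statistic
used to scan candidate cutoffs.

A note on the cutoff search: scanning many cutpoints and keeping the best
inflates the log-rank test; the naive p-value attached to the chosen cutoff
is therefore reported with an explicit ``selection_corrected=False`` flag
and must not be read as a valid significance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.exceptions import NoComparablePairException
from sksurv.metrics import concordance_index_censored

logger = logging.getLogger(__name__)

__all__ = [
    "KMFit",
    "CoxFit",
    "CutpointResult",
    "km_fit",
    "logrank_zstat",
    "max_selected_cutoff",
    "cox_fit",
    "concordance_index",
    "timedep_cindex",
    "km_optimal_split_report",
]


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events


@dataclass
class KMFit:
    """Product-limit curves per group plus the cross-group log-rank test."""

    tables: dict[str, pd.DataFrame]  # per group: time, survival, at_risk, events
    logrank_statistic: float | None
    logrank_p: float | None
    degrees_of_freedom: int | None


def km_fit(times, events, groups=None) -> KMFit:
    """Kaplan–Meier estimate per group with a log-rank comparison.

    With a single (or no) group label, only the curve is returned and the
    log-rank fields are None. Raises if any group is empty or if there are
    no events at all.
    """
    times, events = _as_arrays(times, events)
    if events.sum() == 0:
        raise ValueError("no events: survival curve degenerate, log-rank undefined")
    if groups is None:
        groups = np.repeat("all", len(times))
    groups = np.asarray(groups).astype(str)
    if groups.shape[0] != times.shape[0]:
        raise ValueError("groups must match times in length")

    tables: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        tab = kmf.event_table
        tables[g] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_at_times(tab.index).to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(dtype=int),
                "events": tab["observed"].to_numpy(dtype=int),
            }
        )

    n_groups = len(tables)
    if n_groups < 2:
        return KMFit(tables=tables, logrank_statistic=None, logrank_p=None, degrees_of_freedom=None)
    res = multivariate_logrank_test(times, groups, events)
    return KMFit(
        tables=tables,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        degrees_of_freedom=n_groups - 1,
    )


def logrank_zstat(times, events, in_group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic z = (O1 − E1) / √V.

    ``in_group`` flags membership of group 1. Positive z means group 1
    experienced more events than expected under the null. Vectorized over
    the pooled event times; used by the cutoff scan.
    """
    times, events = _as_arrays(times, events)
    in_group = np.asarray(in_group, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], in_group[order]

    ev = e == 1
    event_times, inv = np.unique(t[ev], return_inverse=True)
    n = len(t)
    # at-risk counts just before each event time
    idx = np.searchsorted(t, event_times, side="left")
    n_at_risk = n - idx
    cum_g = np.concatenate([[0], np.cumsum(g)])
    n1_at_risk = cum_g[-1] - cum_g[idx]
    # events at each event time, overall and in group 1
    d = np.bincount(inv).astype(float)
    d1 = np.bincount(inv, weights=g[ev].astype(float))

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d * n1_at_risk / n_at_risk
        var = np.where(
            n_at_risk > 1,
            d * (n1_at_risk / n_at_risk) * (1 - n1_at_risk / n_at_risk) * (n_at_risk - d) / (n_at_risk - 1),
            0.0,
        )
    v = var.sum()
    if v <= 0:
        raise ValueError("log-rank variance is zero (degenerate grouping)")
    return float((d1.sum() - expected.sum()) / np.sqrt(v))


@dataclass
class CutpointResult:
    """Outcome of the maximally-selected log-rank cutoff search."""

    cutoff: float
    statistic: float  # max |standardized log-rank z|
    candidates: np.ndarray
    statistics: np.ndarray
    p_naive: float
    selection_corrected: bool = False
    note: str = (
        "p_naive is the unadjusted log-rank p at the selected cutoff; "
        "maximal selection inflates it and no correction is applied"
    )


def max_selected_cutoff(scores, times, events, min_prop: float = 0.1) -> CutpointResult:
    """Find the cutoff maximizing the absolute standardized log-rank statistic.

    Candidates are the observed score values lying between the ``min_prop``
    and ``1 − min_prop`` quantiles (half-open on the right so both groups
    stay non-degenerate). Requires at least 3 candidates after trimming.
    """
    scores = np.asarray(scores, dtype=float)
    times, events = _as_arrays(times, events)
    if scores.shape != times.shape:
        raise ValueError("scores and survival data must have equal length")
    if not 0.0 < min_prop < 0.5:
        if min_prop >= 0.5:
            raise ValueError("min_prop >= 0.5 leaves no candidate cutoffs")
        raise ValueError("min_prop must lie in (0, 0.5)")
    qlo, qhi = np.quantile(scores, [min_prop, 1.0 - min_prop])
    candidates = np.unique(scores)
    candidates = candidates[(candidates >= qlo) & (candidates < qhi)]
    if len(candidates) < 3:
        raise ValueError(
            f"only {len(candidates)} candidate cutoffs after min_prop={min_prop} trimming; need >= 3"
        )
    zs = np.array([logrank_zstat(times, events, scores > c) for c in candidates])
    best = int(np.argmax(np.abs(zs)))
    zmax = float(np.abs(zs[best]))
    return CutpointResult(
        cutoff=float(candidates[best]),
        statistic=zmax,
        candidates=candidates,
        statistics=zs,
        p_naive=float(2.0 * stats.norm.sf(zmax)),
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame  # index=term; coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    concordance: float
    n_used: int
    n_events: int
    n_dropped: int


def cox_fit(times, events, covariates: pd.DataFrame, covariate_names=None) -> CoxFit:
    """Fit a Cox PH model (Efron ties, Newton–Raphson via lifelines).

    Missing covariate values are handled complete-case with the dropped
    count logged. Raises on constant covariates, over-parameterization, or
    non-convergence (monotone likelihood / separation).
    """
    times, events = _as_arrays(times, events)
    cov = pd.DataFrame(covariates).copy()
    if covariate_names is not None:
        cov.columns = list(covariate_names)
    if cov.shape[0] != len(times):
        raise ValueError("covariate rows must match survival data length")

    cov = cov.reset_index(drop=True)
    df = cov.assign(_time=times, _event=events)
    n_total = len(df)
    df = df.dropna()
    n_dropped = n_total - len(df)
    if n_dropped:
        logger.info("cox_fit complete-case: dropped %d rows with missing covariates", n_dropped)
    if df["_event"].sum() < 1:
        raise ValueError("no events after complete-case filtering")

    X = pd.get_dummies(df.drop(columns=["_time", "_event"]), drop_first=True, dtype=float)
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"constant covariate: {col!r}")
    if len(df) <= X.shape[1]:
        raise ValueError("more covariates than samples")

    fit_df = X.assign(_time=df["_time"].to_numpy(), _event=df["_event"].to_numpy())
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge (possible separation): {exc}") from exc

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        concordance=float(cph.concordance_index_),
        n_used=int(len(df)),
        n_events=int(df["_event"].sum()),
        n_dropped=int(n_dropped),
    )


def concordance_index(times, events, risk_scores) -> tuple[float, int]:
    """Harrell's C over usable pairs (tied risks count 0.5).

    Returns ``(C, n_comparable_pairs)``. Higher risk is expected to fail
    earlier; C = 1 means perfect anti-ordering of risk and time.
    """
    times, events = _as_arrays(times, events)
    risk = np.asarray(risk_scores, dtype=float)
    try:
        c, concordant, discordant, tied_risk, _ = concordance_index_censored(
            events.astype(bool), times, risk
        )
    except NoComparablePairException as exc:
        raise ValueError("no comparable pairs for the concordance index") from exc
    return float(c), int(concordant + discordant + tied_risk)


def timedep_cindex(times, events, risk_scores, eval_times) -> pd.DataFrame:
    """Truncated-pair time-dependent concordance curve C(t).

    At each ``t``, usable pairs are (i, j) with ``times_i < times_j``,
    subject *i* an observed event, and ``times_i <= t``; tied risks count
    0.5. With no censoring, C at the maximum follow-up equals Harrell's C.
    """
    times, events = _as_arrays(times, events)
    risk = np.asarray(risk_scores, dtype=float)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    event_times = times[events == 1]
    if event_times.size == 0:
        raise ValueError("no events")
    if (eval_times < event_times.min()).any():
        raise ValueError("eval time precedes the first event")
    if (eval_times > times.max()).any():
        raise ValueError("eval time beyond observed follow-up")

    earlier = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    conc = (risk[:, None] > risk[None, :]).astype(float) + 0.5 * (risk[:, None] == risk[None, :])
    rows = []
    for t in eval_times:
        usable = earlier & (times[:, None] <= t)
        n_pairs = int(usable.sum())
        if n_pairs == 0:
            rows.append((t, np.nan, 0))
            continue
        rows.append((t, float(conc[usable].sum() / n_pairs), n_pairs))
    return pd.DataFrame(rows, columns=["time", "cindex", "n_pairs"])


def km_optimal_split_report(
    expr: pd.DataFrame,
    genes,
    times,
    events,
    min_prop: float = 0.1,
) -> pd.DataFrame:
    """Per-gene survival report: optimal-cutoff split, log-rank, HR direction.

    For each gene, finds the maximally-selected expression cutoff, fits KM
    curves on the resulting high/low groups and a univariate Cox model on
    the high-group indicator. Log-rank p-values inherit the selection
    inflation of the cutoff search (see :func:`max_selected_cutoff`).
    """
    times, events = _as_arrays(times, events)
    rows = []
    for gene in np.atleast_1d(genes):
        if gene not in expr.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        values = expr.loc[gene].to_numpy(dtype=float)
        cut = max_selected_cutoff(values, times, events, min_prop=min_prop)
        high = values > cut.cutoff
        km = km_fit(times, events, np.where(high, "high", "low"))
        cox = cox_fit(times, events, pd.DataFrame({"high": high.astype(float)}))
        hr = float(cox.summary.loc["high", "hr"])
        rows.append(
            {
                "gene": gene,
                "cutoff": cut.cutoff,
                "logrank_statistic": km.logrank_statistic,
                "logrank_p": km.logrank_p,
                "hr_high_vs_low": hr,
                "direction": "protective" if hr < 1 else "adverse",
                "selection_corrected": False,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
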
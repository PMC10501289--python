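"""Descriptive statistics: correlations, group comparisons, checkpoint panel.

All tests are two-sided. Continuous group comparisons default to the
Wilcoxon rank-sum (Mann–Whitney) test — robust to the skewed enrichment
scores — with Student's t available; categorical features use the χ² test
with Fisher's exact fallback when any expected cell count drops below 5.
Correlations are Pearson with pairwise-complete missing-value handling;
multiple-testing adjustment is Benjamini–Hochberg within each analysis
family, with both raw p and q reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "GroupComparison",
    "GENE_ALIASES",
    "correlate",
    "compare_groups",
    "correlation_matrix",
    "checkpoint_panel",
]

#: common literature aliases → HGNC symbols for the checkpoint panel
GENE_ALIASES: dict[str, str] = {
    "PD-L1": "CD274",
    "PDL1": "CD274",
    "B7-H1": "CD274",
    "PD-1": "PDCD1",
    "PD1": "PDCD1",
    "CTLA-4": "CTLA4",
    "PD-L2": "PDCD1LG2",
}


@dataclass
class CorrelationReport:
    """One Pearson correlation with its test."""

    pair: str
    r: float
    p: float
    n: int
    q: float | None = None


@dataclass
class GroupComparison:
    """Two-group comparison of one variable."""

    variable: str
    test: str  # "wilcoxon", "t", "chi2", "fisher"
    statistic: float
    p: float
    group_summary: dict


def correlate(x, y, name: str = "x~y") -> CorrelationReport:
    """Pearson correlation with a two-sided t-approximation p-value.

    Missing values are removed pairwise-complete; the n actually used is
    reported. Raises if fewer than 3 complete pairs remain or either vector
    is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return CorrelationReport(pair=name, r=float(res.statistic), p=float(res.pvalue), n=int(len(x)))


def compare_groups(
    values,
    groups,
    variable_type: str = "continuous",
    test: str | None = None,
    variable: str = "value",
) -> GroupComparison:
    """Two-sided two-group comparison.

    Continuous: Wilcoxon rank-sum by default (exact when both groups are
    small and untied, normal approximation with tie correction otherwise),
    or Student's t on request. Categorical: χ² on the contingency table,
    falling back to Fisher's exact on a 2×2 when any expected count < 5.
    """
    groups = pd.Series(np.asarray(groups).astype(str))
    uniq = sorted(groups.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(uniq)}")

    if variable_type == "continuous":
        values = np.asarray(values, dtype=float)
        a = values[(groups == uniq[0]).to_numpy()]
        b = values[(groups == uniq[1]).to_numpy()]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs at least 2 finite values")
        summary = {
            uniq[0]: {"n": len(a), "median": float(np.median(a)), "mean": float(np.mean(a))},
            uniq[1]: {"n": len(b), "median": float(np.median(b)), "mean": float(np.mean(b))},
        }
        if test in (None, "wilcoxon"):
            no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
            method = "exact" if (max(len(a), len(b)) <= 25 and no_ties) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            return GroupComparison(variable, "wilcoxon", float(res.statistic), float(res.pvalue), summary)
        if test == "t":
            res = stats.ttest_ind(a, b)
            return GroupComparison(variable, "t", float(res.statistic), float(res.pvalue), summary)
        raise ValueError(f"unknown continuous test {test!r}")

    if variable_type == "categorical":
        values = pd.Series(np.asarray(values).astype(str))
        table = pd.crosstab(values, groups)
        if (table.to_numpy().sum(axis=1) == 0).any():
            raise ValueError("empty category")
        chi2, p, _, expected = stats.chi2_contingency(table.to_numpy())
        if (expected < 5).any():
            if table.shape == (2, 2):
                odds, p = stats.fisher_exact(table.to_numpy())
                return GroupComparison(variable, "fisher", float(odds), float(p), {"table": table.to_dict()})
            logger.warning("expected counts < 5 on a %s table; χ² retained (no exact fallback)", table.shape)
        return GroupComparison(variable, "chi2", float(chi2), float(p), {"table": table.to_dict()})

    raise ValueError(f"unknown variable_type {variable_type!r}")


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Pearson correlations among profile rows, BH-adjusted.

    ``profiles`` holds one variable per row (e.g. the signature score plus
    enrichment signatures), samples in columns. Constant rows are dropped
    with a warning. Returns a long-format frame (var_a, var_b, r, p, q, n).
    """
    profiles = profiles.astype(float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profile rows")
    keep = []
    for name, row in profiles.iterrows():
        if np.ptp(row.dropna().to_numpy()) == 0:
            logger.warning("constant profile row %r dropped from correlation matrix", name)
            continue
        keep.append(name)
    profiles = profiles.loc[keep]
    if profiles.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant rows")

    rows = []
    names = list(profiles.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rep = correlate(
                profiles.iloc[i].to_numpy(),
                profiles.iloc[j].to_numpy(),
                name=f"{names[i]}~{names[j]}",
            )
            rows.append({"var_a": names[i], "var_b": names[j], "r": rep.r, "p": rep.p, "n": rep.n})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def resolve_gene(symbol: str, available, log: bool = True) -> str | None:
    """Resolve a panel gene through the alias table against a gene index."""
    if symbol in available:
        return symbol
    alias = GENE_ALIASES.get(symbol)
    if alias is not None and alias in available:
        if log:
            logger.info("alias %r resolved to %r", symbol, alias)
        return alias
    return None


def checkpoint_panel(
    expr: pd.DataFrame,
    scores: pd.Series,
    genes=("CD274", "CTLA4", "PDCD1"),
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlate checkpoint-gene expression with the signature score.

    Aliases (PD-L1 → CD274, ...) are resolved and logged. With group labels
    supplied, a Wilcoxon high-vs-low comparison per gene is added. Raises if
    none of the panel genes is found.
    """
    scores = pd.Series(scores).astype(float)
    available = set(expr.index)
    rows = []
    pvals = []
    for symbol in genes:
        resolved = resolve_gene(symbol, available)
        if resolved is None:
            logger.warning("checkpoint gene %r not in matrix; skipped", symbol)
            continue
        values = expr.loc[resolved, scores.index].to_numpy(dtype=float)
        rep = correlate(values, scores.to_numpy(), name=f"{resolved}~score")
        row = {"gene": resolved, "requested": symbol, "r": rep.r, "p": rep.p, "n": rep.n}
        if groups is not None:
            cmp = compare_groups(values, groups.loc[scores.index], variable="expression")
            row["group_p"] = cmp.p
            row["group_test"] = cmp.test
        rows.append(row)
        pvals.append(rep.p)
    if not rows:
        raise ValueError("none of the panel genes found in the matrix")
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = multipletests(np.asarray(pvals), method="fdr_bh")[1]
    return out
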
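"""Gene-set enrichment: ssGSEA, named immune scores, ESTIMATE-style scores,
and pre-ranked two-group GSEA.

The single-sample enrichment statistic is a weighted running-sum integral.
Within one sample, genes get ascending average ranks ``r`` (highest
expression → rank N) and are walked in descending-expression order; at each
position the in-set ECDF weighted by ``|r|^alpha`` minus the unweighted
out-of-set ECDF is accumulated, and the enrichment score is the sum of
these step differences. Being rank-based, the score is invariant to any
strictly monotone per-sample transform of expression. Ties receive average
ranks (equal weights); tied genes are walked in matrix row order, which
makes the statistic deterministic.

The two-group GSEA ranks genes by the signal-to-noise statistic, uses the
classic weighted Kolmogorov–Smirnov enrichment score (weight exponent 1),
and draws its null from seeded phenotype permutations; NES divides the ES
by the mean same-sign null magnitude and p-values are floored at
``1/(n_perm+1)`` with Benjamini–Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, load_packaged_gene_sets

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentProfile",
    "EstimateResult",
    "GseaResult",
    "SSGSEATransformer",
    "ssgsea",
    "named_signature_scores",
    "cyt_geometric_mean",
    "estimate_scores",
    "preranked_gsea",
]

#: published cosine fit mapping the combined immune+stromal score to tumor
#: purity; calibrated on Affymetrix data, hence off by default elsewhere
PURITY_COS_INTERCEPT = 0.6049872018
PURITY_COS_SLOPE = 0.0001467884


@dataclass
class EnrichmentProfile:
    """Signature × sample score matrix with the parameters that produced it."""

    scores: pd.DataFrame  # signatures in rows, samples in columns
    alpha: float
    normalize: str
    skipped_sets: list[str]


def _sample_set_score(rank_values: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum integral for one sample and one gene set.

    ``rank_values`` are ascending average ranks, ``order`` walks genes in
    descending expression, ``in_set`` flags membership over genes.
    """
    m = in_set[order]
    n_in = int(m.sum())
    n_out = len(m) - n_in
    if n_out == 0:
        return 0.0  # set covers the whole matrix: out-set ECDF undefined
    w = np.abs(rank_values[order]) ** alpha * m
    denom = w.sum()
    if denom == 0:
        ecdf_in = np.cumsum(m) / n_in
    else:
        ecdf_in = np.cumsum(w) / denom
    ecdf_out = np.cumsum(~m) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(
    expr: pd.DataFrame,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: str = "range",
    min_overlap: int = 2,
) -> EnrichmentProfile:
    """Single-sample enrichment scores for every set, every sample.

    Sets sharing fewer than ``min_overlap`` genes with the matrix are
    skipped with a warning. With ``normalize="range"`` all scores are
    divided by (max − min) over the full profile matrix; ``"none"`` leaves
    the raw running-sum integrals.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    if normalize not in ("range", "none"):
        raise ValueError("normalize must be 'range' or 'none'")
    genes = expr.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    values = expr.to_numpy(dtype=float)
    n_genes, n_samples = values.shape

    masks: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for name in sets:
        idx = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if len(idx) < min_overlap:
            skipped.append(name)
            logger.warning("set %r overlaps %d genes (< min_overlap=%d); skipped", name, len(idx), min_overlap)
            continue
        m = np.zeros(n_genes, dtype=bool)
        m[idx] = True
        masks[name] = m
    if not masks:
        raise ValueError("all gene sets were filtered out by min_overlap")

    out = np.empty((len(masks), n_samples))
    names = list(masks)
    for s in range(n_samples):
        col = values[:, s]
        ranks = rankdata(col)  # ascending, average ties
        order = np.argsort(-col, kind="stable")  # ties walked in row order
        for k, name in enumerate(names):
            out[k, s] = _sample_set_score(ranks, order, masks[name], alpha)

    if normalize == "range":
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    return EnrichmentProfile(
        scores=pd.DataFrame(out, index=names, columns=expr.columns),
        alpha=alpha,
        normalize=normalize,
        skipped_sets=skipped,
    )


class SSGSEATransformer(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`ssgsea`.

    ``fit``/``transform`` follow the sample-major convention: ``X`` is a
    DataFrame with samples in rows and genes in columns; ``transform``
    returns a samples × signatures DataFrame. The statistic is per-sample,
    so ``fit`` only records the gene universe.
    """

    def __init__(
        self,
        gene_sets: GeneSetCollection | Mapping[str, Sequence[str]] | None = None,
        alpha: float = 0.25,
        normalize: str = "range",
        min_overlap: int = 2,
    ):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize
        self.min_overlap = min_overlap

    def fit(self, X: pd.DataFrame, y=None) -> "SSGSEATransformer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("SSGSEATransformer requires a DataFrame with gene-name columns")
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        sets = self.gene_sets if self.gene_sets is not None else load_packaged_gene_sets("immune")
        profile = ssgsea(X.T, sets, alpha=self.alpha, normalize=self.normalize, min_overlap=self.min_overlap)
        return profile.scores.T


def named_signature_scores(
    expr: pd.DataFrame,
    registry: GeneSetCollection | None = None,
    alpha: float = 0.25,
    normalize: str = "range",
) -> EnrichmentProfile:
    """Score the named immune signatures (APM, CYT, IFNG6, GEP, cycle steps,
    immune-cell sets) via ssGSEA with pipeline defaults.

    ``registry`` defaults to the packaged GMT and is user-editable; gene
    lists are configuration, not code.
    """
    if registry is None:
        registry = load_packaged_gene_sets("immune")
    return ssgsea(expr, registry, alpha=alpha, normalize=normalize)


def cyt_geometric_mean(expr: pd.DataFrame, genes: Sequence[str] = ("GZMA", "PRF1")) -> pd.Series:
    """Closed-form cytolytic-activity score: mean log2 expression of GZMA/PRF1.

    On log2-scale input the arithmetic mean is the log-scale geometric mean
    of the underlying intensities, the form in which CYT was originally
    defined. Offered alongside the ssGSEA variant of the two-gene set.
    """
    present = [g for g in genes if g in expr.index]
    if len(present) < len(genes):
        raise ValueError(f"CYT genes absent from matrix: {sorted(set(genes) - set(present))}")
    return expr.loc[list(genes)].mean(axis=0).rename("cyt_geometric_mean")


@dataclass
class EstimateResult:
    """ESTIMATE-style immune/stromal/combined scores with optional purity."""

    scores: pd.DataFrame  # per sample: immune_score, stromal_score, estimate_score, tumor_purity
    purity_enabled: bool


def estimate_scores(
    expr: pd.DataFrame,
    stromal_set: Sequence[str] | None = None,
    immune_set: Sequence[str] | None = None,
    purity_formula_enabled: bool = False,
) -> EstimateResult:
    """Immune/stromal enrichment and their sum; optionally the purity cosine.

    Immune and stromal scores are unnormalized ssGSEA scores of the
    respective sets; ``estimate_score`` is exactly their sum. When enabled,
    ``purity = cos(0.6049872018 + 0.0001467884 · estimate_score)`` clipped
    to [0, 1] with a warning outside the calibrated range; the formula's
    calibration is platform-specific, hence the flag.
    """
    if stromal_set is None or immune_set is None:
        tme = load_packaged_gene_sets("tme")
        immune_set = immune_set or tme["ESTIMATE_IMMUNE"]
        stromal_set = stromal_set or tme["ESTIMATE_STROMAL"]
    profile = ssgsea(
        expr,
        {"immune": list(immune_set), "stromal": list(stromal_set)},
        normalize="none",
    )
    if set(profile.scores.index) != {"immune", "stromal"}:
        raise ValueError("immune or stromal set does not overlap the matrix")
    immune = profile.scores.loc["immune"]
    stromal = profile.scores.loc["stromal"]
    estimate = immune + stromal
    df = pd.DataFrame(
        {"immune_score": immune, "stromal_score": stromal, "estimate_score": estimate}
    )
    if purity_formula_enabled:
        raw = np.cos(PURITY_COS_INTERCEPT + PURITY_COS_SLOPE * estimate.to_numpy())
        if ((raw < 0) | (raw > 1)).any():
            logger.warning("purity cosine left [0, 1] for some samples; values clipped")
        df["tumor_purity"] = np.clip(raw, 0.0, 1.0)
    else:
        df["tumor_purity"] = np.nan
    return EstimateResult(scores=df, purity_enabled=purity_formula_enabled)


@dataclass
class GseaResult:
    """Per-set pre-ranked GSEA outcome."""

    table: pd.DataFrame  # index=set; es, nes, p, q, size, leading_edge
    n_permutations: int
    seed: int


def _signal_to_noise(values: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise: (μ_pos − μ_neg) / (σ_pos + σ_neg)."""
    pos = values[:, pos_mask]
    neg = values[:, ~pos_mask]
    num = pos.mean(axis=1) - neg.mean(axis=1)
    denom = pos.std(axis=1, ddof=1) + neg.std(axis=1, ddof=1)
    return num / np.maximum(denom, 1e-8)


def _weighted_ks_es(metric: np.ndarray, in_set: np.ndarray) -> tuple[float, int]:
    """Classic weighted KS enrichment score; returns (ES, extremum index)."""
    order = np.argsort(-metric, kind="stable")
    m = in_set[order]
    w = np.abs(metric[order]) * m
    denom = w.sum()
    hit = np.cumsum(w) / denom if denom > 0 else np.cumsum(m) / max(int(m.sum()), 1)
    miss = np.cumsum(~m) / max(len(m) - int(m.sum()), 1)
    run = hit - miss
    idx = int(np.argmax(np.abs(run)))
    return float(run[idx]), idx


def _batch_es(metrics: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    """Enrichment scores for a batch of ranking-metric vectors (B × N)."""
    order = np.argsort(-metrics, axis=1, kind="stable")
    sm = np.take_along_axis(metrics, order, axis=1)
    m = in_set[order]
    w = np.abs(sm) * m
    denom = w.sum(axis=1, keepdims=True)
    n_in = int(in_set.sum())
    safe = np.where(denom > 0, denom, 1.0)
    hit = np.where(denom > 0, np.cumsum(w, axis=1) / safe, np.cumsum(m, axis=1) / max(n_in, 1))
    miss = np.cumsum(~m, axis=1) / max(in_set.size - n_in, 1)
    run = hit - miss
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(run.shape[0]), idx]


def preranked_gsea(
    expr: pd.DataFrame,
    group_labels,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 999,
    seed: int = 0,
    min_overlap: int = 2,
    positive_label: str | None = None,
) -> GseaResult:
    """Two-group GSEA with signal-to-noise ranking and phenotype permutation.

    Positive enrichment means the set sits at the top of the ranking, i.e.
    is up in ``positive_label`` (default: the alphabetically first label).
    """
    labels = pd.Series(group_labels, index=expr.columns).astype(str)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(uniq)}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    pos_label = positive_label if positive_label is not None else uniq[0]
    if pos_label not in uniq:
        raise ValueError(f"positive_label {pos_label!r} not among group labels")
    pos_mask = (labels == pos_label).to_numpy()
    if pos_mask.sum() < 3 or (~pos_mask).sum() < 3:
        raise ValueError("each group needs at least 3 samples")

    values = expr.to_numpy(dtype=float)
    genes = expr.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    metric = _signal_to_noise(values, pos_mask)

    rng = np.random.default_rng(seed)
    null_metrics = np.empty((n_perm, len(genes)))
    for b in range(n_perm):
        null_metrics[b] = _signal_to_noise(values, rng.permutation(pos_mask))

    rows = []
    order = np.argsort(-metric, kind="stable")
    for name in sets:
        idx = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if len(idx) < min_overlap:
            logger.warning("set %r overlaps %d genes; skipped", name, len(idx))
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[idx] = True
        es, ext = _weighted_ks_es(metric, in_set)
        null_es = _batch_es(null_metrics, in_set)
        same_sign = null_es[null_es >= 0] if es >= 0 else -null_es[null_es < 0]
        if same_sign.size == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign)) if es >= 0 else -abs(es) / np.mean(np.abs(same_sign))
            exceed = int(np.sum(same_sign >= abs(es)))
            p = (1.0 + exceed) / (1.0 + same_sign.size)
        sorted_in = in_set[order]
        if es >= 0:
            leading = genes[order[: ext + 1]][sorted_in[: ext + 1]]
        else:
            leading = genes[order[ext:]][sorted_in[ext:]]
        rows.append({"set": name, "es": es, "nes": nes, "p": p, "size": len(idx), "leading_edge": ",".join(leading)})
    if not rows:
        raise ValueError("all gene sets were filtered out by min_overlap")
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table[["es", "nes", "p", "q", "size", "leading_edge"]]
    return GseaResult(table=table, n_permutations=n_perm, seed=seed)
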
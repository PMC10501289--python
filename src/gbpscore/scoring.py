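"""GBP-family signature score: correlation-PCA construction and stratification.

The score condenses the expression of the seven guanylate-binding-protein
genes (GBP1–GBP7) into one per-sample scalar. Each family gene is first
standardized across samples (z-score); the gene–gene correlation matrix is
eigen-decomposed; and a sample's score is the sum of its coordinates on the
first two principal components,

    score_s = Σ_g (w1_g + w2_g) · z_{g,s},

where ``w1``/``w2`` are the unit-norm PC1/PC2 loading vectors. Each retained
component's sign is flipped so its loading sum is strictly positive (ties
broken by making the first gene's loading positive), which anchors the
score's polarity: it rises with family expression.

Also here: cohort stratification (median or maximally-selected survival
cutoff), a PCA group-separation diagnostic with a permutation test, the
family mutation-landscape summary, and the immunohistochemistry composite
score (intensity grade × positive-cell rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import GBP_FAMILY

logger = logging.getLogger(__name__)

__all__ = [
    "GBPScorer",
    "ScoreResult",
    "MutationSummary",
    "PcaSeparation",
    "fit_score_model",
    "compute_scores",
    "stratify",
    "pca_group_separation",
    "mutation_landscape",
    "ihc_composite",
]


class GBPScorer(TransformerMixin, BaseEstimator):
    """PCA-based gene-family signature scorer (scikit-learn estimator).

    Follows the sklearn sample-major convention: ``fit``/``transform`` take
    ``X`` with samples in rows and genes in columns (a DataFrame whose
    columns include the family genes, or an array whose columns *are* the
    family genes in order).

    Parameters
    ----------
    family_genes
        Gene symbols defining the signature family (default GBP1–GBP7).
        Family genes absent from the input are recorded in
        ``missing_genes_`` and excluded, provided at least two remain.
    n_components
        Number of leading components summed into the score (default 2).

    Attributes
    ----------
    genes_ : list of str — family genes actually used.
    missing_genes_ : list of str — requested but absent.
    means_, sds_ : ndarray — per-gene standardization constants (ddof=1).
    loadings_pc1_, loadings_pc2_ : ndarray — unit-norm, sign-oriented.
    explained_variance_ratio_ : ndarray over *all* components (sums to 1).
    sign_flips_ : ndarray of ±1 applied to the retained components.
    """

    def __init__(self, family_genes: Sequence[str] = GBP_FAMILY, n_components: int = 2):
        self.family_genes = family_genes
        self.n_components = n_components

    def _select(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            present = [g for g in self.family_genes if g in X.columns]
            return X.loc[:, present].to_numpy(dtype=float), present
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.family_genes):
            raise ValueError("array input must have one column per family gene")
        return X, list(self.family_genes)

    def fit(self, X, y=None) -> "GBPScorer":
        M, present = self._select(X)
        missing = [g for g in self.family_genes if g not in present]
        if len(present) < 2:
            raise ValueError(f"need at least 2 family genes in the matrix; found {len(present)}")
        if M.shape[0] < 3:
            raise ValueError("need at least 3 samples to fit the score model")
        if missing:
            logger.warning("family genes missing from matrix and excluded: %s", missing)

        means = M.mean(axis=0)
        sds = M.std(axis=0, ddof=1)
        # relative threshold: a constant gene row can carry rounding noise
        zero = [g for g, s, m in zip(present, sds, means) if s <= 1e-12 * (abs(m) + 1.0)]
        if zero:
            raise ValueError(f"zero-variance family gene(s): {zero}")
        Z = (M - means) / sds
        corr = Z.T @ Z / (M.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]

        k = min(self.n_components, len(present))
        flips = np.ones(k)
        for j in range(k):
            total = eigvecs[:, j].sum()
            if total < 0 or (total == 0 and eigvecs[0, j] < 0):
                flips[j] = -1.0
        eigvecs[:, :k] *= flips

        self.genes_ = present
        self.missing_genes_ = missing
        self.means_ = means
        self.sds_ = sds
        self.components_ = eigvecs[:, :k].T
        self.loadings_pc1_ = eigvecs[:, 0].copy()
        self.loadings_pc2_ = eigvecs[:, 1].copy() if k > 1 else np.zeros(len(present))
        self.explained_variance_ratio_ = eigvals / eigvals.sum()
        self.sign_flips_ = flips
        self.n_samples_fit_ = M.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        """Per-sample coordinates on the retained components (n_samples × k)."""
        check_is_fitted(self, "genes_")
        Z = self._standardize(X)
        return Z @ self.components_.T

    def score_samples(self, X) -> pd.Series | np.ndarray:
        """The signature score: sum of the retained-component coordinates."""
        check_is_fitted(self, "genes_")
        Z = self._standardize(X)
        scores = Z @ self.components_.sum(axis=0)
        if isinstance(X, pd.DataFrame):
            return pd.Series(scores, index=X.index, name="gbps_score")
        return scores

    def _standardize(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            absent = [g for g in self.genes_ if g not in X.columns]
            if absent:
                raise ValueError(f"model genes absent from matrix: {absent}")
            M = X.loc[:, self.genes_].to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            if M.shape[1] != len(self.genes_):
                raise ValueError("array input must have one column per fitted gene")
        return (M - self.means_) / self.sds_

    def to_dict(self) -> dict:
        """JSON-serializable model description."""
        check_is_fitted(self, "genes_")
        return {
            "genes": list(self.genes_),
            "missing_genes": list(self.missing_genes_),
            "means": self.means_.tolist(),
            "sds": self.sds_.tolist(),
            "loadings_pc1": self.loadings_pc1_.tolist(),
            "loadings_pc2": self.loadings_pc2_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "sign_flips": self.sign_flips_.tolist(),
        }


def fit_score_model(expr: pd.DataFrame, family_genes: Sequence[str] = GBP_FAMILY) -> GBPScorer:
    """Fit the score model on a genes × samples expression matrix."""
    return GBPScorer(family_genes=family_genes).fit(expr.T)


def compute_scores(model: GBPScorer, expr: pd.DataFrame) -> pd.Series:
    """Score every sample of a genes × samples matrix with a fitted model."""
    return model.score_samples(expr.T)


@dataclass
class ScoreResult:
    """Per-sample scores with high/low group labels."""

    scores: pd.Series
    group: pd.Series  # "high" / "low"
    cutoff: float
    rule: str  # "median" or "maxsel"

    @property
    def n_high(self) -> int:
        return int((self.group == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.group == "low").sum())


def stratify(
    scores: pd.Series,
    rule: str = "median",
    times: np.ndarray | pd.Series | None = None,
    events: np.ndarray | pd.Series | None = None,
    min_prop: float = 0.1,
) -> ScoreResult:
    """Split a cohort into high/low score groups.

    ``rule="median"`` cuts at the sample median; ``rule="maxsel"`` searches
    the maximally-selected log-rank cutoff and requires survival data.
    Samples exactly at the cutoff go to the **low** group (strict ``>`` for
    high); both groups must end up non-empty.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; cannot stratify")
    if rule == "median":
        cutoff = float(scores.median())
    elif rule == "maxsel":
        if times is None or events is None:
            raise ValueError("maxsel stratification requires survival times and events")
        from .survival import max_selected_cutoff

        cut = max_selected_cutoff(scores.to_numpy(), np.asarray(times, float), np.asarray(events, int), min_prop=min_prop)
        cutoff = cut.cutoff
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    group = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index, name="group")
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise ValueError("stratification produced an empty group")
    return ScoreResult(scores=scores, group=group, cutoff=cutoff, rule=rule)


@dataclass
class PcaSeparation:
    """First-two-PC projection of two labelled groups plus a permutation test."""

    coordinates: pd.DataFrame  # samples × (PC1, PC2)
    explained_variance_ratio: np.ndarray
    cumulative_variance_pc1_pc2: float
    observed_distance: float
    p_value: float
    n_permutations: int


def pca_group_separation(
    expr: pd.DataFrame,
    family_genes: Sequence[str],
    labels: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> PcaSeparation:
    """Project samples onto the family-gene PC1–PC2 plane and test separation.

    The statistic is the Euclidean distance between the two group centroids
    in the PC1–PC2 plane; its null distribution comes from label
    permutations (seeded). Used to check that tumors separate from normals.
    """
    labels = pd.Series(labels).reindex(expr.columns)
    uniq = labels.dropna().unique()
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 labels, found {len(uniq)}")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError("each group needs at least 3 samples")

    model = fit_score_model(expr, family_genes)
    coords = model.transform(expr.T)
    coords = pd.DataFrame(coords[:, :2], index=expr.columns, columns=["PC1", "PC2"])

    mask = (labels == uniq[0]).to_numpy()
    xy = coords.to_numpy()

    def centroid_distance(m: np.ndarray) -> float:
        return float(np.linalg.norm(xy[m].mean(axis=0) - xy[~m].mean(axis=0)))

    observed = centroid_distance(mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = centroid_distance(rng.permutation(mask))
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return PcaSeparation(
        coordinates=coords,
        explained_variance_ratio=model.explained_variance_ratio_,
        cumulative_variance_pc1_pc2=float(model.explained_variance_ratio_[:2].sum()),
        observed_distance=observed,
        p_value=float(p),
        n_permutations=n_permutations,
    )


@dataclass
class MutationSummary:
    """Family-level mutation landscape of a cohort."""

    per_gene_counts: dict[str, int]
    family_mutated_samples: int
    cohort_size: int
    family_frequency_percent: float
    excluded_genes: list[str] = field(default_factory=list)


def mutation_landscape(
    mutations: pd.DataFrame,
    cohort_size: int,
    family_genes: Sequence[str] = GBP_FAMILY,
) -> MutationSummary:
    """Summarize family-gene mutations over a cohort.

    A sample counts once toward ``family_mutated_samples`` regardless of how
    many family genes are hit; the family frequency is reported as a
    percentage rounded to 2 decimals. Records for genes outside the family
    universe are excluded with a warning.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be at least 1")
    family = list(family_genes)
    known = mutations[mutations["gene"].isin(family)]
    unknown = sorted(set(mutations["gene"]) - set(family))
    if unknown:
        logger.warning("mutation records for genes outside the family universe excluded: %s", unknown)
    per_gene = {g: int(known.loc[known["gene"] == g, "sample_id"].nunique()) for g in family}
    mutated = int(known["sample_id"].nunique())
    if mutated > cohort_size:
        raise ValueError("more mutated samples than cohort_size")
    freq = round(100.0 * mutated / cohort_size, 2)
    return MutationSummary(
        per_gene_counts=per_gene,
        family_mutated_samples=mutated,
        cohort_size=int(cohort_size),
        family_frequency_percent=freq,
        excluded_genes=unknown,
    )


def ihc_composite(intensity_grade: int, positive_rate: float) -> float:
    """Immunohistochemistry composite: staining intensity grade × positive-cell rate.

    Grade 0–3 codes negative / weak / moderate / strong staining; the rate
    is the fraction of positive cells in [0, 1]. The product lies in [0, 3].
    """
    if intensity_grade not in (0, 1, 2, 3):
        raise ValueError("intensity_grade must be one of {0, 1, 2, 3}")
    if not 0.0 <= positive_rate <= 1.0:
        raise ValueError("positive_rate must lie in [0, 1]")
    return float(intensity_grade) * float(positive_rate)
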
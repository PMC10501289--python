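"""Synthetic HCC-like cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any cohort download:

* a per-sample latent "immune-hot" factor (standard normal);
* a 7-gene family plus immune-signature genes co-expressed with that
  factor (``x_gs = loading_g * latent_s + eps``, Gaussian noise);
* overall survival from an exponential proportional-hazards model in which
  the latent factor is protective by default;
* independent exponential right-censoring whose rate is calibrated by
  bisection so the realized censored fraction matches a target;
* a binary immunotherapy-responder label whose log-odds rise with the
  latent factor;
* sparse, expression-independent per-gene mutation indicators.

All randomness flows from a single integer seed; identical configs yield
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSetCollection, load_packaged_gene_sets

__all__ = [
    "GBP_FAMILY",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_two_group_expression",
    "default_signature_groups",
    "default_latent_loadings",
]

GBP_FAMILY: tuple[str, ...] = ("GBP1", "GBP2", "GBP3", "GBP4", "GBP5", "GBP6", "GBP7")

#: immune-checkpoint genes wired to the latent factor so responder analyses
#: have signal to recover
CHECKPOINT_GENES: tuple[str, ...] = ("CD274", "CTLA4", "PDCD1")

_NOISE_PREFIX = "NOISE"


def default_signature_groups() -> dict[str, list[str]]:
    """Gene groups co-regulated with the latent factor by default.

    Pulls the packaged immune signature sets (APM, CYT, IFNG6, GEP,
    cancer-immunity-cycle steps, immune-cell sets) plus the ESTIMATE-style
    immune/stromal lists and the checkpoint panel.
    """
    groups: dict[str, list[str]] = {}
    for which in ("immune", "tme"):
        coll: GeneSetCollection = load_packaged_gene_sets(which)
        for name in coll:
            groups[name] = list(coll[name])
    groups["CHECKPOINTS"] = list(CHECKPOINT_GENES)
    return groups


def default_latent_loadings(
    family_genes: Sequence[str],
    signature_groups: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Per-gene latent-factor loadings: family 1.0, immune 0.8, stromal 0.3."""
    loadings: dict[str, float] = {g: 1.0 for g in family_genes}
    for name, genes in signature_groups.items():
        weight = 0.3 if "STROMAL" in name.upper() else 0.8
        for g in genes:
            if g not in loadings:
                loadings[g] = weight
    return loadings


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``hazard_coef_latent`` is the log hazard ratio per latent-factor unit
    (negative → protective, the default direction). ``hazard_step_at``
    switches to a step hazard ``exp(hazard_coef_latent * 1[latent > s])``
    for cutoff-recovery experiments.
    """

    n_samples: int = 400
    n_noise_genes: int = 200
    family_genes: tuple[str, ...] = GBP_FAMILY
    signature_gene_groups: dict[str, list[str]] = field(default_factory=default_signature_groups)
    latent_loading: dict[str, float] | None = None
    noise_sd: float = 1.0
    hazard_coef_latent: float = -0.8
    baseline_hazard: float = 0.05
    censoring_rate_target: float = 0.3
    responder_logit_slope: float = 1.0
    mutation_rate_per_gene: float = 0.004
    hazard_step_at: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 < self.censoring_rate_target < 1.0:
            raise ValueError("censoring_rate_target must lie in (0, 1)")
        if not 0.0 <= self.mutation_rate_per_gene <= 1.0:
            raise ValueError("mutation_rate_per_gene must lie in [0, 1]")
        if len(set(self.family_genes)) != len(self.family_genes):
            raise ValueError("family gene symbols must be unique")
        named = set(self.family_genes)
        for genes in self.signature_gene_groups.values():
            named.update(genes)
        clash = [g for g in named if g.startswith(_NOISE_PREFIX)]
        if clash:
            raise ValueError(f"gene symbols collide with the noise-gene namespace: {clash}")

    @property
    def gene_order(self) -> list[str]:
        """Deterministic gene order: family, signature genes, then noise."""
        genes = list(self.family_genes)
        for group in self.signature_gene_groups.values():
            for g in group:
                if g not in genes:
                    genes.append(g)
        genes.extend(f"{_NOISE_PREFIX}{i:04d}" for i in range(self.n_noise_genes))
        return genes

    @property
    def loadings(self) -> dict[str, float]:
        if self.latent_loading is not None:
            return dict(self.latent_loading)
        return default_latent_loadings(self.family_genes, self.signature_gene_groups)


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    latent: np.ndarray
    true_hazard_coef: float
    true_cutpoint: float | None
    seed: int

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["latent"] = [float(v) for v in self.latent]
        return d


def _calibrate_censoring_rate(event_times: np.ndarray, unit_draws: np.ndarray, target: float) -> float:
    """Bisect the exponential censoring rate to hit the target censored fraction.

    ``unit_draws`` are fixed Exp(1) variates; censor time = draw / rate, so
    the realized censored fraction mean(draw/rate < T) is non-decreasing in
    the rate, making bisection valid for fixed draws.
    """
    lo, hi = 1e-9, 1e9

    def frac(rate: float) -> float:
        return float(np.mean(unit_draws / rate < event_times))

    for _ in range(200):
        mid = np.sqrt(lo * hi)  # log-scale bisection over 18 decades
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic cohort.

    Returns
    -------
    expression : DataFrame, genes × samples
    clinical : DataFrame indexed by sample_id with ``os_time``, ``os_event``,
        categorical/continuous covariates and a ``response`` label
    mutations : long DataFrame (sample_id, gene, variant_class)
    truth : :class:`SyntheticTruth`
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    genes = config.gene_order
    sample_ids = [f"S{i:04d}" for i in range(n)]

    latent = rng.standard_normal(n)
    loadings = config.loadings
    w = np.array([loadings.get(g, 0.0) for g in genes])
    noise = rng.standard_normal((len(genes), n)) * config.noise_sd
    values = w[:, None] * latent[None, :] + noise
    expr = pd.DataFrame(values, index=genes, columns=sample_ids)

    # exponential PH survival
    if config.hazard_step_at is None:
        log_hr = config.hazard_coef_latent * latent
    else:
        log_hr = config.hazard_coef_latent * (latent > config.hazard_step_at).astype(float)
    hazard = config.baseline_hazard * np.exp(log_hr)
    event_times = rng.exponential(1.0, size=n) / hazard

    censor_draws = rng.exponential(1.0, size=n)
    rate = _calibrate_censoring_rate(event_times, censor_draws, config.censoring_rate_target)
    censor_times = censor_draws / rate
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)

    prob = 1.0 / (1.0 + np.exp(-config.responder_logit_slope * latent))
    responder = rng.random(n) < prob

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=[0.35, 0.30, 0.20, 0.15]),
            "grade": rng.choice(["G1", "G2", "G3", "G4"], size=n, p=[0.15, 0.40, 0.35, 0.10]),
            "tumor_size_cm": np.round(rng.lognormal(1.2, 0.5, size=n), 2),
            "afp_ng_ml": np.round(rng.lognormal(3.0, 2.0, size=n), 1),
            "cirrhosis": rng.integers(0, 2, size=n),
            "response": np.where(responder, "responder", "non_responder"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    variant_classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]
    records = []
    for gene in config.family_genes:
        hits = np.flatnonzero(rng.random(n) < config.mutation_rate_per_gene)
        for i in hits:
            records.append((sample_ids[i], gene, variant_classes[int(rng.integers(len(variant_classes)))]))
    mutations = pd.DataFrame(records, columns=["sample_id", "gene", "variant_class"])

    truth = SyntheticTruth(
        latent=latent,
        true_hazard_coef=config.hazard_coef_latent,
        true_cutpoint=config.hazard_step_at,
        seed=config.seed,
    )
    return expr, clinical, mutations, truth


def generate_two_group_expression(
    n_per_group: int,
    shift: float,
    seed: int,
    family_genes: Sequence[str] = GBP_FAMILY,
    n_noise_genes: int = 50,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group fixture: family genes shifted by ``shift`` in group ``B``.

    Used to test tumor-vs-normal PCA separation. Returns a genes × samples
    matrix and a per-sample label Series (``A``/``B``).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    genes = list(family_genes) + [f"{_NOISE_PREFIX}{i:04d}" for i in range(n_noise_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    labels = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=sample_ids, name="group")

    latent = rng.standard_normal(n)
    w = np.array([1.0 if g in set(family_genes) else 0.0 for g in genes])
    values = w[:, None] * latent[None, :] + rng.standard_normal((len(genes), n)) * noise_sd
    values[: len(family_genes), n_per_group:] += shift
    return pd.DataFrame(values, index=genes, columns=sample_ids), labels
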
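"""End-to-end orchestration: io → scoring → stratify → survival → enrichment
→ association, with a reproducible output bundle.

One global seed is fanned out to fixed per-stage child seeds (derived from
``numpy.random.SeedSequence([seed, stage_index])``), so toggling a stage
off never shifts another stage's randomness. Every table carries a header
comment with the config hash and seed; ``run_manifest.json`` records the
config, versions and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import enrichment as enrich
from . import io as gio
from . import scoring
from . import survival as surv
from .simulate import GBP_FAMILY, SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo"]

_STAGES = ("io", "scoring", "stratify", "survival", "enrichment", "association")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run (YAML-serializable)."""

    expression: str
    clinical: str
    out_dir: str
    gmt: str | None = None  # None → packaged immune signatures
    mutations: str | None = None
    family_genes: list[str] = field(default_factory=lambda: list(GBP_FAMILY))
    rule: str = "median"  # or "maxsel"
    min_prop: float = 0.1
    log_transform: bool = False
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: str = "range"
    covariates: list[str] = field(default_factory=list)
    seed: int = 0
    survival_time_unit: str = "months"  # reporting label only; never rescaled
    stages: dict[str, bool] = field(default_factory=lambda: {"survival": True, "enrichment": True, "association": True})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def enabled(self, stage: str) -> bool:
        if stage in ("io", "scoring", "stratify"):
            return True
        return bool(self.stages.get(stage, True))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns the manifest dict. On a stage failure a :class:`PipelineError`
    is raised carrying the stage name; outputs already written stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comment = f"gbpscore {__version__} config_hash={config.config_hash()} seed={config.seed}"
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }

    def done(stage: str, rows: dict) -> None:
        manifest["stages"][stage] = {"status": "completed", "rows": rows}
        _write_manifest(manifest, out)

    def skipped(stage: str) -> None:
        manifest["stages"][stage] = {"status": "skipped"}
        _write_manifest(manifest, out)

    # ---- io ----
    try:
        expr = gio.read_expression(config.expression, log_transform=config.log_transform)
        clin = gio.read_clinical(config.clinical)
        expr, clin = gio.align_cohort(expr, clin)
        sets = gio.read_gmt(config.gmt) if config.gmt else gio.load_packaged_gene_sets("immune")
        mutations = gio.read_mutations(config.mutations) if config.mutations else None
    except Exception as exc:
        raise PipelineError("io", "read_failed", str(exc)) from exc
    done("io", {"genes": int(expr.shape[0]), "samples": int(expr.shape[1]), "gene_sets": len(sets)})

    # ---- scoring ----
    try:
        model = scoring.fit_score_model(expr, config.family_genes)
        scores = scoring.compute_scores(model, expr)
        gio._write_table(scores.to_frame(), out / "scores.tsv", index_label="sample_id", header_comment=comment)
        with open(out / "score_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        if mutations is not None:
            summary = scoring.mutation_landscape(mutations, cohort_size=expr.shape[1], family_genes=config.family_genes)
            mut_df = pd.DataFrame(
                [{"gene": g, "mutated_samples": c} for g, c in summary.per_gene_counts.items()]
                + [{"gene": "FAMILY_ANY", "mutated_samples": summary.family_mutated_samples}]
            ).set_index("gene")
            mut_df["cohort_size"] = summary.cohort_size
            mut_df["frequency_percent"] = (100.0 * mut_df["mutated_samples"] / summary.cohort_size).round(2)
            gio._write_table(mut_df, out / "mutation_summary.tsv", index_label="gene", header_comment=comment)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("scoring", "score_failed", str(exc)) from exc
    done("scoring", {"scores": int(len(scores))})

    # ---- stratify ----
    try:
        result = scoring.stratify(
            scores,
            rule=config.rule,
            times=clin["os_time"] if config.rule == "maxsel" else None,
            events=clin["os_event"] if config.rule == "maxsel" else None,
            min_prop=config.min_prop,
        )
        groups_df = pd.DataFrame({"gbps_score": result.scores, "group": result.group})
        gio._write_table(groups_df, out / "groups.tsv", index_label="sample_id", header_comment=comment)
    except Exception as exc:
        raise PipelineError("stratify", "stratify_failed", str(exc)) from exc
    done("stratify", {"groups": int(len(result.group)), "cutoff": result.cutoff, "rule": result.rule})

    times = clin["os_time"].to_numpy()
    events = clin["os_event"].to_numpy()

    # ---- survival ----
    if not config.enabled("survival"):
        skipped("survival")
        km = None
    else:
        try:
            km = surv.km_fit(times, events, result.group.to_numpy())
            km_dir = out / "km_tables"
            for g, tab in km.tables.items():
                gio._write_table(tab.set_index("time"), km_dir / f"{g}.tsv", index_label="time", header_comment=comment)
            forest_rows = []
            high = (result.group == "high").astype(float).to_numpy()
            uni = surv.cox_fit(times, events, pd.DataFrame({"high_group": high}))
            for term, row in uni.summary.iterrows():
                forest_rows.append({"model": "univariate", "term": term, **row.to_dict(), "n": uni.n_used})
            available = [c for c in config.covariates if c in clin.columns]
            if available:
                cov = clin[available].copy()
                cov.insert(0, "high_group", high)
                multi = surv.cox_fit(times, events, cov)
                for term, row in multi.summary.iterrows():
                    forest_rows.append({"model": "multivariate", "term": term, **row.to_dict(), "n": multi.n_used})
            forest = pd.DataFrame(forest_rows).set_index("term")
            gio._write_table(forest, out / "cox_forest.tsv", index_label="term", header_comment=comment)
            cindex, n_pairs = surv.concordance_index(times, events, -result.scores.to_numpy())
        except Exception as exc:
            raise PipelineError("survival", "survival_failed", str(exc)) from exc
        done(
            "survival",
            {
                "km_groups": len(km.tables),
                "cox_terms": int(len(forest)),
                "logrank_p": km.logrank_p,
                "cindex_score": cindex,
                "cindex_pairs": n_pairs,
                "time_unit": config.survival_time_unit,
            },
        )

    # ---- enrichment ----
    profile = None
    if not config.enabled("enrichment"):
        skipped("enrichment")
    else:
        try:
            profile = enrich.ssgsea(expr, sets, alpha=config.ssgsea_alpha, normalize=config.ssgsea_normalize)
            gio._write_table(profile.scores, out / "enrichment.tsv", index_label="signature", header_comment=comment)
            est = enrich.estimate_scores(expr)
            gio._write_table(est.scores, out / "estimate_scores.tsv", index_label="sample_id", header_comment=comment)
        except Exception as exc:
            raise PipelineError("enrichment", "enrichment_failed", str(exc)) from exc
        done("enrichment", {"signatures": int(profile.scores.shape[0]), "estimate_rows": int(est.scores.shape[0])})

    # ---- association ----
    if not config.enabled("association"):
        skipped("association")
    else:
        try:
            rows_written = {}
            if profile is not None:
                stacked = pd.concat([result.scores.rename("GBPS_SCORE").to_frame().T, profile.scores])
                corr = assoc.correlation_matrix(stacked)
                corr = corr[(corr["var_a"] == "GBPS_SCORE") | (corr["var_b"] == "GBPS_SCORE")].reset_index(drop=True)
                gio._write_table(corr, out / "correlations.tsv", index_label=None, header_comment=comment)
                rows_written["correlations"] = int(len(corr))
            try:
                panel = assoc.checkpoint_panel(expr, result.scores, groups=result.group)
                gio._write_table(panel, out / "checkpoint_panel.tsv", index_label="gene", header_comment=comment)
                rows_written["checkpoint_genes"] = int(len(panel))
            except ValueError:
                logger.info("no checkpoint genes in matrix; panel skipped")
            tests = []
            if "response" in clin.columns:
                cmp = assoc.compare_groups(result.scores.to_numpy(), clin["response"], variable="gbps_score")
                tests.append(
                    {
                        "variable": cmp.variable,
                        "test": cmp.test,
                        "statistic": cmp.statistic,
                        "p": cmp.p,
                        "summary": json.dumps(cmp.group_summary, sort_keys=True),
                    }
                )
            if tests:
                gio._write_table(pd.DataFrame(tests), out / "group_tests.tsv", index_label=None, header_comment=comment)
                rows_written["group_tests"] = len(tests)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("association", "association_failed", str(exc)) from exc
        done("association", rows_written)

    return manifest


def make_demo(out_dir: str | Path, seed: int = 1, run: bool = True) -> dict:
    """Write a small self-contained demo workspace and (optionally) run it.

    The cohort has 120 samples and 300 genes (family + immune-signature
    genes + noise fill). Returns the run manifest (or the written config as
    a dict when ``run=False``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    base = SimulationConfig(n_samples=120, n_noise_genes=0, seed=seed)
    fill = max(0, 300 - len(base.gene_order))
    cfg = SimulationConfig(n_samples=120, n_noise_genes=fill, seed=seed)
    expr, clin, mut, truth = generate_cohort(cfg)

    gio.write_expression(expr, out / "expression.tsv")
    gio.write_clinical(clin, out / "clinical.tsv")
    gio.write_mutations(mut, out / "mutations.tsv")
    gio.write_gmt(gio.load_packaged_gene_sets("immune"), out / "signatures.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh)

    pconf = PipelineConfig(
        expression=str(out / "expression.tsv"),
        clinical=str(out / "clinical.tsv"),
        gmt=str(out / "signatures.gmt"),
        mutations=str(out / "mutations.tsv"),
        out_dir=str(out / "results"),
        covariates=["stage", "grade"],
        seed=seed,
    )
    pconf.to_yaml(out / "run.yaml")
    if run:
        return run_pipeline(pconf)
    return asdict(pconf)


def _versions() -> dict[str, str]:
    import lifelines
    import scipy
    import sklearn

    return {
        "gbpscore": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
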
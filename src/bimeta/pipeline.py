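"""End-to-end orchestration: simulate -> bimodal screen -> survival meta ->
genotype screen -> associations -> GSEA, with a hashed output manifest.

All randomness flows from the single config seed through named substreams, so a
re-run with the same config reproduces every output file bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import correlation_screen, metabolite_multivariate
from .bimodality import (dichotomize_cluster, fit_gmm2, screen_bimodal_genes,
                         screen_bimodal_study)
from .dataio import GeneSetCollection
from .genotype import assign_genotype_group, call_tsg_status, oncogenotype_screen
from .gsea import gsea_permutation
from .survival import run_survival_screen
from .synthetic import SyntheticConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen_bimodal", "survival_meta", "genotype_screen",
          "associate", "gsea")


@dataclass
class RunConfig:
    """Flat run configuration: stage toggles, thresholds, seed, output dir."""

    outdir: str = "bimeta_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synthetic: SyntheticConfig | None = None
    # thresholds (defaults follow the study rules)
    min_n: int = 10          # minimum cohort size entering the meta-analysis
    min_mut: int = 9         # minimum mutant count for the oncogenotype screen
    cn_loss_threshold: float = -1.0
    hi_q: float = 0.8
    lo_q: float = 0.7
    min_bi: float = 1.1      # annotation threshold for the bimodal screen
    n_perm: int = 200        # GSEA permutations for pipeline runs
    gsea_sets: str | None = None  # GMT path; None -> a built-in demo collection

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid: {STAGES}")
        if not (0 <= self.lo_q <= self.hi_q <= 1):
            raise ValueError("require 0 <= lo_q <= hi_q <= 1")
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn_raw = raw.pop("synthetic", None)
        cfg = cls(**{k: (tuple(v) if k == "stages" else v) for k, v in raw.items()})
        if syn_raw is not None:
            from .synthetic import (CensoringParams, CovariateParams, GenotypeParams,
                                    HazardParams, MetaboliteParams, MixtureParams)
            parts = {
                "mixture": MixtureParams, "hazard": HazardParams,
                "censoring": CensoringParams, "genotype": GenotypeParams,
                "metabolite": MetaboliteParams, "covariates": CovariateParams,
            }
            kwargs = {}
            for key, value in syn_raw.items():
                if key in parts:
                    if isinstance(value, dict):
                        value = {k: tuple(v) if isinstance(v, list) else v
                                 for k, v in value.items()}
                        value = parts[key](**value)
                    kwargs[key] = value
                elif key == "n_samples" and isinstance(value, list):
                    kwargs[key] = tuple(value)
                else:
                    kwargs[key] = value
            kwargs.setdefault("seed", cfg.seed)
            cfg.synthetic = SyntheticConfig(**kwargs)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_gene_sets(gene_ids: list[str], target: str) -> GeneSetCollection:
    """Small deterministic collection over the dataset's own gene universe."""
    nulls = [g for g in gene_ids if g != target]
    sets = {
        "TOP_NULL_BLOCK": nulls[:20],
        "MID_NULL_BLOCK": nulls[20:40],
        "TARGET_NEIGHBORHOOD": [target] + nulls[40:55],
    }
    return GeneSetCollection(sets={k: v for k, v in sets.items() if len(v) >= 5},
                             descriptions={k: "demo set" for k in sets})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run manifest.

    Every output file is listed in ``manifest.json`` with its sha256 hash; a
    stage failure aborts the run with the failing stage named, leaving partial
    outputs plus a FAILED marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": {
            "min_n": config.min_n, "min_mut": config.min_mut,
            "cn_loss_threshold": config.cn_loss_threshold,
            "hi_q": config.hi_q, "lo_q": config.lo_q, "min_bi": config.min_bi,
            "n_perm": config.n_perm,
        },
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path.relative_to(outdir)),
                                     "sha256": _sha256(path)}

    current = "setup"
    try:
        current = "simulate"
        study = simulate_study(config.synthetic)
        if "simulate" in config.stages:
            write_study(study, outdir / "study")
            for p in sorted((outdir / "study").iterdir()):
                record(f"study/{p.name}", p)
        target = config.synthetic.target_gene
        cohort0 = study.cohorts[0]

        if "screen_bimodal" in config.stages:
            current = "screen_bimodal"
            screen = screen_bimodal_study(
                [c.expression for c in study.cohorts], min_bi=config.min_bi)
            path = outdir / "bimodal_screen.tsv"
            screen.to_csv(path, sep="\t", index=False, float_format="%.6g")
            record("bimodal_screen", path)
            cohort_screen = screen_bimodal_genes(cohort0.expression,
                                                 min_bi=config.min_bi)
            path = outdir / "bimodal_screen_cohort0.tsv"
            cohort_screen.to_csv(path, sep="\t", index=False, float_format="%.6g")
            record("bimodal_screen_cohort0", path)

        if "survival_meta" in config.stages:
            current = "survival_meta"
            surv = run_survival_screen(study.survival_inputs(), [target],
                                       min_n=config.min_n)
            path = outdir / "survival_meta.tsv"
            surv.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
            record("survival_meta", path)
            path = outdir / "survival_effects.tsv"
            surv.effects_frame().to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")
            record("survival_effects", path)
            (outdir / "survival_exclusions.log").write_text(
                "\n".join(surv.exclusions) + ("\n" if surv.exclusions else ""))
            record("survival_exclusions", outdir / "survival_exclusions.log")

        have_mutations = cohort0.mutations is not None and len(cohort0.mutations) > 0
        if "genotype_screen" in config.stages and have_mutations:
            current = "genotype_screen"
            candidates = sorted(set(cohort0.mutations.data["gene"]))
            hits = oncogenotype_screen(cohort0.expression, target,
                                       cohort0.mutations, candidates,
                                       min_mut=config.min_mut)
            path = outdir / "oncogenotype_screen.tsv"
            hits.to_csv(path, sep="\t", index=False, float_format="%.6g")
            record("oncogenotype_screen", path)
            status = call_tsg_status(cohort0.expression.sample_ids,
                                     mutations=cohort0.mutations,
                                     cn_loss_threshold=config.cn_loss_threshold)
            groups = assign_genotype_group(status)
            path = outdir / "genotype_groups.tsv"
            groups.to_frame().to_csv(path, sep="\t")
            record("genotype_groups", path)

        if "associate" in config.stages:
            current = "associate"
            corr = correlation_screen(cohort0.expression, target)
            path = outdir / "correlation_screen.tsv"
            corr.to_csv(path, sep="\t", index=False, float_format="%.6g")
            record("correlation_screen", path)
            if have_mutations:
                expr = cohort0.expression.gene_values(target)
                fit = fit_gmm2(expr)
                labels = dichotomize_cluster(expr, fit)
                sample_ids = cohort0.expression.sample_ids
                keap1 = np.array([s in cohort0.mutations.mutated_samples("KEAP1")
                                  for s in sample_ids], dtype=float)
                stk11 = np.array([s in cohort0.mutations.mutated_samples("STK11")
                                  for s in sample_ids], dtype=float)
                met = cohort0.metabolites.iloc[:, 0].reindex(sample_ids).to_numpy()
                model = metabolite_multivariate(met, labels.high_mask.astype(float),
                                                keap1, stk11)
                path = outdir / "metabolite_model.tsv"
                model.terms.to_csv(path, sep="\t", index_label="term",
                                   float_format="%.6g")
                record("metabolite_model", path)

        if "gsea" in config.stages:
            current = "gsea"
            if config.gsea_sets:
                from .dataio import read_gmt
                sets = read_gmt(config.gsea_sets)
            else:
                sets = _demo_gene_sets(cohort0.expression.gene_ids, target)
            expr = cohort0.expression.gene_values(target)
            fit = fit_gmm2(expr)
            labels = dichotomize_cluster(expr, fit)
            screen = gsea_permutation(cohort0.expression, labels.high_mask, sets,
                                      n_perm=config.n_perm, seed=config.seed)
            path = outdir / "gsea_results.tsv"
            screen.to_frame().to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")
            record("gsea_results", path)
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {current}\n")
        logger.exception("pipeline failed at stage %r", current)
        raise

    man_df = json.dumps(manifest, indent=2, sort_keys=True)
    (outdir / "manifest.json").write_text(man_df)
    return manifest
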
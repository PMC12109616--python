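"""Synthetic multi-cohort studies with the structure the analysis assumes.

Each cohort draws, per sample i:

* a latent component z_i ~ Bernoulli(pi_high);
* target-gene expression x_i = mu_low + z_i * delta + N(0, sigma^2);
* an event time T_i ~ Exponential(rate = lambda0 * exp(beta * z_i)), censored at
  min(administrative horizon, Exponential(random censor rate));
* tumor-suppressor mutations (KEAP1, STK11) ~ Bernoulli(q_high if z_i else q_low),
  plus background-mutated null candidate genes independent of z;
* a metabolite m_i = alpha + b * x_i + gamma_K * mutK + gamma_S * mutS + N(0, tau^2);
* i.i.d. unimodal null genes ~ N(mu_low + delta * pi_high, sigma^2).

Cohorts use independent, reproducible random substreams derived from the master
seed and the cohort index, so any subset of cohorts regenerates bit-identically.
Defaults mirror the multi-study design the pipeline targets: 23 cohorts of 135
patients (~3100 cases), mixture (0, 3, 1, 0.3), component log-HR ln 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    ClinicalTable,
    ExpressionDataset,
    MutationTable,
    write_clinical,
    write_expression,
    write_mutations,
)


@dataclass(frozen=True)
class MixtureParams:
    mu_low: float = 0.0
    delta: float = 3.0          # separation mu_high - mu_low (expression units)
    sigma: float = 1.0          # common within-component SD
    pi_high: float = 0.3        # proportion of the high component


@dataclass(frozen=True)
class HazardParams:
    baseline_rate: float = 0.1          # events per unit time in the low component
    log_hr_component: float = math.log(2.0)  # beta: log-HR of high vs low


@dataclass(frozen=True)
class CensoringParams:
    admin_time: float = 10.0            # administrative follow-up horizon
    random_censor_rate: float = 0.05    # rate of random loss to follow-up (0 = none)


@dataclass(frozen=True)
class GenotypeParams:
    genes: tuple[str, ...] = ("KEAP1", "STK11")
    q_high: float = 0.5     # P(mutation | high component)
    q_low: float = 0.05     # P(mutation | low component)
    n_null_candidates: int = 50   # background-mutated genes independent of z
    background_rate: float = 0.1
    variant_class: str = "Missense_Mutation"


@dataclass(frozen=True)
class MetaboliteParams:
    name: str = "metabolite_1"
    intercept: float = 0.0
    slope: float = 0.5          # per unit target-gene expression
    effect_keap1: float = 0.5
    effect_stk11: float = 0.5
    noise_sd: float = 1.0


@dataclass(frozen=True)
class CovariateParams:
    age_mean: float = 65.0
    age_sd: float = 10.0
    p_male: float = 0.5
    stage_probs: tuple[float, ...] = (0.5, 0.25, 0.15, 0.10)  # stages I-IV
    p_smoker: float = 0.7


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters of a simulated multi-cohort study."""

    n_cohorts: int = 23
    n_samples: int | tuple[int, ...] = 135
    n_null_genes: int = 200
    target_gene: str = "KYNU"
    mixture: MixtureParams = field(default_factory=MixtureParams)
    hazard: HazardParams = field(default_factory=HazardParams)
    censoring: CensoringParams = field(default_factory=CensoringParams)
    genotype: GenotypeParams = field(default_factory=GenotypeParams)
    metabolite: MetaboliteParams = field(default_factory=MetaboliteParams)
    covariates: CovariateParams = field(default_factory=CovariateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mixture.pi_high < 1.0:
            raise ValueError("pi_high must lie in (0, 1)")
        if self.mixture.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.hazard.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for q in (self.genotype.q_high, self.genotype.q_low,
                  self.genotype.background_rate):
            if not 0.0 <= q <= 1.0:
                raise ValueError("mutation probabilities must lie in [0, 1]")
        if min(self.samples_per_cohort()) < 2:
            raise ValueError("each cohort needs n_samples >= 2")
        if self.n_cohorts < 1:
            raise ValueError("need at least one cohort")

    def samples_per_cohort(self) -> tuple[int, ...]:
        if isinstance(self.n_samples, int):
            return (self.n_samples,) * self.n_cohorts
        if len(self.n_samples) != self.n_cohorts:
            raise ValueError("n_samples sequence length must equal n_cohorts")
        return tuple(self.n_samples)


@dataclass
class SyntheticCohort:
    """One simulated cohort plus its latent truth."""

    cohort_id: str
    expression: ExpressionDataset
    clinical: ClinicalTable
    mutations: MutationTable
    metabolites: pd.DataFrame  # sample_id-indexed
    truth: dict  # z labels, true parameters


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    cohorts: list[SyntheticCohort]

    def survival_inputs(self) -> list[tuple[ExpressionDataset, ClinicalTable]]:
        return [(c.expression, c.clinical) for c in self.cohorts]


def _cohort_rng(seed: int, cohort_index: int) -> np.random.Generator:
    """Independent substream for one cohort, stable under cohort subsets."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(cohort_index,)))


def simulate_cohort(config: SyntheticConfig, cohort_index: int) -> SyntheticCohort:
    """Draw one cohort under the generative model (deterministic in seed+index)."""
    rng = _cohort_rng(config.seed, cohort_index)
    n = config.samples_per_cohort()[cohort_index]
    cohort_id = f"cohort{cohort_index:02d}"
    sample_ids = [f"{cohort_id}_s{i:04d}" for i in range(n)]
    mx, hz, cz = config.mixture, config.hazard, config.censoring

    z = rng.binomial(1, mx.pi_high, size=n)
    x = mx.mu_low + z * mx.delta + rng.normal(0.0, mx.sigma, size=n)

    # survival: exponential baseline, proportional hazards in z
    rate = hz.baseline_rate * np.exp(hz.log_hr_component * z)
    event_time = rng.exponential(1.0 / rate)
    censor_time = np.full(n, cz.admin_time)
    if cz.random_censor_rate > 0:
        censor_time = np.minimum(
            censor_time, rng.exponential(1.0 / cz.random_censor_rate, size=n))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # genotype: TSG mutations coupled to the component, plus background genes
    gt = config.genotype
    mut_records: list[tuple[str, str, str]] = []
    mut_flags: dict[str, np.ndarray] = {}
    for gene in gt.genes:
        q = np.where(z == 1, gt.q_high, gt.q_low)
        flags = rng.binomial(1, q)
        mut_flags[gene] = flags
        mut_records += [(sample_ids[i], gene, gt.variant_class)
                        for i in np.flatnonzero(flags)]
    for j in range(gt.n_null_candidates):
        flags = rng.binomial(1, gt.background_rate, size=n)
        mut_records += [(sample_ids[i], f"NULLMUT{j:03d}", gt.variant_class)
                        for i in np.flatnonzero(flags)]
    mutations = MutationTable(pd.DataFrame(
        mut_records, columns=["sample_id", "gene", "variant_classification"]))

    # metabolite linearly coupled to expression and genotype
    mb = config.metabolite
    mut_k = mut_flags.get("KEAP1", np.zeros(n, dtype=int))
    mut_s = mut_flags.get("STK11", np.zeros(n, dtype=int))
    metabolite = (mb.intercept + mb.slope * x
                  + mb.effect_keap1 * mut_k + mb.effect_stk11 * mut_s
                  + rng.normal(0.0, mb.noise_sd, size=n))
    metabolites = pd.DataFrame({mb.name: metabolite},
                               index=pd.Index(sample_ids, name="sample_id"))

    # expression matrix: target gene + i.i.d. unimodal null genes
    null_mean = mx.mu_low + mx.delta * mx.pi_high
    nulls = rng.normal(null_mean, mx.sigma, size=(config.n_null_genes, n))
    gene_ids = [config.target_gene] + [f"NULL{j:04d}" for j in range(config.n_null_genes)]
    expression = ExpressionDataset(
        cohort_id=cohort_id,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.vstack([x[None, :], nulls]),
        preprocessing={"log2": True, "quantile_normalized": False, "synthetic": True},
    )

    cv = config.covariates
    clin = pd.DataFrame({
        "time": time,
        "event": event,
        "age": rng.normal(cv.age_mean, cv.age_sd, size=n).round(1),
        "sex": rng.binomial(1, cv.p_male, size=n),
        "stage": rng.choice(np.arange(1, len(cv.stage_probs) + 1), size=n,
                            p=np.asarray(cv.stage_probs) / sum(cv.stage_probs)),
        "smoker": rng.binomial(1, cv.p_smoker, size=n),
    }, index=pd.Index(sample_ids, name="sample_id"))
    clinical = ClinicalTable(cohort_id=cohort_id, data=clin)

    truth = {
        "z": z,
        "mu_low": mx.mu_low, "mu_high": mx.mu_low + mx.delta,
        "sigma": mx.sigma, "pi_high": mx.pi_high,
        "log_hr_component": hz.log_hr_component,
        "baseline_rate": hz.baseline_rate,
        "mut_flags": mut_flags,
    }
    return SyntheticCohort(cohort_id=cohort_id, expression=expression,
                           clinical=clinical, mutations=mutations,
                           metabolites=metabolites, truth=truth)


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Simulate all cohorts from independent substreams of the master seed."""
    cohorts = [simulate_cohort(config, i) for i in range(config.n_cohorts)]
    return SyntheticStudy(config=config, cohorts=cohorts)


def write_study(study: SyntheticStudy, outdir) -> Path:
    """Write every cohort in the dataio formats plus a truth/seed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": study.config.seed,
        "n_cohorts": study.config.n_cohorts,
        "target_gene": study.config.target_gene,
        "config": _config_to_jsonable(study.config),
        "cohorts": [],
    }
    for i, cohort in enumerate(study.cohorts):
        stem = outdir / cohort.cohort_id
        write_expression(cohort.expression, f"{stem}_expression.tsv")
        write_clinical(cohort.clinical, f"{stem}_clinical.tsv")
        write_mutations(cohort.mutations, f"{stem}_mutations.tsv")
        cohort.metabolites.to_csv(f"{stem}_metabolites.tsv", sep="\t")
        manifest["cohorts"].append({
            "cohort_id": cohort.cohort_id,
            "cohort_index": i,
            "n_samples": cohort.clinical.n,
            "n_events": int(cohort.clinical.data["event"].sum()),
        })
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = asdict(config)

    def conv(obj):
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return conv(d)
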
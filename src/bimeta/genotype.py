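"""Tumor-suppressor loss calling and mutation-vs-expression screening.

Functional loss of KEAP1/STK11 is called from the union of available evidence:
retained (non-silent) mutations, deep copy-number loss (< -1 by default), a
fusion/translocation breakpoint in the gene, a bimodal-mixture split of RPPA
protein levels (below the model cutoff = loss), or a pre-classified external
call. Samples are then partitioned into the four-way oncogenotype
(WT / KEAP1-only / STK11-only / double).

The oncogenotype screen compares target-gene expression between mutants and
wild-type per candidate gene by Mann-Whitney U, gated at a minimum mutant count
(default 9), with Benjamini-Hochberg adjustment across tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bimodality import dichotomize_cluster, fit_gmm2
from .dataio import ExpressionDataset, MutationTable
from .errors import DomainError

logger = logging.getLogger(__name__)

EVIDENCE_VOCABULARY = ("mutation", "copy_number", "fusion", "rppa", "external_call")

#: largest n_a * n_b for which the exact U distribution is used (untied data)
EXACT_MAX_PRODUCT = 400
#: largest C(n, n_a) enumerated exactly when ties forbid the distribution-based path
EXACT_MAX_COMBINATIONS = 200_000

GENOTYPE_GROUPS = ("WT", "KEAP1_only", "STK11_only", "double")


@dataclass
class TsgStatusTable:
    """Per (sample, gene) loss calls with their evidence lists."""

    data: pd.DataFrame  # columns: sample_id, gene, loss, evidence (tuple)

    def loss_mask(self, gene: str, sample_ids) -> np.ndarray:
        sel = self.data[(self.data["gene"] == gene) & self.data["loss"]]
        lost = set(sel["sample_id"])
        return np.array([s in lost for s in sample_ids])


def call_tsg_status(
    samples,
    mutations: MutationTable | None = None,
    copy_number: pd.DataFrame | None = None,
    fusions: dict | None = None,
    rppa: pd.DataFrame | None = None,
    external_calls: pd.DataFrame | None = None,
    genes: tuple[str, ...] = ("KEAP1", "STK11"),
    cn_loss_threshold: float = -1.0,
) -> TsgStatusTable:
    """Call functional loss per sample and gene as the union of evidence sources.

    ``copy_number``/``rppa``/``external_calls`` are sample x gene tables (bool for
    external calls); ``fusions`` maps sample_id -> iterable of breakpoint genes.
    At least one source must be provided. A degenerate RPPA distribution (the
    mixture cannot be fit or split) drops only the RPPA evidence, with a warning.
    """
    sources = (mutations, copy_number, fusions, rppa, external_calls)
    if all(s is None for s in sources):
        raise ValueError("at least one evidence source is required")
    samples = list(samples)

    rppa_low: dict[str, set] = {}
    if rppa is not None:
        for gene in genes:
            if gene not in rppa.columns:
                continue
            vals = rppa[gene].dropna()
            try:
                fit = fit_gmm2(vals.to_numpy())
                labels = dichotomize_cluster(vals.to_numpy(), fit)
            except Exception as exc:  # degenerate protein distribution
                logger.warning("RPPA clustering for %s failed (%s); "
                               "rppa evidence skipped", gene, exc)
                continue
            rppa_low[gene] = set(vals.index[labels.labels == "low"])

    rows = []
    for gene in genes:
        mutated = mutations.mutated_samples(gene) if mutations is not None else set()
        for s in samples:
            evidence = []
            if s in mutated:
                evidence.append("mutation")
            if (copy_number is not None and gene in copy_number.columns
                    and s in copy_number.index
                    and pd.notna(copy_number.loc[s, gene])
                    and copy_number.loc[s, gene] < cn_loss_threshold):
                evidence.append("copy_number")
            if fusions is not None and gene in set(fusions.get(s, ())):
                evidence.append("fusion")
            if s in rppa_low.get(gene, ()):
                evidence.append("rppa")
            if (external_calls is not None and gene in external_calls.columns
                    and s in external_calls.index
                    and bool(external_calls.loc[s, gene])):
                evidence.append("external_call")
            rows.append({"sample_id": s, "gene": gene,
                         "loss": bool(evidence), "evidence": tuple(evidence)})
    return TsgStatusTable(pd.DataFrame(rows))


def assign_genotype_group(status: TsgStatusTable,
                          genes: tuple[str, str] = ("KEAP1", "STK11")) -> pd.Series:
    """Four-way oncogenotype partition: WT / KEAP1_only / STK11_only / double."""
    gene_a, gene_b = genes
    pivot = status.data.pivot(index="sample_id", columns="gene", values="loss")
    a = pivot[gene_a].fillna(False).astype(bool)
    b = pivot[gene_b].fillna(False).astype(bool)
    group = pd.Series("WT", index=pivot.index, name="genotype_group")
    group[a & ~b] = f"{gene_a}_only"
    group[~a & b] = f"{gene_b}_only"
    group[a & b] = "double"
    return group


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mwu_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Uses the exact null distribution of U when n_a*n_b <= 400 and the pooled data
    are untied; with ties, small cases are handled by full enumeration over all
    group labelings, and everything else falls back to the tie-corrected normal
    approximation with continuity correction. Returns (U of sample *a*, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    small = a.size * b.size <= EXACT_MAX_PRODUCT

    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if small and _n_combinations(pooled.size, a.size) <= EXACT_MAX_COMBINATIONS:
        return _mwu_enumerate(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _n_combinations(n: int, k: int) -> int:
    from math import comb
    return comb(n, k)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def _mwu_enumerate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact permutation p by enumerating every split of the pooled sample."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    u_obs = _u_statistic(a, b)
    center = n_a * b.size / 2.0
    dev_obs = abs(u_obs - center)
    count = 0
    total = 0
    idx = np.arange(n)
    for chosen in combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
    return float(u_obs), count / total


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# oncogenotype screen


@dataclass
class ScreenHit:
    """One candidate gene's mutant-vs-wild-type expression comparison."""

    gene: str
    n_mut: int
    n_wt: int
    U: float = np.nan
    p: float = np.nan
    p_adj: float = np.nan
    direction: int = 0  # sign of median(mutant) - median(wild-type)
    tested: bool = True


def oncogenotype_screen(
    ds: ExpressionDataset,
    target: str,
    mutations: MutationTable,
    candidate_genes,
    min_mut: int = 9,
) -> pd.DataFrame:
    """Screen candidate genes for mutation-associated target-gene expression.

    Candidates with fewer than ``min_mut`` mutant samples in the cohort are
    reported ``tested=False`` with no p-value (the gate mirrors the >= 9
    independent-mutant rule for small-cohort driver screens). BH adjustment is
    computed across the tested genes only; both nominal and adjusted p are kept.
    """
    expr = pd.Series(ds.gene_values(target), index=ds.sample_ids)
    hits: list[ScreenHit] = []
    for gene in candidate_genes:
        mut_samples = mutations.mutated_samples(gene) & set(ds.sample_ids)
        mut_mask = expr.index.isin(mut_samples)
        n_mut, n_wt = int(mut_mask.sum()), int((~mut_mask).sum())
        if n_mut < min_mut or n_wt == 0:
            hits.append(ScreenHit(gene=gene, n_mut=n_mut, n_wt=n_wt, tested=False))
            continue
        a = expr[mut_mask].to_numpy()
        b = expr[~mut_mask].to_numpy()
        U, p = mwu_test(a, b)
        direction = int(np.sign(np.median(a) - np.median(b)))
        hits.append(ScreenHit(gene=gene, n_mut=n_mut, n_wt=n_wt, U=U, p=p,
                              direction=direction))
    df = pd.DataFrame([vars(h) for h in hits])
    tested = df["tested"]
    if tested.any():
        df.loc[tested, "p_adj"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    df = df.sort_values(["tested", "p"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df
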
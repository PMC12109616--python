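"""Correlation screens, group comparisons and over-representation tests.

These are the downstream characterization analyses: genome-wide Pearson
correlation against the target gene (optionally stratified, e.g. by genotype
group), within-dichotomy correlations with external covariates such as immune
infiltrate scores, one-way ANOVA across oncogenotypes, a small multivariate
linear model for metabolite differences adjusted for KEAP1/STK11 status, and
hypergeometric pathway over-representation of a hit list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bimodality import DichotomyLabels
from .dataio import ExpressionDataset, GeneSetCollection
from .errors import RankDeficiencyError
from .genotype import bh_adjust

logger = logging.getLogger(__name__)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the exact t-transform p (n-2 df)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def correlation_screen(
    ds: ExpressionDataset,
    target: str,
    strata: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Correlate every other gene with the target, per stratum.

    ``strata`` maps stratum label -> boolean sample mask; the default is a single
    "all" stratum. BH adjustment is applied within each stratum. Zero-variance
    genes are reported with NaN statistics and ``flagged=True``. The target
    itself is excluded. Columns: feature, group, r, p, p_adj, n, flagged.
    """
    target_values = ds.gene_values(target)
    if strata is None:
        strata = {"all": np.ones(ds.n_samples, dtype=bool)}
    records = []
    for label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n < 3:
            raise ValueError(f"stratum {label!r} has n={n} < 3")
        tv = target_values[mask]
        for gene, row in zip(ds.gene_ids, ds.values):
            if gene == target:
                continue
            y = row[mask]
            if np.std(y) == 0 or np.std(tv) == 0:
                records.append({"feature": gene, "group": label, "r": np.nan,
                                "p": np.nan, "n": n, "flagged": True})
                continue
            r, p = pearson(tv, y)
            records.append({"feature": gene, "group": label, "r": r, "p": p,
                            "n": n, "flagged": False})
    df = pd.DataFrame(records)
    df["p_adj"] = np.nan
    for label in strata:
        sel = (df["group"] == label) & ~df["flagged"]
        if sel.any():
            df.loc[sel, "p_adj"] = bh_adjust(df.loc[sel, "p"].to_numpy())
    return df


def within_group_correlation(x, y, labels: DichotomyLabels) -> pd.DataFrame:
    """Pearson correlation of x vs y separately in the low and high groups.

    Excluded samples are dropped; a group with fewer than 3 samples is skipped
    with a notice. Columns: group, r, p, n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = []
    for group, mask in (("low", labels.low_mask), ("high", labels.high_mask)):
        n = int(mask.sum())
        if n < 3:
            logger.info("group %r skipped (n=%d < 3)", group, n)
            continue
        r, p = pearson(x[mask], y[mask])
        rows.append({"group": group, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def anova_oneway(values, groups) -> tuple[float, float]:
    """One-way ANOVA F-test of a numeric variable across group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in pd.unique(groups)]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least 2 non-empty groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 samples")
    F, p = stats.f_oneway(*arrays)
    return float(F), float(p)


@dataclass
class ModelFitRecord:
    """OLS fit summary with one row per term."""

    response: str
    terms: pd.DataFrame  # index = term; columns coef, se, p
    n: int
    r_squared: float

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def metabolite_multivariate(metabolite, kynu_status, keap1, stk11,
                            response_name: str = "metabolite") -> ModelFitRecord:
    """OLS: metabolite ~ expression-status + KEAP1 + STK11 (all binary terms).

    The headline value is the expression-status ("kynu_status") coefficient and
    its p-value, i.e. the metabolite difference by target-gene expression group
    adjusted for the two tumor-suppressor genotypes.
    """
    y = np.asarray(metabolite, dtype=float)
    X = pd.DataFrame({
        "kynu_status": np.asarray(kynu_status, dtype=float),
        "keap1": np.asarray(keap1, dtype=float),
        "stk11": np.asarray(stk11, dtype=float),
    })
    if len(y) <= 5:
        raise ValueError("need n > 5 observations")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise RankDeficiencyError("collinear design (e.g. status identical to a genotype)")
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return ModelFitRecord(response=response_name, terms=terms,
                          n=int(fit.nobs), r_squared=float(fit.rsquared))


def hypergeom_enrichment(hits, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of *hits* in each gene set.

    Sets are intersected with the universe first; sets with no members in the
    universe are skipped with a notice. p = P(X >= k) for overlap k out of a set
    of size K, with |hits| draws from a universe of size N; BH across tested
    sets. Columns: set_name, overlap, set_size, n_hits, universe, p, p_adj.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    N, n_h = len(universe), len(hits)
    rows = []
    for name, members in sets.items():
        members_u = set(members) & universe
        if not members_u:
            logger.info("gene set %r disjoint from universe; skipped", name)
            continue
        K = len(members_u)
        k = len(members_u & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_h))
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "n_hits": n_h, "universe": N, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df


def intersect_significant(frames: list[pd.DataFrame], alpha: float = 0.05,
                          p_col: str = "p_adj", key: str = "feature") -> set[str]:
    """Features significant (p_col < alpha) in every cohort's screen frame."""
    sets = [set(f.loc[f[p_col] < alpha, key]) for f in frames]
    return set.intersection(*sets) if sets else set()
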
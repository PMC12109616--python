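"""Gene set enrichment analysis: signal-to-noise ranking, weighted running-sum
enrichment score, sample-label permutation significance, leading edge.

Genes are ranked by the signal-to-noise ratio (mu_A - mu_B) / (sigma_A + sigma_B)
between two phenotype classes, with per-class SD floors (sigma >= max(0.2*|mu|,
0.2)) so that near-constant genes cannot dominate the ranking. The enrichment
score walks the ranked list, incrementing by |metric|^w (normalized over set
hits) at set members and decrementing by 1/(N - N_H) elsewhere; ES is the
maximum-magnitude excursion. Significance comes from permuting the sample labels
and comparing against same-sign permutation scores with an add-one estimator, so
the nominal p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset, GeneSetCollection

SD_FLOOR_FRACTION = 0.2
SD_FLOOR_ABSOLUTE = 0.2


@dataclass
class RankedList:
    """Genes ordered by metric descending, ties broken by gene id (stable)."""

    genes: list[str]
    metrics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metrics):
            raise ValueError("genes and metrics must have equal length")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    leading_edge: list[str]
    n_perm: int
    seed: int | None = None


def _floored_sd(sd: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return np.maximum(sd, np.maximum(SD_FLOOR_FRACTION * np.abs(mu), SD_FLOOR_ABSOLUTE))


def _s2n_matrix(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Signal-to-noise per row for class A (mask) vs class B (rest)."""
    A, B = X[:, mask_a], X[:, ~mask_a]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    sd_a = _floored_sd(A.std(axis=1, ddof=1), mu_a)
    sd_b = _floored_sd(B.std(axis=1, ddof=1), mu_b)
    return (mu_a - mu_b) / (sd_a + sd_b)


def signal_to_noise(ds: ExpressionDataset, labels) -> RankedList:
    """Rank all genes by signal-to-noise between the two phenotype classes.

    ``labels`` is a boolean/0-1 vector over samples (True = class A). Each class
    needs at least 3 samples.
    """
    mask = np.asarray(labels, dtype=bool)
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each phenotype class needs >= 3 samples")
    metric = _s2n_matrix(ds.values, mask)
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], ds.gene_ids[i]))
    return RankedList(genes=[ds.gene_ids[i] for i in order],
                      metrics=metric[np.array(order)])


def enrichment_score(ranked: RankedList, geneset, weight: float = 1.0
                     ) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    Returns (ES, running sum over positions, leading-edge genes). The leading
    edge is the set members at or before the ES extremum (at or after it when
    ES is negative).
    """
    members = set(geneset) & set(ranked.genes)
    N = len(ranked.genes)
    n_h = len(members)
    if n_h == 0 or n_h == N:
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    hit = np.array([g in members for g in ranked.genes])
    weights = np.abs(ranked.metrics) ** weight
    hit_sum = weights[hit].sum()
    if hit_sum == 0:
        # all hit metrics exactly zero: fall back to equal hit increments
        increments = hit / n_h
    else:
        increments = np.where(hit, weights / hit_sum, 0.0)
    decrements = np.where(hit, 0.0, 1.0 / (N - n_h))
    running = np.cumsum(increments - decrements)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


@dataclass
class GseaScreen:
    results: list[GseaResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"set_name": r.set_name, "ES": r.es, "NES": r.nes,
             "p_nominal": r.p_nominal, "n_perm": r.n_perm,
             "leading_edge": ",".join(r.leading_edge)}
            for r in self.results
        ])


def gsea_permutation(
    ds: ExpressionDataset,
    labels,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> GseaScreen:
    """Sample-label permutation GSEA over a gene-set collection.

    Nominal p per set is add-one over same-sign permutation scores:
    p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #{ES_perm same sign});
    NES = ES / mean(|same-sign ES_perm|). Sets outside [min_size, max_size]
    after universe intersection are skipped. Deterministic given *seed*.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    ranked_obs = signal_to_noise(ds, mask)
    universe = set(ds.gene_ids)

    kept = []
    for name, members in sets.items():
        size = len(set(members) & universe)
        if min_size <= size <= max_size and size < len(universe):
            kept.append(name)

    obs: dict[str, tuple[float, list[str]]] = {}
    for name in kept:
        es, _, leading = enrichment_score(ranked_obs, sets[name], weight=weight)
        obs[name] = (es, leading)

    perm_es = {name: np.empty(n_perm) for name in kept}
    X = ds.values
    n_samples = X.shape[1]
    for b in range(n_perm):
        perm_mask = np.zeros(n_samples, dtype=bool)
        perm_mask[rng.permutation(n_samples)[: int(mask.sum())]] = True
        metric = _s2n_matrix(X, perm_mask)
        order = sorted(range(len(metric)), key=lambda i: (-metric[i], ds.gene_ids[i]))
        ranked = RankedList(genes=[ds.gene_ids[i] for i in order],
                            metrics=metric[np.array(order)])
        for name in kept:
            es, _, _ = enrichment_score(ranked, sets[name], weight=weight)
            perm_es[name][b] = es

    results = []
    for name in kept:
        es, leading = obs[name]
        perms = perm_es[name]
        same_sign = perms >= 0 if es >= 0 else perms < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(perms[same_sign]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_same)
        denom = np.abs(perms[same_sign]).mean() if n_same else np.nan
        nes = es / denom if (n_same and denom > 0) else np.nan
        results.append(GseaResult(set_name=name, es=es, nes=nes, p_nominal=p,
                                  leading_edge=leading, n_perm=n_perm, seed=seed))
    return GseaScreen(results=results)


def leading_edge_consensus(result_lists: list[list[GseaResult]],
                           min_count: int = 2) -> dict[str, int]:
    """Genes appearing in at least *min_count* leading-edge lists across runs."""
    counts: dict[str, int] = {}
    for results in result_lists:
        seen = set()
        for r in results:
            seen.update(r.leading_edge)
        for g in seen:
            counts[g] = counts.get(g, 0) + 1
    return {g: c for g, c in counts.items() if c >= min_count}
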
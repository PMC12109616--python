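"""Per-cohort survival modelling and random-effects pooling across cohorts.

Each cohort contributes a Cox proportional-hazards estimate for the gene of
interest in one of two modes: *binary* (samples dichotomized by the fitted
mixture model) or *continuous* (per-gene z-scored expression). Cohort estimates
(log hazard ratios with standard errors) are pooled by DerSimonian-Laird
random-effects meta-analysis; cohorts below a minimum size are excluded before
fitting, mirroring the >= 10-patient inclusion rule of multi-study survival
meta-analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .bimodality import dichotomize_cluster, fit_gmm2, zscore_standardize
from .dataio import ClinicalTable, ExpressionDataset
from .errors import (
    BimetaError,
    DegenerateInputError,
    DomainError,
    NotEstimableError,
    RankDeficiencyError,
)

logger = logging.getLogger(__name__)


@dataclass
class SurvivalEffect:
    """One cohort's Cox estimate for one gene in one mode."""

    cohort_id: str
    gene: str
    mode: str  # {"binary", "continuous"} or a covariate name for multivariate fits
    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool = True

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.log_hr - z * self.se, self.log_hr + z * self.se


@dataclass
class MetaResult:
    """DerSimonian-Laird pooled effect across k cohorts."""

    k: int
    pooled_log_hr: float
    pooled_se: float
    pooled_p: float
    tau2: float
    Q: float
    I2: float

    @property
    def pooled_hr(self) -> float:
        return math.exp(self.pooled_log_hr)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.pooled_log_hr - z * self.pooled_se,
                self.pooled_log_hr + z * self.pooled_se)


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate: right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t) of the step function (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


# ---------------------------------------------------------------------------
# Cox PH


def _efron_loglik_grad_hess(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                            X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron-corrected Cox partial log-likelihood with gradient and Hessian.

    Subjects are processed from the latest time backwards so that risk-set sums
    are running totals; tied event times share the Efron fractional subtraction
    of the tied subjects' own contributions.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="mergesort")
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = X_s @ beta
    w = np.exp(eta)
    wx = w[:, None] * X_s
    wxx = wx[:, :, None] * X_s[:, None, :]

    # group rows by distinct time (descending); risk sums are running cumsums
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t_s[1:] != t_s[:-1]
    starts = np.flatnonzero(new_group)
    ends = np.append(starts[1:], n) - 1  # last row of each group
    R0 = np.cumsum(w)[ends]
    R1 = np.cumsum(wx, axis=0)[ends]
    R2 = np.cumsum(wxx.reshape(n, -1), axis=0)[ends].reshape(-1, p, p)

    ev = e_s == 1
    d = np.add.reduceat(ev.astype(np.int64), starts)
    tie0 = np.add.reduceat(w * ev, starts)
    tie1 = np.add.reduceat(wx * ev[:, None], starts, axis=0)
    tie2 = np.add.reduceat(wxx.reshape(n, -1) * ev[:, None], starts,
                           axis=0).reshape(-1, p, p)

    ll = float(eta[ev].sum())
    grad = X_s[ev].sum(axis=0)

    has_ev = d > 0
    reps = d[has_ev]
    idx = np.repeat(np.flatnonzero(has_ev), reps)
    within = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    frac = within / np.repeat(reps, reps)

    phi0 = R0[idx] - frac * tie0[idx]
    phi1 = R1[idx] - frac[:, None] * tie1[idx]
    phi2 = R2[idx] - frac[:, None, None] * tie2[idx]
    ll -= float(np.log(phi0).sum())
    v = phi1 / phi0[:, None]
    grad = grad - v.sum(axis=0)
    hess = -(phi2 / phi0[:, None, None] - v[:, :, None] * v[:, None, :]).sum(axis=0)
    return ll, grad, hess


def _cox_newton(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                tol: float = 1e-9, max_iter: int = 60
                ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson maximization of the Efron partial likelihood.

    Returns (beta, se, converged); non-convergence (monotone likelihood /
    separation) is reported, not raised.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik_grad_hess(beta, time, event, X)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, hess_new = _efron_loglik_grad_hess(
                beta_new, time, event, X)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        if not np.isfinite(ll_new):
            break
        delta_ll = ll_new - ll
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < 1e-7 or abs(delta_ll) < tol * max(abs(ll), 1.0):
            converged = True
            break
    if np.max(np.abs(beta)) > 15.0:  # drifting towards a monotone likelihood
        converged = False
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return beta, se, converged


def cox_fit(clinical: ClinicalTable, predictors: pd.DataFrame | dict,
            gene: str = "", mode: str | None = None) -> list[SurvivalEffect]:
    """Fit one Cox PH model with the given predictors (Efron tie handling).

    Maximizes the partial likelihood by Newton iteration; standard errors come
    from the observed information, p-values are two-sided Wald. Returns one
    :class:`SurvivalEffect` per predictor column (for a univariate call, a
    single effect). Complete separation / monotone likelihood yields a flagged
    non-convergent effect with an infinite ``log_hr`` sentinel rather than an
    exception; fewer than two events raise :class:`NotEstimableError` and a
    rank-deficient design raises :class:`RankDeficiencyError`.
    """
    if isinstance(predictors, dict):
        predictors = pd.DataFrame(predictors, index=clinical.data.index)
    df = pd.concat([clinical.data[["time", "event"]], predictors], axis=1).dropna()
    pred_cols = list(predictors.columns)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise NotEstimableError(
            f"cohort {clinical.cohort_id!r}: {n_events} events, need >= 2")
    X = df[pred_cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise RankDeficiencyError(
            f"cohort {clinical.cohort_id!r}: predictors {pred_cols} are collinear")
    if np.any(X.std(axis=0) == 0):
        const = [c for c, s in zip(pred_cols, X.std(axis=0)) if s == 0]
        raise DegenerateInputError(
            f"cohort {clinical.cohort_id!r}: constant predictor(s) {const}")

    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    beta, se, converged = _cox_newton(time, event, X)
    effects = []
    for k, col in enumerate(pred_cols):
        label = mode if (mode and len(pred_cols) == 1) else col
        if not converged or not np.isfinite(se[k]) or se[k] == 0:
            sign = float(np.sign(beta[k]) or 1.0)
            effects.append(SurvivalEffect(
                cohort_id=clinical.cohort_id, gene=gene, mode=label,
                log_hr=sign * math.inf, se=math.inf, p=1.0,
                n=len(df), n_events=n_events, converged=False))
            continue
        z = beta[k] / se[k]
        effects.append(SurvivalEffect(
            cohort_id=clinical.cohort_id, gene=gene, mode=label,
            log_hr=float(beta[k]), se=float(se[k]),
            p=float(2.0 * stats.norm.sf(abs(z))),
            n=len(df), n_events=n_events))
    return effects


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"log-rank test needs exactly 2 non-empty groups, got {len(uniq)}")
    mask = groups == uniq[0]
    res = _ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


def km_estimate(time, event) -> KMEstimate:
    """Product-limit survival estimate; censored-only input gives S = 1."""
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise DomainError("negative survival times")
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMEstimate(times=times, survival=surv, at_risk=at_risk)


# ---------------------------------------------------------------------------
# random-effects meta-analysis


def meta_random_effects(effects) -> MetaResult:
    """DerSimonian-Laird pooling of log hazard ratios.

    Accepts a list of :class:`SurvivalEffect` or a tuple ``(log_hrs, ses)``.
    Fixed-effect weights w_i = 1/se_i^2 give Q; the method-of-moments
    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))) re-weights the
    estimates; I^2 = max(0, (Q - (k-1)) / Q).
    """
    if isinstance(effects, tuple) and len(effects) == 2:
        theta = np.asarray(effects[0], dtype=float)
        se = np.asarray(effects[1], dtype=float)
    else:
        theta = np.array([e.log_hr for e in effects], dtype=float)
        se = np.array([e.se for e in effects], dtype=float)
    if theta.size == 0:
        raise ValueError("meta-analysis needs at least one effect")
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(se))):
        raise BimetaError("non-finite effect passed to meta-analysis; "
                          "exclude non-convergent fits first")
    k = theta.size
    w = 1.0 / se ** 2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_fe) ** 2))
    if k == 1:
        tau2 = 0.0
        I2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(k=k, pooled_log_hr=pooled, pooled_se=pooled_se,
                      pooled_p=p, tau2=tau2, Q=Q, I2=I2)


# ---------------------------------------------------------------------------
# dual-mode screen across cohorts


@dataclass
class GeneScreenResult:
    """Pooled dual-mode survival association for one gene."""

    gene: str
    meta_binary: MetaResult | None
    meta_continuous: MetaResult | None
    effects: list[SurvivalEffect] = field(default_factory=list)


@dataclass
class SurvivalScreen:
    """Full screen output: per-gene pooled results plus the exclusion log."""

    results: dict[str, GeneScreenResult]
    exclusions: list[str]
    not_screened: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, r in self.results.items():
            row: dict = {"gene": gene}
            for mode, meta in (("binary", r.meta_binary),
                               ("continuous", r.meta_continuous)):
                if meta is None:
                    continue
                lo, hi = meta.ci()
                row.update({
                    f"{mode}_log_hr": meta.pooled_log_hr,
                    f"{mode}_hr": meta.pooled_hr,
                    f"{mode}_ci_low": math.exp(lo),
                    f"{mode}_ci_high": math.exp(hi),
                    f"{mode}_p": meta.pooled_p,
                    f"{mode}_tau2": meta.tau2,
                    f"{mode}_I2": meta.I2,
                    f"{mode}_k": meta.k,
                })
            rows.append(row)
        return pd.DataFrame(rows)

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results.values():
            for e in r.effects:
                rows.append({
                    "gene": e.gene, "cohort_id": e.cohort_id, "mode": e.mode,
                    "log_hr": e.log_hr, "se": e.se, "p": e.p,
                    "n": e.n, "n_events": e.n_events, "converged": e.converged,
                })
        return pd.DataFrame(rows)


def run_survival_screen(
    studies: list[tuple[ExpressionDataset, ClinicalTable]],
    genes: list[str],
    min_n: int = 10,
    modes: tuple[str, ...] = ("binary", "continuous"),
) -> SurvivalScreen:
    """Dual-mode Cox screen pooled by random-effects meta-analysis.

    Cohorts with fewer than ``min_n`` patients are excluded up front. For each
    retained cohort and gene, the *binary* mode dichotomizes samples by the
    fitted mixture cutoff and the *continuous* mode uses z-scored expression;
    both are pooled across cohorts on the log-HR scale. Per-cohort failures
    (degenerate gene, non-convergence, too few events) are logged and excluded
    from pooling, never silently dropped.
    """
    exclusions: list[str] = []
    usable: list[tuple[ExpressionDataset, ClinicalTable]] = []
    for ds, clin in studies:
        if clin.n < min_n:
            exclusions.append(
                f"cohort {clin.cohort_id}: excluded (n={clin.n} < min_n={min_n})")
        else:
            usable.append((ds, clin))

    results: dict[str, GeneScreenResult] = {}
    not_screened: list[str] = []
    for gene in genes:
        per_mode: dict[str, list[SurvivalEffect]] = {m: [] for m in modes}
        all_effects: list[SurvivalEffect] = []
        seen = False
        for ds, clin in usable:
            if gene not in ds.gene_ids:
                continue
            seen = True
            # align expression to clinical samples
            expr = pd.Series(ds.gene_values(gene), index=ds.sample_ids)
            expr = expr.reindex(clin.data.index).dropna()
            clin_sub = ClinicalTable(clin.cohort_id, clin.data.loc[expr.index])
            for m in modes:
                try:
                    if m == "binary":
                        fit = fit_gmm2(expr.to_numpy())
                        labels = dichotomize_cluster(expr.to_numpy(), fit)
                        pred = (labels.labels == "high").astype(float)
                    else:
                        pred = zscore_standardize(expr.to_numpy())
                    effs = cox_fit(clin_sub, {"x": pred}, gene=gene, mode=m)
                except BimetaError as exc:
                    exclusions.append(
                        f"cohort {clin.cohort_id}, gene {gene}, mode {m}: {exc}")
                    continue
                eff = effs[0]
                all_effects.append(eff)
                if eff.converged:
                    per_mode[m].append(eff)
                else:
                    exclusions.append(
                        f"cohort {clin.cohort_id}, gene {gene}, mode {m}: "
                        "non-convergent fit excluded from pooling")
        if not seen:
            not_screened.append(gene)
            continue
        metas = {
            m: (meta_random_effects(per_mode[m]) if per_mode[m] else None)
            for m in modes
        }
        results[gene] = GeneScreenResult(
            gene=gene,
            meta_binary=metas.get("binary"),
            meta_continuous=metas.get("continuous"),
            effects=all_effects,
        )
    for line in exclusions:
        logger.info(line)
    return SurvivalScreen(results=results, exclusions=exclusions,
                          not_screened=not_screened)
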
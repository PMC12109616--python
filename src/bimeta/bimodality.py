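"""Two-component equal-variance Gaussian mixture fitting and dichotomization.

The model for one gene's expression across samples is

    x ~ (1 - pi) * N(mu_low, sigma^2) + pi * N(mu_high, sigma^2),

fitted by EM with multiple quantile-split starts. Bimodality is summarized by the
bimodal index BI = delta * sqrt(pi * (1 - pi)) with delta = (mu_high - mu_low) / sigma:
large only when the components are both well separated and reasonably balanced.

Samples are dichotomized either by the fitted model (maximum posterior, equivalent
to thresholding at the closed-form posterior-0.5 crossing), by the median, or by a
quantile band (e.g. > 80th percentile high, < 70th percentile low, middle excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset
from .errors import DegenerateFitError, DegenerateInputError

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: initial high-component proportions for the multi-start EM
DEFAULT_START_PROPORTIONS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class MixtureFit:
    """Fitted equal-variance two-component Gaussian mixture for one gene."""

    mu_low: float
    mu_high: float
    sigma: float
    pi_high: float
    loglik: float
    n_iter: int
    converged: bool
    n: int

    def __post_init__(self) -> None:
        if not self.mu_low <= self.mu_high:
            raise ValueError("components must be ordered mu_low <= mu_high")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.pi_high < 1.0:
            raise ValueError("pi_high must lie strictly in (0, 1)")

    @property
    def delta(self) -> float:
        """Standardized separation (mu_high - mu_low) / sigma."""
        return (self.mu_high - self.mu_low) / self.sigma

    @property
    def bimodal_index(self) -> float:
        return self.delta * math.sqrt(self.pi_high * (1.0 - self.pi_high))

    @property
    def cutoff(self) -> float:
        """Expression level where the posterior of 'high' crosses 0.5.

        For equal variances the crossing has the closed form
        x* = (mu_low + mu_high)/2 + sigma^2 * ln((1-pi)/pi) / (mu_high - mu_low).
        NaN for a degenerate (delta = 0) fit.
        """
        if self.mu_high == self.mu_low:
            return math.nan
        return (self.mu_low + self.mu_high) / 2.0 + (
            self.sigma ** 2
            * math.log((1.0 - self.pi_high) / self.pi_high)
            / (self.mu_high - self.mu_low)
        )

    def posterior_high(self, x) -> np.ndarray:
        """P(component = high | x) under the fitted mixture."""
        x = np.asarray(x, dtype=float)
        log_hi = math.log(self.pi_high) - 0.5 * ((x - self.mu_high) / self.sigma) ** 2
        log_lo = math.log(1.0 - self.pi_high) - 0.5 * ((x - self.mu_low) / self.sigma) ** 2
        m = np.maximum(log_hi, log_lo)
        return np.exp(log_hi - m) / (np.exp(log_hi - m) + np.exp(log_lo - m))


@dataclass
class DichotomyLabels:
    """Per-sample low/high/excluded labels plus the cutoff(s) that produced them."""

    labels: np.ndarray  # array of {"low", "high", "excluded"}
    method: str  # {"cluster", "median", "quantile"}
    cutoff_low: float
    cutoff_high: float

    @property
    def high_mask(self) -> np.ndarray:
        return self.labels == "high"

    @property
    def low_mask(self) -> np.ndarray:
        return self.labels == "low"

    @property
    def excluded_mask(self) -> np.ndarray:
        return self.labels == "excluded"


# ---------------------------------------------------------------------------
# EM


def _batch_em(
    X: np.ndarray,
    tol: float,
    max_iter: int,
    start_proportions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized multi-start EM over the rows of X (one mixture per row).

    Returns (mu_low, mu_high, sigma, pi_high, loglik, n_iter, converged) arrays,
    keeping the best start per row by log-likelihood.

    The equal-variance structure is exploited throughout: the posterior of the
    high component is logistic in x (gamma = expit(a*x + b)) and the M-step and
    log-likelihood reduce to the sufficient statistics (sum x, sum x^2,
    sum gamma, sum gamma*x), so one EM iteration makes only a handful of passes
    over the data. All restarts are stacked into one compaction loop.
    """
    G, n = X.shape
    n_starts = len(start_proportions)
    sd = X.std(axis=1)
    sigma_floor = np.tile(1e-6 * np.where(sd > 0, sd, 1.0), n_starts)

    # stack starts: rows [start0 genes..., start1 genes..., ...]
    Xs = np.tile(X, (n_starts, 1))
    gamma = np.empty_like(Xs)
    for s, p0 in enumerate(start_proportions):
        thr = np.quantile(X, 1.0 - p0, axis=1, keepdims=True)
        gamma[s * G:(s + 1) * G] = np.clip((X > thr).astype(float), 0.01, 0.99)

    if _em_rows_jit is not None:
        mu1, mu2, sig, pi, ll, n_iter, converged = _em_rows_jit(
            Xs, gamma, sigma_floor, tol, max_iter)
    else:
        mu1, mu2, sig, pi, ll, n_iter, converged = _em_core_numpy(
            Xs, gamma, sigma_floor, tol, max_iter)

    # order components so mu_low <= mu_high
    swap = mu1 > mu2
    mu_low = np.where(swap, mu2, mu1)
    mu_high = np.where(swap, mu1, mu2)
    pi_high = np.where(swap, 1.0 - pi, pi)

    # best start per gene by log-likelihood
    ll_m = ll.reshape(n_starts, G)
    best_s = np.argmax(ll_m, axis=0)
    take = best_s * G + np.arange(G)
    return (mu_low[take], mu_high[take], sig[take], pi_high[take],
            ll[take], n_iter[take], converged[take])


def _em_core_numpy(Xs, gamma, sigma_floor, tol, max_iter):
    """Vectorized EM over stacked rows (pure-numpy path)."""
    R, n = Xs.shape
    S1 = Xs.sum(axis=1)
    Sxx = (Xs * Xs).sum(axis=1)

    mu1 = np.empty(R)
    mu2 = np.empty(R)
    sig = np.empty(R)
    pi = np.empty(R)
    ll = np.full(R, -np.inf)
    n_iter = np.zeros(R, dtype=int)
    converged = np.zeros(R, dtype=bool)

    # active-row compaction: iterate only on rows not yet converged
    idx = np.arange(R)
    Xa, S1a, Sxxa, floor_a = Xs, S1, Sxx, sigma_floor
    ll_a = np.full(R, -np.inf)
    eps = 1e-10
    for it in range(1, max_iter + 1):
        # M-step from sufficient statistics
        w2 = np.clip(gamma.sum(axis=1), eps, n - eps)
        T = (gamma * Xa).sum(axis=1)
        w1 = n - w2
        pi_new = np.clip(w2 / n, eps, 1.0 - eps)
        mu2_new = T / w2
        mu1_new = (S1a - T) / w1
        var = (Sxxa - w1 * mu1_new ** 2 - w2 * mu2_new ** 2) / n
        sig_new = np.maximum(np.sqrt(np.maximum(var, 0.0)), floor_a)

        # E-step: posterior of the high component is logistic in x
        a = (mu2_new - mu1_new) / sig_new ** 2
        b = ((mu1_new ** 2 - mu2_new ** 2) / (2.0 * sig_new ** 2)
             + np.log(pi_new / (1.0 - pi_new)))
        eta = a[:, None] * Xa + b[:, None]
        gamma = 1.0 / (1.0 + np.exp(-eta))

        # log-likelihood: sum log[(1-pi) phi_low] + sum log1p(exp(eta))
        ll_new = (
            n * (np.log1p(-pi_new) - np.log(sig_new) - _LOG_SQRT_2PI)
            - (Sxxa - 2.0 * mu1_new * S1a + n * mu1_new ** 2) / (2.0 * sig_new ** 2)
            + np.logaddexp(0.0, eta).sum(axis=1)
        )

        mu1[idx], mu2[idx], sig[idx], pi[idx] = mu1_new, mu2_new, sig_new, pi_new
        n_iter[idx] = it
        ll[idx] = ll_new
        rel = np.abs(ll_new - ll_a) / np.maximum(np.abs(ll_new), 1.0)
        done = rel < tol
        converged[idx[done]] = True
        if done.all():
            break
        keep = ~done
        idx = idx[keep]
        Xa, S1a, Sxxa, floor_a = Xa[keep], S1a[keep], Sxxa[keep], floor_a[keep]
        gamma = gamma[keep]
        ll_a = ll_new[keep]

    return mu1, mu2, sig, pi, ll, n_iter, converged


def _em_rows_impl(X, gamma, floors, tol, max_iter):  # pragma: no cover - jitted
    """Per-row EM with early exit; numerically identical to the numpy path."""
    R, n = X.shape
    log_sqrt_2pi = 0.5 * np.log(2.0 * np.pi)
    mu1o = np.empty(R)
    mu2o = np.empty(R)
    sigo = np.empty(R)
    pio = np.empty(R)
    llo = np.empty(R)
    nio = np.zeros(R, np.int64)
    convo = np.zeros(R, np.bool_)
    eps = 1e-10
    for r in range(R):
        x = X[r]
        S1 = 0.0
        Sxx = 0.0
        for i in range(n):
            S1 += x[i]
            Sxx += x[i] * x[i]
        g = gamma[r].copy()
        ll_old = -np.inf
        mu1 = mu2 = 0.0
        sig = 1.0
        pi = 0.5
        ll = -np.inf
        it_done = 0
        conv = False
        for it in range(1, max_iter + 1):
            w2 = 0.0
            T = 0.0
            for i in range(n):
                w2 += g[i]
                T += g[i] * x[i]
            w2 = min(max(w2, eps), n - eps)
            w1 = n - w2
            pi = min(max(w2 / n, eps), 1.0 - eps)
            mu2 = T / w2
            mu1 = (S1 - T) / w1
            var = (Sxx - w1 * mu1 * mu1 - w2 * mu2 * mu2) / n
            sig = max(np.sqrt(max(var, 0.0)), floors[r])
            a = (mu2 - mu1) / (sig * sig)
            b = ((mu1 * mu1 - mu2 * mu2) / (2.0 * sig * sig)
                 + np.log(pi / (1.0 - pi)))
            acc = 0.0
            for i in range(n):
                eta = a * x[i] + b
                if eta > 0.0:
                    e = np.exp(-eta)
                    g[i] = 1.0 / (1.0 + e)
                    acc += eta + np.log1p(e)
                else:
                    e = np.exp(eta)
                    g[i] = e / (1.0 + e)
                    acc += np.log1p(e)
            ll = (n * (np.log(1.0 - pi) - np.log(sig) - log_sqrt_2pi)
                  - (Sxx - 2.0 * mu1 * S1 + n * mu1 * mu1) / (2.0 * sig * sig)
                  + acc)
            it_done = it
            if abs(ll - ll_old) / max(abs(ll), 1.0) < tol:
                conv = True
                break
            ll_old = ll
        mu1o[r] = mu1
        mu2o[r] = mu2
        sigo[r] = sig
        pio[r] = pi
        llo[r] = ll
        nio[r] = it_done
        convo[r] = conv
    return mu1o, mu2o, sigo, pio, llo, nio, convo


try:  # jit-compiled fast path; the numpy implementation remains authoritative
    from numba import njit

    _em_rows_jit = njit(cache=True)(_em_rows_impl)
except Exception:  # pragma: no cover - numba always present in supported envs
    _em_rows_jit = None


def fit_gmm2(
    values,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 3,
    seed: int | None = None,
) -> MixtureFit:
    """Fit the equal-variance two-component Gaussian mixture to one vector.

    Multi-start EM from quantile-split initializations (deterministic; *seed* is
    accepted for interface stability but the default starts are not random).
    Raises :class:`DegenerateInputError` for constant or too-short input;
    non-convergence is reported via ``converged=False``, not an exception.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateInputError(f"need >= 10 finite values, got {x.size}")
    if x.std() == 0:
        raise DegenerateInputError("constant input: mixture is not identifiable")
    starts = DEFAULT_START_PROPORTIONS[:n_starts] if n_starts <= 3 else tuple(
        np.linspace(0.15, 0.85, n_starts)
    )
    mu_low, mu_high, sig, pi, ll, n_iter, conv = _batch_em(
        x[None, :], tol=tol, max_iter=max_iter, start_proportions=starts
    )
    pi_f = float(np.clip(pi[0], 1e-10, 1 - 1e-10))
    return MixtureFit(
        mu_low=float(mu_low[0]),
        mu_high=float(mu_high[0]),
        sigma=float(sig[0]),
        pi_high=pi_f,
        loglik=float(ll[0]),
        n_iter=int(n_iter[0]),
        converged=bool(conv[0]),
        n=int(x.size),
    )


def bimodal_index(fit: MixtureFit) -> float:
    """BI = delta * sqrt(pi * (1 - pi)): separation weighted by balance."""
    return fit.bimodal_index


# ---------------------------------------------------------------------------
# dichotomization


def dichotomize_cluster(values, fit: MixtureFit) -> DichotomyLabels:
    """Label samples by maximum posterior component, i.e. threshold at the cutoff."""
    if fit.mu_high == fit.mu_low:
        raise DegenerateFitError("delta = 0: posterior cutoff undefined")
    x = np.asarray(values, dtype=float)
    cutoff = fit.cutoff
    labels = np.where(x > cutoff, "high", "low").astype(object)
    return DichotomyLabels(
        labels=np.asarray(labels, dtype=object),
        method="cluster",
        cutoff_low=cutoff,
        cutoff_high=cutoff,
    )


def dichotomize_median(values) -> DichotomyLabels:
    """High iff value > median; ties at the median go low."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need >= 2 values for a median split")
    med = float(np.median(x))
    labels = np.where(x > med, "high", "low").astype(object)
    return DichotomyLabels(labels=labels, method="median", cutoff_low=med, cutoff_high=med)


def dichotomize_quantile(values, hi_q: float = 0.8, lo_q: float = 0.7) -> DichotomyLabels:
    """Quantile-band split: high above the *hi_q* quantile, low below the *lo_q* one.

    Uses linear-interpolation quantiles with strict inequalities at both edges, so
    100 distinct values under the 0.8/0.7 defaults give exactly 20 high and 70 low;
    the middle band is excluded.
    """
    if not 0.0 <= lo_q <= hi_q <= 1.0:
        raise ValueError(f"require 0 <= lo_q <= hi_q <= 1, got lo_q={lo_q}, hi_q={hi_q}")
    x = np.asarray(values, dtype=float)
    hi_cut = float(np.quantile(x, hi_q))
    lo_cut = float(np.quantile(x, lo_q))
    labels = np.full(x.shape, "excluded", dtype=object)
    labels[x > hi_cut] = "high"
    labels[x < lo_cut] = "low"
    return DichotomyLabels(labels=labels, method="quantile",
                           cutoff_low=lo_cut, cutoff_high=hi_cut)


def zscore_standardize(values) -> np.ndarray:
    """Center and scale to unit SD (ddof=1), preserving order."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need >= 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# genome-wide screen


def screen_bimodal_genes(
    ds: ExpressionDataset,
    min_bi: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Fit the mixture to every gene and rank by bimodal index (descending).

    Zero-variance genes are flagged (``degenerate=True``, statistics NaN) rather
    than silently dropped; ``min_bi`` only annotates the ``passes_min_bi`` column.
    Returns columns: gene, mu_low, mu_high, sigma, pi, delta, BI, cutoff,
    converged, degenerate, passes_min_bi.
    """
    X = ds.values
    sd = X.std(axis=1)
    ok = sd > 0
    rows = []
    if ok.any():
        mu_low, mu_high, sig, pi, ll, n_iter, conv = _batch_em(
            X[ok], tol=tol, max_iter=max_iter,
            start_proportions=DEFAULT_START_PROPORTIONS,
        )
        delta = (mu_high - mu_low) / sig
        bi = delta * np.sqrt(pi * (1 - pi))
        with np.errstate(divide="ignore", invalid="ignore"):
            cutoff = np.where(
                mu_high > mu_low,
                (mu_low + mu_high) / 2 + sig ** 2 * np.log((1 - pi) / pi) / (mu_high - mu_low),
                np.nan,
            )
        fit_cols = dict(mu_low=mu_low, mu_high=mu_high, sigma=sig, pi=pi,
                        delta=delta, BI=bi, cutoff=cutoff, converged=conv)
        genes_ok = [g for g, o in zip(ds.gene_ids, ok) if o]
        fitted = pd.DataFrame({"gene": genes_ok, **fit_cols})
        fitted["degenerate"] = False
        rows.append(fitted)
    degenerate_genes = [g for g, o in zip(ds.gene_ids, ok) if not o]
    if degenerate_genes:
        rows.append(pd.DataFrame({
            "gene": degenerate_genes,
            "mu_low": np.nan, "mu_high": np.nan, "sigma": np.nan, "pi": np.nan,
            "delta": np.nan, "BI": np.nan, "cutoff": np.nan,
            "converged": False, "degenerate": True,
        }))
    out = pd.concat(rows, ignore_index=True)
    out["passes_min_bi"] = out["BI"] >= min_bi
    out = out.sort_values("BI", ascending=False, na_position="last",
                          kind="mergesort").reset_index(drop=True)
    return out


def screen_bimodal_study(
    datasets: list[ExpressionDataset],
    min_bi: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Rank genes by their *median* bimodal index across cohorts.

    A gene that is genuinely bimodal shows a high BI consistently across
    studies, whereas spurious mixture splits of unimodal genes are cohort
    idiosyncrasies that a median suppresses; this is the study-level screen the
    multi-cohort design calls for. Returns columns: gene, BI (median),
    BI_iqr_low/high (25th/75th percentile), n_cohorts, n_converged,
    passes_min_bi; sorted by median BI descending.
    """
    per_cohort = [
        screen_bimodal_genes(ds, min_bi=min_bi, tol=tol, max_iter=max_iter)
        for ds in datasets
    ]
    long = pd.concat(per_cohort, ignore_index=True)
    grouped = long.groupby("gene")
    out = pd.DataFrame({
        "BI": grouped["BI"].median(),
        "BI_iqr_low": grouped["BI"].quantile(0.25),
        "BI_iqr_high": grouped["BI"].quantile(0.75),
        "n_cohorts": grouped.size(),
        "n_converged": grouped["converged"].sum(),
    }).reset_index()
    out["passes_min_bi"] = out["BI"] >= min_bi
    return out.sort_values("BI", ascending=False, na_position="last",
                           kind="mergesort").reset_index(drop=True)
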
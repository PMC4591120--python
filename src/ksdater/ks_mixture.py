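"""Age-distribution histogram and normal-mixture fitting on ln(Ks).

The node-Ks age distribution is histogrammed at width 0.05 over [0, 2.0).
Mixtures of 1-10 normal components are fitted to ln(Ks) by EM — normal
components on the log scale are lognormal components on the Ks scale, which
is why the location parameter back-transforms (exp) to the component's
median Ks.  Each fit runs 100 random starts plus 10 k-means starts and
keeps the start with the highest converged log-likelihood; the number of
components is selected by BIC (and AIC, reported alongside).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

BIN_WIDTH = 0.05
KS_RANGE = (0.0, 2.0)

VAR_FLOOR = 1e-4      # ln-scale variance floor
WEIGHT_FLOOR = 1e-8


@dataclasses.dataclass
class KsHistogram:
    bin_width: float
    range: tuple[float, float]
    counts: np.ndarray
    n: int

    @property
    def edges(self) -> np.ndarray:
        lo, hi = self.range
        return np.arange(lo, hi + self.bin_width / 2, self.bin_width)


@dataclasses.dataclass
class MixtureFit:
    K: int
    weights: np.ndarray
    mus: np.ndarray          # ln-scale means, sorted ascending
    sigmas: np.ndarray       # ln-scale standard deviations
    loglik: float
    n: int
    start_label: str
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray

    @property
    def n_params(self) -> int:
        return 3 * self.K - 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n)


@dataclasses.dataclass
class ComponentSummary:
    mu: float
    sigma: float
    weight: float
    median_ks: float
    role: str                       # "discrete-event" | "background"
    divergence_mya: float | None = None


def ks_histogram(values: Sequence[float], bin_width: float = BIN_WIDTH,
                 ks_range: tuple[float, float] = KS_RANGE) -> KsHistogram:
    """Histogram of Ks values on half-open bins [low, low + width).

    Values at or below the range start, or at/above the range end, are a
    hard error — range filtering is the caller's contract.
    """
    lo, hi = ks_range
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (arr.min() <= lo or arr.max() >= hi):
        bad = arr[(arr <= lo) | (arr >= hi)][0]
        raise ValueError(f"Ks value {bad} outside ({lo}, {hi})")
    n_bins = int(round((hi - lo) / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    if arr.size:
        bins = np.floor((arr - lo) / bin_width).astype(int)
        np.add.at(counts, bins, 1)
    return KsHistogram(bin_width=bin_width, range=ks_range, counts=counts,
                       n=int(arr.size))


def _em_batch(x: np.ndarray, W: np.ndarray, MU: np.ndarray, VAR: np.ndarray,
              tol: float, max_iter: int) -> tuple[np.ndarray, ...]:
    """Run EM from many starts at once (vectorized over the start axis).

    Returns (W, MU, VAR, loglik, ok) with degenerate starts flagged ok=False.
    Identical update rule to :func:`_em`; used to keep 110-start fits fast.
    """
    S, K = W.shape
    n = x.size
    X = x[None, :, None]
    loglik = np.full(S, -np.inf)
    prev = np.full(S, -np.inf)
    ok = np.ones(S, dtype=bool)
    active = np.ones(S, dtype=bool)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        w, mu, var = W[idx], MU[idx], VAR[idx]
        log_comp = (
            np.log(w)[:, None, :]
            - 0.5 * np.log(2 * np.pi * var)[:, None, :]
            - 0.5 * (X - mu[:, None, :]) ** 2 / var[:, None, :]
        )
        m = log_comp.max(axis=2)
        log_norm = m + np.log(np.exp(log_comp - m[..., None]).sum(axis=2))
        ll = log_norm.sum(axis=1)
        resp = np.exp(log_comp - log_norm[..., None])
        nk = resp.sum(axis=1)
        dead = (nk <= 0).any(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * X).sum(axis=1) / nk
        var = (resp * (X - mu[:, None, :]) ** 2).sum(axis=1) / nk
        var = np.maximum(var, VAR_FLOOR)
        w = np.maximum(w, WEIGHT_FLOOR)
        w /= w.sum(axis=1, keepdims=True)
        spike = ((w <= WEIGHT_FLOOR * 1.01) & (var <= VAR_FLOOR * 1.01)).any(axis=1)
        dead |= spike
        W[idx], MU[idx], VAR[idx] = w, mu, var
        loglik[idx] = ll
        conv = (ll - prev[idx]) < tol * np.maximum(np.abs(ll), 1.0)
        conv &= it > 1
        ok[idx[dead]] = False
        active[idx[dead | conv]] = False
        prev[idx] = ll
    # final log-likelihood at the last parameters for surviving starts
    idx = np.flatnonzero(ok)
    if idx.size:
        w, mu, var = W[idx], MU[idx], VAR[idx]
        log_comp = (
            np.log(w)[:, None, :]
            - 0.5 * np.log(2 * np.pi * var)[:, None, :]
            - 0.5 * (X - mu[:, None, :]) ** 2 / var[:, None, :]
        )
        m = log_comp.max(axis=2)
        loglik[idx] = (m + np.log(np.exp(log_comp - m[..., None]).sum(axis=2))).sum(axis=1)
    return W, MU, VAR, loglik, ok


def _em(x: np.ndarray, w: np.ndarray, mu: np.ndarray, var: np.ndarray,
        tol: float, max_iter: int) -> tuple | None:
    """Run EM from one start; returns (w, mu, var, loglik, trace, n_iter,
    converged) or None if the start degenerates."""
    n = x.size
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        log_norm = logsumexp(log_comp, axis=1)
        loglik = float(log_norm.sum())
        trace.append(loglik)
        resp = np.exp(log_comp - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            return None
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, VAR_FLOOR)
        w = np.maximum(w, WEIGHT_FLOOR)
        w = w / w.sum()
        # a component pinned at both floors is a collapsed spike
        if np.any((w <= WEIGHT_FLOOR * 1.01) & (var <= VAR_FLOOR * 1.01)):
            return None
        if loglik - prev < tol * max(abs(loglik), 1.0) and it > 1:
            converged = True
            break
        prev = loglik
    # final log-likelihood at the converged parameters
    log_comp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi * var)[None, :]
        - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    )
    loglik = float(logsumexp(log_comp, axis=1).sum())
    trace.append(loglik)
    return w, mu, var, loglik, np.array(trace), it, converged


def fit_mixture(values: Sequence[float], K: int, n_random_starts: int = 100,
                n_kmeans_starts: int = 10, seed: int = 0, tol: float = 1e-8,
                max_iter: int = 1000) -> MixtureFit:
    """Fit a K-component normal mixture to ln(values) by multi-start EM.

    Random starts draw component means from sample quantiles at uniform
    random positions with a small jitter; k-means starts partition the
    ln-values with Lloyd's algorithm and take cluster moments.  Start-level
    seeds derive deterministically from ``seed`` + start index.  The best
    converged start by log-likelihood wins; components are returned sorted
    by ascending mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if np.any(arr <= 0):
        raise ValueError("mixture fitting requires strictly positive Ks values")
    if arr.size < 3 * K:
        raise ValueError(f"need at least {3 * K} values to fit K={K}")
    x = np.log(arr)
    sd = float(x.std()) or 1.0

    starts_w, starts_mu, starts_var, labels = [], [], [], []
    for s in range(n_random_starts):
        rng = np.random.default_rng((seed + s) % 2**31)
        qs = np.sort(rng.uniform(0, 1, size=K))
        starts_mu.append(np.quantile(x, qs) + rng.normal(0, 0.1 * sd, size=K))
        starts_var.append(np.full(K, max(sd**2 / K, VAR_FLOOR)))
        starts_w.append(np.full(K, 1.0 / K))
        labels.append(f"random:{s}")
    for s in range(n_kmeans_starts):
        rs = (seed + n_random_starts + s) % 2**31
        km = KMeans(n_clusters=min(K, x.size), n_init=1, random_state=rs)
        lab = km.fit_predict(x[:, None])
        mu0 = np.empty(K)
        var0 = np.empty(K)
        w0 = np.empty(K)
        for k in range(K):
            pts = x[lab == k] if k < km.n_clusters else x
            if pts.size == 0:
                pts = x
            mu0[k] = pts.mean()
            var0[k] = max(float(pts.var()), VAR_FLOOR)
            w0[k] = max(pts.size / x.size, 1.0 / (10 * K))
        starts_mu.append(mu0)
        starts_var.append(var0)
        starts_w.append(w0 / w0.sum())
        labels.append(f"kmeans:{s}")

    _, _, _, logliks, ok = _em_batch(
        x, np.array(starts_w), np.array(starts_mu), np.array(starts_var),
        tol, max_iter)
    if not ok.any():
        raise RuntimeError(
            f"all EM starts degenerated for K={K}; try a smaller K"
        )
    winner = int(np.flatnonzero(ok)[np.argmax(logliks[ok])])
    best_label = labels[winner]
    # re-run the winning start alone to recover its likelihood trace
    best = _em(x, starts_w[winner].copy(), starts_mu[winner].copy(),
               starts_var[winner].copy(), tol, max_iter)
    if best is None:  # pragma: no cover - winner cannot degenerate
        raise RuntimeError("winning start degenerated on re-run")
    w, mu, var, loglik, trace, n_iter, converged = best
    order = np.argsort(mu)
    return MixtureFit(K=K, weights=w[order], mus=mu[order],
                      sigmas=np.sqrt(var[order]), loglik=loglik, n=x.size,
                      start_label=best_label, n_iter=n_iter,
                      converged=converged, loglik_trace=trace)


def fit_mixtures(values: Sequence[float], k_max: int = 10, seed: int = 0,
                 **kw) -> list[MixtureFit]:
    """Fits for K = 1..k_max (K values exceeding the identifiability guard
    n >= 3K are skipped)."""
    n = len(list(values))
    fits = []
    for K in range(1, k_max + 1):
        if n < 3 * K:
            break
        fits.append(fit_mixture(values, K, seed=seed, **kw))
    return fits


def select_model(fits: Sequence[MixtureFit]) -> tuple[MixtureFit, MixtureFit, list[dict]]:
    """(best by BIC, best by AIC, criterion table); ties go to smaller K."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted K values")
    fits = sorted(fits, key=lambda f: f.K)
    by_bic = min(fits, key=lambda f: (f.bic, f.K))
    by_aic = min(fits, key=lambda f: (f.aic, f.K))
    table = [
        {"K": f.K, "loglik": f.loglik, "n_params": f.n_params,
         "aic": f.aic, "bic": f.bic}
        for f in fits
    ]
    return by_bic, by_aic, table


def summarize_components(fit: MixtureFit,
                         sigma_background_threshold: float = 0.4,
                         clock=None) -> list[ComponentSummary]:
    """Back-transform each component: median Ks = exp(mu).

    Components with a ln-scale standard deviation above the threshold are
    labelled "background" (continuous small-scale duplication across time);
    the rest are "discrete-event".  With a clock, discrete-event components
    also get a divergence estimate in Mya.
    """
    out = []
    for w, mu, sigma in zip(fit.weights, fit.mus, fit.sigmas):
        role = "background" if sigma > sigma_background_threshold else "discrete-event"
        med = math.exp(mu)
        mya = None
        if clock is not None and role == "discrete-event":
            from .wgd_dating import date_event
            mya = date_event(med, clock)
        out.append(ComponentSummary(mu=float(mu), sigma=float(sigma),
                                    weight=float(w), median_ks=med, role=role,
                                    divergence_mya=mya))
    return out
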
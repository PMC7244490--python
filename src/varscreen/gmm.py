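"""Univariate Gaussian mixtures by EM with BIC model selection.

Used to verify that anchored viabilities follow a two-component mixture
and to fix the normal-component centre ``eta_nor`` that the Bayesian
model takes as a known constant.  The BIC convention is the mclust one,
``BIC = 2*logL - k*log(n)``, so higher is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

_MIN_SD_FRACTION = 1e-6


class DegenerateFitError(RuntimeError):
    """Every EM start collapsed (a component shrank onto a point)."""


@dataclass
class GmmFit:
    n_components: int
    variance_mode: str  # "equal" | "unequal"
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float
    n_obs: int
    ll_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        k = self.n_components
        n_sd = 1 if self.variance_mode == "equal" else k
        return (k - 1) + k + n_sd


def _loglik(x, means, sds, weights):
    comp = (np.log(weights)[None, :]
            + norm.logpdf(x[:, None], means[None, :], sds[None, :]))
    return logsumexp(comp, axis=1)


def _em_once(x: np.ndarray, k: int, variance_mode: str, resp0: np.ndarray,
             tol: float, max_iter: int):
    """One EM run from an initial responsibility matrix.

    Returns (means, sds, weights, ll_trace) or None when degenerate.
    """
    n = len(x)
    scale = float(np.std(x))
    if scale == 0:
        return None
    resp = resp0
    trace = []
    means = sds = weights = None
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            return None
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        sq = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if variance_mode == "equal":
            sds = np.full(k, np.sqrt(sq.sum() / n))
        else:
            sds = np.sqrt(sq / nk)
        if np.any(sds < _MIN_SD_FRACTION * scale):
            return None
        # E step + log-likelihood
        comp = (np.log(weights)[None, :]
                + norm.logpdf(x[:, None], means[None, :], sds[None, :]))
        ll_i = logsumexp(comp, axis=1)
        ll = float(ll_i.sum())
        resp = np.exp(comp - ll_i[:, None])
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1):
            break
    return means, sds, weights, np.asarray(trace)


def _initial_resps(x: np.ndarray, k: int, n_starts: int,
                   rng: np.random.Generator):
    """First start splits at the median (k-means-like for k=2); the rest
    are random responsibilities."""
    n = len(x)
    inits = []
    if k == 1:
        return [np.ones((n, 1))]
    cut = np.median(x)
    hard = np.zeros((n, k))
    hard[x <= cut, 0] = 1.0
    hard[x > cut, 1] = 1.0
    # guard empty side
    if hard[:, 0].sum() > 0 and hard[:, 1].sum() > 0:
        inits.append(hard)
    while len(inits) < n_starts:
        r = rng.dirichlet(np.ones(k), size=n)
        inits.append(r)
    return inits


def fit_gmm(values, candidates=((1, "equal"), (1, "unequal"),
                                (2, "equal"), (2, "unequal")),
            tol: float = 1e-8, max_iter: int = 500, n_starts: int = 10,
            seed: int | None = 0) -> tuple[GmmFit, list[GmmFit]]:
    """Fit each candidate (n_components, variance_mode) by EM and select
    the fit with the highest BIC.

    Each candidate is run from ``n_starts`` initializations; starts where
    a component collapses are discarded.  Ties on BIC break toward the
    higher log-likelihood.  Raises :class:`DegenerateFitError` when no
    candidate admits a non-degenerate fit (e.g. all values identical).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    kmax = max(k for k, _ in candidates)
    if len(x) < 2 * kmax:
        raise ValueError(f"need at least {2 * kmax} values")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rng = np.random.default_rng(seed)
    n = len(x)
    fits: list[GmmFit] = []
    for k, mode in candidates:
        if mode not in ("equal", "unequal"):
            raise ValueError(f"unknown variance mode {mode!r}")
        best = None
        for resp0 in _initial_resps(x, k, n_starts, rng):
            res = _em_once(x, k, mode, resp0, tol, max_iter)
            if res is None:
                continue
            means, sds, weights, trace = res
            ll = float(trace[-1])
            if best is None or ll > best[3][-1]:
                best = (means, sds, weights, trace)
        if best is None:
            continue
        means, sds, weights, trace = best
        order = np.argsort(means)  # ascending: component 0 = lower centre
        fit = GmmFit(
            n_components=k, variance_mode=mode,
            means=means[order], sds=sds[order], weights=weights[order],
            log_likelihood=float(trace[-1]), bic=np.nan, n_obs=n,
            ll_trace=trace,
        )
        fit.bic = 2.0 * fit.log_likelihood - fit.n_params * np.log(n)
        fits.append(fit)
    if not fits:
        raise DegenerateFitError(
            "all EM starts degenerate for every candidate model")
    best_fit = max(fits, key=lambda f: (f.bic, f.log_likelihood))
    return best_fit, fits


def fit_summary(fits: list[GmmFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "n_components": f.n_components, "variance_mode": f.variance_mode,
            "log_likelihood": f.log_likelihood, "bic": f.bic,
            "means": ",".join(f"{m:.4f}" for m in f.means),
            "sds": ",".join(f"{s:.4f}" for s in f.sds),
            "weights": ",".join(f"{w:.4f}" for w in f.weights),
        }
        for f in fits
    ])


def estimate_eta_nor(observations: pd.DataFrame, annotations: pd.DataFrame,
                     tol: float = 1e-8, n_starts: int = 10,
                     seed: int | None = 0) -> float:
    """Centre of the normal (upper) component of the training data.

    Fits the candidate set on the anchored viabilities of reference-
    labelled (benign or pathogenic) variants and returns the mean of the
    component with the larger mean from the selected two-component fit.
    Raises if the training set is empty or a one-component model wins.
    """
    labelled = annotations.loc[
        annotations["label"].isin(["benign", "pathogenic"]), "variant_id"]
    if labelled.empty:
        raise ValueError("training set contains no labelled variants")
    vals = observations.loc[
        observations["variant_id"].isin(set(labelled)), "f"].to_numpy()
    if vals.size == 0:
        raise ValueError("no observations for labelled variants")
    best, _ = fit_gmm(vals, tol=tol, n_starts=n_starts, seed=seed)
    if best.n_components != 2:
        raise RuntimeError(
            "selected model has one component; cannot identify the normal "
            "centre (training data not bimodal)")
    return float(best.means[-1])
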
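"""Performance metrics against reference labels and MCMC diagnostics.

Covers exact (Clopper-Pearson) binomial confidence intervals for
sensitivity/specificity, ROC threshold selection by the Youden index,
the positive likelihood ratio, split R-hat convergence checks, posterior
expected standardized residuals (QQ), and posterior predictive density
overlays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest, gaussian_kde, norm


# ---------------------------------------------------------------------------
# label-based performance

def exact_binomial_ci(k: int, n: int, level: float = 0.95
                      ) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a proportion."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid successes/trials: {k}/{n}")
    ci = binomtest(k, n).proportion_ci(confidence_level=level,
                                       method="exact")
    return float(ci.low), float(ci.high)


def positive_likelihood_ratio(sens_k: int, sens_n: int,
                              spec_k: int, spec_n: int) -> float:
    """LR+ = sensitivity / (1 - specificity).

    A specificity of exactly 1 yields ``inf`` (flagged by the caller, not
    raised): the assay made no false-positive calls.
    """
    sens = sens_k / sens_n
    spec = spec_k / spec_n
    if spec == 1.0:
        return float("inf")
    return sens / (1.0 - spec)


class PerformanceReport(NamedTuple):
    threshold: float
    direction: str                # "low" = low score calls pathogenic
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    lr_plus: float
    tp: int
    fn: int
    tn: int
    fp: int


def roc_optimal_threshold(scores: pd.Series, labels: pd.Series,
                          level: float = 0.95) -> PerformanceReport:
    """Optimal ROC operating point by the Youden index.

    ``labels`` holds "pathogenic"/"benign" per variant; scores are swept
    over all observed values in both calling directions (low-calls-
    pathogenic and high-calls-pathogenic) and the threshold maximizing
    sensitivity + specificity - 1 is selected, ties broken toward higher
    specificity.  Exact binomial CIs accompany both proportions.
    """
    scores, labels = scores.align(labels, join="inner")
    y = labels.to_numpy()
    s = scores.to_numpy(dtype=float)
    pos = y == "pathogenic"
    neg = y == "benign"
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best = None
    cuts = np.unique(s)
    midpoints = np.concatenate(
        [[cuts[0] - 1.0], (cuts[:-1] + cuts[1:]) / 2.0, [cuts[-1] + 1.0]])
    for direction in ("low", "high"):
        for t in midpoints:
            call_path = s <= t if direction == "low" else s >= t
            tp = int((call_path & pos).sum())
            fp = int((call_path & neg).sum())
            sens = tp / n_pos
            spec = (n_neg - fp) / n_neg
            key = (sens + spec - 1.0, spec)
            if best is None or key > best[0]:
                best = (key, t, direction, tp, fp)
    _, t, direction, tp, fp = best
    fn, tn = n_pos - tp, n_neg - fp
    return PerformanceReport(
        threshold=float(t), direction=direction,
        sensitivity=tp / n_pos, specificity=tn / n_neg,
        sens_ci=exact_binomial_ci(tp, n_pos, level),
        spec_ci=exact_binomial_ci(tn, n_neg, level),
        lr_plus=positive_likelihood_ratio(tp, n_pos, tn, n_neg),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def format_report(report: PerformanceReport) -> str:
    """Paper-style rendering: percentages to whole numbers, LR to one
    decimal."""
    sl, sh = (round(100 * x) for x in report.sens_ci)
    pl, ph = (round(100 * x) for x in report.spec_ci)
    lr = ("inf" if np.isinf(report.lr_plus)
          else f"{report.lr_plus:.1f}")
    return (f"sensitivity {round(100 * report.sensitivity)}% "
            f"(95% CI {sl}-{sh}%), "
            f"specificity {round(100 * report.specificity)}% "
            f"(95% CI {pl}-{ph}%), LR+ {lr}:1")


# ---------------------------------------------------------------------------
# convergence

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (rank-free form).

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before the between/within variance comparison.
    """
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    b = half * split.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def convergence_check(draws, threshold: float = 1.1) -> pd.Series:
    """Split R-hat for every continuous parameter of a posterior.

    Returns a Series indexed by parameter name; anchor etas (constants)
    are excluded.  The fit passes when all values are below ``threshold``.
    """
    table = {}
    for name, arr in draws.scalar_views().items():
        if np.allclose(arr, arr.reshape(-1)[0]):
            continue  # held fixed (e.g. clamped parameters in oracle runs)
        table[name] = split_rhat(arr)
    return pd.Series(table, name="rhat")


# ---------------------------------------------------------------------------
# posterior predictive machinery

def qq_standardized_residuals(draws, n_band_sim: int = 2000,
                              seed: int = 0) -> pd.DataFrame:
    """Posterior expected standardized residuals with normal quantiles.

    The residual of observation i is the posterior mean of
    ``(f_i - (beta_b + tau_b*eta_v)) / (tau_b*psi)``.  A 95% simultaneous
    band for the ordered residuals of a standard normal sample of the
    same size is attached (columns ``band_low``/``band_high``), computed
    by simulation.
    """
    data = draws.data
    beta = draws.flat("beta")          # (S, n_batch)
    tau = draws.flat("tau")
    eta = draws.flat("eta")            # (S, n_var)
    psi = draws.flat("psi")            # (S,)
    mu = beta[:, data.batch_idx] + tau[:, data.batch_idx] * eta[:, data.var_idx]
    sd = tau[:, data.batch_idx] * psi[:, None]
    resid = ((data.f[None, :] - mu) / sd).mean(axis=0)

    n = len(resid)
    order = np.argsort(resid)
    theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)

    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_band_sim, n)), axis=1)
    lo, hi = _simultaneous_band(sims, coverage=0.95)
    return pd.DataFrame({
        "observation": order,
        "residual": resid[order],
        "theoretical": theo,
        "band_low": lo,
        "band_high": hi,
    })


def _simultaneous_band(sorted_sims: np.ndarray, coverage: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-order-statistic envelope whose simultaneous coverage over the
    simulated curves reaches the target, found by bisecting the
    pointwise tail level."""

    def band(alpha):
        lo = np.quantile(sorted_sims, alpha / 2, axis=0)
        hi = np.quantile(sorted_sims, 1 - alpha / 2, axis=0)
        inside = np.all((sorted_sims >= lo) & (sorted_sims <= hi), axis=1)
        return lo, hi, inside.mean()

    lo_a, hi_a = 1e-5, 1 - coverage
    for _ in range(40):
        mid = 0.5 * (lo_a + hi_a)
        _, _, cov = band(mid)
        if cov >= coverage:
            lo_a = mid
        else:
            hi_a = mid
    lo, hi, _ = band(lo_a)
    return lo, hi


@dataclass
class PpcConfig:
    """Posterior predictive check settings: number of parameter draws and
    of replicate values generated per variant."""

    n_param_samples: int = 512
    n_values_per_variant: int = 612
    seed: int = 0

    def __post_init__(self):
        if self.n_param_samples < 1 or self.n_values_per_variant < 1:
            raise ValueError("PPC sample counts must be >= 1")


class PpcResult(NamedTuple):
    grid: np.ndarray
    replicate_density: np.ndarray   # (n_param_samples, len(grid))
    observed_density: np.ndarray
    envelope_coverage: float        # fraction of grid inside 2.5-97.5% band


def posterior_predictive_density(draws, config: PpcConfig | None = None,
                                 grid_size: int = 101) -> PpcResult:
    """Replicate-data density curves against the observed density.

    For each sampled parameter set, replicate anchored viabilities are
    generated per variant from the likelihood, with batches drawn
    proportionally to each batch's share of that variant's observations
    (the batch-to-batch ratio).  Densities are Gaussian KDEs on a common
    grid spanning the observed values.
    """
    config = config or PpcConfig()
    data = draws.data
    rng = np.random.default_rng(config.seed)

    beta = draws.flat("beta")
    tau = draws.flat("tau")
    eta = draws.flat("eta")
    psi = draws.flat("psi")
    total = beta.shape[0]
    pick = rng.choice(total, size=min(config.n_param_samples, total),
                      replace=config.n_param_samples > total)

    # per-variant batch shares
    counts = np.zeros((data.n_var, data.n_batch))
    np.add.at(counts, (data.var_idx, data.batch_idx), 1.0)
    shares = counts / counts.sum(axis=1, keepdims=True)

    pad = 0.5
    grid = np.linspace(data.f.min() - pad, data.f.max() + pad, grid_size)
    obs_kde = gaussian_kde(data.f)
    observed = obs_kde(grid)
    # replicate sets are much larger than the observed one; evaluating
    # their KDEs at the same absolute bandwidth keeps the curves
    # comparable with the observed density
    h_abs = obs_kde.factor * float(np.std(data.f, ddof=1))

    m = config.n_values_per_variant
    rep_density = np.empty((len(pick), grid_size))
    for row, s in enumerate(pick):
        batch_draw = np.array([
            rng.choice(data.n_batch, size=m, p=shares[v])
            for v in range(data.n_var)
        ])
        mu = beta[s][batch_draw] + tau[s][batch_draw] * eta[s][:, None]
        sd = tau[s][batch_draw] * psi[s]
        values = rng.normal(mu, sd).ravel()
        spread = float(np.std(values, ddof=1))
        rep_density[row] = gaussian_kde(
            values, bw_method=h_abs / spread if spread > 0 else None)(grid)

    lo = np.quantile(rep_density, 0.025, axis=0)
    hi = np.quantile(rep_density, 0.975, axis=0)
    coverage = float(((observed >= lo) & (observed <= hi)).mean())
    return PpcResult(grid, rep_density, observed, coverage)
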
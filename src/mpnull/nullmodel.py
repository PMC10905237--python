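"""Null model of multiple paternity under equal siring success.

Brood sizes K follow a zero-truncated Poisson (ZTP) with rate λ; conditional
on K = k, the number of sires S follows a Poisson with rate θ doubly truncated
to {1, ..., k} (a brood has at least one and at most k sires).  Under the null
hypothesis every mated male has the same chance of siring, so the expected
probability of multiple paternity is

    pB(θ, λ) = Σ_k  P(K = k | λ) · P(S > 1 | θ, k),

and the deviation of an observed population from the null is pB − p, where p
is the observed proportion of multiply-sired broods.  θ and λ are estimated
per population from the reported summaries (k̄, s̄, n) by Metropolis-within-
Gibbs MCMC with gamma priors.

Two conventions relate the observed mean sire count s̄ to θ:

* ``rate_plugin`` (default): s̄ identifies the Poisson rate before truncation,
  i.e. s̄ ~ Normal(θ, sd(S)/√n).
* ``mean_calibrated``: s̄ estimates the truncated mean, s̄ ~ Normal(E[S], sd(S)/√n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .records import PopulationRecord

__all__ = [
    "NullModelConfig",
    "NullModelFit",
    "ztp_pmf",
    "ztp_mean",
    "ztp_var",
    "ztp_lambda_from_mean",
    "dtp_sire_pmf",
    "prob_mp_given_k",
    "prob_mp",
    "expected_sires",
    "simulate_null_broods",
    "fit_null_model",
    "deviation_summary",
    "pb_curve",
]


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _check_positive(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def _auto_kmax(lam_max: float, cap: int) -> int:
    # tail mass of Poisson(λ) beyond λ + 10√λ + 25 is far below 1e-10
    return int(min(cap, max(25, math.ceil(lam_max + 10.0 * math.sqrt(lam_max) + 25))))


def ztp_pmf(k, lam) -> np.ndarray | float:
    """P(K = k) for K ~ zero-truncated Poisson(λ): λ^k e^{-λ} / (k! (1-e^{-λ}))."""
    lam_arr = _check_positive("lambda", lam)
    k_arr = np.asarray(k)
    logp = k_arr * np.log(lam_arr) - lam_arr - gammaln(k_arr + 1)
    out = np.where(k_arr >= 1, np.exp(logp) / (-np.expm1(-lam_arr)), 0.0)
    return float(out) if np.isscalar(k) and np.isscalar(lam) else out


def ztp_mean(lam) -> np.ndarray | float:
    """E[K] = λ / (1 - e^{-λ})."""
    lam_arr = _check_positive("lambda", lam)
    return lam_arr / (-np.expm1(-lam_arr))


def ztp_var(lam) -> np.ndarray | float:
    """Var[K] = E[K] (1 + λ - E[K])."""
    m = ztp_mean(lam)
    lam_arr = np.asarray(lam, dtype=float)
    return m * (1.0 + lam_arr - m)


def ztp_lambda_from_mean(mean_brood_size: float, tol: float = 1e-10) -> float:
    """Invert the ZTP mean: the λ with λ/(1-e^{-λ}) equal to k̄ (bisection).

    The ZTP mean is strictly increasing in λ with limit 1 as λ → 0+, so the
    inversion requires k̄ > 1; k̄ ≤ 1 is a degenerate brood distribution
    (point mass at one offspring) and raises.
    """
    kbar = float(mean_brood_size)
    if kbar <= 1.0:
        raise ValueError("degenerate brood distribution: mean brood size must exceed 1")
    f = lambda lam: lam / (-math.expm1(-lam)) - kbar
    return float(brentq(f, 1e-12, kbar, xtol=tol))


def dtp_sire_pmf(s, theta, k) -> np.ndarray | float:
    """P(S = s | θ, k): Poisson(θ) doubly truncated to {1..k}.

    P(S = s) = (θ^s / s!) / Σ_{j=1..k} θ^j / j!; zero outside the support.
    Broadcasts over array arguments.
    """
    _check_positive("theta", theta)
    scalar = np.isscalar(s) and np.isscalar(theta) and np.isscalar(k)
    s_b, th_b, k_b = np.broadcast_arrays(
        np.atleast_1d(s), np.atleast_1d(np.asarray(theta, float)), np.atleast_1d(k)
    )
    if np.any(np.asarray(k_b) < 1):
        raise ValueError("brood size k must be >= 1")
    kmax = int(np.max(k_b))
    j = np.arange(1, kmax + 1)
    logt = j * np.log(th_b)[..., None] - gammaln(j + 1)
    shift = logt.max(axis=-1)
    z = np.cumsum(np.exp(logt - shift[..., None]), axis=-1)
    zk = np.take_along_axis(z, (np.asarray(k_b, int) - 1)[..., None], axis=-1)[..., 0]
    valid = (s_b >= 1) & (s_b <= k_b)
    s_safe = np.where(valid, s_b, 1)
    num = np.where(valid, np.exp(s_safe * np.log(th_b) - gammaln(s_safe + 1) - shift), 0.0)
    out = num / zk
    return float(out[0]) if scalar else out


def _sire_tables(theta: np.ndarray, kmax: int):
    """Cumulative Σ θ^j/j!, Σ j θ^j/j!, Σ j² θ^j/j! for j = 1..kmax (stable)."""
    j = np.arange(1, kmax + 1)
    logt = j * np.log(theta)[..., None] - gammaln(j + 1)
    t = np.exp(logt - logt.max(axis=-1, keepdims=True))
    z = np.cumsum(t, axis=-1)
    m1 = np.cumsum(j * t, axis=-1) / z
    m2 = np.cumsum(j * j * t, axis=-1) / z
    p_single = t[..., :1] / z
    return p_single, m1, m2


def _ztp_weights(lam: np.ndarray, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    logw = k * np.log(lam)[..., None] - lam[..., None] - gammaln(k + 1)
    w = np.exp(logw)
    return w / w.sum(axis=-1, keepdims=True)


def prob_mp_given_k(theta, k) -> np.ndarray | float:
    """P(S > 1 | θ, k) = 1 - P(S = 1 | θ, k); zero for broods of one."""
    if np.isscalar(theta) and np.isscalar(k):
        return 1.0 - dtp_sire_pmf(1, theta, k)
    return 1.0 - dtp_sire_pmf(np.ones_like(np.atleast_1d(k)), theta, k)


def prob_mp(theta, lam, max_k: int = 400) -> np.ndarray | float:
    """Expected probability of multiple paternity pB(θ, λ) under the null.

    Marginalises P(S > 1 | θ, k) over the ZTP brood-size distribution;
    broadcasts over array-valued θ, λ.
    """
    th = _check_positive("theta", theta)
    la = _check_positive("lambda", lam)
    th, la = np.broadcast_arrays(np.atleast_1d(th), np.atleast_1d(la))
    kmax = _auto_kmax(float(la.max()), max_k)
    w = _ztp_weights(la, kmax)
    p_single, _, _ = _sire_tables(th, kmax)
    pb = (w * (1.0 - p_single)).sum(axis=-1)
    if np.isscalar(theta) and np.isscalar(lam):
        return float(pb[0])
    return pb.reshape(np.broadcast_shapes(np.shape(theta), np.shape(lam)))


def expected_sires(theta, lam, max_k: int = 400) -> tuple:
    """Mean and variance of the sire count S under the null model.

    E[S] = Σ_k P(K=k|λ) E[S|θ,k]; Var[S] by the law of total variance.
    """
    th = _check_positive("theta", theta)
    la = _check_positive("lambda", lam)
    th, la = np.broadcast_arrays(np.atleast_1d(th), np.atleast_1d(la))
    kmax = _auto_kmax(float(la.max()), max_k)
    w = _ztp_weights(la, kmax)
    _, m1, m2 = _sire_tables(th, kmax)
    es = (w * m1).sum(axis=-1)
    es2 = (w * m2).sum(axis=-1)
    var = es2 - es * es
    if np.isscalar(theta) and np.isscalar(lam):
        return float(es[0]), float(max(var[0], 0.0))
    shape = np.broadcast_shapes(np.shape(theta), np.shape(lam))
    return es.reshape(shape), np.maximum(var, 0.0).reshape(shape)


# ---------------------------------------------------------------------------
# simulation (Monte-Carlo oracle and generator backend)
# ---------------------------------------------------------------------------

def simulate_null_broods(theta: float, lam: float, n: int, seed) -> pd.DataFrame:
    """Draw n independent broods (k, s) from the null generative model.

    K by inversion sampling of the ZTP cdf; S | K = k by inversion of the
    doubly truncated Poisson over {1..k}.  ``seed`` may be an int or a
    ``numpy.random.Generator``; the same seed yields the same table.
    """
    _check_positive("theta", theta)
    _check_positive("lambda", lam)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kmax = _auto_kmax(lam, 10_000)
    cdf = np.cumsum(ztp_pmf(np.arange(1, kmax + 1), lam))
    k = np.searchsorted(cdf, rng.random(n), side="right") + 1
    k = np.minimum(k, kmax)
    s = np.ones(n, dtype=int)
    j = np.arange(1, int(k.max()) + 1)
    t = np.exp(j * math.log(theta) - gammaln(j + 1))
    for kv in np.unique(k):
        mask = k == kv
        if kv == 1:
            continue
        probs = t[:kv] / t[:kv].sum()
        s[mask] = np.searchsorted(np.cumsum(probs), rng.random(mask.sum()), side="right") + 1
    return pd.DataFrame({"k": k, "s": np.minimum(s, k)})


# ---------------------------------------------------------------------------
# Bayesian fit
# ---------------------------------------------------------------------------

@dataclass
class NullModelConfig:
    """MCMC settings and priors for the per-population null-model fit."""

    sire_rate_convention: str = "rate_plugin"  # or "mean_calibrated"
    prior_theta: tuple[float, float] = (1.0, 0.5)  # gamma (shape, rate)
    prior_lambda: tuple[float, float] = (1.0, 0.25)
    n_iter: int = 10_000
    n_burnin: int = 2_000
    n_chains: int = 3
    seed: int = 0
    max_k: int = 400
    sd_floor: float = 0.005  # floor on the summary-level sampling sds

    def __post_init__(self) -> None:
        if self.sire_rate_convention not in {"rate_plugin", "mean_calibrated"}:
            raise ValueError(f"unknown convention {self.sire_rate_convention!r}")
        if not self.n_iter > self.n_burnin >= 0:
            raise ValueError("need n_iter > n_burnin >= 0")


@dataclass
class NullModelFit:
    """Posterior of (θ, λ) and the derived null prediction for one population."""

    population_id: str
    theta_samples: np.ndarray
    lambda_samples: np.ndarray
    pB_samples: np.ndarray
    pB_mean: float
    pB_ci: tuple[float, float]
    deviation: float
    deviation_ci: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    degenerate: bool = False


def _log_gamma_pdf_on_log(x: float, shape: float, rate: float) -> float:
    # density of log X when X ~ Gamma(shape, rate): includes the Jacobian e^x
    return shape * math.log(rate) - math.lgamma(shape) + shape * x - rate * math.exp(x)


def _sire_moments_scalar(th: float, la: float, kmax: int) -> tuple[float, float]:
    """E[S] and Var[S] by one fused pass over k (fast path for the sampler)."""
    es = es2 = wsum = 0.0
    w = math.exp(-la) * la  # Poisson weight at k=1
    t = th                  # θ^j/j! running term, j=1
    z = th
    m1 = th
    m2 = th
    for k in range(1, kmax + 1):
        es += w * (m1 / z)
        es2 += w * (m2 / z)
        wsum += w
        j = k + 1
        w *= la / j
        tj = t * th / j
        t = tj
        z += tj
        m1 += j * tj
        m2 += j * j * tj
    es /= wsum
    es2 /= wsum
    return es, max(es2 - es * es, 0.0)


def _make_logpost(rec: PopulationRecord, cfg: NullModelConfig):
    kbar, sbar, n = rec.mean_brood_size, rec.mean_n_sires, rec.n_broods
    floor2 = cfg.sd_floor ** 2
    plugin = cfg.sire_rate_convention == "rate_plugin"
    a_t, b_t = cfg.prior_theta
    a_l, b_l = cfg.prior_lambda

    def logpost(logth: float, logla: float) -> float:
        th, la = math.exp(logth), math.exp(logla)
        if not (1e-8 < th < 100.0 and 1e-8 < la < 100.0):
            return -math.inf
        em1 = -math.expm1(-la)
        mk = la / em1
        vk = mk * (1.0 + la - mk)
        var_k = vk / n + floor2
        lp = -0.5 * (math.log(2 * math.pi * var_k) + (kbar - mk) ** 2 / var_k)
        kmax = _auto_kmax(la, cfg.max_k)
        es, vs = _sire_moments_scalar(th, la, kmax)
        mu_s = th if plugin else es
        var_s = vs / n + floor2
        lp += -0.5 * (math.log(2 * math.pi * var_s) + (sbar - mu_s) ** 2 / var_s)
        lp += _log_gamma_pdf_on_log(logth, a_t, b_t)
        lp += _log_gamma_pdf_on_log(logla, a_l, b_l)
        return lp

    return logpost


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (chains: n_chains × n)."""
    half = chains.shape[1] // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    x = x - x.mean()
    n = len(x)
    if n < 10 or np.allclose(x, 0):
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var() + 1e-300)
    s = 0.0
    for t in range(1, min(n // 2, 1000)):
        if acf[t] < 0.0:
            break
        s += acf[t]
    return float(n / (1.0 + 2.0 * s))


def fit_null_model(rec: PopulationRecord, cfg: NullModelConfig) -> NullModelFit:
    """Fit the null model to one population's summaries by adaptive MCMC.

    Metropolis-within-Gibbs on (log θ, log λ): each component gets a Gaussian
    random-walk proposal whose scale adapts during burn-in towards a 20-50%
    acceptance rate.  ``cfg.n_chains`` chains are run from dispersed starts
    with per-chain seeds derived deterministically from ``cfg.seed``.  The
    derived pB draw is computed for every retained (θ, λ) draw.

    Populations with k̄ ≤ 1 cannot show multiple paternity; they return a
    degenerate fit with pB ≡ 0 and deviation −p.
    """
    if rec.mean_brood_size <= 1.0:
        z = np.zeros(1)
        return NullModelFit(
            population_id=rec.population_id,
            theta_samples=z, lambda_samples=z, pB_samples=z,
            pB_mean=0.0, pB_ci=(0.0, 0.0),
            deviation=-rec.prop_mp, deviation_ci=(-rec.prop_mp, -rec.prop_mp),
            diagnostics={"note": "degenerate brood size"},
            warnings=["degenerate brood size: k̄ <= 1, pB is identically 0"],
            degenerate=True,
        )

    logpost = _make_logpost(rec, cfg)
    lam0 = ztp_lambda_from_mean(max(rec.mean_brood_size, 1.0 + 1e-6))
    th0 = max(rec.mean_n_sires if cfg.sire_rate_convention == "rate_plugin"
              else rec.mean_n_sires, 0.05)
    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = ss.spawn(cfg.n_chains)
    keep = cfg.n_iter - cfg.n_burnin
    th_chains = np.empty((cfg.n_chains, keep))
    la_chains = np.empty((cfg.n_chains, keep))
    acc_total = np.zeros(2)

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        x = np.array([
            math.log(th0) + 0.3 * rng.standard_normal(),
            math.log(lam0) + 0.2 * rng.standard_normal(),
        ])
        lp = logpost(*x)
        scales = np.array([0.4, 0.25])
        acc = np.zeros(2)
        for it in range(cfg.n_iter):
            for d in range(2):
                prop = x.copy()
                prop[d] += scales[d] * rng.standard_normal()
                lp_prop = logpost(*prop)
                if math.log(rng.random() + 1e-300) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc[d] += 1
                if it < cfg.n_burnin and (it + 1) % 50 == 0:
                    rate = acc[d] / (it + 1)
                    scales[d] *= math.exp((rate - 0.3) / math.sqrt(1 + it / 50))
                    scales[d] = min(max(scales[d], 1e-3), 5.0)
            if it >= cfg.n_burnin:
                th_chains[c, it - cfg.n_burnin] = x[0]
                la_chains[c, it - cfg.n_burnin] = x[1]
        acc_total += acc / cfg.n_iter
    acc_total /= cfg.n_chains

    theta = np.exp(th_chains.reshape(-1))
    lam = np.exp(la_chains.reshape(-1))
    pb = prob_mp(theta, lam, cfg.max_k)
    pb_mean = float(pb.mean())
    lo, hi = np.percentile(pb, [2.5, 97.5])
    rhat = max(_split_rhat(th_chains), _split_rhat(la_chains))
    warnings = []
    if rhat > 1.01:
        warnings.append(f"split-chain R-hat {rhat:.3f} exceeds 1.01: chains may not have converged")
    diagnostics = {
        "acceptance_rate": {"log_theta": float(acc_total[0]), "log_lambda": float(acc_total[1])},
        "ess_theta": _ess(theta),
        "ess_lambda": _ess(lam),
        "split_rhat": rhat,
    }
    return NullModelFit(
        population_id=rec.population_id,
        theta_samples=theta,
        lambda_samples=lam,
        pB_samples=pb,
        pB_mean=pb_mean,
        pB_ci=(float(lo), float(hi)),
        deviation=pb_mean - rec.prop_mp,
        deviation_ci=(float(lo) - rec.prop_mp, float(hi) - rec.prop_mp),
        diagnostics=diagnostics,
        warnings=warnings,
    )


def deviation_summary(
    fits: Sequence[NullModelFit], records: Sequence[PopulationRecord]
) -> tuple[pd.DataFrame, dict]:
    """Per-population deviations pB − p plus cohort aggregates.

    Returns a table ordered by mean brood size (one row per population: p,
    pB and its credible interval, the deviation and whether its interval
    spans zero) and a dict of aggregates: the mean deviation, the number and
    fraction of populations whose deviation interval overlaps zero, and the
    count/fraction of populations with observed p below the null mean.
    """
    by_id = {r.population_id: r for r in records}
    rows = []
    for f in fits:
        if f.population_id not in by_id:
            raise ValueError(f"fit for unknown population {f.population_id!r}")
        r = by_id[f.population_id]
        lo, hi = f.deviation_ci
        rows.append({
            "population_id": r.population_id,
            "species_name": r.species_name,
            "clade": r.clade,
            "mean_brood_size": r.mean_brood_size,
            "p_observed": r.prop_mp,
            "pB_mean": f.pB_mean,
            "pB_lo": f.pB_ci[0],
            "pB_hi": f.pB_ci[1],
            "deviation": f.deviation,
            "deviation_lo": lo,
            "deviation_hi": hi,
            "ci_overlaps_zero": bool(lo <= 0.0 <= hi),
        })
    if len(rows) != len(records):
        raise ValueError("fits and records are not aligned one-to-one")
    table = pd.DataFrame(rows).sort_values("mean_brood_size", kind="stable").reset_index(drop=True)
    n = len(table)
    agg = {
        "n_populations": n,
        "mean_deviation": float(table["deviation"].mean()),
        "n_ci_overlap_zero": int(table["ci_overlaps_zero"].sum()),
        "frac_ci_overlap_zero": float(table["ci_overlaps_zero"].mean()),
        "n_obs_above_null_mean": int((table["p_observed"] > table["pB_mean"]).sum()),
        "frac_obs_below_null_mean": float((table["p_observed"] < table["pB_mean"]).mean()),
    }
    return table, agg


def pb_curve(
    theta_samples: np.ndarray,
    brood_sizes: np.ndarray | None = None,
    max_k: int = 400,
) -> pd.DataFrame:
    """Null prediction pB with 95% credible band over a mean-brood-size grid.

    For each grid value k̄ the ZTP rate is recovered by inversion and pB is
    evaluated for every posterior θ draw; k̄ ≤ 1 maps to pB = 0.
    """
    if brood_sizes is None:
        brood_sizes = np.arange(1.0, 12.01, 0.25)
    th = np.asarray(theta_samples, dtype=float)
    rows = []
    for kbar in np.asarray(brood_sizes, dtype=float):
        if kbar <= 1.0:
            rows.append({"mean_brood_size": kbar, "pB_mean": 0.0, "pB_lo": 0.0, "pB_hi": 0.0})
            continue
        lam = ztp_lambda_from_mean(kbar)
        pb = prob_mp(th, np.full_like(th, lam), max_k)
        lo, hi = np.percentile(pb, [2.5, 97.5])
        rows.append({
            "mean_brood_size": kbar,
            "pB_mean": float(pb.mean()),
            "pB_lo": float(lo),
            "pB_hi": float(hi),
        })
    return pd.DataFrame(rows)
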
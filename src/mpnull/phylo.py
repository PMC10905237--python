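"""Trees, phylogenetic correlation, and Bayesian phylogenetic mixed models.

Trees are time-calibrated (ultrametric) phylogenies handled through dendropy;
the phylogenetic correlation matrix C scales shared ancestry (root-to-MRCA
path length) by total tree depth.  The mixed models decompose among-species
trait variance into a phylogenetic component (random effect with covariance
σ²_p C) and a residual, giving the phylogenetic heritability
h = σ²_p / (σ²_p + σ²_e); for binary traits a logistic liability is used with
residual variance fixed at π²/3, so the group fixed effect is a log odds
ratio.
"""

from __future__ import annotations

import math
import warnings as _warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "PMMConfig",
    "PhyloMixedFit",
    "parse_newick",
    "write_newick",
    "majority_rule_consensus",
    "graft_trees",
    "phylo_correlation",
    "fit_pmm_gaussian",
    "fit_pmm_binary",
    "phylo_heritability",
]

_ULTRAMETRIC_RTOL = 1e-6


class PhyloTree:
    """A rooted tree with branch lengths in time units (thin dendropy wrapper)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        self.tip_labels: list[str] = labels

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _tip_depths(self) -> np.ndarray:
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return np.array([leaf.root_distance for leaf in self._tree.leaf_node_iter()])

    @property
    def depth(self) -> float:
        return float(self._tip_depths().max())

    @property
    def is_ultrametric(self) -> bool:
        d = self._tip_depths()
        top = d.max()
        return bool(top > 0 and np.all(np.abs(d - top) <= _ULTRAMETRIC_RTOL * top))

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required on all non-root edges)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError(
                f"missing branch length on edge above {node.taxon.label if node.taxon else 'an internal node'}"
            )
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree to Newick (inverse of :func:`parse_newick`)."""
    return tree.newick()


def majority_rule_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Majority-rule consensus: clades in more than half of the input trees.

    All inputs must share the same tip set.  Retained branches get the mean
    length of that branch over the trees that contain it; parts of the tree
    without a majority clade remain polytomies.
    """
    if not trees:
        raise ValueError("no trees given")
    tipsets = {frozenset(t.tip_labels) for t in trees}
    if len(tipsets) != 1:
        raise ValueError("all trees must share the same tip set")
    tl = dendropy.TreeList()
    for t in trees:
        tl.read(data=t.newick(), schema="newick", rooting="force-rooted")
    sd = dendropy.SplitDistribution(taxon_namespace=tl.taxon_namespace)
    lengths: dict[frozenset, list[float]] = defaultdict(list)

    def leafset(node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    for t in tl:
        t.encode_bipartitions()
        for edge in t.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue
            lengths[leafset(edge.head_node)].append(edge.length or 0.0)
        sd.count_splits_on_tree(t, is_bipartitions_updated=True)
    con = sd.consensus_tree(min_freq=0.5 + 1e-9)
    for edge in con.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        vals = lengths.get(leafset(edge.head_node))
        edge.length = float(np.mean(vals)) if vals else 0.0
    return PhyloTree(con)


def graft_trees(a: PhyloTree, b: PhyloTree, divergence_time: float) -> PhyloTree:
    """Join two ultrametric trees under a new root at ``divergence_time``.

    Each subtree keeps its internal structure; its stem gets length
    ``divergence_time - depth`` so the grafted tree is ultrametric with depth
    equal to the divergence time.
    """
    if not a.is_ultrametric or not b.is_ultrametric:
        raise ValueError("both trees must be ultrametric")
    if set(a.tip_labels) & set(b.tip_labels):
        raise ValueError("tip sets must be disjoint")
    da, db = a.depth, b.depth
    if divergence_time < max(da, db):
        raise ValueError("divergence time must be at least the deeper tree's depth")

    def subtree(t: PhyloTree, stem: float) -> str:
        nwk = t.newick()
        if nwk.startswith("[&R] ") or nwk.startswith("[&U] "):
            nwk = nwk[5:]
        nwk = nwk.rstrip().rstrip(";")
        return f"{nwk}:{stem:.10g}"

    combined = f"({subtree(a, divergence_time - da)},{subtree(b, divergence_time - db)});"
    return parse_newick(combined)


def phylo_correlation(tree: PhyloTree) -> pd.DataFrame:
    """Phylogenetic correlation matrix over tips of an ultrametric tree.

    C[i, j] is the root-to-MRCA shared path length divided by tree depth:
    diagonal 1, symmetric, positive semidefinite.  For an ultrametric tree
    this equals (depth − d(i, j)/2) / depth with d the patristic distance.
    """
    if not tree.is_ultrametric:
        raise ValueError("correlation matrix requires an ultrametric tree")
    t = tree.dendropy_tree
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda x: x.label)
    labels = [x.label for x in taxa]
    depth = tree.depth
    n = len(labels)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            C[i, j] = C[j, i] = (depth - d / 2.0) / depth
    return pd.DataFrame(C, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Bayesian phylogenetic mixed models
# ---------------------------------------------------------------------------

@dataclass
class PMMConfig:
    """MCMC settings and priors for the phylogenetic mixed models."""

    n_iter: int = 4000
    n_burnin: int = 1000
    n_chains: int = 2
    seed: int = 0
    beta_prior_sd: float = 100.0
    var_prior: tuple[float, float] = (0.01, 0.01)  # inverse-gamma (shape, scale)
    ridge: float = 1e-8

    def __post_init__(self):
        if not self.n_iter > self.n_burnin >= 0:
            raise ValueError("need n_iter > n_burnin >= 0")


@dataclass
class PhyloMixedFit:
    """Posterior draws and summaries for a phylogenetic mixed model."""

    beta_samples: np.ndarray  # columns: intercept, group contrast (δ or LOR)
    sigma2_p_samples: np.ndarray
    sigma2_e_samples: np.ndarray | None
    h_samples: np.ndarray
    summaries: dict
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    response: str = "gaussian"


def _align(y, x_group, C: pd.DataFrame):
    labels = list(C.index)
    ys = pd.Series(y).reindex(labels)
    if ys.isna().any():
        missing = list(ys.index[ys.isna()])
        raise ValueError(f"response missing for tips: {missing[:5]}")
    if x_group is None:
        X = np.ones((len(labels), 1))
    else:
        xs = pd.Series(x_group).reindex(labels)
        if xs.isna().any():
            raise ValueError("group covariate missing for some tips")
        X = np.column_stack([np.ones(len(labels)), xs.to_numpy(float)])
    return ys.to_numpy(float), X, labels


def _chol_C(C: pd.DataFrame, ridge: float):
    M = 0.5 * (C.to_numpy(float) + C.to_numpy(float).T)
    n = len(M)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        _warnings.warn(f"singular correlation matrix; adding ridge {ridge:g}")
        M = M + ridge * np.eye(n)
        L = np.linalg.cholesky(M)
    Li = np.linalg.inv(L)
    Cinv = Li.T @ Li
    return L, 0.5 * (Cinv + Cinv.T)


def _summaries(beta: np.ndarray, h: np.ndarray, contrast_name: str) -> dict:
    out = {
        "intercept_mean": float(beta[:, 0].mean()),
        "intercept_ci": tuple(np.percentile(beta[:, 0], [2.5, 97.5]).tolist()),
        "h_mean": float(h.mean()),
        "h_ci": tuple(np.percentile(h, [2.5, 97.5]).tolist()),
    }
    if beta.shape[1] > 1:
        out[f"{contrast_name}_mean"] = float(beta[:, 1].mean())
        out[f"{contrast_name}_ci"] = tuple(np.percentile(beta[:, 1], [2.5, 97.5]).tolist())
    return out


def fit_pmm_gaussian(y, x_group, C: pd.DataFrame, cfg: PMMConfig) -> PhyloMixedFit:
    """Gaussian phylogenetic mixed model by conjugate Gibbs sampling.

    Model: y = β0 + δ·x + u + e with u ~ N(0, σ²_p C), e ~ N(0, σ²_e I);
    normal prior on β, inverse-gamma priors on both variances.  Updates are
    fully conjugate: β and u from their Gaussian full conditionals, variances
    from inverse-gamma full conditionals.  h = σ²_p / (σ²_p + σ²_e).
    """
    yv, X, _ = _align(y, x_group, C)
    n, p = X.shape
    # marginalise the phylogenetic effect: y ~ N(Xβ, σ²_p C + σ²_e I).
    # In the eigenbasis of C the covariance is diagonal, so each likelihood
    # evaluation is O(n) and the sampler cannot stick at σ²_p = 0.
    evals, Q = np.linalg.eigh(0.5 * (C.to_numpy(float) + C.to_numpy(float).T))
    evals = np.clip(evals, 0.0, None)
    ystar = Q.T @ yv
    Xstar = Q.T @ X
    a0, b0 = cfg.var_prior
    tau2 = cfg.beta_prior_sd ** 2

    def logpost_var(log_s2p, log_s2e, beta):
        s2p, s2e = math.exp(log_s2p), math.exp(log_s2e)
        if not (1e-12 < s2p < 1e8 and 1e-12 < s2e < 1e8):
            return -math.inf
        v = s2p * evals + s2e
        r = ystar - Xstar @ beta
        ll = -0.5 * float(np.log(v).sum() + (r * r / v).sum())
        # inverse-gamma priors, with the log-scale Jacobian
        ll += -a0 * log_s2p - b0 / s2p
        ll += -a0 * log_s2e - b0 / s2e
        return ll

    ss = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    keep = cfg.n_iter - cfg.n_burnin
    betas = np.empty((cfg.n_chains * keep, p))
    s2ps = np.empty(cfg.n_chains * keep)
    s2es = np.empty(cfg.n_chains * keep)
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(ss[c])
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        v0 = max(float(yv.var()), 1e-6)
        ls = np.log([v0 * rng.uniform(0.2, 0.8), v0 * rng.uniform(0.2, 0.8)])
        scales = np.array([0.8, 0.8])
        acc = np.zeros(2)
        lp = logpost_var(ls[0], ls[1], beta)
        for it in range(cfg.n_iter):
            # β | variances: Gaussian (GLS) full conditional in the eigenbasis
            v = np.exp(ls[0]) * evals + np.exp(ls[1])
            Xw = Xstar / v[:, None]
            prec = Xstar.T @ Xw + np.eye(p) / tau2
            cov = np.linalg.inv(prec)
            mean = cov @ (Xw.T @ ystar)
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            lp = logpost_var(ls[0], ls[1], beta)
            # adaptive random-walk Metropolis on (log σ²_p, log σ²_e)
            for d in range(2):
                prop = ls.copy()
                prop[d] += scales[d] * rng.standard_normal()
                lp_prop = logpost_var(prop[0], prop[1], beta)
                if math.log(rng.random() + 1e-300) < lp_prop - lp:
                    ls, lp = prop, lp_prop
                    acc[d] += 1
                if it < cfg.n_burnin and (it + 1) % 50 == 0:
                    rate = acc[d] / (it + 1)
                    scales[d] *= math.exp((rate - 0.3) / math.sqrt(1 + it / 50))
                    scales[d] = min(max(scales[d], 1e-3), 5.0)
            if it >= cfg.n_burnin:
                idx = c * keep + (it - cfg.n_burnin)
                betas[idx] = beta
                s2ps[idx] = math.exp(ls[0])
                s2es[idx] = math.exp(ls[1])
    h = s2ps / (s2ps + s2es)
    summaries = _summaries(betas, h, "delta")
    summaries["sigma2_p_mean"] = float(s2ps.mean())
    summaries["sigma2_e_mean"] = float(s2es.mean())
    return PhyloMixedFit(
        beta_samples=betas, sigma2_p_samples=s2ps, sigma2_e_samples=s2es,
        h_samples=h, summaries=summaries, response="gaussian",
    )


def _ess_update(u, eta_fixed, loglik, sigma_p, L, rng):
    """One elliptical slice sampling update of the phylogenetic effect u."""
    nu = sigma_p * (L @ rng.standard_normal(len(u)))
    log_y = loglik(eta_fixed + u) + math.log(rng.random() + 1e-300)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    lo, hi = angle - 2.0 * math.pi, angle
    while True:
        u_prop = u * math.cos(angle) + nu * math.sin(angle)
        if loglik(eta_fixed + u_prop) > log_y:
            return u_prop
        if angle < 0:
            lo = angle
        else:
            hi = angle
        angle = rng.uniform(lo, hi)


def fit_pmm_binary(y, x_group, C: pd.DataFrame, cfg: PMMConfig) -> PhyloMixedFit:
    """Binary phylogenetic mixed model on the logistic liability scale.

    P(y=1) = logistic(β0 + LOR·x + u), u ~ N(0, σ²_p C); the residual is the
    standard logistic with variance π²/3 (fixed), so the group effect is a
    log odds ratio and h = σ²_p / (σ²_p + π²/3).  Sampling: elliptical slice
    updates for u, adaptive random-walk Metropolis for β, conjugate
    inverse-gamma for σ²_p.
    """
    yv, X, _ = _align(y, x_group, C)
    yv = yv.astype(int)
    if len(np.unique(yv)) == 1:
        _warnings.warn("response is constant: posterior for the contrast is prior-dominated")
    n, p = X.shape
    L, Cinv = _chol_C(C, cfg.ridge)
    a0, b0 = cfg.var_prior
    tau2 = cfg.beta_prior_sd ** 2
    sign = 2.0 * yv - 1.0

    def loglik(eta: np.ndarray) -> float:
        return float(-np.logaddexp(0.0, -sign * eta).sum())

    ss = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    keep = cfg.n_iter - cfg.n_burnin
    betas = np.empty((cfg.n_chains * keep, p))
    s2ps = np.empty(cfg.n_chains * keep)
    warn: list[str] = []
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(ss[c])
        beta = np.zeros(p)
        u = np.zeros(n)
        s2p = 1.0
        scale = 0.5
        acc = 0
        for it in range(cfg.n_iter):
            u = _ess_update(u, X @ beta, loglik, math.sqrt(s2p), L, rng)
            prop = beta + scale * rng.standard_normal(p)
            d = (
                loglik(X @ prop + u) - loglik(X @ beta + u)
                - 0.5 * (prop @ prop - beta @ beta) / tau2
            )
            if math.log(rng.random() + 1e-300) < d:
                beta = prop
                acc += 1
            if it < cfg.n_burnin and (it + 1) % 50 == 0:
                scale *= math.exp((acc / (it + 1) - 0.25) / math.sqrt(1 + it / 50))
                scale = min(max(scale, 1e-3), 5.0)
            s2p = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * u @ Cinv @ u))
            if it >= cfg.n_burnin:
                idx = c * keep + (it - cfg.n_burnin)
                betas[idx] = beta
                s2ps[idx] = s2p
    resid_var = math.pi ** 2 / 3.0
    h = s2ps / (s2ps + resid_var)
    summaries = _summaries(betas, h, "lor")
    summaries["sigma2_p_mean"] = float(s2ps.mean())
    return PhyloMixedFit(
        beta_samples=betas, sigma2_p_samples=s2ps, sigma2_e_samples=None,
        h_samples=h, summaries=summaries, warnings=warn, response="binary",
    )


def phylo_heritability(fit: PhyloMixedFit) -> tuple[float, tuple[float, float]]:
    """Posterior mean and equal-tailed 95% credible interval of h."""
    h = np.asarray(fit.h_samples)
    lo, hi = np.percentile(h, [2.5, 97.5])
    return float(h.mean()), (float(lo), float(hi))
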
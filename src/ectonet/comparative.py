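"""Across-network comparative inference.

Per network, female-male differences in each position index are summarized
as the natural log of the larger-to-smaller ratio of the sex means (so the
predictor is always >= 0).  Network structure (Z-standardized NODF / H2' by
default) is regressed on these predictors with phylogenetic generalized
least squares under a Brownian-motion covariance derived from a host tree,
fitting all subsets of the four predictors and selecting by AIC.  Role
proportions are compared between sexes with a beta mixed model (logit mean
link, constant precision, Gaussian species random intercept, marginal ML by
Laplace approximation with adaptive Gauss-Hermite cross-checking).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.special
import scipy.stats

logger = logging.getLogger(__name__)

PREDICTORS = ("dNR", "dSS", "dEC", "dDP")


# --------------------------------------------------------------------------
# sex-difference predictors

def sex_difference_predictor(mean_f: float, mean_m: float) -> float:
    """ln of the larger-to-smaller ratio of the per-sex means (>= 0)."""
    if mean_f <= 0 or mean_m <= 0:
        raise ValueError(
            f"means must be strictly positive for a log ratio, got "
            f"F={mean_f}, M={mean_m}; consider offsetting the index"
        )
    return abs(math.log(mean_m / mean_f))


# --------------------------------------------------------------------------
# phylogeny

@dataclass
class PhyloCovariance:
    """Brownian-motion covariance (shared branch lengths) over tree tips."""

    tips: list[str]
    C: np.ndarray

    def subset(self, labels: list[str]) -> np.ndarray:
        """Covariance restricted (and ordered) to ``labels``."""
        missing = [t for t in labels if t not in self.tips]
        if missing:
            raise ValueError(f"species missing from the tree: {missing}")
        idx = [self.tips.index(t) for t in labels]
        return self.C[np.ix_(idx, idx)]


def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed or duplicate-tip Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def add_sister_tip(tree: dendropy.Tree, tip_label: str, new_label: str) -> dendropy.Tree:
    """Split a tip into a unit-length cherry of the old and a new tip.

    Used for host species sampled in two regions, which enter the
    comparative data as sister species.
    """
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == tip_label:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"tip {tip_label!r} not found")
    old_taxon = leaf.taxon
    leaf.taxon = None
    child1 = leaf.new_child(edge_length=1.0)
    child1.taxon = old_taxon
    child2 = leaf.new_child(edge_length=1.0)
    tree.taxon_namespace.add_taxon(dendropy.Taxon(label=new_label))
    child2.taxon = tree.taxon_namespace.get_taxon(new_label)
    return tree


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    depths = np.asarray(depths, dtype=float)
    return bool(np.ptp(depths) <= rel_tol * max(depths.max(), 1.0))


def phylo_covariance(tree: dendropy.Tree, unit_branches: bool = False) -> PhyloCovariance:
    """Shared-branch-length covariance matrix under Brownian motion.

    ``C_ij`` is the root-to-MRCA distance of tips i and j; the diagonal
    holds root-to-tip distances.  With ``unit_branches`` every edge length
    is set to 1 first (the convention used when topology is trusted more
    than branch lengths).
    """
    tree = tree.clone(depth=1)
    if unit_branches:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    if not is_ultrametric(tree):
        logger.warning("tree is not ultrametric; Brownian covariance may be distorted")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    tips = [lf.taxon.label for lf in leaves]
    depth = np.array([lf.root_distance for lf in leaves])
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[i]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[i] + depth[j] - d)
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-9 * max(eig.max(), 1.0):
        raise ValueError("phylogenetic covariance is not positive semi-definite")
    return PhyloCovariance(tips=tips, C=C)


# --------------------------------------------------------------------------
# PGLS

@dataclass
class PGLSFit:
    names: list[str]  # coefficient names, first is intercept
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float  # ML residual variance
    loglik: float
    aic: float
    r2: float
    f_stat: float
    f_p: float
    n: int


def pgls_fit(
    y: np.ndarray, X: np.ndarray, C: np.ndarray, names: list[str] | None = None
) -> PGLSFit:
    """Generalized least squares under y ~ N(X b, sigma^2 C).

    ``X`` must include the intercept column.  sigma^2 is the ML estimate
    (RSS/n) used for the log-likelihood and AIC; coefficient standard
    errors use the unbiased RSS/(n-k) so t-tests match standard GLS
    output.  AIC counts all regression coefficients plus sigma^2.
    R^2 compares GLS residual to GLS intercept-only sums of squares, and
    the overall F tests all non-intercept slopes jointly.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, k)]
    if n <= k:
        raise ValueError(f"need n > number of coefficients ({n} <= {k})")
    try:
        Lchol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; consider jittering zero "
            "branch lengths"
        ) from exc
    yw = scipy.linalg.solve_triangular(Lchol, y, lower=True)
    Xw = scipy.linalg.solve_triangular(Lchol, X, lower=True)
    if np.linalg.matrix_rank(Xw) < k:
        raise ValueError(f"collinear design columns among {names}")
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdetC = 2.0 * np.log(np.diag(Lchol)).sum()
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetC + n)
    n_params = k + 1  # coefficients + sigma^2
    aic = -2 * loglik + 2 * n_params
    cov = np.linalg.inv(Xw.T @ Xw) * (rss / (n - k))
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * scipy.stats.t.sf(np.abs(t), df=n - k)
    # intercept-only GLS for TSS
    ones_w = scipy.linalg.solve_triangular(Lchol, np.ones(n), lower=True)
    mu = float(ones_w @ yw / (ones_w @ ones_w))
    tss = float(((yw - mu * ones_w) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if k > 1 and rss > 0:
        f_stat = ((tss - rss) / (k - 1)) / (rss / (n - k))
        f_p = float(scipy.stats.f.sf(f_stat, k - 1, n - k))
    elif k > 1:
        f_stat, f_p = float("inf"), 0.0
    else:
        f_stat, f_p = float("nan"), float("nan")
    return PGLSFit(
        names=names, beta=beta, se=se, t=t, p=p, sigma2=sigma2_ml,
        loglik=float(loglik), aic=float(aic), r2=float(r2),
        f_stat=float(f_stat), f_p=f_p, n=n,
    )


def all_subsets_pgls(
    y: np.ndarray,
    predictors: dict[str, np.ndarray],
    C: np.ndarray,
    max_k: int | None = None,
) -> tuple[PGLSFit, list[dict]]:
    """Fit all subsets of predictors (including intercept-only); rank by AIC.

    Ties are broken by fewer predictors, then lexicographically by subset
    name.  ``max_k`` caps the subset size (useful when there are few
    networks).  Returns the best fit and the full AIC-sorted ranking.
    """
    if not predictors:
        raise ValueError("need at least one candidate predictor")
    names = list(predictors)
    n = len(np.asarray(y))
    if max_k is None:
        max_k = len(names)
    ranking = []
    fits = {}
    for r in range(min(len(names), max_k) + 1):
        for subset in itertools.combinations(names, r):
            X = np.column_stack(
                [np.ones(n)] + [np.asarray(predictors[s], dtype=float) for s in subset]
            )
            fit = pgls_fit(y, X, C, names=["intercept"] + list(subset))
            key = " + ".join(subset) if subset else "(intercept)"
            fits[key] = fit
            ranking.append(
                {
                    "subset": key,
                    "k": len(subset),
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                }
            )
    ranking.sort(key=lambda row: (row["aic"], row["k"], row["subset"]))
    best_aic = ranking[0]["aic"]
    for row in ranking:
        row["delta_aic"] = row["aic"] - best_aic
    return fits[ranking[0]["subset"]], ranking


# --------------------------------------------------------------------------
# beta regression and beta GLMM on role proportions

def adjust_proportions(p: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Move exact 0s and 1s off the boundary by +-eps (beta support is open)."""
    p = np.asarray(p, dtype=float).copy()
    p[p <= 0.0] = eps
    p[p >= 1.0] = 1.0 - eps
    return p


def _beta_loglik_eta(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
    """Per-observation beta log-density with logit-mean parameterization."""
    mu = scipy.special.expit(eta)
    a = mu * phi
    b = (1 - mu) * phi
    return (
        scipy.special.gammaln(phi)
        - scipy.special.gammaln(a)
        - scipy.special.gammaln(b)
        + (a - 1) * np.log(y)
        + (b - 1) * np.log1p(-y)
    )


def _beta_deriv_eta(y, eta, phi):
    """First and second derivatives of the beta log-density wrt eta."""
    mu = scipy.special.expit(eta)
    w = mu * (1 - mu)
    tstar = np.log(y) - np.log1p(-y)
    mustar = scipy.special.digamma(mu * phi) - scipy.special.digamma((1 - mu) * phi)
    g1 = phi * (tstar - mustar) * w
    trig = scipy.special.polygamma(1, mu * phi) + scipy.special.polygamma(1, (1 - mu) * phi)
    g2 = phi * (-(phi * trig) * w**2 + (tstar - mustar) * (1 - 2 * mu) * w)
    return g1, g2


def beta_regression(
    y: np.ndarray, X: np.ndarray, maxiter: int = 500
) -> dict:
    """Fixed-effects beta regression (logit mean link, constant precision).

    Maximum likelihood via quasi-Newton; returns coefficients, Wald z/p,
    phi and the log-likelihood.
    """
    y = adjust_proportions(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape

    def nll(theta):
        beta, logphi = theta[:k], theta[k]
        return -_beta_loglik_eta(y, X @ beta, np.exp(logphi)).sum()

    # moment-based start
    mu0 = np.clip(y.mean(), 0.05, 0.95)
    var0 = max(y.var(), 1e-4)
    phi0 = max(mu0 * (1 - mu0) / var0 - 1, 1.0)
    x0 = np.concatenate([[scipy.special.logit(mu0)], np.zeros(k - 1), [np.log(phi0)]])
    res = scipy.optimize.minimize(nll, x0, method="BFGS", options={"maxiter": maxiter})
    if not res.success and res.fun > nll(x0):
        raise RuntimeError(f"beta regression did not converge: {res.message}")
    theta = res.x
    hess = _numeric_hessian(nll, theta)
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    beta = theta[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return {
        "beta": beta,
        "se": se,
        "z": z,
        "p": 2 * scipy.stats.norm.sf(np.abs(z)),
        "phi": float(np.exp(theta[k])),
        "loglik": float(-res.fun),
    }


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


_GH_NODES_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    if n_nodes not in _GH_NODES_CACHE:
        _GH_NODES_CACHE[n_nodes] = np.polynomial.hermite.hermgauss(n_nodes)
    return _GH_NODES_CACHE[n_nodes]


def _marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    phi: float,
    sigma: float,
    n_agh: int = 1,
) -> float:
    """Marginal log-likelihood of the beta GLMM, integrating the random
    intercepts by Laplace (n_agh=1) or adaptive Gauss-Hermite quadrature."""
    eta_fix = X @ beta
    G = groups.max() + 1
    b = np.zeros(G)
    # vectorized damped Newton for the per-group posterior modes
    for _ in range(100):
        eta = eta_fix + b[groups]
        g1, g2 = _beta_deriv_eta(y, eta, phi)
        grad = np.bincount(groups, weights=g1, minlength=G) - b / sigma**2
        hess = np.bincount(groups, weights=g2, minlength=G) - 1.0 / sigma**2
        hess = np.minimum(hess, -1e-8)
        step = -grad / hess
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.abs(step).max() < 1e-10:
            break
    eta = eta_fix + b[groups]
    g1, g2 = _beta_deriv_eta(y, eta, phi)
    H = -(np.bincount(groups, weights=g2, minlength=G) - 1.0 / sigma**2)
    H = np.maximum(H, 1e-8)
    ll_obs = np.bincount(
        groups, weights=_beta_loglik_eta(y, eta, phi), minlength=G
    )
    h_mode = ll_obs - b**2 / (2 * sigma**2)
    if n_agh <= 1:
        log_int = h_mode + 0.5 * np.log(2 * np.pi / H)
    else:
        nodes, weights = _gh(n_agh)
        scale = np.sqrt(2.0 / H)  # per group
        bk = b[:, None] + scale[:, None] * nodes[None, :]  # G x K
        eta_k = eta_fix[:, None] + bk[groups]  # N x K
        ll_k = np.zeros((G, len(nodes)))
        for k in range(len(nodes)):
            ll_k[:, k] = np.bincount(
                groups, weights=_beta_loglik_eta(y, eta_k[:, k], phi), minlength=G
            )
        h_k = ll_k - bk**2 / (2 * sigma**2) + nodes[None, :] ** 2
        shift = h_k.max(axis=1, keepdims=True)
        log_int = (
            np.log((weights[None, :] * np.exp(h_k - shift)).sum(axis=1))
            + shift[:, 0]
            + np.log(scale)
        )
    return float((log_int - 0.5 * np.log(2 * np.pi * sigma**2)).sum())


def beta_glmm_roles(
    proportions: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    adjust: float = 1e-7,
    n_agh: int = 1,
    sigma_floor: float = 1e-4,
) -> dict:
    """Beta mixed model for role proportions.

    ``proportions`` in [0,1] (shifted off the boundary by ``adjust``), ``X``
    the fixed design including intercept (typically intercept + sex), and
    ``groups`` integer species codes for the Gaussian random intercept.
    Marginal ML by Laplace approximation (``n_agh > 1`` switches to adaptive
    Gauss-Hermite).  If the random-intercept variance collapses to the
    boundary, the model is refit as a fixed-effects beta regression and
    flagged with ``collapsed=True``.
    """
    y = adjust_proportions(proportions, eps=adjust)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    if groups.dtype.kind not in "iu":
        _, groups = np.unique(groups, return_inverse=True)
    if groups.max() + 1 < 2:
        raise ValueError("need >=2 species for a random intercept")
    n, k = X.shape
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, k)]

    def nll(theta):
        beta, logphi, logsigma = theta[:k], theta[k], theta[k + 1]
        # soft bound on the precision keeps near-constant data from driving
        # phi to numerical infinity
        penalty = 1e3 * max(logphi - 12.0, 0.0) ** 2 + 1e3 * max(-logsigma - 12.0, 0.0) ** 2
        logphi = min(logphi, 12.0)
        try:
            return penalty - _marginal_loglik(
                y, X, groups, beta, np.exp(logphi), np.exp(logsigma), n_agh=n_agh
            )
        except FloatingPointError:
            return 1e10

    start = beta_regression(y, X)
    x0 = np.concatenate([start["beta"], [np.log(start["phi"])], [np.log(0.3)]])
    res = scipy.optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    theta = res.x
    sigma_hat = float(np.exp(theta[k + 1]))
    if sigma_hat < sigma_floor:
        logger.warning(
            "random-intercept variance collapsed (sigma=%.2g); reporting the "
            "fixed-effects beta regression", sigma_hat,
        )
        fe = beta_regression(y, X)
        return {
            "names": names, "beta": fe["beta"], "se": fe["se"], "z": fe["z"],
            "p": fe["p"], "phi": fe["phi"], "sigma_b": 0.0,
            "loglik": fe["loglik"], "collapsed": True,
        }
    if not res.success:
        raise RuntimeError(
            f"beta GLMM did not converge: {res.message} (nfev={res.nfev})"
        )
    hess = _numeric_hessian(nll, theta, h=1e-3)
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    beta = theta[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return {
        "names": names,
        "beta": beta,
        "se": se,
        "z": z,
        "p": 2 * scipy.stats.norm.sf(np.abs(z)),
        "phi": float(np.exp(theta[k])),
        "sigma_b": sigma_hat,
        "loglik": float(-res.fun),
        "collapsed": False,
    }
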
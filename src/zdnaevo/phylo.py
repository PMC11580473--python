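"""Phylogenetic comparative machinery, implemented from first principles.

Continuous traits are modelled as multivariate normal with a covariance
structure induced by a trait-evolution model on a rooted tree with branch
lengths: Brownian motion (BM), the fixed-root Ornstein-Uhlenbeck process
(OU, attraction strength alpha), early burst (EB, rate decaying as
exp(r t), r <= 0), and Pagel's lambda (off-diagonal shared history scaled
by lambda in [0, 1]).  On top of these sit profile-likelihood model fitting
with AICc selection, ML ancestral-state reconstruction under BM,
phylogenetic generalized least squares (PGLS) with a parametric bootstrap,
allometric trait adjustment, and the correlated/uncorrelated call rule
(slope p < 0.05 and adjusted R^2 > 0.1).

All likelihoods are exact dense multivariate-normal likelihoods evaluated
via Cholesky factorization; location (root state / regression
coefficients) and scale (sigma^2) are profiled analytically, leaving at
most one scalar shape parameter to a bounded multi-start search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import DataError

__all__ = [
    "Phylogeny",
    "EvoModelFit",
    "PglsResult",
    "bm_covariance",
    "model_covariance",
    "fit_continuous",
    "select_model",
    "ancestral_states_bm",
    "pgls_fit",
    "pgls_bootstrap",
    "correlation_call",
    "adjust_trait",
    "prune_to_common",
]

ULTRAMETRIC_TOL = 1e-6

# scalar shape-parameter bounds, relative to tree height T where noted
LAMBDA_BOUNDS = (0.0, 1.0)
ALPHA_BOUNDS_OVER_T = (1e-8, 50.0)      # alpha in (1e-8/T, 50/T]
EB_LOG_FLOOR = math.log(1e-5)           # r in [ln(1e-5)/T, 0]
N_STARTS = 5


class Phylogeny:
    """A rooted tree with branch lengths plus cached depth/covariance data.

    Wraps a :class:`dendropy.Tree`; all comparative computations read the
    cached tip depths, MRCA-depth matrix and patristic distances rather
    than re-traversing the tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = list(tree.leaf_node_iter())
        labels = [t.taxon.label if t.taxon else "" for t in tips]
        if len(set(labels)) != len(labels) or "" in labels:
            raise DataError("tip labels must be unique and non-empty")
        self.tip_labels: list[str] = labels
        self.n = len(labels)

        # node depths (root-to-node path lengths)
        depth: dict = {}
        for node in tree.preorder_node_iter():
            elen = node.edge.length
            if elen is None:
                elen = 0.0
            if elen < 0:
                raise DataError("negative branch length")
            depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + elen
        self._node_depth = depth
        self.depths = np.array([depth[t] for t in tips])
        self.height = float(self.depths.max()) if self.n else 0.0

        # MRCA depth matrix via postorder tip-set merging
        idx = {t: i for i, t in enumerate(tips)}
        C = np.zeros((self.n, self.n))
        below: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = [idx[node]]
                continue
            groups = [below.pop(c) for c in node.child_nodes()]
            d = depth[node]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    ii = np.asarray(groups[gi])
                    jj = np.asarray(groups[gj])
                    C[np.ix_(ii, jj)] = d
                    C[np.ix_(jj, ii)] = d
            merged: list[int] = []
            for g in groups:
                merged.extend(g)
            below[node] = merged
        np.fill_diagonal(C, self.depths)
        self.mrca_depth = C
        self.tip_dist = self.depths[:, None] + self.depths[None, :] - 2 * C

        # internal nodes: stable ids and node-to-tip distances
        self._internal_nodes = [nd for nd in tree.preorder_node_iter()
                                if not nd.is_leaf()]
        self.internal_ids: list[str] = []
        for i, nd in enumerate(self._internal_nodes):
            lab = nd.label or ("root" if nd.parent_node is None else f"N{i}")
            self.internal_ids.append(lab)

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Parse a newick tree from a path or a newick string."""
        text = None
        p = Path(str(source))
        try:
            if p.exists():
                text = p.read_text()
        except OSError:
            pass
        if text is None:
            text = str(source)
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     rooting="default-rooted")
        except Exception as exc:  # dendropy raises schema-specific errors
            raise DataError(f"invalid newick: {exc}") from None
        return cls(tree)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        if self.height == 0:
            return True
        return bool(np.ptp(self.depths) / self.height <= tol)

    def internal_node_tip_distances(self) -> np.ndarray:
        """(n_internal x n_tips) matrix of patristic node-to-tip distances."""
        tips = list(self._tree.leaf_node_iter())
        tip_index = {t: i for i, t in enumerate(tips)}
        out = np.zeros((len(self._internal_nodes), self.n))
        for r, node in enumerate(self._internal_nodes):
            # undirected BFS from node
            dist = {node: 0.0}
            stack = [node]
            while stack:
                cur = stack.pop()
                dcur = dist[cur]
                nbrs = list(cur.child_nodes())
                if cur.parent_node is not None:
                    nbrs.append(cur.parent_node)
                for nb in nbrs:
                    if nb in dist:
                        continue
                    edge = cur.edge.length if nb is cur.parent_node else nb.edge.length
                    dist[nb] = dcur + (edge or 0.0)
                    stack.append(nb)
            for t, i in tip_index.items():
                out[r, i] = dist[t]
        return out


def _align(tree: Phylogeny, x: Mapping[str, float] | pd.Series | Sequence[float]
           ) -> np.ndarray:
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, Mapping):
        missing = [t for t in tree.tip_labels if t not in x]
        if missing:
            raise DataError(f"trait values missing for tips: {missing[:5]}")
        return np.array([float(x[t]) for t in tree.tip_labels])
    arr = np.asarray(x, dtype=float)
    if arr.shape != (tree.n,):
        raise DataError(f"expected {tree.n} values, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Covariance structures
# ---------------------------------------------------------------------------

def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """BM covariance: C_ij = depth of MRCA(i, j), C_ii = depth of tip i."""
    return tree.mrca_depth.copy()


def model_covariance(tree: Phylogeny, model: str,
                     shape_param: float | None = None) -> np.ndarray:
    """Unit-rate covariance matrix for a trait-evolution model.

    ``sigma^2`` scaling is applied at likelihood time, not here.  OU and EB
    require an ultrametric tree (fixed-root OU; EB integrates the decaying
    rate along shared history).
    """
    C = tree.mrca_depth
    if model == "BM":
        return C.copy()
    if model == "lambda":
        lam = shape_param
        if lam is None or not (0.0 <= lam <= 1.0):
            raise DataError(f"lambda must be in [0, 1], got {shape_param}")
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
        return V
    if model in ("OU", "EB") and not tree.is_ultrametric():
        raise DataError(f"{model} covariance requires an ultrametric tree")
    if model == "OU":
        alpha = shape_param
        if alpha is None or alpha <= 0:
            raise DataError(f"alpha must be > 0, got {shape_param}")
        t = tree.depths
        ta = C
        return (1.0 / (2 * alpha)
                * np.exp(-alpha * (t[:, None] + t[None, :] - 2 * ta))
                * (1.0 - np.exp(-2 * alpha * ta)))
    if model == "EB":
        r = shape_param
        if r is None or r > 0:
            raise DataError(f"EB rate r must be <= 0, got {shape_param}")
        if r == 0:
            return C.copy()
        return (np.exp(r * C) - 1.0) / r
    raise DataError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _profiled_mean_loglik(V: np.ndarray, x: np.ndarray
                          ) -> tuple[float, float, float]:
    """Profile mu and sigma^2 out of the MVN likelihood.

    Returns (mu_hat, sigma2_hat_ML, logLik at the profiled optimum).
    Raises np.linalg.LinAlgError if V is not positive definite.
    """
    n = x.size
    L = np.linalg.cholesky(V)
    ones_t = linalg.solve_triangular(L, np.ones(n), lower=True)
    x_t = linalg.solve_triangular(L, x, lower=True)
    mu = float(ones_t @ x_t / (ones_t @ ones_t))
    resid = x_t - mu * ones_t
    sigma2 = float(resid @ resid / n)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return mu, max(sigma2, 0.0), math.inf
    loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2)
                     + logdet + n)
    return mu, sigma2, loglik


def _shape_bounds(model: str, height: float) -> tuple[float, float] | None:
    if model == "BM":
        return None
    if model == "lambda":
        return LAMBDA_BOUNDS
    if model == "OU":
        return (ALPHA_BOUNDS_OVER_T[0] / height, ALPHA_BOUNDS_OVER_T[1] / height)
    if model == "EB":
        return (EB_LOG_FLOOR / height, 0.0)
    raise DataError(f"unknown model {model!r}")


def _maximize_scalar(f, lo: float, hi: float, n_starts: int = N_STARTS
                     ) -> tuple[float, float]:
    """Maximize f on [lo, hi] by bounded local searches from a grid.

    Returns (argmax, max).  Endpoints are always evaluated, so boundary
    optima (e.g. lambda-hat = 1) are found exactly.
    """
    best_x, best_v = lo, f(lo)
    for x in (hi,):
        v = f(x)
        if v > best_v:
            best_x, best_v = x, v
    edges = np.linspace(lo, hi, n_starts + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            lambda t: -f(t), bounds=(a, b), method="bounded",
            options={"xatol": 1e-8 * max(1.0, abs(hi - lo))})
        if -res.fun > best_v:
            best_x, best_v = float(res.x), float(-res.fun)
    return best_x, best_v


@dataclass(frozen=True)
class EvoModelFit:
    """Maximum-likelihood fit of one trait-evolution model."""

    model: str
    sigma2: float
    root_state: float
    shape_param: float | None
    logLik: float
    k_params: int
    AICc: float
    n: int
    degenerate: bool = False
    data_key: tuple = field(default=(), repr=False, compare=False)


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_continuous(tree: Phylogeny,
                   x: Mapping[str, float] | pd.Series | Sequence[float],
                   model: str) -> EvoModelFit:
    """Fit a single trait-evolution model by maximum likelihood.

    The root state mu and rate sigma^2 are profiled analytically; the
    scalar shape parameter (lambda, alpha or r) is optimized by a bounded
    multi-start search.  A constant trait vector produces a flagged
    degenerate fit (sigma^2 = 0, unbounded likelihood) rather than an
    exception.
    """
    arr = _align(tree, x)
    k = 2 if model == "BM" else 3
    # BM has a closed form from 2 tips up; shape-parameter models need one
    # more observation (AICc degenerates to +inf until n > k + 1)
    min_n = 2 if model == "BM" else 3
    if tree.n < min_n:
        raise DataError(f"{model} fit needs n >= {min_n} tips")
    data_key = (tuple(tree.tip_labels), tuple(np.round(arr, 12)))
    if np.ptp(arr) == 0:
        return EvoModelFit(model=model, sigma2=0.0, root_state=float(arr[0]),
                           shape_param=None, logLik=math.inf, k_params=k,
                           AICc=float("nan"), n=tree.n, degenerate=True,
                           data_key=data_key)
    bounds = _shape_bounds(model, tree.height)
    if model in ("OU", "EB") and not tree.is_ultrametric():
        raise DataError(f"{model} fit requires an ultrametric tree")

    def loglik_at(theta: float | None) -> tuple[float, float, float]:
        V = model_covariance(tree, model, theta)
        try:
            return _profiled_mean_loglik(V, arr)
        except np.linalg.LinAlgError:
            raise DataError(f"singular covariance for {model} "
                            f"(shape={theta})") from None

    if bounds is None:
        theta = None
        mu, sigma2, ll = loglik_at(None)
    else:
        def f(t: float) -> float:
            try:
                return loglik_at(t)[2]
            except DataError:
                return -math.inf
        theta, ll = _maximize_scalar(f, bounds[0], bounds[1])
        mu, sigma2, ll = loglik_at(theta)
    if not np.isfinite(ll):
        return EvoModelFit(model=model, sigma2=sigma2, root_state=mu,
                           shape_param=theta, logLik=math.inf, k_params=k,
                           AICc=float("nan"), n=tree.n, degenerate=True,
                           data_key=data_key)
    return EvoModelFit(model=model, sigma2=sigma2, root_state=mu,
                       shape_param=theta, logLik=ll, k_params=k,
                       AICc=_aicc(ll, k, tree.n), n=tree.n,
                       data_key=data_key)


def select_model(fits: Sequence[EvoModelFit], tol: float = 1e-6) -> EvoModelFit:
    """Minimum-AICc fit; ties (dAICc < tol) go to the fewer-parameter model."""
    if len(fits) < 2:
        raise DataError("need at least two fits to select among")
    keys = {f.data_key for f in fits}
    if len(keys) != 1:
        raise DataError("fits were computed on different data")
    if any(f.degenerate for f in fits):
        raise DataError("cannot select among degenerate fits")
    best = min(fits, key=lambda f: (f.AICc, f.k_params))
    contenders = [f for f in fits if f.AICc - best.AICc < tol]
    return min(contenders, key=lambda f: (f.k_params, f.AICc))


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------

def ancestral_states_bm(tree: Phylogeny,
                        x: Mapping[str, float] | pd.Series | Sequence[float]
                        ) -> pd.Series:
    """ML ancestral states under BM at every internal node.

    The estimate at node v is the BM root-state MLE of the tree re-rooted
    at v: with C_v the tip covariance of the re-rooted tree,
    a_v = (1' C_v^-1 x) / (1' C_v^-1 1).  C_v is assembled from patristic
    distances: (C_v)_ij = (d(v,i) + d(v,j) - d(i,j)) / 2.
    """
    arr = _align(tree, x)
    D = tree.tip_dist
    node_tip = tree.internal_node_tip_distances()
    ones = np.ones(tree.n)
    out = {}
    for node_id, dv in zip(tree.internal_ids, node_tip):
        Cv = 0.5 * (dv[:, None] + dv[None, :] - D)
        np.fill_diagonal(Cv, dv)
        try:
            cf = linalg.cho_factor(Cv)
            w = linalg.cho_solve(cf, ones)
        except np.linalg.LinAlgError:
            raise DataError(f"singular re-rooted covariance at node "
                            f"{node_id} (zero-length internal branch?)") from None
        out[node_id] = float(w @ arr / (w @ ones))
    return pd.Series(out, name="ancestral_state")


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PglsResult:
    """A phylogenetic regression fit, reported on the selected model."""

    model: str
    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray
    r2: float
    adj_r2: float
    shape_param: float | None
    sigma2_ml: float
    logLik: float
    AICc: float
    n: int
    n_predictors: int
    correlation_call: bool
    bootstrap: dict | None = None


def _gls_profile(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    """GLS under covariance V: returns (beta, RSS, RSS0, XtX_inv, logdet)."""
    n = y.size
    L = np.linalg.cholesky(V)
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < X.shape[1]:
        raise DataError("rank-deficient design matrix")
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    ones_t = linalg.solve_triangular(L, np.ones(n), lower=True)
    c0 = float(ones_t @ yt / (ones_t @ ones_t))
    r0 = yt - c0 * ones_t
    rss0 = float(r0 @ r0)
    XtX_inv = np.linalg.inv(Xt.T @ Xt)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, rss0, XtX_inv, logdet


PGLS_MODELS = ("BM", "OU", "lambda")


def pgls_fit(tree: Phylogeny,
             y: Mapping[str, float] | pd.Series | Sequence[float],
             X: np.ndarray | pd.DataFrame,
             model: str | Sequence[str] = PGLS_MODELS,
             fixed_shape: float | None = None) -> PglsResult:
    """Phylogenetic generalized least squares with AICc model selection.

    ``X`` must include an intercept column (first column).  When ``model``
    lists several covariance structures, each is fitted by profile
    likelihood over its shape parameter and the minimum-AICc structure is
    reported.  Standard errors use the unbiased residual variance
    RSS/(n - p - 1); the log-likelihood and AICc use the ML divisor n.
    R^2 compares the full model with the GLS intercept-only model at the
    same shape parameter.
    """
    yv = _align(tree, y)
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim != 2 or Xm.shape[0] != tree.n:
        raise DataError(f"X must be (n, q) with n = {tree.n}")
    q = Xm.shape[1]
    p = q - 1
    n = tree.n
    if not np.allclose(Xm[:, 0], 1.0):
        raise DataError("X must include an intercept as its first column")
    if np.linalg.matrix_rank(Xm) < q:
        raise DataError("rank-deficient design matrix")
    if n <= p + 2:
        raise DataError(f"too few species: n = {n} <= p + 2 = {p + 2}")
    models = (model,) if isinstance(model, str) else tuple(model)
    for m in models:
        if m not in PGLS_MODELS:
            raise DataError(f"unsupported PGLS model {m!r}; choose from "
                            + ", ".join(PGLS_MODELS))
    if fixed_shape is not None and (len(models) != 1 or models[0] == "BM"):
        raise DataError("fixed_shape requires a single non-BM model")

    def fit_one(m: str):
        bounds = _shape_bounds(m, tree.height)

        def ll_at(theta):
            V = model_covariance(tree, m, theta)
            beta, rss, rss0, XtX_inv, logdet = _gls_profile(V, yv, Xm)
            sigma2 = rss / n
            if sigma2 <= 0:
                return None
            ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2)
                         + logdet + n)
            return ll, theta, beta, rss, rss0, XtX_inv

        if bounds is None or fixed_shape is not None:
            res = ll_at(fixed_shape)
            if res is None:
                raise DataError("degenerate response (zero GLS residual variance)")
            return res

        def f(t):
            try:
                r = ll_at(t)
            except np.linalg.LinAlgError:
                return -math.inf
            return -math.inf if r is None else r[0]

        theta, _ = _maximize_scalar(f, bounds[0], bounds[1])
        res = ll_at(theta)
        if res is None:
            raise DataError("degenerate response (zero GLS residual variance)")
        return res

    results = {}
    for m in models:
        ll, theta, beta, rss, rss0, XtX_inv = fit_one(m)
        k = q + 1 + (0 if m == "BM" else 1)
        results[m] = (ll, _aicc(ll, k, n), theta, beta, rss, rss0, XtX_inv, k)

    best_m = min(results, key=lambda m: (results[m][1], results[m][7]))
    ll, aicc, theta, beta, rss, rss0, XtX_inv, k = results[best_m]

    dof = n - p - 1
    sigma2_e = rss / dof
    se = np.sqrt(sigma2_e * np.diag(XtX_inv))
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    call = correlation_call(float(pvals[1]), adj_r2) if q >= 2 else False
    return PglsResult(model=best_m, coef=beta, se=se, tstat=tstat,
                      pvalues=pvals, r2=r2, adj_r2=adj_r2, shape_param=theta,
                      sigma2_ml=rss / n, logLik=ll, AICc=aicc, n=n,
                      n_predictors=p, correlation_call=call)


def pgls_bootstrap(fit: PglsResult, tree: Phylogeny,
                   y: Mapping[str, float] | pd.Series | Sequence[float],
                   X: np.ndarray | pd.DataFrame,
                   B: int = 1000, seed: int = 0,
                   coef_index: int = 1) -> dict:
    """Parametric bootstrap of a PGLS slope.

    Simulates B response vectors from the fitted model (X beta-hat +
    MVN(0, sigma2_ML V(theta-hat))), refits the same covariance structure
    to each, and reports the replicate slopes with their 2.5/50/97.5%
    quantiles.  Fully reproducible from ``seed``.
    """
    if B < 2:
        raise DataError("B must be >= 2")
    Xm = np.asarray(X, dtype=float)
    V = model_covariance(tree, fit.model, fit.shape_param)
    L = np.linalg.cholesky(fit.sigma2_ml * V)
    mean = Xm @ fit.coef
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        ystar = mean + L @ rng.standard_normal(tree.n)
        refit = pgls_fit(tree, ystar, Xm, model=fit.model)
        reps[b] = refit.coef[coef_index]
    qs = np.quantile(reps, [0.025, 0.5, 0.975])
    return {"replicates": reps, "quantiles": {"2.5%": float(qs[0]),
                                              "50%": float(qs[1]),
                                              "97.5%": float(qs[2])},
            "seed": seed, "B": B, "coef_index": coef_index}


def correlation_call(p_slope: float, adj_r2: float) -> bool:
    """True iff the slope p-value is < 0.05 and adjusted R^2 > 0.1."""
    if not (np.isfinite(p_slope) and np.isfinite(adj_r2)):
        raise DataError("correlation_call requires finite inputs")
    return bool(p_slope < 0.05 and adj_r2 > 0.1)


# ---------------------------------------------------------------------------
# Trait plumbing
# ---------------------------------------------------------------------------

def adjust_trait(duration: Sequence[float], mass: Sequence[float]) -> np.ndarray:
    """Mass-adjusted duration: residuals of OLS log10(duration) ~ log10(mass).

    Standard allometric adjustment; both inputs must be strictly positive
    and aligned by species.
    """
    d = np.asarray(duration, dtype=float)
    m = np.asarray(mass, dtype=float)
    if d.shape != m.shape or d.ndim != 1:
        raise DataError("duration and mass must be aligned 1-D vectors")
    if (d <= 0).any() or (m <= 0).any():
        raise DataError("durations and masses must be strictly positive")
    ld, lm = np.log10(d), np.log10(m)
    Xm = np.column_stack([np.ones_like(lm), lm])
    beta, *_ = np.linalg.lstsq(Xm, ld, rcond=None)
    return ld - Xm @ beta


def prune_to_common(tree: Phylogeny, table: pd.DataFrame,
                    columns: Sequence[str] | None = None
                    ) -> tuple[Phylogeny, pd.DataFrame]:
    """Restrict tree and trait table to species with complete data.

    ``table`` must be indexed by species label (or carry a ``species``
    column).  Rows with missing values in ``columns`` (default: all
    columns) are dropped; the tree is pruned to the survivors with
    degree-2 nodes merged and branch lengths summed, and the table is
    reordered to tip order.
    """
    tbl = table.copy()
    if "species" in tbl.columns:
        tbl = tbl.set_index("species")
    if tbl.index.duplicated().any():
        dupes = sorted(set(tbl.index[tbl.index.duplicated()]))
        raise DataError(f"duplicate species rows: {dupes}")
    cols = list(columns) if columns is not None else list(tbl.columns)
    complete = tbl.dropna(subset=cols)
    shared = [t for t in tree.tip_labels if t in set(complete.index)]
    if len(shared) < 3:
        raise DataError(f"fewer than 3 shared species with complete data "
                        f"({len(shared)})")
    if len(shared) == tree.n:
        return tree, tbl.loc[tree.tip_labels]
    pruned = tree.dendropy_tree.extract_tree_with_taxa_labels(shared)
    ptree = Phylogeny(pruned)
    return ptree, tbl.loc[ptree.tip_labels]
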
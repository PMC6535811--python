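"""Phylogenetic comparative methods for continuous traits.

Covers the continuous-trait side of the analysis: Brownian-motion (BM)
ancestral state reconstruction with confidence intervals, the two
standard phylogenetic-signal statistics (Pagel's lambda by maximum
likelihood with a likelihood-ratio test, Blomberg's K with a permutation
test), Felsenstein's phylogenetically independent contrasts (PIC) with
through-origin regression, and detection of shifts in the optimum of an
Ornstein--Uhlenbeck (OU) process by forward selection over branches
scored with BIC.

All methods work on rooted trees with branch lengths; tip values are
supplied as :class:`~paleowgd.phylo_io.TraitVector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from ._treeutil import ensure_node_labels, leaf_label, node_depths, vcv_matrix
from .phylo_io import TraitVector

__all__ = [
    "SignalEstimate",
    "ContrastSet",
    "PICRegression",
    "OUShiftFit",
    "asr_bm",
    "pagel_lambda",
    "blomberg_k",
    "pic",
    "pic_correlation",
    "ou_shift_scan",
]


@dataclass
class SignalEstimate:
    """A phylogenetic-signal statistic with its significance test."""

    statistic: str  # "lambda" | "K"
    estimate: float
    p_value: float
    n_species: int
    logL: float | None = None  # lambda only
    n_permutations: int | None = None  # K only


@dataclass
class ContrastSet:
    """Standardized independent contrasts, one per internal node."""

    node_ids: list[str]
    contrasts: np.ndarray
    variances: np.ndarray  # sum of adjusted child branch lengths per contrast

    def __len__(self) -> int:
        return len(self.contrasts)


@dataclass
class PICRegression:
    """Through-origin regression of y-contrasts on x-contrasts."""

    slope: float
    F: float
    p_value: float
    n_contrasts: int
    df_resid: int


@dataclass
class OUShiftFit:
    """Selected OU optimum-shift configuration."""

    shift_edges: list[str]  # edges named by their child node
    shift_effects: dict[str, float]  # edge -> change in optimum
    base_optimum: float
    alpha: float
    sigma2: float
    bic: float
    n_shifts: int


# ---------------------------------------------------------------------------
# shared helpers


def _aligned(tree, trait: TraitVector) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels, C = vcv_matrix(tree)
    missing = [lb for lb in labels if lb not in trait.values]
    if missing:
        raise ValueError(f"trait missing for tips {missing[:5]}")
    x = np.array([trait.values[lb] for lb in labels], dtype=float)
    return labels, C, x


def _gls_mean(Cinv: np.ndarray, x: np.ndarray) -> float:
    one = np.ones(len(x))
    return float(one @ Cinv @ x / (one @ Cinv @ one))


# ---------------------------------------------------------------------------
# BM ancestral state reconstruction


def asr_bm(tree, trait: TraitVector) -> tuple[pd.DataFrame, float]:
    """GLS ancestral estimates under Brownian motion, with 95% CIs.

    The root estimate is the phylogenetic (GLS) mean; every internal
    node's estimate is the best linear unbiased prediction given the tips,
    and its CI is estimate +/- 1.96 * SE from the conditional variance
    (which includes the uncertainty of the phylogenetic mean). The BM rate
    sigma2 is the ML estimate. Returns (table indexed by node label with
    columns estimate/lower/upper/variance, sigma2_hat).
    """
    ensure_node_labels(tree)
    labels, C, x = _aligned(tree, trait)
    if np.max(np.diag(C)) <= 0:
        raise ValueError("tree has zero total depth")
    n = len(x)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Cinv @ one
    mu = _gls_mean(Cinv, x)
    resid = x - mu
    sigma2 = float(resid @ Cinv @ resid / n)
    depths = node_depths(tree)
    index = {lb: i for i, lb in enumerate(labels)}

    rows, names = [], []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        c = np.zeros(n)
        inside = {index[leaf_label(lf)] for lf in node.leaf_iter()}
        for i in inside:
            c[i] = depths[node]
        anc = node
        seen = set(inside)
        while anc.parent_node is not None:
            anc = anc.parent_node
            tips_a = {index[leaf_label(lf)] for lf in anc.leaf_iter()}
            for i in tips_a - seen:
                c[i] = depths[anc]
            seen |= tips_a
        w = Cinv @ c
        est = mu + float(w @ resid)
        var = sigma2 * (
            depths[node] - float(c @ w) + (1.0 - float(one @ w)) ** 2 / denom
        )
        var = max(var, 0.0)
        se = np.sqrt(var)
        rows.append((est, est - 1.96 * se, est + 1.96 * se, var))
        names.append(node.label)
    df = pd.DataFrame(
        rows, index=names, columns=["estimate", "lower", "upper", "variance"]
    )
    return df, sigma2


# ---------------------------------------------------------------------------
# Pagel's lambda


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _bm_profile_loglik(C: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    Cinv = np.linalg.inv(C)
    mu = _gls_mean(Cinv, x)
    r = x - mu
    q = float(r @ Cinv @ r)
    if q <= 0:
        return np.inf  # degenerate (constant) data
    sigma2 = q / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(tree, trait: TraitVector) -> SignalEstimate:
    """ML estimate of Pagel's lambda with a LRT against lambda = 0.

    lambda multiplies the off-diagonal entries of the BM covariance;
    lambda = 0 erases phylogenetic covariance (star tree), lambda = 1 is
    plain BM. The upper bound keeps the transformed covariance positive
    definite. p is from chi-square(1) on 2*(logL(lambda_hat) - logL(0)).
    """
    labels, C, x = _aligned(tree, trait)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 tips")
    off = C - np.diag(np.diag(C))
    offmax = off.max(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.where(offmax > 0, np.diag(C) / np.maximum(offmax, 1e-300), np.inf)
    lam_max = float(min(ratios.min(), 10.0))
    if not np.isfinite(lam_max):  # star tree: no phylogenetic covariance at all
        return SignalEstimate(
            "lambda", 0.0, 1.0, n, logL=_bm_profile_loglik(np.diag(np.diag(C)), x)
        )

    def nll(lam):
        ll = _bm_profile_loglik(_lambda_transform(C, lam), x)
        return -ll if np.isfinite(ll) else 1e12

    res = scipy.optimize.minimize_scalar(
        nll, bounds=(0.0, lam_max), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(nll(0.0), 0.0), (res.fun, float(res.x)), (nll(lam_max), lam_max)]
    best_nll, lam_hat = min(candidates, key=lambda c: c[0])
    ll0 = -candidates[0][0]
    ll_hat = -best_nll
    if ll_hat - ll0 < 1e-8:  # flat likelihood: report the boundary at 0
        lam_hat, ll_hat = 0.0, ll0
    lr = max(0.0, 2 * (ll_hat - ll0))
    p = float(scipy.stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return SignalEstimate("lambda", lam_hat, p, n, logL=ll_hat)


# ---------------------------------------------------------------------------
# Blomberg's K


def blomberg_k(
    tree, trait: TraitVector, n_perm: int = 999, seed: int = 0
) -> SignalEstimate:
    """Blomberg's K with a one-tailed tip-permutation test.

    K is the ratio (MSE0/MSE) of the variance of tip deviations around the
    phylogenetic mean to the phylogenetically corrected mean square,
    standardized by its BM expectation from the covariance trace, so that
    E[K] = 1 under BM. p is the fraction of tip-label permutations whose
    MSE0/MSE reaches the observed value, with the +1 correction.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    labels, C, x = _aligned(tree, trait)
    n = len(x)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = float(one @ Cinv @ one)
    w = Cinv @ one / denom  # GLS-mean weights

    def ratio(cols: np.ndarray) -> np.ndarray:
        # cols: (n, B) matrix of trait columns
        a = w @ cols
        d = cols - a
        mse0 = np.sum(d * d, axis=0) / (n - 1)
        mse = np.einsum("ib,ij,jb->b", d, Cinv, d) / (n - 1)
        return mse0 / mse

    obs = float(ratio(x[:, None])[0])
    expected = (np.trace(C) - n / denom) / (n - 1)
    K = obs / expected
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = x[rng.permutation(n)]
    r = ratio(perms)
    p = (1 + int(np.sum(r >= obs))) / (n_perm + 1)
    return SignalEstimate("K", float(K), float(p), n, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts


def pic(tree, trait: TraitVector) -> ContrastSet:
    """Felsenstein's standardized independent contrasts.

    Requires a binary tree with positive branch lengths (resolve
    polytomies to zero-length edges first — but note zero-length sibling
    pairs make the contrast variance vanish). Under BM the contrasts are
    i.i.d. N(0, sigma2).
    """
    ensure_node_labels(tree)
    node_ids: list[str] = []
    contrasts: list[float] = []
    variances: list[float] = []
    vals: dict[int, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lb = leaf_label(node)
            if lb not in trait.values:
                raise ValueError(f"trait missing for tip {lb!r}")
            vals[id(node)] = (float(trait.values[lb]), node.edge.length or 0.0)
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError(
                f"node {node.label!r} is a polytomy; resolve polytomies to "
                "zero-length bifurcations before computing contrasts"
            )
        (x1, v1), (x2, v2) = vals[id(kids[0])], vals[id(kids[1])]
        vsum = v1 + v2
        if vsum <= 0:
            raise ValueError(f"zero contrast variance at node {node.label!r}")
        contrasts.append((x1 - x2) / np.sqrt(vsum))
        variances.append(vsum)
        node_ids.append(node.label)
        xa = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 else (
            x2 if v1 == 0 else x1
        )
        va = (node.edge.length or 0.0) + v1 * v2 / vsum
        vals[id(node)] = (xa, va)
    return ContrastSet(node_ids, np.array(contrasts), np.array(variances))


def pic_correlation(
    tree,
    trait_x: TraitVector,
    trait_y: TraitVector,
    log_x: bool = False,
    log_y: bool = False,
) -> PICRegression:
    """Correlation of two traits by through-origin regression of contrasts.

    Each trait may first be log10-transformed (requires positive values).
    The F statistic tests slope = 0 with (1, n-2) degrees of freedom where
    n is the number of contrasts; the p-value is two-sided.
    """
    def transform(t: TraitVector, flag: bool) -> TraitVector:
        if not flag:
            return t
        if min(t.values.values()) <= 0:
            raise ValueError("log transform requires positive trait values")
        return TraitVector(
            {k: float(np.log10(v)) for k, v in t.values.items()}, kind=t.kind
        )

    cx = pic(tree, transform(trait_x, log_x))
    cy = pic(tree, transform(trait_y, log_y))
    u, v = cx.contrasts, cy.contrasts
    n = len(u)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    suu = float(u @ u)
    slope = float(u @ v) / suu
    sse = float(v @ v) - slope**2 * suu
    df = n - 2
    se2 = sse / df / suu
    F = slope**2 / se2 if se2 > 0 else np.inf
    p = float(scipy.stats.f.sf(F, 1, df))
    return PICRegression(slope=slope, F=float(F), p_value=p, n_contrasts=n, df_resid=df)


# ---------------------------------------------------------------------------
# OU shift scan


def _ou_covariance(C: np.ndarray, T: float, alpha: float) -> np.ndarray:
    # C holds shared times t_ij; fixed-root OU covariance with sigma2 = 1
    return np.exp(-2 * alpha * (T - C)) * (1 - np.exp(-2 * alpha * C)) / (2 * alpha)


def ou_shift_scan(
    tree,
    trait: TraitVector,
    alpha_grid: np.ndarray | None = None,
    max_shifts: int = 10,
    criterion: str = "bic",
) -> OUShiftFit:
    """Detect shifts in the optimum of an OU process, no locations assumed.

    For each candidate pull strength alpha, tip values are whitened by the
    OU covariance; a shift on an edge then contributes a known mean offset
    to every descendant tip, so shift placement reduces to variable
    selection over edge-indicator predictors. Shifts are added by forward
    selection (largest residual-sum-of-squares drop) and pruned backward;
    the configuration minimizing BIC across the alpha grid wins. The BIC
    parameter count is 2 * n_shifts + 3 (locations, optima, alpha,
    sigma2). Deterministic; ties keep fewer shifts.

    Requires an ultrametric tree (tip depths are rescaled to their mean
    when within 0.1% relative tolerance).
    """
    if criterion != "bic":
        raise ValueError("only the BIC criterion is implemented")
    ensure_node_labels(tree)
    labels, C, x = _aligned(tree, trait)
    n = len(x)
    if not 0 <= max_shifts < n:
        raise ValueError("need 0 <= max_shifts < n_tips")
    depths = np.diag(C)
    T = float(depths.mean())
    if np.max(np.abs(depths - T)) > 1e-3 * max(T, 1e-12):
        raise ValueError("tree is not ultrametric")
    if alpha_grid is None:
        alpha_grid = np.logspace(np.log10(0.05 / T), np.log10(20.0 / T), 10)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("alpha_grid must be nonempty")

    index = {lb: i for i, lb in enumerate(labels)}
    depths_by_node = node_depths(tree)
    edges = []  # (edge label, tip index array, start depth)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = np.array(sorted(index[leaf_label(lf)] for lf in node.leaf_iter()))
        lbl = leaf_label(node) if node.is_leaf() else node.label
        edges.append((lbl, tips, depths_by_node[node.parent_node]))

    best: OUShiftFit | None = None
    for alpha in alpha_grid:
        V = _ou_covariance(C, T, alpha)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            continue
        sign, logdetV = np.linalg.slogdet(V)
        yw = scipy.linalg.solve_triangular(L, x, lower=True)
        onew = scipy.linalg.solve_triangular(L, np.ones(n), lower=True)
        cols = np.zeros((n, len(edges)))
        for e, (lbl, tips, t_start) in enumerate(edges):
            cols[tips, e] = 1 - np.exp(-alpha * (T - t_start))
        colsw = scipy.linalg.solve_triangular(L, cols, lower=True)

        def rss_of(sel: list[int]) -> tuple[float, np.ndarray]:
            A = np.column_stack([onew] + [colsw[:, e] for e in sel])
            beta, *_ = np.linalg.lstsq(A, yw, rcond=None)
            r = yw - A @ beta
            return float(r @ r), beta

        scale = float(x @ x) / n + 1e-30
        def bic_of(rss: float, n_shifts: int) -> float:
            # floor sigma2 at numerical-noise level relative to the data so a
            # perfectly fitted trait cannot create spurious BIC differences
            sigma2 = max(rss / n, 1e-12 * scale)
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdetV)
            k = 2 * n_shifts + 3
            # extended-BIC location term: each shift is chosen among all
            # edges, so its placement costs log(#edges) on top of the usual
            # parameter penalty (otherwise selection over ~2n candidate
            # edges badly overfits; cf. the pBIC used by l1ou)
            return -2 * ll + k * np.log(n) + 2 * n_shifts * np.log(len(edges))

        selected: list[int] = []
        rss, beta = rss_of(selected)
        path = [(list(selected), rss, beta)]
        while len(selected) < max_shifts:
            cand_best = None
            for e in range(len(edges)):
                if e in selected:
                    continue
                r2, b2 = rss_of(selected + [e])
                if cand_best is None or r2 < cand_best[1]:
                    cand_best = (e, r2, b2)
            if cand_best is None:
                break
            selected = selected + [cand_best[0]]
            path.append((list(selected), cand_best[1], cand_best[2]))
        # backward prune the largest model, then score every visited config
        sel = list(path[-1][0])
        improved = True
        while improved and sel:
            improved = False
            base_bic = bic_of(rss_of(sel)[0], len(sel))
            for e in list(sel):
                trial = [q for q in sel if q != e]
                if bic_of(rss_of(trial)[0], len(trial)) < base_bic:
                    sel = trial
                    improved = True
                    break
        configs = [p[0] for p in path] + [sel]
        for config in configs:
            rss, beta = rss_of(config)
            bic = bic_of(rss, len(config))
            if best is None or bic < best.bic - 1e-9 or (
                abs(bic - best.bic) <= 1e-9 and len(config) < best.n_shifts
            ):
                best = OUShiftFit(
                    shift_edges=[edges[e][0] for e in config],
                    shift_effects={
                        edges[e][0]: float(b) for e, b in zip(config, beta[1:])
                    },
                    base_optimum=float(beta[0]),
                    alpha=float(alpha),
                    sigma2=max(rss / n, 0.0),
                    bic=float(bic),
                    n_shifts=len(config),
                )
    if best is None:
        raise RuntimeError("no alpha in the grid yielded a valid OU covariance")
    return best
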
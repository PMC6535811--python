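"""Likelihood models of chromosome-number evolution.

Chromosome counts evolve along the phylogeny as a continuous-time Markov
chain over haploid numbers n. Transitions are ascending dysploidy
(i -> i+1, rate gain_i), descending dysploidy (i -> i-1, rate loss_i),
polyploidy/duplication (i -> 2i, rate rho) and demiduplication
(i -> 1.5i, rate mu, split over the two neighbouring integers for odd i).
"Linear" models let the dysploidy rates depend on the current count:
gain_i = max(0, lambda0 + lambda1 * (i - n_min)), and likewise for loss.

The module provides the generator-matrix construction, a Felsenstein
pruning likelihood, bounded multi-start maximum-likelihood fitting, an
AIC/Akaike-weight model comparison over a ten-model battery, marginal
ancestral-state reconstruction, and stochastic mapping of expected event
counts. Data enter as diploid counts (2n) and are modeled as n = 2n/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from ._treeutil import ensure_node_labels, leaf_label
from .phylo_io import TraitVector
from .synthetic_data import classify_change

__all__ = [
    "ChromosomeModelSpec",
    "ChromFit",
    "RATE_PARAMS",
    "build_rate_matrix",
    "likelihood",
    "fit_model",
    "compare_models",
    "ancestral_states",
    "expected_changes",
    "default_model_battery",
    "haploid_counts",
    "default_state_space",
]

RATE_PARAMS = ("gain", "loss", "gain_slope", "loss_slope", "dupl", "demi")
EVENT_TYPES = ("gain", "loss", "duplication", "demiduplication", "other")


@dataclass
class ChromosomeModelSpec:
    """One parameterization of the chromosome-number CTMC.

    ``free`` lists the parameters estimated by ML; the rest stay at their
    field values (0 excludes the move). ``demi_tied`` constrains the
    demiduplication rate to equal the duplication rate without spending a
    free parameter. State space is the haploid interval
    [``n_min``, ``n_max``].
    """

    name: str = "CONST"
    n_min: int = 1
    n_max: int = 50
    gain: float = 0.0
    loss: float = 0.0
    gain_slope: float = 0.0
    loss_slope: float = 0.0
    dupl: float = 0.0
    demi: float = 0.0
    free: tuple[str, ...] = ("gain", "loss")
    demi_tied: bool = False

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_max <= self.n_min:
            raise ValueError("need 1 <= n_min < n_max")
        for p in ("gain", "loss", "dupl", "demi"):
            if getattr(self, p) < 0:
                raise ValueError(f"base rate {p} must be >= 0")
        unknown = set(self.free) - set(RATE_PARAMS)
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free)

    def with_values(self, values: dict[str, float]) -> "ChromosomeModelSpec":
        spec = replace(self, **values)
        if spec.demi_tied:
            spec = replace(spec, demi=spec.dupl)
        return spec

    @property
    def n_states(self) -> int:
        return self.n_max - self.n_min + 1


def build_rate_matrix(spec: ChromosomeModelSpec) -> np.ndarray:
    """Generator matrix over haploid counts n_min..n_max.

    Linear dysploidy rates are clamped at zero state-wise. Duplication
    mass from states with 2i > n_max is routed to the n_max boundary so Q
    remains a proper generator (i = n_max itself gains no self-move).
    Demiduplication from odd i splits mu/2 to (3i-1)/2 and (3i+1)/2.
    """
    m = spec.n_states
    Q = np.zeros((m, m))
    demi = spec.dupl if spec.demi_tied else spec.demi
    for idx in range(m):
        i = spec.n_min + idx
        gain_i = max(0.0, spec.gain + spec.gain_slope * (i - spec.n_min))
        loss_i = max(0.0, spec.loss + spec.loss_slope * (i - spec.n_min))
        if idx + 1 < m and gain_i > 0:
            Q[idx, idx + 1] += gain_i
        if idx > 0 and loss_i > 0:
            Q[idx, idx - 1] += loss_i
        if spec.dupl > 0:
            j = min(2 * i, spec.n_max)
            if j != i:
                Q[idx, j - spec.n_min] += spec.dupl
        if demi > 0:
            if i % 2 == 0:
                targets = {3 * i // 2: demi}
            else:
                targets = {(3 * i - 1) // 2: demi / 2, (3 * i + 1) // 2: demi / 2}
            for j, rate in targets.items():
                j = min(j, spec.n_max)
                if j != i:
                    Q[idx, j - spec.n_min] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class _Propagator:
    """Computes exp(Q t) @ v per edge, via eigendecomposition when Q is
    well-conditioned and scipy.linalg.expm otherwise."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._cache: dict[float, np.ndarray] = {}
        self._eig = None
        if Q.shape[0] > 3 and np.any(Q):
            try:
                w, V = scipy.linalg.eig(Q)
                Vinv = np.linalg.inv(V)
                if np.linalg.cond(V) < 1e8:
                    self._eig = (w, V, Vinv)
            except np.linalg.LinAlgError:
                pass

    def matrix(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is None:
            if self._eig is not None:
                w, V, Vinv = self._eig
                P = np.real(V @ np.diag(np.exp(w * t)) @ Vinv)
            else:
                P = scipy.linalg.expm(self.Q * t)
            np.clip(P, 0.0, None, out=P)
            self._cache[t] = P
        return P

    def apply(self, t: float, v: np.ndarray) -> np.ndarray:
        """exp(Q t) @ v without forming the matrix (when eig is available)."""
        if self._eig is None:
            return self.matrix(t) @ v
        w, V, Vinv = self._eig
        out = np.real(V @ (np.exp(w * t) * (Vinv @ v)))
        np.clip(out, 0.0, None, out=out)
        return out

    def apply_left(self, t: float, u: np.ndarray) -> np.ndarray:
        """u @ exp(Q t) without forming the matrix."""
        if self._eig is None:
            return u @ self.matrix(t)
        w, V, Vinv = self._eig
        out = np.real(((u @ V) * np.exp(w * t)) @ Vinv)
        np.clip(out, 0.0, None, out=out)
        return out


def _tip_state_index(counts: TraitVector, spec: ChromosomeModelSpec, label: str) -> int:
    n = int(counts.values[label])
    if not spec.n_min <= n <= spec.n_max:
        raise ValueError(
            f"tip {label!r} has count n={n} outside the state space "
            f"[{spec.n_min}, {spec.n_max}]; widen the space (e.g. raise n_max)"
        )
    return n - spec.n_min


def _partials(tree, counts, spec, prop) -> tuple[dict, float]:
    """Postorder conditional likelihoods; returns per-node partials and the
    accumulated log scaling factor."""
    m = spec.n_states
    partial: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(m)
            v[_tip_state_index(counts, spec, leaf_label(node))] = 1.0
        else:
            v = np.ones(m)
            for child in node.child_nodes():
                v = v * prop.apply(child.edge.length or 0.0, partial[id(child)])
            mx = v.max()
            if mx <= 0:
                return {id(tree.seed_node): v}, -np.inf
            v = v / mx
            logscale += np.log(mx)
        partial[id(node)] = v
    return partial, logscale


class _PruningKernel:
    """Vectorized pruning for repeated likelihood evaluations on one tree.

    The tree topology, edge lengths, and tip states are fixed across
    optimizer iterations; only Q changes. Leaf-edge contributions are
    batched into a single complex matrix product in the eigenbasis of Q,
    and internal nodes are processed in height order so that each level is
    two matrix products. Falls back to the per-edge path when Q is not
    cleanly diagonalizable.
    """

    def __init__(self, tree, counts: TraitVector, spec: ChromosomeModelSpec):
        self.tree = tree
        self.counts = counts
        self.spec = spec
        self.m = spec.n_states
        leaf_t, leaf_state, leaf_slot = [], [], {}
        internal, height = [], {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                leaf_slot[id(node)] = len(leaf_t)
                leaf_t.append(node.edge.length or 0.0)
                leaf_state.append(_tip_state_index(counts, spec, leaf_label(node)))
                height[id(node)] = 0
            else:
                height[id(node)] = 1 + max(height[id(c)] for c in node.child_nodes())
                internal.append(node)
        self.leaf_t = np.array(leaf_t)
        self.leaf_state = np.array(leaf_state)
        self.leaf_slot = leaf_slot
        # internal nodes grouped by height (children always in lower groups)
        self.levels: list[list] = []
        for h in sorted({height[id(n)] for n in internal}):
            self.levels.append([n for n in internal if height[id(n)] == h])
        self.int_t = {
            id(n): n.edge.length or 0.0 for n in internal if n.parent_node is not None
        }
        self.degenerate = not self.levels  # single-tip tree

    def loglik(self, Q: np.ndarray, root_prior: str) -> float:
        if self.degenerate:
            prop = _Propagator(Q)
            partial, logscale = _partials(self.tree, self.counts, self.spec, prop)
            return _root_aggregate(
                partial[id(self.tree.seed_node)], logscale, root_prior
            )
        backend = _EigBackend.build(Q)
        if backend is None:
            backend = _DyadicBackend(Q, max(max(self.leaf_t, default=0.0),
                                            max(self.int_t.values(), default=0.0)))
        m = self.m
        onehots = np.zeros((m, len(self.leaf_state)))
        onehots[self.leaf_state, np.arange(len(self.leaf_state))] = 1.0
        Mleaf = backend.propagate(self.leaf_t, onehots)
        logscale = 0.0
        partial: dict[int, np.ndarray] = {}
        for level in self.levels:
            vs = []
            for node in level:
                v = np.ones(m)
                for c in node.child_nodes():
                    if c.is_leaf():
                        v = v * Mleaf[:, self.leaf_slot[id(c)]]
                    else:
                        v = v * partial.pop(id(c))
                mx = v.max()
                if mx <= 0:
                    return -np.inf
                logscale += np.log(mx)
                vs.append(v / mx)
            edged = [n for n in level if n.parent_node is not None]
            if edged:
                t = np.array([self.int_t[id(n)] for n in edged])
                cols = np.column_stack(
                    [v for n, v in zip(level, vs) if n.parent_node is not None]
                )
                M = backend.propagate(t, cols)
                for k_, n in enumerate(edged):
                    partial[id(n)] = M[:, k_]
            for n, v in zip(level, vs):
                if n.parent_node is None:
                    partial[id(n)] = v
        return _root_aggregate(partial[id(self.tree.seed_node)], logscale, root_prior)


class _EigBackend:
    """Edge propagation through the eigenbasis of Q (fast, requires a
    well-conditioned eigenvector matrix)."""

    def __init__(self, w, V, W):
        self.w, self.V, self.W = w, V, W

    @classmethod
    def build(cls, Q: np.ndarray):
        try:
            w, V = scipy.linalg.eig(Q)
            W = np.linalg.inv(V)
        except (np.linalg.LinAlgError, ValueError):
            return None
        err = np.abs(V @ W - np.eye(Q.shape[0])).max()
        if not np.isfinite(err) or err > 1e-8:
            return None
        return cls(w, V, W)

    def propagate(self, t: np.ndarray, cols: np.ndarray) -> np.ndarray:
        # columnwise exp(Q t_j) @ cols[:, j]
        A = (self.W @ cols) * np.exp(np.outer(self.w, t))
        M = np.real(self.V @ A)
        np.clip(M, 0.0, None, out=M)
        return M


class _DyadicBackend:
    """Edge propagation by binary decomposition of branch lengths.

    One Pade expm of Q*delta plus repeated squaring gives exp(Q delta 2^k)
    for all k; exp(Q t) @ v is then the product over the set bits of
    round(t/delta). Branch lengths are thereby quantized to delta =
    t_max / 2^22, a relative perturbation below 3e-7 of the longest edge.
    Robust for defective Q (e.g. strongly state-dependent linear models)
    where the eigenbasis is useless."""

    LEVELS = 22

    def __init__(self, Q: np.ndarray, t_max: float):
        self.delta = max(t_max, 1e-12) / (1 << self.LEVELS)
        E = scipy.linalg.expm(Q * self.delta)
        self.powers = [E]
        for _ in range(self.LEVELS - 1):
            E = E @ E
            np.clip(E, 0.0, None, out=E)
            self.powers.append(E)

    def propagate(self, t: np.ndarray, cols: np.ndarray) -> np.ndarray:
        steps = np.round(np.asarray(t) / self.delta).astype(np.int64)
        steps = np.minimum(steps, (1 << self.LEVELS) - 1)
        X = cols.copy()
        for k in range(self.LEVELS):
            mask = (steps >> k) & 1 == 1
            if mask.any():
                X[:, mask] = self.powers[k] @ X[:, mask]
        np.clip(X, 0.0, None, out=X)
        return X


def _root_aggregate(root_partial: np.ndarray, logscale: float, root_prior: str) -> float:
    if not np.isfinite(logscale):
        return -np.inf
    agg = root_partial.max() if root_prior == "ml" else root_partial.mean()
    if agg <= 0:
        return -np.inf
    return logscale + float(np.log(agg))


def likelihood(
    tree,
    counts: TraitVector,
    spec: ChromosomeModelSpec,
    root_prior: str = "ml",
) -> float:
    """Felsenstein pruning log-likelihood of tip counts under `spec`.

    ``root_prior='ml'`` maximizes over root states (ChromEvol default);
    ``'uniform'`` averages over a flat root prior.
    """
    if root_prior not in ("ml", "uniform"):
        raise ValueError("root_prior must be 'ml' or 'uniform'")
    Q = build_rate_matrix(spec)
    prop = _Propagator(Q)
    partial, logscale = _partials(tree, counts, spec, prop)
    if not np.isfinite(logscale):
        return -np.inf
    root = partial[id(tree.seed_node)]
    agg = root.max() if root_prior == "ml" else root.mean()
    if agg <= 0:
        return -np.inf
    return logscale + float(np.log(agg))


@dataclass
class ChromFit:
    """A fitted chromosome-number model."""

    spec: ChromosomeModelSpec
    params: dict[str, float]
    logL: float
    k: int
    aic: float
    root_prior: str
    fingerprint: tuple
    weight: float | None = None
    n_starts: int = 1
    seed: int = 0


def _fingerprint(tree, counts: TraitVector) -> tuple:
    return (
        tuple(sorted((k, float(v)) for k, v in counts.values.items())),
        round(sum(nd.edge.length or 0.0 for nd in tree.preorder_node_iter()), 10),
    )


def fit_model(
    tree,
    counts: TraitVector,
    spec: ChromosomeModelSpec,
    n_starts: int = 3,
    seed: int = 0,
    root_prior: str = "ml",
) -> ChromFit:
    """Bounded multi-start ML fit of the free parameters of `spec`.

    Rates are optimized on a log scale within [1e-6, 100]; linear-slope
    coefficients on a natural scale within [-5, 5]. Start points are
    log-uniform over [1e-4, 10] for rates and uniform over [-0.5, 0.5]
    for slopes; the surface can be multimodal, hence the restarts.
    Deterministic for a given seed.
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    rng = np.random.default_rng(seed)
    free = list(spec.free)
    is_slope = [p.endswith("_slope") for p in free]

    def unpack(x):
        vals = {}
        for p, s, xi in zip(free, is_slope, x):
            vals[p] = xi if s else float(np.exp(xi))
        return vals

    kernel = _PruningKernel(tree, counts, spec)

    def objective(x):
        try:
            Q = build_rate_matrix(spec.with_values(unpack(x)))
            ll = kernel.loglik(Q, root_prior)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        return 1e12 if not np.isfinite(ll) else -ll

    bounds = [(-5.0, 5.0) if s else (np.log(1e-6), np.log(100.0)) for s in is_slope]
    best = None
    for start in range(n_starts):
        if start == 0:
            # deterministic neutral start: modest rates, flat slopes — keeps
            # nested models comparable run-to-run
            x0 = np.array([0.0 if s else np.log(0.1) for s in is_slope])
        else:
            x0 = np.array(
                [
                    rng.uniform(-0.5, 0.5)
                    if s
                    else np.log(1e-4) + rng.uniform() * (np.log(10.0) - np.log(1e-4))
                    for s in is_slope
                ]
            )
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-8, "gtol": 1e-4, "maxiter": 120},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError(
            "likelihood was non-finite at every start; try widening the state space"
        )
    params = unpack(best.x)
    fitted = spec.with_values(params)
    logL = -best.fun
    return ChromFit(
        spec=fitted,
        params=params,
        logL=logL,
        k=spec.k,
        aic=2 * spec.k - 2 * logL,
        root_prior=root_prior,
        fingerprint=_fingerprint(tree, counts),
        n_starts=n_starts,
        seed=seed,
    )


def compare_models(fits: list[ChromFit]) -> pd.DataFrame:
    """Rank fitted models by AIC and attach Akaike weights.

    weight_m = exp(-delta_m / 2) / sum exp(-delta / 2) with
    delta_m = AIC_m - min AIC. All fits must be on identical data.
    """
    if not fits:
        raise ValueError("no fits to compare")
    fp = fits[0].fingerprint
    if any(f.fingerprint != fp for f in fits):
        raise ValueError("fits were computed on different data sets")
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    df = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "k": [f.k for f in fits],
            "logL": [f.logL for f in fits],
            "AIC": aic,
            "delta_AIC": delta,
            "akaike_weight": w,
        }
    ).sort_values("AIC", ignore_index=True)
    return df


def _downpass(tree, counts, spec, prop):
    """Outside ('flow') vectors per node under a uniform root prior."""
    m = spec.n_states
    partial, _ = _partials(tree, counts, spec, prop)
    out: dict[int, np.ndarray] = {id(tree.seed_node): np.full(m, 1.0 / m)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        M = {
            id(c): prop.apply(c.edge.length or 0.0, partial[id(c)]) for c in children
        }
        for c in children:
            sib = np.ones(m)
            for b in children:
                if b is not c:
                    sib = sib * M[id(b)]
            vec = prop.apply_left(c.edge.length or 0.0, out[id(node)] * sib)
            s = vec.sum()
            out[id(c)] = vec / s if s > 0 else vec
    return partial, out


def ancestral_states(
    fit: ChromFit, tree, counts: TraitVector
) -> tuple[pd.DataFrame, pd.Series]:
    """Marginal posterior state distributions and ML states per node.

    Standard two-pass conditioning under a uniform root prior. Ties in
    the argmax are broken toward the smaller count. Returns a posterior
    DataFrame (nodes x haploid states) and a Series of ML states.
    """
    spec = fit.spec
    ensure_node_labels(tree)
    prop = _Propagator(build_rate_matrix(spec))
    partial, out = _downpass(tree, counts, spec, prop)
    states = np.arange(spec.n_min, spec.n_max + 1)
    rows, labels = [], []
    for node in tree.preorder_node_iter():
        post = out[id(node)] * partial[id(node)]
        total = post.sum()
        if total <= 0:
            raise RuntimeError("zero posterior mass; data inconsistent with model")
        rows.append(post / total)
        labels.append(leaf_label(node) if node.is_leaf() else node.label)
    posterior = pd.DataFrame(rows, index=labels, columns=states)
    ml_state = pd.Series(
        # argmax returns the first (smallest-count) index on ties
        posterior.values.argmax(axis=1) + spec.n_min,
        index=labels,
        name="ml_state",
    )
    return posterior, ml_state


def expected_changes(
    fit: ChromFit,
    tree,
    counts: TraitVector,
    n_mappings: int = 100,
    seed: int = 0,
    rejection_cap: int = 200,
) -> pd.DataFrame:
    """Expected numbers of events per branch and type via stochastic mapping.

    Joint node states are sampled from the conditional distribution given
    the tips, then each branch history is drawn conditional on its
    endpoint states — by rejection sampling up to `rejection_cap`
    attempts, falling back to uniformization when the endpoints are hard
    to bridge. Returns a DataFrame indexed by branch (child node label)
    with one column per event type, averaged over `n_mappings` mappings.
    """
    if n_mappings < 1:
        raise ValueError("n_mappings must be >= 1")
    spec = fit.spec
    ensure_node_labels(tree)
    Q = build_rate_matrix(spec)
    prop = _Propagator(Q)
    rng = np.random.default_rng(seed)
    partial, _ = _partials(tree, counts, spec, prop)
    m = spec.n_states
    nodes = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    branch_labels = [leaf_label(nd) if nd.is_leaf() else nd.label for nd in nodes]
    acc = pd.DataFrame(0.0, index=branch_labels, columns=list(EVENT_TYPES))
    root = tree.seed_node
    root_post = partial[id(root)] / partial[id(root)].sum()
    for _ in range(n_mappings):
        state: dict[int, int] = {id(root): int(rng.choice(m, p=root_post))}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            i = state[id(nd.parent_node)]
            p = prop.matrix(nd.edge.length or 0.0)[i] * partial[id(nd)]
            p = p / p.sum()
            state[id(nd)] = int(rng.choice(m, p=p))
        for nd, lbl in zip(nodes, branch_labels):
            i, j = state[id(nd.parent_node)], state[id(nd)]
            t = nd.edge.length or 0.0
            events = _sample_branch_history(
                Q, prop, i, j, t, rng, rejection_cap, spec.n_min
            )
            for ev in events:
                acc.loc[lbl, ev] += 1
    return acc / n_mappings


def _sample_branch_history(Q, prop, i, j, t, rng, cap, n_min) -> list[str]:
    if t <= 0 or not np.any(Q):
        return []
    for _ in range(cap):
        path = _gillespie_path(Q, i, t, rng)
        if path[-1] == j:
            return [
                classify_change(a + n_min, b + n_min)
                for a, b in zip(path, path[1:])
            ]
    warnings.warn(
        f"rejection cap reached bridging states {i + n_min}->{j + n_min}; "
        "using uniformization",
        stacklevel=2,
    )
    return _uniformization_path(Q, prop, i, j, t, rng, n_min)


def _gillespie_path(Q, i, t, rng) -> list[int]:
    path = [i]
    s, clock = i, 0.0
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            return path
        clock += rng.exponential(1.0 / rate)
        if clock >= t:
            return path
        p = Q[s].copy()
        p[s] = 0.0
        s = int(rng.choice(len(p), p=p / p.sum()))
        path.append(s)


def _uniformization_path(Q, prop, i, j, t, rng, n_min) -> list[str]:
    m = Q.shape[0]
    omega = max(-Q.diagonal().min(), 1e-12)
    R = np.eye(m) + Q / omega
    Pt_ij = prop.matrix(t)[i, j]
    if Pt_ij <= 0:
        return []
    # sample the number of uniformized jumps
    powers = [np.eye(m)]
    u = rng.uniform() * Pt_ij
    cum, n = 0.0, -1
    log_pois = -omega * t
    term = np.exp(log_pois)
    while n < 500:
        n += 1
        if n > 0:
            powers.append(powers[-1] @ R)
            term *= omega * t / n
        cum += term * powers[n][i, j]
        if cum >= u:
            break
    # sample the jump chain bridge, then drop virtual self-jumps
    states = [i]
    for k in range(1, n):
        prev = states[-1]
        w = R[prev] * powers[n - k][:, j]
        states.append(int(rng.choice(m, p=w / w.sum())))
    if n > 0:
        states.append(j)
    return [
        classify_change(a + n_min, b + n_min)
        for a, b in zip(states, states[1:])
        if a != b
    ]


def default_model_battery(n_min: int, n_max: int) -> list[ChromosomeModelSpec]:
    """Ten-model comparison set over dysploidy, duplication, and
    demiduplication moves with constant or count-dependent (linear) rates."""
    def spec(name, free, demi_tied=False):
        return ChromosomeModelSpec(
            name=name, n_min=n_min, n_max=n_max, free=free, demi_tied=demi_tied
        )

    return [
        spec("CONST", ("gain", "loss")),
        spec("CONST_DUPL", ("gain", "loss", "dupl")),
        spec("CONST_DUPL_DEMI_TIED", ("gain", "loss", "dupl"), demi_tied=True),
        spec("CONST_DUPL_DEMI_FREE", ("gain", "loss", "dupl", "demi")),
        spec("LINEAR", ("gain", "loss", "gain_slope", "loss_slope")),
        spec("LINEAR_DUPL", ("gain", "loss", "gain_slope", "loss_slope", "dupl")),
        spec(
            "LINEAR_DUPL_DEMI_TIED",
            ("gain", "loss", "gain_slope", "loss_slope", "dupl"),
            demi_tied=True,
        ),
        spec(
            "LINEAR_DUPL_DEMI_FREE",
            ("gain", "loss", "gain_slope", "loss_slope", "dupl", "demi"),
        ),
        spec("CONST_DUPL_ONLY", ("dupl",)),
        spec("LINEAR_GAIN_DUPL", ("gain", "gain_slope", "dupl")),
    ]


def haploid_counts(
    traits: TraitVector, exclude: list[str] | None = None
) -> TraitVector:
    """Convert diploid 2n counts to the haploid n the CTMC models.

    Odd 2n values are rejected (they indicate data errors or unreduced
    hybrid counts the model cannot represent). ``exclude`` drops named
    outlier species, e.g. a count too extreme for the sampled state space.
    """
    excluded = set(exclude or [])
    values = {}
    for sp, v in traits.values.items():
        if sp in excluded:
            continue
        v = int(v)
        if v % 2:
            raise ValueError(f"species {sp!r} has odd diploid count 2n={v}")
        values[sp] = v // 2
    return TraitVector(values, kind="chromosome_count_n")


def default_state_space(counts: TraitVector, pad: int = 10) -> tuple[int, int]:
    """[1, max observed n + pad] — wide enough that the boundary does not
    distort the fit, narrow enough to keep the matrix exponentials cheap."""
    return 1, int(max(counts.values.values())) + pad
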
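"""Simulators for every input the pipeline consumes.

Four generators cover the study's data types:

* ultrametric species trees (birth--death),
* multilabeled gene families evolving under duplication--loss inside the
  species tree, with an optional episodic whole-genome duplication (WGD)
  retained per family with a fixed probability,
* chromosome counts evolving along the tree under an arbitrary CTMC
  generator matrix (Gillespie),
* continuous traits under Brownian motion, lambda-transformed BM, or an
  Ornstein--Uhlenbeck process with regime shifts.

Every generator takes an integer seed and is bit-reproducible. Ground
truth (true duplication nodes, true ancestral states, per-event logs) is
returned alongside the data so downstream inference can be scored without
re-deriving events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy

from ._treeutil import (
    ensure_node_labels,
    find_node,
    leaf_label,
    node_depths,
    vcv_matrix,
)
from .phylo_io import LabelMap, TraitVector
from .single_copy_filter import GeneFamily

__all__ = [
    "WGDScenario",
    "TraitSimSpec",
    "simulate_species_tree",
    "simulate_gene_families",
    "simulate_chromosome_counts",
    "simulate_trait",
    "classify_change",
]


# ---------------------------------------------------------------------------
# species trees


class _SimNode:
    __slots__ = ("t_birth", "t_end", "children", "alive", "extinct")

    def __init__(self, t_birth: float):
        self.t_birth = t_birth
        self.t_end: float | None = None
        self.children: list[_SimNode] = []
        self.alive = True
        self.extinct = False


def simulate_species_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    seed: int = 0,
    tip_prefix: str = "S",
) -> dendropy.Tree:
    """Simulate an ultrametric rooted species tree with `n_tips` extant tips.

    Forward Gillespie birth--death starting from two lineages at the root;
    the simulation stops one exponential waiting time after the extant
    count first reaches `n_tips`, so terminal branches are strictly
    positive. Runs with total extinction are discarded and re-drawn.
    Extinct lineages are pruned; the returned tree's root is the MRCA of
    the extant tips. Tips are labeled ``S01..`` and internal nodes ``N1..``
    in preorder.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = np.random.default_rng(seed)
    while True:
        root = _SimNode(0.0)
        a, b = _SimNode(0.0), _SimNode(0.0)
        root.children = [a, b]
        root.t_end = 0.0
        root.alive = False
        active = [a, b]
        t = 0.0
        total = birth_rate + death_rate
        while active and len(active) < n_tips:
            t += rng.exponential(1.0 / (len(active) * total))
            node = active[rng.integers(len(active))]
            node.t_end = t
            node.alive = False
            if rng.random() < birth_rate / total:
                node.children = [_SimNode(t), _SimNode(t)]
                active.remove(node)
                active.extend(node.children)
            else:
                node.extinct = True
                active.remove(node)
        if not active:
            continue  # clade died out; redraw
        t_present = t + rng.exponential(1.0 / (len(active) * total))
        for node in active:
            node.t_end = t_present
            node.alive = True
        tree = _simnodes_to_tree(root)
        if tree is not None and len(tree.leaf_nodes()) == n_tips:
            _label_species_tree(tree, tip_prefix)
            return tree


def _simnodes_to_tree(root: _SimNode) -> dendropy.Tree | None:
    def build(sim: _SimNode) -> dendropy.Node | None:
        if not sim.children:
            if sim.extinct or not sim.alive:
                return None
            nd = dendropy.Node()
            nd.edge.length = sim.t_end - sim.t_birth
            return nd
        kids = [build(c) for c in sim.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress unifurcation from pruned extinct sister
            kids[0].edge.length += sim.t_end - sim.t_birth
            return kids[0]
        nd = dendropy.Node()
        nd.edge.length = sim.t_end - sim.t_birth
        for k in kids:
            nd.add_child(k)
        return nd

    top = build(root)
    if top is None:
        return None
    tree = dendropy.Tree()
    tree.seed_node = top
    top.edge.length = None
    tree.is_rooted = True
    return tree


def _label_species_tree(tree: dendropy.Tree, tip_prefix: str) -> None:
    leaves = tree.leaf_nodes()
    width = max(2, len(str(len(leaves))))
    # deterministic order: preorder position
    i = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            i += 1
            nd.taxon = tree.taxon_namespace.require_taxon(
                label=f"{tip_prefix}{i:0{width}d}"
            )
    for nd in tree.preorder_node_iter():
        nd.support = None
    ensure_node_labels(tree)


# ---------------------------------------------------------------------------
# gene families under duplication-loss with an episodic WGD


@dataclass
class WGDScenario:
    """Study conditions for the gene-family simulator.

    ``wgd_node`` names an internal species-tree node (label, or iterable of
    tip labels whose MRCA it is); the WGD is a single synchronous
    duplication at the stem of that node, applied per family with
    probability ``retention_prob`` — the chance a family keeps the
    WGD-derived duplicate after fractionation. Background duplication and
    loss rates are per gene lineage per unit branch length.
    """

    species_tree: dendropy.Tree
    wgd_node: object = None
    retention_prob: float = 0.0
    background_dup_rate: float = 0.0
    loss_rate: float = 0.0
    n_families: int = 100
    seed: int = 0
    p_low_support: float = 0.0  # fraction of nodes drawn with support < 80

    def __post_init__(self) -> None:
        if not 0 <= self.retention_prob <= 1:
            raise ValueError("retention_prob must be in [0, 1]")
        if self.background_dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.wgd_node is not None:
            node = find_node(self.species_tree, self.wgd_node)
            if node.is_leaf():
                raise ValueError("wgd_node must be an internal node")


class _GNode:
    __slots__ = ("children", "length", "label", "event", "support")

    def __init__(self, length: float = 0.0, event: str | None = None):
        self.children: list[_GNode] = []
        self.length = length
        self.label: str | None = None
        self.event = event  # 'dup' | 'wgd' | 'spec' | None (leaf)
        self.support: float | None = None


def simulate_gene_families(scenario: WGDScenario) -> list[GeneFamily]:
    """Evolve gene families inside the species tree.

    Each family starts as one gene lineage at the species-tree root and
    undergoes Poisson duplication/loss along every branch. Families
    sampled (with ``retention_prob``) to retain the WGD get one extra
    synchronous duplication at the stem of ``wgd_node``. Tips are labeled
    ``Species@copyN``; transcript lengths are drawn uniformly from
    300--3000 nt. Metadata records per-family ground truth:
    ``wgd_retained`` (duplication simulated), ``wgd_observable`` (both
    daughter copies left surviving tips), ``n_background_dups``, and
    ``wgd_species_tips`` (the species set of the WGD clade). Surviving
    gene-tree duplication nodes carry ``true_event`` attributes
    (``"wgd"``/``"dup"``).
    """
    rng = np.random.default_rng(scenario.seed)
    stree = scenario.species_tree
    wgd = find_node(stree, scenario.wgd_node) if scenario.wgd_node is not None else None
    families = []
    for i in range(scenario.n_families):
        fam = _simulate_one_family(scenario, stree, wgd, rng, f"F{i+1:05d}")
        families.append(fam)
    return families


def _simulate_one_family(scenario, stree, wgd, rng, family_id) -> GeneFamily:
    retained = wgd is not None and rng.random() < scenario.retention_prob
    copy_counter: dict[str, int] = {}
    truth = {
        "wgd_retained": retained,
        "wgd_observable": False,
        "n_background_dups": 0,
        "wgd_species_tips": sorted(leaf_label(lf) for lf in wgd.leaf_iter())
        if wgd is not None
        else None,
    }

    def evolve_along_edge(gnode: _GNode, remaining: float, snode) -> list[_GNode]:
        """Background duplication-loss for one lineage; returns survivors at
        the edge bottom, building dup nodes into the gene tree."""
        d, l = scenario.background_dup_rate, scenario.loss_rate
        while True:
            t_dup = rng.exponential(1.0 / d) if d > 0 else np.inf
            t_loss = rng.exponential(1.0 / l) if l > 0 else np.inf
            t_evt = min(t_dup, t_loss)
            if t_evt >= remaining:
                gnode.length += remaining
                return [gnode]
            gnode.length += t_evt
            remaining -= t_evt
            if t_loss < t_dup:
                gnode.event = "lost"
                return []
            truth["n_background_dups"] += 1
            gnode.event = "dup"
            left, right = _GNode(), _GNode()
            gnode.children = [left, right]
            return evolve_along_edge(left, remaining, snode) + evolve_along_edge(
                right, remaining, snode
            )

    def process(snode, entering: list[_GNode]) -> None:
        """`entering` are gene lineages at the top of snode's edge."""
        edge_len = snode.edge.length or 0.0
        if wgd is not None and snode is wgd and retained:
            doubled = []
            for g in entering:
                g.event = "wgd"
                a, b = _GNode(), _GNode()
                g.children = [a, b]
                doubled.extend([a, b])
            entering = doubled
        survivors: list[_GNode] = []
        for g in entering:
            survivors.extend(evolve_along_edge(g, edge_len, snode))
        if snode.is_leaf():
            sp = leaf_label(snode)
            for g in survivors:
                copy_counter[sp] = copy_counter.get(sp, 0) + 1
                g.label = f"{sp}@copy{copy_counter[sp]}"
                g.event = "tip"
        else:
            for g in survivors:
                g.event = "spec"
                g.children = [_GNode() for _ in snode.child_nodes()]
            for idx, schild in enumerate(snode.child_nodes()):
                process(schild, [g.children[idx] for g in survivors])

    # the root has no subtending edge: treat it as a speciation of the single
    # ancestral gene copy (with a WGD first if the WGD node is the root itself)
    root = _GNode()
    sroot = stree.seed_node
    root_survivors: list[_GNode] = [root]
    if wgd is not None and sroot is wgd and retained:
        root.event = "wgd"
        root.children = [_GNode(), _GNode()]
        root_survivors = list(root.children)
    for g in root_survivors:
        g.event = "spec"
        g.children = [_GNode() for _ in sroot.child_nodes()]
    for idx, schild in enumerate(sroot.child_nodes()):
        process(schild, [g.children[idx] for g in root_survivors])

    pruned = _prune_dead(root)
    tree = None
    truth["extinct"] = pruned is None
    if pruned is not None:
        truth["wgd_observable"] = _wgd_survives(pruned)
        tree = _gnodes_to_tree(pruned, rng, scenario.p_low_support)
    else:
        tree = dendropy.Tree()
        tree.is_rooted = True
    tips = [leaf_label(lf) for lf in tree.leaf_node_iter()] if pruned is not None else []
    label_map = LabelMap({t: t.split("@", 1)[0] for t in tips})
    lengths = {t: int(rng.integers(300, 3001)) for t in tips}
    return GeneFamily(
        family_id=family_id,
        gene_tree=tree,
        label_map=label_map,
        transcript_length=lengths,
        metadata=truth,
    )


def _prune_dead(g: _GNode) -> _GNode | None:
    """Drop lineages with no sampled descendants; suppress unary nodes."""
    if not g.children:
        return g if g.event == "tip" else None
    kept = [c for c in (_prune_dead(c) for c in g.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].length += g.length
        return kept[0]
    g.children = kept
    return g


def _wgd_survives(g: _GNode) -> bool:
    if g.event == "wgd" and len(g.children) >= 2:
        return True
    return any(_wgd_survives(c) for c in g.children)


def _gnodes_to_tree(root: _GNode, rng, p_low_support: float) -> dendropy.Tree:
    tree = dendropy.Tree()
    tree.is_rooted = True

    def build(g: _GNode) -> dendropy.Node:
        nd = dendropy.Node()
        nd.edge.length = g.length
        if g.children:
            if p_low_support > 0 and rng.random() < p_low_support:
                nd.support = float(rng.integers(0, 80))
            elif p_low_support > 0:
                nd.support = float(rng.integers(80, 101))
            else:
                nd.support = 100.0
            nd.true_event = g.event
            for c in g.children:
                nd.add_child(build(c))
        else:
            nd.support = None
            nd.taxon = tree.taxon_namespace.require_taxon(label=g.label)
        return nd

    tree.seed_node = build(root)
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# chromosome counts (CTMC Gillespie)


def classify_change(i: int, j: int) -> str:
    """Name a chromosome-number transition: gain, loss, duplication,
    demiduplication (1.5x, rounded either way for odd counts), or other."""
    if j == i + 1:
        return "gain"
    if j == i - 1:
        return "loss"
    if j == 2 * i:
        return "duplication"
    if j in {(3 * i) // 2, (3 * i + 1) // 2} and j not in (i, i + 1, i - 1, 2 * i):
        return "demiduplication"
    return "other"


def simulate_chromosome_counts(
    tree: dendropy.Tree,
    Q: np.ndarray,
    root_count: int,
    seed: int = 0,
    n_min: int = 1,
) -> tuple[TraitVector, dict[str, int], list[dict]]:
    """Gillespie simulation of a chromosome-number CTMC along a tree.

    `Q` is a generator matrix over haploid counts ``n_min .. n_min+m-1``
    (rows sum to zero, off-diagonals nonnegative). Returns tip counts (as a
    TraitVector of haploid n), true states for every labeled node, and an
    event log with one record per change (node, time along edge, from, to,
    and the event type from :func:`classify_change`).
    """
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    if Q.shape != (m, m):
        raise ValueError("Q must be square")
    if np.any(Q - np.diag(np.diag(Q)) < -1e-12):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
        raise ValueError("rows of Q must sum to 0")
    if not n_min <= root_count < n_min + m:
        raise ValueError(f"root_count {root_count} outside state space [{n_min}, {n_min+m-1}]")
    rng = np.random.default_rng(seed)
    ensure_node_labels(tree)
    states: dict[str, int] = {}
    log: list[dict] = []
    node_state: dict[int, int] = {id(tree.seed_node): root_count}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[_node_name(node)] = root_count
            continue
        s = node_state[id(node.parent_node)] - n_min
        t, tmax = 0.0, node.edge.length or 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= tmax:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s_new = rng.choice(m, p=probs)
            log.append(
                {
                    "node": _node_name(node),
                    "time": t,
                    "from": s + n_min,
                    "to": s_new + n_min,
                    "type": classify_change(s + n_min, s_new + n_min),
                }
            )
            s = s_new
        node_state[id(node)] = s + n_min
        states[_node_name(node)] = s + n_min
    tips = {
        leaf_label(lf): float(states[_node_name(lf)]) for lf in tree.leaf_node_iter()
    }
    return TraitVector(tips, kind="chromosome_count_n"), states, log


def _node_name(node) -> str:
    return leaf_label(node) if node.is_leaf() else node.label


# ---------------------------------------------------------------------------
# continuous traits


@dataclass
class TraitSimSpec:
    """Parameters for continuous-trait simulation.

    model 'BM': Gaussian increments, Var = sigma2 * branch length.
    model 'lambda-BM': tips drawn from N(root_value, sigma2 * C_lambda)
    where C_lambda multiplies off-diagonal BM covariance by ``lam``.
    model 'OU': exact Ornstein--Uhlenbeck transitions with pull ``alpha``
    toward the current regime's optimum; ``shift_edges`` maps an edge
    (named by its child node: label, tip label, or tip set) to a new
    optimum that applies from the start of that edge downward.
    """

    model: str = "BM"
    sigma2: float = 1.0
    alpha: float = 0.0
    root_value: float = 0.0
    optimum: float | None = None
    shift_edges: dict = field(default_factory=dict)
    lam: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("BM", "OU", "lambda-BM"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "OU" and not self.alpha > 0:
            raise ValueError("OU requires alpha > 0")
        if self.model != "OU" and self.shift_edges:
            raise ValueError("shift_edges only apply to the OU model")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must be in [0, 1]")


def simulate_trait(
    tree: dendropy.Tree, spec: TraitSimSpec
) -> tuple[TraitVector, dict[str, float]]:
    """Simulate one continuous trait; returns tip values and true node values.

    For 'lambda-BM' only the root's true value is reported (internal node
    values are not defined by the covariance-transform construction).
    """
    rng = np.random.default_rng(spec.seed)
    ensure_node_labels(tree)
    if spec.model == "lambda-BM":
        labels, C = vcv_matrix(tree)
        Cl = C * spec.lam
        np.fill_diagonal(Cl, np.diag(C))
        x = rng.multivariate_normal(
            np.full(len(labels), spec.root_value), spec.sigma2 * Cl, method="cholesky"
        )
        tips = dict(zip(labels, x))
        return TraitVector(tips, kind="trait"), {_node_name(tree.seed_node): spec.root_value}

    shift_nodes = {
        id(find_node(tree, key)): theta for key, theta in spec.shift_edges.items()
    }
    values: dict[str, float] = {}
    node_val: dict[int, float] = {}
    node_opt: dict[int, float] = {}
    base_opt = spec.optimum if spec.optimum is not None else spec.root_value
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_val[id(node)] = spec.root_value
            node_opt[id(node)] = base_opt
            values[_node_name(node)] = spec.root_value
            continue
        t = node.edge.length or 0.0
        x0 = node_val[id(node.parent_node)]
        theta = shift_nodes.get(id(node), node_opt[id(node.parent_node)])
        if spec.model == "BM":
            x = x0 + rng.normal(0.0, np.sqrt(spec.sigma2 * t)) if t > 0 else x0
        else:  # OU exact transition
            e = np.exp(-spec.alpha * t)
            mean = theta + (x0 - theta) * e
            var = spec.sigma2 / (2 * spec.alpha) * (1 - e * e)
            x = rng.normal(mean, np.sqrt(var)) if var > 0 else mean
        node_val[id(node)] = x
        node_opt[id(node)] = theta
        values[_node_name(node)] = x
    tips = {
        leaf_label(lf): values[_node_name(lf)] for lf in tree.leaf_node_iter()
    }
    return TraitVector(tips, kind="trait"), values
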
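"""Reversible-jump MCMC over classification-tree space.

The sampler explores trees of varying size with four move types -- birth,
death, change-split, change-rule -- under a uniform prior over all valid
trees (leaf sizes >= p_min, at most s_max splits, rules restricted to the
observed values of each feature).  Acceptance follows the
Metropolis-Hastings-Green rule: a candidate is accepted with probability
min(1, exp(delta log marginal likelihood + log prior ratio + log proposal
ratio)).  Proposals that violate the leaf-size floor (or have no applicable
target) auto-reject but still count toward the acceptance-rate denominator.

Chains start from a single randomly drawn valid split, run a burn-in phase
whose states are discarded, then a post-burn-in phase from which every
``thin``-th state is collected into the posterior ensemble.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble
from .tree import Dataset, DecisionTree, Node, make_leaf, single_leaf_tree

logger = logging.getLogger(__name__)

MOVES = ("birth", "death", "change_split", "change_rule")
_NEG_INF = float("-inf")


@dataclass(frozen=True)
class ChainConfig:
    """Sampler settings.

    Defaults are the full-scale study settings: 200,000 burn-in and 10,000
    post-burn-in iterations with every-7th collection (~1,428 kept trees),
    pruning factor 6, move probabilities (0.15, 0.15, 0.1, 0.6) for
    (birth, death, change-split, change-rule) and change-rule proposal
    scale 1.0 (the local jump's rank-space sd is ``scale * L / 100`` steps
    along the sorted observed values).  ``s_max=None`` means n-1.
    """

    burn_in: int = 200_000
    post_burn_in: int = 10_000
    thin: int = 7
    p_min: int = 6
    move_probs: tuple[float, float, float, float] = (0.15, 0.15, 0.10, 0.60)
    proposal_scale: float = 1.0
    s_max: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.post_burn_in < 0:
            raise ValueError("phase lengths must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.p_min < 1:
            raise ValueError("p_min must be >= 1")
        mp = tuple(float(p) for p in self.move_probs)
        if len(mp) != 4 or any(p < 0 for p in mp):
            raise ValueError("move_probs must be four non-negative numbers")
        if abs(sum(mp) - 1.0) > 1e-12:
            raise ValueError(f"move_probs must sum to 1, got {sum(mp)}")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")
        object.__setattr__(self, "move_probs", mp)


@dataclass
class Proposal:
    """Candidate state plus the log ratios the acceptance rule needs.

    ``log_proposal_ratio`` is -inf for auto-rejected proposals (no valid
    target, leaf-size violation, empty child, rank step out of range).
    """

    tree: DecisionTree | None
    log_proposal_ratio: float
    log_prior_ratio: float = 0.0
    move: str = ""

    @property
    def auto_rejected(self) -> bool:
        return self.tree is None or self.log_proposal_ratio == _NEG_INF


@dataclass
class ChainDiagnostics:
    """Per-iteration traces and acceptance statistics."""

    size_trace: np.ndarray
    loglik_trace: np.ndarray
    move_trace: np.ndarray  # indices into MOVES
    accepted_trace: np.ndarray
    acceptance_rate: float = 0.0
    acceptance_by_move: dict = field(default_factory=dict)

    def summarize(self) -> None:
        n = self.accepted_trace.size
        self.acceptance_rate = float(self.accepted_trace.mean()) if n else 0.0
        self.acceptance_by_move = {}
        for i, name in enumerate(MOVES):
            sel = self.move_trace == i
            self.acceptance_by_move[name] = (
                float(self.accepted_trace[sel].mean()) if sel.any() else float("nan")
            )


# -- tree copy-and-edit helpers --------------------------------------------

def _clone(node: Node) -> Node:
    new = Node(node.feature, node.rule, idx=node.idx, counts=node.counts)
    new._loglik = node._loglik
    if not node.is_leaf:
        new.left = _clone(node.left)
        new.right = _clone(node.right)
    return new


def _reroute(node: Node, idx: np.ndarray, ds: Dataset, p_min: int) -> bool:
    """Re-partition ``idx`` down an already-parameterised subtree.

    Returns False as soon as any leaf would fall below ``p_min``.
    """
    node.idx = idx
    node.counts = ds.class_counts(idx)
    node._loglik = None
    if node.is_leaf:
        return idx.size >= p_min
    go_left = ds.X[idx, node.feature] <= node.rule
    return _reroute(node.left, idx[go_left], ds, p_min) and _reroute(
        node.right, idx[~go_left], ds, p_min
    )


def _prunable(tree: DecisionTree) -> list[Node]:
    """Split nodes whose both children are leaves (death targets)."""
    return [
        s for s in tree.split_nodes() if s.left.is_leaf and s.right.is_leaf
    ]


def _reject(move: str) -> Proposal:
    return Proposal(None, _NEG_INF, move=move)


# -- the four moves ---------------------------------------------------------

def propose(tree: DecisionTree, move: str, ds: Dataset, config: ChainConfig,
            rng: np.random.Generator) -> Proposal:
    """One candidate transition of the requested move type."""
    if move == "birth":
        return _propose_birth(tree, ds, config, rng)
    if move == "death":
        return _propose_death(tree, ds, config, rng)
    if move == "change_split":
        return _propose_change_split(tree, ds, config, rng)
    if move == "change_rule":
        return _propose_change_rule(tree, ds, config, rng)
    raise ValueError(f"unknown move type {move!r}")


def _propose_birth(tree, ds, config, rng) -> Proposal:
    p_b, p_d = config.move_probs[0], config.move_probs[1]
    s_max = ds.n - 1 if config.s_max is None else config.s_max
    cand = DecisionTree(_clone(tree.root), tree.n_classes)
    leaves = cand.leaves()
    k = len(leaves)
    if k - 1 >= s_max or ds.splittable.size == 0:
        return _reject("birth")
    leaf = leaves[rng.integers(k)]
    j = int(ds.splittable[rng.integers(ds.splittable.size)])
    lv = ds.levels[j]
    rule = float(lv[rng.integers(lv.size)])
    go_left = ds.X[leaf.idx, j] <= rule
    left_idx, right_idx = leaf.idx[go_left], leaf.idx[~go_left]
    if left_idx.size < config.p_min or right_idx.size < config.p_min:
        return _reject("birth")
    leaf.feature, leaf.rule = j, rule
    leaf.left = make_leaf(ds, left_idx)
    leaf.right = make_leaf(ds, right_idx)
    leaf._loglik = None
    # forward: pick leaf (1/k), feature (1/m_eff), rule (1/L);
    # reverse: death picking this split among the candidate's prunable ones
    log_q_fwd = math.log(p_b) - math.log(k * ds.splittable.size * lv.size)
    log_q_rev = math.log(p_d) - math.log(len(_prunable(cand))) if p_d > 0 else _NEG_INF
    return Proposal(cand, log_q_rev - log_q_fwd, move="birth")


def _propose_death(tree, ds, config, rng) -> Proposal:
    p_b, p_d = config.move_probs[0], config.move_probs[1]
    cand = DecisionTree(_clone(tree.root), tree.n_classes)
    prun = _prunable(cand)
    if not prun:
        return _reject("death")
    node = prun[rng.integers(len(prun))]
    L = ds.levels[node.feature].size
    node.feature = None
    node.rule = None
    node.left = node.right = None
    node._loglik = None
    k_after = len(cand.leaves())
    log_q_fwd = math.log(p_d) - math.log(len(prun))
    log_q_rev = (
        math.log(p_b) - math.log(k_after * ds.splittable.size * L)
        if p_b > 0
        else _NEG_INF
    )
    return Proposal(cand, log_q_rev - log_q_fwd, move="death")


def _propose_change_split(tree, ds, config, rng) -> Proposal:
    cand = DecisionTree(_clone(tree.root), tree.n_classes)
    splits = cand.split_nodes()
    if not splits or ds.splittable.size == 0:
        return _reject("change_split")
    node = splits[rng.integers(len(splits))]
    L_old = ds.levels[node.feature].size
    j = int(ds.splittable[rng.integers(ds.splittable.size)])
    lv = ds.levels[j]
    node.feature, node.rule = j, float(lv[rng.integers(lv.size)])
    if not _reroute(node, node.idx, ds, config.p_min):
        return _reject("change_split")
    # rule-choice probabilities differ between the old and new feature
    return Proposal(cand, math.log(lv.size) - math.log(L_old), move="change_split")


def _propose_change_rule(tree, ds, config, rng) -> Proposal:
    cand = DecisionTree(_clone(tree.root), tree.n_classes)
    splits = cand.split_nodes()
    if not splits:
        return _reject("change_rule")
    node = splits[rng.integers(len(splits))]
    lv = ds.levels[node.feature]
    L = lv.size
    if L == 1:
        # nowhere to move: the candidate is the current state
        return Proposal(cand, 0.0, move="change_rule")
    pos = int(np.searchsorted(lv, node.rule))
    z = rng.normal(0.0, config.proposal_scale * L / 100.0)
    mag = min(max(abs(int(round(z))), 1), L)
    step = mag if z >= 0 else -mag
    new_pos = pos + step
    if not 0 <= new_pos < L:
        return _reject("change_rule")  # symmetric kernel: drop mass off the ends
    node.rule = float(lv[new_pos])
    if not _reroute(node, node.idx, ds, config.p_min):
        return _reject("change_rule")
    return Proposal(cand, 0.0, move="change_rule")


def accept(current: DecisionTree, proposal: Proposal, delta_loglik: float,
           rng: np.random.Generator) -> tuple[DecisionTree, bool]:
    """Metropolis-Hastings-Green accept/reject step."""
    if proposal.auto_rejected:
        return current, False
    log_alpha = delta_loglik + proposal.log_prior_ratio + proposal.log_proposal_ratio
    if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
        return proposal.tree, True
    return current, False


# -- chain driver -----------------------------------------------------------

def initial_tree(ds: Dataset, config: ChainConfig,
                 rng: np.random.Generator, attempts: int = 100) -> DecisionTree:
    """One-split starting state drawn from the priors; single leaf if the
    dataset admits no valid split under p_min."""
    all_idx = np.arange(ds.n)
    for _ in range(attempts):
        if ds.splittable.size == 0:
            break
        j = int(ds.splittable[rng.integers(ds.splittable.size)])
        lv = ds.levels[j]
        rule = float(lv[rng.integers(lv.size)])
        go_left = ds.X[:, j] <= rule
        if go_left.sum() >= config.p_min and (~go_left).sum() >= config.p_min:
            root = Node(j, rule, make_leaf(ds, all_idx[go_left]),
                        make_leaf(ds, all_idx[~go_left]),
                        idx=all_idx, counts=ds.class_counts(all_idx))
            return DecisionTree(root, ds.n_classes)
    logger.warning(
        "dataset admits no valid split under p_min=%d; starting (and staying) "
        "at the single-leaf tree", config.p_min
    )
    return single_leaf_tree(ds)


def run_chain(ds: Dataset, config: ChainConfig, likelihood: str = "marginal",
              validate_every: bool = False) -> tuple[Ensemble, ChainDiagnostics]:
    """Run one chain; collect the post-burn-in ensemble and diagnostics.

    ``likelihood="flat"`` replaces the marginal likelihood with a constant,
    so the chain samples the tree prior alone -- a sampler-correctness
    diagnostic checked against direct enumeration of the prior.
    """
    if likelihood not in ("marginal", "flat"):
        raise ValueError(f"unknown likelihood mode {likelihood!r}")
    flat = likelihood == "flat"
    rng = np.random.default_rng(config.seed)
    s_max = ds.n - 1 if config.s_max is None else config.s_max
    tree = initial_tree(ds, config, rng)
    ll = 0.0 if flat else tree.log_marginal_likelihood()

    total = config.burn_in + config.post_burn_in
    size_trace = np.empty(total, dtype=np.int32)
    ll_trace = np.empty(total)
    move_trace = np.empty(total, dtype=np.int8)
    acc_trace = np.zeros(total, dtype=bool)
    collected: list[DecisionTree] = []
    probs = np.asarray(config.move_probs)

    for t in range(total):
        mv = int(rng.choice(4, p=probs))
        prop = propose(tree, MOVES[mv], ds, config, rng)
        if prop.auto_rejected:
            accepted = False
        else:
            ll_cand = 0.0 if flat else prop.tree.log_marginal_likelihood()
            tree_next, accepted = accept(tree, prop, ll_cand - ll, rng)
            if accepted:
                tree, ll = tree_next, ll_cand
        size_trace[t] = tree.n_leaves
        ll_trace[t] = ll
        move_trace[t] = mv
        acc_trace[t] = accepted
        if validate_every:
            sizes = [int(l.counts.sum()) for l in tree.leaves()]
            assert min(sizes) >= config.p_min or tree.n_leaves == 1
            assert tree.n_leaves - 1 <= s_max
        if t >= config.burn_in and (t - config.burn_in + 1) % config.thin == 0:
            collected.append(tree.strip())

    diag = ChainDiagnostics(size_trace, ll_trace, move_trace, acc_trace)
    diag.summarize()
    ens = Ensemble(
        collected if collected else [tree.strip()],
        n_features=ds.m,
        classes=ds.classes,
        provenance={"config": config.__dict__.copy(), "likelihood": likelihood},
    )
    return ens, diag
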
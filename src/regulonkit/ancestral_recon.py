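"""Ancestral regulation states on the TF tree by bootstrapped Mk reconstruction.

Each ortholog group's regulatory history is modeled as a three-state discrete
character on the TF phylogeny: s0 (present, not regulated), s1 (present,
regulated) and sa (ortholog absent).  Because the per-species evidence is
itself probabilistic, leaf states are not fixed: each bootstrap replicate
samples s1 with probability equal to the species' posterior of regulation (sa
deterministically where the group has no member), reconstructs marginal
ancestral state probabilities under an equal-rates continuous-time Markov
model (pruning algorithm, uniform root prior), and the replicate marginals
are averaged into ancestral posterior probabilities of regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import TreeNode

from .errors import InputError

STATES = ("s0", "s1", "sa")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_N_STATES = 3
_ROOT_PRIOR = np.full(_N_STATES, 1.0 / _N_STATES)

#: Fixed transition rate used when per-replicate rate optimization fails.
FALLBACK_RATE = 1.0
DEFAULT_N_REPLICATES = 100


@dataclass(frozen=True)
class AncestralReport:
    group_id: str
    node_probabilities: dict[str, np.ndarray]  # node id -> P(s0), P(s1), P(sa)
    n_replicates: int
    seed: int


def transition_matrix(rate: float, t: float) -> np.ndarray:
    """Equal-rates 3-state CTMC transition probabilities over branch length t.

    P(same) = 1/3 + 2/3 exp(-3rt); P(different) = 1/3 - 1/3 exp(-3rt).
    As t -> 0 this tends to the identity, so zero-length branches copy states.
    """
    e = np.exp(-_N_STATES * rate * t)
    same = (1.0 + (_N_STATES - 1) * e) / _N_STATES
    diff = (1.0 - e) / _N_STATES
    return np.full((_N_STATES, _N_STATES), diff) + np.eye(_N_STATES) * (same - diff)


def sample_leaf_states(
    leaf_posteriors: dict[str, Optional[float]],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Draw one leaf-state assignment: s1 with probability p, s0 otherwise,
    and sa deterministically where the species lacks an ortholog (p is None)."""
    states = {}
    for leaf, p in leaf_posteriors.items():
        if p is None:
            states[leaf] = "sa"
        else:
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{leaf}: posterior {p} outside [0,1]")
            states[leaf] = "s1" if rng.random() < p else "s0"
    return states


def _branch_length(node: TreeNode) -> float:
    return float(node.length) if node.length is not None else 0.0


def _down_pass(tree: TreeNode, states: dict[str, str], rate: float):
    """Felsenstein pruning: partial likelihood of each subtree per state."""
    partials: dict[int, np.ndarray] = {}
    messages: dict[int, np.ndarray] = {}  # P(t_child) @ L_child, keyed by child
    for node in tree.postorder():
        if node.is_tip():
            if node.name not in states:
                raise InputError(f"leaf {node.name!r} has no assigned state")
            L = np.zeros(_N_STATES)
            L[_STATE_INDEX[states[node.name]]] = 1.0
        else:
            L = np.ones(_N_STATES)
            for child in node.children:
                msg = transition_matrix(rate, _branch_length(child)) @ partials[id(child)]
                messages[id(child)] = msg
                L = L * msg
        partials[id(node)] = L
    return partials, messages


def log_likelihood(tree: TreeNode, states: dict[str, str], rate: float) -> float:
    partials, _ = _down_pass(tree, states, rate)
    lik = float(_ROOT_PRIOR @ partials[id(tree)])
    return np.log(lik) if lik > 0 else -np.inf


def mk_ancestral_marginals(
    tree: TreeNode, states: dict[str, str], rate: float
) -> dict[str, np.ndarray]:
    """Marginal posterior of each state at every internal node.

    Down pass (pruning) plus an outside pass: with O_root = the uniform root
    prior and, for a child c of v, O_c(x) = sum_y P_c(x,y) O_v(y)
    prod_{siblings j} msg_j(y), the marginal at node v is proportional to
    L_v(x) O_v(x).
    """
    if rate <= 0:
        raise InputError("rate must be positive")
    partials, messages = _down_pass(tree, states, rate)
    outside: dict[int, np.ndarray] = {id(tree): _ROOT_PRIOR.copy()}
    marginals: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        O = outside[id(node)]
        if not node.is_tip():
            post = partials[id(node)] * O
            total = post.sum()
            if total <= 0:
                # conflicting states over zero-length branches: fall back to prior
                post = _ROOT_PRIOR.copy()
                total = 1.0
            marginals[node.name] = post / total
            for child in node.children:
                sib = np.ones(_N_STATES)
                for other in node.children:
                    if other is not child:
                        sib = sib * messages[id(other)]
                P = transition_matrix(rate, _branch_length(child))
                outside[id(child)] = P.T @ (O * sib)
    return marginals


def estimate_rate(
    tree: TreeNode,
    states: dict[str, str],
    bounds: tuple[float, float] = (1e-3, 100.0),
    xatol: float = 1e-4,
) -> float:
    """Per-replicate transition-rate MLE: coarse log-grid scan, then bounded
    scalar refinement (the likelihood is flat at high rates, so a pure local
    search can stall on the plateau)."""

    def objective(r: float) -> float:
        return -log_likelihood(tree, states, r)

    grid = np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), 25)
    vals = np.array([objective(r) for r in grid])
    if not np.isfinite(vals).any():
        return FALLBACK_RATE
    i = int(np.nanargmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    if not res.success or not np.isfinite(res.fun) or res.fun > vals[i]:
        return float(grid[i])
    return float(res.x)


def bootstrap_ancestral_regulation(
    tree: TreeNode,
    group_id: str,
    leaf_posteriors: dict[str, Optional[float]],
    n_replicates: int = DEFAULT_N_REPLICATES,
    rng_seed: int = 0,
) -> AncestralReport:
    """Average ancestral state marginals over bootstrap replicates of the leaf
    states; bit-identical for identical seeds."""
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    leaves = {t.name for t in tree.tips()}
    if leaves != set(leaf_posteriors):
        raise InputError(
            f"leaf posteriors {sorted(leaf_posteriors)} do not match tree leaves {sorted(leaves)}"
        )
    rng = np.random.default_rng(rng_seed)
    sums: dict[str, np.ndarray] = {}
    leaf_order = sorted(leaves)
    # distinct leaf-state patterns recur across replicates; reconstruct each once
    cache: dict[tuple[str, ...], dict[str, np.ndarray]] = {}
    for _ in range(n_replicates):
        states = sample_leaf_states(leaf_posteriors, rng)
        key = tuple(states[leaf] for leaf in leaf_order)
        marginals = cache.get(key)
        if marginals is None:
            rate = estimate_rate(tree, states)
            marginals = mk_ancestral_marginals(tree, states, rate)
            cache[key] = marginals
        for node, probs in marginals.items():
            sums[node] = sums.get(node, 0.0) + probs
    averaged = {node: probs / n_replicates for node, probs in sums.items()}
    return AncestralReport(group_id, averaged, n_replicates, rng_seed)
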
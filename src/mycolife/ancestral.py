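"""Wagner-parsimony reconstruction of ancestral gene-family copy numbers.

Copy numbers are integer character states on a rooted species tree.  A
change from parent state ``a`` to child state ``b`` along a branch costs
``gain_cost * max(0, b - a) + loss_cost * max(0, a - b)``; the
reconstruction minimizes the total cost over all branches (Sankoff
dynamic programming with linear asymmetric costs).  Ties are broken by
choosing the smallest state at every choice point, applied root-down, so
results are deterministic.

Under linear costs an optimal ancestral state never exceeds the maximum
observed tip count of the family, so the DP state space is capped there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneFamilyMatrix, Phylogeny


@dataclass
class AncestralReconstruction:
    """Per-node inferred copy numbers and per-branch changes.

    ``states`` has one row per tree node (preorder, internal + tips) and
    one column per family.  ``branch_changes`` has one row per non-root
    node (the branch above it) holding child - parent signed changes.
    """

    states: pd.DataFrame
    branch_changes: pd.DataFrame
    family_costs: pd.Series
    gain_cost: float
    loss_cost: float

    @property
    def total_cost(self) -> float:
        return float(self.family_costs.sum())

    def internal_states(self, internal_names: list[str]) -> pd.DataFrame:
        return self.states.loc[internal_names]


def _min_plus_linear(child_cost: np.ndarray, gain_cost: float,
                     loss_cost: float) -> np.ndarray:
    """min over child states b of trans(s, b) + child_cost[b], all s.

    Linear costs decompose the min-plus product into a suffix minimum of
    child_cost[b] - gain_cost*b and a prefix minimum of
    child_cost[b] + loss_cost*b, so the step is O(S) per family instead
    of O(S^2).
    """
    states = np.arange(child_cost.shape[0], dtype=float)[:, None]
    # child above parent: g*(b-s); child below parent: l*(s-b)
    up = child_cost + gain_cost * states
    suffix = np.minimum.accumulate(up[::-1], axis=0)[::-1]
    down = child_cost - loss_cost * states
    prefix = np.minimum.accumulate(down, axis=0)
    return np.minimum(suffix - gain_cost * states,
                      prefix + loss_cost * states)


def wagner_reconstruct(tree: Phylogeny, matrix: GeneFamilyMatrix,
                       gain_cost: float = 1.0, loss_cost: float = 1.0,
                       max_state: int | None = None) -> AncestralReconstruction:
    """Reconstruct ancestral copy numbers for every family on the tree.

    Parameters
    ----------
    gain_cost, loss_cost:
        Per-copy penalties for gains and losses (both > 0).  The default
        1/1 is the neutral symmetric setting; an asymmetric gain penalty
        can be emulated by raising ``gain_cost``.
    max_state:
        Cap of the integer state space.  ``None`` caps each family at its
        maximum observed tip count, which is sufficient for optimality
        under linear costs.
    """
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("gain_cost and loss_cost must be positive")
    tips = set(tree.tip_names)
    missing = tips - set(matrix.genome_ids)
    if missing:
        raise ValueError(f"tips missing from matrix: {sorted(missing)[:5]}")

    counts = matrix.counts.loc[list(tree.tip_names)]
    x = counts.to_numpy()
    n_fam = x.shape[1]
    caps = x.max(axis=0)
    if max_state is not None:
        caps = np.minimum(np.maximum(caps, 0), max_state)
        if (x > max_state).any():
            raise ValueError("max_state below an observed tip count")
    smax = int(caps.max()) if n_fam else 0
    tip_idx = {name: i for i, name in enumerate(counts.index)}
    state_mask = np.arange(smax + 1)[:, None] > caps[None, :]  # states above cap

    # down-pass: minimal subtree cost per node per state per family
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder_nodes():
        if node.is_leaf():
            obs = x[tip_idx[node.taxon.label]]
            c = np.full((smax + 1, n_fam), np.inf)
            c[obs, np.arange(n_fam)] = 0.0
        else:
            c = np.zeros((smax + 1, n_fam))
            for child in node.child_nodes():
                c += _min_plus_linear(cost[id(child)], gain_cost, loss_cost)
            c[state_mask] = np.inf
        cost[id(node)] = c

    # up-pass: root argmin, then per-branch argmin given the parent state
    nodes = tree.preorder_nodes()
    node_names = [Phylogeny.node_name(n) for n in nodes]
    states = np.zeros((len(nodes), n_fam), dtype=int)
    pos = {id(n): i for i, n in enumerate(nodes)}

    root = nodes[0]
    root_cost = cost[id(root)]
    family_costs = root_cost.min(axis=0)
    states[0] = root_cost.argmin(axis=0)  # argmin -> smallest state on ties
    state_col = np.arange(smax + 1, dtype=float)[:, None]
    for node in nodes:
        parent_states = states[pos[id(node)]][None, :]
        for child in node.child_nodes():
            cc = cost[id(child)]
            trans_vals = (gain_cost * np.maximum(0, state_col - parent_states)
                          + loss_cost * np.maximum(0, parent_states - state_col))
            # argmin picks the smallest optimal child state (tie-break)
            states[pos[id(child)]] = (trans_vals + cc).argmin(axis=0)

    states_df = pd.DataFrame(states, index=node_names, columns=counts.columns)
    changes = []
    change_index = []
    for node in nodes[1:]:
        p = states[pos[id(node.parent_node)]]
        c = states[pos[id(node)]]
        changes.append(c - p)
        change_index.append(Phylogeny.node_name(node))
    branch_changes = pd.DataFrame(
        np.array(changes, dtype=int) if changes else np.zeros((0, n_fam), int),
        index=pd.Index(change_index, name="child"), columns=counts.columns)
    return AncestralReconstruction(
        states=states_df, branch_changes=branch_changes,
        family_costs=pd.Series(family_costs, index=counts.columns),
        gain_cost=gain_cost, loss_cost=loss_cost)


def branch_events(recon: AncestralReconstruction) -> pd.DataFrame:
    """Per-branch counts of gained and lost families.

    A family counts as a gain on a branch when its inferred copy number
    strictly increases from parent to child, a loss when it strictly
    decreases; ``net = n_gains - n_losses`` is the statistic that scales
    branch widths in ancestral-genome plots.
    """
    ch = recon.branch_changes.to_numpy()
    n_gains = (ch > 0).sum(axis=1)
    n_losses = (ch < 0).sum(axis=1)
    return pd.DataFrame(
        {"n_gains": n_gains, "n_losses": n_losses, "net": n_gains - n_losses},
        index=recon.branch_changes.index)


def brute_force_cost(tree: Phylogeny, tip_counts: dict[str, int],
                     gain_cost: float = 1.0, loss_cost: float = 1.0,
                     max_state: int | None = None) -> float:
    """Minimal parsimony cost by exhaustive enumeration (test oracle).

    Only feasible for tiny instances (<= 7 internal nodes, small state
    caps); raises for anything larger.
    """
    internals = [n for n in tree.preorder_nodes() if not n.is_leaf()]
    if max_state is None:
        max_state = max(tip_counts.values())
    if len(internals) > 7 or max_state > 6:
        raise ValueError("instance too large for brute force")
    branches = []
    for node in tree.preorder_nodes():
        if node.parent_node is not None:
            branches.append((node.parent_node, node))

    def node_state(assign, node):
        if node.is_leaf():
            return tip_counts[node.taxon.label]
        return assign[id(node)]

    best = np.inf
    for combo in itertools.product(range(max_state + 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        total = 0.0
        for parent, child in branches:
            a, b = node_state(assign, parent), node_state(assign, child)
            total += gain_cost * max(0, b - a) + loss_cost * max(0, a - b)
        best = min(best, total)
    return float(best)
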
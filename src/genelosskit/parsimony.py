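"""Dollo parsimony mapping of irreversible gene-inactivation events.

The character model: the gene is functional at the root; along any branch
it may be lost (inactivated) at most once, and a loss is never regained.
Given per-tip functional states, the minimum set of loss edges is the set
of stems of the maximal clades that contain at least one nonfunctional
tip and no functional tip — computable by one post-order pass. Tips whose
state is unknown (gene possibly in an assembly gap) are unconstrained and
may be absorbed into a loss clade for free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import dendropy


class TipState(str, Enum):
    FUNCTIONAL = "FUNCTIONAL"
    NONFUNCTIONAL = "NONFUNCTIONAL"
    MISSING = "MISSING"


class StructuralError(ValueError):
    """Malformed tree or inconsistent tip-state map."""


class SizeError(ValueError):
    """Tree too large for exhaustive search."""


@dataclass(frozen=True)
class EventPlacement:
    """A set of loss edges, identified by the tip sets below them."""

    loss_edges: frozenset[frozenset[str]]

    @property
    def n_events(self) -> int:
        return len(self.loss_edges)


def _tip_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    if node.label is not None:
        return node.label
    raise StructuralError("unlabeled tip in species tree")


def _check_states(tree: dendropy.Tree,
                  states: dict[str, TipState]) -> dict[str, TipState]:
    tips = [_tip_label(leaf) for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise StructuralError("duplicate tip labels in species tree")
    full = {}
    for tip in tips:
        state = states.get(tip, TipState.MISSING)
        full[tip] = TipState(state)
    unknown = set(states) - set(tips)
    if unknown:
        raise StructuralError(f"states given for unknown tips: {sorted(unknown)}")
    return full


def dollo_min_events(tree: dendropy.Tree,
                     states: dict[str, TipState]) -> EventPlacement:
    """Minimum-cardinality loss-edge set under the Dollo model.

    Post-order pass computes, per node, whether its clade holds any
    FUNCTIONAL and any NONFUNCTIONAL tip. A loss edge is placed above
    every maximal node whose clade has a nonfunctional tip and no
    functional tip. Tips absent from ``states`` are treated as MISSING.
    """
    full = _check_states(tree, states)
    has_func: dict[dendropy.Node, bool] = {}
    has_nonf: dict[dendropy.Node, bool] = {}
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _tip_label(node)
            has_func[node] = full[label] == TipState.FUNCTIONAL
            has_nonf[node] = full[label] == TipState.NONFUNCTIONAL
            below[node] = frozenset([label])
        else:
            kids = node.child_nodes()
            has_func[node] = any(has_func[k] for k in kids)
            has_nonf[node] = any(has_nonf[k] for k in kids)
            below[node] = frozenset().union(*(below[k] for k in kids))
    root = tree.seed_node
    losses = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        clean = not has_func[node]
        # The root is FUNCTIONAL by model assumption, so a clean clade
        # hanging directly off the root still needs its own loss edge even
        # when no functional tip exists anywhere.
        parent_clean = parent is not root and not has_func[parent]
        if clean and has_nonf[node] and not parent_clean:
            losses.append(below[node])
    return EventPlacement(loss_edges=frozenset(losses))


def _candidate_edges(tree: dendropy.Tree,
                     full: dict[str, TipState]) -> list[frozenset[str]]:
    """Edges that could carry a loss in some minimal solution: clades with
    at least one NONFUNCTIONAL tip and no FUNCTIONAL tip."""
    candidates = []
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        tips = [_tip_label(leaf) for leaf in node.leaf_iter()]
        if any(full[t] == TipState.FUNCTIONAL for t in tips):
            continue
        if any(full[t] == TipState.NONFUNCTIONAL for t in tips):
            candidates.append(frozenset(tips))
    return candidates


def brute_force_min_events(
    tree: dendropy.Tree,
    states: dict[str, TipState],
    max_candidates: int = 26,
) -> EventPlacement:
    """Exhaustive-search oracle for :func:`dollo_min_events`.

    Enumerates subsets of candidate loss edges in increasing cardinality
    and returns the first subset under which every NONFUNCTIONAL tip
    descends from exactly one chosen edge. The search space is capped by
    the number of candidate edges rather than the tip count, so it also
    runs on large trees whose nonfunctional tips are clustered.
    """
    full = _check_states(tree, states)
    candidates = _candidate_edges(tree, full)
    if len(candidates) > max_candidates:
        raise SizeError(
            f"tree too large: {len(candidates)} candidate loss edges "
            f"(cap {max_candidates})")
    nonf = [t for t, s in full.items() if s == TipState.NONFUNCTIONAL]
    if not nonf:
        return EventPlacement(loss_edges=frozenset())
    for k in range(1, len(nonf) + 1):
        for combo in itertools.combinations(candidates, k):
            if all(sum(tip in edge for edge in combo) == 1 for tip in nonf):
                return EventPlacement(loss_edges=frozenset(combo))
    raise StructuralError("no feasible loss placement found")  # unreachable


def fitch_min_changes(tree: dendropy.Tree,
                      states: dict[str, TipState]) -> int:
    """Diagnostic: unordered (reversible) Fitch parsimony change count for
    the binary functional/nonfunctional character; MISSING tips carry the
    full state set."""
    full = _check_states(tree, states)
    changes = 0
    sets: dict[dendropy.Node, frozenset[str]] = {}
    both = frozenset({"F", "N"})
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = full[_tip_label(node)]
            sets[node] = (frozenset({"F"}) if state == TipState.FUNCTIONAL
                          else frozenset({"N"})
                          if state == TipState.NONFUNCTIONAL else both)
        else:
            kid_sets = [sets[k] for k in node.child_nodes()]
            inter = frozenset.intersection(*kid_sets)
            if inter:
                sets[node] = inter
            else:
                sets[node] = frozenset.union(*kid_sets)
                changes += 1
    return changes


LOSS_COMMENT = "psi=loss"


def annotate_tree(tree: dendropy.Tree, placement: EventPlacement) -> str:
    """Decorated Newick with a comment marking each loss edge.

    Each loss edge is identified by its descendant tip set; the annotated
    node gets a ``[&psi=loss]`` comment. Unknown edges raise ValueError.
    """
    tree = tree.clone(depth=1)
    below: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        tips = frozenset(_tip_label(leaf) for leaf in node.leaf_iter())
        if node is not tree.seed_node:
            below[tips] = node
    for edge_tips in placement.loss_edges:
        if edge_tips not in below:
            raise ValueError(f"loss edge {sorted(edge_tips)} not in tree")
        below[edge_tips].comments.append(LOSS_COMMENT)
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True,
                          suppress_item_comments=False).strip()
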
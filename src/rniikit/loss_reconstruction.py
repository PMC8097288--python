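"""Parsimony reconstruction of the binary active-site character on a tree.

Two reconstructions are offered for tips labelled active/inactive:

* **Fitch/Sankoff parsimony** — unordered binary character, minimum number
  of state changes over all ancestral assignments, with an ambiguity flag
  when several most-parsimonious assignments exist.
* **Dollo parsimony** (default) — loss is irreversible and the root is
  constrained active (the ancestral enzyme was a nuclease), so the minimum
  explanation is one loss event on the stem edge of each *maximal* clade
  whose tips are all inactive. The number of such clades is the number of
  independent losses.

Trees are dendropy objects; tip labels must match sequence ids. Polytomies
are allowed: several all-inactive children of a polytomy count one loss
each, matching minimal-event semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

ACTIVE = "active"
INACTIVE = "inactive"
_STATES = (ACTIVE, INACTIVE)
_INF = float("inf")

#: parent name used for a loss on the root's own (stem) edge
ROOT_EDGE = "ROOT"


class ReconstructionError(ValueError):
    """Raised for invalid trees, states, or id mismatches."""


@dataclass
class LossReport:
    reconstruction_mode: str  # "fitch" | "dollo"
    min_changes: int
    loss_edges: list[tuple[str, str]]  # (parent name, child name)
    n_independent_losses: int
    ambiguous: bool
    node_states: dict[str, str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"parent": p, "child": c, "event": "loss"} for p, c in self.loss_edges
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "event"])


# ---------------------------------------------------------------------------
# tree helpers
# ---------------------------------------------------------------------------

def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _ensure_names(tree: dendropy.Tree) -> None:
    """Give every unlabelled internal node a stable preorder name."""
    i = 0
    for node in tree.preorder_node_iter():
        if not node_name(node):
            node.label = f"node{i}"
        i += 1


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [node_name(leaf) for leaf in tree.leaf_node_iter()]


def _check_rooted(tree: dendropy.Tree) -> None:
    root = tree.seed_node
    if not tree.is_rooted and len(root.child_nodes()) > 2:
        raise ReconstructionError(
            "tree is unrooted; root it (e.g. with root_on_outgroup) first"
        )


def _check_states(tree: dendropy.Tree, states: Mapping[str, str]) -> None:
    tips = set(tip_labels(tree))
    missing = tips - set(states)
    extra = set(states) - tips
    if missing or extra:
        raise ReconstructionError(
            f"tip/state mismatch; tips without state: {sorted(missing)}, "
            f"states without tip: {sorted(extra)}"
        )
    bad = {k: v for k, v in states.items() if v not in _STATES}
    if bad:
        raise ReconstructionError(f"states must be in {_STATES}; got {bad}")


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_on_outgroup(
    tree: dendropy.Tree, outgroup_tips: Iterable[str]
) -> dendropy.Tree:
    """Root a tree on the edge separating the outgroup from the ingroup.

    The outgroup must be monophyletic in some rooting of the input;
    otherwise an error names the conflicting tips. The input tree is not
    modified.
    """
    outgroup = set(outgroup_tips)
    tree = tree.clone(depth=1)
    tips = tip_labels(tree)
    unknown = outgroup - set(tips)
    if unknown:
        raise ReconstructionError(f"outgroup tips not in tree: {sorted(unknown)}")
    if not outgroup or outgroup == set(tips):
        raise ReconstructionError("outgroup must be a proper nonempty subset of tips")

    # reroot provisionally at an ingroup tip so the outgroup cannot span the
    # root, then find the minimal node covering the outgroup
    ingroup_leaf = next(
        leaf for leaf in tree.leaf_node_iter() if node_name(leaf) not in outgroup
    )
    tree.reroot_at_edge(ingroup_leaf.edge, update_bipartitions=False)
    leaves_by_name = {node_name(leaf): leaf for leaf in tree.leaf_node_iter()}
    node = leaves_by_name[next(iter(sorted(outgroup)))]
    covered = {node_name(node)}
    while covered < outgroup:
        node = node.parent_node
        covered = {node_name(l) for l in node.leaf_iter()}
    if covered != outgroup:
        raise ReconstructionError(
            "outgroup is not monophyletic; smallest covering clade also "
            f"contains {sorted(covered - outgroup)}"
        )
    length = node.edge.length
    halves = (length / 2.0, length / 2.0) if length is not None else (None, None)
    tree.reroot_at_edge(node.edge, length1=halves[0], length2=halves[1],
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Fitch (Sankoff) parsimony
# ---------------------------------------------------------------------------

def fitch_reconstruct(tree: dendropy.Tree, states: Mapping[str, str]) -> LossReport:
    """Minimum-change reconstruction of the binary character.

    Reports one most-parsimonious ancestral assignment (ties resolved
    toward ``active``), the active→inactive edges of that assignment, and
    ``ambiguous=True`` when some node takes different states in different
    most-parsimonious assignments.
    """
    _check_rooted(tree)
    _check_states(tree, states)
    _ensure_names(tree)

    up: dict[dendropy.Node, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node_name(node)]
            up[node] = (0.0 if s == ACTIVE else _INF,
                        0.0 if s == INACTIVE else _INF)
        else:
            costs = [0.0, 0.0]
            for child in node.child_nodes():
                c0, c1 = up[child]
                costs[0] += min(c0, c1 + 1)
                costs[1] += min(c1, c0 + 1)
            up[node] = (costs[0], costs[1])

    root = tree.seed_node
    min_changes = int(min(up[root]))

    # one most-parsimonious assignment, ties toward 'active'
    assign: dict[dendropy.Node, int] = {}
    assign[root] = 0 if up[root][0] <= up[root][1] else 1
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = assign[node.parent_node]
        c = up[node]
        same, flip = c[p], c[1 - p] + 1
        assign[node] = p if same <= flip else 1 - p

    # in-out pass: total[v][s] = best tree score with v forced to state s;
    # a node is ambiguous when both states achieve the optimum
    out: dict[dendropy.Node, tuple[float, float]] = {root: (0.0, 0.0)}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            vals = []
            for t in (0, 1):
                best = _INF
                for s in (0, 1):
                    rest = out[node][s]
                    for other in node.child_nodes():
                        if other is child:
                            continue
                        oc = up[other]
                        rest += min(oc[0] + (0 != s), oc[1] + (1 != s))
                    best = min(best, rest + (t != s))
                vals.append(best)
            out[child] = (vals[0], vals[1])

    ambiguous = False
    for node in tree.preorder_node_iter():
        totals = [up[node][s] + out[node][s] for s in (0, 1)]
        if totals[0] == totals[1] == min_changes:
            ambiguous = True
            break

    loss_edges = []
    node_states = {}
    for node in tree.preorder_node_iter():
        node_states[node_name(node)] = _STATES[assign[node]]
        if node is not root and assign[node.parent_node] == 0 and assign[node] == 1:
            loss_edges.append((node_name(node.parent_node), node_name(node)))

    return LossReport(
        reconstruction_mode="fitch",
        min_changes=min_changes,
        loss_edges=loss_edges,
        n_independent_losses=len(loss_edges),
        ambiguous=ambiguous,
        node_states=node_states,
    )


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

def dollo_losses(tree: dendropy.Tree, states: Mapping[str, str]) -> LossReport:
    """Minimum irreversible-loss reconstruction with the root held active.

    Loss edges are the stem edges of maximal all-inactive clades. If every
    tip is inactive the single loss sits on the root's own edge (parent
    reported as :data:`ROOT_EDGE`).
    """
    _check_rooted(tree)
    _check_states(tree, states)
    _ensure_names(tree)

    all_inactive: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            all_inactive[node] = states[node_name(node)] == INACTIVE
        else:
            all_inactive[node] = all(all_inactive[c] for c in node.child_nodes())

    root = tree.seed_node
    loss_edges: list[tuple[str, str]] = []
    node_states: dict[str, str] = {}
    if all_inactive[root]:
        loss_edges.append((ROOT_EDGE, node_name(root)))
        for node in tree.preorder_node_iter():
            node_states[node_name(node)] = INACTIVE
    else:
        for node in tree.preorder_node_iter():
            if node is root:
                node_states[node_name(node)] = ACTIVE
                continue
            if all_inactive[node] and not all_inactive[node.parent_node]:
                loss_edges.append((node_name(node.parent_node), node_name(node)))
            node_states[node_name(node)] = (
                INACTIVE if all_inactive[node] else ACTIVE
            )

    return LossReport(
        reconstruction_mode="dollo",
        min_changes=len(loss_edges),
        loss_edges=loss_edges,
        n_independent_losses=len(loss_edges),
        ambiguous=False,
        node_states=node_states,
    )


# ---------------------------------------------------------------------------
# feature-table composition
# ---------------------------------------------------------------------------

def states_from_features(features: pd.DataFrame) -> dict[str, str]:
    """Binary active/inactive states from a feature table's active_site column."""
    return {
        str(row["id"]): (ACTIVE if bool(row["active_site"]) else INACTIVE)
        for _, row in features.iterrows()
    }


def map_losses(
    tree: dendropy.Tree,
    features: pd.DataFrame,
    mode: str = "dollo",
) -> tuple[LossReport, dendropy.Tree]:
    """Reconstruct losses from a feature table and annotate the tree.

    Returns the report and a copy of the tree in which loss-edge child
    nodes carry a ``loss`` annotation (written as a Newick comment when the
    tree is serialised with annotations enabled).
    """
    tip_ids = set(tip_labels(tree))
    table_ids = set(features["id"].astype(str))
    if tip_ids != table_ids:
        raise ReconstructionError(
            "tree tips and feature-table ids differ; only in tree: "
            f"{sorted(tip_ids - table_ids)}, only in table: "
            f"{sorted(table_ids - tip_ids)}"
        )
    states = states_from_features(features)
    if mode == "dollo":
        report = dollo_losses(tree, states)
    elif mode == "fitch":
        report = fitch_reconstruct(tree, states)
    else:
        raise ReconstructionError(f"unknown reconstruction mode {mode!r}")

    annotated = tree.clone(depth=1)
    _ensure_names(annotated)
    loss_children = {child for _, child in report.loss_edges}
    for node in annotated.preorder_node_iter():
        if node_name(node) in loss_children:
            node.annotations.add_new("loss", "true")
    return report, annotated
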
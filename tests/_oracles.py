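"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and
character-by-character checks — and shares no logic with the package
implementations it validates.
"""

from __future__ import annotations

import itertools

import dendropy

# ---------------------------------------------------------------------------
# trees: all rooted binary tree shapes, and brute-force parsimony
# ---------------------------------------------------------------------------


def tree_shapes(n: int):
    """All rooted binary tree shapes with n tips, as nested tuples.

    A tip is the integer 0; an internal node is a pair (left, right).
    Shapes are deduplicated up to left/right swaps.
    """
    if n == 1:
        return [0]
    shapes = set()
    for i in range(1, n // 2 + 1):
        for left in tree_shapes(i):
            for right in tree_shapes(n - i):
                a, b = sorted((left, right), key=repr)
                shapes.add((a, b))
    return sorted(shapes, key=repr)


def shape_to_tree(shape, labels: list[str]) -> dendropy.Tree:
    """Materialise a shape as a dendropy tree, labelling tips left-to-right."""
    tree = dendropy.Tree()
    tree.is_rooted = True
    it = iter(labels)

    def build(node, sub):
        if sub == 0:
            node.taxon = tree.taxon_namespace.new_taxon(label=next(it))
        else:
            build(node.new_child(edge_length=1.0), sub[0])
            build(node.new_child(edge_length=1.0), sub[1])

    build(tree.seed_node, shape)
    return tree


def _edges(tree: dendropy.Tree):
    return [
        (node.parent_node, node)
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]


def brute_force_min_changes(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Parsimony minimum by enumerating every ancestral assignment."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    fixed = {
        n: states[n.taxon.label] for n in tree.leaf_node_iter()
    }
    best = None
    for combo in itertools.product(("active", "inactive"), repeat=len(internals)):
        assign = dict(fixed)
        assign.update(dict(zip(internals, combo)))
        changes = sum(1 for p, c in _edges(tree) if assign[p] != assign[c])
        best = changes if best is None else min(best, changes)
    return best


def brute_force_dollo(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimum irreversible losses: enumerate assignments with the root
    active and no inactive->active edge; count active->inactive edges.
    An all-inactive assignment still needs one loss above the root."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    fixed = {n: states[n.taxon.label] for n in tree.leaf_node_iter()}
    root = tree.seed_node
    best = None
    for combo in itertools.product(("active", "inactive"), repeat=len(internals)):
        assign = dict(fixed)
        assign.update(dict(zip(internals, combo)))
        losses = 0
        valid = True
        for p, c in _edges(tree):
            if assign[p] == "inactive" and assign[c] == "active":
                valid = False
                break
            if assign[p] == "active" and assign[c] == "inactive":
                losses += 1
        if not valid:
            continue
        if assign[root] == "inactive":
            losses += 1  # loss on the root's own edge (root constrained active)
        best = losses if best is None else min(best, losses)
    return best


# ---------------------------------------------------------------------------
# motifs: regex-free sliding-window scanners with explicit conditionals
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def naive_cbk1_phospho(seq: str, central_positions=(2, 3)) -> list[int]:
    """1-based starts of Hxxxx[ST] with K/R among the given 0-based
    window offsets (defaults: the middle two wildcards)."""
    out = []
    for i in range(len(seq) - 5):
        w = seq[i:i + 6]
        if w[0] != "H":
            continue
        if w[5] not in ("S", "T"):
            continue
        if any(c not in _AA for c in w[1:5]):
            continue
        if not any(w[p] in ("K", "R") for p in central_positions):
            continue
        out.append(i + 1)
    return out


def naive_cbk1_docking(seq: str) -> list[int]:
    out = []
    for i in range(len(seq) - 2):
        w = seq[i:i + 3]
        if w[0] in ("Y", "F") and w[1] in _AA and w[2] in ("F", "P"):
            out.append(i + 1)
    return out


def naive_active_site(seq: str) -> list[int]:
    out = []
    for i in range(len(seq) - 9):
        w = seq[i:i + 10]
        if w[0] == "D" and w[6] == "D" and w[8] == "D" and w[9] == "D":
            if all(c in _AA for c in (w[1], w[2], w[3], w[4], w[5], w[7])):
                out.append(i + 1)
    return out


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def enumerate_residue_columns(aligned_row: str) -> dict[int, int]:
    """Residue->column map by listing non-gap positions."""
    cols = [i + 1 for i, c in enumerate(aligned_row) if c != "-"]
    return {r + 1: c for r, c in enumerate(cols)}


def column_walk_identity(row_a: str, row_b: str) -> float | None:
    """Percent identity over co-ungapped columns, walked one by one."""
    matches = 0
    total = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        total += 1
        if a == b and a != "X":
            matches += 1
    if total == 0:
        return None
    return 100.0 * matches / total


def kept_columns_by_counting(rows: list[str], threshold: float) -> list[int]:
    n = len(rows)
    kept = []
    for col in range(len(rows[0])):
        non_gap = sum(1 for r in rows if r[col] != "-")
        if non_gap / n >= threshold:
            kept.append(col + 1)
    return kept
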
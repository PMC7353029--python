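"""Per-patient parsimony trees from the binary presence matrix.

The germline (all-absent state vector, leaf label ``GL``) roots the tree.
All rooted binary topologies over the tumor leaves are enumerated
exhaustively (bounded at 8 leaves: 135135 topologies) and scored by Fitch
parsimony on the binary characters; ties are broken by the
lexicographically smallest topology-only Newick string. Edge lengths
count the characters whose state change is assigned to that edge under a
rootward-accelerated minimum-cost assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io_model import PresenceMatrix

__all__ = ["TumorTree", "build_tree", "to_newick", "fitch_score"]

MAX_LEAVES = 8

GERMLINE_LABEL = "GL"


@dataclass(frozen=True)
class _Node:
    """Immutable rooted-subtree node; leaf iff children is empty."""

    label: str = ""
    children: tuple["_Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        out: tuple[str, ...] = ()
        for ch in self.children:
            out += ch.leaves()
        return out


@dataclass
class TumorTree:
    patient_id: str
    root: _Node  # root's children: tumor subtree + GL leaf
    score: int
    edge_lengths: dict[tuple[str, ...], int]  # clade leafset -> length of edge above it
    edge_characters: dict[tuple[str, ...], list[tuple]]  # clade -> variant keys gained

    @property
    def trunk_length(self) -> int:
        tumor_leaves = tuple(
            sorted(l for l in self.root.leaves() if l != GERMLINE_LABEL)
        )
        return self.edge_lengths.get(tumor_leaves, 0)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": self.patient_id,
                "clade": ",".join(clade),
                "length": self.edge_lengths[clade],
                "variants": ";".join("{}:{}:{}>{}".format(*k) for k in chars),
            }
            for clade, chars in sorted(self.edge_characters.items())
            if self.edge_lengths[clade] or chars
        ]
        return pd.DataFrame(rows, columns=["patient_id", "clade", "length", "variants"])


def _rooted_topologies(leaves: Sequence[str]) -> Iterator[_Node]:
    """All rooted binary topologies on the given leaves (1, 1, 3, 15, ...)."""
    leaves = sorted(leaves)
    if len(leaves) == 1:
        yield _Node(label=leaves[0])
        return
    first, rest = leaves[0], leaves[1:]
    # Assign each non-first leaf to the left (with `first`) or right block;
    # recursing over splits enumerates every topology exactly once.
    n = len(rest)
    for mask in range(2**n):
        left = [first] + [rest[i] for i in range(n) if mask >> i & 1]
        right = [rest[i] for i in range(n) if not mask >> i & 1]
        if not right:
            continue
        for lt in _rooted_topologies(left):
            for rt in _rooted_topologies(right):
                yield _Node(children=_order_children(lt, rt))


def _order_children(a: _Node, b: _Node) -> tuple[_Node, _Node]:
    return (a, b) if min(a.leaves()) <= min(b.leaves()) else (b, a)


def _topology_newick(node: _Node) -> str:
    if node.is_leaf:
        return node.label
    return "(" + ",".join(_topology_newick(c) for c in node.children) + ")"


def fitch_score(root: _Node, states: dict[str, np.ndarray]) -> int:
    """Fitch parsimony score of a rooted tree over binary characters.

    ``states[label]`` is the 0/1 character vector of that leaf. The union
    count over all characters and internal nodes is the score; the root's
    germline child fixes the ancestral state at 0 wherever ambiguous.
    """
    score = 0

    def post(node: _Node) -> np.ndarray:
        nonlocal score
        if node.is_leaf:
            s = states[node.label]
            # bitmask per character: 1 -> {0}, 2 -> {1}
            return np.where(s > 0, 2, 1).astype(np.int8)
        sets = [post(c) for c in node.children]
        acc = sets[0]
        for other in sets[1:]:
            inter = acc & other
            union = acc | other
            disjoint = inter == 0
            score += int(disjoint.sum())
            acc = np.where(disjoint, union, inter).astype(np.int8)
        return acc

    post(root)
    return score


def _assign_changes(
    root: _Node, states: dict[str, np.ndarray]
) -> tuple[int, dict[tuple[str, ...], list[int]]]:
    """Minimum-cost state assignment per character with gains pushed
    rootward; returns (total cost, clade -> character indices changed on
    the edge above that clade)."""
    n_char = len(next(iter(states.values())))
    INF = 10**9

    cost: dict[int, np.ndarray] = {}  # id(node) -> (2, n_char) subtree cost

    def down(node: _Node) -> np.ndarray:
        if node.is_leaf:
            s = states[node.label]
            c = np.empty((2, n_char), dtype=np.int64)
            c[0] = np.where(s == 0, 0, INF)
            c[1] = np.where(s == 1, 0, INF)
        else:
            c = np.zeros((2, n_char), dtype=np.int64)
            for ch in node.children:
                cc = down(ch)
                # min over child state of (change cost + child subtree cost)
                c[0] += np.minimum(cc[0], cc[1] + 1)
                c[1] += np.minimum(cc[1], cc[0] + 1)
        cost[id(node)] = c
        return c

    down(root)

    changes: dict[tuple[str, ...], list[int]] = {}

    def up(node: _Node, parent_state: np.ndarray) -> None:
        c = cost[id(node)]
        # state s chosen to minimize change(parent->s) + subtree cost(s);
        # ties resolved toward the derived state 1 (rootward gains)
        cost_if_0 = c[0] + (parent_state != 0)
        cost_if_1 = c[1] + (parent_state != 1)
        state = np.where(cost_if_1 <= cost_if_0, 1, 0).astype(np.int8)
        changed = np.nonzero(state != parent_state)[0]
        if changed.size:
            clade = tuple(sorted(node.leaves()))
            changes.setdefault(clade, []).extend(int(i) for i in changed)
        for ch in node.children:
            up(ch, state)

    # root state = germline = all zeros
    root_state = np.zeros(n_char, dtype=np.int8)
    for ch in root.children:
        up(ch, root_state)
    total = int(np.minimum(cost[id(root)][0], cost[id(root)][1] + 1).sum())
    return total, changes


def build_tree(matrix: PresenceMatrix) -> TumorTree:
    """Exhaustive minimum-parsimony tree over the patient's biopsies."""
    leaves = list(matrix.biopsy_ids)
    if len(leaves) < 2:
        raise ValueError("need >= 2 tumor leaves")
    if len(leaves) > MAX_LEAVES:
        raise ValueError(
            f"{len(leaves)} leaves exceeds the exhaustive-search bound "
            f"({MAX_LEAVES}); use a heuristic phylogeny tool for larger inputs"
        )
    if GERMLINE_LABEL in leaves:
        raise ValueError(f"biopsy id clashes with the germline label {GERMLINE_LABEL!r}")
    states = {
        b: matrix.presence[:, j].astype(np.int8) for j, b in enumerate(leaves)
    }
    states[GERMLINE_LABEL] = np.zeros(matrix.n_variants, dtype=np.int8)

    best: tuple[int, str, _Node] | None = None
    for tumor in _rooted_topologies(leaves):
        rooted = _Node(children=_order_children(tumor, _Node(label=GERMLINE_LABEL)))
        s = fitch_score(rooted, states)
        key = _topology_newick(rooted)
        if best is None or (s, key) < (best[0], best[1]):
            best = (s, key, rooted)
    assert best is not None
    score, _, rooted = best

    total, change_idx = _assign_changes(rooted, states)
    if matrix.n_variants and total != score:  # pragma: no cover - internal check
        raise AssertionError("assignment cost disagrees with Fitch score")

    def clades(node: _Node, acc: list[tuple[str, ...]]) -> None:
        acc.append(tuple(sorted(node.leaves())))
        for ch in node.children:
            clades(ch, acc)

    all_clades: list[tuple[str, ...]] = []
    for ch in rooted.children:
        clades(ch, all_clades)
    edge_lengths = {c: 0 for c in all_clades}
    edge_chars: dict[tuple[str, ...], list[tuple]] = {c: [] for c in all_clades}
    for clade, idxs in change_idx.items():
        edge_lengths[clade] = len(idxs)
        edge_chars[clade] = [matrix.variant_keys[i] for i in idxs]

    return TumorTree(
        patient_id=matrix.patient_id,
        root=rooted,
        score=score,
        edge_lengths=edge_lengths,
        edge_characters=edge_chars,
    )


def to_newick(tree: TumorTree) -> str:
    """Deterministic Newick with mutation-count branch lengths; children
    alphabetical by smallest leaf label; germline leaf labeled GL."""

    def render(node: _Node) -> str:
        clade = tuple(sorted(node.leaves()))
        length = tree.edge_lengths.get(clade, 0)
        if node.is_leaf:
            return f"{node.label}:{length}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{length}"

    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"
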
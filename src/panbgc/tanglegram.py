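"""Tanglegram crossing statistics.

A tanglegram joins matching leaves of two trees with straight lines; the
number of line crossings is the inversion count of the permutation mapping
one leaf order onto the other. Many crossings indicate discordance between
gene-level and cluster-level histories (plasticity, possible horizontal
transfer); zero crossings, perfectly congruent orders. Leaf orders are
taken from the trees as serialized — no layout optimization — because a
deterministic, layout-faithful count is the honest statistic. A greedy
rotation pass that only accepts crossing-reducing flips is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy

from .exceptions import NoSharedLeavesError


@dataclass
class TanglegramStats:
    crossings: int
    max_possible: int
    normalized: float
    shared_leaves: int


def _inversions(perm: Sequence[int]) -> int:
    """Inversion count by merge sort, O(m log m)."""

    def sort(a: list[int]) -> tuple[list[int], int]:
        if len(a) <= 1:
            return list(a), 0
        mid = len(a) // 2
        left, nl = sort(a[:mid])
        right, nr = sort(a[mid:])
        merged: list[int] = []
        inv = nl + nr
        i = j = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                merged.append(right[j])
                inv += len(left) - i
                j += 1
        merged.extend(left[i:])
        merged.extend(right[j:])
        return merged, inv

    return sort(list(perm))[1]


def count_crossings(
    order_left: Sequence[str], order_right: Sequence[str]
) -> TanglegramStats:
    """Count label pairs whose relative order differs between two leaf
    sequences.

    Both orders must be duplicate-free; the count is taken over the
    intersection of the label sets, and leaves present on one side only
    are dropped (the intersection size is reported as ``shared_leaves``).
    """
    if len(set(order_left)) != len(order_left):
        raise ValueError("left order contains duplicate labels")
    if len(set(order_right)) != len(order_right):
        raise ValueError("right order contains duplicate labels")
    shared = set(order_left) & set(order_right)
    if not shared:
        raise NoSharedLeavesError("the two leaf orders share no labels")
    left = [lab for lab in order_left if lab in shared]
    right_pos = {lab: i for i, lab in enumerate(lab for lab in order_right if lab in shared)}
    perm = [right_pos[lab] for lab in left]
    crossings = _inversions(perm)
    m = len(shared)
    max_possible = m * (m - 1) // 2
    normalized = crossings / max_possible if max_possible else 0.0
    return TanglegramStats(
        crossings=crossings,
        max_possible=max_possible,
        normalized=normalized,
        shared_leaves=m,
    )


def leaf_order_from_newick(path: str | Path) -> list[str]:
    """Leaf labels in the order the newick serialization visits them."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]


def untangle_greedy(
    tree: dendropy.Tree, reference_order: Sequence[str], max_passes: int = 10
) -> list[str]:
    """Optional greedy rotation: flip children of internal nodes whenever
    the flip strictly reduces crossings against a fixed reference order.
    Deterministic; stops when a full pass makes no improvement."""

    def current_order() -> list[str]:
        return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]

    def score(order: list[str]) -> int:
        return count_crossings(reference_order, order).crossings

    best = score(current_order())
    for _ in range(max_passes):
        improved = False
        for node in tree.preorder_node_iter():
            children = node.child_nodes()
            if len(children) < 2:
                continue
            node.set_child_nodes(list(reversed(children)))
            trial = score(current_order())
            if trial < best:
                best = trial
                improved = True
            else:
                node.set_child_nodes(children)
        if not improved:
            break
    return current_order()
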
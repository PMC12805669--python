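"""Time-tree data model, node-height ratio transform, coalescent intervals.

Time is measured in *height*: years before the most recent sample, so the
youngest tip sits at height 0 and heights increase toward the root.  The
topology is fixed for the whole analysis; only node heights vary.

Internal node heights are reparameterized for unconstrained optimization:
each non-root internal node carries a ratio in (0,1) locating its height
between the tightest descendant-tip bound and its parent's height, while
the root carries its positive excess over the same bound.  The transform is
a bijection whose log-Jacobian is a simple sum of logs, which is what lets
gradient-based engines move node heights freely without violating the
parent-older-than-child constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad


class TreeError(ValueError):
    pass


class DegenerateTreeError(TreeError):
    pass


@dataclass
class TimeTree:
    """Rooted binary time tree with fixed topology.

    Tips are node indices ``0..n-1`` (label ``taxa[i]``); internal nodes are
    ``n..2n-2``.  ``children[j]`` holds the two children of internal node
    ``n + j``.  ``heights`` has length ``2n-1``.
    """

    taxa: list
    children: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.children = np.asarray(self.children, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.taxa)
        if self.children.shape != (n - 1, 2):
            raise TreeError("children array must have shape (n-1, 2)")
        if self.heights.shape != (2 * n - 1,):
            raise TreeError("heights array must have length 2n-1")
        self.parent = np.full(2 * n - 1, -1, dtype=int)
        seen = np.zeros(2 * n - 1, dtype=bool)
        for j in range(n - 1):
            for c in self.children[j]:
                if seen[c]:
                    raise TreeError("node has two parents")
                seen[c] = True
                self.parent[c] = n + j
        roots = [v for v in range(2 * n - 1) if self.parent[v] == -1]
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = roots[0]
        self.postorder = self._postorder()
        self._lower_bounds = None

    # -- structure ---------------------------------------------------------
    @property
    def n_taxa(self):
        return len(self.taxa)

    def _postorder(self):
        """Internal node indices, children before parents."""
        n = self.n_taxa
        order, stack, emitted = [], [self.root], []
        visited = set()
        while stack:
            v = stack.pop()
            if v < n:
                continue
            if v in visited:
                order.append(v)
                continue
            visited.add(v)
            stack.append(v)
            stack.extend(self.children[v - n])
        return order

    def validate(self):
        n = self.n_taxa
        for v in self.postorder:
            for c in self.children[v - n]:
                if self.heights[v] <= self.heights[c]:
                    raise DegenerateTreeError(
                        f"internal node {v} not strictly older than child {c}")
        if abs(min(self.heights[:n])) > 1e-9:
            raise TreeError("youngest tip must be at height 0")

    def lower_bounds(self) -> np.ndarray:
        """Max descendant tip height for every node (tips: own height).

        Computed once; the topology never changes.
        """
        if self._lower_bounds is None:
            n = self.n_taxa
            lb = np.empty(2 * n - 1)
            lb[:n] = self.heights[:n]
            for v in self.postorder:
                lb[v] = max(lb[c] for c in self.children[v - n])
            self._lower_bounds = lb
        return self._lower_bounds

    def branch_duration(self, v) -> float:
        return float(self.heights[self.parent[v]] - self.heights[v])

    def with_heights(self, heights) -> "TimeTree":
        return TimeTree(self.taxa, self.children.copy(), np.asarray(heights, dtype=float))


@dataclass
class HeightRatios:
    """Encoded internal heights: root excess plus one (0,1) ratio per
    non-root internal node, ordered as ``tree.postorder`` minus the root."""

    root_excess: float
    ratios: np.ndarray
    lower_bounds: np.ndarray  # per non-root internal node, same order


def heights_to_ratios(tree: TimeTree) -> HeightRatios:
    tree.validate()
    lb = tree.lower_bounds()
    h = tree.heights
    ratios, lbs = [], []
    for v in tree.postorder:
        if v == tree.root:
            continue
        hp = h[tree.parent[v]]
        if h[v] <= lb[v] or h[v] >= hp:
            raise DegenerateTreeError(f"height of node {v} outside ({lb[v]}, {hp})")
        ratios.append((h[v] - lb[v]) / (hp - lb[v]))
        lbs.append(lb[v])
    excess = float(h[tree.root] - lb[tree.root])
    if excess <= 0:
        raise DegenerateTreeError("root height not above its lower bound")
    return HeightRatios(excess, np.array(ratios), np.array(lbs))


def decode_heights(tree: TimeTree, root_excess, ratios):
    """Preorder decode of internal heights from (excess, ratios).

    Works on floats or autodiff tensors; returns the full heights vector
    (tips are constants) aligned with node indices.
    """
    n = tree.n_taxa
    lb = tree.lower_bounds()
    non_root = [v for v in tree.postorder if v != tree.root]
    pos = {v: i for i, v in enumerate(non_root)}
    h = {v: float(tree.heights[v]) for v in range(n)}
    h[tree.root] = ad.add(lb[tree.root], root_excess)
    for v in reversed(tree.postorder):
        if v == tree.root:
            continue
        r = ratios[pos[v]]
        h[v] = ad.add(lb[v], ad.mul(r, ad.sub(h[tree.parent[v]], lb[v])))
    return ad.stack([h[v] for v in range(2 * n - 1)])


def ratios_to_heights(r: HeightRatios, tree: TimeTree) -> TimeTree:
    """Inverse of :func:`heights_to_ratios` on a fixed topology."""
    if np.any(r.ratios <= 0) or np.any(r.ratios >= 1):
        raise DegenerateTreeError("ratios must lie in (0, 1)")
    if r.root_excess <= 0:
        raise DegenerateTreeError("root excess must be positive")
    heights = decode_heights(tree, r.root_excess, r.ratios)
    return tree.with_heights(np.asarray(heights, dtype=float))


def log_jacobian_heights(tree: TimeTree, heights=None):
    """log|det d(heights)/d(ratios)| = sum over non-root internal nodes of
    log(parent height - lower bound).  Accepts an autodiff heights vector."""
    lb = tree.lower_bounds()
    h = tree.heights if heights is None else heights
    total = 0.0
    for v in tree.postorder:
        if v == tree.root:
            continue
        total = ad.add(total, ad.log(ad.sub(h[tree.parent[v]], lb[v])))
    return total


@dataclass
class CoalescentIntervals:
    """Piecewise-constant lineage-count bookkeeping between event heights."""

    starts: np.ndarray
    ends: np.ndarray
    lineage_counts: np.ndarray
    coalescent_heights: np.ndarray       # height of every coalescence, sorted
    coalescent_lineages: np.ndarray      # lineages present just before each


def coalescent_intervals(tree: TimeTree) -> CoalescentIntervals:
    """Sampling/coalescence events sorted by height; at equal heights
    sampling events are processed first so every coalescence sees k >= 2."""
    n = tree.n_taxa
    events = [(float(tree.heights[i]), 0) for i in range(n)]
    events += [(float(tree.heights[v]), 1) for v in tree.postorder]
    events.sort(key=lambda e: (e[0], e[1]))
    starts, ends, counts = [], [], []
    coal_h, coal_k = [], []
    k = 0
    t = events[0][0]
    for height, kind in events:
        if height > t and k >= 1:
            starts.append(t)
            ends.append(height)
            counts.append(k)
            t = height
        elif height > t:
            t = height
        if kind == 0:
            k += 1
        else:
            coal_h.append(height)
            coal_k.append(k)
            k -= 1
    return CoalescentIntervals(
        np.array(starts), np.array(ends), np.array(counts, dtype=int),
        np.array(coal_h), np.array(coal_k, dtype=int))
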
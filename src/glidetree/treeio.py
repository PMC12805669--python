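"""Newick input/output and tip-date handling.

Calendar dates appear only at this boundary; internally all times are
heights (years before the most recent sample).  Dates can be embedded in
taxon labels as ``name_YYYY`` (split on the last underscore) or supplied as
a two-column tab-separated table; the table wins on conflict.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .tree import TimeTree, TreeError


class NewickFormatError(TreeError):
    pass


def parse_dates_from_labels(taxa) -> dict:
    """Extract ``{taxon: decimal date}`` from ``name_YYYY``-style labels.

    Labels without a parseable numeric suffix are skipped.
    """
    dates = {}
    for name in taxa:
        if "_" not in name:
            continue
        suffix = name.rsplit("_", 1)[1]
        try:
            dates[name] = float(suffix)
        except ValueError:
            continue
    return dates


def read_date_table(path) -> dict:
    """Two-column TSV ``taxon<TAB>decimal_date``; '#' lines are comments."""
    dates = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise NewickFormatError(f"bad date-table row: {line!r}")
            dates[fields[0]] = float(fields[1])
    return dates


def _load_dendropy(source: str, is_path: bool) -> dendropy.Tree:
    kwargs = {"path": source} if is_path else {"data": source}
    return dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)


def read_newick(path=None, *, data=None, dates=None) -> TimeTree:
    """Read a single rooted binary tree with branch lengths into a
    :class:`TimeTree`.

    Without dates the tree must be interpretable with the youngest tip at
    height 0 (heights come from root-to-tip path lengths).  With a
    ``{taxon: date}`` map, tip heights are ``max(date) - date`` and internal
    heights still come from the branch lengths, anchored so the deepest tip
    path equals the tree height.
    """
    if (path is None) == (data is None):
        raise ValueError("supply exactly one of path or data")
    dtree = _load_dendropy(str(path) if path else data, is_path=path is not None)
    leaves = dtree.leaf_nodes()
    taxa = [lf.taxon.label for lf in leaves]
    if len(set(taxa)) != len(taxa):
        raise NewickFormatError("duplicate taxon labels in tree")
    n = len(taxa)
    tip_index = {name: i for i, name in enumerate(taxa)}

    # depths from the root
    depth = {dtree.seed_node: 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        bl = node.edge.length
        if bl is None:
            raise NewickFormatError("branch lengths are required")
        if bl < 0:
            raise NewickFormatError(f"negative branch length {bl}")
        depth[node] = depth[node.parent_node] + bl

    max_depth = max(depth[lf] for lf in leaves)
    heights = np.zeros(2 * n - 1)
    children = np.zeros((n - 1, 2), dtype=int)
    next_internal = n
    index = {}
    for node in dtree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            index[node] = tip_index[node.taxon.label]
        else:
            if len(kids) != 2:
                raise NewickFormatError(
                    f"non-binary node with {len(kids)} children is unsupported")
            index[node] = next_internal
            children[next_internal - n] = [index[k] for k in kids]
            next_internal += 1
        heights[index[node]] = max_depth - depth[node]

    if dates:
        missing = [t for t in taxa if t not in dates]
        if missing:
            raise NewickFormatError(f"taxa missing from date map: {missing}")
        latest = max(dates[t] for t in taxa)
        if len({dates[t] for t in taxa}) == 1:
            _check_ultrametric(heights[:n])
        for t in taxa:
            heights[tip_index[t]] = latest - dates[t]
    else:
        _check_ultrametric(heights[:n])
        heights[:n] = 0.0

    tree = TimeTree(taxa, children, heights)
    tree.validate()
    return tree


def _check_ultrametric(tip_heights, tol=1e-6):
    if np.max(np.abs(tip_heights)) > tol:
        raise NewickFormatError(
            "tree is not ultrametric but all tips share a sampling date")


def write_newick(tree: TimeTree, path=None) -> str:
    """Serialize a :class:`TimeTree` with branch lengths in height units."""
    n = tree.n_taxa

    def render(v) -> str:
        if v < n:
            label = tree.taxa[v]
        else:
            a, b = tree.children[v - n]
            label = f"({render(a)},{render(b)})"
        if v == tree.root:
            return label
        bl = tree.heights[tree.parent[v]] - tree.heights[v]
        return f"{label}:{bl:.12g}"

    text = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def write_date_table(tree: TimeTree, path, latest_date: float = 0.0) -> None:
    with open(path, "w") as fh:
        fh.write("#taxon\tdate\n")
        for i, name in enumerate(tree.taxa):
            fh.write(f"{name}\t{latest_date - tree.heights[i]:.10g}\n")
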
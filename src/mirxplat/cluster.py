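"""Agglomerative hierarchical clustering on Pearson-correlation distances.

Expression profiles (typically log2-ratio vectors) are clustered with the
distance 1 - r, where r is the Pearson correlation, under average (UPGMA),
complete or single linkage. Merge order is deterministic: among equally close
cluster pairs the lexicographically smallest pair (by each cluster's smallest
leaf name) merges first. Trees export to Newick with ultrametric branch
lengths (a pair merging at height h puts each leaf at depth h/2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ClusterError(ValueError):
    pass


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation; in [0, 2]. Constant vectors are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ClusterError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ClusterError("profiles need length >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xd**2).sum()), np.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ClusterError("Pearson correlation undefined for a constant profile")
    r = float((xd * yd).sum() / (sx * sy))
    return 1.0 - max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class ClusterNode:
    """A node of the merge tree; leaves carry a name, internal nodes a height."""

    height: float
    name: str | None = None
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return [n for c in self.children for n in c.leaf_names()]


@dataclass(frozen=True)
class ClusterTree:
    root: ClusterNode
    merges: tuple[tuple[str, str, float], ...]  # (left key, right key, height)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i + 1, l, r, h) for i, (l, r, h) in enumerate(self.merges)],
            columns=["step", "left", "right", "height"],
        )


_LINKAGES = ("average", "complete", "single")


def hca(profiles: pd.DataFrame, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of the rows of ``profiles``.

    Returns a binary merge tree whose heights are the linkage distances on the
    1 - Pearson r scale. Under average linkage the heights are monotone
    non-decreasing from leaves to root.
    """
    if linkage not in _LINKAGES:
        raise ClusterError(f"unknown linkage {linkage!r} (choose from {_LINKAGES})")
    names = [str(n) for n in profiles.index]
    if len(names) < 2:
        raise ClusterError("clustering needs >= 2 rows")
    if len(set(names)) != len(names):
        raise ClusterError("row names must be unique")
    arr = profiles.to_numpy(dtype=float)

    # live clusters: key (smallest leaf name) -> (node, list of row indices)
    clusters: dict[str, tuple[ClusterNode, list[int]]] = {
        name: (ClusterNode(height=0.0, name=name), [i]) for i, name in enumerate(names)
    }
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            dist[frozenset((a, b))] = pearson_distance(arr[clusters[a][1][0]], arr[clusters[b][1][0]])

    merges: list[tuple[str, str, float]] = []
    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        for pair, d in dist.items():
            a, b = sorted(pair)
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d, a, b = best  # type: ignore[misc]
        node_a, rows_a = clusters.pop(a)
        node_b, rows_b = clusters.pop(b)
        new_key = min(a, b)
        new_node = ClusterNode(height=d, children=(node_a, node_b))
        merges.append((a, b, d))
        # Lance-Williams updates against every remaining cluster
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            if linkage == "average":
                na, nb = len(rows_a), len(rows_b)
                dnew = (na * da + nb * db) / (na + nb)
            elif linkage == "complete":
                dnew = max(da, db)
            else:
                dnew = min(da, db)
            dist[frozenset((new_key, other))] = dnew
        dist.pop(frozenset((a, b)))
        clusters[new_key] = (new_node, rows_a + rows_b)

    (root, _), = clusters.values()
    return ClusterTree(root=root, merges=tuple(merges))


_NEEDS_QUOTE = re.compile(r"[\s(),:;'\[\]]")


def _format_name(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def export_tree(tree: ClusterTree, format: str = "newick") -> str:
    """Serialize the merge tree; branch lengths place leaves at depth h/2."""
    if format != "newick":
        raise ClusterError(f"unknown tree format {format!r}")

    def emit(node: ClusterNode) -> str:
        if node.is_leaf:
            return _format_name(node.name)  # type: ignore[arg-type]
        parts = []
        for child in node.children:
            bl = (node.height - child.height) / 2.0
            parts.append(f"{emit(child)}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"

    return emit(tree.root) + ";"


def parse_newick(text: str) -> ClusterTree:
    """Parse a Newick string produced by :func:`export_tree` back to a tree.

    Heights are reconstructed from the ultrametric branch lengths (node height
    = 2 x distance to its deepest leaf); export-parse round trips are identity
    for trees produced by :func:`hca`.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise ClusterError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_name() -> str:
        nonlocal pos
        if s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        m = re.match(r"[^(),:;]+", s[pos:])
        if m is None:
            raise ClusterError(f"expected a name at position {pos}")
        pos += m.end()
        return m.group(0)

    def parse_clade() -> tuple[ClusterNode, float]:
        """Returns (node, depth below this node's position)."""
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children: list[tuple[ClusterNode, float, float]] = []  # node, depth, bl
            while True:
                child, depth = parse_clade()
                bl = 0.0
                if pos < len(s) and s[pos] == ":":
                    pos += 1
                    m = re.match(r"[-+0-9.eE]+", s[pos:])
                    if m is None:
                        raise ClusterError(f"expected a branch length at position {pos}")
                    bl = float(m.group(0))
                    pos += m.end()
                children.append((child, depth, bl))
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                if pos < len(s) and s[pos] == ")":
                    pos += 1
                    break
                raise ClusterError(f"unbalanced parentheses at position {pos}")
            my_depth = max(d + bl for _, d, bl in children)
            node = ClusterNode(height=2.0 * my_depth, children=tuple(c for c, _, _ in children))
            return node, my_depth
        name = parse_name()
        return ClusterNode(height=0.0, name=name), 0.0

    root, _ = parse_clade()
    if pos != len(s):
        raise ClusterError(f"trailing characters after position {pos}")

    merges: list[tuple[str, str, float]] = []

    def collect(node: ClusterNode) -> str:
        if node.is_leaf:
            return node.name  # type: ignore[return-value]
        keys = sorted(collect(c) for c in node.children)
        merges.append((keys[0], keys[-1], node.height))
        return keys[0]

    collect(root)
    merges.sort(key=lambda m: m[2])
    return ClusterTree(root=root, merges=tuple(merges))
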
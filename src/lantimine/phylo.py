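"""Distance-based phylogenetics for LanA/B/C protein families.

Trees are built by standard neighbor joining (Saitou–Nei Q-criterion) from
p-distances (or Poisson-corrected distances) computed on a protein MSA, and
phylogroups are extracted by cutting the longest internal edges. The NJ
implementation is deterministic: ties in the Q matrix break by the
lexicographically smallest (id, id) pair, and negative branch lengths are
clamped to zero with the deficit moved to the sibling edge.

Trees are `skbio.TreeNode` objects, so Newick I/O and tree surgery come for
free; a PHYLIP-format distance-matrix writer is provided for interop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import TreeNode


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{name[:10]:<10s} {row}\n")


@dataclass
class Phylogroup:
    label: str
    member_ids: list[str]
    annotations: dict[str, str]


def distance_matrix(m, model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an MSA.

    p-distance = mismatches / shared non-gap columns; ``model="poisson"``
    applies the −ln(1−p) correction (p is capped just below 1 so saturated
    pairs get a large finite distance). A pair sharing no non-gap column is
    an error.
    """
    rows = m.rows
    n = len(rows)
    if n < 3:
        raise ValueError("need at least 3 aligned sequences")
    ids = [i for i, _ in rows]
    arrs = [np.frombuffer(s.encode(), dtype="S1") for _, s in rows]
    gap = np.bytes_(b"-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arrs[i] != gap) & (arrs[j] != gap)
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"{ids[i]} and {ids[j]} share no aligned columns"
                )
            p = float(((arrs[i] != arrs[j]) & shared).sum()) / total
            if model == "p":
                dist = p
            elif model == "poisson":
                dist = -math.log(max(1.0 - p, 1e-6))
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, represented with a trifurcating root).

    Deterministic: Q-criterion ties break by the lexicographically smallest
    pair of node keys (a node's key is the smallest leaf name under it);
    negative branch lengths are clamped to 0 and the deficit is moved to the
    sibling edge so the pair's summed length is preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    keys: list[str] = list(dm.ids)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        parent.extend([a, b])
        # distances from the new node
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = max(
                0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j])
            )
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = float(max(ln, 0.0))
            root.append(nodes[idx])
    else:  # exactly 2 left (possible when n == 3 never, but keep safe)
        i, j = active
        nodes[i].length = float(d[i, j] / 2)
        nodes[j].length = float(d[i, j] / 2)
        root.extend([nodes[i], nodes[j]])
    return root


def path_length_matrix(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths, in the order of ``ids``."""
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = tree.find(ids[i])
            b = tree.find(ids[j])
            out[i, j] = out[j, i] = a.distance(b)
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def extract_phylogroups(
    tree: TreeNode,
    k: int | None = None,
    branch_threshold: float | None = None,
    annotations: dict[str, str] | None = None,
) -> list[Phylogroup]:
    """Partition the leaves into phylogroups.

    With ``k``, the k−1 longest internal edges are removed (ties break by the
    smallest leaf name under the edge) and the connected leaf sets returned;
    with ``branch_threshold``, every internal edge longer than the threshold
    is removed. Groups are labelled "1", "2", ... in order of their smallest
    member id.
    """
    if (k is None) == (branch_threshold is None):
        raise ValueError("provide exactly one of k or branch_threshold")
    annotations = annotations or {}
    work = tree.copy()
    leaves = [t.name for t in work.tips()]
    if k is not None:
        if not (1 <= k <= len(leaves)):
            raise ValueError("k must be between 1 and the leaf count")
    internal = [
        node
        for node in work.traverse()
        if not node.is_tip() and not node.is_root()
    ]

    def edge_sort_key(node):
        return (-(node.length or 0.0), min(t.name for t in node.tips()))

    internal.sort(key=edge_sort_key)

    def split(cut_set: set[int]) -> list[list[str]]:
        groups: list[list[str]] = []

        def collect(node) -> list[str]:
            """Leaves connected to ``node`` without crossing a cut edge."""
            if node.is_tip():
                return [node.name]
            acc: list[str] = []
            for ch in node.children:
                sub = collect(ch)
                if id(ch) in cut_set:
                    if sub:
                        groups.append(sub)
                else:
                    acc.extend(sub)
            return acc

        rest = collect(work)
        if rest:
            groups.append(rest)
        return groups

    if k is not None:
        # cut the longest internal edges first; fall back to leaf edges for
        # degenerate k close to the leaf count, skipping cuts that cannot
        # add a group
        candidates = internal + sorted(
            work.tips(), key=lambda t: (-(t.length or 0.0), t.name)
        )
        cut_set: set[int] = set()
        groups = split(cut_set)
        for node in candidates:
            if len(groups) >= k:
                break
            cut_set.add(id(node))
            groups = split(cut_set)
    else:
        cut_set = {
            id(node) for node in internal
            if (node.length or 0.0) > branch_threshold
        }
        groups = split(cut_set)
    groups.sort(key=lambda g: min(g))
    return [
        Phylogroup(
            label=str(i + 1),
            member_ids=sorted(g),
            annotations={m: annotations.get(m, "") for m in g},
        )
        for i, g in enumerate(groups)
    ]
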
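"""BioNJ distance-tree inference and newick export.

BioNJ (Gascuel 1997, Mol Biol Evol 14:685) is neighbor joining with a
variance-weighted matrix reduction: when taxa i and j are agglomerated into
node u, the new distances d(u,k) = lambda*(d(i,k) - b_i) + (1-lambda)*(d(j,k) - b_j)
use the weight lambda that minimises the variance of the reduced matrix,
with the variances v(i,j) initialised proportional to d(i,j).  Selection
criterion and branch lengths are those of classical NJ, so BioNJ and NJ
coincide whenever all variances are equal.
"""

from __future__ import annotations

import numpy as np


class TreeNode:
    """Minimal rooted tree node; the root of an unrooted tree trifurcates."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [node for node in self.postorder() if node.is_leaf]

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def tree_length(self) -> float:
        """Sum of all branch lengths (the root's own length is ignored)."""
        return sum(node.length for node in self.postorder() if node.parent is not None)

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf patristic distances, keyed by sorted name pairs."""
        below: dict[TreeNode, dict[str, float]] = {}
        dists: dict[tuple[str, str], float] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name: 0.0}
            else:
                merged: dict[str, float] = {}
                kids = [{name: d + child.length
                         for name, d in below.pop(child).items()}
                        for child in node.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for na, da in kids[a].items():
                            for nb, db in kids[b].items():
                                key = (na, nb) if na < nb else (nb, na)
                                dists[key] = da + db
                    merged.update(kids[a])
                merged.update(kids[-1])
                below[node] = merged
        return dists

    def __repr__(self) -> str:
        return f"TreeNode({to_newick(self)!r})"


_NEWICK_UNSAFE = set("()[]{}:;,|'\" \t\n")


def _quote_label(label: str) -> str:
    if label and not (_NEWICK_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(tree: TreeNode, decimals: int = 6) -> str:
    """Serialise a tree to newick with branch lengths to ``decimals`` places."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = _quote_label(node.name or "")
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                body += _quote_label(node.name)
        if node.parent is None:
            return body
        return f"{body}:{node.length:.{decimals}f}"

    return render(tree) + ";"


def _check_matrix(D) -> np.ndarray:
    values = np.asarray(D.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 taxa for tree inference")
    return values


def bionj_tree(D) -> TreeNode:
    """Infer an unrooted BioNJ tree from a DistanceMatrix.

    Agglomeration ties on the NJ selection criterion are broken by the
    lowest (row, column) index pair in current matrix order, so the result
    is fully deterministic.  Negative branch lengths produced by the NJ
    length formulas are kept (guide-tree export clamps them).
    """
    d = _check_matrix(D).copy()
    v = d.copy()  # variances initialised proportional to distances
    nodes = [TreeNode(name=seq_id) for seq_id in D.ids]

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        # NJ selection criterion Q_ij = (r-2) d_ij - R_i - R_j
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) pair among the minima, for determinism
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        b_i = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        b_j = dij - b_i

        # variance-minimising reduction weight (clamped to [0, 1])
        mask = np.ones(r, dtype=bool)
        mask[[i, j]] = False
        if v[i, j] > 0:
            lam = 0.5 + (v[j, mask] - v[i, mask]).sum() / (2.0 * (r - 2) * v[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5  # degenerate: reduces to classical NJ

        d_new = lam * (d[i, mask] - b_i) + (1.0 - lam) * (d[j, mask] - b_j)
        v_new = lam * v[i, mask] + (1.0 - lam) * v[j, mask] \
            - lam * (1.0 - lam) * v[i, j]

        parent = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = b_i
        child_j.length = b_j
        parent.add_child(child_i)
        parent.add_child(child_j)

        keep = [k for k in range(r) if k not in (i, j)]
        nodes = [nodes[k] for k in keep] + [parent]
        d_red = d[np.ix_(mask, mask)]
        v_red = v[np.ix_(mask, mask)]
        d = np.pad(d_red, ((0, 1), (0, 1)))
        v = np.pad(v_red, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = d_new
        v[-1, :-1] = v[:-1, -1] = v_new

    # final trifurcation: three-point formulas
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, length in zip(nodes, (a, b, c)):
        node.length = length
        root.add_child(node)
    return root
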
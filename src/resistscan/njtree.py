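"""Neighbor-joining haplotype trees over genomic windows.

Distances are raw counts of differing sites (no multiple-hit correction) in
a bp window; trees are built with the Saitou-Nei neighbor-joining algorithm
(Q-criterion, deterministic lowest-index tie-breaking).  Leaves can be
labelled with the line's resistance-mutation combination string (e.g. "011"
= carries the second and third resistance mutation of an ordered locus set),
and trees serialize to Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypePanel

logger = logging.getLogger("resistscan")


@dataclass(eq=False)
class TreeNode:
    """An unrooted tree node; the root holds the final trifurcation."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name or "" for l in self.leaves()]

    def patristic_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        paths: dict[str, dict[TreeNode, float]] = {}

        def walk(node: TreeNode, dist_from_root: float, ancestors: list[tuple[TreeNode, float]]):
            anc = ancestors + [(node, dist_from_root)]
            if node.is_leaf:
                paths[node.name or ""] = {a: d for a, d in anc}
                return
            for child, bl in node.children:
                walk(child, dist_from_root + bl, anc)

        walk(self, 0.0, [])
        names = list(paths)
        D = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i >= j:
                    continue
                pa, pb = paths[a], paths[b]
                common = [n for n in pa if n in pb]
                # deepest common ancestor = max distance from root
                lca_depth = max(pa[n] for n in common)
                da = max(pa.values())
                db = max(pb.values())
                D[i, j] = D[j, i] = (da - lca_depth) + (db - lca_depth)
        return pd.DataFrame(D, index=names, columns=names)


def window_distances(
    panel: GenotypePanel, chrom: str, center_pos: int, width_bp: int = 200_000
) -> pd.DataFrame:
    """Pairwise counts of differing sites in a bp window (closed interval).

    Requires complete (imputed) calls in the window; the window is
    ``[center - width/2, center + width/2]``.
    """
    half = width_bp // 2
    pos = panel.variants["pos"].to_numpy()
    mask = (
        (panel.variants["chrom"] == chrom).to_numpy()
        & (pos >= center_pos - half)
        & (pos <= center_pos + half)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"no sites in window {chrom}:{center_pos}+-{half}")
    calls = panel.calls[:, idx].astype(np.int16)
    if np.any(calls == MISSING):
        raise ValueError("window contains missing calls; impute first")
    # Hamming distances via 0/1 matrix algebra
    x = calls.astype(np.float64)
    same11 = x @ x.T
    ones = x.shape[1]
    ri = x.sum(axis=1)
    D = ri[:, None] + ri[None, :] - 2 * same11
    D = np.rint(D).astype(int)
    np.fill_diagonal(D, 0)
    return pd.DataFrame(D, index=panel.lines, columns=panel.lines)


def neighbor_joining(D: pd.DataFrame | np.ndarray, ids: list[str] | None = None
                     ) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q(a, b) = (n-2) d(a,b) - R_a - R_b
    (R = row sums), with branch lengths from the standard formulas.  Ties
    break to the lowest (row, column) index pair, so output is deterministic.
    Negative branch lengths, possible on non-additive matrices, are clamped
    to zero with the deficit moved to the sister branch.  The final three
    nodes form the root trifurcation.
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        M = D.to_numpy(dtype=float).copy()
    else:
        M = np.asarray(D, dtype=float).copy()
        if ids is None:
            ids = [f"t{i}" for i in range(M.shape[0])]
    n = M.shape[0]
    if M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(M, M.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa (use trivial_pair_tree)")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = M[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) tie-break in the active ordering
        flat = np.argmin(Q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        bl_i = 0.5 * d_ij + (R[i] - R[j]) / (2.0 * (m - 2))
        bl_j = d_ij - bl_i
        bl_i, bl_j = _clamp_pair(bl_i, bl_j)
        a, b = active[i], active[j]
        parent = TreeNode()
        parent.children = [(nodes[a], bl_i), (nodes[b], bl_j)]
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (M[a, :] + M[b, :] - d_ij)
        M = np.pad(M, ((0, 1), (0, 1)), constant_values=0.0)
        M[-1, : len(nodes)] = new_d[: len(nodes)]
        M[: len(nodes), -1] = new_d[: len(nodes)]
        M[-1, -1] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    # root trifurcation over the last three nodes
    a, b, c = active
    bl_a = 0.5 * (M[a, b] + M[a, c] - M[b, c])
    bl_b = 0.5 * (M[a, b] + M[b, c] - M[a, c])
    bl_c = 0.5 * (M[a, c] + M[b, c] - M[a, b])
    lens = _clamp_multi([bl_a, bl_b, bl_c])
    root = TreeNode()
    root.children = [(nodes[a], lens[0]), (nodes[b], lens[1]), (nodes[c], lens[2])]
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, transferring the deficit to the sister."""
    if x < 0:
        logger.debug("neighbor_joining: clamped negative branch %.4g", x)
        return 0.0, max(y + x, 0.0)
    if y < 0:
        logger.debug("neighbor_joining: clamped negative branch %.4g", y)
        return max(x + y, 0.0), 0.0
    return x, y


def _clamp_multi(lens: list[float]) -> list[float]:
    out = list(lens)
    for i, v in enumerate(out):
        if v < 0:
            logger.debug("neighbor_joining: clamped negative root branch %.4g", v)
            j = int(np.argmax(out))
            out[j] = max(out[j] + v, 0.0)
            out[i] = 0.0
    return out


def trivial_pair_tree(name_a: str, name_b: str, distance: float) -> TreeNode:
    """Two-taxon tree with the distance split equally."""
    root = TreeNode()
    half = distance / 2.0
    root.children = [(TreeNode(name=name_a), half), (TreeNode(name=name_b), half)]
    return root


def combo_string(calls: np.ndarray, resistant_alleles: np.ndarray) -> str:
    """Presence/absence string of resistance alleles; '?' for missing."""
    out = []
    for c, r in zip(calls, resistant_alleles):
        if c == MISSING:
            out.append("?")
        else:
            out.append("1" if int(c) == int(r) else "0")
    return "".join(out)


def label_leaves(
    tree: TreeNode, panel: GenotypePanel, locus_set: pd.DataFrame, sep: str = "|"
) -> TreeNode:
    """Append each leaf's resistance-combination string to its label.

    The string follows the ordered locus set ("1" = resistant allele carried,
    "?" = missing genotype).  Modifies the tree in place and returns it.
    """
    cols = [panel.site_index(r.arm, int(r.pos)) for r in locus_set.itertuples()]
    res = locus_set["resistant_allele"].to_numpy(dtype=int)
    line_row = {l: i for i, l in enumerate(panel.lines)}
    for leaf in tree.leaves():
        base = (leaf.name or "").split(sep)[0]
        if base not in line_row:
            raise KeyError(f"leaf {base!r} not among panel lines")
        combo = combo_string(panel.calls[line_row[base], cols], res)
        leaf.name = f"{base}{sep}{combo}"
    return tree


_NEWICK_RESERVED = set("();:,[]' \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode) -> str:
    """Serialize to a Newick string with branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name or "")
        inner = ",".join(f"{render(c)}:{bl:.10g}" for c, bl in node.children)
        label = _quote(node.name) if node.name else ""
        return f"({inner}){label}"

    return render(tree) + ";"
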
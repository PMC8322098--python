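"""Individual-level distance trees: consensus-base p-distances, canonical
neighbor-joining with deterministic tie-breaks, and block-bootstrap support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl import GLMatrix, allele_freq_em
from .divergence import assign_blocks

__all__ = [
    "DistMatrix",
    "TreeNode",
    "ibs_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
]


@dataclass
class DistMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < -1e-12):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def drop(self, labels) -> "DistMatrix":
        drop = set(labels)
        keep = [i for i, l in enumerate(self.labels) if l not in drop]
        return DistMatrix([self.labels[i] for i in keep],
                          self.matrix[np.ix_(keep, keep)])


@dataclass
class TreeNode:
    label: str | None = None
    children: list = field(default_factory=list)  # (child, branch_length)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, _root: bool = True) -> str:
        if self.is_leaf():
            return str(self.label)
        parts = []
        for child, bl in self.children:
            s = child.to_newick(_root=False)
            if child.support is not None and not child.is_leaf():
                s += f"{child.support:g}"
            parts.append(f"{s}:{bl:.10g}")
        inner = "(" + ",".join(parts) + ")"
        return inner + ";" if _root else inner


def _consensus_base_codes(gl: GLMatrix, rng) -> np.ndarray:
    """Per-site, per-individual sampled consensus base (0=major, 1=minor,
    -1=missing).  The posterior genotype uses an HWE prior at the panel EM
    frequency; heterozygous calls resolve by a seeded fair coin."""
    f = allele_freq_em(gl.L)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)
    w = gl.L * prior[:, None, :]
    g = np.argmax(w, axis=2)
    coin = rng.random(g.shape) < 0.5
    base = np.where(g == 0, 0, np.where(g == 2, 1, np.where(coin, 1, 0)))
    base = base.astype(np.int8)
    base[gl.missing_mask()] = -1
    return base


def ibs_distance_matrix(gl: GLMatrix, seed: int = 0, return_base=False):
    """Pairwise p-distance by sampling one consensus base per individual.

    Distance is the mismatch fraction over sites non-missing in both
    individuals; a pair with no overlapping sites raises.
    """
    rng = np.random.default_rng(seed)
    base = _consensus_base_codes(gl, rng)
    return _distance_from_codes(base, gl.individuals, return_base)


def _distance_from_codes(base: np.ndarray, labels, return_base=False):
    ok = (base >= 0).astype(np.float64)
    b = np.where(base >= 0, base, 0).astype(np.float64)
    overlap = ok.T @ ok
    if np.any(overlap == 0):
        i, j = np.argwhere(overlap == 0)[0]
        raise ValueError(f"no overlapping sites for pair ({labels[i]}, {labels[j]})")
    # mismatches among binary codes: x(1-y) + y(1-x), restricted to sites
    # where both are called
    bo = b * ok
    mism = (bo.T @ ok) + (ok.T @ bo) - 2 * (bo.T @ bo)
    d = mism / overlap
    np.fill_diagonal(d, 0.0)
    dm = DistMatrix(list(labels), d)
    if return_base:
        return dm, base
    return dm


def nj_tree(d: DistMatrix, outgroup: str | None = None) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Ties are broken by the lexicographically smallest label pair, so the
    topology is deterministic.  If ``outgroup`` is given the tree is rooted
    at the midpoint of its pendant edge.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(label=l) for l in d.labels]
    names = [str(l) for l in d.labels]  # lexicographic tie-break keys
    D = d.matrix.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((names[active[i]], names[active[j]]))), i, j)
            for i, j in cands if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances to the new node
        dnew = 0.5 * (sub[i, :] + sub[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        new_idx = D.shape[0] - 1
        for k, ak in enumerate(active):
            D[new_idx, ak] = D[ak, new_idx] = dnew[k]
        nodes.append(parent)
        names.append(min(names[ai], names[aj]))
        active = [a for a in active if a not in (ai, aj)] + [new_idx]
    ai, aj = active
    bl = D[ai, aj]
    root = TreeNode(children=[(nodes[ai], 0.5 * bl), (nodes[aj], 0.5 * bl)])
    if outgroup is not None:
        root = _root_on(root, outgroup)
    return root


def _root_on(root: TreeNode, outgroup: str) -> TreeNode:
    """Re-root at the midpoint of the outgroup's pendant edge."""
    # build parent map on the unrooted representation
    edges = []

    def collect(node):
        for child, bl in node.children:
            edges.append((node, child, bl))
            collect(child)

    collect(root)
    target = None
    for parent, child, bl in edges:
        if child.is_leaf() and child.label == outgroup:
            target = (parent, child, bl)
    if target is None:
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    parent, og, bl = target
    # detach outgroup; reorient the rest of the tree to hang from `parent`
    parent.children = [(c, l) for c, l in parent.children if c is not og]
    tree = _reorient(root, parent)
    new_root = TreeNode(children=[(og, bl / 2), (tree, bl / 2)])
    return _suppress_unary(new_root)


def _reorient(root: TreeNode, new_top: TreeNode) -> TreeNode:
    parent_of = {}

    def walk(node):
        for child, bl in node.children:
            parent_of[id(child)] = (node, bl)
            walk(child)

    walk(root)
    # flip edges on the path from new_top up to root
    node = new_top
    while id(node) in parent_of:
        parent, bl = parent_of[id(node)]
        parent.children = [(c, l) for c, l in parent.children if c is not node]
        node.children.append((parent, bl))
        node = parent
    return new_top


def _suppress_unary(node: TreeNode) -> TreeNode:
    new_children = []
    for child, bl in node.children:
        child = _suppress_unary(child)
        if len(child.children) == 1 and child.label is None:
            gchild, gbl = child.children[0]
            new_children.append((gchild, bl + gbl))
        else:
            new_children.append((child, bl))
    node.children = new_children
    return node


def bipartitions(root: TreeNode) -> set:
    """Non-trivial splits of the tree as frozensets (smaller side, by the
    canonical min-label rule on the full leaf set)."""
    all_leaves = frozenset(root.leaves())
    out = set()

    def walk(node):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                out.add(min(side, other, key=lambda s: sorted(s)))
            walk(child)

    walk(root)
    return out


def bootstrap_support(gl: GLMatrix, n_reps: int = 100, block_bp: int = 5_000_000,
                      seed: int = 0, outgroup: str | None = None):
    """NJ tree with % block-bootstrap support on internal edges.

    Genomic blocks are resampled with replacement, the distance matrix and
    NJ tree recomputed, and each internal bipartition of the main tree
    scored by its replicate frequency.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    base = _consensus_base_codes(gl, rng)
    main_dm = _distance_from_codes(base, gl.individuals)
    main = nj_tree(main_dm, outgroup=outgroup)
    blocks = assign_blocks(gl.sites, block_bp)
    nb = blocks.max() + 1
    counts = {bp: 0 for bp in bipartitions(main)}
    for _ in range(n_reps):
        chosen = rng.integers(0, nb, size=nb)
        idx = np.concatenate([np.flatnonzero(blocks == b) for b in chosen])
        dm = _distance_from_codes(base[idx], gl.individuals)
        reps = bipartitions(nj_tree(dm, outgroup=outgroup))
        for bp in counts:
            if bp in reps:
                counts[bp] += 1

    def annotate(node):
        for child, _ in node.children:
            if not child.is_leaf():
                side = frozenset(child.leaves())
                all_leaves = frozenset(main.leaves())
                key = min(side, all_leaves - side, key=lambda s: sorted(s))
                if key in counts:
                    child.support = 100.0 * counts[key] / n_reps
            annotate(child)

    annotate(main)
    return main, {tuple(sorted(k)): 100.0 * v / n_reps for k, v in counts.items()}
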
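"""Genotype likelihoods, allele-frequency EM, site filtering and LD pruning.

The analysis panel is a matrix of per-site, per-individual biallelic
genotype-likelihood (GL) triples ``L(g)`` for minor-allele dose
``g in {0, 1, 2}``, max-normalised per triple.  Missing data is encoded as a
flat triple (all entries equal), the convention every downstream EM in this
package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GLMatrix",
    "LinkedBlock",
    "gl_from_counts",
    "gl_from_count_arrays",
    "allele_freq_em",
    "posterior_mean_genotypes",
    "filter_sites",
    "ld_prune",
]


@dataclass
class GLMatrix:
    """Biallelic genotype-likelihood panel.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, major, minor``; ``pos`` is
        1-based and strictly increasing within each chromosome.
    individuals : list of str
        Sample identifiers, one per GL column block.
    colonies : list of str
        Colony (population) label per individual, aligned with
        ``individuals``.
    L : numpy.ndarray, shape (n_sites, n_individuals, 3)
        Likelihood triples normalised so that ``max(L) == 1`` per triple; a
        flat triple marks a missing observation.
    """

    sites: pd.DataFrame
    individuals: list
    colonies: list
    L: np.ndarray
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 3 or self.L.shape[2] != 3:
            raise ValueError("L must have shape (sites, individuals, 3)")
        if self.L.shape[0] != len(self.sites):
            raise ValueError("site table and L disagree on number of sites")
        if self.L.shape[1] != len(self.individuals):
            raise ValueError("individuals and L disagree")
        if len(self.colonies) != len(self.individuals):
            raise ValueError("colonies must align with individuals")
        if np.any(self.L < 0):
            raise ValueError("likelihoods must be non-negative")
        for _, sub in self.sites.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_sites(self) -> int:
        return self.L.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.L.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (sites, individuals) array, True where the triple is flat."""
        return (np.ptp(self.L, axis=2) == 0)

    def subset_individuals(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            individuals=[self.individuals[i] for i in idx],
            colonies=[self.colonies[i] for i in idx],
            L=self.L[:, idx, :],
        )

    def subset_sites(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, sites=self.sites.iloc[idx].reset_index(drop=True), L=self.L[idx])

    def by_colony(self, colony) -> "GLMatrix":
        return self.subset_individuals([i for i, c in enumerate(self.colonies) if c == colony])


@dataclass
class LinkedBlock:
    """A connected component of the r² > threshold linkage graph."""

    members: list
    representative: int
    r2_edges: list  # (i, j, r2) tuples for edges that formed the block


def gl_from_counts(n_major: int, n_minor: int, eps: float):
    """Likelihood triple from major/minor read counts under a symmetric
    base-error model.

    ``P(minor read | g) = (g/2)(1-eps) + (1-g/2) eps``; the triple is the
    product over reads, max-normalised.  Zero total reads gives the flat
    (missing) triple.
    """
    if n_major < 0 or n_minor < 0:
        raise ValueError("read counts must be non-negative")
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    t = gl_from_count_arrays(np.array([n_major]), np.array([n_minor]), eps)
    return t[0]

def gl_from_count_arrays(n_major: np.ndarray, n_minor: np.ndarray, eps: float) -> np.ndarray:
    """Vectorised :func:`gl_from_counts`; returns array shaped like input + (3,).

    Computed in log space so very deep sites do not underflow.
    """
    n_major = np.asarray(n_major, dtype=float)
    n_minor = np.asarray(n_minor, dtype=float)
    if np.any(n_major < 0) or np.any(n_minor < 0):
        raise ValueError("read counts must be non-negative")
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    p_minor = np.array([eps, 0.5, 1.0 - eps])  # P(minor read | g)
    logs = (
        n_minor[..., None] * np.log(p_minor)
        + n_major[..., None] * np.log1p(-p_minor)
    )
    logs -= logs.max(axis=-1, keepdims=True)
    return np.exp(logs)


def _hwe(f):
    """HWE genotype prior column stack for frequency array ``f``."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def allele_freq_em(L, tol: float = 1e-8, max_iter: int = 200, return_trajectory: bool = False):
    """Maximum-likelihood minor-allele frequency per site by EM.

    ``L`` is a (sites, individuals, 3) GL block (a single site may be passed
    as (individuals, 3)).  Missing individuals carry flat triples and are
    neutral in the update.  Raises if a site has no data at all.
    """
    L = np.asarray(L, dtype=float)
    single = L.ndim == 2
    if single:
        L = L[None]
    if L.shape[1] == 0:
        raise ValueError("no individuals")
    flat = np.ptp(L, axis=2) == 0
    if np.any(flat.all(axis=1)):
        raise ValueError("site with all individuals missing")
    f = np.full(L.shape[0], 0.2)
    traj = []
    for _ in range(max_iter):
        w = L * _hwe(f)[:, None, :]
        tot = w.sum(axis=2)
        eg = (w[:, :, 1] + 2 * w[:, :, 2]) / tot
        if return_trajectory:
            traj.append(np.log(tot / L.sum(axis=2)).sum(axis=1))
        f_new = eg.mean(axis=1) / 2.0
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break
    f = np.clip(f, 0.0, 1.0)
    out = f[0] if single else f
    if return_trajectory:
        return out, np.array(traj)
    return out


def posterior_mean_genotypes(L, f) -> np.ndarray:
    """Posterior mean minor-allele dose with an HWE prior at frequency ``f``.

    Missing (flat) triples fall back to the prior mean ``2f``.
    """
    L = np.asarray(L, dtype=float)
    w = L * _hwe(f)[:, None, :]
    return (w[:, :, 1] + 2 * w[:, :, 2]) / w.sum(axis=2)


def filter_sites(gl: GLMatrix, maf_min: float = 0.05, max_missing: float = 0.0):
    """Keep sites with EM MAF >= ``maf_min`` and missingness <= ``max_missing``.

    The default ``max_missing=0`` keeps only sites covered in all
    individuals.  Returns the filtered panel and a removal report.
    """
    if not (0 <= maf_min <= 1) or not (0 <= max_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss_frac = gl.missing_mask().mean(axis=1)
    ok_missing = miss_frac <= max_missing
    maf = np.zeros(gl.n_sites)
    # frequency is estimated only where at least one individual has data
    has_data = miss_frac < 1.0
    if has_data.any():
        f = allele_freq_em(gl.L[has_data])
        maf[has_data] = np.minimum(f, 1 - f)
    ok_maf = maf >= maf_min
    keep = ok_missing & ok_maf
    report = {
        "n_input": gl.n_sites,
        "removed_missing": int((~ok_missing).sum()),
        "removed_maf": int((ok_missing & ~ok_maf).sum()),
        "n_kept": int(keep.sum()),
    }
    return gl.subset_sites(keep), report


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def ld_prune(gl: GLMatrix, r2_threshold: float = 0.2, max_dist_bp: int = 100_000):
    """Prune linked sites, keeping the most central site of each linked block.

    r² is the squared Pearson correlation of posterior mean genotypes
    (composite LD) between site pairs closer than ``max_dist_bp`` on the same
    chromosome.  Blocks are connected components of the r² > threshold graph;
    the kept member minimises the bp distance to the block midpoint (lower
    position on ties).  Returns (pruned GLMatrix, list of LinkedBlock).
    """
    for _, sub in gl.sites.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
            raise ValueError("sites must be position-sorted within chromosomes")
    f = allele_freq_em(gl.L)
    dose = posterior_mean_genotypes(gl.L, f)
    dose = dose - dose.mean(axis=1, keepdims=True)
    norm = np.sqrt((dose**2).sum(axis=1))
    norm[norm == 0] = np.inf  # monomorphic posterior: uncorrelated with anything
    dosen = dose / norm[:, None]

    chrom = gl.sites["chrom"].to_numpy()
    pos = gl.sites["pos"].to_numpy()
    uf = _UnionFind(gl.n_sites)
    all_edges = []
    for i in range(gl.n_sites):
        j = i + 1
        hi = i
        while hi + 1 < gl.n_sites and chrom[hi + 1] == chrom[i] and pos[hi + 1] - pos[i] <= max_dist_bp:
            hi += 1
        if hi < j:
            continue
        r = dosen[j : hi + 1] @ dosen[i]
        for k, rv in zip(range(j, hi + 1), r):
            r2 = rv * rv
            if r2 > r2_threshold:
                uf.union(i, k)
                all_edges.append((i, k, float(r2)))
    edges = {}
    for i, k, r2 in all_edges:
        edges.setdefault(uf.find(i), []).append((i, k, r2))

    groups = {}
    for i in range(gl.n_sites):
        groups.setdefault(uf.find(i), []).append(i)
    keep = []
    blocks = []
    for root, members in groups.items():
        if len(members) == 1:
            keep.append(members[0])
            continue
        p = pos[np.array(members)]
        mid = (p.min() + p.max()) / 2.0
        # most central by bp; ties resolved toward the lower position
        best = min(members, key=lambda m: (abs(pos[m] - mid), pos[m]))
        keep.append(best)
        blocks.append(LinkedBlock(members=sorted(members), representative=best,
                                  r2_edges=edges.get(root, [])))
    keep = sorted(keep)
    return gl.subset_sites(keep), blocks
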
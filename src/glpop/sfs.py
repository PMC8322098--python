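"""Folded site-frequency spectra from genotype likelihoods, and the
diversity statistics built on them: theta_pi, Watterson's theta, Tajima's D,
individual heterozygosity, windowed heterozygosity tracks, runs of
homozygosity (RoH) and the inbreeding coefficient F_RoH.

The SFS likelihood for a site given a minor-allele count uses the standard
dynamic-programming convolution of per-individual GL triples with
multivariate-hypergeometric configuration weights; folding averages the two
unfolded assignments of each folded class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .gl import GLMatrix

__all__ = [
    "FoldedSFS1D",
    "FoldedSFS2D",
    "SFSStats",
    "HetTrack",
    "RoHSegment",
    "site_count_likelihoods",
    "sfs1d_em",
    "sfs2d_em",
    "sfs_summary_stats",
    "tajima_constants",
    "tajimas_d_from_pi_s",
    "individual_heterozygosity",
    "window_het_track",
    "roh_cutoff",
    "call_roh_and_froh",
]


@dataclass
class FoldedSFS1D:
    """Folded 1D spectrum: expected site counts per minor-allele class.

    ``counts[k]`` is the expected number of sites with folded minor-allele
    count ``k`` for ``k = 0..N`` diploid-pair classes (2N chromosomes).
    """

    n_chromosomes: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n_chromosomes // 2 + 1:
            raise ValueError("folded spectrum must have N+1 = n_chromosomes/2 + 1 classes")
        if np.any(self.counts < -1e-9):
            raise ValueError("counts must be non-negative")

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class FoldedSFS2D:
    """Folded joint spectrum for two populations.

    Stored on the full unfolded grid (2N1+1, 2N2+1) with mass split equally
    between each folded cell's two unfolded assignments, so the matrix is
    symmetric under joint conjugation (j1, j2) -> (2N1-j1, 2N2-j2).
    """

    n_chromosomes: tuple
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n1, n2 = self.n_chromosomes
        if self.matrix.shape != (n1 + 1, n2 + 1):
            raise ValueError("matrix shape must be (2N1+1, 2N2+1)")
        if np.any(self.matrix < -1e-9):
            raise ValueError("entries must be non-negative")

    @property
    def total_sites(self) -> float:
        return float(self.matrix.sum())

    def marginal(self, which: int) -> FoldedSFS1D:
        axis = 1 - which
        m = self.matrix.sum(axis=axis)
        n = self.n_chromosomes[which]
        folded = np.array([m[k] + m[n - k] if k != n - k else m[k] for k in range(n // 2 + 1)])
        return FoldedSFS1D(n_chromosomes=n, counts=folded)


@dataclass
class SFSStats:
    theta_pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float  # NaN when undefined (S == 0)
    segregating_sites: float
    total_sites: float


@dataclass
class HetTrack:
    """Windowed heterozygosity for one individual."""

    individual: str
    windows: pd.DataFrame  # chrom, start, end, n_sites, het, usable


@dataclass
class RoHSegment:
    individual: str
    chrom: str
    start: int
    end: int
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


def site_count_likelihoods(L: np.ndarray, fold: bool = True) -> np.ndarray:
    """P(data | minor-allele count) per site.

    For N diploids the unfolded count j runs over 0..2N with

        P(data | j) = coeff_j[ prod_i (L_i0 + 2 L_i1 z + L_i2 z^2) ] / C(2N, j)

    (hypergeometric configuration weights).  With ``fold=True`` the two
    unfolded assignments of each folded class are averaged:
    ``P(data | k) = (P(j=k) + P(j=2N-k)) / 2`` for ``k < N`` and ``P(j=N)``
    for the middle class.  Rows are max-normalised (EM is scale-free).
    """
    L = np.asarray(L, dtype=float)
    S, N, _ = L.shape
    coeff = np.zeros((S, 2 * N + 1))
    coeff[:, 0] = 1.0
    for i in range(N):
        tri = np.stack([L[:, i, 0], 2.0 * L[:, i, 1], L[:, i, 2]], axis=1)
        new = np.zeros((S, 2 * i + 3))
        for g in range(3):
            new[:, g : g + 2 * i + 1] += coeff[:, : 2 * i + 1] * tri[:, g : g + 1]
        coeff = np.zeros((S, 2 * N + 1))
        coeff[:, : 2 * i + 3] = new
        m = coeff.max(axis=1, keepdims=True)
        m[m == 0] = 1.0
        coeff /= m
    q = coeff / comb(2 * N, np.arange(2 * N + 1))[None, :]
    if not fold:
        return q
    folded = np.empty((S, N + 1))
    for k in range(N + 1):
        if k == 2 * N - k:
            folded[:, k] = q[:, k]
        else:
            folded[:, k] = 0.5 * (q[:, k] + q[:, 2 * N - k])
    return folded


def _sfs_em(Q: np.ndarray, tol: float, max_iter: int, return_trajectory=False):
    """Generic mixture-weight EM over per-site class likelihoods ``Q``."""
    S, K = Q.shape
    phi = np.full(K, 1.0 / K)
    traj = []
    for _ in range(max_iter):
        w = Q * phi
        tot = w.sum(axis=1, keepdims=True)
        if np.any(tot == 0):
            raise ValueError("site with zero likelihood under all classes")
        if return_trajectory:
            traj.append(np.log(tot).sum())
        phi_new = (w / tot).mean(axis=0)
        delta = np.abs(phi_new - phi).max()
        phi = phi_new
        if delta < tol:
            break
    if return_trajectory:
        return phi, np.array(traj)
    return phi


def sfs1d_em(gl_or_L, tol: float = 1e-6, max_iter: int = 500, return_trajectory: bool = False):
    """Folded 1D SFS by EM for one population (or one individual).

    Accepts a :class:`~glpop.gl.GLMatrix` or a raw (sites, individuals, 3)
    block.  Sites where every individual is missing are rejected.
    """
    L = gl_or_L.L if isinstance(gl_or_L, GLMatrix) else np.asarray(gl_or_L, dtype=float)
    if L.ndim != 3 or L.shape[1] < 1:
        raise ValueError("need a (sites, individuals, 3) GL block with >=1 individual")
    informative = ~(np.ptp(L, axis=2) == 0).all(axis=1)
    if not informative.any():
        raise ValueError("all sites missing")
    L = L[informative]  # all-missing sites carry no information
    S, N, _ = L.shape
    Q = site_count_likelihoods(L, fold=True)
    out = _sfs_em(Q, tol, max_iter, return_trajectory)
    if return_trajectory:
        phi, traj = out
        return FoldedSFS1D(2 * N, phi * S), traj
    return FoldedSFS1D(2 * N, out * S)


def sfs2d_em(gl_a, gl_b, tol: float = 1e-6, max_iter: int = 500) -> FoldedSFS2D:
    """Folded joint 2D SFS by EM over the two populations' count pair.

    The joint class likelihood factorises over populations; folding is joint
    ((j1, j2) with (2N1-j1, 2N2-j2)), and the estimate is stored with mass
    split equally between the two assignments of each folded cell.
    """
    La = gl_a.L if isinstance(gl_a, GLMatrix) else np.asarray(gl_a, dtype=float)
    Lb = gl_b.L if isinstance(gl_b, GLMatrix) else np.asarray(gl_b, dtype=float)
    if La.shape[0] != Lb.shape[0]:
        raise ValueError("populations must share the site list")
    S = La.shape[0]
    n1, n2 = 2 * La.shape[1], 2 * Lb.shape[1]
    qa = site_count_likelihoods(La, fold=False)
    qb = site_count_likelihoods(Lb, fold=False)
    # joint unfolded likelihood per site, then symmetrise = joint folding
    Q = qa[:, :, None] * qb[:, None, :]
    Q = 0.5 * (Q + Q[:, ::-1, ::-1])
    phi = _sfs_em(Q.reshape(S, -1), tol, max_iter).reshape(n1 + 1, n2 + 1)
    # enforce exact conjugation symmetry (EM preserves it up to roundoff)
    phi = 0.5 * (phi + phi[::-1, ::-1])
    return FoldedSFS2D((n1, n2), phi * S)


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalising constants for n chromosomes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_pi_s(theta_pi_total: float, S: float, n: int) -> float:
    """Tajima's D from total pairwise diversity and segregating sites."""
    if S <= 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (theta_pi_total - S / c["a1"]) / np.sqrt(var)


def sfs_summary_stats(sfs: FoldedSFS1D) -> SFSStats:
    """theta_pi, Watterson's theta and Tajima's D from a folded spectrum.

    Pairwise-difference weights k(n-k)/C(n,2) are invariant under folding, so
    theta_pi is exact on folded input.  Per-site values divide by the total
    number of sites in the spectrum.
    """
    n = sfs.n_chromosomes
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    k = np.arange(len(sfs.counts))
    w = k * (n - k) / (n * (n - 1) / 2.0)
    theta_pi = float(np.sum(w * sfs.counts))
    S = float(sfs.counts[1:].sum())
    c = tajima_constants(n)
    total = sfs.total_sites
    d = tajimas_d_from_pi_s(theta_pi, S, n)
    return SFSStats(
        theta_pi_per_site=theta_pi / total,
        theta_w_per_site=S / c["a1"] / total,
        tajimas_d=d,
        segregating_sites=S,
        total_sites=total,
    )


def individual_heterozygosity(sfs: FoldedSFS1D) -> float:
    """Polymorphic fraction of a single-individual folded spectrum."""
    if sfs.n_chromosomes != 2:
        raise ValueError("individual heterozygosity needs a single-individual SFS")
    total = sfs.counts.sum()
    if total == 0:
        raise ValueError("empty spectrum")
    return float(sfs.counts[1] / total)


def _window_grid(chrom_len: int, window: int, step: int):
    """Deterministic tiling: starts at multiples of step, truncated at the
    chromosome end; trailing windows shorter than one step are dropped."""
    starts = np.arange(0, chrom_len, step)
    out = []
    for s in starts:
        e = min(s + window, chrom_len)
        if e - s >= step:
            out.append((int(s), int(e)))
    return out


def _het_em_grouped(A: np.ndarray, H: np.ndarray, win_id: np.ndarray, n_windows: int,
                    tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Two-class (hom/het) EM run simultaneously for every window.

    ``A`` = per-site folded class-0 likelihood, ``H`` = class-1, ``win_id``
    maps sites to windows.  Returns per-window heterozygosity.
    """
    counts = np.bincount(win_id, minlength=n_windows).astype(float)
    counts[counts == 0] = np.inf
    het = np.full(n_windows, 0.1)
    for _ in range(max_iter):
        h = het[win_id]
        num = h * H
        r = num / ((1 - h) * A + num)
        het_new = np.bincount(win_id, weights=r, minlength=n_windows) / counts
        if np.abs(het_new - het).max() < tol:
            het = het_new
            break
        het = het_new
    return het


def window_het_track(gl: GLMatrix, individual, window: int = 100_000, step: int = 50_000,
                     min_sites: int = 10) -> HetTrack:
    """Local heterozygosity of one individual in sliding windows.

    Per window the single-individual folded SFS is estimated by EM restricted
    to the window's sites and summarised as the polymorphic fraction; windows
    with fewer than ``min_sites`` sites are flagged unusable.
    """
    if window <= 0 or step <= 0 or step > window:
        raise ValueError("need 0 < step <= window")
    try:
        ind_idx = gl.individuals.index(individual)
    except ValueError:
        raise KeyError(f"unknown individual {individual!r}")
    L = gl.L[:, ind_idx, :]
    A = 0.5 * (L[:, 0] + L[:, 2])  # folded class 0 (hom), averaged assignment
    H = L[:, 1]
    rows = []
    chrom_arr = gl.sites["chrom"].to_numpy()
    pos_arr = gl.sites["pos"].to_numpy()
    for chrom, clen in gl.chrom_lengths.items():
        grid = _window_grid(clen, window, step)
        if not grid:
            continue
        on_chrom = chrom_arr == chrom
        cpos = pos_arr[on_chrom]
        cA, cH = A[on_chrom], H[on_chrom]
        starts = np.array([s for s, _ in grid])
        ends = np.array([e for _, e in grid])
        # map each (site, window) incidence; windows overlap so use per-window slices
        het = np.full(len(grid), np.nan)
        nsit = np.zeros(len(grid), dtype=int)
        lo = np.searchsorted(cpos, starts + 1, side="left")
        hi = np.searchsorted(cpos, ends, side="right")
        # grouped EM over an expanded site list (each site appears in every
        # window that contains it)
        idx_all, win_all = [], []
        for w, (l, h) in enumerate(zip(lo, hi)):
            nsit[w] = h - l
            if h - l >= min_sites:
                idx_all.append(np.arange(l, h))
                win_all.append(np.full(h - l, w))
        if idx_all:
            idx_all = np.concatenate(idx_all)
            win_all = np.concatenate(win_all)
            est = _het_em_grouped(cA[idx_all], cH[idx_all], win_all, len(grid))
            usable_w = np.unique(win_all)
            het[usable_w] = est[usable_w]
        for w, (s, e) in enumerate(grid):
            rows.append({"chrom": chrom, "start": s, "end": e, "n_sites": int(nsit[w]),
                         "het": het[w], "usable": bool(nsit[w] >= min_sites)})
    return HetTrack(individual=individual, windows=pd.DataFrame(rows))


def roh_cutoff(tracks, quantile: float = 0.10) -> float:
    """Low-heterozygosity cutoff: the given quantile (linear interpolation)
    of per-window heterozygosity averaged across individuals."""
    if not tracks:
        raise ValueError("no tracks")
    frames = []
    for t in tracks:
        w = t.windows
        frames.append(w.assign(ind=t.individual))
    allw = pd.concat(frames)
    usable = allw[allw["usable"]]
    if usable.empty:
        raise ValueError("no usable windows")
    means = usable.groupby(["chrom", "start"])["het"].mean().to_numpy()
    return float(np.quantile(means, quantile))


def call_roh_and_froh(track: HetTrack, cutoff: float, min_len: int = 150_000):
    """Call RoH segments and the inbreeding coefficient F_RoH.

    A run of >= 2 consecutive usable windows with heterozygosity below the
    cutoff becomes one segment spanning from the first window start to the
    last window end (overlapping windows merge by construction); unusable
    windows break runs.  ``F_RoH`` is the summed length of segments of at
    least ``min_len`` divided by the total span scanned (union of usable
    windows).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    w = track.windows
    if not w["usable"].any():
        raise ValueError("no usable windows")
    segments = []
    scanned = 0
    for chrom, sub in w.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        us = sub[sub["usable"]]
        # union length of usable windows
        last_end = -1
        for s, e in zip(us["start"], us["end"]):
            scanned += e - max(s, last_end) if e > last_end else 0
            last_end = max(last_end, e)
        run = []
        for _, row in sub.iterrows():
            if row["usable"] and row["het"] < cutoff:
                run.append(row)
            else:
                if len(run) >= 2:
                    segments.append(RoHSegment(track.individual, chrom,
                                               int(run[0]["start"]), int(run[-1]["end"]),
                                               len(run)))
                run = []
        if len(run) >= 2:
            segments.append(RoHSegment(track.individual, chrom,
                                       int(run[0]["start"]), int(run[-1]["end"]), len(run)))
    froh = sum(s.length for s in segments if s.length >= min_len) / scanned if scanned else float("nan")
    return segments, float(froh)
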
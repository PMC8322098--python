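"""Population differentiation and admixture statistics.

F_ST uses the Hudson/Bhatia ratio-of-averages estimator evaluated over a
folded joint site-frequency spectrum (global and pairwise) or over per-site
posterior expectations for sliding windows.  f3- and D-statistics follow the
standard allele-frequency-moment definitions, with significance from a
weighted delete-one block jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gl import GLMatrix, allele_freq_em
from .sfs import FoldedSFS2D, site_count_likelihoods

__all__ = [
    "FstEstimate",
    "hudson_components",
    "fst_from_sfs2d",
    "site_fst_components",
    "sliding_window_fst",
    "block_jackknife",
    "assign_blocks",
    "dstat",
    "f3stat",
    "colony_freqs_em",
]


@dataclass
class FstEstimate:
    alpha_sum: float
    beta_sum: float

    @property
    def fst(self) -> float:
        if self.beta_sum == 0:
            return float("nan")
        return self.alpha_sum / self.beta_sum

    @property
    def slatkin(self) -> float:
        """Slatkin's linearised F_ST, F/(1-F)."""
        f = self.fst
        return f / (1 - f) if np.isfinite(f) and f < 1 else float("nan")


def hudson_components(n1: int, n2: int):
    """Per-cell unbiased Hudson numerator/denominator grids.

    For sample minor-allele counts (j1, j2) out of (n1, n2) chromosomes:
    ``alpha = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    ``beta = p1(1-p2) + p2(1-p1)``.  Both grids are symmetric under joint
    conjugation, so the two unfolded assignments of a folded cell agree and
    folding introduces no ambiguity.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 chromosomes per population")
    p1 = np.arange(n1 + 1)[:, None] / n1
    p2 = np.arange(n2 + 1)[None, :] / n2
    alpha = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    beta = p1 * (1 - p2) + p2 * (1 - p1)
    return alpha, beta


def fst_from_sfs2d(sfs: FoldedSFS2D) -> FstEstimate:
    """Global Hudson F_ST (ratio of averages) from a folded joint SFS."""
    n1, n2 = sfs.n_chromosomes
    alpha, beta = hudson_components(n1, n2)
    a = float(np.sum(sfs.matrix * alpha))
    b = float(np.sum(sfs.matrix * beta))
    return FstEstimate(alpha_sum=a, beta_sum=b)


def site_fst_components(gl_a, gl_b, prior: FoldedSFS2D):
    """Per-site posterior-expected Hudson (alpha, beta) pairs.

    The global folded 2D SFS acts as the prior over joint counts; each site's
    posterior expectation of the per-cell Hudson terms gives additive
    contributions whose total ratio reproduces the global estimate at the EM
    fixed point.
    """
    La = gl_a.L if isinstance(gl_a, GLMatrix) else np.asarray(gl_a)
    Lb = gl_b.L if isinstance(gl_b, GLMatrix) else np.asarray(gl_b)
    qa = site_count_likelihoods(La, fold=False)
    qb = site_count_likelihoods(Lb, fold=False)
    Q = qa[:, :, None] * qb[:, None, :]
    Q = 0.5 * (Q + Q[:, ::-1, ::-1])
    W = Q * prior.matrix[None, :, :]
    W /= W.sum(axis=(1, 2), keepdims=True)
    n1, n2 = prior.n_chromosomes
    alpha, beta = hudson_components(n1, n2)
    a = np.einsum("sij,ij->s", W, alpha)
    b = np.einsum("sij,ij->s", W, beta)
    return a, b


def _window_starts(chrom_len: int, window: int, step: int):
    """Tiling that covers chromosome edges with truncated windows so every
    position falls in exactly window/step windows (when step divides window)."""
    first = -window + step
    return np.arange(first, chrom_len, step)


def sliding_window_fst(gl_a: GLMatrix, gl_b: GLMatrix, prior: FoldedSFS2D,
                       window: int = 50_000, step: int = 12_500,
                       min_sites: int = 5) -> pd.DataFrame:
    """Hudson F_ST in sliding windows; per-window sums of per-site terms.

    Windows with fewer than ``min_sites`` sites are flagged unusable rather
    than reported as zero.  Because per-site contributions are additive, the
    ratio of summed window numerators/denominators over any exact tiling
    equals the global estimate.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    a, b = site_fst_components(gl_a, gl_b, prior)
    chrom_arr = gl_a.sites["chrom"].to_numpy()
    pos_arr = gl_a.sites["pos"].to_numpy()
    rows = []
    for chrom, clen in gl_a.chrom_lengths.items():
        on = chrom_arr == chrom
        cpos = pos_arr[on]
        ca, cb = a[on], b[on]
        for s in _window_starts(int(clen), window, step):
            e = min(s + window, clen)
            s0 = max(s, 0)
            lo = np.searchsorted(cpos, s0 + 1, side="left")
            hi = np.searchsorted(cpos, e, side="right")
            n = hi - lo
            asum = float(ca[lo:hi].sum())
            bsum = float(cb[lo:hi].sum())
            rows.append({"chrom": chrom, "start": int(s0), "end": int(e),
                         "n_sites": int(n), "alpha": asum, "beta": bsum,
                         "fst": asum / bsum if (n >= min_sites and bsum > 0) else np.nan,
                         "usable": bool(n >= min_sites)})
    return pd.DataFrame(rows)


def assign_blocks(sites: pd.DataFrame, block_bp: int = 5_000_000) -> np.ndarray:
    """Contiguous genomic block index per site for jackknife/bootstrap."""
    ids = np.empty(len(sites), dtype=int)
    next_id = 0
    for chrom, sub in sites.groupby("chrom", sort=False):
        b = (sub["pos"].to_numpy() - 1) // block_bp
        uniq, inv = np.unique(b, return_inverse=True)
        ids[sub.index.to_numpy()] = inv + next_id
        next_id += len(uniq)
    return ids


def block_jackknife(num: np.ndarray, den: np.ndarray, weights=None):
    """Weighted delete-one block jackknife for a ratio statistic.

    ``num``/``den`` hold per-block numerator and denominator sums; the
    estimate is ``sum(num)/sum(den)``.  Weights default to the block
    denominators.  Returns (estimate, SE, Z).  With equal weights this
    reduces to the textbook delete-one jackknife variance
    ``(n-1)/n * sum((theta_j - mean)^2)``.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    n = len(num)
    if n < 10:
        raise ValueError("need at least 10 blocks")
    w = np.abs(den) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        w = np.full(n, 1.0)
    W = w.sum()
    theta = num.sum() / den.sum()
    theta_j = (num.sum() - num) / (den.sum() - den)
    h = W / w
    tau = h * theta - (h - 1) * theta_j
    theta_jack = n * theta - np.sum((1 - w / W) * theta_j)
    var = np.sum((tau - theta_jack) ** 2 / (h - 1)) / n
    se = float(np.sqrt(var))
    z = theta / se if se > 0 else float("inf")
    return float(theta), se, float(z)


def colony_freqs_em(gl: GLMatrix, colonies=None) -> pd.DataFrame:
    """Per-colony ML allele frequencies (EM) at every site."""
    if colonies is None:
        colonies = list(dict.fromkeys(gl.colonies))
    out = {}
    for c in colonies:
        sub = gl.by_colony(c)
        if sub.n_individuals == 0:
            raise KeyError(f"no individuals in colony {c!r}")
        out[c] = allele_freq_em(sub.L)
    return pd.DataFrame(out)


def dstat(gl: GLMatrix, p1: str, p2: str, p3: str, outgroup: str,
          block_bp: int = 5_000_000, seed: int = 0, mode: str = "sample",
          outgroup_consensus_min: float = 0.9):
    """ABBA-BABA D-statistic with block-jackknife Z.

    The outgroup's consensus (majority) allele defines the ancestral state;
    sites where the outgroup is too polymorphic for a consensus call
    (majority frequency below ``outgroup_consensus_min``) are skipped and
    counted.  In ``sample`` mode one allele is drawn per population per site
    weighted by its EM frequency (mirroring consensus-base sampling engines);
    ``freq`` mode uses frequency-weighted expectations.
    """
    rng = np.random.default_rng(seed)
    freqs = colony_freqs_em(gl, [p1, p2, p3, outgroup])
    fo = freqs[outgroup].to_numpy()
    anc_is_minor = fo > 0.5
    maj = np.maximum(fo, 1 - fo)
    ok = maj >= outgroup_consensus_min
    n_skipped = int((~ok).sum())
    # derived-allele frequency per population
    d = {}
    for p in (p1, p2, p3):
        f = freqs[p].to_numpy()
        d[p] = np.where(anc_is_minor, 1 - f, f)
    if mode == "sample":
        b1 = (rng.random(len(fo)) < d[p1]).astype(float)
        b2 = (rng.random(len(fo)) < d[p2]).astype(float)
        b3 = (rng.random(len(fo)) < d[p3]).astype(float)
    elif mode == "freq":
        b1, b2, b3 = d[p1], d[p2], d[p3]
    else:
        raise ValueError("mode must be 'sample' or 'freq'")
    abba = (1 - b1) * b2 * b3
    baba = b1 * (1 - b2) * b3
    abba[~ok] = 0.0
    baba[~ok] = 0.0
    blocks = assign_blocks(gl.sites, block_bp)
    nb = blocks.max() + 1
    num = np.bincount(blocks, weights=abba - baba, minlength=nb)
    den = np.bincount(blocks, weights=abba + baba, minlength=nb)
    D, se, z = block_jackknife(num, den)
    return {"D": D, "SE": se, "Z": z, "nABBA": float(abba.sum()),
            "nBABA": float(baba.sum()), "n_blocks": int(nb),
            "n_skipped_outgroup": n_skipped}


def f3stat(gl: GLMatrix, target: str, source_a: str, source_b: str,
           block_bp: int = 5_000_000):
    """f3(target; A, B) with the finite-sample heterozygosity correction.

    ``f3 = mean[(c-a)(c-b) - c(1-c)/(n_c - 1)]`` over sites, with c the
    target's EM allele frequency and n_c its chromosome count; Z from the
    weighted block jackknife.  Significantly negative f3 indicates the
    target is a mixture of sources related to A and B.
    """
    n_c = 2 * gl.by_colony(target).n_individuals
    if n_c < 4:
        raise ValueError("target needs at least 2 diploids for the bias correction")
    freqs = colony_freqs_em(gl, [target, source_a, source_b])
    c = freqs[target].to_numpy()
    a = freqs[source_a].to_numpy()
    b = freqs[source_b].to_numpy()
    per_site = (c - a) * (c - b) - c * (1 - c) / (n_c - 1)
    blocks = assign_blocks(gl.sites, block_bp)
    nb = blocks.max() + 1
    num = np.bincount(blocks, weights=per_site, minlength=nb)
    den = np.bincount(blocks, minlength=nb).astype(float)
    f3, se, z = block_jackknife(num, den, weights=den)
    return {"f3": f3, "SE": se, "Z": z, "n_blocks": int(nb)}
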
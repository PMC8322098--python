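"""Population structure from genotype likelihoods: PCA, admixture EM with
replicate alignment/averaging, and Evanno delta-K model choice.

The admixture model is the standard GL-aware mixture: individual i carries
ancestry fractions q_i over K clusters with allele frequencies F, the
individual allele frequency is h_is = sum_k q_ik F_sk, and genotypes are
Binomial(2, h) under the likelihood triples.  EM maximises
sum_sites sum_ind log sum_g GL(g) C(2,g) h^g (1-h)^(2-g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .gl import GLMatrix, allele_freq_em, posterior_mean_genotypes

__all__ = [
    "PCAResult",
    "QMatrix",
    "EvannoTable",
    "pca_gl",
    "admixture_em",
    "align_and_average_replicates",
    "evanno_best_k",
]


@dataclass
class PCAResult:
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns = PCs, rows = individuals
    variance_explained: np.ndarray
    individuals: list

    def coords(self, k: int = 2) -> np.ndarray:
        """Individual coordinates on the first k axes (scaled by sqrt(eig))."""
        lam = np.sqrt(np.maximum(self.eigenvalues[:k], 0))
        return self.eigenvectors[:, :k] * lam


@dataclass
class QMatrix:
    Q: np.ndarray  # individuals x K, rows sum to 1
    F: np.ndarray  # sites x K cluster allele frequencies
    log_likelihood: float
    K: int
    seed: int
    individuals: list

    def __post_init__(self):
        if np.any(self.Q < -1e-9) or np.any(self.Q > 1 + 1e-9):
            raise ValueError("ancestry fractions must lie in [0, 1]")
        if np.abs(self.Q.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("ancestry rows must sum to 1")


@dataclass
class EvannoTable:
    table: pd.DataFrame  # K, n_reps, mean_l, sd_l, lprime, lsecond, delta_k
    best_k: int | None


def pca_gl(gl: GLMatrix) -> PCAResult:
    """Covariance PCA of posterior mean genotypes.

    Posterior mean doses use an HWE prior at the panel EM frequency, are
    standardised by sqrt(2 f (1-f)), and averaged over non-missing pairs.
    Sites fixed at f in {0, 1} are excluded with a warning count.
    Deterministic up to eigenvector sign; signs are fixed so the
    largest-magnitude entry of each PC is positive.
    """
    if gl.n_individuals < 2:
        raise ValueError("need at least two individuals")
    f = allele_freq_em(gl.L)
    keep = (f > 0) & (f < 1)
    f = f[keep]
    L = gl.L[keep]
    dose = posterior_mean_genotypes(L, f)
    z = (dose - 2 * f[:, None]) / np.sqrt(2 * f * (1 - f))[:, None]
    miss = np.ptp(L, axis=2) == 0
    z = np.where(miss, 0.0, z)
    ok = (~miss).astype(float)
    M = ok.T @ ok
    M[M == 0] = 1.0
    cov = (z.T @ z) / M
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for j in range(v.shape[1]):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] = -v[:, j]
    tot = np.sum(np.maximum(w, 0))
    return PCAResult(covariance=cov, eigenvalues=w, eigenvectors=v,
                     variance_explained=np.maximum(w, 0) / tot,
                     individuals=list(gl.individuals))


def admixture_em(gl: GLMatrix, K: int, seed: int = 0, max_iter: int = 2000,
                 tol: float = 1e-4, check_monotone: bool = False,
                 return_trajectory: bool = False, accelerate: bool = True,
                 n_init: int = 1):
    """Admixture-proportion EM (ngsAdmix-style) at a fixed K.

    Stops when the log-likelihood improves by less than ``tol`` between
    (accelerated) iterations, or after ``max_iter``.  Q rows are initialised
    Dirichlet(1), F uniform in (0.05, 0.95); F is floored at 1e-5 to avoid
    log(0).  ``accelerate=True`` wraps the EM map in SQUAREM extrapolation
    with a monotonicity safeguard (falls back to the plain double step
    whenever the extrapolated point does not improve the likelihood), so the
    reported log-likelihood trajectory is still non-decreasing.  ``n_init``
    runs that many independently initialised optimisations and returns the
    best, the usual mixture-EM guard against poor random starts; ``n_init=1``
    is a single-start run.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gl.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    L = gl.L
    S, N, _ = L.shape
    floor = 1e-5

    def loglik(Q_, F_):
        h = np.clip(F_ @ Q_.T, floor, 1 - floor)
        P = (L[:, :, 0] * (1 - h) ** 2 + L[:, :, 1] * 2 * h * (1 - h) + L[:, :, 2] * h**2)
        return float(np.log(np.maximum(P, 1e-300)).sum())

    def em_step(Q_, F_):
        h = np.clip(F_ @ Q_.T, floor, 1 - floor)
        w1 = L[:, :, 1] * 2 * h * (1 - h)
        w2 = L[:, :, 2] * h**2
        tot = L[:, :, 0] * (1 - h) ** 2 + w1 + w2
        eg = (w1 + 2 * w2) / tot            # expected minor dose
        U = eg / h
        V = (2 - eg) / (1 - h)
        UQ = U @ Q_
        VQ = V @ Q_
        F_new = np.clip(F_ * UQ / (F_ * UQ + (1 - F_) * VQ), floor, 1 - floor)
        Q_new = Q_ * (U.T @ F_ + V.T @ (1 - F_)) / (2 * S)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        return Q_new, F_new

    def project(Q_, F_):
        Q_ = np.clip(Q_, 1e-8, None)
        Q_ /= Q_.sum(axis=1, keepdims=True)
        return Q_, np.clip(F_, floor, 1 - floor)

    def run_once(Q, F):
        ll = loglik(Q, F)
        traj = [ll]
        it = 0
        while it < max_iter:
            Q1, F1 = em_step(Q, F)
            Q2, F2 = em_step(Q1, F1)
            it += 2
            if accelerate:
                rQ, rF = Q1 - Q, F1 - F
                vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
                vnorm = np.sqrt(np.sum(vQ**2) + np.sum(vF**2))
                if vnorm > 0:
                    alpha = -np.sqrt((np.sum(rQ**2) + np.sum(rF**2))) / vnorm
                    alpha = min(alpha, -1.0)
                    Qs, Fs = project(Q - 2 * alpha * rQ + alpha**2 * vQ,
                                     F - 2 * alpha * rF + alpha**2 * vF)
                    Qs, Fs = em_step(Qs, Fs)  # stabilising EM step
                    it += 1
                    if loglik(Qs, Fs) >= loglik(Q2, F2):
                        Q2, F2 = Qs, Fs
            ll_new = loglik(Q2, F2)
            if check_monotone and ll_new < ll - 1e-6 * max(1.0, abs(ll)):
                raise AssertionError(f"log-likelihood decreased: {ll} -> {ll_new}")
            delta = ll_new - ll
            Q, F = Q2, F2
            ll = ll_new
            traj.append(ll)
            if abs(delta) < tol:
                break
        return Q, F, ll, traj

    if K == 1:
        Q = np.ones((N, 1))
        F = allele_freq_em(L)[:, None]
        Q, F, ll, traj = Q, F, loglik(Q, F), [loglik(Q, F)]
    else:
        best = None
        for _ in range(max(1, n_init)):
            Q0 = rng.dirichlet(np.ones(K), size=N)
            F0 = rng.uniform(0.05, 0.95, size=(S, K))
            out = run_once(Q0, F0)
            if best is None or out[2] > best[2]:
                best = out
        Q, F, ll, traj = best
    qm = QMatrix(Q=Q, F=F, log_likelihood=ll, K=K, seed=seed,
                 individuals=list(gl.individuals))
    if return_trajectory:
        return qm, np.array(traj)
    return qm


def _align_columns(ref: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Permutation of ``run`` columns maximising agreement with ``ref``."""
    K = ref.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.sum((ref[:, a] - run[:, b]) ** 2)
    _, perm = linear_sum_assignment(cost)
    return perm


def align_and_average_replicates(runs, rmsd_threshold: float = 0.05):
    """CLUMPAK-style replicate handling: align columns to the best-likelihood
    run, cluster runs by post-alignment RMSD, and average the largest cluster.

    Returns (averaged QMatrix, list of clusters as run-index lists).
    """
    if not runs:
        raise ValueError("no runs")
    if len({r.K for r in runs}) != 1:
        raise ValueError("runs must share K")
    if len(runs) == 1:
        return runs[0], [[0]]
    best = int(np.argmax([r.log_likelihood for r in runs]))
    ref = runs[best].Q
    aligned = []
    for r in runs:
        perm = _align_columns(ref, r.Q)
        aligned.append(r.Q[:, perm])
    rmsd = np.array([np.sqrt(np.mean((a - ref) ** 2)) for a in aligned])
    # single-linkage components of the RMSD <= threshold graph (to the ref
    # and transitively among runs)
    n = len(runs)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.sqrt(np.mean((aligned[i] - aligned[j]) ** 2)) <= rmsd_threshold:
                parent[find(j)] = find(i)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    clusters = sorted(comps.values(), key=lambda c: (-len(c), c))
    major = clusters[0]
    if best not in major:
        # prefer the cluster containing the best run on size ties
        for c in clusters:
            if best in c and len(c) == len(major):
                major = c
                break
    mean_q = np.mean([aligned[i] for i in major], axis=0)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    out = QMatrix(Q=mean_q, F=runs[best].F, K=runs[best].K,
                  log_likelihood=float(np.mean([runs[i].log_likelihood for i in major])),
                  seed=runs[best].seed, individuals=runs[best].individuals)
    return out, clusters


def evanno_best_k(logls: dict) -> EvannoTable:
    """Evanno et al. second-order model choice over replicate log-likelihoods.

    ``logls`` maps K -> list of replicate log-likelihoods.  L'(K) is the mean
    first difference, L''(K) = |L'(K+1) - L'(K)| and delta-K = L''(K)/sd(K),
    defined for interior K only.  K values with zero replicate sd are
    reported as infinite but excluded from the argmax.
    """
    ks = sorted(logls)
    rows = []
    means = {k: float(np.mean(logls[k])) for k in ks}
    sds = {k: float(np.std(logls[k], ddof=1)) if len(logls[k]) > 1 else 0.0 for k in ks}
    for v in logls.values():
        if not np.all(np.isfinite(v)):
            raise ValueError("replicate log-likelihoods must be finite")
    for k in ks:
        lp = means[k] - means[k - 1] if k - 1 in means else np.nan
        lp_next = means[k + 1] - means[k] if k + 1 in means else np.nan
        lsec = abs(lp_next - lp) if np.isfinite(lp) and np.isfinite(lp_next) else np.nan
        if np.isfinite(lsec):
            dk = lsec / sds[k] if sds[k] > 0 else float("inf")
        else:
            dk = np.nan
        rows.append({"K": k, "n_reps": len(logls[k]), "mean_l": means[k],
                     "sd_l": sds[k], "lprime": lp, "lsecond": lsec, "delta_k": dk})
    df = pd.DataFrame(rows)
    interior = df[np.isfinite(df["delta_k"])]
    if interior.empty or np.allclose(interior["delta_k"], 0):
        return EvannoTable(table=df, best_k=None)
    best = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return EvannoTable(table=df, best_k=best)
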
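"""Geographic distance over water and isolation-by-distance inference.

Least-cost-path distances run Dijkstra over the water cells of a rasterised
lat/lon grid (8-neighbourhood, great-circle edge costs), the ecologically
meaningful between-colony distance for seabirds.  IBD is tested with a
Mantel permutation test and multiple regression on distance matrices (MRM),
plus the greedy progressive-removal refinement that drops the colony whose
removal most improves the variance explained by geography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .simdata import Geography
from .trees import DistMatrix

__all__ = [
    "IBDResult",
    "RemovalTrajectory",
    "haversine_km",
    "water_lcp_distance",
    "mantel_test",
    "mrm",
    "progressive_removal",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class IBDResult:
    mantel_r: float
    mantel_p: float
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    colonies: list


@dataclass
class RemovalTrajectory:
    removed: list
    r_squared: list  # R^2 after each removal; [0] = full matrix
    stopped_because: str


def haversine_km(lat1, lon1, lat2, lon2):
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def _snap_to_water(geo: Geography, lat, lon, max_cells: int = 2):
    r0, c0 = geo.cell_of(lat, lon)
    nrows, ncols = geo.shape
    best = None
    for dr in range(-max_cells, max_cells + 1):
        for dc in range(-max_cells, max_cells + 1):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < nrows and 0 <= c < ncols and geo.water[r, c]:
                cl, cg = geo.cell_center(r, c)
                dist = haversine_km(lat, lon, cl, cg)
                if best is None or dist < best[0]:
                    best = (dist, r, c)
    if best is None:
        raise ValueError(f"no water cell within {max_cells} cells of ({lat}, {lon})")
    return best[1], best[2]


def water_lcp_distance(geo: Geography) -> DistMatrix:
    """Least-cost-path distances (km) between colonies over water cells."""
    nrows, ncols = geo.shape
    idx = -np.ones((nrows, ncols), dtype=int)
    wr, wc = np.nonzero(geo.water)
    idx[wr, wc] = np.arange(len(wr))
    lat_c = geo.lat_min + (wr + 0.5) * geo.cell_deg
    lon_c = geo.lon_min + (wc + 0.5) * geo.cell_deg
    rows, cols, costs = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r2, c2 = wr + dr, wc + dc
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
        ok[ok] &= geo.water[r2[ok], c2[ok]]
        a = idx[wr[ok], wc[ok]]
        b = idx[r2[ok], c2[ok]]
        cost = haversine_km(lat_c[ok], lon_c[ok],
                            geo.lat_min + (r2[ok] + 0.5) * geo.cell_deg,
                            geo.lon_min + (c2[ok] + 0.5) * geo.cell_deg)
        rows.extend([a, b])
        cols.extend([b, a])
        costs.extend([cost, cost])
    n = len(wr)
    g = coo_matrix((np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n, n)).tocsr()
    names = list(geo.colonies["name"])
    sources = []
    for _, row in geo.colonies.iterrows():
        r, c = _snap_to_water(geo, row["lat"], row["lon"])
        sources.append(idx[r, c])
    dist = dijkstra(g, indices=sources)
    m = dist[:, sources]
    m = 0.5 * (m + m.T)  # symmetric up to float noise
    if np.any(~np.isfinite(m)):
        i, j = np.argwhere(~np.isfinite(m))[0]
        raise ValueError(f"colonies not connected through water: {names[i]}, {names[j]}")
    np.fill_diagonal(m, 0.0)
    return DistMatrix(names, m)


def _lower(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel_test(d1: DistMatrix, d2: DistMatrix, n_perm: int = 999, seed: int = 0,
                alternative: str = "greater"):
    """Mantel test: Pearson r of lower triangles, permutation p-value.

    One matrix's labels are jointly permuted over rows and columns;
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)`` for the one-tailed
    (greater) alternative.
    """
    if d1.labels != d2.labels:
        raise ValueError("matrices must share labels in the same order")
    x = _lower(d1.matrix)
    y = _lower(d2.matrix)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(d1.labels)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = _lower(d2.matrix[np.ix_(p, p)])
        r = np.corrcoef(x, yp)[0, 1]
        if alternative == "greater" and r >= r_obs - 1e-15:
            count += 1
        elif alternative == "two-sided" and abs(r) >= abs(r_obs) - 1e-15:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def mrm(response: DistMatrix, predictors, n_perm: int = 999, seed: int = 0):
    """Multiple regression on distance matrices (OLS on lower triangles).

    Coefficient significance comes from jointly permuting the response
    matrix's labels; R^2 significance is one-tailed.  Raises on collinear
    predictors (condition number > 1e10).
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    for p in predictors:
        if p.labels != response.labels:
            raise ValueError("all matrices must share labels")
    y = _lower(response.matrix)
    X = np.column_stack([np.ones(len(y))] + [_lower(p.matrix) for p in predictors])
    if np.linalg.cond(X) > 1e10:
        raise ValueError("collinear predictors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rng = np.random.default_rng(seed)
    n = len(response.labels)
    exceed_b = np.zeros(len(beta))
    exceed_r2 = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = _lower(response.matrix[np.ix_(p, p)])
        bp, *_ = np.linalg.lstsq(X, yp, rcond=None)
        yhp = X @ bp
        r2p = 1 - np.sum((yp - yhp) ** 2) / np.sum((yp - yp.mean()) ** 2)
        exceed_b += np.abs(bp) >= np.abs(beta) - 1e-15
        exceed_r2 += r2p >= r2 - 1e-15
    p_b = (exceed_b + 1) / (n_perm + 1)
    p_r2 = (exceed_r2 + 1) / (n_perm + 1)
    return {"coef": beta, "p_coef": p_b, "r_squared": float(r2), "p_r_squared": float(p_r2)}


def progressive_removal(genetic: DistMatrix, geographic: DistMatrix,
                        max_removals: int = 4, min_gain: float = 0.01,
                        n_perm: int = 0, seed: int = 0) -> RemovalTrajectory:
    """Greedy colony removal maximising the variance in genetic distance
    explained by geographic distance.

    At each step every remaining colony is tentatively removed, the
    single-predictor regression refitted, and the colony with the largest
    R^2 gain dropped; stops after ``max_removals``, when the best gain falls
    below ``min_gain``, or when fewer than 5 colonies would remain.
    """
    if genetic.labels != geographic.labels:
        raise ValueError("matrices must share labels")
    if len(genetic.labels) < 5:
        raise ValueError("need at least 5 colonies")

    def fit_r2(gen, geo):
        return mrm(gen, [geo], n_perm=0)["r_squared"]

    gen, geo = genetic, geographic
    removed = []
    r2s = [fit_r2(gen, geo)]
    reason = "max_removals reached"
    for _ in range(max_removals):
        if len(gen.labels) - 1 < 5:
            reason = "fewer than 5 colonies would remain"
            break
        best = None
        for cand in gen.labels:
            r2 = fit_r2(gen.drop([cand]), geo.drop([cand]))
            if best is None or r2 > best[1]:
                best = (cand, r2)
        gain = best[1] - r2s[-1]
        if gain < min_gain:
            reason = f"best gain {gain:.4f} below min_gain"
            break
        removed.append(best[0])
        r2s.append(best[1])
        gen = gen.drop([best[0]])
        geo = geo.drop([best[0]])
    return RemovalTrajectory(removed=removed, r_squared=r2s, stopped_because=reason)
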
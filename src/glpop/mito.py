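"""Mitochondrial haplotype summaries and population differentiation.

Haplotypes are collapsed by exact identity at all co-called columns;
diversity statistics (haplotype diversity h, nucleotide diversity pi,
Tajima's D) are computed per group; Phi_ST and the three-level hierarchical
AMOVA follow the classical sums-of-squared-pairwise-differences variance
decomposition with permutation significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfs import tajimas_d_from_pi_s

__all__ = [
    "HaplotypeSet",
    "AmovaResult",
    "seqs_to_array",
    "pairwise_diffs",
    "collapse_haplotypes",
    "mito_diversity",
    "pairwise_phist",
    "amova",
]

_MISSING = set("NRYSWKMBDHV-?.")


@dataclass
class HaplotypeSet:
    sequences: list           # representative sequence per haplotype
    counts: pd.DataFrame      # haplotype x colony counts
    assignments: dict         # individual -> haplotype index

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_ct: float
    p_phi_sc: float
    p_phi_st: float
    table: pd.DataFrame


def seqs_to_array(records) -> tuple:
    """(names, (n, L) uint8 array) with 255 marking missing/ambiguous."""
    names = [n for n, _ in records]
    L = len(records[0][1])
    for n, s in records:
        if len(s) != L:
            raise ValueError(f"sequence length mismatch for {n}")
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.vstack([lut[np.frombuffer(s.encode(), dtype=np.uint8)] for _, s in records])
    return names, arr


def pairwise_diffs(arr: np.ndarray) -> np.ndarray:
    """Number of differing co-called positions for every sequence pair."""
    n = arr.shape[0]
    d = np.zeros((n, n))
    called = arr != 255
    for i in range(n):
        both = called[i] & called
        diff = (arr[i] != arr) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0)
    return d


def collapse_haplotypes(records, colony_of: dict) -> HaplotypeSet:
    """Collapse sequences into haplotypes.

    Two sequences belong to the same haplotype when they agree at every
    column where both are called; sequences differing only by missingness
    collapse together, with the more complete sequence kept as the
    representative.
    """
    names, arr = seqs_to_array(records)
    called = arr != 255
    reps = []      # (array row, n_called, representative name)
    assign = {}
    for i, name in enumerate(names):
        hit = None
        for h, (row, ncall, rep) in enumerate(reps):
            both = called[i] & (row != 255)
            if not np.any((arr[i] != row) & both):
                hit = h
                break
        if hit is None:
            reps.append([arr[i].copy(), int(called[i].sum()), name])
            assign[name] = len(reps) - 1
        else:
            assign[name] = hit
            if called[i].sum() > reps[hit][1]:
                reps[hit] = [arr[i].copy(), int(called[i].sum()), name]
    colonies = sorted(set(colony_of.values()))
    counts = pd.DataFrame(0, index=range(len(reps)), columns=colonies)
    for name, h in assign.items():
        counts.loc[h, colony_of[name]] += 1
    bases = np.array(list("ACGTN"))
    seqs = ["".join(bases[np.where(r[0] == 255, 4, r[0])]) for r in reps]
    return HaplotypeSet(sequences=seqs, counts=counts, assignments=assign)


def mito_diversity(records, group_of: dict | None = None) -> pd.DataFrame:
    """h, pi (per site), S and Tajima's D per group (None = one global group)."""
    names, arr = seqs_to_array(records)
    L = arr.shape[1]
    if group_of is None:
        group_of = {n: "all" for n in names}
    rows = []
    for grp in sorted(set(group_of.values())):
        idx = [i for i, n in enumerate(names) if group_of.get(n) == grp]
        n = len(idx)
        if n < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 sequences")
        sub = arr[idx]
        d = pairwise_diffs(sub)
        iu = np.triu_indices(n, k=1)
        mean_pair = d[iu].mean()
        # haplotype diversity on exact-identity within the group
        hs = collapse_haplotypes([(names[i], "".join("ACGTN"[min(b, 4)] for b in arr[i]))
                                  for i in idx], {names[i]: "g" for i in idx})
        cnt = hs.counts.sum(axis=1).to_numpy()
        p = cnt / cnt.sum()
        h = n / (n - 1) * (1 - np.sum(p**2))
        called_all = (sub != 255).all(axis=0)
        seg = np.sum(called_all & (np.ptp(sub, axis=0) > 0))
        D = tajimas_d_from_pi_s(mean_pair, float(seg), n)
        rows.append({"group": grp, "n": n, "n_haplotypes": hs.n_haplotypes,
                     "h": float(h), "pi_per_site": mean_pair / L,
                     "S": int(seg), "tajimas_d": D})
    return pd.DataFrame(rows)


def _two_level_components(d2: np.ndarray, groups: np.ndarray):
    """Variance components for a one-level AMOVA (groups of individuals)."""
    N = len(groups)
    labels = np.unique(groups)
    G = len(labels)
    iu = np.triu_indices(N, k=1)
    ssd_total = d2[iu].sum() / N
    ssd_within = 0.0
    sizes = []
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sizes.append(len(idx))
        sub = d2[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    sizes = np.array(sizes)
    df_among = G - 1
    df_within = N - G
    if df_within == 0:
        return np.nan, np.nan
    n_eff = (N - np.sum(sizes**2) / N) / df_among
    ms_within = ssd_within / df_within
    ms_among = ssd_among / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_eff
    return sigma_a, sigma_w


def pairwise_phist(records, colony_of: dict, n_perm: int = 999, seed: int = 0):
    """Pairwise Phi_ST matrix (+ one-tailed permutation p-values).

    Phi_ST = sigma2_among / (sigma2_among + sigma2_within) from the
    squared-pairwise-difference AMOVA for each colony pair; permutations
    shuffle individuals between the two colonies.
    """
    names, arr = seqs_to_array(records)
    d2 = pairwise_diffs(arr)  # difference counts serve as squared distances
    colonies = sorted({colony_of[n] for n in names})
    rng = np.random.default_rng(seed)
    phi = pd.DataFrame(0.0, index=colonies, columns=colonies)
    pval = pd.DataFrame(1.0, index=colonies, columns=colonies)
    col_arr = np.array([colony_of[n] for n in names])
    for i, a in enumerate(colonies):
        for b in colonies[i + 1 :]:
            idx = np.flatnonzero((col_arr == a) | (col_arr == b))
            if min(np.sum(col_arr[idx] == a), np.sum(col_arr[idx] == b)) < 2:
                raise ValueError("need >= 2 individuals per group")
            sub = d2[np.ix_(idx, idx)]
            labs = col_arr[idx]
            sa, sw = _two_level_components(sub, labs)
            tot = sa + sw
            obs = sa / tot if tot > 0 else np.nan
            phi.loc[a, b] = phi.loc[b, a] = obs
            if not np.isfinite(obs):
                pval.loc[a, b] = pval.loc[b, a] = np.nan
                continue
            count = 0
            for _ in range(n_perm):
                pl = rng.permutation(labs)
                sa_p, sw_p = _two_level_components(sub, pl)
                tp = sa_p + sw_p
                if tp > 0 and sa_p / tp >= obs - 1e-15:
                    count += 1
            pval.loc[a, b] = pval.loc[b, a] = (count + 1) / (n_perm + 1)
    return phi, pval


def _amova_components(d2, colony_arr, group_arr):
    """Three-level Excoffier-style variance components."""
    N = len(colony_arr)
    iu = np.triu_indices(N, k=1)
    ssd_total = d2[iu].sum() / N
    groups = np.unique(group_arr)
    colonies = np.unique(colony_arr)
    G, P = len(groups), len(colonies)

    ssd_wp = 0.0
    for p in colonies:
        idx = np.flatnonzero(colony_arr == p)
        sub = d2[np.ix_(idx, idx)]
        ssd_wp += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_wg = 0.0
    for g in groups:
        idx = np.flatnonzero(group_arr == g)
        sub = d2[np.ix_(idx, idx)]
        ssd_wg += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P
    n_p = {p: np.sum(colony_arr == p) for p in colonies}
    n_g = {g: np.sum(group_arr == g) for g in groups}
    grp_of_colony = {}
    for p in colonies:
        grp_of_colony[p] = group_arr[np.flatnonzero(colony_arr == p)[0]]
    s1 = sum(n_p[p] ** 2 / n_g[grp_of_colony[p]] for p in colonies)
    s2 = sum(n_p[p] ** 2 for p in colonies) / N
    s3 = sum(n_g[g] ** 2 for g in groups) / N
    n1 = (N - s1) / df_ap if df_ap > 0 else np.nan
    n2 = (s1 - s2) / df_ag if df_ag > 0 else np.nan
    n3 = (N - s3) / df_ag if df_ag > 0 else np.nan

    ms_wp = ssd_wp / df_wp if df_wp > 0 else np.nan
    ms_ap = ssd_ap_wg / df_ap if df_ap > 0 else np.nan
    ms_ag = ssd_ag / df_ag if df_ag > 0 else np.nan
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if df_ag > 0 else 0.0
    ssd = {"ag": ssd_ag, "ap": ssd_ap_wg, "wp": ssd_wp, "total": ssd_total,
           "df": (df_ag, df_ap, df_wp)}
    return sigma_a, sigma_b, sigma_c, ssd


def amova(records, colony_of: dict, group_of_colony: dict, n_perm: int = 999,
          seed: int = 0) -> AmovaResult:
    """Hierarchical AMOVA (groups > colonies > individuals).

    Permutation schemes: Phi_CT permutes whole colonies among groups;
    Phi_SC permutes individuals among colonies within their group; Phi_ST
    permutes individuals among all colonies.
    """
    names, arr = seqs_to_array(records)
    d2 = pairwise_diffs(arr)  # difference counts serve as squared distances
    colony_arr = np.array([colony_of[n] for n in names])
    group_arr = np.array([group_of_colony[c] for c in colony_arr])
    if len(np.unique(colony_arr)) < 2:
        raise ValueError("need at least 2 colonies")
    sa, sb, sc, ssd = _amova_components(d2, colony_arr, group_arr)
    total = sa + sb + sc
    phi_ct = sa / total if total > 0 else np.nan
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else np.nan
    phi_st = (sa + sb) / total if total > 0 else np.nan
    rng = np.random.default_rng(seed)

    colonies = list(np.unique(colony_arr))
    grp_of = {c: group_of_colony[c] for c in colonies}
    c_ct = c_sc = c_st = 0
    for _ in range(n_perm):
        # Phi_ST: individuals among all colonies
        perm = rng.permutation(colony_arr)
        garr = np.array([grp_of[c] for c in perm])
        a, b, c = _amova_components(d2, perm, garr)[:3]
        t = a + b + c
        if t > 0 and (a + b) / t >= phi_st - 1e-15:
            c_st += 1
        # Phi_SC: individuals among colonies within groups
        perm2 = colony_arr.copy()
        for g in np.unique(group_arr):
            idx = np.flatnonzero(group_arr == g)
            perm2[idx] = rng.permutation(colony_arr[idx])
        a, b, c = _amova_components(d2, perm2, group_arr)[:3]
        if (b + c) > 0 and b / (b + c) >= phi_sc - 1e-15:
            c_sc += 1
        # Phi_CT: whole colonies among groups
        gl = [grp_of[c] for c in colonies]
        shuffled = rng.permutation(gl)
        gmap = dict(zip(colonies, shuffled))
        garr3 = np.array([gmap[c] for c in colony_arr])
        a, b, c = _amova_components(d2, colony_arr, garr3)[:3]
        t = a + b + c
        if t > 0 and a / t >= phi_ct - 1e-15:
            c_ct += 1
    df = pd.DataFrame({
        "level": ["among_groups", "among_colonies_within_groups", "within_colonies"],
        "df": list(ssd["df"]),
        "ssd": [ssd["ag"], ssd["ap"], ssd["wp"]],
        "sigma2": [sa, sb, sc],
    })
    return AmovaResult(
        sigma_among_groups=float(sa), sigma_among_pops=float(sb),
        sigma_within=float(sc), phi_ct=float(phi_ct), phi_sc=float(phi_sc),
        phi_st=float(phi_st),
        p_phi_ct=(c_ct + 1) / (n_perm + 1), p_phi_sc=(c_sc + 1) / (n_perm + 1),
        p_phi_st=(c_st + 1) / (n_perm + 1), table=df,
    )
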
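"""Synthetic multi-colony seabird datasets.

The generator emulates the statistical structure the downstream analyses
assume: twelve colonies of six diploids each, organised in four divergent
genomic clusters, with stepping-stone isolation-by-distance inside the large
central cluster, one admixed colony sitting between the high-Arctic cluster
and the central chain, one bottlenecked/inbred colony carrying implanted runs
of homozygosity, a high-divergence outgroup population for rooting and
D-statistics, a star-genealogy mitochondrial alignment (recent-expansion
signal), and a rasterised sea map for least-cost-path distances.

Allele frequencies drift down a population tree under the Balding–Nichols
model (Beta sampling per branch with drift coefficient F); admixture mixes
frequencies (internal nodes) or allele-copy origins (colonies).  Reads are
Poisson-distributed with a symmetric base-error, matching the likelihood in
:mod:`glpop.gl`, with per-individual mean depth drawn uniformly in a 3-10x
band around the 7x average typical of whole-genome resequencing studies of
this design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl import GLMatrix, gl_from_count_arrays

__all__ = [
    "PopulationModel",
    "SimulatedTruth",
    "Geography",
    "SimulatedDataset",
    "build_population_model",
    "draw_allele_frequencies",
    "sample_genotypes_and_reads",
    "implant_roh_tracts",
    "simulate_mito_alignment",
    "make_geography",
    "simulate_dataset",
    "DEFAULT_CONFIG",
]


# ---------------------------------------------------------------------------
# model description

# The default ("puffin12") layout: four clusters — one high-Arctic isolate
# (with a bottleneck), one western two-colony cluster, one southern isolate,
# and a seven-colony central chain whose ancestor lies midway between the
# western and southern lineages (a broad-scale cline) with its own drift on
# top.  One colony is a recent 50/50 mixture of the high-Arctic isolate and
# the nearest chain colony.  An outgroup population roots trees and polarises
# D-statistics.
DEFAULT_CONFIG = {
    "n_per_colony": 6,
    "n_sites": 20_000,
    "chromosomes": {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000,
                    "chr4": 20_000_000, "chr5": 20_000_000},
    "depth_range": (3.0, 10.0),
    "error_rate": 0.01,
    "missing_rate": 0.0,
    "ancestral_beta": (0.8, 0.8),
    "ancestral_trunc": (0.05, 0.95),
    "ld_block_rho": 0.0,  # optional block-copy correlation for pruner tests
    "outgroup": {"name": "Outgroup", "F": 0.6, "n_diploids": 2, "depth": 20.0},
    "tree": {
        "arctic_anc": ("root", 0.18),
        "Spitsbergen": ("arctic_anc", 0.01),
        "west_anc": ("root", 0.11),
        "GannetIsl": ("west_anc", 0.004),
        "GullIsl": ("west_anc", 0.004),
        "south_anc": ("south_anchor", 0.25),
        "IsleOfMay": ("south_anc", 0.004),
        "central_anc": ("root", 0.025),
        # stepping-stone chain through the central cluster; each step's drift
        # is proportional to the sea-route distance of that leg, so expected
        # differentiation grows with geographic distance (isolation by
        # distance by construction)
        "Hornoya": ("central_anc", 0.0005),
        "Rost": ("Hornoya", 0.0033),
        "Faroe": ("Rost", 0.0041),
        "Papey": ("Faroe", 0.0018),
        "Grimsey": ("Papey", 0.0012),
        "Breidafjordur": ("Grimsey", 0.0007),
        "Vestmannaeyjar": ("Breidafjordur", 0.0008),
    },
    # the southern isolate's ancestor sits midway between the western and
    # central lineages before its own long drift: the four cluster means then
    # stay mutually separated in any two-dimensional principal-component
    # projection, while the long private branch keeps the cluster from being
    # modelled away as an admixture combination at too-small K
    "mixtures": {"south_anchor": ("west_anc", "central_anc", 0.5)},
    "colonies": ["Spitsbergen", "Bjornoya", "Hornoya", "Rost", "Faroe", "Papey",
                 "Vestmannaeyjar", "Breidafjordur", "Grimsey", "IsleOfMay",
                 "GannetIsl", "GullIsl"],
    "clusters": {
        "Spitsbergen": "Arctic", "Bjornoya": "Admixed",
        "Hornoya": "Central", "Rost": "Central", "Faroe": "Central",
        "Papey": "Central", "Vestmannaeyjar": "Central",
        "Breidafjordur": "Central", "Grimsey": "Central",
        "IsleOfMay": "South", "GannetIsl": "West", "GullIsl": "West",
    },
    # colony-level admixture: allele copies drawn from either parent colony
    "admixture_events": [("Bjornoya", "Spitsbergen", "Hornoya", 0.5)],
    "bottleneck": {"colony": "Spitsbergen", "roh_fraction": 0.16,
                   "tract_length_range": (500_000, 2_500_000)},
    "mito": {"length": 5000, "private_rate": 3.0, "island_fixed_diffs": 0,
             "outgroup_diffs": 120},
    "geography": {
        "lat_min": 44.0, "lat_max": 80.0, "lon_min": -62.0, "lon_max": 32.0,
        "cell_deg": 1.0,
        # land boxes (lat_min, lat_max, lon_min, lon_max)
        "land": [
            (59.0, 82.0, -46.0, -22.0),   # Greenland-like block
            (58.0, 70.0, 14.0, 30.0),     # Scandinavian block
            (50.0, 57.5, -7.0, -2.8),     # British block
            (64.2, 65.6, -21.0, -15.5),   # island interior
            (44.0, 60.0, -62.0, -56.0),   # western continental margin
        ],
        "colony_coords": {
            "Spitsbergen": (78.2, 15.6), "Bjornoya": (74.5, 19.0),
            "Hornoya": (70.4, 31.1), "Rost": (67.5, 12.1),
            "Faroe": (62.0, -6.8), "Papey": (64.6, -14.2),
            "Vestmannaeyjar": (63.4, -20.3), "Breidafjordur": (65.1, -23.9),
            "Grimsey": (66.5, -18.0), "IsleOfMay": (56.2, -2.5),
            "GannetIsl": (47.3, -54.0), "GullIsl": (47.2, -52.8),
        },
    },
    "seed": 0,
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


@dataclass
class PopulationModel:
    """Validated description of a synthetic multi-colony study."""

    tree: dict
    mixtures: dict
    colonies: list
    n_per_colony: int
    clusters: dict
    admixture_events: list
    bottleneck: dict | None
    n_sites: int
    chromosomes: dict
    depth_range: tuple
    error_rate: float
    missing_rate: float
    ancestral_beta: tuple
    ancestral_trunc: tuple
    ld_block_rho: float
    outgroup: dict | None
    mito: dict
    geography: dict
    seed: int

    @property
    def n_individuals(self) -> int:
        return len(self.colonies) * self.n_per_colony

    @property
    def cluster_names(self) -> list:
        seen = []
        for c in self.colonies:
            k = self.clusters[c]
            if k not in seen and k != "Admixed":
                seen.append(k)
        return seen

    def individuals(self):
        """(individual id, colony) pairs, colony-ordered."""
        out = []
        for c in self.colonies:
            for i in range(self.n_per_colony):
                out.append((f"{c}_{i:02d}", c))
        return out


def _toposort(nodes: dict, mixtures: dict):
    order, seen, visiting = [], set(), set()

    def visit(name):
        if name == "root" or name in seen:
            return
        if name in visiting:
            raise ValueError(f"tree contains a cycle through {name!r}")
        visiting.add(name)
        if name in mixtures:
            a, b, _ = mixtures[name]
            visit(a)
            visit(b)
        elif name in nodes:
            visit(nodes[name][0])
        else:
            raise ValueError(f"node {name!r} has no definition")
        visiting.discard(name)
        seen.add(name)
        order.append(name)

    for n in list(nodes) + list(mixtures):
        visit(n)
    return order


def build_population_model(config: dict | None = None) -> PopulationModel:
    """Build and validate a :class:`PopulationModel`.

    ``config`` overrides keys of the default twelve-colony layout; unknown
    keys are rejected.  An empty config returns the default model (12
    colonies x 6 diploids, four clusters, one admixed and one bottlenecked
    colony, plus the outgroup).
    """
    config = dict(config or {})
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}

    tree = dict(cfg["tree"])
    mixtures = dict(cfg["mixtures"])
    colonies = list(cfg["colonies"])
    admixture_targets = {e[0] for e in cfg["admixture_events"]}
    for name, (parent, F) in tree.items():
        if not (0 <= F < 1):
            raise ValueError(f"tree: branch F for {name!r} must lie in [0, 1)")
    for name, (a, b, alpha) in mixtures.items():
        if not (0 <= alpha <= 1):
            raise ValueError(f"mixtures: alpha for {name!r} must lie in [0, 1]")
    for target, a, b, alpha in cfg["admixture_events"]:
        if not (0 <= alpha <= 1):
            raise ValueError(f"admixture_events: alpha for {target!r} must lie in [0, 1]")
        if target not in colonies:
            raise ValueError(f"admixture_events: unknown target colony {target!r}")
        for p in (a, b):
            if p not in tree and p not in mixtures:
                raise ValueError(f"admixture_events: unknown source {p!r}")
    for c in colonies:
        if c not in tree and c not in mixtures and c not in admixture_targets:
            raise ValueError(f"colony {c!r} does not map to a tree leaf or admixture event")
    if cfg["n_per_colony"] <= 0:
        raise ValueError("n_per_colony must be positive")
    if cfg["n_sites"] <= 0:
        raise ValueError("n_sites must be positive")
    for chrom, ln in cfg["chromosomes"].items():
        if ln <= 0:
            raise ValueError(f"chromosomes: length of {chrom!r} must be positive")
    lo, hi = cfg["depth_range"]
    if lo <= 0 or hi < lo:
        raise ValueError("depth_range must be positive and ordered")
    if not (0 < cfg["error_rate"] < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    _toposort(tree, mixtures)  # raises on cycles / undefined parents

    return PopulationModel(
        tree=tree, mixtures=mixtures, colonies=colonies,
        n_per_colony=int(cfg["n_per_colony"]), clusters=dict(cfg["clusters"]),
        admixture_events=list(cfg["admixture_events"]),
        bottleneck=cfg["bottleneck"], n_sites=int(cfg["n_sites"]),
        chromosomes=dict(cfg["chromosomes"]), depth_range=tuple(cfg["depth_range"]),
        error_rate=float(cfg["error_rate"]), missing_rate=float(cfg["missing_rate"]),
        ancestral_beta=tuple(cfg["ancestral_beta"]),
        ancestral_trunc=tuple(cfg["ancestral_trunc"]),
        ld_block_rho=float(cfg["ld_block_rho"]), outgroup=cfg["outgroup"],
        mito=dict(cfg["mito"]), geography=dict(cfg["geography"]), seed=int(cfg["seed"]),
    )


@dataclass
class SimulatedTruth:
    """Ground truth recorded alongside a simulated dataset."""

    colony_freqs: pd.DataFrame  # colonies (+outgroup) x sites
    genotypes: np.ndarray       # (sites, individuals) in {0,1,2}
    ancestry: pd.DataFrame      # individuals x cluster names, rows sum to 1
    roh_intervals: pd.DataFrame # individual, chrom, start, end
    expected_fst: pd.DataFrame  # colony x colony Hudson F_ST from true freqs


@dataclass
class Geography:
    """Rectangular lat/lon grid of water/land cells plus colony coordinates."""

    water: np.ndarray  # (nrows, ncols) bool, row 0 = southernmost
    lat_min: float
    lon_min: float
    cell_deg: float
    colonies: pd.DataFrame  # name, lat, lon

    @property
    def shape(self):
        return self.water.shape

    def cell_center(self, row, col):
        return (self.lat_min + (row + 0.5) * self.cell_deg,
                self.lon_min + (col + 0.5) * self.cell_deg)

    def cell_of(self, lat, lon):
        return (int((lat - self.lat_min) // self.cell_deg),
                int((lon - self.lon_min) // self.cell_deg))


@dataclass
class SimulatedDataset:
    model: PopulationModel
    gl: GLMatrix
    truth: SimulatedTruth
    mito: list  # (name, sequence) pairs, colony-ordered, outgroup last
    geography: Geography


def _balding_nichols(rng, p, F):
    if np.any(F >= 1):
        raise ValueError("branch F = 1 is degenerate")
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def _hudson_fst_true(f1, f2):
    num = np.sum((f1 - f2) ** 2)
    den = np.sum(f1 * (1 - f2) + f2 * (1 - f1))
    return num / den if den > 0 else np.nan


def draw_allele_frequencies(model: PopulationModel, rng=None):
    """Drift allele frequencies down the tree (Balding–Nichols per branch).

    Returns (colony x site DataFrame incl. outgroup, node frequency dict).
    Mixture nodes take ``alpha * f_A + (1 - alpha) * f_B`` exactly.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    a, b = model.ancestral_beta
    lo, hi = model.ancestral_trunc
    p0 = np.empty(model.n_sites)
    filled = 0
    while filled < model.n_sites:
        draw = rng.beta(a, b, size=2 * model.n_sites)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), model.n_sites - filled)
        p0[filled : filled + take] = draw[:take]
        filled += take
    freqs = {"root": p0}
    for name in _toposort(model.tree, model.mixtures):
        if name in model.mixtures:
            pa, pb, alpha = model.mixtures[name]
            freqs[name] = alpha * freqs[pa] + (1 - alpha) * freqs[pb]
        else:
            parent, F = model.tree[name]
            freqs[name] = _balding_nichols(rng, freqs[parent], F)
    rows = {}
    for c in model.colonies:
        if c in freqs:
            rows[c] = freqs[c]
    for target, pa, pb, alpha in model.admixture_events:
        rows[target] = alpha * freqs[pa] + (1 - alpha) * freqs[pb]
    if model.outgroup:
        og = model.outgroup
        freqs[og["name"]] = _balding_nichols(rng, p0, og["F"])
        rows[og["name"]] = freqs[og["name"]]
    table = pd.DataFrame(rows).T
    table = table.loc[[c for c in model.colonies] + ([model.outgroup["name"]] if model.outgroup else [])]
    return table, freqs


def expected_pairwise_fst(colony_freqs: pd.DataFrame, colonies) -> pd.DataFrame:
    m = pd.DataFrame(0.0, index=colonies, columns=colonies)
    for i, a in enumerate(colonies):
        for b_ in colonies[i + 1 :]:
            v = _hudson_fst_true(colony_freqs.loc[a].to_numpy(), colony_freqs.loc[b_].to_numpy())
            m.loc[a, b_] = m.loc[b_, a] = v
    return m


def _site_table(model: PopulationModel, rng) -> pd.DataFrame:
    chroms = list(model.chromosomes)
    lens = np.array([model.chromosomes[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    counts = rng.multinomial(model.n_sites, probs)
    rows = []
    for chrom, n in zip(chroms, counts):
        pos = np.sort(rng.choice(int(model.chromosomes[chrom]), size=n, replace=False)) + 1
        for p in pos:
            rows.append((chrom, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["major"] = "A"
    df["minor"] = "C"
    return df


def sample_genotypes_and_reads(colony_freqs: pd.DataFrame, model: PopulationModel,
                               rng=None, genotypes=None, sites=None):
    """Draw genotypes, Poisson reads and GL triples; record truth.

    Unadmixed individuals draw ``g ~ Binomial(2, f_colony)``; individuals of
    an admixed colony draw each allele copy from a parent colony chosen with
    probability ``alpha``.  Read counts are Poisson with a per-individual
    mean depth uniform in ``depth_range``; minor-read counts are binomial
    with the symmetric error rate.  Pass precomputed ``genotypes`` (e.g.
    after RoH implanting) to re-emit reads without redrawing genotypes.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    lo, hi = model.depth_range
    eps = model.error_rate
    if not (0 < eps < 0.5):
        raise ValueError("error rate must lie in (0, 0.5)")
    if lo <= 0:
        raise ValueError("depth must be positive")
    inds = model.individuals()
    names = [n for n, _ in inds]
    cols = [c for _, c in inds]
    S = model.n_sites
    admix = {t: (a, b, al) for t, a, b, al in model.admixture_events}

    if genotypes is None:
        genotypes = np.empty((S, len(inds)), dtype=np.int8)
        for j, (_, colony) in enumerate(inds):
            if colony in admix:
                a, b, alpha = admix[colony]
                fa = colony_freqs.loc[a].to_numpy() if a in colony_freqs.index else None
                fb = colony_freqs.loc[b].to_numpy() if b in colony_freqs.index else None
                src1 = rng.random(S) < alpha
                src2 = rng.random(S) < alpha
                c1 = rng.random(S) < np.where(src1, fa, fb)
                c2 = rng.random(S) < np.where(src2, fa, fb)
                genotypes[:, j] = c1.astype(np.int8) + c2.astype(np.int8)
            else:
                genotypes[:, j] = rng.binomial(2, colony_freqs.loc[colony].to_numpy())

    depths = rng.uniform(lo, hi, size=len(inds))
    out_names, out_cols, out_depths = [], [], []
    if model.outgroup:
        og = model.outgroup
        fo = colony_freqs.loc[og["name"]].to_numpy()
        og_g = rng.binomial(2, fo, size=(og["n_diploids"], S)).T.astype(np.int8)
        genotypes = np.concatenate([genotypes, og_g], axis=1)
        out_names = [f"{og['name']}_{i:02d}" for i in range(og["n_diploids"])]
        out_cols = [og["name"]] * og["n_diploids"]
        out_depths = [og["depth"]] * og["n_diploids"]
    all_names = names + out_names
    all_cols = cols + out_cols
    all_depths = np.concatenate([depths, np.array(out_depths)]) if out_depths else depths

    n_reads = rng.poisson(all_depths[None, :], size=(S, len(all_names)))
    if model.missing_rate > 0:
        n_reads[rng.random(n_reads.shape) < model.missing_rate] = 0
    p_minor = genotypes / 2.0 * (1 - eps) + (1 - genotypes / 2.0) * eps
    n_minor = rng.binomial(n_reads, p_minor)
    n_major = n_reads - n_minor
    L = gl_from_count_arrays(n_major, n_minor, eps)

    sites = _site_table(model, rng) if sites is None else sites
    glm = GLMatrix(sites=sites, individuals=all_names, colonies=all_cols, L=L,
                   chrom_lengths=dict(model.chromosomes))

    clusters = model.cluster_names
    q = pd.DataFrame(0.0, index=names, columns=clusters)
    for nme, colony in zip(names, cols):
        if colony in admix:
            a, b, alpha = admix[colony]
            ka = model.clusters.get(a, None)
            kb = model.clusters.get(b, None)
            if ka in clusters:
                q.loc[nme, ka] += alpha
            if kb in clusters:
                q.loc[nme, kb] += 1 - alpha
        elif colony in model.clusters and model.clusters[colony] in clusters:
            q.loc[nme, model.clusters[colony]] = 1.0

    fst = expected_pairwise_fst(colony_freqs, model.colonies)
    truth = SimulatedTruth(
        colony_freqs=colony_freqs, genotypes=genotypes, ancestry=q,
        roh_intervals=pd.DataFrame(columns=["individual", "chrom", "start", "end"]),
        expected_fst=fst,
    )
    return glm, truth


def implant_roh_tracts(genotypes: np.ndarray, model: PopulationModel,
                       colony: str, tract_spec: dict, sites: pd.DataFrame, rng,
                       colony_freqs: pd.DataFrame):
    """Implant homozygous tracts into every individual of ``colony``.

    Inside a tract the individual is homozygous at every site: a single
    haplotype is sampled from the colony frequency and doubled.  Tract
    lengths are uniform in ``tract_length_range`` and placed without overlap
    (abutting draws merge); total tract length targets ``roh_fraction`` of
    the genome.  Returns (genotypes, truth interval DataFrame).
    """
    frac = tract_spec["roh_fraction"]
    lo, hi = tract_spec["tract_length_range"]
    genome = sum(model.chromosomes.values())
    if hi > max(model.chromosomes.values()):
        raise ValueError("tract longer than the longest chromosome")
    inds = model.individuals()
    col_idx = [j for j, (_, c) in enumerate(inds) if c == colony]
    f = colony_freqs.loc[colony].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    rows = []
    for j in col_idx:
        target = frac * genome
        placed = {c: [] for c in model.chromosomes}
        total = 0.0
        attempts = 0
        while total < target and attempts < 10_000:
            attempts += 1
            chroms = list(model.chromosomes)
            c = chroms[rng.integers(len(chroms))]
            ln = int(rng.uniform(lo, min(hi, target - total + lo)))
            ln = min(ln, model.chromosomes[c])
            start = int(rng.integers(0, model.chromosomes[c] - ln + 1))
            end = start + ln
            if any(s < end and start < e for s, e in placed[c]):
                continue
            placed[c].append((start, end))
            total += ln
        name = inds[j][0]
        for c, ivs in placed.items():
            ivs = sorted(ivs)
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
                else:
                    merged.append((s, e))
            for s, e in merged:
                mask = (chrom_arr == c) & (pos_arr > s) & (pos_arr <= e)
                hap = (rng.random(mask.sum()) < f[mask]).astype(np.int8)
                genotypes[mask, j] = 2 * hap
                rows.append({"individual": name, "chrom": c, "start": s, "end": e})
    return genotypes, pd.DataFrame(rows)


def simulate_mito_alignment(model: PopulationModel, rng=None):
    """Star-genealogy mitochondrial alignment with private mutations.

    Every individual receives ``Poisson(private_rate)`` private substitutions
    on an ancestral sequence — the excess of rare variants characteristic of
    a recent expansion (expected Tajima's D < 0).  ``island_fixed_diffs > 0``
    instead splits the colonies into two equal island groups separated by
    fixed differences (for Phi_ST truth checks).  The outgroup sequence gets
    ``outgroup_diffs`` substitutions.  Returns a list of (name, sequence).
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    cfg = model.mito
    L = int(cfg["length"])
    if L <= 0:
        raise ValueError("mito length must be positive")
    bases = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=L)
    inds = model.individuals()
    records = []
    island_sites = {}
    if cfg.get("island_fixed_diffs", 0) > 0:
        k = cfg["island_fixed_diffs"]
        positions = rng.choice(L, size=k, replace=False)
        half = set(model.colonies[len(model.colonies) // 2 :])
        island_sites = {"positions": positions, "colonies": half}
    for name, colony in inds:
        seq = anc.copy()
        if island_sites and colony in island_sites["colonies"]:
            for p in island_sites["positions"]:
                seq[p] = (seq[p] + 1) % 4
        k = rng.poisson(cfg["private_rate"])
        if k:
            pos = rng.choice(L, size=min(k, L), replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=len(pos))) % 4
        records.append((name, "".join(bases[seq])))
    if model.outgroup:
        seq = anc.copy()
        pos = rng.choice(L, size=min(int(cfg["outgroup_diffs"]), L), replace=False)
        seq[pos] = (seq[pos] + rng.integers(1, 4, size=len(pos))) % 4
        records.append((model.outgroup["name"], "".join(bases[seq])))
    return records


def make_geography(model: PopulationModel) -> Geography:
    """Rasterise the configured sea map and colony coordinates."""
    g = model.geography
    cell = g["cell_deg"]
    nrows = int(round((g["lat_max"] - g["lat_min"]) / cell))
    ncols = int(round((g["lon_max"] - g["lon_min"]) / cell))
    water = np.ones((nrows, ncols), dtype=bool)
    lat_c = g["lat_min"] + (np.arange(nrows) + 0.5) * cell
    lon_c = g["lon_min"] + (np.arange(ncols) + 0.5) * cell
    for la0, la1, lo0, lo1 in g["land"]:
        rmask = (lat_c >= la0) & (lat_c <= la1)
        cmask = (lon_c >= lo0) & (lon_c <= lo1)
        water[np.ix_(rmask, cmask)] = False
    coords = pd.DataFrame(
        [(name, la, lo) for name, (la, lo) in g["colony_coords"].items()
         if name in model.colonies],
        columns=["name", "lat", "lon"],
    )
    geo = Geography(water=water, lat_min=g["lat_min"], lon_min=g["lon_min"],
                    cell_deg=cell, colonies=coords)
    for _, row in coords.iterrows():
        r, c = geo.cell_of(row["lat"], row["lon"])
        r0, r1 = max(r - 2, 0), min(r + 3, nrows)
        c0, c1 = max(c - 2, 0), min(c + 3, ncols)
        if not water[r0:r1, c0:c1].any():
            raise ValueError(f"colony {row['name']} has no water cell within 2 cells")
    return geo


def simulate_dataset(config: dict | None = None, seed: int | None = None) -> SimulatedDataset:
    """One-call simulation of the full default study (or an override of it).

    All randomness flows from a single seed: identical config + seed gives
    byte-identical outputs.
    """
    config = dict(config or {})
    if seed is not None:
        config["seed"] = int(seed)
    model = build_population_model(config)
    root = np.random.SeedSequence(model.seed)
    r_freq, r_geno, r_roh, r_reads, r_mito = [np.random.default_rng(s) for s in root.spawn(5)]

    colony_freqs, _ = draw_allele_frequencies(model, r_freq)
    sites = _site_table(model, r_geno)
    glm0, truth = sample_genotypes_and_reads(colony_freqs, model, rng=r_geno, sites=sites)
    genotypes = truth.genotypes
    roh_df = truth.roh_intervals
    if model.bottleneck:
        genotypes, roh_df = implant_roh_tracts(
            genotypes[:, : model.n_individuals], model, model.bottleneck["colony"],
            model.bottleneck, sites, r_roh, colony_freqs)
        # outgroup genotypes are untouched; re-emit reads for everyone
        genotypes = np.concatenate([genotypes, truth.genotypes[:, model.n_individuals :]], axis=1)

    # re-emit reads from the final genotypes with a dedicated stream so the
    # read layer is identical with and without implanted tracts elsewhere
    lo, hi = model.depth_range
    depths = r_reads.uniform(lo, hi, size=model.n_individuals)
    if model.outgroup:
        depths = np.concatenate([depths, np.full(model.outgroup["n_diploids"], model.outgroup["depth"])])
    n_reads = r_reads.poisson(depths[None, :], size=genotypes.shape)
    if model.missing_rate > 0:
        n_reads[r_reads.random(n_reads.shape) < model.missing_rate] = 0
    eps = model.error_rate
    p_minor = genotypes / 2.0 * (1 - eps) + (1 - genotypes / 2.0) * eps
    n_minor = r_reads.binomial(n_reads, p_minor)
    L = gl_from_count_arrays(n_reads - n_minor, n_minor, eps)
    if model.ld_block_rho > 0:
        # optional block-copy LD: copy the previous site's GL column block
        copy = r_reads.random(model.n_sites) < model.ld_block_rho
        same_chrom = np.concatenate([[False], sites["chrom"].to_numpy()[1:] == sites["chrom"].to_numpy()[:-1]])
        for s in np.flatnonzero(copy & same_chrom):
            L[s] = L[s - 1]
            genotypes[s] = genotypes[s - 1]
    glm = GLMatrix(sites=sites, individuals=glm0.individuals, colonies=glm0.colonies,
                   L=L, chrom_lengths=dict(model.chromosomes))
    truth.genotypes = genotypes
    truth.roh_intervals = roh_df

    mito = simulate_mito_alignment(model, r_mito)
    geo = make_geography(model)
    return SimulatedDataset(model=model, gl=glm, truth=truth, mito=mito, geography=geo)
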
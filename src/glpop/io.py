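"""Readers and writers for the text formats the pipeline exchanges:
Beagle genotype-likelihood tables, VCF import, FASTA alignments, ESRI ASCII
grids for the water mask, and simple TSV tables.

All writers use fixed numeric formatting so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gl import GLMatrix
from .simdata import Geography

__all__ = [
    "write_beagle",
    "read_beagle",
    "read_vcf_gl",
    "write_vcf_gl",
    "write_sfs",
    "read_sfs",
    "write_fasta",
    "read_fasta",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_colonies_tsv",
    "read_colonies_tsv",
    "write_dist_tsv",
    "read_dist_tsv",
]


def write_beagle(gl: GLMatrix, path, float_fmt: str = "%.6f"):
    """Beagle-GL text: marker, allele1, allele2, then 3 columns/individual."""
    with open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for ind in gl.individuals:
            cols += [str(ind)] * 3
        fh.write("\t".join(cols) + "\n")
        markers = gl.sites["chrom"].astype(str) + "_" + gl.sites["pos"].astype(str)
        flat = gl.L.reshape(gl.n_sites, -1)
        a1 = gl.sites["major"].to_numpy()
        a2 = gl.sites["minor"].to_numpy()
        for m, x, y, row in zip(markers, a1, a2, flat):
            fh.write(f"{m}\t{x}\t{y}\t" + "\t".join(float_fmt % v for v in row) + "\n")


def read_beagle(path, colonies: dict | None = None, chrom_lengths: dict | None = None) -> GLMatrix:
    """Read a Beagle-GL file; individual names from the header triplets.

    ``colonies`` maps individual -> colony label (defaults to the name).
    """
    df = pd.read_csv(path, sep="\t")
    inds = list(dict.fromkeys(df.columns[3:]))
    if 3 + 3 * len(inds) != df.shape[1]:
        # pandas dedups duplicate names with .1/.2 suffixes
        raw = list(df.columns[3:])
        inds = [raw[i] for i in range(0, len(raw), 3)]
    marker = df.iloc[:, 0].astype(str)
    chrom = marker.str.rsplit("_", n=1).str[0]
    pos = marker.str.rsplit("_", n=1).str[1].astype(int)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos,
                          "major": df.iloc[:, 1], "minor": df.iloc[:, 2]})
    L = df.iloc[:, 3:].to_numpy(dtype=float).reshape(len(df), len(inds), 3)
    m = L.max(axis=2, keepdims=True)
    m[m == 0] = 1.0
    L = L / m
    col = [colonies.get(i, i) if colonies else i for i in inds]
    return GLMatrix(sites=sites.reset_index(drop=True), individuals=inds,
                    colonies=col, L=L, chrom_lengths=chrom_lengths or {})


def read_vcf_gl(path, colonies: dict | None = None, chrom_lengths: dict | None = None) -> GLMatrix:
    """Import biallelic SNPs with GL or PL FORMAT fields from a VCF."""
    from cyvcf2 import VCF  # local import: only needed for VCF input

    vcf = VCF(path)
    inds = list(vcf.samples)
    rows, trips = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gl = var.format("GL")
        if gl is not None:
            logl = np.asarray(gl, dtype=float)
            like = np.power(10.0, logl)
        else:
            pl = var.format("PL")
            if pl is None:
                continue
            like = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
        m = like.max(axis=1, keepdims=True)
        m[m == 0] = 1.0
        trips.append(like / m)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "major", "minor"])
    L = np.stack(trips) if trips else np.empty((0, len(inds), 3))
    col = [colonies.get(i, i) if colonies else i for i in inds]
    return GLMatrix(sites=sites, individuals=inds, colonies=col, L=L,
                    chrom_lengths=chrom_lengths or {})


def write_vcf_gl(gl: GLMatrix, path):
    """Minimal VCF 4.2 export with log10-scaled GL FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in gl.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(ln)}>\n")
        fh.write('##FORMAT=<ID=GL,Number=G,Type=Float,'
                 'Description="Genotype likelihood, log10-scaled">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in gl.individuals) + "\n")
        logs = np.log10(np.maximum(gl.L, 1e-300))
        for s in range(gl.n_sites):
            row = gl.sites.iloc[s]
            fields = ["%.4f,%.4f,%.4f" % tuple(logs[s, j]) for j in range(gl.n_individuals)]
            fh.write(f"{row['chrom']}\t{row['pos']}\t.\t{row['major']}\t"
                     f"{row['minor']}\t.\tPASS\t.\tGL\t" + "\t".join(fields) + "\n")


def write_sfs(counts, path):
    """Whitespace-separated expected count vector (ANGSD-style .sfs layout)."""
    arr = np.asarray(counts, dtype=float).ravel()
    with open(path, "w") as fh:
        fh.write(" ".join("%.6f" % v for v in arr) + "\n")


def read_sfs(path) -> np.ndarray:
    with open(path) as fh:
        return np.array([float(x) for x in fh.read().split()])


def write_fasta(records, path):
    SeqIO.write(
        (SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records),
        path, "fasta")


def read_fasta(path):
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_ascii_grid(geo: Geography, path):
    """ESRI ASCII grid of the water mask (1 = water, 0 = land)."""
    nrows, ncols = geo.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {geo.lon_min:.6f}\n")
        fh.write(f"yllcorner {geo.lat_min:.6f}\n")
        fh.write(f"cellsize {geo.cell_deg:.6f}\n")
        fh.write("NODATA_value -9999\n")
        # ESRI grids list the northernmost row first
        for row in geo.water[::-1]:
            fh.write(" ".join("1" if w else "0" for w in row) + "\n")


def read_ascii_grid(path, colonies: pd.DataFrame | None = None) -> Geography:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            k, v = fh.readline().split()
            header[k.lower()] = float(v)
        rows = [[int(float(x)) for x in line.split()] for line in fh if line.strip()]
    water = np.array(rows[::-1], dtype=bool)
    return Geography(water=water, lat_min=header["yllcorner"],
                     lon_min=header["xllcorner"], cell_deg=header["cellsize"],
                     colonies=colonies if colonies is not None
                     else pd.DataFrame(columns=["name", "lat", "lon"]))


def write_colonies_tsv(colonies: pd.DataFrame, path):
    colonies.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_colonies_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dist_tsv(labels, matrix, path):
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g")


def read_dist_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
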
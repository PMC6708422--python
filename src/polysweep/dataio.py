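"""Readers and writers for genotype, map, score and region formats.

The in-memory genotype container is :class:`HaplotypeSet`: phased (or
effectively inbred) biallelic haplotypes, two rows per individual, with per
locus map metadata.  Wheat cultivars are near-fully selfed, so a "phased"
matrix is really a pair of near-identical gamete vectors per line; chip
heterozygote calls are unreliable in hexaploid wheat, which is why the plain
haplotype-matrix dialect (0/1/NA, one row per haplotype) is the primary
on-disk format, with VCF supported for interoperability.

Two packaged fixtures transcribe published results used by the reporting
layer: an 86-row table of sweep regions (chromosome, cM interval, detecting
methods, populations) and a 17x17 matrix of inter-region r2 values among
unlinked sweeps and characterized genes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

ALL_POPULATIONS = ("Post70", "All", "NSW", "QLD", "SA", "VIC", "WA")
ALL_METHODS = ("FST", "IHS", "NSL", "XPCLR")

#: method-name normalization applied when reading region tables; the printed
#: source contains one "his" typo for iHS.
_METHOD_ALIASES = {
    "FST": "FST", "F_ST": "FST", "F ST": "FST",
    "IHS": "IHS", "HIS": "IHS",
    "NSL": "NSL",
    "XPCLR": "XPCLR",
    "ALL": "ALL",
}


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    """Phased biallelic haplotypes with locus metadata.

    Parameters
    ----------
    individuals
        Sample identifiers, one per individual.
    loci
        DataFrame with columns ``locus`` (str), ``chrom`` (str, subgenome
        letter included, e.g. ``"1B"`` or ``"A1"``), ``cM`` (float) and
        ``bp`` (int).  Sorted by (chrom, cM).
    alleles
        int8 array of shape ``(2 * n_individuals, n_loci)`` with values in
        {0, 1, MISSING}.  Rows ``2*i`` and ``2*i + 1`` are the two haplotypes
        of individual ``i``; within each chromosome this gives the two
        homologous copies (disomic inheritance).
    ploidy_note
        Number of homoeologous subgenomes represented in ``loci`` (1-3).
    sample_groups
        Optional mapping individual -> cohort label (e.g. Pre70/Post70).
    """

    individuals: list[str]
    loci: pd.DataFrame
    alleles: np.ndarray
    ploidy_note: int = 1
    sample_groups: dict[str, str] | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        a = self.alleles
        if a.shape != (2 * self.n_individuals, self.n_loci):
            raise ValueError(
                f"allele matrix shape {a.shape} does not match "
                f"(2*{self.n_individuals}, {self.n_loci})")
        bad = ~np.isin(a, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele values outside {0,1,missing}")
        if not 1 <= self.ploidy_note <= 3:
            raise ValueError("ploidy_note must be in 1..3")
        _check_sorted_loci(self.loci)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Column indices of loci on one chromosome (contiguous block)."""
        idx = np.flatnonzero((self.loci["chrom"] == chrom).to_numpy())
        return idx

    def group_indices(self, label: str) -> np.ndarray:
        """Individual indices belonging to one cohort label."""
        if self.sample_groups is None:
            raise ValueError("HaplotypeSet carries no sample_groups")
        return np.array([i for i, s in enumerate(self.individuals)
                         if self.sample_groups.get(s) == label], dtype=int)

    def haplotype_rows(self, individuals: np.ndarray) -> np.ndarray:
        """Haplotype row indices for a set of individual indices."""
        individuals = np.asarray(individuals, dtype=int)
        return np.stack([2 * individuals, 2 * individuals + 1], axis=1).ravel()

    def restrict_loci(self, keep: np.ndarray) -> "HaplotypeSet":
        """New HaplotypeSet restricted to the given locus column indices."""
        keep = np.sort(np.asarray(keep, dtype=int))
        return HaplotypeSet(
            individuals=list(self.individuals),
            loci=self.loci.iloc[keep].reset_index(drop=True),
            alleles=self.alleles[:, keep].copy(),
            ploidy_note=self.ploidy_note,
            sample_groups=dict(self.sample_groups) if self.sample_groups else None,
        )


def _check_sorted_loci(loci: pd.DataFrame) -> None:
    for col in ("locus", "chrom", "cM", "bp"):
        if col not in loci.columns:
            raise ValueError(f"loci table lacks column {col!r}")
    for chrom, sub in loci.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy(float)
        bp = sub["bp"].to_numpy(float)
        if np.any(np.diff(cm) < 0):
            i = int(np.flatnonzero(np.diff(cm) < 0)[0])
            raise FormatError(
                f"loci unsorted on {chrom}: cM decreases at index {i + 1}")
        if np.any(np.diff(bp) <= 0):
            i = int(np.flatnonzero(np.diff(bp) <= 0)[0])
            raise FormatError(
                f"bp positions not strictly increasing on {chrom} at index {i + 1}")
    # chromosome blocks must be contiguous
    chroms = loci["chrom"].to_numpy()
    seen = set()
    prev = None
    for c in chroms:
        if c != prev and c in seen:
            raise FormatError(f"chromosome {c} appears in non-contiguous blocks")
        seen.add(c)
        prev = c


@dataclass
class GeneticMap:
    """Per-locus genetic (cM) and physical (bp) positions."""

    table: pd.DataFrame  # columns: locus, chrom, cM, bp

    def validate(self) -> None:
        if (self.table["cM"] < 0).any():
            raise ValueError("negative cM position")
        _check_sorted_loci(self.table)

    @classmethod
    def from_haplotype_set(cls, hs: HaplotypeSet) -> "GeneticMap":
        return cls(hs.loci[["locus", "chrom", "cM", "bp"]].copy())


@dataclass
class SweepTable:
    """Intervals under selection: closed [start, end] in cM.

    ``pops`` and ``methods`` are frozensets over the population and method
    vocabularies; a single-SNP region has start == end (length 0).
    """

    rows: pd.DataFrame  # region, chrom, start_cm, end_cm, pops, methods, annotation

    def __len__(self) -> int:
        return len(self.rows)

    def validate(self) -> None:
        r = self.rows
        if (r["start_cm"] > r["end_cm"]).any():
            raise ValueError("region with start > end")
        if any(len(m) == 0 for m in r["methods"]):
            raise ValueError("region with empty method set")
        if any(len(p) == 0 for p in r["pops"]):
            raise ValueError("region with empty population set")

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out["Pops"] = [",".join(sorted(p)) for p in out.pop("pops")]
        out["Methods"] = [",".join(sorted(m)) for m in out.pop("methods")]
        out = out.rename(columns={"region": "Region", "chrom": "Chr",
                                  "start_cm": "PosStart", "end_cm": "PosEnd"})
        cols = ["Region", "Chr", "PosStart", "PosEnd", "Pops", "Methods"]
        extra = [c for c in out.columns if c not in cols]
        out[cols + extra].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SweepTable":
        raw = pd.read_csv(path, sep="\t")
        rows = pd.DataFrame({
            "region": raw["Region"],
            "chrom": raw["Chr"],
            "start_cm": raw["PosStart"].astype(float),
            "end_cm": raw["PosEnd"].astype(float),
            "pops": [frozenset(s.split(",")) for s in raw["Pops"]],
            "methods": [frozenset(s.split(",")) for s in raw["Methods"]],
        })
        t = cls(rows)
        t.validate()
        return t


@dataclass
class LDMatrixFixture:
    """Square matrix of pairwise r2 values with explicit missing cells."""

    labels: list[str]
    values: np.ndarray  # float matrix, NaN = missing

    def validate(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix not square against labels")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be 1.0")
        v = self.values[np.isfinite(self.values)]
        if ((v < 0) | (v > 1)).any():
            raise ValueError("r2 values outside [0,1]")

    def cell(self, row: str, col: str) -> float:
        return float(self.values[self.labels.index(row), self.labels.index(col)])


# ---------------------------------------------------------------------------
# Haplotype I/O
# ---------------------------------------------------------------------------

def _map_companion(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".map") if path.suffix != ".tsv" \
        else path.with_name(path.stem + ".map.tsv")


def read_haplotypes(path: str | Path, format: str = "hapmatrix",
                    map_path: str | Path | None = None) -> HaplotypeSet:
    """Read a haplotype set from ``hapmatrix`` TSV or ``vcf``.

    hapmatrix: TSV with a ``sample`` column followed by one column per locus,
    values 0/1/NA, one row per haplotype (two consecutive rows per
    individual), plus a companion map TSV (locus, chrom, cM, bp).

    VCF: biallelic SNPs only; phased and unphased diploid calls are treated
    identically (a het call becomes one 0-row and one 1-row; the order of the
    two haplotype rows is unspecified because downstream statistics operate
    on haplotype multisets).  Genetic positions are taken from an ``INFO/cM``
    field when present, else from a companion map.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hapmatrix":
        return _read_hapmatrix(path, Path(map_path) if map_path else _map_companion(path))
    if format == "vcf":
        return _read_vcf(path, Path(map_path) if map_path else None)
    raise ValueError(f"unknown format {format!r}")


def _read_hapmatrix(path: Path, map_path: Path) -> HaplotypeSet:
    mat = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in mat.columns:
        raise FormatError("hapmatrix lacks a 'sample' column")
    loci = pd.read_csv(map_path, sep="\t")
    loci["locus"] = loci["locus"].astype(str)
    locus_cols = [c for c in mat.columns if c != "sample"]
    if locus_cols != list(loci["locus"]):
        raise FormatError("hapmatrix locus header does not match map file")
    _check_sorted_loci(loci)
    samples = mat["sample"].tolist()
    if len(samples) % 2 != 0:
        raise FormatError("hapmatrix must contain two rows per individual")
    individuals = samples[::2]
    if samples[1::2] != individuals:
        raise FormatError("hapmatrix rows must pair consecutive haplotypes per sample")
    vals = mat[locus_cols].to_numpy(dtype=object)
    out = np.full(vals.shape, MISSING, dtype=np.int8)
    numeric = pd.DataFrame(vals).apply(pd.to_numeric, errors="coerce").to_numpy()
    out[numeric == 0] = 0
    out[numeric == 1] = 1
    hs = HaplotypeSet(individuals=individuals,
                      loci=loci.reset_index(drop=True),
                      alleles=out,
                      ploidy_note=_infer_ploidy(loci))
    hs.validate()
    return hs


def _infer_ploidy(loci: pd.DataFrame) -> int:
    sub = {str(c)[-1] if str(c)[-1].isalpha() else str(c)[0]
           for c in loci["chrom"].unique()}
    letters = {s for s in sub if s in "ABD"}
    return max(1, min(3, len(letters))) if letters else 1


def _read_vcf(path: Path, map_path: Path | None) -> HaplotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    meta = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} ({rec.ID})")
        gts = rec.genotype.array()  # (n_samples, ploidy+1)
        a = np.full(2 * len(individuals), MISSING, dtype=np.int8)
        for i in range(len(individuals)):
            g0, g1 = int(gts[i, 0]), int(gts[i, 1])
            a[2 * i] = g0 if g0 >= 0 else MISSING
            a[2 * i + 1] = g1 if g1 >= 0 else MISSING
        rows.append(a)
        cm = rec.INFO.get("cM")
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM,
                     float(cm) if cm is not None else np.nan, rec.POS))
    loci = pd.DataFrame(meta, columns=["locus", "chrom", "cM", "bp"])
    if map_path is not None:
        ext = pd.read_csv(map_path, sep="\t")
        loci = loci.drop(columns="cM").merge(
            ext[["locus", "cM"]], on="locus", how="left")
        loci = loci[["locus", "chrom", "cM", "bp"]]
    if loci["cM"].isna().any():
        loci["cM"] = loci["bp"] / 1e6  # 1 Mb == 1 cM fallback embedding
    alleles = np.stack(rows, axis=1) if rows else \
        np.zeros((2 * len(individuals), 0), dtype=np.int8)
    hs = HaplotypeSet(individuals=individuals, loci=loci, alleles=alleles,
                      ploidy_note=_infer_ploidy(loci) if len(loci) else 1)
    hs.validate()
    return hs


def write_haplotypes(hs: HaplotypeSet, path: str | Path,
                     format: str = "hapmatrix",
                     map_path: str | Path | None = None) -> None:
    """Write a haplotype set losslessly; inverse of :func:`read_haplotypes`."""
    hs.validate()
    path = Path(path)
    if format == "hapmatrix":
        _write_hapmatrix(hs, path, Path(map_path) if map_path else _map_companion(path))
    elif format == "vcf":
        _write_vcf(hs, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_hapmatrix(hs: HaplotypeSet, path: Path, map_path: Path) -> None:
    vals = hs.alleles.astype(object)
    vals[hs.alleles == MISSING] = "NA"
    df = pd.DataFrame(vals, columns=hs.loci["locus"].tolist())
    df.insert(0, "sample", np.repeat(hs.individuals, 2))
    df.to_csv(path, sep="\t", index=False)
    hs.loci[["locus", "chrom", "cM", "bp"]].to_csv(map_path, sep="\t", index=False)


def _write_vcf(hs: HaplotypeSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=cM,Number=1,Type=Float,Description="Genetic position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in hs.loci["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hs.individuals) + "\n")
        a = hs.alleles
        for j, loc in hs.loci.iterrows():
            gts = []
            for i in range(hs.n_individuals):
                g0, g1 = a[2 * i, j], a[2 * i + 1, j]
                s0 = "." if g0 == MISSING else str(int(g0))
                s1 = "." if g1 == MISSING else str(int(g1))
                gts.append(f"{s0}|{s1}")
            fh.write(f"{loc.chrom}\t{int(loc.bp)}\t{loc.locus}\tA\tT\t.\tPASS\t"
                     f"cM={loc.cM:g}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("polysweep").joinpath("data", name)))


def _parse_pops(text: str) -> frozenset[str]:
    text = text.strip()
    if text.lower() == "all comparisons":
        return frozenset(ALL_POPULATIONS)
    toks = [t for chunk in text.split(",") for t in chunk.split()]
    bad = [t for t in toks if t not in ALL_POPULATIONS]
    if bad:
        raise FormatError(f"unknown population token(s) {bad}")
    return frozenset(toks)


def _parse_methods(text: str) -> frozenset[str]:
    toks = [t.strip().upper() for t in text.split(",")]
    norm = set()
    for t in toks:
        if t not in _METHOD_ALIASES:
            raise FormatError(f"unknown method token {t!r}")
        norm.add(_METHOD_ALIASES[t])
    if "ALL" in norm:
        return frozenset(ALL_METHODS)
    return frozenset(norm)


def load_sweep_table_fixture() -> SweepTable:
    """The packaged 86-region sweep table.

    Expansion rules are part of the fixture contract: a Pops value of
    "All comparisons" expands to all seven population labels, an Analysis
    value of "All" to all four methods, and the stray "his" token is
    normalized to IHS.
    """
    raw = pd.read_csv(_data_path("sweep_regions.tsv"), sep="\t")
    rows = pd.DataFrame({
        "region": raw["region"],
        "chrom": raw["chrom"],
        "start_cm": raw["start_cm"].astype(float),
        "end_cm": raw["end_cm"].astype(float),
        "pops": [_parse_pops(s) for s in raw["pops"]],
        "methods": [_parse_methods(s) for s in raw["methods"]],
        "annotation": raw["genes"].fillna("-"),
    })
    t = SweepTable(rows)
    t.validate()
    return t


def load_ld_matrix_fixture() -> LDMatrixFixture:
    """The packaged 17x17 inter-region r2 matrix (13 sweeps + 4 genes).

    Asymmetric cells and missing entries are preserved exactly as printed.
    """
    df = pd.read_csv(_data_path("ld_matrix.tsv"), sep="\t", index_col=0)
    fx = LDMatrixFixture(labels=list(df.index), values=df.to_numpy(float))
    fx.validate()
    return fx
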
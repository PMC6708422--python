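"""Linkage disequilibrium: Hill-Robertson r2, decay curves, background-LD
percentile, and the inter-region LD criterion with cluster analysis.

r2 between two biallelic loci is D^2 / (pA (1-pA) pB (1-pB)) from haplotype
counts, equivalently the squared Pearson correlation of the 0/1 haplotype
vectors; missing entries are dropped pairwise and monomorphic inputs are
undefined (NaN).

For inbred cultivars, LD between loci is computed on one haplotype per
homozygous individual; individuals heterozygous at a locus are treated as
missing for it (chip heterozygote calls are unreliable in hexaploid wheat).

Two sweep regions are declared "in LD" when, after excluding individual SNPs
whose inter-region LD does not follow the general pattern (default: more than
3 median absolute deviations above the region-pair median), strictly more
than half of the retained SNPs in EACH region have inter-region LD above the
99th percentile of background LD (LD between SNPs on different chromosomes;
empirical default 0.161).  The reported value is the highest r2 among
retained SNP pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MISSING, HaplotypeSet, SweepTable

#: 99th percentile of background (inter-chromosomal) r2 in the Australian
#: wheat panel; used when no empirical panel is supplied.
DEFAULT_BACKGROUND_R2 = 0.161


@dataclass(frozen=True)
class LDConfig:
    background_percentile: float = 0.99
    background_threshold: float = DEFAULT_BACKGROUND_R2
    min_snps: int = 5
    outlier_mads: float = 3.0
    decay_bin_cm: float = 1.0
    max_decay_cm: float = 50.0
    unlinked_min_cm: float = 50.0

    def __post_init__(self):
        if not 0 <= self.background_threshold <= 1:
            raise ValueError("background_threshold must be in [0,1]")
        if not 0 < self.background_percentile < 1:
            raise ValueError("background_percentile must be in (0,1)")


@dataclass
class RegionLDResult:
    """Inter-region LD evaluation for one region pair."""

    region_x: str
    region_y: str
    eligible: bool
    per_snp_x: np.ndarray = field(default_factory=lambda: np.array([]))
    per_snp_y: np.ndarray = field(default_factory=lambda: np.array([]))
    retained_x: np.ndarray = field(default_factory=lambda: np.array([], int))
    retained_y: np.ndarray = field(default_factory=lambda: np.array([], int))
    majority_x: bool = False
    majority_y: bool = False
    max_r2: float = float("nan")

    @property
    def in_ld(self) -> bool:
        return self.eligible and self.majority_x and self.majority_y


# ---------------------------------------------------------------------------
# Pairwise r2
# ---------------------------------------------------------------------------

def r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Hill-Robertson r2 between two haplotype allele vectors.

    Missing entries (MISSING or NaN) are dropped pairwise; if either locus is
    monomorphic after filtering the value is undefined (NaN).
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    ok = np.isfinite(a) & np.isfinite(b) & (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise r2 between matching columns of two (n, m) matrices with
    NaN for missing; vectorized pairwise-complete computation."""
    okx = np.isfinite(x)
    oky = np.isfinite(y)
    ok = okx & oky
    n = ok.sum(axis=0).astype(float)
    xs = np.where(ok, x, 0.0)
    ys = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=0) / n
        my = ys.sum(axis=0) / n
        exy = (xs * ys).sum(axis=0) / n
        d = exy - mx * my
        va = mx * (1 - mx)
        vb = my * (1 - my)
        out = d * d / (va * vb)
    out[(n < 2) | (va <= 0) | (vb <= 0)] = np.nan
    return out


def inbred_haplotypes(hs: HaplotypeSet) -> np.ndarray:
    """One haplotype per individual: the consensus of the two rows, with
    heterozygous calls set to NaN (missing).  float (n_ind, n_loci)."""
    a0 = hs.alleles[0::2].astype(float)
    a1 = hs.alleles[1::2].astype(float)
    a0[a0 == MISSING] = np.nan
    a1[a1 == MISSING] = np.nan
    out = np.where(a0 == a1, a0, np.nan)
    return out


def r2_matrix(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Full r2 matrix between columns of ``x`` (and ``y``), complete-case
    over rows with no missing data; NaN-robust fallback per pair is not
    attempted here (intended for complete blocks)."""
    if y is None:
        y = x
    xc = x - np.nanmean(x, axis=0)
    yc = y - np.nanmean(y, axis=0)
    xc = np.nan_to_num(xc)
    yc = np.nan_to_num(yc)
    nx = np.sqrt((xc ** 2).sum(axis=0))
    ny = np.sqrt((yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(nx, ny)
    return r ** 2


def mean_inter_r2(hs: HaplotypeSet, loci_a: np.ndarray,
                  loci_b: np.ndarray) -> float:
    """Mean pairwise r2 between two locus index sets (inbred haplotypes)."""
    h = inbred_haplotypes(hs)
    vals = []
    for i in np.asarray(loci_a, int):
        for j in np.asarray(loci_b, int):
            if i == j:
                continue
            vals.append(r2(h[:, i], h[:, j]))
    vals = np.asarray(vals, float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


# ---------------------------------------------------------------------------
# Decay curve and background percentile
# ---------------------------------------------------------------------------

def ld_decay_curve(hs: HaplotypeSet, bin_width_cm: float = 1.0,
                   max_cm: float = 50.0, use: str = "haplotypes",
                   maf_floor: float = 0.0) -> pd.DataFrame:
    """Mean r2 against genetic distance over all intra-chromosomal locus
    pairs up to ``max_cm``, binned by cM distance.

    Returns columns bin_mid_cM, mean_r2, n_pairs.  ``use='inbred'`` computes
    LD on per-individual consensus haplotypes instead of raw haplotype rows.
    ``maf_floor`` drops rare variants, whose pairwise r2 is dominated by
    sampling noise (0.05 is the usual choice for decay curves).
    """
    if use == "inbred":
        H = inbred_haplotypes(hs)
    else:
        H = hs.alleles.astype(float)
        H[H == MISSING] = np.nan
    cm = hs.loci["cM"].to_numpy(float)
    n_bins = int(np.ceil(max_cm / bin_width_cm))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    any_pair = False
    for chrom in hs.loci["chrom"].unique():
        idx = hs.chrom_slice(chrom)
        if idx.size < 2:
            continue
        block = H[:, idx]
        complete = ~np.isnan(block).any(axis=0)
        p = np.nanmean(block, axis=0)
        keep = complete & (np.minimum(p, 1 - p) > max(maf_floor, 0))
        if maf_floor <= 0:
            keep = complete & (p > 0) & (p < 1)
        if keep.sum() < 2:
            continue
        any_pair = True
        block = block[:, keep]
        pos = cm[idx][keep]
        r2m = r2_matrix(block)
        iu, ju = np.triu_indices(block.shape[1], 1)
        dist = np.abs(pos[iu] - pos[ju])
        vals = r2m[iu, ju]
        sel = (dist < max_cm) & np.isfinite(vals)
        b = np.floor(dist[sel] / bin_width_cm).astype(int)
        np.add.at(sums, b, vals[sel])
        np.add.at(counts, b, 1)
    if not any_pair:
        raise ValueError("no mapped intra-chromosomal pairs")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (np.arange(n_bins) + 0.5) * bin_width_cm
    return pd.DataFrame({"bin_mid_cM": mids, "mean_r2": mean,
                         "n_pairs": counts})


def background_ld_percentile(hs: HaplotypeSet | None = None, q: float = 0.99,
                             n_pairs: int = 50_000,
                             rng: np.random.Generator | int | None = None
                             ) -> float:
    """Empirical q-quantile of r2 over a seeded random sample of
    inter-chromosomal SNP pairs (linear-interpolation quantile, same rule as
    threshold derivation).  Without a panel, returns the published empirical
    constant 0.161 for the 99th percentile."""
    if hs is None:
        if q != 0.99:
            raise ValueError("default constant is defined for q=0.99 only")
        return DEFAULT_BACKGROUND_R2
    chroms = hs.loci["chrom"].to_numpy()
    if len(set(chroms)) < 2:
        raise ValueError("background LD requires >= 2 chromosomes")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    H = hs.alleles.astype(float)
    H[H == MISSING] = np.nan
    p = np.nanmean(H, axis=0)
    poly = np.flatnonzero((p > 0) & (p < 1))
    i = rng.choice(poly, size=n_pairs, replace=True)
    j = rng.choice(poly, size=n_pairs, replace=True)
    keep = chroms[i] != chroms[j]
    vals = pairwise_r2(H[:, i[keep]], H[:, j[keep]])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid inter-chromosomal pairs sampled")
    return float(np.quantile(vals, q, method="linear"))


# ---------------------------------------------------------------------------
# Inter-region criterion and clustering
# ---------------------------------------------------------------------------

def interregion_ld(region_x: np.ndarray, region_y: np.ndarray,
                   hs: HaplotypeSet, cfg: LDConfig = LDConfig(),
                   labels: tuple[str, str] = ("X", "Y")) -> RegionLDResult:
    """Evaluate the inter-region LD criterion for two SNP index sets.

    A SNP's inter-region LD is its median r2 against the SNPs of the other
    region (a max-based summary would be dominated by exactly the outliers
    the criterion excludes).  SNPs more than ``cfg.outlier_mads`` MADs above
    the region-pair median are excluded as not following the general pattern.
    """
    region_x = np.asarray(region_x, int)
    region_y = np.asarray(region_y, int)
    res = RegionLDResult(labels[0], labels[1], eligible=True)
    if region_x.size < cfg.min_snps or region_y.size < cfg.min_snps:
        res.eligible = False
        return res
    h = inbred_haplotypes(hs)
    R = np.empty((region_x.size, region_y.size))
    for a, i in enumerate(region_x):
        for b, j in enumerate(region_y):
            R[a, b] = r2(h[:, i], h[:, j])
    with np.errstate(all="ignore"):
        ld_x = np.nanmedian(R, axis=1)
        ld_y = np.nanmedian(R, axis=0)
    res.per_snp_x, res.per_snp_y = ld_x, ld_y

    def retain(ld):
        ok = np.isfinite(ld)
        if not ok.any():
            return np.array([], int)
        med = np.nanmedian(ld)
        mad = np.nanmedian(np.abs(ld - med))
        keep = ok & ~(ld - med > cfg.outlier_mads * mad)
        return np.flatnonzero(keep)

    res.retained_x = retain(ld_x)
    res.retained_y = retain(ld_y)
    if res.retained_x.size == 0 or res.retained_y.size == 0:
        res.eligible = False
        return res
    thr = cfg.background_threshold
    res.majority_x = (ld_x[res.retained_x] > thr).sum() > res.retained_x.size / 2
    res.majority_y = (ld_y[res.retained_y] > thr).sum() > res.retained_y.size / 2
    sub = R[np.ix_(res.retained_x, res.retained_y)]
    if np.isfinite(sub).any():
        res.max_r2 = float(np.nanmax(sub))
    return res


def region_snp_sets(sweeps: SweepTable, hs: HaplotypeSet) -> dict[str, np.ndarray]:
    """Locus indices inside each region's closed cM interval."""
    cm = hs.loci["cM"].to_numpy(float)
    chroms = hs.loci["chrom"].to_numpy()
    out = {}
    for _, r in sweeps.rows.iterrows():
        sel = (chroms == r["chrom"]) & (cm >= r["start_cm"]) & (cm <= r["end_cm"])
        out[r["region"]] = np.flatnonzero(sel)
    return out


def ld_cluster(sweeps: SweepTable, hs: HaplotypeSet,
               cfg: LDConfig = LDConfig()) -> dict:
    """Cluster unlinked sweep regions by the inter-region LD criterion.

    Region pairs on different chromosomes (or farther apart than
    ``cfg.unlinked_min_cm`` on the same chromosome) are evaluated with
    :func:`interregion_ld`; in-LD pairs become graph edges and connected
    components are reported with the mean of the reported pairwise r2 values.
    """
    import networkx as nx

    snps = region_snp_sets(sweeps, hs)
    ids = list(snps)
    g = nx.Graph()
    g.add_nodes_from(ids)
    pair_rows = []
    rows = sweeps.rows.set_index("region")
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ra, rb = rows.loc[ids[a]], rows.loc[ids[b]]
            if ra["chrom"] == rb["chrom"]:
                gap = max(rb["start_cm"] - ra["end_cm"],
                          ra["start_cm"] - rb["end_cm"])
                if gap < cfg.unlinked_min_cm:
                    continue
            res = interregion_ld(snps[ids[a]], snps[ids[b]], hs, cfg,
                                 labels=(ids[a], ids[b]))
            pair_rows.append({"region_x": ids[a], "region_y": ids[b],
                              "eligible": res.eligible, "in_ld": res.in_ld,
                              "max_r2": res.max_r2})
            if res.in_ld:
                g.add_edge(ids[a], ids[b], r2=res.max_r2)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comp_means = []
    for c in comps:
        vals = [g.edges[e]["r2"] for e in g.edges(c)
                if np.isfinite(g.edges[e].get("r2", np.nan))]
        comp_means.append(float(np.mean(vals)) if vals else float("nan"))
    return {"components": comps, "component_mean_r2": comp_means,
            "pairs": pd.DataFrame(pair_rows)}
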
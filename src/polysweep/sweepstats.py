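"""The four selection statistics: windowed Fst, iHS, nSL and XPCLR.

All four are computed from phased/inbred biallelic haplotypes.  Conventions:

* Fst is a per-locus population-drift moment statistic,
  ``F = (1/K) * sum_j (p_j - pbar)^2 / (pbar (1 - pbar))`` with unweighted
  mean ``pbar`` over the K populations, averaged in 15-SNP sliding windows
  with step 1 and reported at the window-center SNP.
* iHS is ``ln(iHH_major / iHH_minor)`` where iHH integrates extended
  haplotype homozygosity (EHH) over genetic distance away from the core SNP
  until EHH falls below a cutoff; chip data lack ancestral states, so
  polarization is by the major allele in the combined sample and scores are
  standardized within allele-frequency bins (mean 0, variance 1).
* nSL is the map-free analogue: the pair statistic is the number of
  consecutive segregating sites of the maximal interval containing the core
  on which a haplotype pair is identical, averaged over carrier pairs.
* XPCLR contrasts objective-population allele counts against expectations
  given reference-population frequencies under Brownian drift versus a
  hitchhiking model evaluated on a physical grid; the drift variance scale is
  estimated genome-wide by the method of moments, and the selection intensity
  is maximized over a fixed logarithmic grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .dataio import MISSING, HaplotypeSet

# ---------------------------------------------------------------------------
# Configuration / result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameterization.

    Defaults: 15-SNP Fst windows with step 1; XPCLR on a 1 Mb grid with a
    1 cM window, at most 50 SNPs per window and LD pruning at r2 > 0.95;
    iHS/nSL with MAF floor 0.05, EHH truncation cutoff 0.05, a 2 cM maximum
    gap and 0.025-wide frequency bins for standardization.
    """

    fst_window: int = 15
    fst_step: int = 1
    xpclr_grid_bp: float = 1e6
    xpclr_window_cm: float = 1.0
    xpclr_max_snps: int = 50
    xpclr_prune_r2: float = 0.95
    xpclr_sel_grid: tuple = tuple(np.geomspace(1e-5, 1e-1, 20))
    xpclr_quad_nodes: int = 24
    maf_floor: float = 0.05
    ehh_cutoff: float = 0.05
    max_gap_cm: float = 2.0
    max_extend_cm: float = 20.0
    bin_width: float = 0.025
    min_bin_count: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.fst_window < 1:
            raise ValueError("window must be >= 1")
        for name in ("xpclr_prune_r2", "ehh_cutoff", "bin_width"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")


@dataclass
class ScoreTrack:
    """Per-evaluation-point statistic values.

    ``data`` columns: chrom, pos_cM, pos_bp, raw, std, score, n_snps, where
    ``score`` is the value significance is assessed on (standardized for
    iHS/nSL, raw for Fst and XPCLR) and n_snps counts the contributing SNPs
    (dropped loci are visible here, never silently imputed).
    """

    statistic: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def scores(self) -> np.ndarray:
        return self.data["score"].to_numpy(float)


TWO_SIDED_STATISTICS = frozenset({"IHS", "NSL"})


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def _group_frequencies(hs: HaplotypeSet, pop_labels: dict[str, str] | None):
    labels = pop_labels or hs.sample_groups
    if labels is None:
        raise ValueError("no population labels supplied")
    pops = sorted(set(labels.values()))
    freqs, ns = [], []
    for pop in pops:
        idx = np.array([i for i, s in enumerate(hs.individuals)
                        if labels.get(s) == pop], dtype=int)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} has zero samples")
        rows = hs.haplotype_rows(idx)
        a = hs.alleles[rows]
        nn = (a != MISSING).sum(axis=0)
        k = (a == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nn > 0, k / np.maximum(nn, 1), np.nan)
        freqs.append(p)
        ns.append(nn)
    return pops, np.array(freqs), np.array(ns)


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def nicholson_fst(freqs: np.ndarray) -> np.ndarray:
    """Per-locus population-drift moment Fst from a (K, L) frequency matrix.

    Loci where the unweighted mean frequency is 0 or 1 are undefined (NaN).
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    pbar = freqs.mean(axis=0)
    denom = pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((freqs - pbar) ** 2).mean(axis=0) / denom
    f[denom == 0] = np.nan
    return f


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-locus Hudson-style two-population Fst from population frequencies
    (no sample-size correction; inputs are whole-population frequencies)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def hudson_fst_mean(p1: np.ndarray, p2: np.ndarray) -> float:
    """Genome-wide Hudson Fst as a ratio of averages (the recommended
    aggregation: unbiased for the drift differentiation 1 - exp(-t/2N))."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    num = np.nansum((p1 - p2) ** 2)
    den = np.nansum(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den) if den > 0 else 0.0


def fst_scan(hs: HaplotypeSet, pop_labels: dict[str, str] | None = None,
             cfg: ScanConfig = ScanConfig()) -> ScoreTrack:
    """Sliding-window Fst track (window of ``cfg.fst_window`` SNPs, step
    ``cfg.fst_step``), reported at the window-center SNP."""
    pops, freqs, _ = _group_frequencies(hs, pop_labels)
    if len(pops) < 2:
        raise ValueError("fst_scan needs >= 2 populations")
    per_locus = nicholson_fst(freqs)
    w, step = cfg.fst_window, cfg.fst_step
    rows = []
    for chrom in hs.loci["chrom"].unique():
        idx = hs.chrom_slice(chrom)
        vals = per_locus[idx]
        cm = hs.loci["cM"].to_numpy(float)[idx]
        bp = hs.loci["bp"].to_numpy(float)[idx]
        if idx.size < w:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(vals, w)[::step]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sw, axis=1)
        n_ok = np.isfinite(sw).sum(axis=1)
        centers = np.arange(0, idx.size - w + 1, step) + w // 2
        for m, n, c in zip(means, n_ok, centers):
            rows.append((chrom, cm[c], bp[c], m, np.nan, m, int(n)))
    data = pd.DataFrame(rows, columns=["chrom", "pos_cM", "pos_bp", "raw",
                                       "std", "score", "n_snps"])
    return ScoreTrack("FST", data, {"populations": pops,
                                    "window": w, "step": step})


# ---------------------------------------------------------------------------
# EHH / iHS / nSL kernels
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _extend_sum(haps, carr, core, step, pos, cutoff, max_gap, max_extend,
                nsl_mode, mapbuf, group, sizes):  # pragma: no cover - numba
    """Accumulate EHH outward from ``core`` in one direction.

    iHS mode (nsl_mode=False): trapezoidal integral of EHH over genetic
    distance until EHH < cutoff or the maximum extension distance
    ``max_extend`` is reached (integration censored there, as in standard
    haplotype-scan tooling: in strongly selfing populations a clonal-pair
    floor can keep EHH above any cutoff indefinitely); returns
    (integral, ok) with ok=False when the chromosome edge or a gap >
    max_gap is hit before truncation.

    nSL mode: sum over successive sites of the fraction of carrier pairs
    still identical (pairs reaching the edge are censored there).
    """
    nc = carr.size
    L = pos.size
    tot = nc * (nc - 1) * 0.5
    for i in range(nc):
        group[i] = 0
    ng = 1
    ehh_prev = 1.0
    acc = 0.0
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= L:
            if nsl_mode:
                return acc, True
            return acc, False
        gap = abs(pos[jn] - pos[j])
        if (not nsl_mode) and gap > max_gap:
            return acc, False
        for k in range(2 * ng + 2):
            mapbuf[k] = -1
        ng_new = 0
        for i in range(nc):
            key = group[i] * 2 + haps[carr[i], jn]
            g = mapbuf[key]
            if g == -1:
                g = ng_new
                mapbuf[key] = g
                sizes[g] = 0
                ng_new += 1
            group[i] = g
            sizes[g] += 1
        pairs = 0.0
        for g in range(ng_new):
            s = sizes[g]
            pairs += s * (s - 1) * 0.5
        ehh = pairs / tot
        if nsl_mode:
            acc += ehh
            if ehh <= 0.0:
                return acc, True
        else:
            acc += 0.5 * (ehh_prev + ehh) * gap
            if ehh < cutoff:
                return acc, True
            if abs(pos[jn] - pos[core]) >= max_extend:
                return acc, True
        ehh_prev = ehh
        ng = ng_new
        j = jn


@numba.njit(cache=True)
def _raw_haplotype_scores(haps, pos, maf_floor, cutoff, max_gap, max_extend,
                          nsl_mode):  # pragma: no cover - numba
    """Raw iHS or nSL per core SNP on one chromosome; also returns the
    allele-1 frequency.  NaN where the statistic is undefined."""
    n, L = haps.shape
    raw = np.full(L, np.nan)
    freq = np.full(L, np.nan)
    mapbuf = np.full(2 * n + 4, -1, dtype=np.int64)
    group = np.zeros(n, dtype=np.int64)
    sizes = np.zeros(n + 1, dtype=np.int64)
    for core in range(L):
        c1 = np.where(haps[:, core] == 1)[0]
        c0 = np.where(haps[:, core] == 0)[0]
        p1 = c1.size / n
        freq[core] = p1
        maf = min(p1, 1.0 - p1)
        if maf < maf_floor or c0.size < 2 or c1.size < 2:
            continue
        vals = np.empty(2)
        ok_all = True
        for ai, carr in enumerate((c0, c1)):
            v = 0.0
            for step in (-1, 1):
                acc, ok = _extend_sum(haps, carr, core, step, pos, cutoff,
                                      max_gap, max_extend, nsl_mode,
                                      mapbuf, group, sizes)
                if not ok:
                    ok_all = False
                    break
                v += acc
            if not ok_all:
                break
            vals[ai] = v + 1.0 if nsl_mode else v
        if not ok_all:
            continue
        major = 0 if c0.size >= c1.size else 1
        num, den = vals[major], vals[1 - major]
        if num > 0 and den > 0:
            raw[core] = math.log(num / den)
    return raw, freq


def ehh(haps: np.ndarray, core: int, direction: int,
        allele: int = 1) -> pd.DataFrame | None:
    """EHH curve for carriers of ``allele`` at ``core``, moving site by site
    in ``direction`` (+1/-1): the probability that two random carrier
    haplotypes are identical from the core out to each site.  EHH(0) = 1 and
    the curve is non-increasing.  Returns None when there are fewer than two
    carriers (undefined)."""
    haps = np.ascontiguousarray(haps, dtype=np.uint8)
    carr = np.flatnonzero(haps[:, core] == allele)
    nc = carr.size
    if nc < 2:
        return None
    tot = nc * (nc - 1) / 2
    group = np.zeros(nc, dtype=np.int64)
    offs, vals = [0], [1.0]
    j = core
    while True:
        jn = j + direction
        if jn < 0 or jn >= haps.shape[1]:
            break
        key = group * 2 + haps[carr, jn]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        e = float((counts * (counts - 1) / 2).sum() / tot)
        offs.append(abs(jn - core))
        vals.append(e)
        if e == 0.0:
            break
        j = jn
    return pd.DataFrame({"offset": offs, "ehh": vals})


def _standardize_bins(raw: np.ndarray, freq: np.ndarray, bin_width: float,
                      min_count: int) -> np.ndarray:
    """Standardize raw scores to mean 0 / sd 1 within minor-allele-frequency
    bins; bins with fewer than ``min_count`` finite scores give NaN."""
    maf = np.minimum(freq, 1 - freq)
    std = np.full_like(raw, np.nan)
    ok = np.isfinite(raw)
    bins = np.floor(maf / bin_width).astype(int)
    for b in np.unique(bins[ok]):
        sel = ok & (bins == b)
        if sel.sum() < min_count:
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std()
        if sd > 0:
            std[sel] = (raw[sel] - mu) / sd
    return std


def _haplotype_scan(hs: HaplotypeSet, cfg: ScanConfig, nsl_mode: bool,
                    statistic: str) -> ScoreTrack:
    rows = []
    raw_all, freq_all = [], []
    chrom_of, cm_all, bp_all = [], [], []
    for chrom in hs.loci["chrom"].unique():
        idx = hs.chrom_slice(chrom)
        a = hs.alleles[:, idx]
        complete = ~(a == MISSING).any(axis=0)
        idx = idx[complete]
        if idx.size == 0:
            continue
        haps = np.ascontiguousarray(hs.alleles[:, idx], dtype=np.uint8)
        cm = hs.loci["cM"].to_numpy(float)[idx]
        bp = hs.loci["bp"].to_numpy(float)[idx]
        pos = np.arange(idx.size, dtype=float) if nsl_mode else cm
        raw, freq = _raw_haplotype_scores(
            haps, pos, cfg.maf_floor, cfg.ehh_cutoff, cfg.max_gap_cm,
            cfg.max_extend_cm, nsl_mode)
        raw_all.append(raw)
        freq_all.append(freq)
        chrom_of.append(np.repeat(chrom, idx.size))
        cm_all.append(cm)
        bp_all.append(bp)
    raw = np.concatenate(raw_all) if raw_all else np.array([])
    freq = np.concatenate(freq_all) if freq_all else np.array([])
    std = _standardize_bins(raw, freq, cfg.bin_width, cfg.min_bin_count) \
        if raw.size else raw
    data = pd.DataFrame({
        "chrom": np.concatenate(chrom_of) if chrom_of else [],
        "pos_cM": np.concatenate(cm_all) if cm_all else [],
        "pos_bp": np.concatenate(bp_all) if bp_all else [],
        "raw": raw, "std": std, "score": std,
        "n_snps": np.where(np.isfinite(raw), 1, 0),
    })
    return ScoreTrack(statistic, data, {"maf_floor": cfg.maf_floor})


def ihs_scan(hs: HaplotypeSet, gmap=None,
             cfg: ScanConfig = ScanConfig()) -> ScoreTrack:
    """Integrated haplotype score per SNP, standardized in frequency bins.

    SNPs whose EHH fails to truncate before the chromosome edge, or whose
    extension would cross an inter-SNP gap larger than ``cfg.max_gap_cm``,
    are missing.  The genetic map is taken from ``hs.loci`` (an explicit
    ``gmap`` argument overrides the cM column).
    """
    if gmap is not None:
        hs = HaplotypeSet(hs.individuals,
                          hs.loci.drop(columns="cM").merge(
                              gmap.table[["locus", "cM"]], on="locus")[
                              ["locus", "chrom", "cM", "bp"]],
                          hs.alleles, hs.ploidy_note, hs.sample_groups)
    if hs.loci["cM"].isna().any():
        raise ValueError("unmapped loci: cM positions required for iHS")
    return _haplotype_scan(hs, cfg, nsl_mode=False, statistic="IHS")


def nsl_scan(hs: HaplotypeSet, cfg: ScanConfig = ScanConfig()) -> ScoreTrack:
    """Number-of-segregating-sites-by-length score per SNP (map-free),
    standardized in frequency bins."""
    return _haplotype_scan(hs, cfg, nsl_mode=True, statistic="NSL")


# ---------------------------------------------------------------------------
# XPCLR
# ---------------------------------------------------------------------------

def _log_binom_pmf(k: np.ndarray, n: np.ndarray, q: np.ndarray) -> np.ndarray:
    """log C(n,k) + k log q + (n-k) log(1-q), safe at q in {0,1}."""
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    out = coef + xlogy(k, q) + xlogy(n - k, 1.0 - q)
    return out


def _window_loglik(k, n, p1, c, omega, nodes, wts):
    """Composite log-likelihood of objective counts k (of n haplotypes) given
    reference frequencies p1 under drift (variance omega*p1(1-p1)) followed by
    a hitchhiking event with per-SNP escape probability c (c=1: neutral).

    Shapes: k,n,p1,c are (S,); nodes,wts are quadrature abscissae on (0,1).
    Returns scalar sum of per-SNP log-probabilities.
    """
    from scipy.stats import norm

    S = k.size
    sd = np.sqrt(omega * p1 * (1 - p1))
    # drift density at quadrature nodes + boundary masses
    z = (nodes[None, :] - p1[:, None]) / sd[:, None]
    dens = norm.pdf(z) / sd[:, None]                       # (S, M)
    mass0 = norm.cdf((0.0 - p1) / sd)
    mass1 = norm.sf((1.0 - p1) / sd)
    # renormalize the continuous part so the three pieces sum to one
    interior = dens @ wts
    scale = np.where(interior > 0, (1.0 - mass0 - mass1) / interior, 0.0)
    dens = dens * scale[:, None]

    cN = c[:, None]
    q_hitch = 1.0 - cN + cN * nodes[None, :]
    q_escape = cN * nodes[None, :]
    kb = k[:, None]
    nb = n[:, None]
    pmf = (nodes[None, :] * np.exp(_log_binom_pmf(kb, nb, q_hitch))
           + (1 - nodes[None, :]) * np.exp(_log_binom_pmf(kb, nb, q_escape)))
    prob = (dens * pmf) @ wts
    prob = prob + mass0 * (k == 0) + mass1 * (k == n)
    return float(np.sum(np.log(np.maximum(prob, 1e-300))))


def estimate_drift_variance(p_obj: np.ndarray, p_ref: np.ndarray,
                            floor: float = 0.05) -> float:
    """Genome-wide moment estimate of the Brownian drift variance scale:
    mean of (p_obj - p_ref)^2 / (p_ref (1 - p_ref)) over loci with reference
    MAF above ``floor``."""
    ok = np.isfinite(p_obj) & np.isfinite(p_ref) & \
        (p_ref > floor) & (p_ref < 1 - floor)
    if not ok.any():
        raise ValueError("no usable loci to estimate drift variance")
    return float(np.mean((p_obj[ok] - p_ref[ok]) ** 2
                         / (p_ref[ok] * (1 - p_ref[ok]))))


def _prune_window(r2m: np.ndarray, threshold: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Greedy LD pruning: for each pair with r2 > threshold keep one SNP at
    random; returns indices of kept SNPs."""
    S = r2m.shape[0]
    alive = np.ones(S, dtype=bool)
    ii, jj = np.where(np.triu(r2m, 1) > threshold)
    for i, j in zip(ii, jj):
        if alive[i] and alive[j]:
            drop = i if rng.integers(0, 2) == 0 else j
            alive[drop] = False
    return np.flatnonzero(alive)


def _window_r2(haps: np.ndarray) -> np.ndarray:
    """r2 matrix among SNP columns of a complete 0/1 haplotype block."""
    x = haps.astype(float)
    x = x - x.mean(axis=0)
    denom = np.sqrt((x ** 2).sum(axis=0))
    denom[denom == 0] = np.nan
    r = (x.T @ x) / np.outer(denom, denom)
    return np.nan_to_num(r ** 2, nan=0.0)


def xpclr_scan(obj: HaplotypeSet, ref: HaplotypeSet, gmap=None,
               cfg: ScanConfig = ScanConfig(),
               rng: np.random.Generator | None = None) -> ScoreTrack:
    """Cross-population composite likelihood ratio on a physical grid.

    Evaluation points are placed every ``cfg.xpclr_grid_bp`` bp; each point
    uses SNPs within ``cfg.xpclr_window_cm`` of genetic distance (pruned at
    r2 > ``cfg.xpclr_prune_r2`` and capped at ``cfg.xpclr_max_snps`` by
    seeded uniform thinning).  The score is
    ``2 * (max_s CLL(s) - CLL(neutral))`` over the selection grid.
    """
    if list(obj.loci["locus"]) != list(ref.loci["locus"]):
        raise ValueError("objective and reference must share loci")
    if obj.loci["bp"].isna().any():
        raise ValueError("missing bp positions")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    def freqs(hs):
        a = hs.alleles
        nn = (a != MISSING).sum(axis=0)
        k = (a == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nn > 0, k / np.maximum(nn, 1), np.nan), k, nn

    p_obj, k_obj, n_obj = freqs(obj)
    p_ref, _, _ = freqs(ref)
    # floor keeps the drift density proper when the populations are
    # (near-)identical and omega would degenerate to zero
    omega = max(estimate_drift_variance(p_obj, p_ref), 1e-4)
    two_n = max(4.0, float(np.median(n_obj)))
    nodes, wts = np.polynomial.legendre.leggauss(cfg.xpclr_quad_nodes)
    nodes = 0.5 * (nodes + 1.0)
    wts = 0.5 * wts

    cm = obj.loci["cM"].to_numpy(float)
    bp = obj.loci["bp"].to_numpy(float)
    usable = np.isfinite(p_ref) & (p_ref > 0) & (p_ref < 1)

    rows = []
    for chrom in obj.loci["chrom"].unique():
        idx = obj.chrom_slice(chrom)
        grid = np.arange(bp[idx].min(), bp[idx].max() + 1, cfg.xpclr_grid_bp)
        grid_cm = np.interp(grid, bp[idx], cm[idx])
        for g_bp, g_cm in zip(grid, grid_cm):
            win = idx[(np.abs(cm[idx] - g_cm) <= cfg.xpclr_window_cm / 2)
                      & usable[idx]]
            if win.size == 0:
                rows.append((chrom, g_cm, g_bp, np.nan, np.nan, np.nan, 0))
                continue
            if win.size > 1:
                block = obj.alleles[:, win]
                keep_rows = ~(block == MISSING).any(axis=1)
                r2m = _window_r2(block[keep_rows]) if keep_rows.sum() >= 4 \
                    else np.zeros((win.size, win.size))
                win = win[_prune_window(r2m, cfg.xpclr_prune_r2, rng)]
            if win.size > cfg.xpclr_max_snps:
                win = np.sort(rng.choice(win, cfg.xpclr_max_snps, replace=False))
            k = k_obj[win].astype(float)
            n = n_obj[win].astype(float)
            p1 = p_ref[win]
            r = np.abs(cm[win] - g_cm) / 100.0  # Morgans
            ll0 = _window_loglik(k, n, p1, np.ones_like(p1), omega, nodes, wts)
            best = ll0
            for s in cfg.xpclr_sel_grid:
                c = 1.0 - np.exp(-r * math.log(two_n) / s)
                ll = _window_loglik(k, n, p1, c, omega, nodes, wts)
                if ll > best:
                    best = ll
            score = 2.0 * (best - ll0)
            rows.append((chrom, g_cm, g_bp, score, np.nan, score, win.size))
    data = pd.DataFrame(rows, columns=["chrom", "pos_cM", "pos_bp", "raw",
                                       "std", "score", "n_snps"])
    return ScoreTrack("XPCLR", data, {"omega": omega, "two_n": two_n})
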
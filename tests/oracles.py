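"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: EHH/iHS/nSL are computed
by explicit enumeration of haplotype pairs, r2 from 2x2 contingency counts,
and interval union by point-membership scanning.  They are only feasible for
tiny inputs, which is the point.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def contingency_r2(a, b):
    """r2 from the 2x2 haplotype contingency table; NaN where undefined."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b) & (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        return float("nan")
    f11 = np.sum((a == 1) & (b == 1)) / n
    pa = a.mean()
    pb = b.mean()
    if pa in (0, 1) or pb in (0, 1):
        return float("nan")
    d = f11 - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def pair_identical(h1, h2, lo, hi):
    """True if two haplotypes agree on every site of the closed range."""
    return bool(np.all(h1[lo:hi + 1] == h2[lo:hi + 1]))


def brute_ehh(haps, core, allele, offset, direction):
    """EHH at ``offset`` sites from the core in one direction, by pair
    enumeration.  None when fewer than 2 carriers."""
    haps = np.asarray(haps)
    carriers = np.flatnonzero(haps[:, core] == allele)
    if carriers.size < 2:
        return None
    target = core + direction * offset
    lo, hi = min(core, target), max(core, target)
    pairs = list(itertools.combinations(carriers, 2))
    same = sum(pair_identical(haps[i], haps[j], lo, hi) for i, j in pairs)
    return same / len(pairs)


def brute_ihh_one_side(haps, carriers, core, direction, pos, cutoff,
                       max_gap, max_extend):
    """Trapezoidal iHH in one direction with the package's truncation rules,
    but EHH from explicit pair enumeration.  Returns (value, ok)."""
    L = haps.shape[1]
    pairs = list(itertools.combinations(carriers, 2))
    tot = len(pairs)
    acc, ehh_prev, j = 0.0, 1.0, core
    while True:
        jn = j + direction
        if jn < 0 or jn >= L:
            return acc, False
        gap = abs(pos[jn] - pos[j])
        if gap > max_gap:
            return acc, False
        lo, hi = min(core, jn), max(core, jn)
        same = sum(pair_identical(haps[i], haps[k], lo, hi) for i, k in pairs)
        e = same / tot
        acc += 0.5 * (ehh_prev + e) * gap
        if e < cutoff:
            return acc, True
        if abs(pos[jn] - pos[core]) >= max_extend:
            return acc, True
        ehh_prev, j = e, jn


def brute_ihs(haps, pos, maf_floor=0.0, cutoff=0.05, max_gap=1e9,
              max_extend=1e9):
    """Raw iHS per core SNP by pair enumeration (major/minor polarization)."""
    haps = np.asarray(haps)
    n, L = haps.shape
    out = np.full(L, np.nan)
    for core in range(L):
        c1 = np.flatnonzero(haps[:, core] == 1)
        c0 = np.flatnonzero(haps[:, core] == 0)
        p1 = c1.size / n
        if min(p1, 1 - p1) < maf_floor or c0.size < 2 or c1.size < 2:
            continue
        vals = {}
        ok = True
        for name, carr in (("c0", c0), ("c1", c1)):
            v = 0.0
            for d in (-1, 1):
                acc, good = brute_ihh_one_side(haps, carr, core, d, pos,
                                               cutoff, max_gap, max_extend)
                if not good:
                    ok = False
                    break
                v += acc
            if not ok:
                break
            vals[name] = v
        if not ok:
            continue
        major, minor = ("c0", "c1") if c0.size >= c1.size else ("c1", "c0")
        if vals[major] > 0 and vals[minor] > 0:
            out[core] = math.log(vals[major] / vals[minor])
    return out


def brute_pair_sl(h1, h2, core):
    """Number of consecutive sites of the maximal interval containing the
    core on which the pair is identical (censored at the edges)."""
    L = h1.size
    if h1[core] != h2[core]:
        return 0
    lo = core
    while lo - 1 >= 0 and h1[lo - 1] == h2[lo - 1]:
        lo -= 1
    hi = core
    while hi + 1 < L and h1[hi + 1] == h2[hi + 1]:
        hi += 1
    return hi - lo + 1


def brute_nsl(haps, maf_floor=0.0):
    """Raw nSL per core SNP by exhaustive pair enumeration."""
    haps = np.asarray(haps)
    n, L = haps.shape
    out = np.full(L, np.nan)
    for core in range(L):
        c1 = np.flatnonzero(haps[:, core] == 1)
        c0 = np.flatnonzero(haps[:, core] == 0)
        p1 = c1.size / n
        if min(p1, 1 - p1) < maf_floor or c0.size < 2 or c1.size < 2:
            continue
        sl = {}
        for name, carr in (("c0", c0), ("c1", c1)):
            vals = [brute_pair_sl(haps[i], haps[j], core)
                    for i, j in itertools.combinations(carr, 2)]
            sl[name] = float(np.mean(vals))
        major, minor = ("c0", "c1") if c0.size >= c1.size else ("c1", "c0")
        if sl[major] > 0 and sl[minor] > 0:
            out[core] = math.log(sl[major] / sl[minor])
    return out


def brute_union_intervals(intervals):
    """Transitive union of closed intervals [(start, end), ...] on one
    chromosome, by sorting and chaining."""
    ivs = sorted(intervals)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def hudson_fst_counts(p1, p2):
    """Textbook Hudson two-population per-locus Fst from frequencies."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den > 0 else float("nan")
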
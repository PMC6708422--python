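import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

import oracles
from polysweep.dataio import HaplotypeSet, MISSING
from polysweep.sweepstats import (ScanConfig, ehh, fst_scan, hudson_fst,
                                  nicholson_fst, ihs_scan, nsl_scan,
                                  _raw_haplotype_scores, xpclr_scan)


def make_hs(alleles, chrom="1A", cm=None, groups=None):
    """HaplotypeSet from a (2n, L) array on one chromosome."""
    alleles = np.asarray(alleles, dtype=np.int8)
    L = alleles.shape[1]
    cm = np.arange(L, dtype=float) if cm is None else np.asarray(cm, float)
    loci = pd.DataFrame({"locus": [f"l{i}" for i in range(L)],
                         "chrom": chrom, "cM": cm,
                         "bp": (cm * 1e6 + 1).astype(int)})
    n = alleles.shape[0] // 2
    ids = [f"s{i}" for i in range(n)]
    return HaplotypeSet(ids, loci, alleles, 1,
                        sample_groups=groups and {f"s{i}": groups[i]
                                                  for i in range(n)})


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

class TestFst:
    def test_hand_evaluated_cases(self):
        assert nicholson_fst(np.array([[0.5], [0.5]]))[0] == 0.0
        assert nicholson_fst(np.array([[1.0], [0.0]]))[0] == pytest.approx(1.0)
        assert nicholson_fst(np.array([[0.9], [0.1]]))[0] == pytest.approx(0.64)

    def test_fixed_mean_frequency_is_missing(self):
        f = nicholson_fst(np.array([[0.0], [0.0]]))
        assert np.isnan(f[0])

    def test_windowing_matches_brute_force(self, rng):
        """20 loci, window 15 / step 1 -> 6 windows, each the arithmetic mean
        of its 15 per-locus values."""
        n = 40
        a = rng.integers(0, 2, size=(2 * n, 20)).astype(np.int8)
        groups = ["P1"] * (n // 2) + ["P2"] * (n - n // 2)
        hs = make_hs(a, groups=groups)
        track = fst_scan(hs, cfg=ScanConfig())
        assert len(track.data) == 6
        p1 = a[:n][..., :].mean(axis=0)
        p2 = a[n:][..., :].mean(axis=0)
        per_locus = nicholson_fst(np.array([p1, p2]))
        for w in range(6):
            expected = np.nanmean(per_locus[w:w + 15])
            assert track.data["raw"][w] == pytest.approx(expected)
            # reported at the window-center locus
            assert track.data["pos_cM"][w] == pytest.approx(w + 7.0)

    def test_allele_relabel_invariance(self, rng):
        a = rng.integers(0, 2, size=(30, 16)).astype(np.int8)
        hs1 = make_hs(a, groups=["P1"] * 8 + ["P2"] * 7)
        hs2 = make_hs(1 - a, groups=["P1"] * 8 + ["P2"] * 7)
        t1 = fst_scan(hs1)
        t2 = fst_scan(hs2)
        assert np.allclose(t1.data["raw"], t2.data["raw"], equal_nan=True)

    def test_rank_agreement_with_hudson(self, rng):
        """Ordering agrees with the textbook Hudson estimator even though the
        values differ (rank correlation > 0.99 over 1,000 frequency pairs)."""
        p1 = rng.uniform(0.02, 0.98, 1000)
        p2 = np.clip(p1 + rng.normal(0, 0.2, 1000), 0.01, 0.99)
        nich = nicholson_fst(np.array([p1, p2]))
        huds = np.array([oracles.hudson_fst_counts(a, b)
                         for a, b in zip(p1, p2)])
        assert np.allclose(huds, hudson_fst(p1, p2), equal_nan=True)
        rho = spearmanr(nich, huds).statistic
        assert rho > 0.99

    def test_zero_sample_population_error(self, rng):
        a = rng.integers(0, 2, size=(8, 16)).astype(np.int8)
        hs = make_hs(a, groups=["P1"] * 4)
        with pytest.raises(ValueError, match="zero samples"):
            fst_scan(hs, pop_labels={f"s{i}": "P1" for i in range(4)}
                     | {"ghost": "P2"})

    def test_missing_alleles_reflected_in_n_snps(self, rng):
        """A locus unusable in one population is dropped from the window and
        the contributing-SNP count says so (nothing is imputed silently)."""
        a = rng.integers(0, 2, size=(40, 20)).astype(np.int8)
        a[:20, 3] = MISSING  # population P1 entirely missing at locus 3
        hs = make_hs(a, groups=["P1"] * 10 + ["P2"] * 10)
        track = fst_scan(hs)
        assert track.data["n_snps"].iloc[0] == 14
        assert track.data["n_snps"].iloc[5] == 15


# ---------------------------------------------------------------------------
# EHH / iHS / nSL
# ---------------------------------------------------------------------------

class TestEHH:
    def test_identical_carriers_stay_at_one(self):
        carriers = np.tile(np.array([0, 1, 0, 1, 0], dtype=np.uint8), (4, 1))
        others = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.uint8), (2, 1))
        haps = np.vstack([carriers, others])
        curve = ehh(haps, core=2, direction=1, allele=0)
        assert np.allclose(curve["ehh"], 1.0)

    def test_four_carriers_two_groups(self):
        # 4 carriers of allele 1 split 2/2 at the first flanking site:
        # EHH = (C(2,2)+C(2,2)) / C(4,2) = 2/6 = 1/3
        haps = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=np.uint8)
        curve = ehh(haps, core=0, direction=1, allele=1)
        assert curve["ehh"].iloc[1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_undefined(self):
        haps = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.uint8)
        assert ehh(haps, core=0, direction=1, allele=1) is None

    def test_monotone_non_increasing_and_matches_oracle(self, rng):
        haps = rng.integers(0, 2, size=(12, 9)).astype(np.uint8)
        haps[:, 4] = [1] * 6 + [0] * 6
        curve = ehh(haps, core=4, direction=1, allele=1)
        assert np.all(np.diff(curve["ehh"]) <= 1e-12)
        for _, row in curve.iterrows():
            want = oracles.brute_ehh(haps, 4, 1, int(row["offset"]), 1)
            assert row["ehh"] == pytest.approx(want)


class TestIHS:
    def test_raw_matches_pair_enumeration_oracle(self, rng):
        """Kernel output equals a brute-force pairwise-homozygosity
        integrator on small haplotype sets (8 haplotypes, 7 loci),
        NaN pattern included."""
        for trial in range(25):
            haps = rng.integers(0, 2, size=(8, 7)).astype(np.uint8)
            pos = np.sort(rng.uniform(0, 10, size=7))
            raw, _ = _raw_haplotype_scores(
                np.ascontiguousarray(haps), pos, 0.0, 0.05, 1e9, 1e9, False)
            want = oracles.brute_ihs(haps, pos, 0.0, 0.05, 1e9, 1e9)
            assert np.allclose(raw, want, equal_nan=True), trial

    def test_symmetric_structure_gives_zero(self):
        """When the two allele classes carry identical flanking haplotype
        structure, iHH_0 = iHH_1 and raw iHS = 0 at the core."""
        flanks = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        class0 = np.hstack([flanks, np.zeros((4, 1), np.uint8), flanks])
        class1 = np.hstack([flanks, np.ones((4, 1), np.uint8), flanks])
        haps = np.vstack([class0, class1])
        pos = np.arange(5, dtype=float)
        raw, _ = _raw_haplotype_scores(
            np.ascontiguousarray(haps), pos, 0.0, 0.05, 1e9, 1e9, False)
        assert raw[2] == pytest.approx(0.0, abs=1e-12)

    def test_unmapped_loci_rejected(self, rng):
        a = rng.integers(0, 2, size=(12, 10)).astype(np.int8)
        hs = make_hs(a)
        hs.loci.loc[3, "cM"] = np.nan
        with pytest.raises(ValueError, match="unmapped"):
            ihs_scan(hs)

    def test_standardized_bins_mean_zero_sd_one(self, null_scan_suite):
        """Frequency-bin standardization on neutral simulated data."""
        raws, stds, freqs = [], [], []
        for rep in null_scan_suite:
            d = rep["tracks"]["IHS"].data
            stds.append(d["std"])
        s = pd.concat(stds).dropna()
        assert abs(s.mean()) < 0.15
        assert 0.8 < s.std() < 1.2


class TestNSL:
    def test_identical_pair_spans_all_sites(self):
        # both carriers of allele 1 identical over all S sites -> SL = S
        haps = np.array([[1, 0, 1, 1], [1, 0, 1, 1],
                         [0, 1, 0, 0], [0, 1, 0, 0]], dtype=np.uint8)
        assert oracles.brute_pair_sl(haps[0], haps[1], core=0) == 4

    def test_raw_matches_exhaustive_enumeration(self, rng):
        for trial in range(25):
            haps = rng.integers(0, 2, size=(6, 8)).astype(np.uint8)
            pos = np.arange(8, dtype=float)
            raw, _ = _raw_haplotype_scores(
                np.ascontiguousarray(haps), pos, 0.0, 0.0, 1e9, 1e9, True)
            want = oracles.brute_nsl(haps, 0.0)
            assert np.allclose(raw, want, equal_nan=True), trial

    def test_relabel_invariance(self, rng):
        """Major-allele polarization makes raw nSL invariant to a global 0/1
        relabeling, except at exact 50/50 ties where only the magnitude is
        defined (orientation is a tie-break)."""
        a = rng.integers(0, 2, size=(16, 30)).astype(np.int8)
        cfg = ScanConfig(maf_floor=0.0, min_bin_count=1)
        t1 = nsl_scan(make_hs(a), cfg)
        t2 = nsl_scan(make_hs(1 - a), cfg)
        tied = a.mean(axis=0) == 0.5
        r1, r2 = t1.data["raw"].to_numpy(), t2.data["raw"].to_numpy()
        assert np.allclose(r1[~tied], r2[~tied], equal_nan=True)
        assert np.allclose(np.abs(r1[tied]), np.abs(r2[tied]), equal_nan=True)

    def test_standardized_bins_mean_zero_sd_one(self, null_scan_suite):
        stds = [rep["tracks"]["NSL"].data["std"] for rep in null_scan_suite]
        s = pd.concat(stds).dropna()
        assert abs(s.mean()) < 0.15
        assert 0.8 < s.std() < 1.2


# ---------------------------------------------------------------------------
# XPCLR
# ---------------------------------------------------------------------------

class TestXPCLR:
    def test_identical_populations_score_near_zero(self, rng):
        """When objective frequencies equal reference frequencies the sweep
        model cannot beat neutral drift: scores ~ 0 everywhere."""
        a = rng.integers(0, 2, size=(60, 40)).astype(np.int8)
        hs = make_hs(a, cm=np.linspace(0, 20, 40))
        track = xpclr_scan(hs, hs, rng=np.random.default_rng(0))
        s = track.scores()
        assert np.nanmax(s) < 1.0
        assert np.nanmedian(s) < 0.1

    def test_neutral_null_top_scores_not_localized(self, null_scan_suite):
        """On neutral splits the locations of the top XPCLR scores are
        uniform along the chromosome (KS test)."""
        pos = []
        for rep in null_scan_suite:
            d = rep["tracks"]["XPCLR"].data
            ok = d[np.isfinite(d["score"])]
            thr = ok["score"].quantile(0.90)
            pos.extend(ok.loc[ok["score"] > thr, "pos_cM"] / 100.0)
        assert len(pos) > 50
        assert kstest(pos, "uniform").pvalue > 0.005

    def test_empty_window_reported_missing(self, rng):
        a = rng.integers(0, 2, size=(40, 6)).astype(np.int8)
        cm = np.array([0.0, 0.1, 0.2, 30.0, 30.1, 30.2])
        hs = make_hs(a, cm=cm)
        track = xpclr_scan(hs, make_hs(rng.integers(0, 2, size=(40, 6)),
                                       cm=cm),
                           rng=np.random.default_rng(0))
        mid = track.data[(track.data["pos_cM"] > 5)
                         & (track.data["pos_cM"] < 25)]
        assert mid["score"].isna().all()
        assert (mid["n_snps"] == 0).all()

    def test_pruning_and_cap_bound_snp_count(self, rng):
        a = rng.integers(0, 2, size=(60, 300)).astype(np.int8)
        hs1 = make_hs(a, cm=np.linspace(0, 3, 300))
        b = a.copy()
        flip = rng.random(b.shape) < 0.05
        b[flip] = 1 - b[flip]
        hs2 = make_hs(b, cm=np.linspace(0, 3, 300))
        track = xpclr_scan(hs2, hs1, cfg=ScanConfig(xpclr_max_snps=50),
                           rng=np.random.default_rng(1))
        assert track.data["n_snps"].max() <= 50
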
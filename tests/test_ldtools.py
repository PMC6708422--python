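import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from polysweep.dataio import MISSING, SweepTable
from polysweep.ldtools import (DEFAULT_BACKGROUND_R2, LDConfig,
                               background_ld_percentile, inbred_haplotypes,
                               interregion_ld, ld_cluster, ld_decay_curve, r2)
from test_sweepstats import make_hs
from test_sweepcall import region_row


class TestR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 0, 1, 1, 0])
        assert r2(v, v) == pytest.approx(1.0)

    def test_hill_robertson_counts_example(self):
        """Haplotype counts (AB, Ab, aB, ab) = (40, 10, 10, 40):
        D = 0.4 - 0.25 = 0.15, r2 = 0.15^2 / 0.0625 = 0.36."""
        a = np.array([1] * 40 + [1] * 10 + [0] * 10 + [0] * 40)
        b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        assert r2(a, b) == pytest.approx(0.36)

    def test_independent_loci(self):
        a = np.array([1] * 25 + [1] * 25 + [0] * 25 + [0] * 25)
        b = np.array([1] * 25 + [0] * 25 + [1] * 25 + [0] * 25)
        assert r2(a, b) == pytest.approx(0.0)

    def test_monomorphic_missing(self):
        assert np.isnan(r2(np.zeros(10), np.arange(10) % 2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            r2(np.zeros(3), np.zeros(4))

    def test_exhaustive_four_haplotype_configurations(self):
        """Agreement with the 2x2 contingency oracle on every pair of binary
        vectors of length 4 (256 configurations) and on configurations with
        missing entries."""
        vecs = list(itertools.product([0, 1], repeat=4))
        for a in vecs:
            for b in vecs:
                got = r2(np.array(a), np.array(b))
                want = oracles.contingency_r2(np.array(a), np.array(b))
                assert (np.isnan(got) and np.isnan(want)) or \
                    got == pytest.approx(want)
        # missing entries dropped pairwise
        a = np.array([1, 0, MISSING, 1, 0, 1], float)
        b = np.array([1, 0, 1, MISSING, 0, 1], float)
        got = r2(a, b)
        want = oracles.contingency_r2(
            np.array([1, 0, 0, 1]), np.array([1, 0, 0, 1]))
        assert got == pytest.approx(want)

    @given(a=st.lists(st.integers(0, 1), min_size=4, max_size=40),
           data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_symmetry_relabel_and_bounds(self, a, data):
        b = data.draw(st.lists(st.integers(0, 1), min_size=len(a),
                               max_size=len(a)))
        a, b = np.array(a), np.array(b)
        v = r2(a, b)
        if np.isnan(v):
            assert a.std() == 0 or b.std() == 0
            return
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(r2(b, a))
        assert v == pytest.approx(r2(1 - a, b))
        assert v == pytest.approx(r2(a, 1 - b))


class TestDecayCurve:
    def test_three_loci_pair_enumeration(self, rng):
        a = rng.integers(0, 2, size=(40, 3)).astype(np.int8)
        hs = make_hs(a, cm=[0.0, 0.6, 2.5])
        curve = ld_decay_curve(hs, bin_width_cm=1.0, max_cm=5.0)
        # pairs at distances 0.6, 1.9, 2.5 -> bins 0, 1, 2
        assert curve["n_pairs"].tolist()[:3] == [1, 1, 1]
        assert curve["n_pairs"].sum() == 3
        assert (curve["mean_r2"].dropna() >= 0).all()

    def test_no_mapped_pairs_error(self, rng):
        a = rng.integers(0, 2, size=(10, 1)).astype(np.int8)
        with pytest.raises(ValueError, match="pairs"):
            ld_decay_curve(make_hs(a))

    def test_selfing_raises_short_range_ld(self):
        """A high-selfing population keeps more LD at ~1 cM than a
        random-mating population of the same size (medians over replicates)."""
        from polysweep.scenario import simulate_ld_curve
        from polysweep.popsim import SimParams

        base = dict(N=100, mu=5e-4, lambda_xo=1.0, n_chrom=1, n_loci=800)
        selfing, outcross = [], []
        for seed in (1, 2, 3):
            c1 = simulate_ld_curve(SimParams(s_out=0.033, **base), 150,
                                   seed=seed, bin_width_cm=2.0)
            c2 = simulate_ld_curve(SimParams(s_out=1.0, **base), 150,
                                   seed=seed, bin_width_cm=2.0)
            selfing.append(c1["mean_r2"].iloc[0])
            outcross.append(c2["mean_r2"].iloc[0])
        assert np.median(selfing) > np.median(outcross)


class TestBackgroundLD:
    def test_default_constant_without_panel(self):
        assert background_ld_percentile(None) == DEFAULT_BACKGROUND_R2 == 0.161

    def test_default_constant_only_at_99(self):
        with pytest.raises(ValueError):
            background_ld_percentile(None, q=0.95)

    def test_independent_loci_percentile_near_null(self, rng):
        """With independent loci the 99th percentile of inter-chromosomal r2
        is of order chi2_1(0.99)/n_haplotypes."""
        a = rng.integers(0, 2, size=(400, 120)).astype(np.int8)
        loci = pd.DataFrame({"locus": [f"l{i}" for i in range(120)],
                             "chrom": ["1A"] * 60 + ["2B"] * 60,
                             "cM": list(np.arange(60.0)) * 2,
                             "bp": list(np.arange(1, 61) * 10 ** 6) * 2})
        from polysweep.dataio import HaplotypeSet
        hs = HaplotypeSet([f"s{i}" for i in range(200)], loci, a, 1)
        p99 = background_ld_percentile(hs, n_pairs=20_000, rng=7)
        assert 0.005 < p99 < 0.06  # ~6.6/400 with sampling slack

    def test_single_chromosome_rejected(self, rng):
        a = rng.integers(0, 2, size=(20, 10)).astype(np.int8)
        with pytest.raises(ValueError, match="chromosome"):
            background_ld_percentile(make_hs(a))

    def test_deterministic_under_seed(self, rng):
        a = rng.integers(0, 2, size=(100, 80)).astype(np.int8)
        loci_chrom = ["1A"] * 40 + ["2B"] * 40
        from polysweep.dataio import HaplotypeSet
        loci = pd.DataFrame({"locus": [f"l{i}" for i in range(80)],
                             "chrom": loci_chrom,
                             "cM": list(np.arange(40.0)) * 2,
                             "bp": list(np.arange(1, 41) * 10 ** 6) * 2})
        hs = HaplotypeSet([f"s{i}" for i in range(50)], loci, a, 1)
        assert background_ld_percentile(hs, n_pairs=5000, rng=11) == \
            background_ld_percentile(hs, n_pairs=5000, rng=11)


def _two_region_hs(rng, n_linked_x=4, n_x=6, n_linked_y=3, n_y=5):
    """Homozygous individuals; regions on different chromosomes where
    n_linked SNPs per region copy a shared pattern v and the rest are
    independent noise."""
    n_ind = 40
    v = np.array([0] * 20 + [1] * 20, dtype=np.int8)
    cols = []
    for i in range(n_x):
        cols.append(v if i < n_linked_x else
                    rng.permutation(v))
    for i in range(n_y):
        cols.append(v if i < n_linked_y else rng.permutation(v))
    g = np.stack(cols, axis=1)  # (40, nx+ny) genotypes
    a = np.repeat(g, 2, axis=0).reshape(n_ind, 2, -1).reshape(2 * n_ind, -1)
    loci = pd.DataFrame({
        "locus": [f"l{i}" for i in range(n_x + n_y)],
        "chrom": ["1A"] * n_x + ["2B"] * n_y,
        "cM": list(np.arange(float(n_x))) + list(np.arange(float(n_y))),
        "bp": list((np.arange(n_x) + 1) * 10 ** 6)
        + list((np.arange(n_y) + 1) * 10 ** 6)})
    from polysweep.dataio import HaplotypeSet
    return HaplotypeSet([f"s{i}" for i in range(n_ind)], loci, a, 1)


class TestInterregionLD:
    def test_full_ld_in_ld_with_max_one(self, rng):
        hs = _two_region_hs(rng, n_linked_x=6, n_x=6, n_linked_y=5, n_y=5)
        res = interregion_ld(np.arange(6), np.arange(6, 11), hs,
                             LDConfig())
        assert res.in_ld and res.max_r2 == pytest.approx(1.0)

    def test_no_ld_not_in_ld(self, rng):
        hs = _two_region_hs(rng, n_linked_x=0, n_x=6, n_linked_y=0, n_y=5)
        res = interregion_ld(np.arange(6), np.arange(6, 11), hs, LDConfig())
        assert not res.in_ld

    def test_strict_majority_rule(self, rng):
        """4/6 and 3/5 SNPs above threshold -> in LD; 3/6 on one side is not
        a strict majority -> not in LD."""
        hs = _two_region_hs(rng, n_linked_x=4, n_x=6, n_linked_y=3, n_y=5)
        res = interregion_ld(np.arange(6), np.arange(6, 11), hs, LDConfig())
        assert res.majority_x and res.majority_y and res.in_ld
        hs2 = _two_region_hs(rng, n_linked_x=3, n_x=6, n_linked_y=3, n_y=5)
        res2 = interregion_ld(np.arange(6), np.arange(6, 11), hs2, LDConfig())
        assert not res2.majority_x
        assert not res2.in_ld

    def test_min_snp_eligibility(self, rng):
        hs = _two_region_hs(rng)
        res = interregion_ld(np.arange(4), np.arange(6, 11), hs, LDConfig())
        assert not res.eligible and not res.in_ld

    def test_verdict_invariant_to_snp_order(self, rng):
        hs = _two_region_hs(rng, n_linked_x=4, n_x=6, n_linked_y=3, n_y=5)
        ref = interregion_ld(np.arange(6), np.arange(6, 11), hs, LDConfig())
        perm = rng.permutation(6)
        res = interregion_ld(perm, np.arange(6, 11)[rng.permutation(5)], hs,
                             LDConfig())
        assert res.in_ld == ref.in_ld
        assert res.max_r2 == pytest.approx(ref.max_r2)

    def test_inbred_haplotypes_drop_het_calls(self):
        a = np.array([[0, 1], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        hs = make_hs(a)
        h = inbred_haplotypes(hs)
        assert h[0, 0] == 0 and np.isnan(h[0, 1])
        assert h[1, 0] == 1 and h[1, 1] == 1


class TestLDCluster:
    def _three_region_hs(self, rng, linked=True):
        n_ind = 40
        v = np.array([0] * 20 + [1] * 20, dtype=np.int8)
        cols = []
        for c in range(3):
            for i in range(5):
                cols.append(v if linked else rng.permutation(v))
        g = np.stack(cols, axis=1)
        a = np.repeat(g, 2, axis=0).reshape(n_ind, 2, -1).reshape(2 * n_ind, -1)
        loci = pd.DataFrame({
            "locus": [f"l{i}" for i in range(15)],
            "chrom": ["1A"] * 5 + ["2B"] * 5 + ["3D"] * 5,
            "cM": list(np.arange(5.0)) * 3,
            "bp": list((np.arange(5) + 1) * 10 ** 6) * 3})
        from polysweep.dataio import HaplotypeSet
        hs = HaplotypeSet([f"s{i}" for i in range(n_ind)], loci, a, 1)
        rows = pd.concat([region_row("1A", 0, 4, {"P"}, {"FST"}),
                          region_row("2B", 0, 4, {"P"}, {"FST"}),
                          region_row("3D", 0, 4, {"P"}, {"FST"})],
                         ignore_index=True)
        return hs, SweepTable(rows)

    def test_clique_single_component(self, rng):
        hs, sweeps = self._three_region_hs(rng, linked=True)
        out = ld_cluster(sweeps, hs, LDConfig())
        assert len(out["components"]) == 1
        assert len(out["components"][0]) == 3
        assert out["component_mean_r2"][0] == pytest.approx(1.0)

    def test_no_ld_all_singletons(self, rng):
        hs, sweeps = self._three_region_hs(rng, linked=False)
        out = ld_cluster(sweeps, hs, LDConfig())
        assert all(len(c) == 1 for c in out["components"])
        assert not out["pairs"]["in_ld"].any()
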
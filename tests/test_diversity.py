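"""Allele frequencies, windowed pi / D_XY / Hudson F_ST, folded SFS."""

import numpy as np
import pytest

from admixscan import allele_freqs, folded_sfs, windowed_diversity
from admixscan.diversity import dxy_self_check

from conftest import popmap_for, toy_matrix


class TestAlleleFreqs:
    def test_alt_frequency_simple(self):
        gm = toy_matrix([[0, 1, 2]])
        pm = popmap_for(gm, ["p"] * 3)
        f = allele_freqs(gm, pm)
        assert f.alt_freq[f.pop_index("p"), 0] == pytest.approx(0.5)

    def test_polarization_flips_when_outgroup_fixed_alt(self):
        # outgroup fixed alt => ancestral is alt => derived freq = 1 - alt freq
        gm = toy_matrix([[2, 2, 2, 1, 2, 2, 1, 2]])
        pm = popmap_for(gm, ["out"] * 3 + ["hyb"] * 5)
        f = allele_freqs(gm, pm, outgroup="out")
        assert f.polarized[0]
        assert f.alt_freq[f.pop_index("hyb"), 0] == pytest.approx(0.8)
        assert f.derived_freq[f.pop_index("hyb"), 0] == pytest.approx(0.2)

    def test_polymorphic_outgroup_flagged_unpolarized(self):
        gm = toy_matrix([[1, 1, 1, 0, 1, 2]])
        pm = popmap_for(gm, ["out"] * 3 + ["p"] * 3)
        f = allele_freqs(gm, pm, outgroup="out")
        assert not f.polarized[0]
        assert np.isnan(f.derived_freq[f.pop_index("p"), 0])

    def test_matches_per_site_counting_oracle(self):
        rng = np.random.default_rng(2)
        g = rng.integers(-1, 3, size=(50, 12))
        gm = toy_matrix(g)
        pm = popmap_for(gm, ["a"] * 6 + ["b"] * 6)
        f = allele_freqs(gm, pm)
        for pi, cols in (("a", range(6)), ("b", range(6, 12))):
            for s in range(50):
                obs = [g[s, c] for c in cols if g[s, c] >= 0]
                want = sum(obs) / (2 * len(obs)) if obs else np.nan
                got = f.alt_freq[f.pop_index(pi), s]
                assert got == pytest.approx(want, nan_ok=True, abs=1e-12)

    def test_unknown_population_raises(self):
        gm = toy_matrix([[0, 1]])
        pm = popmap_for(gm, ["a", "a"])
        with pytest.raises(KeyError):
            allele_freqs(gm, pm, populations=["missing"])


class TestWindowedDiversity:
    def test_pi_two_haplotypes(self):
        # one diploid sample (2 haplotypes) heterozygous at 3 sites in a 10-bp window
        gm = toy_matrix([[1], [1], [1]], pos=[2, 5, 9])
        pm = popmap_for(gm, ["p"])
        win = windowed_diversity(gm, pm, window_bp=10, chrom_lengths={"chr1": 10})
        assert win["pi_p"].iloc[0] == pytest.approx(0.3)

    def test_fst_one_at_fixed_differences(self):
        gm = toy_matrix([[0, 0, 2, 2], [0, 0, 2, 2]])
        pm = popmap_for(gm, ["a", "a", "b", "b"])
        win = windowed_diversity(gm, pm, window_bp=100, chrom_lengths={"chr1": 100})
        assert win["fst_a__b"].iloc[0] == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        hap = rng.integers(0, 2, size=(30, 8, 2))
        g = hap.sum(axis=2)
        gm = toy_matrix(g, pos=np.arange(1, 31), haplotypes=hap)
        pm = popmap_for(gm, ["a"] * 4 + ["b"] * 4)
        win = windowed_diversity(gm, pm, window_bp=1000, chrom_lengths={"chr1": 1000})
        flat = hap.reshape(30, 16)
        a, b = flat[:, :8], flat[:, 8:]

        def pi_pairs(mat):
            tot = 0
            n = mat.shape[1]
            for i in range(n):
                for j in range(i + 1, n):
                    tot += (mat[:, i] != mat[:, j]).sum()
            return tot / (n * (n - 1) / 2) / 1000

        def dxy_pairs(x, y):
            tot = sum(
                (x[:, i] != y[:, j]).sum() for i in range(x.shape[1]) for j in range(y.shape[1])
            )
            return tot / (x.shape[1] * y.shape[1]) / 1000

        assert win["pi_a"].iloc[0] == pytest.approx(pi_pairs(a), abs=1e-9)
        assert win["pi_b"].iloc[0] == pytest.approx(pi_pairs(b), abs=1e-9)
        assert win["dxy_a__b"].iloc[0] == pytest.approx(dxy_pairs(a, b), abs=1e-9)
        # Hudson ratio of sums from per-site components
        num = den = 0.0
        for s in range(30):
            p1, p2 = a[s].mean(), b[s].mean()
            n1, n2 = 8, 8
            num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den += p1 * (1 - p2) + p2 * (1 - p1)
        assert win["fst_a__b"].iloc[0] == pytest.approx(num / den, abs=1e-9)

    def test_dxy_of_population_with_itself_equals_pi(self):
        rng = np.random.default_rng(5)
        gm = toy_matrix(rng.integers(0, 3, size=(40, 6)))
        pm = popmap_for(gm, ["p"] * 6)
        pi, dxy = dxy_self_check(gm, pm, "p")
        assert pi == pytest.approx(dxy, abs=1e-12)

    def test_windows_tile_chromosome_exactly(self, small_cohort):
        gm, pm, _ = small_cohort
        win = windowed_diversity(gm, pm, populations=["donorA"], chrom_lengths={"chr10": 5_000_000})
        assert (win["end"] - win["start"]).sum() == 5_000_000
        assert (win["start"].to_numpy()[1:] == win["end"].to_numpy()[:-1]).all()

    def test_empty_windows_carry_zeros(self):
        gm = toy_matrix([[0, 1]], pos=[25_000])
        pm = popmap_for(gm, ["p", "p"])
        win = windowed_diversity(gm, pm, window_bp=10_000, chrom_lengths={"chr1": 30_000})
        assert win["n_snps"].tolist() == [0, 0, 1]
        assert win["pi_p"].iloc[0] == 0.0

    def test_fst_never_exceeds_one(self, small_cohort):
        gm, pm, _ = small_cohort
        win = windowed_diversity(gm, pm, populations=["donorA", "donorB"])
        assert (win["fst_donorA__donorB"] <= 1 + 1e-12).all()


class TestFoldedSfs:
    def test_singletons_fill_first_bin(self):
        # n = 4 haplotypes, each SNP a singleton
        gm = toy_matrix([[1, 0], [0, 1], [1, 0]])
        pm = popmap_for(gm, ["p", "p"])
        rec = folded_sfs(gm, pm, "p")
        assert rec.counts.tolist() == [3, 0]

    def test_midpoint_fold(self):
        gm = toy_matrix([[1, 1]])  # 2/2 in n=4
        pm = popmap_for(gm, ["p", "p"])
        rec = folded_sfs(gm, pm, "p")
        assert rec.counts.tolist() == [0, 1]

    def test_total_equals_segregating_sites(self, small_cohort):
        gm, pm, _ = small_cohort
        rec = folded_sfs(gm, pm, "donorA")
        idx = pm.indices(gm, "donorA")
        g = gm.genotypes[:, idx]
        alt = g.sum(axis=1)
        seg = ((alt > 0) & (alt < 2 * len(idx))).sum()
        assert rec.counts.sum() == seg

    def test_requires_two_samples(self):
        gm = toy_matrix([[1]])
        pm = popmap_for(gm, ["p"])
        with pytest.raises(ValueError):
            folded_sfs(gm, pm, "p")
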
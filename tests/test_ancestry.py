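"""Supervised admixture, local-ancestry HMM posteriors, ADD score."""

import itertools

import numpy as np
import pytest

from admixscan import (
    HmmConfig,
    add_quantile_mask,
    ancestry_dosage_hmm,
    supervised_admixture,
)
from admixscan.ancestry import DosageTrack

from conftest import popmap_for, toy_matrix


def _panel_matrix(freqA, freqB, hybrid_geno, hybrid_hap=None, nA=6, nB=6):
    """Donor panels with genotypes engineered to hit target frequencies."""
    rows = []
    hap_rows = [] if hybrid_hap is not None else None
    n_sites = len(freqA)
    for s in range(n_sites):
        cA = int(round(freqA[s] * 2 * nA))
        cB = int(round(freqB[s] * 2 * nB))
        gA = [2] * (cA // 2) + [1] * (cA % 2)
        gA += [0] * (nA - len(gA))
        gB = [2] * (cB // 2) + [1] * (cB % 2)
        gB += [0] * (nB - len(gB))
        rows.append(gA + gB + list(hybrid_geno[s]))
        if hap_rows is not None:
            donor_haps = [[1, 1]] * (cA // 2) + [[1, 0]] * (cA % 2)
            donor_haps += [[0, 0]] * (nA - len(donor_haps))
            donor_hapsB = [[1, 1]] * (cB // 2) + [[1, 0]] * (cB % 2)
            donor_hapsB += [[0, 0]] * (nB - len(donor_hapsB))
            hap_rows.append(donor_haps + donor_hapsB + list(hybrid_hap[s]))
    g = np.array(rows)
    hap = np.array(hap_rows) if hap_rows is not None else None
    gm = toy_matrix(g, pos=[1000 * (i + 1) for i in range(n_sites)], haplotypes=hap)
    pm = popmap_for(gm, ["A"] * nA + ["B"] * nB + ["H"] * (g.shape[1] - nA - nB))
    return gm, pm


class TestSupervisedAdmixture:
    def test_exact_mixture_recovers_half_half(self):
        # complementary panel frequencies on the realizable count grid, so the
        # all-heterozygous sample is exactly the alpha = 0.5 mixture
        rng = np.random.default_rng(0)
        fA = rng.integers(5, 46, 200) / 50.0  # multiples of 1/(2 * nA)
        fB = 1.0 - fA
        hyb = np.ones((200, 1), dtype=int)  # dosage 1 = 2 * (fA + fB) / 2
        gm, pm = _panel_matrix(fA, fB, hyb, nA=25, nB=25)
        props = supervised_admixture(gm, pm, ["A", "B"], samples=pm.samples("H"))
        assert props.iloc[0]["A"] == pytest.approx(0.5, abs=1e-4)

    def test_pure_donor_sample_assigned_to_its_panel(self, small_cohort):
        gm, pm, _ = small_cohort
        target = pm.samples("donorA")[:3]
        props = supervised_admixture(gm, pm, ["donorA", "donorB"], samples=target)
        assert (props["donorA"] >= 0.95).all()

    def test_proportions_form_a_simplex(self, small_cohort):
        gm, pm, _ = small_cohort
        props = supervised_admixture(gm, pm, ["donorA", "donorB"], samples=pm.samples("hybrid_north"))
        vals = props.to_numpy()
        assert np.all(vals >= -1e-9) and np.all(vals <= 1 + 1e-9)
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)

    def test_monomorphic_panels_rejected(self):
        g = np.zeros((10, 13), dtype=int)
        gm = toy_matrix(g)
        pm = popmap_for(gm, ["A"] * 6 + ["B"] * 6 + ["H"])
        with pytest.raises(ValueError):
            supervised_admixture(gm, pm, ["A", "B"], samples=["s12"])


def _hmm_posterior_oracle_phased(alleles, pos, pA, pB, cfg):
    """Exhaustive path enumeration for one haplotype chain."""
    eps = cfg.epsilon
    qA = (1 - eps) * pA + eps * (1 - pA)
    qB = (1 - eps) * pB + eps * (1 - pB)
    q = {0: qA, 1: qB}
    pi = {0: cfg.prior_a, 1: 1 - cfg.prior_a}
    n = len(alleles)
    gaps = np.diff(pos)
    t = 1 - np.exp(-cfg.generations * cfg.recomb_rate_per_bp * gaps)

    def trans(g, i, j):
        stay = 1 - t[g] + t[g] * pi[i]
        return stay if i == j else t[g] * pi[j]

    post = np.zeros((n, 2))
    for path in itertools.product([0, 1], repeat=n):
        p = pi[path[0]]
        for s in range(n):
            e = q[path[s]][s] if alleles[s] == 1 else 1 - q[path[s]][s]
            p *= e
            if s < n - 1:
                p *= trans(s, path[s], path[s + 1])
        for s in range(n):
            post[s, path[s]] += p
    return post[:, 1] / post.sum(axis=1)


def _hmm_posterior_oracle_unphased(geno, pos, pA, pB, cfg):
    """Exhaustive enumeration over joint two-haplotype state paths."""
    eps = cfg.epsilon
    qA = (1 - eps) * pA + eps * (1 - pA)
    qB = (1 - eps) * pB + eps * (1 - pB)
    q = {0: qA, 1: qB}
    pi = {0: cfg.prior_a, 1: 1 - cfg.prior_a}
    n = len(geno)
    gaps = np.diff(pos)
    t = 1 - np.exp(-cfg.generations * cfg.recomb_rate_per_bp * gaps)

    def trans(g, i, j):
        stay = 1 - t[g] + t[g] * pi[i]
        return stay if i == j else t[g] * pi[j]

    dosage = np.zeros(n)
    total = 0.0
    paths = list(itertools.product([0, 1], repeat=n))
    contrib = np.zeros((len(paths), len(paths)))
    for i1, path1 in enumerate(paths):
        for i2, path2 in enumerate(paths):
            p = pi[path1[0]] * pi[path2[0]]
            for s in range(n):
                q1, q2 = q[path1[s]][s], q[path2[s]][s]
                g = geno[s]
                e = {
                    0: (1 - q1) * (1 - q2),
                    1: q1 * (1 - q2) + (1 - q1) * q2,
                    2: q1 * q2,
                }[g]
                p *= e
                if s < n - 1:
                    p *= trans(s, path1[s], path1[s + 1]) * trans(s, path2[s], path2[s + 1])
            contrib[i1, i2] = p
    total = contrib.sum()
    for i1, path1 in enumerate(paths):
        for i2, path2 in enumerate(paths):
            for s in range(n):
                dosage[s] += contrib[i1, i2] * (path1[s] + path2[s]) / 2
    return dosage / total


class TestAncestryHmm:
    CFG = HmmConfig("A", "B", generations=100, recomb_rate_per_bp=4e-8, epsilon=0.05, prior_a=0.4)

    def _freqs(self, gm, pm, pop):
        idx = pm.indices(gm, pop)
        g = gm.genotypes[:, idx]
        return (g.sum(axis=1) + 0.5) / (2 * g.shape[1] + 1.0)

    def test_fully_informative_limit(self):
        n = 12
        fA = np.zeros(n)
        fB = np.ones(n)
        hyb_hap = [[[1, 1]]] * n
        hyb_g = [[2]] * n
        gm, pm = _panel_matrix(fA, fB, hyb_g, hyb_hap, nA=10, nB=10)
        cfg = HmmConfig("A", "B", epsilon=0.01)
        track = ancestry_dosage_hmm(gm, pm, cfg, "H")
        assert (track.dosage_b >= 0.99).all()

    def test_phased_posteriors_match_enumeration(self):
        fA = np.array([0.9, 0.2, 0.7])
        fB = np.array([0.1, 0.8, 0.3])
        hyb_hap = [[[1, 0]], [[0, 1]], [[1, 1]]]
        hyb_g = [[1], [1], [2]]
        gm, pm = _panel_matrix(fA, fB, hyb_g, hyb_hap, nA=5, nB=5)
        track = ancestry_dosage_hmm(gm, pm, self.CFG, "H")
        pA = self._freqs(gm, pm, "A")
        pB = self._freqs(gm, pm, "B")
        pos = gm.pos
        want_h1 = _hmm_posterior_oracle_phased([1, 0, 1], pos, pA, pB, self.CFG)
        want_h2 = _hmm_posterior_oracle_phased([0, 1, 1], pos, pA, pB, self.CFG)
        np.testing.assert_allclose(track.dosage_b[:, 0], (want_h1 + want_h2) / 2, atol=1e-9)

    def test_unphased_posteriors_match_enumeration(self):
        fA = np.array([0.9, 0.2, 0.7])
        fB = np.array([0.1, 0.8, 0.3])
        hyb_g = [[1], [1], [2]]
        gm, pm = _panel_matrix(fA, fB, hyb_g, nA=5, nB=5)  # no haplotypes: unphased path
        track = ancestry_dosage_hmm(gm, pm, self.CFG, "H")
        pA = self._freqs(gm, pm, "A")
        pB = self._freqs(gm, pm, "B")
        want = _hmm_posterior_oracle_unphased([1, 1, 2], gm.pos, pA, pB, self.CFG)
        np.testing.assert_allclose(track.dosage_b[:, 0], want, atol=1e-9)

    def test_dosages_lie_in_unit_interval_and_sum_to_one(self, small_cohort):
        gm, pm, _ = small_cohort
        track = ancestry_dosage_hmm(gm, pm, HmmConfig("donorA", "donorB"), "hybrid_north")
        assert np.all(track.dosage_b >= -1e-9) and np.all(track.dosage_b <= 1 + 1e-9)
        np.testing.assert_allclose(track.dosage_a + track.dosage_b, 1.0, atol=1e-9)

    def test_recovers_true_dosages_and_tract(self, default_cohort):
        gm, pm, truth = default_cohort
        track = ancestry_dosage_hmm(gm, pm, HmmConfig("donorA", "donorB"), "hybrid_north")
        err = np.abs(track.dosage_b - truth.hybrid_dosage_b["hybrid_north"].T)
        assert err.mean() <= 0.1
        tract = (track.pos > truth.tract[0]) & (track.pos <= truth.tract[1])
        assert track.mean_dosage_b[tract].mean() >= 0.9

    def test_add_invariant_to_donor_relabeling(self, small_cohort):
        gm, pm, _ = small_cohort
        fwd = ancestry_dosage_hmm(gm, pm, HmmConfig("donorA", "donorB"), "hybrid_north")
        rev = ancestry_dosage_hmm(gm, pm, HmmConfig("donorB", "donorA"), "hybrid_north")
        np.testing.assert_allclose(fwd.add, rev.add, atol=1e-9)

    def test_more_generations_shorten_decoded_segments(self, small_cohort):
        gm, pm, _ = small_cohort
        lengths = []
        for g in (10, 100, 1000):
            track = ancestry_dosage_hmm(
                gm, pm, HmmConfig("donorA", "donorB", generations=g), "hybrid_north"
            )
            states = track.dosage_b > 0.5
            runs = []
            for col in states.T:
                switch = np.flatnonzero(np.diff(col.astype(int)) != 0)
                runs.append(len(switch) + 1)
            lengths.append(gm.n_sites / np.mean(runs))  # mean segment length in sites
        assert lengths[0] >= lengths[1] >= lengths[2]


class TestAddScore:
    def _track(self, dosage_b):
        d = np.asarray(dosage_b, float)
        return DosageTrack(
            chrom=np.array(["chr1"] * d.shape[0], dtype=object),
            pos=np.arange(1, d.shape[0] + 1),
            sample_ids=[f"s{i}" for i in range(d.shape[1])],
            donor_a="A",
            donor_b="B",
            dosage_b=d,
        )

    def test_add_is_absolute_dosage_difference(self):
        track = self._track([[0.1], [0.5]])
        # mean dosage_a = 0.9, 0.5 => ADD = 0.8, 0.0
        np.testing.assert_allclose(track.add, [0.8, 0.0], atol=1e-12)

    def test_quantile_threshold_linear_interpolation(self):
        thr, mask = add_quantile_mask([0, 0, 0, 1], q=0.75)
        assert thr == pytest.approx(0.25)
        assert mask.tolist() == [False, False, False, True]

    def test_constant_add_masks_everything(self):
        thr, mask = add_quantile_mask([0.3, 0.3, 0.3], q=0.75)
        assert thr == pytest.approx(0.3) and mask.all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            add_quantile_mask([])
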
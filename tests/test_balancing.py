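"""Folded-beta scores, shared-site intersection, bins, beta x ADD classification."""

import numpy as np
import pandas as pd
import pytest

from admixscan import beta_add_classify, beta_scores, bs_bins, shared_bs_sites
from admixscan.ancestry import DosageTrack

from conftest import popmap_for, toy_matrix


def _beta_oracle(gm, pm, pop, minfreq=0.1, halfwidth=1000, maxdiff=0.15):
    """Direct per-core computation of the folded beta score."""
    idx = pm.indices(gm, pop)
    g = gm.genotypes[:, idx]
    tot = 2 * (g >= 0).sum(axis=1)
    alt = np.where(g > 0, g, 0).sum(axis=1)
    minor = np.minimum(alt, tot - alt)
    seg = (minor > 0) & (tot >= 4)
    pos = gm.pos[seg]
    f = minor[seg] / tot[seg]
    n = tot[seg]
    a_n = np.sum(1.0 / np.arange(1, int(round(n.mean()))))
    span = gm.pos.max() - gm.pos.min() + 1
    theta_null = seg.sum() / (a_n * span) * 2 * halfwidth

    out = {}
    for i in range(len(pos)):
        if f[i] < minfreq:
            continue
        wsum = 0.0
        for j in range(len(pos)):
            if j == i or abs(pos[j] - pos[i]) > halfwidth:
                continue
            wsum += max(0.0, 1 - abs(f[j] - f[i]) / maxdiff)
        ni = int(n[i])
        c = 0.0
        for k in range(1, ni // 2 + 1):
            w = max(0.0, 1 - abs(k / ni - f[i]) / maxdiff)
            gk = (1 / k + 1 / (ni - k)) / (2.0 if 2 * k == ni else 1.0)
            c += w * gk
        out[int(pos[i])] = wsum / c - theta_null
    return out


class TestBetaScores:
    def test_isolated_core_scores_negative(self):
        # intermediate-frequency sites spaced far beyond the halfwidth
        g = [[1, 1, 0, 2, 1, 0, 1, 2]] * 5
        gm = toy_matrix(g, pos=[1, 5000, 10_000, 15_000, 20_000])
        pm = popmap_for(gm, ["p"] * 8)
        tab = beta_scores(gm, pm, "p", halfwidth_bp=1000)
        assert (tab["n_flank"] == 0).all()
        assert (tab["beta"] < 0).all()

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(10, 10))
        gm = toy_matrix(g, pos=np.array([10, 200, 350, 500, 640, 800, 950, 1100, 1900, 2500]))
        pm = popmap_for(gm, ["p"] * 10)
        tab = beta_scores(gm, pm, "p")
        want = _beta_oracle(gm, pm, "p")
        assert set(tab["pos"]) == set(want)
        for _, row in tab.iterrows():
            assert row["beta"] == pytest.approx(want[row["pos"]], abs=1e-9)

    def test_invariant_to_allele_label_flips(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(30, 10))
        gm = toy_matrix(g, pos=np.arange(30) * 100 + 1)
        flipped = toy_matrix(2 - g, pos=np.arange(30) * 100 + 1)
        pm = popmap_for(gm, ["p"] * 10)
        a = beta_scores(gm, pm, "p")
        b = beta_scores(flipped, pm, "p")
        np.testing.assert_allclose(a["beta"], b["beta"], atol=1e-12)

    def test_small_population_rejected(self):
        gm = toy_matrix([[0, 1]])
        pm = popmap_for(gm, ["p", "p"])  # 4 haplotypes is the minimum
        beta_scores(gm, pm, "p")
        gm1 = toy_matrix([[1]])
        with pytest.raises(ValueError):
            beta_scores(gm1, popmap_for(gm1, ["p"]), "p")

    def test_planted_clusters_reach_top_percentile(self, default_cohort):
        gm, pm, truth = default_cohort
        tab = beta_scores(gm, pm, "donorA")
        cut = tab["beta"].quantile(0.99)
        planted = tab[tab["pos"].isin(truth.bs_positions)]
        assert (planted["beta"] > cut).mean() > 0.6


def _table(chrom_pos_q):
    return pd.DataFrame(chrom_pos_q, columns=["chrom", "pos", "q"]).assign(
        f_core=0.4, beta=1.0, p=lambda d: d["q"]
    )


class TestSharedSites:
    def test_identical_tables_intersect_to_their_set(self):
        t = _table([("c", 1, 0.001), ("c", 2, 0.5), ("c", 3, 0.004)])
        shared, counts = shared_bs_sites({"a": t, "b": t.copy()}, fdr=0.01)
        assert shared == [("c", 1), ("c", 3)]
        assert counts == {"a": 2, "b": 2, "shared": 2}

    def test_toy_set_algebra(self):
        rows = lambda sig: _table([("c", p, 0.001 if p in sig else 0.9) for p in (1, 2, 3, 4)])
        tabs = {"x": rows({1, 2, 3}), "y": rows({2, 3, 4}), "z": rows({3})}
        shared, _ = shared_bs_sites(tabs, fdr=0.01)
        assert shared == [("c", 3)]

    def test_intersection_monotone_and_order_invariant(self):
        rng = np.random.default_rng(1)
        tabs = {
            f"p{i}": _table([("c", p, float(rng.random() * 0.02)) for p in range(40)])
            for i in range(4)
        }
        keys = list(tabs)
        s3, _ = shared_bs_sites({k: tabs[k] for k in keys[:3]}, fdr=0.01)
        s4, _ = shared_bs_sites(tabs, fdr=0.01)
        s4r, _ = shared_bs_sites({k: tabs[k] for k in reversed(keys)}, fdr=0.01)
        assert set(s4) <= set(s3)
        assert s4 == s4r

    def test_disjoint_universes_rejected(self):
        a = _table([("c", 1, 0.001)])
        b = _table([("c", 99, 0.001)])
        with pytest.raises(ValueError):
            shared_bs_sites({"a": a, "b": b})


class TestBsBins:
    def test_threshold_is_at_least_min_sites(self):
        sites = [("c", 100 + i) for i in range(14)]
        bins, _ = bs_bins(sites, {"c": 20_000}, min_sites=15)
        assert not bins["qualifies"].any()
        bins2, _ = bs_bins(sites + [("c", 200)], {"c": 20_000}, min_sites=15)
        assert bins2["qualifies"].iloc[0]

    def test_binning_arithmetic(self):
        sites = [("c", 100), ("c", 10_050), ("c", 10_051)]
        bins, _ = bs_bins(sites, {"c": 20_000})
        assert bins["n_bs_sites"].tolist() == [1, 2]

    def test_pi_contrast_direction_on_simulation(self, default_cohort):
        from admixscan import windowed_diversity

        gm, pm, truth = default_cohort
        win = windowed_diversity(
            gm, pm, ["donorA", "donorB", "hybrid_north", "hybrid_south"],
            chrom_lengths={"chr10": 5_000_000},
        )
        sites = [("chr10", int(p)) for p in truth.bs_positions]
        bins, summary = bs_bins(sites, {"chr10": 5_000_000}, window_records=win, min_sites=15)
        assert summary["n_qualifying_bins"] >= 4
        assert summary["mean_pi_bs_bins"] > summary["mean_pi_genome"]


class TestClassification:
    def _track(self, add_values, mean_b):
        n = len(add_values)
        # build per-sample dosages realizing the requested mean dosage_b and ADD
        d = np.asarray(mean_b, float)[:, None]
        track = DosageTrack(
            chrom=np.array(["c"] * n, dtype=object),
            pos=np.arange(1, n + 1),
            sample_ids=["s0"],
            donor_a="A",
            donor_b="B",
            dosage_b=d,
        )
        return track

    def test_rule_table(self):
        # sites: ADD = |1 - 2*mean_b|
        mean_b = [0.5, 0.9, 0.1, 0.5]  # ADD = 0, 0.8, 0.8, 0
        track = self._track([0, 0.8, 0.8, 0], mean_b)
        beta = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "pos": [1, 2, 3, 4],
                "beta": [5.0] * 4,
                "q": [0.001, 0.001, 0.001, 0.5],
            }
        )
        out = beta_add_classify(beta, track, fdr=0.01, add_min=0.5)
        assert out["class"].tolist() == [
            "shared-standing",
            "donor-derived-B",
            "donor-derived-A",
            "nonsignificant",
        ]

    def test_missing_add_marked_unscored(self):
        track = self._track([0], [0.5])
        beta = pd.DataFrame(
            {"chrom": ["c"], "pos": [99], "beta": [5.0], "q": [0.001]}  # pos not in track
        )
        out = beta_add_classify(beta, track, fdr=0.01)
        assert out["class"].tolist() == ["unscored"]

    def test_planted_loci_separate_by_origin(self, default_cohort):
        from admixscan import HmmConfig, ancestry_dosage_hmm

        gm, pm, truth = default_cohort
        track = ancestry_dosage_hmm(gm, pm, HmmConfig("donorA", "donorB"), "hybrid_north")
        tab = beta_scores(gm, pm, "hybrid_north")
        out = beta_add_classify(tab, track)
        planted = out[out["pos"].isin(truth.bs_positions) & (out["q"] < 0.01)]
        in_tract = planted[planted["pos"] > truth.tract[0]]
        outside = planted[planted["pos"] <= 4_000_000]
        assert (in_tract["class"] == "donor-derived-donorB").mean() >= 0.9
        assert (outside["class"] == "shared-standing").mean() >= 0.9
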
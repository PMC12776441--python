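"""Site curation, per-position profiles, flank scaling and the Poisson test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phototf.genome import GenomeSequence
from phototf.intervals import GenomicInterval, IntervalSet
from phototf.damage import DamageMap
from phototf.background import ContextRateTable, estimate_context_rates
from phototf.motif import pwm_log_odds_score, pwm_from_consensus
from phototf.profiles import (CurationConfig, build_accessible_regions,
                              curate_active_sites, stratify_by_strength,
                              observed_profile, expected_profile, flank_scale,
                              poisson_position_test, naked_dna_filter,
                              analyze_formation)
from helpers import make_sites


class TestAccessibleRegions:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                           "strand", "signal", "pvalue", "qvalue",
                                           "summit"])

    def test_summit_window_arithmetic(self):
        peaks = self._peaks([("c", 900, 1100, "p", 0, ".", 10.0, 1, 1, 100)])
        out = build_accessible_regions(peaks, top_fraction=1.0)
        iv = next(iter(out))
        assert (iv.start, iv.end) == (925, 1075)

    def test_top_fraction_by_signal(self):
        rows = [("c", 1000 * i, 1000 * i + 200, f"p{i}", 0, ".", float(i), 1, 1, 100)
                for i in range(10)]
        out = build_accessible_regions(self._peaks(rows), top_fraction=0.5)
        assert len(out) == 5
        # the 5 highest-signal peaks are i=5..9
        assert min(iv.start for iv in out) == 5 * 1000 + 100 - 75

    def test_fully_genic_window_removed(self):
        peaks = self._peaks([("c", 900, 1100, "p", 0, ".", 10.0, 1, 1, 100)])
        genic = IntervalSet([GenomicInterval("c", 900, 1100)])
        assert build_accessible_regions(peaks, genic, top_fraction=1.0).is_empty()

    def test_missing_summit_errors(self):
        with pytest.raises(ValueError):
            build_accessible_regions(pd.DataFrame({"chrom": ["c"], "start": [0],
                                                   "end": [10], "signal": [1.0]}))


class TestPwm:
    def test_deterministic_pwm_scores_two_bits_per_position(self):
        pwm = np.zeros((3, 4))
        pwm[0, 0] = pwm[1, 2] = pwm[2, 3] = 1.0  # AGT
        assert pwm_log_odds_score(pwm, "AGT") == pytest.approx(6.0)

    def test_background_column_contributes_zero(self):
        pwm = np.array([[0.25, 0.25, 0.25, 0.25]])
        assert pwm_log_odds_score(pwm, "C") == pytest.approx(0.0)

    def test_hand_example_and_n_base(self):
        pwm = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
        assert pwm_log_odds_score(pwm, "AG") == pytest.approx(3.0)
        assert pwm_log_odds_score(pwm, "NG") == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pwm_log_odds_score(pwm_from_consensus("ACGT"), "ACG")


class TestCuration:
    def _sites(self, n, chrom="c"):
        return make_sites([(chrom, 100 * i, 100 * i + 6, "+", float(i))
                           for i in range(n)])

    def test_accessible_then_top_fraction(self):
        sites = self._sites(10)
        acc = IntervalSet([GenomicInterval("c", 0, 2000)])  # all accessible
        out = curate_active_sites(sites, acc, CurationConfig(top_fraction=0.5))
        assert len(out) == 5
        assert out.sites["score"].min() == 5.0

    def test_site_cap(self):
        out = curate_active_sites(self._sites(5),
                                  IntervalSet([GenomicInterval("c", 0, 1000)]),
                                  CurationConfig(top_fraction=1.0, site_cap=3))
        assert len(out) == 3
        assert sorted(out.sites["score"]) == [2.0, 3.0, 4.0]

    def test_inaccessible_dropped(self):
        sites = self._sites(10)
        acc = IntervalSet([GenomicInterval("c", 0, 350)])  # sites 0..3 overlap
        out = curate_active_sites(sites, acc, CurationConfig(top_fraction=1.0))
        assert len(out) == 4

    def test_min_aggregate_flags_cluster(self, sim_cluster):
        cfg = CurationConfig(min_aggregate=10 ** 9)
        prof = analyze_formation(sim_cluster["sites"], sim_cluster["damage"],
                                 sim_cluster["genome"], sim_cluster["rates"], cfg)
        assert prof.insufficient

    def test_stratify_sizes_and_order(self):
        tiers = stratify_by_strength(self._sites(9), 3)
        assert [len(t) for t in tiers] == [3, 3, 3]
        tiers = stratify_by_strength(self._sites(10), 3)
        assert [len(t) for t in tiers] == [4, 3, 3]
        assert tiers[0].sites["score"].min() > tiers[1].sites["score"].max()
        with pytest.raises(ValueError):
            stratify_by_strength(self._sites(2), 3)


class TestObservedProfile:
    def test_plus_site_complement_strand(self):
        # + site, motif length 6, center = start+3
        sites = make_sites([("c", 100, 106, "+", 1.0)])
        # lesion on - strand with dinucleotide spanning axis 3/4: lo = 103+3
        rec = pd.DataFrame({"chrom": ["c"], "strand": ["-"], "pos5": [107],
                            "dinuc": ["TT"], "count": [4]})
        obs = observed_profile(sites, DamageMap("CPD", "0h", rec), window=10)
        assert obs[3 + 10, 1] == 4
        assert obs.sum() == 4

    def test_minus_site_mirrors_position(self):
        """Coordinate-flip oracle on a toy: the same genomic lesion lands at
        the mirrored axis position when the site strand flips."""
        plus = make_sites([("c", 100, 106, "+", 1.0)])
        minus = make_sites([("c", 100, 106, "-", 1.0)])
        rec = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "pos5": [105],
                            "dinuc": ["TT"], "count": [2]})
        dmap = DamageMap("CPD", "0h", rec)
        obs_p = observed_profile(plus, dmap, 10)
        obs_m = observed_profile(minus, dmap, 10)
        # + site: center 103, lo=105 -> p=2 on motif strand
        assert obs_p[2 + 10, 0] == 2
        # - site: center = 105-3=102, p = 102-105-1 = -4, complement strand
        assert obs_m[-4 + 10, 1] == 2

    def test_no_damage_zero_profile(self):
        sites = make_sites([("c", 100, 106, "+", 1.0)])
        assert observed_profile(sites, DamageMap(), 10).sum() == 0


class TestExpectedProfile:
    def test_additivity_over_sites(self):
        g = GenomeSequence({"c": "ACGTACGTAATTCCGGTACGTACGT",
                            "d": "ACGTACGGAATTACGGTACGTACGT"})
        s1 = make_sites([("c", 8, 14, "+", 1.0)])
        s2 = make_sites([("d", 7, 13, "+", 1.0)])
        both = make_sites([("c", 8, 14, "+", 1.0), ("d", 7, 13, "+", 1.0)])
        occ = np.ones(4 ** 6, dtype=np.int64)
        dam = np.zeros(4 ** 6, dtype=np.int64)
        rt = ContextRateTable(2, occ, dam)
        rt.damages = (np.random.default_rng(0).integers(0, 50, 4 ** 6))
        lam = expected_profile(both, g, rt, 3)
        lam1 = expected_profile(s1, g, rt, 3)
        lam2 = expected_profile(s2, g, rt, 3)
        assert np.allclose(lam, lam1 + lam2)

    def test_position_without_dipyrimidine_is_zero(self):
        g = GenomeSequence({"c": "G" * 30})
        sites = make_sites([("c", 10, 16, "+", 1.0)])
        occ = np.ones(4 ** 6, dtype=np.int64)
        rt = ContextRateTable(2, occ, occ.copy())
        lam = expected_profile(sites, g, rt, 5)
        assert np.all(lam[:, 0] == 0)       # poly-G motif strand: no YY
        assert np.all(lam[:, 1] > 0)        # complement poly-C: CC everywhere

    def test_observed_matches_expected_on_simulation(self, sim_cluster):
        """Poisson concentration: X/lambda -> 1 using the true rates."""
        truth_arr = sim_cluster["truth"].hexamer_rate_array()
        occ = (truth_arr > 0).astype(np.int64)
        rt = ContextRateTable(2, occ, occ)  # placeholder; rates injected below
        lam_est = expected_profile(sim_cluster["sites"], sim_cluster["genome"],
                                   sim_cluster["rates"], 40)
        obs = observed_profile(sim_cluster["sites"], sim_cluster["damage"], 40)
        mask = lam_est > 30
        # exclude the planted cell (effect multiplier 3)
        mask[1 + 40, 0] = False
        ratio = obs[mask] / lam_est[mask]
        z = (obs[mask] - lam_est[mask]) / np.sqrt(lam_est[mask])
        assert np.mean(np.abs(z) < 3.5) > 0.95
        assert abs(ratio.mean() - 1) < 0.05


class TestFlankScale:
    def _toy(self):
        window, span = 10, (-1, 0)  # flanks are |p| in 7..10
        positions = np.arange(-window, window + 1)
        lam = np.ones((2 * window + 1, 2))
        return window, span, positions, lam

    def test_identity_when_flanks_match(self):
        w, span, _, lam = self._toy()
        scaled, factors = flank_scale(lam.copy(), lam, span, w)
        assert np.allclose(scaled, lam)
        assert all(f == 1.0 for f in factors.values())

    def test_uniform_ratio(self):
        w, span, _, lam = self._toy()
        scaled, factors = flank_scale(1.2 * lam, lam, span, w)
        assert np.allclose(scaled, 1.2 * lam)

    def test_left_right_split(self):
        w, span, positions, lam = self._toy()
        obs = lam.copy()
        obs[positions < span[0] - 5] *= 2.0     # left flank ratio 2
        scaled, factors = flank_scale(obs, lam, span, w)
        assert factors[("motif", "left")] == pytest.approx(2.0)
        assert factors[("motif", "right")] == pytest.approx(1.0)
        assert np.allclose(scaled[positions <= 0], 2.0)
        assert np.allclose(scaled[positions > 0], 1.0)

    def test_no_usable_flank_warns_factor_one(self):
        w, span, _, lam = self._toy()
        scaled, factors = flank_scale(lam * 0, lam * 0, span, w)
        assert all(f == 1.0 for f in factors.values())


class TestPoissonPositionTest:
    def test_equal_observed_expected(self):
        obs = np.full((3, 2), 9.0)
        prof = poisson_position_test(obs, obs.copy(), 1, 0.05)
        assert (prof.table["direction"] == "none").all()
        assert np.allclose(prof.table["z"], 0.0)

    def test_tail_example_and_oracle(self):
        obs = np.zeros((3, 2))
        lam = np.full((3, 2), 4.0)
        obs[1, 0] = 8.0
        prof = poisson_position_test(obs, lam, 1, 0.05)
        row = prof.table.set_index(["position", "strand"]).loc[(0, "motif")]
        assert row["z"] == pytest.approx(2.0)
        # direct pmf summation oracle: P(X >= 8) = 1 - sum pmf(0..7)
        p_oracle = 1.0 - sum(stats.poisson.pmf(k, 4.0) for k in range(8))
        assert row["p"] == pytest.approx(p_oracle, abs=1e-12)
        assert row["p"] == pytest.approx(0.051134, abs=1e-5)

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_model_gap_excluded_from_bh(self):
        obs = np.zeros((3, 2))
        lam = np.zeros((3, 2))
        obs[0, 0] = 5.0
        lam[1, :] = 4.0
        prof = poisson_position_test(obs, lam, 1, 0.05)
        t = prof.table.set_index(["position", "strand"])
        assert t.loc[(-1, "motif"), "flag"] == "model_gap"
        assert np.isnan(t.loc[(-1, "motif"), "q"])


class TestNakedFilter:
    def _profile(self, qs, directions, threshold=0.05):
        rows = []
        for i, (q, d) in enumerate(zip(qs, directions)):
            rows.append({"position": i, "strand": "motif", "observed": 1.0,
                         "expected": 1.0, "scaled": 1.0, "z": 1.0,
                         "p": q, "q": q, "direction": d, "flag": ""})
        from phototf.profiles import PositionProfile
        return PositionProfile("T", 1, (0, 0), 1, threshold, pd.DataFrame(rows))

    def test_demotion_rules(self):
        cell = self._profile([0.01, 0.01, 0.01], ["enriched"] * 3)
        naked = self._profile([0.01, 0.5, 0.01],
                              ["enriched", "enriched", "depleted"])
        out = naked_dna_filter(cell, naked)
        labels = out.table["label"].tolist()
        assert labels[0] == "sequence-intrinsic"       # both significant, same dir
        assert labels[1] == ""                         # naked not significant
        assert labels[2] == "naked-direction-mismatch"  # opposite direction kept


class TestEndToEndFormation:
    def test_planted_effect_detected_uniquely(self, sim_cluster):
        prof = analyze_formation(sim_cluster["sites"], sim_cluster["damage"],
                                 sim_cluster["genome"], sim_cluster["rates"],
                                 CurationConfig())
        sig = prof.significant()
        assert len(sig) >= 1
        top = prof.table.loc[prof.table["z"].idxmax()]
        assert (top["position"], top["strand"]) == (1, "motif")
        assert top["direction"] == "enriched" and top["q"] < 1e-10

    def test_tier_monotonicity_with_score_coupled_effect(self):
        """|z| at the planted cell decreases from the strongest to the weakest
        score tier when the effect strength tracks the motif score."""
        from phototf.simulate import (default_truth_tables, generate_genome,
                                      plant_sites, simulate_damage, PlantedEffect)
        truth = default_truth_tables(21)
        g = generate_genome(1, 900 * 220 + 2000, 0.41, 22)
        g, sites, acc = plant_sites(g, "GGAATT", 900, 220, 23, score_noise=0.3)
        tiers = stratify_by_strength(sites, 3)
        multipliers = [4.0, 2.0, 1.0]  # effect proportional to binding strength
        maps = []
        for k, (tier, m) in enumerate(zip(tiers, multipliers)):
            # damage drawn only over this tier's accessible windows so the
            # combined map counts every locus exactly once
            tier_acc = IntervalSet(
                GenomicInterval(r.chrom, int(c) - 75, int(c) + 75)
                for r, c in zip(tier.sites.itertuples(), tier.centers))
            eff = [PlantedEffect(1, "motif", "formation", m)] if m > 1 else []
            maps.append(simulate_damage(g, tier_acc, truth, eff, tier, seed=24 + k))
        rec = pd.concat([d.records for d in maps], ignore_index=True)
        dmap = DamageMap("CPD", "0h", rec).aggregate()
        rates = estimate_context_rates(dmap, g, acc, 2)
        zs = []
        for tier in tiers:
            prof = analyze_formation(tier, dmap, g, rates, CurationConfig())
            t = prof.table.set_index(["position", "strand"])
            zs.append(abs(t.loc[(1, "motif"), "z"]))
        assert zs[0] > zs[1] > zs[2]
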
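"""Context-conditioned repair efficiency and the bootstrap repair test."""

import numpy as np
import pandas as pd
import pytest

from phototf.genome import GenomeSequence
from phototf.intervals import GenomicInterval, IntervalSet
from phototf.damage import DamageMap
from phototf.background import kmer_to_id
from phototf.repair import (RepairEfficiencyTable, repair_efficiency_by_context,
                            bootstrap_unrepaired_test, context_efficiency_comparison)
from phototf.simulate import (default_truth_tables, generate_genome, plant_sites,
                              simulate_damage, simulate_repair, PlantedEffect)


@pytest.fixture(scope="module")
def repair_fixture():
    """Cluster with high TT damage burden and a planted 2x survival effect at
    the motif-strand TT (position 1)."""
    truth = default_truth_tables(31, dinuc_rates={"TT": 0.2, "TC": 0.07,
                                                  "CT": 0.03, "CC": 0.05})
    g = generate_genome(1, 1200 * 220 + 2000, 0.41, 32)
    g, sites, acc = plant_sites(g, "GGAATT", 1200, 220, 33, score_noise=0.05)
    m0 = simulate_damage(g, acc, truth, (), sites, seed=34)
    eff = [PlantedEffect(1, "motif", "survival", 2.0)]
    with pytest.warns(UserWarning):
        # some NYYN survivals exceed 0.5, so 2x is clamped at other loci? no:
        # the clamp warning fires when survival*multiplier > 1 at planted loci
        mt = simulate_repair(m0, truth, g, eff, sites, seed=35)
    return {"truth": truth, "genome": g, "sites": sites, "accessible": acc,
            "m0": m0, "mt": mt}


class TestEfficiencyTable:
    def _maps(self, n0, nt):
        g = GenomeSequence({"c": "G" * 5 + "ATTA" * 2000 + "G" * 5})
        regions = IntervalSet([GenomicInterval("c", 0, g.lengths["c"])])
        rows0, rowst = [], []
        for i in range(2000):
            p = 5 + 4 * i + 1
            rows0.append(("c", "+", p, "TT", n0))
            if nt:
                rowst.append(("c", "+", p, "TT", nt))
        cols = ["chrom", "strand", "pos5", "dinuc", "count"]
        m0 = DamageMap("CPD", "0h", pd.DataFrame(rows0, columns=cols))
        mt = DamageMap("CPD", "6h", pd.DataFrame(rowst, columns=cols))
        return g, regions, m0, mt

    def test_survival_ratio(self):
        g, regions, m0, mt = self._maps(1, 0)
        mt = DamageMap("CPD", "6h", m0.records.iloc[:800].copy())
        table = repair_efficiency_by_context(m0, mt, g, regions)
        i = kmer_to_id("ATTA")
        assert table.survival_array()[i] == pytest.approx(0.4)
        assert table.efficiency_array()[i] == pytest.approx(0.6)

    def test_identical_maps_full_survival(self):
        g, regions, m0, _ = self._maps(2, 0)
        table = repair_efficiency_by_context(m0, m0, g, regions)
        s = table.survival_array()
        assert s[kmer_to_id("ATTA")] == pytest.approx(1.0)

    def test_insufficient_contexts_flagged(self):
        g, regions, m0, mt = self._maps(1, 1)
        table = repair_efficiency_by_context(m0, mt, g, regions, min_initial=10 ** 9)
        assert np.isnan(table.survival_array()[kmer_to_id("ATTA")])
        assert table.insufficient[kmer_to_id("ATTA")]

    def test_simulated_truth_survival_recovered(self, repair_fixture):
        f = repair_fixture
        table = repair_efficiency_by_context(f["m0"], f["mt"], f["genome"],
                                             f["accessible"])
        surv = table.survival_array()
        truth_surv = f["truth"].survival_array()
        ids = np.flatnonzero(table.count_0h >= 200)
        assert len(ids) > 10
        for i in ids:
            n = table.count_0h[i]
            se = np.sqrt(truth_surv[i] * (1 - truth_surv[i]) / n)
            # planted effect perturbs one context upward slightly; 4 SE margin
            assert abs(surv[i] - truth_surv[i]) < 4 * se + 0.02


class TestBootstrap:
    def test_planted_survival_effect_flagged_uniquely(self, repair_fixture):
        f = repair_fixture
        res = bootstrap_unrepaired_test(f["sites"], f["m0"], f["mt"], f["genome"],
                                        f["accessible"], n_boot=4000, seed=36,
                                        window=30)
        sig = res.significant()
        t = res.table.set_index(["position", "strand"])
        assert t.loc[(1, "motif"), "z"] > 5
        assert (1, "motif") in {(int(r.position), r.strand) for r in sig.itertuples()}
        # composition at the planted position is all NTTN classes
        comp = res.composition[(1, "motif")]
        assert all(k[1:3] == "TT" for k in comp)

    def test_no_repair_degenerate_case(self):
        """survival = 1 for every context and observed = initial: z ~ 0."""
        g = GenomeSequence({"c": "G" * 3 + "AATTAC" * 800 + "G" * 3})
        regions = IntervalSet([GenomicInterval("c", 0, g.lengths["c"])])
        rows = [("c", "+", 3 + 6 * i + 2, "TT", 2) for i in range(800)]
        m0 = DamageMap("CPD", "0h", pd.DataFrame(
            rows, columns=["chrom", "strand", "pos5", "dinuc", "count"]))
        from helpers import make_sites
        sites = make_sites([("c", 3 + 6 * k, 3 + 6 * k + 6, "+", 1.0)
                            for k in range(0, 800, 4)])
        res = bootstrap_unrepaired_test(sites, m0, m0, g, regions, n_boot=500,
                                        seed=1, window=10, min_initial=1)
        t = res.table.dropna(subset=["p"])
        assert len(t)
        assert np.abs(t["z"].to_numpy(dtype=float)).max() < 1e-9
        assert (t["p"] > 0.99).all()

    def test_bootstrap_mean_matches_binomial_expectation(self, repair_fixture):
        """Analytic oracle: E[draw] = sum_c n_c s_c within Monte-Carlo error."""
        f = repair_fixture
        table = repair_efficiency_by_context(f["m0"], f["mt"], f["genome"],
                                             f["accessible"])
        surv = table.survival_array()
        n_boot = 3000
        res = bootstrap_unrepaired_test(f["sites"], f["m0"], f["mt"], f["genome"],
                                        f["accessible"], n_boot=n_boot, seed=37,
                                        window=30, efficiency_table=table)
        checked = 0
        for (pos, strand), comp in res.composition.items():
            row = res.table.set_index(["position", "strand"]).loc[(pos, strand)]
            expect = sum(n * surv[kmer_to_id(k)] for k, n in comp.items())
            var = sum(n * surv[kmer_to_id(k)] * (1 - surv[kmer_to_id(k)])
                      for k, n in comp.items())
            # undo the flank scaling applied to the draws
            side = "left" if pos <= 0 else "right"
            factor = res.factors[(strand, side)]
            tol = 4 * factor * np.sqrt(var / n_boot) + 1e-9
            assert abs(row["boot_mean"] - factor * expect) < tol
            checked += 1
        assert checked > 50

    def test_monotonicity_in_planted_multiplier(self):
        """Median z at the planted cell never decreases with the multiplier."""
        truth = default_truth_tables(41, dinuc_rates={"TT": 0.2, "TC": 0.07,
                                                      "CT": 0.03, "CC": 0.05},
                                     survival_range=(0.25, 0.45))
        g = generate_genome(1, 600 * 220 + 2000, 0.41, 42)
        g, sites, acc = plant_sites(g, "GGAATT", 600, 220, 43)
        m0 = simulate_damage(g, acc, truth, (), sites, seed=44)
        med = []
        for mult in (1.0, 1.5, 2.0):
            zs = []
            for s in range(3):
                eff = [PlantedEffect(1, "motif", "survival", mult)] if mult > 1 else []
                mt = simulate_repair(m0, truth, g, eff, sites, seed=45 + s)
                res = bootstrap_unrepaired_test(sites, m0, mt, g, acc,
                                                n_boot=1000, seed=50 + s,
                                                window=30, min_initial=5)
                t = res.table.set_index(["position", "strand"])
                zs.append(float(t.loc[(1, "motif"), "z"]))
            med.append(np.median(zs))
        assert med[0] <= med[1] <= med[2]

    def test_resampling_kernel_agrees_with_binomial(self, repair_fixture):
        f = repair_fixture
        kw = dict(n_boot=800, window=30)
        r1 = bootstrap_unrepaired_test(f["sites"], f["m0"], f["mt"], f["genome"],
                                       f["accessible"], seed=60, kernel="binomial", **kw)
        r2 = bootstrap_unrepaired_test(f["sites"], f["m0"], f["mt"], f["genome"],
                                       f["accessible"], seed=60, kernel="resample", **kw)
        a = r1.table.set_index(["position", "strand"])["z"]
        b = r2.table.set_index(["position", "strand"])["z"]
        m = a.notna() & b.notna()
        from scipy import stats
        assert stats.pearsonr(a[m], b[m]).statistic > 0.9


class TestEfficiencyComparison:
    def _table(self, effs):
        c0 = np.zeros(256)
        ct = np.zeros(256)
        kmers = []
        from phototf.background import pyrimidine_centered_mask, id_to_kmer
        ids = np.flatnonzero(pyrimidine_centered_mask(1))[:len(effs)]
        for i, e in zip(ids, effs):
            c0[i] = 1000
            ct[i] = 1000 * (1 - e)
            kmers.append(id_to_kmer(int(i), 4))
        return RepairEfficiencyTable(c0, ct, min_initial=1), kmers

    def test_hand_counted_u_statistic(self):
        table, kmers = self._table([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        comp = {k: 1 for k in kmers[:3]}  # {0.1,0.2,0.3} vs all six
        res = context_efficiency_comparison(comp, table)
        # ranks of group1 within combined = all below group2 except overlap
        from scipy import stats
        ref = stats.mannwhitneyu([0.1, 0.2, 0.3],
                                 [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                                 alternative="two-sided")
        assert res.statistic == ref.statistic
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_slow_repair_composition_detected(self):
        effs = [0.05, 0.06, 0.07] + [0.5 + 0.01 * i for i in range(20)]
        table, kmers = self._table(effs)
        comp = {k: 10 for k in kmers[:3]}  # heavy weight on slow contexts
        res = context_efficiency_comparison(comp, table)
        assert res.pvalue < 1e-4

    def test_degenerate_identical_groups(self):
        table, kmers = self._table([0.3] * 8)
        res = context_efficiency_comparison({k: 1 for k in kmers}, table)
        assert res.pvalue == 1.0
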
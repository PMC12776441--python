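"""Self-contained validation experiments on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant part of
the analysis pipeline, and returns summary numbers: null calibration of the
per-position formation test, planted-effect recovery, agreement between the
analytic Poisson null and the context-preserving shuffle null, repair
bootstrap calibration and power, mutation projection identities, and the
geometric round-trips. The test suite asserts on these numbers and the
acceptance script reports them.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .background import ContextRateTable, estimate_context_rates
from .damage import DamageMap
from .mutations import concordance, project_mutations
from .profiles import (CurationConfig, analyze_formation, observed_profile,
                       shuffle_null_test)
from .repair import bootstrap_unrepaired_test
from .simulate import (PlantedEffect, default_truth_tables, generate_genome,
                       plant_sites, simulate_damage, simulate_repair)

#: UVDE-seq-like 6-4 PP baseline: TC steps are the preferred substrate.
PP64_DINUC_RATES = {"TC": 0.06, "TT": 0.04, "CT": 0.012, "CC": 0.018}

#: high-burden baseline used for the repair experiments, so the planted
#: position carries several hundred initial lesions.
REPAIR_DINUC_RATES = {"TT": 0.2, "TC": 0.07, "CT": 0.03, "CC": 0.05}

CONSENSUS = "GGAATT"          # motif-strand TT at axis position 1 ("1/2")
PLANTED_CELL = (1, "motif")


def _seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _cluster(seed: int, n_sites: int, dinuc_rates=None, effects=(),
             lesion_type: str = "CPD"):
    s = _seeds(seed, 4)
    truth = default_truth_tables(s[0], dinuc_rates=dinuc_rates)
    g = generate_genome(1, n_sites * 220 + 2000, 0.41, s[1])
    g, sites, acc = plant_sites(g, CONSENSUS, n_sites, 220, s[2], score_noise=0.05)
    dmap = simulate_damage(g, acc, truth, effects, sites, seed=s[3],
                           lesion_type=lesion_type)
    return truth, g, sites, acc, dmap


# -- 1. Poisson tail oracle ---------------------------------------------


def poisson_tail_max_error(lambdas: Iterable[float] = (0.1, 0.5, 1, 2, 5, 10,
                                                       20, 35, 50),
                           x_max: int = 200) -> float:
    """Max |implementation - direct pmf summation| over both one-sided tails.

    The oracle accumulates exp(-lam) lam^k / k! iteratively, independent of
    the tail functions under test.
    """
    worst = 0.0
    for lam in lambdas:
        pmf = math.exp(-lam)
        cum = pmf
        cdf_oracle = [cum]
        for k in range(1, x_max + 1):
            pmf *= lam / k
            cum += pmf
            cdf_oracle.append(cum)
        for x in range(0, x_max + 1):
            # enrichment tail P(X >= x) and depletion tail P(X <= x)
            p_up = float(stats.poisson.sf(x - 1, lam))
            p_dn = float(stats.poisson.cdf(x, lam))
            oracle_up = 1.0 - (cdf_oracle[x - 1] if x >= 1 else 0.0)
            oracle_dn = cdf_oracle[x]
            worst = max(worst, abs(p_up - oracle_up), abs(p_dn - oracle_dn))
    return worst


# -- 2. null calibration -------------------------------------------------


def null_calibration(n_clusters: int = 50, n_sites: int = 2000, seed: int = 0,
                     lesion: str = "CPD") -> dict:
    """Fraction of profile cells with raw one-sided p below 0.05 and 0.01
    across no-effect clusters, with their exact binomial 99% bounds."""
    rates = PP64_DINUC_RATES if lesion == "64PP" else None
    cfg = CurationConfig(threshold=0.01 if lesion == "64PP" else 0.05)
    ps = []
    for s in _seeds(seed, n_clusters):
        truth, g, sites, acc, dmap = _cluster(s, n_sites, rates,
                                              lesion_type=lesion)
        table = estimate_context_rates(dmap, g, acc, cfg.k_flank)
        prof = analyze_formation(sites, dmap, g, table, cfg)
        ps.append(prof.table["p"].dropna().to_numpy())
    ps = np.concatenate(ps)
    out = {"n_cells": int(len(ps))}
    for alpha in (0.05, 0.01):
        lo, hi = stats.binom.ppf([0.005, 0.995], len(ps), alpha) / len(ps)
        out[f"fraction_p_lt_{alpha}"] = float(np.mean(ps < alpha))
        out[f"bounds_{alpha}"] = (float(lo), float(hi))
    return out


# -- 3. planted-effect recovery -----------------------------------------


def planted_recovery(n_seeds: int = 20, n_sites: int = 2000,
                     multiplier: float = 3.0, seed: int = 0) -> dict:
    """Detection of one planted formation multiplier across seeds.

    Returns the number of seeds where the planted (position, strand) cell is
    flagged enriched at q < 0.05, and the maximum number of times any other
    cell is flagged across all seeds.
    """
    effect = PlantedEffect(PLANTED_CELL[0], PLANTED_CELL[1], "formation",
                           multiplier)
    cfg = CurationConfig()
    detected = 0
    other_flags: dict = {}
    for s in _seeds(seed, n_seeds):
        truth, g, sites, acc, dmap = _cluster(s, n_sites, effects=[effect])
        table = estimate_context_rates(dmap, g, acc, cfg.k_flank)
        prof = analyze_formation(sites, dmap, g, table, cfg)
        sig = prof.significant()
        for r in sig.itertuples():
            cell = (int(r.position), r.strand)
            if cell == PLANTED_CELL:
                if r.direction == "enriched":
                    detected += 1
            else:
                other_flags[cell] = other_flags.get(cell, 0) + 1
    return {"n_seeds": n_seeds, "n_detected": detected,
            "max_other_cell_flags": max(other_flags.values()) if other_flags else 0,
            "n_other_cells_flagged": len(other_flags)}


# -- 4. analytic vs shuffle consistency ---------------------------------


def shuffle_consistency(n_sites: int = 2000, n_iter: int = 2000,
                        seed: int = 0) -> dict:
    """Pearson r between the analytic Poisson z and the shuffle-null z over
    all testable cells of one planted-effect cluster."""
    s = _seeds(seed, 2)
    effect = PlantedEffect(*PLANTED_CELL, "formation", 3.0)
    truth, g, sites, acc, dmap = _cluster(s[0], n_sites, effects=[effect])
    cfg = CurationConfig()
    table = estimate_context_rates(dmap, g, acc, cfg.k_flank)
    prof = analyze_formation(sites, dmap, g, table, cfg)
    sh = shuffle_null_test(dmap, acc, g, sites, n_iter=n_iter, seed=s[1],
                           window=cfg.window_halfwidth)
    a = prof.table.set_index(["position", "strand"])["z"]
    b = sh.table.set_index(["position", "strand"])["z"]
    m = a.notna() & b.notna()
    r = float(stats.pearsonr(a[m], b[m]).statistic)
    return {"pearson_r": r, "n_cells": int(m.sum())}


# -- 5. repair calibration and power ------------------------------------


def repair_calibration(n_sites: int = 2000, n_boot: int = 2000,
                       seed: int = 0) -> dict:
    """Bootstrap p distribution when site survival matches the background."""
    s = _seeds(seed, 3)
    truth = default_truth_tables(s[0], dinuc_rates=REPAIR_DINUC_RATES)
    g = generate_genome(1, n_sites * 220 + 2000, 0.41, s[0] // 2 + 1)
    g, sites, acc = plant_sites(g, CONSENSUS, n_sites, 220, s[1])
    m0 = simulate_damage(g, acc, truth, (), sites, seed=s[2])
    mt = simulate_repair(m0, truth, g, (), sites, seed=s[2] + 1)
    res = bootstrap_unrepaired_test(sites, m0, mt, g, acc, n_boot=n_boot,
                                    seed=s[2] + 2, window=30)
    p = res.table["p"].dropna().to_numpy()
    ks = float(np.max(np.abs(np.sort(p) - (np.arange(1, len(p) + 1)) / len(p))))
    return {"n_cells": int(len(p)), "mean_p": float(p.mean()),
            "fraction_p_lt_0.05": float(np.mean(p < 0.05)),
            "ks_to_uniform": ks}


def repair_power(n_seeds: int = 20, n_sites: int = 2000, multiplier: float = 2.0,
                 n_boot: int = 10_000, seed: int = 0) -> dict:
    """Detection of a planted survival multiplier at a high-burden position.

    The 0h map is drawn once; each seed rethins it with the planted effect
    and reruns the bootstrap. Reports how many seeds flag the planted cell
    at q < 0.05 and the initial lesion burden there.
    """
    s = _seeds(seed, 3)
    # survival capped so multiplier x survival stays within [0, 1]
    truth = default_truth_tables(s[0], dinuc_rates=REPAIR_DINUC_RATES,
                                 survival_range=(0.25, 0.45))
    g = generate_genome(1, n_sites * 220 + 2000, 0.41, s[0] // 2 + 1)
    g, sites, acc = plant_sites(g, CONSENSUS, n_sites, 220, s[1])
    m0 = simulate_damage(g, acc, truth, (), sites, seed=s[2])
    obs0 = observed_profile(sites, m0, 30)
    initial = float(obs0[PLANTED_CELL[0] + 30, 0])
    effect = PlantedEffect(*PLANTED_CELL, "survival", multiplier)
    detected = 0
    zs = []
    for k, sd in enumerate(_seeds(seed + 1, n_seeds)):
        mt = simulate_repair(m0, truth, g, [effect], sites, seed=sd)
        res = bootstrap_unrepaired_test(sites, m0, mt, g, acc, n_boot=n_boot,
                                        seed=sd + 1, window=30)
        t = res.table.set_index(["position", "strand"])
        row = t.loc[PLANTED_CELL]
        zs.append(float(row["z"]))
        if row["q"] == row["q"] and row["q"] < 0.05 and row["direction"] == "elevated":
            detected += 1
    return {"n_seeds": n_seeds, "n_detected": detected,
            "initial_lesions_at_cell": initial, "median_z": float(np.median(zs))}


# -- 6/7. mutation projection and concordance ---------------------------


def projection_identity(seed: int = 0, n_sites: int = 400) -> dict:
    """Exact conservation of projected counts and the CC>TT tandem rule."""
    truth, g, sites, acc, dmap = _cluster(seed, n_sites)
    proj = project_mutations(dmap, g, sites, 40)
    from .profiles import _site_cell_assignment
    rec = dmap.records
    lo = np.where(rec["strand"] == "-", rec["pos5"] - 1, rec["pos5"]).astype(np.int64)
    idx, _, _ = _site_cell_assignment(sites, rec["chrom"].to_numpy(),
                                      rec["strand"].to_numpy(), lo, 40)
    expected = float((rec["dinuc"].str.count("C").to_numpy()[idx]
                      * rec["count"].to_numpy()[idx]).sum())
    # CC>TT tandem rule on a hand-built lesion at axis 2/3 of a toy site
    from .sites import BindingSiteSet
    toy_sites = BindingSiteSet("TOY/1", 6, pd.DataFrame(
        [("c", 100, 106, "+", 1.0)],
        columns=["chrom", "start", "end", "strand", "score"]))
    toy = DamageMap("CPD", "0h", pd.DataFrame(
        [("c", "+", 105, "CC", 2)],
        columns=["chrom", "strand", "pos5", "dinuc", "count"]))
    tandem = project_mutations(toy, None, toy_sites, 10)
    return {"total_projected": float(proj.sum()), "expected_total": expected,
            "cc_tandem_counts": (float(tandem.loc[2]), float(tandem.loc[3])),
            "cc_tandem_total": float(tandem.sum())}


def concordance_checks(seed: int = 0) -> dict:
    """Identity concordance (r = 1, residual z = 0) and unique-outlier call."""
    rng = np.random.default_rng(seed)
    idx = np.arange(-40, 41)
    x = pd.Series(rng.uniform(0, 50, len(idx)), index=idx)
    res_id = concordance(x, x * 2.0)
    y = 3.0 * x + rng.normal(0, 0.5, len(idx))
    y.loc[0] += 120.0
    res_out = concordance(x, y)
    return {"identity_r": float(res_id.r),
            "identity_max_abs_residual_z": float(np.max(np.abs(res_id.residual_z))),
            "outlier_calls": res_out.discordant,
            "outlier_unique": res_out.discordant == [0]}


# -- 8. geometry round-trips --------------------------------------------


def geometry_checks(seed: int = 0) -> dict:
    """Rigid-motion invariance, helix round-trip, pucker formula, overlap."""
    from scipy.spatial.transform import Rotation
    from .geometry import (STANDARD_BASES, BaseFrame, Residue, d22, d64,
                           phase_from_torsions, stacking_overlap,
                           step_parameters)

    def residue(base, R=np.eye(3), t=np.zeros(3)):
        atoms = {a: R @ np.array(x) + np.asarray(t, dtype=float)
                 for a, x in STANDARD_BASES[base].items()}
        return Residue("A", 1, "D" + base, base, atoms)

    r5 = residue("T")
    r3 = residue("C", Rotation.from_euler("x", 6, degrees=True).as_matrix(),
                 [0.4, 0.6, 3.4])
    R = Rotation.random(random_state=seed).as_matrix()
    t = np.random.default_rng(seed).normal(0, 8, 3)
    r5r = residue("T", R, t)
    r3r = Residue("A", 2, "DC", "C",
                  {a: R @ xyz + t for a, xyz in r3.atoms.items()})
    rigid_err = max(abs(d22(r5, r3) - d22(r5r, r3r)),
                    abs(d64(r5, r3) - d64(r5r, r3r)),
                    abs(stacking_overlap(r5, r3) - stacking_overlap(r5r, r3r)))

    twist, rise, shift, slide = 36.0, 3.4, 0.7, 1.5
    Rz = Rotation.from_rotvec([0, 0, math.radians(twist)]).as_matrix()
    Rm = Rotation.from_rotvec([0, 0, math.radians(twist / 2)]).as_matrix()
    sp = step_parameters(BaseFrame(np.zeros(3), np.eye(3)),
                         BaseFrame(Rm @ np.array([shift, slide, rise]), Rz))
    helix_err = max(abs(sp.twist - twist), abs(sp.rise - rise),
                    abs(sp.shift - shift), abs(sp.slide - slide))

    tau, P0 = 38.0, 162.0
    nus = [tau * math.cos(math.radians(P0 + 144 * (j - 2))) for j in range(5)]
    sp2 = phase_from_torsions(nus)
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2 * nus[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
    pucker_err = abs(sp2.phase - math.degrees(math.atan2(num, den)) % 360)

    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    overlap_half = stacking_overlap(square, square + [0.5, 0, 0])
    return {"rigid_motion_error": float(rigid_err),
            "helix_round_trip_error": float(helix_err),
            "pucker_phase_error": float(pucker_err),
            "unit_square_half_overlap": float(overlap_half)}


# -- 9. curation rules on constructed toys ------------------------------


def curation_checks() -> dict:
    """Exact checks of every curation rule on constructed toy inputs."""
    from .intervals import GenomicInterval, IntervalSet
    from .profiles import build_accessible_regions, curate_active_sites
    from .sites import BindingSiteSet

    peaks = pd.DataFrame(
        [("c", 1000 * i, 1000 * i + 200, f"p{i}", 0, ".", float(i), 1, 1, 100)
         for i in range(10)],
        columns=["chrom", "start", "end", "name", "score", "strand", "signal",
                 "pvalue", "qvalue", "summit"])
    acc = build_accessible_regions(peaks, top_fraction=0.5)
    iv = sorted(acc, key=lambda v: v.start)[0]
    out = {"n_top_peaks": len(acc),
           "summit_window_ok": (iv.start, iv.end) == (5100 - 75, 5100 + 75)}

    sites = BindingSiteSet("TOY/1", 6, pd.DataFrame(
        [("c", 100 * i, 100 * i + 6, "+", float(i)) for i in range(20)],
        columns=["chrom", "start", "end", "strand", "score"]))
    allacc = IntervalSet([GenomicInterval("c", 0, 10_000)])
    kept = curate_active_sites(sites, allacc, CurationConfig(top_fraction=0.5))
    capped = curate_active_sites(sites, allacc,
                                 CurationConfig(top_fraction=1.0, site_cap=7))
    out["n_top_sites"] = len(kept)
    out["n_capped_sites"] = len(capped)

    # minimum-aggregate filter: max position count 29 -> insufficient
    g = generate_genome(1, 5000, 0.41, 1)
    g, s1, acc1 = plant_sites(g, CONSENSUS, 10, 300, 2)
    rec = pd.DataFrame([("chr1", "+", int(c) + 1, "TT", 29)
                        for c in s1.centers[:1]],
                       columns=["chrom", "strand", "pos5", "dinuc", "count"])
    dmap = DamageMap("CPD", "0h", rec)
    occ = np.ones(4 ** 6, dtype=np.int64)
    rt = ContextRateTable(2, occ, np.zeros(4 ** 6, dtype=np.int64))
    prof = analyze_formation(s1, dmap, g, rt, CurationConfig())
    out["min_aggregate_excludes_29"] = bool(prof.insufficient)
    rec30 = rec.assign(count=30)
    prof30 = analyze_formation(s1, DamageMap("CPD", "0h", rec30), g, rt,
                               CurationConfig())
    out["min_aggregate_keeps_30"] = not prof30.insufficient

    # pLDDT filter with terminal trimming
    from .geometry import STANDARD_BASES, Residue, StructureModel, confidence_filter
    def res(i, b):
        return Residue("A", i, "DT", "T",
                       {a: np.array(x) for a, x in STANDARD_BASES["T"].items()},
                       {a: b for a in STANDARD_BASES["T"]})
    chain = [res(i, 10.0 if i < 3 or i >= 7 else 80.0) for i in range(10)]
    ok_trim, retained = confidence_filter(StructureModel("toy", {"A": chain}), 70, 3)
    chain2 = list(chain)
    chain2[4] = res(4, 69.9)
    ok_low, _ = confidence_filter(StructureModel("toy", {"A": chain2}), 70, 3)
    out["plddt_trim_passes"] = bool(ok_trim) and len(retained) == 4
    out["plddt_interior_low_fails"] = not ok_low
    return out
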
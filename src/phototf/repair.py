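"""Context-conditioned CPD repair efficiency and bootstrap repair testing.

Repair is quantified as the per-NYYN survival fraction between an initial
(0h) and a later damage map over intergenic accessible background regions.
Binding-site positions are then tested for significantly elevated
unrepaired lesions with a bootstrap that conditions on both the initial
lesion burden of the position and its NYYN composition: each draw thins the
position's per-context 0h counts with the background survival
probabilities, and the resulting null is flank-scaled exactly as in the
formation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background import (context_ids_of_records, id_to_kmer, kmer_to_id,
                         pyrimidine_centered_mask)
from .damage import DamageMap
from .genome import GenomeSequence
from .intervals import IntervalSet
from .profiles import STRANDS, _site_cell_assignment
from .sites import BindingSiteSet

__all__ = [
    "RepairEfficiencyTable",
    "RepairTestResult",
    "repair_efficiency_by_context",
    "bootstrap_unrepaired_test",
    "context_efficiency_comparison",
]

log = logging.getLogger(__name__)


@dataclass
class RepairEfficiencyTable:
    """Per-NYYN survival (t/0h) and efficiency (1 - survival).

    Arrays indexed by tetranucleotide id; contexts whose 0h count falls
    below ``min_initial`` are flagged insufficient (no ratio reported).
    """

    count_0h: np.ndarray
    count_t: np.ndarray
    norm_factor: float = 1.0
    min_initial: int = 20
    timepoint: str = "6h"

    @property
    def centered_mask(self) -> np.ndarray:
        return pyrimidine_centered_mask(1)

    @property
    def insufficient(self) -> np.ndarray:
        return self.centered_mask & (self.count_0h < self.min_initial)

    def survival_array(self) -> np.ndarray:
        """t/0h per context (NaN where insufficient)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            s = self.count_t * self.norm_factor / self.count_0h
        s = np.where(self.insufficient | ~self.centered_mask, np.nan, s)
        return s

    def efficiency_array(self) -> np.ndarray:
        return 1.0 - self.survival_array()

    def to_frame(self) -> pd.DataFrame:
        ids = np.flatnonzero(self.centered_mask)
        s = self.survival_array()
        return pd.DataFrame({
            "kmer": [id_to_kmer(int(i), 4) for i in ids],
            "count_0h": self.count_0h[ids].astype(int),
            "count_t": self.count_t[ids].astype(int),
            "survival": s[ids],
            "efficiency": 1.0 - s[ids],
            "insufficient": self.insufficient[ids],
        })

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# timepoint={self.timepoint} norm_factor={self.norm_factor} "
                     f"min_initial={self.min_initial}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def repair_efficiency_by_context(map0h: DamageMap, mapT: DamageMap,
                                 genome: GenomeSequence, regions: IntervalSet,
                                 norm_factor: float = 1.0,
                                 min_initial: int = 20) -> RepairEfficiencyTable:
    """Survival and efficiency per NYYN over (intergenic accessible) regions.

    ``norm_factor`` rescales the later timepoint for library depth; by
    default the deposited counts are assumed pre-normalized.
    """
    c0 = np.zeros(256)
    ct = np.zeros(256)
    for dmap, acc in ((map0h, c0), (mapT, ct)):
        filtered = dmap.filter_to_regions(regions, contained=True)
        if not len(filtered.records):
            continue
        ids = context_ids_of_records(filtered, genome, k_flank=1)
        counts = filtered.records["count"].to_numpy()
        ok = ids >= 0
        np.add.at(acc, ids[ok], counts[ok])
    return RepairEfficiencyTable(c0, ct, norm_factor, min_initial,
                                 timepoint=mapT.timepoint)


@dataclass
class RepairTestResult:
    """Bootstrap repair test over one cluster window.

    ``table`` columns: position, strand, observed (remaining at t),
    initial_0h, boot_mean, boot_sd, z, p, q, direction, flag.
    ``composition`` maps (position, strand) -> {NYYN: initial count}.
    """

    cluster_id: str
    window: int
    n_boot: int
    threshold: float
    table: pd.DataFrame
    composition: dict = field(default_factory=dict)
    factors: dict = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[(t["q"] < self.threshold) & (t["direction"] == "elevated")]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cluster={self.cluster_id} window={self.window} "
                     f"n_boot={self.n_boot} threshold={self.threshold}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _cells_by_class(siteset: BindingSiteSet, dmap: DamageMap,
                    genome: GenomeSequence, window: int):
    """Per-cell, per-NYYN aggregated counts for a damage map."""
    rec = dmap.records
    n_cells = (2 * window + 1) * 2
    cell_counts = np.zeros(n_cells)
    by_class: dict[int, dict[int, float]] = {}
    if not len(rec):
        return cell_counts, by_class
    lo = np.where(rec["strand"].to_numpy() == "-", rec["pos5"].to_numpy() - 1,
                  rec["pos5"].to_numpy())
    idx, pos, sidx = _site_cell_assignment(
        siteset, rec["chrom"].to_numpy(), rec["strand"].to_numpy(), lo, window)
    cells = (pos + window) * 2 + sidx
    counts = rec["count"].to_numpy()[idx]
    ids = context_ids_of_records(dmap, genome, k_flank=1)[idx]
    np.add.at(cell_counts, cells, counts)
    for cell, cid, cnt in zip(cells, ids, counts):
        by_class.setdefault(int(cell), {}).setdefault(int(cid), 0.0)
        by_class[int(cell)][int(cid)] += cnt
    return cell_counts, by_class


def bootstrap_unrepaired_test(siteset: BindingSiteSet, map0h: DamageMap,
                              mapT: DamageMap, genome: GenomeSequence,
                              regions: IntervalSet, n_boot: int = 10_000,
                              seed: int = 0, window: int = 30,
                              threshold: float = 0.05, flank_margin: int = 5,
                              efficiency_table: RepairEfficiencyTable | None = None,
                              kernel: str = "binomial", min_initial: int = 20,
                              chunk: int = 2000) -> RepairTestResult:
    """Bootstrap test for elevated unrepaired lesions at each cell.

    For each (position, strand) cell the 0h count decomposes into per-NYYN
    counts n_c; one draw is sum_c Binomial(n_c, s_c) with background survival
    s_c (``kernel="binomial"``), or, as a sensitivity variant
    (``kernel="resample"``), each unit lesion draws a background locus of
    its class (weighted by 0h count) and survives with that locus's own t/0h
    fraction. The null is flank-scaled; the empirical one-sided p for
    elevated remaining damage uses (k+1)/(n+1); BH across the window.
    Cells containing a context with insufficient background survival are
    excluded and flagged.
    """
    rng = np.random.default_rng(seed)
    if efficiency_table is None:
        efficiency_table = repair_efficiency_by_context(map0h, mapT, genome, regions,
                                                        min_initial=min_initial)
    surv = efficiency_table.survival_array()

    obs0, comp0 = _cells_by_class(siteset, map0h, genome, window)
    obsT, _ = _cells_by_class(siteset, mapT, genome, window)
    n_cells = (2 * window + 1) * 2

    # locus pools for the resampling kernel
    pools: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if kernel == "resample":
        bg0 = map0h.filter_to_regions(regions, contained=True)
        bgT = mapT.filter_to_regions(regions, contained=True)
        ids0 = context_ids_of_records(bg0, genome, k_flank=1)
        r0 = bg0.records.assign(cid=ids0)
        rT = bgT.records.copy()
        merged = r0.merge(rT[["chrom", "strand", "pos5", "count"]],
                          on=["chrom", "strand", "pos5"], how="left",
                          suffixes=("0", "T"))
        merged["countT"] = merged["countT"].fillna(0)
        for cid, grp in merged.groupby("cid"):
            if cid < 0:
                continue
            pools[int(cid)] = (grp["count0"].to_numpy().astype(float),
                               grp["countT"].to_numpy().astype(float))
    elif kernel != "binomial":
        raise ValueError(f"unknown bootstrap kernel {kernel!r}")

    draws = np.zeros((n_boot, n_cells))
    flags = [""] * n_cells
    testable = np.zeros(n_cells, dtype=bool)
    for cell in range(n_cells):
        n0 = obs0[cell]
        if n0 <= 0:
            flags[cell] = "no_initial"
            continue
        classes = comp0.get(cell, {})
        bad = [cid for cid in classes
               if cid < 0 or not np.isfinite(surv[cid])]
        if bad:
            flags[cell] = "context_insufficient"
            log.info("cell %d excluded: contexts %s lack background survival",
                     cell, [id_to_kmer(c, 4) if c >= 0 else "NA" for c in bad])
            continue
        testable[cell] = True
        for cid, n_c in classes.items():
            n_c = int(round(n_c))
            if kernel == "binomial":
                draws[:, cell] += rng.binomial(n_c, surv[cid], size=n_boot)
            else:
                w0, wT = pools[cid]
                p_pick = w0 / w0.sum()
                picks = rng.choice(len(w0), size=(n_boot, n_c), p=p_pick)
                s_loc = np.minimum(wT[picks] / w0[picks], 1.0)
                draws[:, cell] += (rng.random((n_boot, n_c)) < s_loc).sum(axis=1)

    # flank scaling of the null, per strand and motif half
    span_lo = siteset.motif_span[0] - flank_margin
    span_hi = siteset.motif_span[1] + flank_margin
    positions = np.arange(-window, window + 1)
    boot_mean = draws.mean(axis=0)
    factors: dict[tuple[str, str], float] = {}
    scale = np.ones(n_cells)
    for sidx, strand in enumerate(STRANDS):
        for side in ("left", "right"):
            fmask = positions < span_lo if side == "left" else positions > span_hi
            amask = positions <= 0 if side == "left" else positions > 0
            fcells = (np.flatnonzero(fmask) * 2) + sidx
            fcells = fcells[testable[fcells] & (boot_mean[fcells] > 0)]
            if len(fcells) == 0:
                log.warning("repair flank_scale: no usable %s flank on %s strand",
                            side, strand)
                factor = 1.0
            else:
                factor = float(np.mean(obsT[fcells] / boot_mean[fcells]))
            factors[(strand, side)] = factor
            acells = (np.flatnonzero(amask) * 2) + sidx
            scale[acells] = factor
    draws *= scale[None, :]

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0)
    rows = []
    comp_out = {}
    for sidx, strand in enumerate(STRANDS):
        for pi, p in enumerate(positions):
            cell = pi * 2 + sidx
            row = {"position": int(p), "strand": strand, "observed": obsT[cell],
                   "initial_0h": obs0[cell], "boot_mean": mean[cell],
                   "boot_sd": sd[cell], "z": np.nan, "p": np.nan, "q": np.nan,
                   "direction": "none", "flag": flags[cell]}
            if testable[cell]:
                if sd[cell] > 0:
                    row["z"] = (obsT[cell] - mean[cell]) / sd[cell]
                elif obsT[cell] == mean[cell]:
                    row["z"] = 0.0  # degenerate null (e.g. survival = 1)
                row["p"] = float((1 + (draws[:, cell] >= obsT[cell]).sum()) / (n_boot + 1))
                row["direction"] = ("elevated" if obsT[cell] > mean[cell]
                                    else "reduced" if obsT[cell] < mean[cell] else "none")
                comp_out[(int(p), strand)] = {
                    id_to_kmer(cid, 4): int(round(n))
                    for cid, n in sorted(comp0.get(cell, {}).items())}
            rows.append(row)
    table = pd.DataFrame(rows)
    mask = table["p"].notna()
    if mask.any():
        _, q, _, _ = multipletests(table.loc[mask, "p"], method="fdr_bh")
        table.loc[mask, "q"] = q
    return RepairTestResult(siteset.cluster_id, window, n_boot, threshold,
                            table, comp_out, factors)


class MannWhitneyResult(NamedTuple):
    statistic: float
    pvalue: float


def context_efficiency_comparison(position_composition: dict[str, int],
                                  table: RepairEfficiencyTable) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U: position-weighted context efficiencies vs all.

    The first group repeats each context's efficiency by its lesion count at
    the position; the second holds every covered context once.
    """
    eff = table.efficiency_array()
    group1 = []
    for kmer, n in position_composition.items():
        e = eff[kmer_to_id(kmer)]
        if np.isfinite(e):
            group1.extend([e] * int(n))
    group2 = [e for e in eff[np.flatnonzero(table.centered_mask)] if np.isfinite(e)]
    if len(set(group1)) < 1 or len(group1) < 3 or len(group2) < 3:
        raise ValueError("need >= 3 context efficiencies per group")
    if set(group1) == set(group2) and len(set(group1)) == 1:
        return MannWhitneyResult(len(group1) * len(group2) / 2.0, 1.0)
    res = stats.mannwhitneyu(group1, group2, alternative="two-sided")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))
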
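"""Actual and CPD-projected C>T mutation profiles over binding sites.

The projection converts every cytosine inside an observed CPD into a C>T
event (a CC lesion projects a tandem CC>TT); the actual profile aggregates
reference C>T and G>A calls onto the pyrimidine strand. Profiles are
strand-aggregated per motif-relative position and span positions
[-window, window+1] so that both bases of a window-edge dipyrimidine are
kept (which makes the projection exactly conserve lesion-cytosine counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .damage import DamageMap, MutationTable
from .genome import GenomeSequence
from .intervals import IntervalSet
from .profiles import _site_cell_assignment
from .sites import BindingSiteSet

__all__ = [
    "project_mutations",
    "actual_mutation_profile",
    "cytosine_loci",
    "trinucleotide_shuffle_test",
    "ClusterConcordance",
    "concordance",
]

log = logging.getLogger(__name__)


def _profile_index(window: int) -> np.ndarray:
    return np.arange(-window, window + 2)


def project_mutations(damage_map: DamageMap, genome: GenomeSequence,
                      siteset: BindingSiteSet, window: int) -> pd.Series:
    """Projected C>T counts per position, assuming every lesion cytosine mutates.

    Each cytosine within a damaged dipyrimidine contributes the lesion count
    at its own motif-relative position; TT lesions contribute nothing.
    Strands are aggregated.
    """
    idx_range = _profile_index(window)
    out = pd.Series(0.0, index=idx_range)
    rec = damage_map.records
    if not len(rec):
        return out
    lo = np.where(rec["strand"].to_numpy() == "-", rec["pos5"].to_numpy() - 1,
                  rec["pos5"].to_numpy())
    idx, pos, sidx = _site_cell_assignment(
        siteset, rec["chrom"].to_numpy(), rec["strand"].to_numpy(), lo, window)
    dinucs = rec["dinuc"].to_numpy()[idx]
    counts = rec["count"].to_numpy()[idx]
    # 5' base of the dinucleotide sits at axis p on the motif strand (sidx 0)
    # and at p+1 on the complement strand (sidx 1)
    b0 = np.where(sidx == 0, pos, pos + 1)
    b1 = np.where(sidx == 0, pos + 1, pos)
    for b, baseidx in ((b0, 0), (b1, 1)):
        isC = np.array([d[baseidx] == "C" for d in dinucs])
        if isC.any():
            np.add.at(out.values, b[isC] + window, counts[isC])
    return out


def actual_mutation_profile(mutations: MutationTable, genome: GenomeSequence,
                            siteset: BindingSiteSet, window: int,
                            substitution_filter: str = "C>T") -> pd.Series:
    """Strand-aggregated observed mutation counts per motif-relative position.

    C>T on the reference and G>A (pyrimidine-strand C>T on the minus strand)
    are combined; ``substitution_filter="all"`` keeps every substitution for
    the broad flank analysis. Records whose ref base mismatches the genome
    are dropped with a logged count.
    """
    muts = mutations.filter_substitution(substitution_filter)
    idx_range = _profile_index(window)
    out = pd.Series(0.0, index=idx_range)
    rec = muts.records
    if not len(rec):
        return out
    ok = np.array([r.chrom in genome and 0 <= r.pos < genome.lengths[r.chrom]
                   and genome.base(r.chrom, int(r.pos)) == r.ref
                   for r in rec.itertuples()])
    if (~ok).any():
        log.info("actual_mutation_profile: dropped %d ref-mismatch records",
                 int((~ok).sum()))
        rec = rec.loc[ok]
    centers = siteset.centers
    s_chrom = siteset.sites["chrom"].to_numpy()
    s_strand = siteset.sites["strand"].to_numpy()
    for chrom, grp in rec.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        for c, sstr in zip(centers[s_chrom == chrom], s_strand[s_chrom == chrom]):
            lo, hi = c - window - 1, c + window + 1
            a, b = np.searchsorted(pos, [lo, hi + 1])
            if a == b:
                continue
            axis = pos[a:b] - c if sstr == "+" else c - pos[a:b]
            inr = (axis >= -window) & (axis <= window + 1)
            np.add.at(out.values, axis[inr] + window, 1)
    return out


def cytosine_loci(genome: GenomeSequence, regions: IntervalSet):
    """Every cytosine (either strand) in the regions with its trinucleotide id.

    The class is the pyrimidine-strand 3-mer centered on the C; loci whose
    flanking base is N or off-chromosome are skipped. Returns parallel
    arrays (chrom, strand, pos, tri_id).
    """
    chroms, strands, poss, ids = [], [], [], []
    for chrom in regions.chroms:
        if chrom not in genome:
            continue
        codes = genome.codes(chrom)
        n = len(codes)
        starts, ends = regions.arrays(chrom)
        for s0, e0 in zip(starts, ends):
            span = np.arange(max(1, int(s0)), min(n - 1, int(e0)))
            if not len(span):
                continue
            mid = codes[span]
            left = codes[span - 1].astype(np.int64)
            right = codes[span + 1].astype(np.int64)
            okf = (left < 4) & (right < 4)
            for gstrand, code in (("+", 1), ("-", 2)):
                m = (mid == code) & okf
                if not m.any():
                    continue
                p = span[m]
                if gstrand == "+":
                    tri = left[m] * 16 + 4 + right[m]
                else:
                    tri = (3 - right[m]) * 16 + 4 + (3 - left[m])
                chroms.append(np.full(m.sum(), chrom, dtype=object))
                strands.append(np.full(m.sum(), gstrand, dtype="U1"))
                poss.append(p)
                ids.append(tri)
    if not poss:
        e = np.empty(0, dtype=np.int64)
        return np.empty(0, dtype=object), np.empty(0, dtype="U1"), e, e
    return (np.concatenate(chroms), np.concatenate(strands),
            np.concatenate(poss).astype(np.int64), np.concatenate(ids))


def trinucleotide_shuffle_test(mutations: MutationTable, regions: IntervalSet,
                               genome: GenomeSequence, siteset: BindingSiteSet,
                               n_iter: int = 1000, seed: int = 0,
                               window: int = 40, threshold: float = 0.05,
                               flank_margin: int = 5,
                               chunk: int = 200) -> pd.DataFrame:
    """Context-preserving shuffle null for the C>T mutation profile.

    Each iteration reassigns every C>T occurrence to a uniformly drawn
    cytosine of the same trinucleotide class within the background regions.
    The null mean is flank-scaled per motif side; empirical p uses
    (k+1)/(n+1); BH across positions. Returns a per-position table
    (position, observed, null_mean, null_sd, z, p, q, direction).
    """
    rng = np.random.default_rng(seed)
    muts = mutations.filter_substitution("C>T")
    l_chrom, l_strand, l_pos, l_tri = cytosine_loci(genome, regions)
    n_loci = len(l_pos)
    idx_range = _profile_index(window)
    n_cells = len(idx_range)

    # locus -> profile cell (-1 outside all windows)
    cell_of_locus = np.full(n_loci, -1, dtype=np.int64)
    centers = siteset.centers
    s_chrom = siteset.sites["chrom"].to_numpy()
    s_strand = siteset.sites["strand"].to_numpy()
    order = np.lexsort((l_pos, l_chrom.astype(str)))
    for chrom in np.unique(s_chrom):
        cmask = l_chrom[order].astype(str) == chrom
        sub = order[cmask]
        sub_pos = l_pos[sub]
        for c, sstr in zip(centers[s_chrom == chrom], s_strand[s_chrom == chrom]):
            a, b = np.searchsorted(sub_pos, [c - window - 1, c + window + 2])
            if a == b:
                continue
            axis = sub_pos[a:b] - c if sstr == "+" else c - sub_pos[a:b]
            inr = (axis >= -window) & (axis <= window + 1)
            cell_of_locus[sub[a:b][inr]] = axis[inr] + window

    # map mutation occurrences to loci
    key = pd.DataFrame({"chrom": l_chrom, "strand": l_strand, "pos": l_pos,
                        "locus": np.arange(n_loci)})
    rec = muts.records.copy()
    rec["strand"] = np.where(rec["ref"] == "C", "+", "-")
    merged = rec.merge(key, on=["chrom", "strand", "pos"], how="left")
    matched = merged["locus"].notna().to_numpy()
    if (~matched).any():
        log.info("trinucleotide_shuffle_test: %d occurrences outside the locus set "
                 "stay put", int((~matched).sum()))
    rec_locus = merged["locus"].to_numpy()[matched].astype(np.int64)
    rec_tri = l_tri[rec_locus]

    obs = np.zeros(n_cells)
    cells = cell_of_locus[rec_locus]
    np.add.at(obs, cells[cells >= 0], 1)

    groups = []
    for tri in np.unique(rec_tri):
        ridx = np.flatnonzero(rec_tri == tri)
        pool = np.flatnonzero(l_tri == tri)
        if len(pool) < 2:
            log.info("trinucleotide class %d has a single locus; records stay put", tri)
            continue
        groups.append((ridx, pool))

    # draws are kept (n_iter x n_cells is small) so the flank factor can be
    # applied to the whole null after the unscaled mean is known
    all_draws = []
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        draws = np.zeros((m, n_cells))
        for ridx, pool in groups:
            pick = pool[rng.integers(0, len(pool), size=(m, len(ridx)))]
            cc = cell_of_locus[pick]
            ok = cc >= 0
            rows = np.broadcast_to(np.arange(m)[:, None], cc.shape)[ok]
            flat = rows * n_cells + cc[ok]
            draws += np.bincount(flat, minlength=m * n_cells).reshape(m, n_cells)
        all_draws.append(draws)
        done += m
    draws = np.concatenate(all_draws, axis=0)

    span_lo = siteset.motif_span[0] - flank_margin
    span_hi = siteset.motif_span[1] + flank_margin
    mean0 = draws.mean(axis=0)
    scale = np.ones(n_cells)
    for side in ("left", "right"):
        fmask = idx_range < span_lo if side == "left" else idx_range > span_hi
        amask = idx_range <= 0 if side == "left" else idx_range > 0
        usable = fmask & (mean0 > 0)
        factor = float(np.mean(obs[usable] / mean0[usable])) if usable.any() else 1.0
        scale[amask] = factor
    draws = draws * scale[None, :]

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0)
    rows = []
    for ci, p in enumerate(idx_range):
        row = {"position": int(p), "observed": obs[ci], "null_mean": mean[ci],
               "null_mean_unscaled": mean0[ci],
               "null_sd": sd[ci], "z": np.nan, "p": np.nan, "q": np.nan,
               "direction": "none"}
        if sd[ci] > 0:
            row["z"] = (obs[ci] - mean[ci]) / sd[ci]
        if mean[ci] > 0 or obs[ci] > 0:
            if obs[ci] > mean[ci]:
                row["direction"] = "enriched"
                row["p"] = (1 + (draws[:, ci] >= obs[ci]).sum()) / (n_iter + 1)
            elif obs[ci] < mean[ci]:
                row["direction"] = "depleted"
                row["p"] = (1 + (draws[:, ci] <= obs[ci]).sum()) / (n_iter + 1)
            else:
                row["p"] = 1.0
        rows.append(row)
    table = pd.DataFrame(rows)
    mask = table["p"].notna()
    if mask.any():
        _, q, _, _ = multipletests(table.loc[mask, "p"], method="fdr_bh")
        table.loc[mask, "q"] = q
    return table


@dataclass
class ClusterConcordance:
    """Projected-vs-actual concordance for one cluster."""

    r: float
    slope: float
    intercept: float
    residual_z: pd.Series
    discordant: list[int]
    baseline_r: float = np.nan
    baseline_rs: list = field(default_factory=list)


def concordance(projected: pd.Series, actual: pd.Series,
                all_actual: dict[str, pd.Series] | None = None,
                n_random: int = 5, seed: int = 0,
                z_cut: float = 2.58) -> ClusterConcordance:
    """Pearson r, OLS fit, residual z discordance, and a randomized baseline.

    Residual z = OLS residual / SD(residuals); positions with |z| > 2.58 are
    discordant. The baseline is the mean Pearson r of this projected profile
    against ``n_random`` other clusters' actual profiles. Zero variance in
    either profile yields r = NaN; SD(residuals) = 0 sets all z to 0.
    """
    common = projected.index.intersection(actual.index)
    if len(common) < 5:
        raise ValueError("need at least 5 shared positions")
    x = projected.loc[common].to_numpy(dtype=float)
    y = actual.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        r = np.nan
        slope = intercept = np.nan
        resid_z = pd.Series(0.0, index=common)
        disc = []
    else:
        r = float(stats.pearsonr(x, y).statistic)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = (float(v) for v in model.params)
        resid = model.resid
        sd = float(np.std(resid))
        # an exact affine relation leaves only float noise; don't divide by it
        tol = 1e-9 * max(1.0, float(np.abs(y).max()))
        z = resid / sd if sd > tol else np.zeros_like(resid)
        resid_z = pd.Series(z, index=common)
        disc = [int(p) for p in common[np.abs(z) > z_cut]]
    baseline_rs: list[float] = []
    baseline = np.nan
    if all_actual:
        rng = np.random.default_rng(seed)
        names = sorted(all_actual)
        take = min(n_random, len(names))
        for name in rng.choice(names, size=take, replace=False):
            other = all_actual[name]
            com = projected.index.intersection(other.index)
            xo = projected.loc[com].to_numpy(dtype=float)
            yo = other.loc[com].to_numpy(dtype=float)
            if np.std(xo) > 0 and np.std(yo) > 0:
                baseline_rs.append(float(stats.pearsonr(xo, yo).statistic))
        baseline = float(np.mean(baseline_rs)) if baseline_rs else np.nan
    return ClusterConcordance(r, slope, intercept, resid_z, disc, baseline, baseline_rs)
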
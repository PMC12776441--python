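"""Per-position damage profiles over TF binding sites and enrichment tests.

The analysis compares the observed lesion count at every motif-relative
position, on both the motif and motif-complement strands, with the count
expected from the sequence-context Poisson background model (sum over sites
of per-hexamer rates). The expectation is rescaled by the observed/expected
ratio in the DNA flanking the motif (separately per strand and motif half)
to absorb local covariates, and each cell is then given a one-sided Poisson
p-value, a z-score, and a BH-adjusted q-value. An orthogonal shuffle null
(context-preserving reassignment of lesions within background regions) is
provided as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background import (ContextRateTable, context_ids_of_records,
                         dipyrimidine_loci, revcomp_id_table, _pow4)
from .damage import DamageMap
from .genome import GenomeSequence
from .intervals import GenomicInterval, IntervalSet
from .sites import BindingSiteSet

__all__ = [
    "CurationConfig",
    "PositionProfile",
    "read_narrowpeak",
    "build_accessible_regions",
    "curate_active_sites",
    "stratify_by_strength",
    "observed_profile",
    "expected_profile",
    "flank_scale",
    "poisson_position_test",
    "shuffle_null_test",
    "naked_dna_filter",
    "analyze_formation",
]

log = logging.getLogger(__name__)

STRANDS = ("motif", "complement")


@dataclass
class CurationConfig:
    """Curation and testing parameters.

    window_halfwidth: profile window, +/- bases from the motif center
        (40 for formation, 30 for the repair analysis).
    flank_margin: binding-site span is motif +/- this many bases; positions
        outside it (but in the window) are the scaling flanks.
    top_fraction: fraction of accessible sites kept, highest score first.
    site_cap: optional per-cluster cap on site count (e.g. 10,000 for CTCF).
    min_aggregate: minimum max-position aggregate count for a cluster to be
        testable (limit of detection).
    threshold: BH q-value significance cutoff (0.05 for CPD, 0.01 for 6-4 PP).
    k_flank: context half-width of the background model (2 = hexanucleotide).
    """

    window_halfwidth: int = 40
    flank_margin: int = 5
    top_fraction: float = 0.5
    site_cap: int | None = None
    min_aggregate: int = 30
    threshold: float = 0.05
    k_flank: int = 2

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0,1)")
        if self.window_halfwidth < 1 or self.flank_margin < 0:
            raise ValueError("window/margin must be positive")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0,1]")


@dataclass
class PositionProfile:
    """Per (motif-relative position, strand) profile and test results.

    ``table`` columns: position, strand, observed, expected, scaled, factor,
    z, p, q, direction, flag. ``factors`` holds the four flank scale factors
    keyed (strand, side).
    """

    cluster_id: str
    window: int
    motif_span: tuple[int, int]
    n_sites: int
    threshold: float
    table: pd.DataFrame
    factors: dict = field(default_factory=dict)
    insufficient: bool = False

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[(t["q"] < self.threshold) & (t["direction"] != "none")]

    def max_aggregate(self) -> int:
        return int(self.table["observed"].max()) if len(self.table) else 0

    def signed_max_z(self) -> pd.Series:
        """Per position, the z with the largest magnitude across strands
        (the heatmap cell-value convention)."""
        def pick(grp):
            z = grp["z"].to_numpy()
            if np.all(np.isnan(z)):
                return np.nan
            return z[np.nanargmax(np.abs(z))]
        return self.table.groupby("position").apply(pick, include_groups=False)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cluster={self.cluster_id} window={self.window} "
                     f"motif_span={self.motif_span[0]}..{self.motif_span[1]} "
                     f"n_sites={self.n_sites} threshold={self.threshold} "
                     f"insufficient={self.insufficient}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# -- curation ------------------------------------------------------------


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read ENCODE narrowPeak (BED6+4); requires the summit offset column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 10:
        raise ValueError(f"{path}: narrowPeak needs 10 columns (summit offset missing)")
    df.columns = ["chrom", "start", "end", "name", "score", "strand",
                  "signal", "pvalue", "qvalue", "summit"][: df.shape[1]]
    return df


def build_accessible_regions(peaks: pd.DataFrame | str | Path,
                             genic: IntervalSet | None = None,
                             top_fraction: float = 0.5,
                             summit_width: int = 150) -> IntervalSet:
    """Summit-centered windows of the strongest peaks, minus genic DNA.

    Peaks are ranked by signal; the top fraction (ceiling) is kept and
    replaced by ``summit_width`` windows centered on the summit. Genic
    intervals are subtracted, which may truncate or split windows.
    """
    if not isinstance(peaks, pd.DataFrame):
        peaks = read_narrowpeak(peaks)
    if "summit" not in peaks.columns:
        raise ValueError("peaks table lacks a summit column")
    n_keep = int(np.ceil(len(peaks) * top_fraction))
    ranked = peaks.sort_values(["signal", "chrom", "start"],
                               ascending=[False, True, True], kind="stable").head(n_keep)
    half = summit_width // 2
    ivs = []
    for r in ranked.itertuples():
        sa = int(r.start) + int(r.summit)
        lo = max(0, sa - half)
        ivs.append(GenomicInterval(r.chrom, lo, sa + half))
    out = IntervalSet(ivs)
    if genic is not None:
        out = out.subtract(genic)
    return out


def curate_active_sites(sites: BindingSiteSet, accessible: IntervalSet,
                        config: CurationConfig) -> BindingSiteSet:
    """Accessible sites, top fraction by motif score, optional cap.

    The minimum-aggregate-signal filter is applied downstream against the
    observed profile (it needs the damage map), dropping whole clusters.
    """
    kept = sites.filter_overlapping(accessible).sorted_by_score()
    n_top = int(np.ceil(len(kept) * config.top_fraction))
    kept = kept.head(n_top)
    if config.site_cap is not None:
        kept = kept.head(config.site_cap)
    if not len(kept):
        log.warning("cluster %s: no sites survive curation (insufficient)", sites.cluster_id)
    return kept


def stratify_by_strength(sites: BindingSiteSet, n_tiers: int = 3) -> list[BindingSiteSet]:
    """Equal-size (+/-1) tiers by descending motif score; remainder to the top tier."""
    if len(sites) < n_tiers:
        raise ValueError(f"{len(sites)} sites cannot fill {n_tiers} tiers")
    ranked = sites.sorted_by_score()
    base, rem = divmod(len(ranked), n_tiers)
    sizes = [base + (1 if i < rem else 0) for i in range(n_tiers)]
    tiers, at = [], 0
    for sz in sizes:
        tiers.append(sites._replace(ranked.sites.iloc[at:at + sz]))
        at += sz
    return tiers


# -- profile construction ------------------------------------------------


def _site_cell_assignment(siteset: BindingSiteSet, chrom: np.ndarray,
                          strand: np.ndarray, lo: np.ndarray, window: int):
    """Map stranded dinucleotide loci to profile cells.

    Returns (locus_index, position, strand_index) triples; a locus hitting
    several site windows yields several triples. Position is the lower axis
    coordinate of the dinucleotide; strand_index 0 = motif, 1 = complement.
    """
    out_idx, out_pos, out_sidx = [], [], []
    centers = siteset.centers
    site_strand = siteset.sites["strand"].to_numpy()
    site_chrom = siteset.sites["chrom"].to_numpy()
    order = np.lexsort((lo, chrom.astype(str)))
    chrom_s, lo_s, strand_s = chrom[order], lo[order], strand[order]
    for chrom_name in np.unique(site_chrom):
        cmask = chrom_s == chrom_name
        sub_lo = lo_s[cmask]
        sub_strand = strand_s[cmask]
        sub_idx = order[cmask]
        for c, sstr in zip(centers[site_chrom == chrom_name],
                           site_strand[site_chrom == chrom_name]):
            if sstr == "+":
                lo_min, lo_max = c - window, c + window
            else:
                lo_min, lo_max = c - window - 1, c + window - 1
            a = np.searchsorted(sub_lo, lo_min, side="left")
            b = np.searchsorted(sub_lo, lo_max, side="right")
            if a == b:
                continue
            ls = sub_lo[a:b]
            pos = ls - c if sstr == "+" else c - ls - 1
            sidx = (sub_strand[a:b] != sstr).astype(np.int64)
            out_idx.append(sub_idx[a:b])
            out_pos.append(pos)
            out_sidx.append(sidx)
    if not out_idx:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    return (np.concatenate(out_idx), np.concatenate(out_pos),
            np.concatenate(out_sidx))


def observed_profile(siteset: BindingSiteSet, damage_map: DamageMap,
                     window: int) -> np.ndarray:
    """Summed lesion counts per (position, strand); shape (2*window+1, 2).

    Minus-strand motif sites are flipped into motif coordinates; a lesion is
    registered at the lower axis coordinate of its dinucleotide ("i/i+1").
    """
    obs = np.zeros((2 * window + 1, 2))
    rec = damage_map.records
    if not len(rec):
        return obs
    lo = np.where(rec["strand"].to_numpy() == "-", rec["pos5"].to_numpy() - 1,
                  rec["pos5"].to_numpy())
    idx, pos, sidx = _site_cell_assignment(
        siteset, rec["chrom"].to_numpy(), rec["strand"].to_numpy(), lo, window)
    counts = rec["count"].to_numpy()[idx]
    np.add.at(obs, (pos + window, sidx), counts)
    return obs


def _oriented_codes(siteset: BindingSiteSet, genome: GenomeSequence,
                    window: int, f: int) -> np.ndarray:
    """(n_sites, 2*window+2f+2) motif-axis-oriented code matrix.

    Row i column j holds the motif-strand base code at axis position
    j - window - f; 255 marks N or off-chromosome.
    """
    M = 2 * window + 2 * f + 2
    out = np.full((len(siteset), M), 255, dtype=np.uint8)
    centers = siteset.centers
    strands = siteset.sites["strand"].to_numpy()
    chroms = siteset.sites["chrom"].to_numpy()
    for i, (chrom, c, s) in enumerate(zip(chroms, centers, strands)):
        codes = genome.codes(chrom)
        n = len(codes)
        if s == "+":
            lo, hi = c - window - f, c + window + f + 2
            seg = codes[max(0, lo):min(n, hi)]
            at = max(0, -lo)
            out[i, at:at + len(seg)] = seg
        else:
            lo, hi = c - window - f - 1, c + window + f + 1
            seg = codes[max(0, lo):min(n, hi)]
            seg = np.where(seg < 4, 3 - seg, seg)[::-1]  # complement, reverse
            at = max(0, hi - n)
            out[i, at:at + len(seg)] = seg
    return out


def expected_profile(siteset: BindingSiteSet, genome: GenomeSequence,
                     rate_table: ContextRateTable, window: int) -> np.ndarray:
    """Poisson-sum expectation per (position, strand); shape (2*window+1, 2).

    lambda(p, strand) sums the background rate of the context at axis
    positions (p, p+1) over all sites; positions without a dipyrimidine, or
    with unavailable context, contribute 0. Uncovered k-mers contribute 0
    and are logged once.
    """
    f = rate_table.k_flank
    width = 2 * f + 2
    rates = rate_table.rate_array()
    uncovered = rate_table.uncovered
    rc = revcomp_id_table(width)
    p4 = _pow4(width)
    ori = _oriented_codes(siteset, genome, window, f)
    lam = np.zeros((2 * window + 1, 2))
    n_uncovered_hits = 0
    py = np.array([1, 3])
    pu = np.array([0, 2])
    for p in range(-window, window + 1):
        j0 = p + window  # window columns [j0, j0+width)
        win = ori[:, j0:j0 + width].astype(np.int64)
        valid = (win < 4).all(axis=1)
        c1, c2 = win[:, f], win[:, f + 1]
        ids = win @ p4
        m_motif = valid & np.isin(c1, py) & np.isin(c2, py)
        m_comp = valid & np.isin(c1, pu) & np.isin(c2, pu)
        if m_motif.any():
            sel = ids[m_motif]
            lam[p + window, 0] = rates[sel].sum()
            n_uncovered_hits += int(uncovered[sel].sum())
        if m_comp.any():
            sel = rc[ids[m_comp]]
            lam[p + window, 1] = rates[sel].sum()
            n_uncovered_hits += int(uncovered[sel].sum())
    if n_uncovered_hits:
        log.info("expected_profile: %d site-position contexts uncovered in the "
                 "rate table (contributed 0)", n_uncovered_hits)
    return lam


def flank_scale(observed: np.ndarray, expected: np.ndarray,
                motif_span: tuple[int, int], window: int,
                flank_margin: int = 5):
    """Rescale the expectation by observed/expected in the motif flanks.

    Four factors, one per (strand, side): the mean over usable flank
    positions (outside motif +/- flank_margin, inside the window, expected >
    0) of observed/expected. Positions at axis <= 0 are scaled by the left
    factor, positions > 0 by the right (center column to the left half);
    flank positions use their own side's factor. A side with no usable flank
    position gets factor 1.0 with a warning.
    """
    span_lo = motif_span[0] - flank_margin
    span_hi = motif_span[1] + flank_margin
    positions = np.arange(-window, window + 1)
    scaled = np.array(observed, dtype=float) * 0.0
    factors: dict[tuple[str, str], float] = {}
    for sidx, strand in enumerate(STRANDS):
        for side in ("left", "right"):
            if side == "left":
                fmask = positions < span_lo
                amask = positions <= 0
            else:
                fmask = positions > span_hi
                amask = positions > 0
            lam = expected[fmask, sidx]
            obs = observed[fmask, sidx]
            usable = lam > 0
            if usable.sum() == 0:
                log.warning("flank_scale: no usable %s flank on %s strand; factor 1.0",
                            side, strand)
                factor = 1.0
            else:
                factor = float(np.mean(obs[usable] / lam[usable]))
            factors[(strand, side)] = factor
            scaled[amask, sidx] = expected[amask, sidx] * factor
    return scaled, factors


# -- testing -------------------------------------------------------------


def poisson_position_test(observed: np.ndarray, scaled: np.ndarray,
                          window: int, threshold: float,
                          cluster_id: str = "", motif_span: tuple[int, int] = (0, 0),
                          n_sites: int = 0, expected: np.ndarray | None = None,
                          factors: dict | None = None) -> PositionProfile:
    """One-sided Poisson test of every profile cell against its scaled mean.

    direction = sign(observed - scaled); p is the corresponding Poisson tail
    (P(X >= obs) for enrichment, P(X <= obs) for depletion); z = (obs -
    lambda')/sqrt(lambda'). BH is applied jointly over all testable cells of
    the window (both strands); cells with lambda' = 0 are excluded from BH
    and flagged ("model_gap" if they carry observed signal).
    """
    positions = np.arange(-window, window + 1)
    rows = []
    for sidx, strand in enumerate(STRANDS):
        for pi, p in enumerate(positions):
            X = float(observed[pi, sidx])
            lam = float(scaled[pi, sidx])
            row = {"position": int(p), "strand": strand, "observed": X,
                   "expected": float(expected[pi, sidx]) if expected is not None else np.nan,
                   "scaled": lam, "z": np.nan, "p": np.nan, "q": np.nan,
                   "direction": "none", "flag": ""}
            if lam > 0:
                row["z"] = (X - lam) / np.sqrt(lam)
                if X > lam:
                    row["direction"] = "enriched"
                    row["p"] = float(stats.poisson.sf(X - 1, lam))
                elif X < lam:
                    row["direction"] = "depleted"
                    row["p"] = float(stats.poisson.cdf(X, lam))
                else:
                    row["p"] = 1.0
            else:
                row["flag"] = "model_gap" if X > 0 else "untestable"
            rows.append(row)
    table = pd.DataFrame(rows)
    testable = table["p"].notna()
    if testable.any():
        _, q, _, _ = multipletests(table.loc[testable, "p"], method="fdr_bh")
        table.loc[testable, "q"] = q
    return PositionProfile(cluster_id, window, motif_span, n_sites, threshold,
                           table, factors or {})


def analyze_formation(siteset: BindingSiteSet, damage_map: DamageMap,
                      genome: GenomeSequence, rate_table: ContextRateTable,
                      config: CurationConfig) -> PositionProfile:
    """Observed vs flank-scaled expected profile with per-cell tests.

    Clusters whose best position carries fewer than ``config.min_aggregate``
    lesions are marked insufficient (tests still reported).
    """
    w = config.window_halfwidth
    obs = observed_profile(siteset, damage_map, w)
    lam = expected_profile(siteset, genome, rate_table, w)
    scaled, factors = flank_scale(obs, lam, siteset.motif_span, w, config.flank_margin)
    prof = poisson_position_test(obs, scaled, w, config.threshold,
                                 siteset.cluster_id, siteset.motif_span,
                                 len(siteset), expected=lam, factors=factors)
    if obs.max(initial=0) < config.min_aggregate:
        prof.insufficient = True
        log.warning("cluster %s: max aggregate %d below detection limit %d",
                    siteset.cluster_id, int(obs.max(initial=0)), config.min_aggregate)
    return prof


def shuffle_null_test(damage_map: DamageMap, regions: IntervalSet,
                      genome: GenomeSequence, siteset: BindingSiteSet,
                      n_iter: int, seed: int, window: int = 40,
                      threshold: float = 0.05, k_flank: int = 1,
                      chunk: int = 200) -> PositionProfile:
    """Context-preserving shuffle null for the same per-cell comparison.

    Each iteration reassigns every damage record (keeping its count) to a
    uniformly drawn dipyrimidine locus of the same NYYN class within the
    background regions. Per-cell null mean/SD give z; the empirical p uses
    the (k+1)/(n+1) convention; BH across the window. Records whose class
    has a single locus, or whose context is unavailable, stay put (they
    shift observed and null equally and are dropped from the shuffle).
    """
    rng = np.random.default_rng(seed)
    loci = dipyrimidine_loci(genome, regions, k_flank)
    n_cells = (2 * window + 1) * 2
    l_idx, l_pos, l_sidx = _site_cell_assignment(siteset, loci.chrom, loci.strand,
                                                 loci.lo, window)
    cell_of_locus = np.full(len(loci), -1, dtype=np.int64)
    if len(np.unique(l_idx)) != len(l_idx):
        log.warning("shuffle_null_test: overlapping site windows; loci keep their "
                    "first window assignment")
    cell_of_locus[l_idx] = (l_pos + window) * 2 + l_sidx

    dmap = damage_map.filter_to_regions(regions, contained=True)
    rec = dmap.records
    class_ids = context_ids_of_records(dmap, genome, k_flank)
    counts = rec["count"].to_numpy().astype(float)
    lo = np.where(rec["strand"].to_numpy() == "-", rec["pos5"].to_numpy() - 1,
                  rec["pos5"].to_numpy())

    # observed counts through the same locus->cell mapping
    key = pd.DataFrame({"chrom": loci.chrom, "strand": loci.strand, "lo": loci.lo,
                        "locus": np.arange(len(loci))})
    rkey = pd.DataFrame({"chrom": rec["chrom"].to_numpy(),
                         "strand": rec["strand"].to_numpy(), "lo": lo})
    merged = rkey.merge(key, on=["chrom", "strand", "lo"], how="left")
    rec_locus = merged["locus"].to_numpy()
    matched = ~pd.isna(rec_locus)
    obs = np.zeros(n_cells)
    cells_obs = cell_of_locus[rec_locus[matched].astype(np.int64)]
    inwin = cells_obs >= 0
    np.add.at(obs, cells_obs[inwin], counts[matched][inwin])

    # shuffleable records: matched to a locus, class has >= 2 loci
    class_loci: dict[int, np.ndarray] = {}
    for cid in np.unique(loci.kmer_id):
        class_loci[int(cid)] = np.flatnonzero(loci.kmer_id == cid)
    shuffleable = matched & (class_ids >= 0)
    n_static = 0
    groups = []
    for cid in np.unique(class_ids[shuffleable]):
        ridx = np.flatnonzero(shuffleable & (class_ids == cid))
        pool = class_loci.get(int(cid), np.empty(0, dtype=np.int64))
        if len(pool) < 2:
            n_static += len(ridx)
            continue
        groups.append((ridx, pool))
    n_static += int((~shuffleable).sum())
    if n_static:
        log.info("shuffle_null_test: %d records stay put (singleton class or "
                 "unavailable context)", n_static)

    null_sum = np.zeros(n_cells)
    null_sq = np.zeros(n_cells)
    ge_obs = np.zeros(n_cells)
    le_obs = np.zeros(n_cells)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        draws = np.zeros((m, n_cells))
        for ridx, pool in groups:
            pick = pool[rng.integers(0, len(pool), size=(m, len(ridx)))]
            cells = cell_of_locus[pick]
            w_counts = np.broadcast_to(counts[ridx], (m, len(ridx)))
            ok = cells >= 0
            rows = np.broadcast_to(np.arange(m)[:, None], cells.shape)[ok]
            flat = rows * n_cells + cells[ok]
            draws += np.bincount(flat, weights=w_counts[ok],
                                 minlength=m * n_cells).reshape(m, n_cells)
        null_sum += draws.sum(axis=0)
        null_sq += (draws ** 2).sum(axis=0)
        ge_obs += (draws >= obs[None, :]).sum(axis=0)
        le_obs += (draws <= obs[None, :]).sum(axis=0)
        done += m

    mean = null_sum / n_iter
    var = np.maximum(null_sq / n_iter - mean ** 2, 0.0)
    sd = np.sqrt(var)
    positions = np.arange(-window, window + 1)
    rows = []
    has_locus = np.zeros(n_cells, dtype=bool)
    has_locus[cell_of_locus[cell_of_locus >= 0]] = True
    for sidx, strand in enumerate(STRANDS):
        for pi, p in enumerate(positions):
            cell = pi * 2 + sidx
            X = obs[cell]
            row = {"position": int(p), "strand": strand, "observed": X,
                   "expected": mean[cell], "scaled": mean[cell],
                   "z": np.nan, "p": np.nan, "q": np.nan,
                   "direction": "none", "flag": "" if has_locus[cell] else "untestable"}
            if has_locus[cell]:
                if sd[cell] > 0:
                    row["z"] = (X - mean[cell]) / sd[cell]
                if X > mean[cell]:
                    row["direction"] = "enriched"
                    row["p"] = (1 + ge_obs[cell]) / (n_iter + 1)
                elif X < mean[cell]:
                    row["direction"] = "depleted"
                    row["p"] = (1 + le_obs[cell]) / (n_iter + 1)
                else:
                    row["p"] = 1.0
            rows.append(row)
    table = pd.DataFrame(rows)
    testable = table["p"].notna()
    if testable.any():
        _, q, _, _ = multipletests(table.loc[testable, "p"], method="fdr_bh")
        table.loc[testable, "q"] = q
    return PositionProfile(siteset.cluster_id, window, siteset.motif_span,
                           len(siteset), threshold, table)


def naked_dna_filter(cell_profile: PositionProfile,
                     naked_profile: PositionProfile) -> PositionProfile:
    """Demote cellular calls that replicate in naked DNA.

    Cells significant in both profiles at the same (position, strand) with
    the same direction are labelled "sequence-intrinsic" (kept in the
    output); same cell but opposite direction is kept and flagged.
    """
    naked = naked_profile.table.set_index(["position", "strand"])
    table = cell_profile.table.copy()
    labels = []
    for r in table.itertuples():
        label = ""
        if r.q == r.q and r.q < cell_profile.threshold and r.direction != "none":
            key = (r.position, r.strand)
            if key in naked.index:
                nk = naked.loc[key]
                if nk["q"] == nk["q"] and nk["q"] < naked_profile.threshold \
                        and nk["direction"] != "none":
                    label = ("sequence-intrinsic" if nk["direction"] == r.direction
                             else "naked-direction-mismatch")
        labels.append(label)
    table["label"] = labels
    out = PositionProfile(cell_profile.cluster_id, cell_profile.window,
                          cell_profile.motif_span, cell_profile.n_sites,
                          cell_profile.threshold, table, cell_profile.factors,
                          cell_profile.insufficient)
    return out
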
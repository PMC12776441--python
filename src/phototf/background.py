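"""Sequence-context damage rate tables and the Poisson background model.

The model treats lesion formation at each dipyrimidine locus as an
independent Poisson draw whose rate depends only on the pyrimidine-centered
k-mer context (NYYN for k_flank=1, NNYYNN for k_flank=2), estimated as
total damages / total occurrences over a background region set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .damage import DamageMap
from .genome import CODE_TO_BASE, BASE_TO_CODE, GenomeSequence
from .intervals import IntervalSet

__all__ = [
    "ContextRateTable",
    "DipyrimidineLoci",
    "dipyrimidine_loci",
    "count_context_occurrences",
    "estimate_context_rates",
    "context_ids_of_records",
    "ks_poisson_check",
    "flank_effect_test",
    "kmer_to_id",
    "id_to_kmer",
]

log = logging.getLogger(__name__)

_PY_CODES = np.array([1, 3])  # C, T


def _pow4(width: int) -> np.ndarray:
    # first base is the most significant digit
    return 4 ** np.arange(width - 1, -1, -1, dtype=np.int64)


def kmer_to_id(kmer: str) -> int:
    codes = BASE_TO_CODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError(f"non-ACGT k-mer {kmer!r}")
    return int(codes.astype(np.int64) @ _pow4(len(kmer)))

def id_to_kmer(idx: int, width: int) -> str:
    digits = (idx // _pow4(width)) % 4
    return "".join(CODE_TO_BASE[digits])


def revcomp_id_table(width: int) -> np.ndarray:
    """id -> id of the reverse complement k-mer, for all 4^width ids."""
    ids = np.arange(4 ** width, dtype=np.int64)
    digits = (ids[:, None] // _pow4(width)[None, :]) % 4
    rc = (3 - digits)[:, ::-1]
    return rc @ _pow4(width)


def pyrimidine_centered_mask(k_flank: int) -> np.ndarray:
    """Mask over 4^(2k+2) ids whose two central bases are both C/T."""
    width = 2 * k_flank + 2
    ids = np.arange(4 ** width, dtype=np.int64)
    p = _pow4(width)
    c1 = (ids // p[k_flank]) % 4
    c2 = (ids // p[k_flank + 1]) % 4
    return np.isin(c1, _PY_CODES) & np.isin(c2, _PY_CODES)


def _window_ids(codes: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding k-mer ids over a code array; (ids, valid) with N windows invalid."""
    if len(codes) < width:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = sliding_window_view(codes, width)
    valid = (win < 4).all(axis=1)
    ids = win.astype(np.int64) @ _pow4(width)
    return ids, valid


class DipyrimidineLoci(NamedTuple):
    """Flat enumeration of dipyrimidine loci: parallel arrays."""

    chrom: np.ndarray   # str array
    strand: np.ndarray  # '+'/'-'
    lo: np.ndarray      # lower reference coordinate of the dinucleotide
    kmer_id: np.ndarray # context id (width 2*k_flank+2), read on the damaged strand

    def __len__(self) -> int:
        return len(self.lo)


def dipyrimidine_loci(genome: GenomeSequence, regions: IntervalSet,
                      k_flank: int) -> DipyrimidineLoci:
    """Enumerate every dipyrimidine (both strands) whose two central bases lie
    inside a region. Flanks may extend past region edges into the genome;
    windows with N or crossing a chromosome end are skipped."""
    f = k_flank
    width = 2 * f + 2
    rc = revcomp_id_table(width)
    chroms, strands, los, ids = [], [], [], []
    for chrom in regions.chroms:
        if chrom not in genome:
            continue
        codes = genome.codes(chrom)
        n = len(codes)
        starts, ends = regions.arrays(chrom)
        for s, e in zip(starts, ends):
            # central dinucleotide at (p, p+1), both in [s, e)
            p_lo, p_hi = int(s), int(e) - 2
            if p_hi < p_lo:
                continue
            w_lo = p_lo - f
            w_hi = p_hi + 2 + f
            pad_l = max(0, -w_lo)
            pad_r = max(0, w_hi - n)
            sub = codes[max(0, w_lo):min(n, w_hi)]
            if pad_l or pad_r:
                sub = np.concatenate([
                    np.full(pad_l, 255, np.uint8), sub, np.full(pad_r, 255, np.uint8)])
            wids, valid = _window_ids(sub, width)
            if not len(wids):
                continue
            ps = np.arange(p_lo, p_hi + 1)
            c1 = codes[p_lo:p_hi + 1]
            c2 = codes[p_lo + 1:p_hi + 2]
            plus = valid & np.isin(c1, _PY_CODES) & np.isin(c2, _PY_CODES)
            minus = valid & np.isin(c1, (0, 2)) & np.isin(c2, (0, 2))
            for strand, mask, table in (("+", plus, None), ("-", minus, rc)):
                if not mask.any():
                    continue
                sel = np.flatnonzero(mask)
                kid = wids[sel] if table is None else table[wids[sel]]
                chroms.append(np.full(len(sel), chrom, dtype=object))
                strands.append(np.full(len(sel), strand, dtype="U1"))
                los.append(ps[sel])
                ids.append(kid)
    if not los:
        empty = np.empty(0, dtype=np.int64)
        return DipyrimidineLoci(np.empty(0, dtype=object), np.empty(0, dtype="U1"), empty, empty)
    return DipyrimidineLoci(
        np.concatenate(chroms), np.concatenate(strands),
        np.concatenate(los).astype(np.int64), np.concatenate(ids))


def count_context_occurrences(genome: GenomeSequence, regions: IntervalSet,
                              k_flank: int) -> np.ndarray:
    """Occurrences of every pyrimidine-centered k-mer (both strands) in regions,
    as an array indexed by k-mer id."""
    if regions.is_empty():
        raise ValueError("empty region set")
    loci = dipyrimidine_loci(genome, regions, k_flank)
    width = 2 * k_flank + 2
    return np.bincount(loci.kmer_id, minlength=4 ** width).astype(np.int64)


def context_ids_of_records(dmap: DamageMap, genome: GenomeSequence,
                           k_flank: int) -> np.ndarray:
    """Context k-mer id for every damage record (-1 where unavailable)."""
    f = k_flank
    width = 2 * f + 2
    rec = dmap.records
    out = np.full(len(rec), -1, dtype=np.int64)
    p4 = _pow4(width)
    for chrom, grp in rec.groupby("chrom", sort=False):
        codes = genome.codes(chrom)
        n = len(codes)
        pos5 = grp["pos5"].to_numpy()
        minus = grp["strand"].to_numpy() == "-"
        w_lo = np.where(minus, pos5 - 1 - f, pos5 - f)
        ok = (w_lo >= 0) & (w_lo + width <= n)
        idx = np.clip(w_lo[:, None] + np.arange(width), 0, n - 1)
        win = codes[idx].astype(np.int64)
        ok &= (win < 4).all(axis=1)
        ids_plus = win @ p4
        rc = revcomp_id_table(width)
        ids = np.where(minus, rc[ids_plus], ids_plus)
        out[grp.index.to_numpy()[ok]] = ids[ok]
    return out


@dataclass
class ContextRateTable:
    """Per-k-mer occurrence/damage counts and rates over a background set.

    Arrays are indexed by k-mer id (width 2*k_flank+2); only
    pyrimidine-centered ids are meaningful. A covered k-mer has
    occurrences > 0; uncovered k-mers are flagged, never silently zero.
    """

    k_flank: int
    occurrences: np.ndarray
    damages: np.ndarray
    lesion_type: str = "CPD"
    timepoint: str = "0h"
    region_id: str = ""
    n_excluded: int = 0

    @property
    def width(self) -> int:
        return 2 * self.k_flank + 2

    @property
    def centered_mask(self) -> np.ndarray:
        return pyrimidine_centered_mask(self.k_flank)

    @property
    def uncovered(self) -> np.ndarray:
        return self.centered_mask & (self.occurrences == 0)

    def rate_array(self) -> np.ndarray:
        """damages/occurrences per id; 0 where uncovered or not centered."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.occurrences > 0, self.damages / np.maximum(self.occurrences, 1), 0.0)
        return np.where(self.centered_mask, r, 0.0)

    def rate(self, kmer: str) -> float:
        idx = kmer_to_id(kmer)
        if self.occurrences[idx] == 0:
            raise KeyError(f"k-mer {kmer} uncovered in background set")
        return float(self.damages[idx] / self.occurrences[idx])

    def to_frame(self) -> pd.DataFrame:
        ids = np.flatnonzero(self.centered_mask)
        rates = self.rate_array()
        return pd.DataFrame({
            "kmer": [id_to_kmer(i, self.width) for i in ids],
            "occurrences": self.occurrences[ids],
            "damages": self.damages[ids],
            "rate": rates[ids],
            "covered": self.occurrences[ids] > 0,
        })

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# lesion_type={self.lesion_type} timepoint={self.timepoint} "
                     f"region_id={self.region_id} k_flank={self.k_flank}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContextRateTable":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t")
        k_flank = int(meta["k_flank"])
        width = 2 * k_flank + 2
        occ = np.zeros(4 ** width, dtype=np.int64)
        dam = np.zeros(4 ** width, dtype=np.int64)
        for r in df.itertuples():
            i = kmer_to_id(r.kmer)
            occ[i] = r.occurrences
            dam[i] = r.damages
        return cls(k_flank, occ, dam, meta["lesion_type"], meta["timepoint"],
                   meta["region_id"])


def estimate_context_rates(damage_map: DamageMap, genome: GenomeSequence,
                           regions: IntervalSet, k_flank: int,
                           region_id: str = "") -> ContextRateTable:
    """Rate = damages/occurrences per pyrimidine-centered k-mer over regions.

    The map is filtered to records whose dinucleotide lies inside the regions;
    records with unavailable context (N / chromosome edge) are excluded and
    counted in ``n_excluded``.
    """
    width = 2 * k_flank + 2
    occ = count_context_occurrences(genome, regions, k_flank)
    dmap = damage_map.filter_to_regions(regions, contained=True)
    dam = np.zeros(4 ** width, dtype=np.int64)
    n_excluded = 0
    if len(dmap.records):
        ids = context_ids_of_records(dmap, genome, k_flank)
        counts = dmap.records["count"].to_numpy()
        ok = ids >= 0
        n_excluded = int(counts[~ok].sum())
        if n_excluded:
            log.info("estimate_context_rates: excluded %d damages with unavailable context",
                     n_excluded)
        dam = np.bincount(ids[ok], weights=counts[ok], minlength=4 ** width).astype(np.int64)
    return ContextRateTable(k_flank, occ, dam, damage_map.lesion_type,
                            damage_map.timepoint, region_id, n_excluded)


def flank_effect_test(table: ContextRateTable,
                      group_by: str = "flanks") -> tuple[float, float]:
    """Kruskal-Wallis QC: does sequence context shift the damage rates?

    ``group_by="flanks"`` groups covered k-mer rates by their flanking
    bases (central dinucleotide variation is within-group), so a small p
    says the flanking identity influences damageability;
    ``group_by="central"`` groups by the central dinucleotide instead.
    Returns (H, p).
    """
    rates = table.rate_array()
    f = table.k_flank
    groups: dict[str, list[float]] = {}
    for i in np.flatnonzero(table.centered_mask & (table.occurrences > 0)):
        kmer = id_to_kmer(int(i), table.width)
        if group_by == "flanks":
            key = kmer[:f] + kmer[f + 2:]
        elif group_by == "central":
            key = kmer[f:f + 2]
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        groups.setdefault(key, []).append(rates[i])
    vals = [v for v in groups.values() if len(v) >= 2]
    if len(vals) < 2:
        raise ValueError("need at least two groups with >= 2 rates")
    res = stats.kruskal(*vals)
    return float(res.statistic), float(res.pvalue)


class KsResult(NamedTuple):
    statistic: float
    pvalue: float
    n_loci: int
    rate: float


def ks_poisson_check(damage_map: DamageMap, genome: GenomeSequence,
                     regions: IntervalSet, kmer: str,
                     min_loci: int = 100) -> KsResult | None:
    """KS test of per-locus counts (zeros included) against Poisson(rate).

    Zero-count loci are reconstructed from the occurrence enumeration, since
    damage BED files omit them. Returns None ("insufficient") below
    ``min_loci`` loci. The KS p-value against a discrete distribution is
    approximate (conservative); this is a model-adequacy check, not an exact
    test.
    """
    k_flank = (len(kmer) - 2) // 2
    target = kmer_to_id(kmer)
    loci = dipyrimidine_loci(genome, regions, k_flank)
    sel = loci.kmer_id == target
    n_loci = int(sel.sum())
    if n_loci < min_loci:
        return None
    key = pd.DataFrame({"chrom": loci.chrom[sel], "strand": loci.strand[sel],
                        "lo": loci.lo[sel]})
    dmap = damage_map.filter_to_regions(regions, contained=True)
    rec = dmap.records.copy()
    if len(rec):
        rec["lo"] = np.where(rec["strand"] == "-", rec["pos5"] - 1, rec["pos5"])
        merged = key.merge(rec[["chrom", "strand", "lo", "count"]],
                           on=["chrom", "strand", "lo"], how="left")
        counts = merged["count"].fillna(0).to_numpy()
    else:
        counts = np.zeros(n_loci)
    rate = counts.mean()
    # D evaluated on the integer support (the naive two-point KS formula
    # misbehaves under heavy ties); asymptotic Kolmogorov p, which is
    # conservative for a discrete comparison distribution
    log.debug("ks_poisson_check(%s): discrete-distribution KS p is approximate "
              "(conservative)", kmer)
    support = np.arange(0, int(counts.max()) + 1)
    f_emp = np.searchsorted(np.sort(counts), support, side="right") / n_loci
    f_model = stats.poisson.cdf(support, rate)
    d = float(np.max(np.abs(f_emp - f_model)))
    pvalue = float(stats.kstwobign.sf(d * np.sqrt(n_loci)))
    return KsResult(d, pvalue, n_loci, float(rate))
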
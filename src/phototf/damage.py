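"""Stranded UV damage maps and somatic mutation tables.

A damage record marks one dipyrimidine on one strand. ``pos5`` is the
reference coordinate of the 5'-most base of the dinucleotide *on the damaged
strand*: for a plus-strand lesion this is the lower reference coordinate; for
a minus-strand lesion it is the higher one. The on-disk BED dialect always
stores the lower reference coordinate of the dinucleotide in the start
column, so a minus-strand record's pos5 is ``start + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSequence, revcomp
from .intervals import IntervalSet

__all__ = [
    "DamageMap",
    "MutationTable",
    "read_damage_bed",
    "write_damage_bed",
    "extract_context",
    "filter_blacklist",
    "read_mutations_tsv",
    "write_mutations_tsv",
]

log = logging.getLogger(__name__)

_PYRIMIDINES = frozenset("CT")
DIPYRIMIDINES = ("TT", "TC", "CT", "CC")


def _lo_coord(pos5: np.ndarray, strand: np.ndarray) -> np.ndarray:
    """Lower reference coordinate of each dinucleotide."""
    return np.where(strand == "-", pos5 - 1, pos5)


@dataclass
class DamageMap:
    """Per-locus lesion counts for one lesion type and timepoint.

    ``records`` has columns chrom (str), strand (+/-), pos5 (int), dinuc
    (str, 5'->3' on the damaged strand), count (int >= 1); one row per
    (chrom, strand, pos5).
    """

    lesion_type: str = "CPD"
    timepoint: str = "0h"
    records: pd.DataFrame = field(default_factory=lambda: _empty_records())
    scale_factor: float = 1.0

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def total_count(self) -> int:
        return int(self.records["count"].sum()) if len(self.records) else 0

    def _replace(self, records: pd.DataFrame) -> "DamageMap":
        return DamageMap(self.lesion_type, self.timepoint, records, self.scale_factor)

    def aggregate(self) -> "DamageMap":
        """Sum counts at duplicate (chrom, strand, pos5) loci."""
        if not len(self.records):
            return self
        grouped = (
            self.records.groupby(["chrom", "strand", "pos5"], as_index=False)
            .agg(dinuc=("dinuc", "first"), count=("count", "sum"))
            .sort_values(["chrom", "pos5", "strand"], kind="stable")
        )
        return self._replace(grouped[["chrom", "strand", "pos5", "dinuc", "count"]])

    def filter_to_regions(self, regions: IntervalSet, contained: bool = True) -> "DamageMap":
        """Keep records whose dinucleotide lies within (or overlaps) a region."""
        if not len(self.records):
            return self
        keep = np.zeros(len(self.records), dtype=bool)
        for chrom, grp in self.records.groupby("chrom", sort=False):
            lo = _lo_coord(grp["pos5"].to_numpy(), grp["strand"].to_numpy())
            if contained:
                m = regions.contains_interval(chrom, lo, lo + 2)
            else:
                m = regions.overlaps(chrom, lo, lo + 2)
            keep[grp.index.to_numpy()] = m
        return self._replace(self.records.loc[keep])


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "strand": pd.Series(dtype=str),
         "pos5": pd.Series(dtype=np.int64), "dinuc": pd.Series(dtype=str),
         "count": pd.Series(dtype=np.int64)}
    )


def read_damage_bed(path: str | Path, lesion_type: str, genome: GenomeSequence,
                    timepoint: str = "0h") -> DamageMap:
    """Read a damage BED6 (chrom, start, end, name, count, strand).

    Rows at non-dipyrimidine loci are dropped (with a logged count);
    duplicate loci are summed; the dinucleotide class is annotated from the
    genome. Counts must be integers >= 1.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "count", "strand"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return DamageMap(lesion_type, timepoint)
    if df.empty:
        return DamageMap(lesion_type, timepoint)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != np.floor(counts)) | (counts < 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: row {row + 1}: count {df['count'].iloc[row]!r} "
                         "is not a positive integer")
    unknown = ~df["chrom"].isin(genome.chroms)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValueError(f"{path}: row {row + 1}: unknown chrom {df['chrom'].iloc[row]!r}")

    rows = []
    n_dropped = 0
    for r in df.itertuples():
        start = int(r.start)
        strand = r.strand
        ref_dinuc = genome.sequence(r.chrom, start, start + 2) if start + 2 <= genome.lengths[r.chrom] else ""
        dinuc = ref_dinuc if strand == "+" else revcomp(ref_dinuc)
        if len(dinuc) != 2 or not (set(dinuc) <= _PYRIMIDINES):
            n_dropped += 1
            continue
        pos5 = start if strand == "+" else start + 1
        rows.append((r.chrom, strand, pos5, dinuc, int(r.count)))
    if n_dropped:
        log.info("%s: dropped %d records at non-dipyrimidine loci", path, n_dropped)
    rec = pd.DataFrame(rows, columns=["chrom", "strand", "pos5", "dinuc", "count"])
    return DamageMap(lesion_type, timepoint, rec).aggregate()


def write_damage_bed(dmap: DamageMap, path: str | Path) -> None:
    """Write the damage BED dialect (start = lower coordinate of the dinuc)."""
    rec = dmap.records
    lo = _lo_coord(rec["pos5"].to_numpy(), rec["strand"].to_numpy()) if len(rec) else np.empty(0, int)
    out = pd.DataFrame({
        "chrom": rec["chrom"], "start": lo, "end": lo + 2,
        "name": rec["dinuc"], "count": rec["count"], "strand": rec["strand"],
    }).sort_values(["chrom", "start", "strand"], kind="stable")
    out.to_csv(path, sep="\t", header=False, index=False)


def extract_context(genome: GenomeSequence, chrom: str, strand: str, pos5: int,
                    k_flank: int) -> str | None:
    """Dipyrimidine-centered (2k+2)-mer read 5'->3' on the damaged strand.

    Returns None ("unavailable") if the window crosses a chromosome boundary,
    contains N, or the central two bases are not both pyrimidines.
    """
    n = genome.lengths[chrom]
    if strand == "+":
        lo, hi = pos5 - k_flank, pos5 + 2 + k_flank
        if lo < 0 or hi > n:
            return None
        ctx = genome.sequence(chrom, lo, hi)
    else:
        lo, hi = pos5 - 1 - k_flank, pos5 + 1 + k_flank
        if lo < 0 or hi > n:
            return None
        ctx = revcomp(genome.sequence(chrom, lo, hi))
    if "N" in ctx:
        return None
    if not set(ctx[k_flank:k_flank + 2]) <= _PYRIMIDINES:
        return None
    return ctx


def filter_blacklist(obj, blacklist: IntervalSet):
    """Remove damage records / sites overlapping blacklist intervals.

    Works for DamageMap and for anything exposing ``.filter_overlapping``
    (e.g. BindingSiteSet). Empty blacklist is the identity.
    """
    if blacklist.is_empty():
        return obj
    if isinstance(obj, DamageMap):
        rec = obj.records
        if not len(rec):
            return obj
        keep = np.zeros(len(rec), dtype=bool)
        for chrom, grp in rec.groupby("chrom", sort=False):
            lo = _lo_coord(grp["pos5"].to_numpy(), grp["strand"].to_numpy())
            keep[grp.index.to_numpy()] = ~blacklist.overlaps(chrom, lo, lo + 2)
        return obj._replace(rec.loc[keep])
    return obj.filter_overlapping(blacklist, invert=True)


# -- mutations -----------------------------------------------------------


@dataclass
class MutationTable:
    """Somatic single-base substitutions: chrom, pos (0-based), ref, alt, sample."""

    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def filter_substitution(self, kinds: str = "C>T") -> "MutationTable":
        """Keep pyrimidine-strand C>T events (reference C>T or G>A) or 'all'."""
        if kinds == "all":
            return self
        if kinds != "C>T":
            raise ValueError(f"unsupported substitution filter {kinds!r}")
        r = self.records
        keep = ((r["ref"] == "C") & (r["alt"] == "T")) | ((r["ref"] == "G") & (r["alt"] == "A"))
        return MutationTable(r.loc[keep].reset_index(drop=True))


def read_mutations_tsv(path: str | Path, genome: GenomeSequence | None = None) -> MutationTable:
    """Read a headered TSV (chrom, pos, ref, alt, sample); 0-based positions.

    If a genome is given, records whose ref base mismatches it are dropped
    with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "sample": str})
    required = {"chrom", "pos", "ref", "alt", "sample"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if (df["ref"] == df["alt"]).any():
        raise ValueError(f"{path}: ref == alt in some rows")
    if genome is not None and len(df):
        ok = np.array([
            r.chrom in genome and 0 <= r.pos < genome.lengths[r.chrom]
            and genome.base(r.chrom, int(r.pos)) == r.ref
            for r in df.itertuples()
        ])
        if (~ok).any():
            log.info("%s: dropped %d records with ref mismatch", path, int((~ok).sum()))
        df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return MutationTable(df)


def write_mutations_tsv(table: MutationTable, path: str | Path) -> None:
    out = table.records.sort_values(["chrom", "pos", "sample"], kind="stable")
    out.to_csv(path, sep="\t", index=False)
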
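"""Genomic intervals and half-open interval-set algebra.

All coordinates are 0-based half-open (BED native). ``IntervalSet`` keeps a
merged, sorted representation per chromosome, so intersection, subtraction
and membership queries are simple sweeps over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "IntervalSet", "read_bed", "write_bed"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Per-chromosome merged interval collection (strand-agnostic)."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @classmethod
    def _from_arrays(cls, starts: dict[str, np.ndarray], ends: dict[str, np.ndarray]) -> "IntervalSet":
        out = cls()
        for chrom in starts:
            if len(starts[chrom]):
                out._starts[chrom] = starts[chrom]
                out._ends[chrom] = ends[chrom]
        return out

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._starts:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._starts[chrom], self._ends[chrom]

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def total_length(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))

    def is_empty(self) -> bool:
        return not self._starts

    # -- queries ---------------------------------------------------------

    def overlaps(self, chrom: str, start: np.ndarray | int, end: np.ndarray | int) -> np.ndarray | bool:
        """Whether query interval(s) [start, end) overlap any interval (half-open)."""
        scalar = np.isscalar(start)
        qs = np.atleast_1d(np.asarray(start, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(end, dtype=np.int64))
        starts, ends = self.arrays(chrom)
        if len(starts) == 0:
            res = np.zeros(len(qs), dtype=bool)
        else:
            # candidate: last interval with start < qe
            idx = np.searchsorted(starts, qe, side="left") - 1
            ok = idx >= 0
            res = np.zeros(len(qs), dtype=bool)
            res[ok] = ends[idx[ok]] > qs[ok]
        return bool(res[0]) if scalar else res

    def contains_interval(self, chrom: str, start: np.ndarray | int, end: np.ndarray | int) -> np.ndarray | bool:
        """Whether query interval(s) lie fully inside a single interval."""
        scalar = np.isscalar(start)
        qs = np.atleast_1d(np.asarray(start, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(end, dtype=np.int64))
        starts, ends = self.arrays(chrom)
        if len(starts) == 0:
            res = np.zeros(len(qs), dtype=bool)
        else:
            idx = np.searchsorted(starts, qs, side="right") - 1
            ok = idx >= 0
            res = np.zeros(len(qs), dtype=bool)
            res[ok] = ends[idx[ok]] >= qe[ok]
        return bool(res[0]) if scalar else res

    # -- algebra ---------------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        starts: dict[str, np.ndarray] = {}
        ends: dict[str, np.ndarray] = {}
        for chrom in self._starts:
            a_s, a_e = self.arrays(chrom)
            b_s, b_e = other.arrays(chrom)
            out_s, out_e = [], []
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                lo = max(a_s[i], b_s[j])
                hi = min(a_e[i], b_e[j])
                if lo < hi:
                    out_s.append(lo)
                    out_e.append(hi)
                if a_e[i] <= b_e[j]:
                    i += 1
                else:
                    j += 1
            starts[chrom] = np.array(out_s, dtype=np.int64)
            ends[chrom] = np.array(out_e, dtype=np.int64)
        return IntervalSet._from_arrays(starts, ends)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        starts: dict[str, np.ndarray] = {}
        ends: dict[str, np.ndarray] = {}
        for chrom in self._starts:
            a_s, a_e = self.arrays(chrom)
            b_s, b_e = other.arrays(chrom)
            out_s, out_e = [], []
            j = 0
            for s, e in zip(a_s, a_e):
                cur = s
                while j < len(b_s) and b_e[j] <= cur:
                    j += 1
                k = j
                while k < len(b_s) and b_s[k] < e:
                    if b_s[k] > cur:
                        out_s.append(cur)
                        out_e.append(b_s[k])
                    cur = max(cur, b_e[k])
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out_s.append(cur)
                    out_e.append(e)
            starts[chrom] = np.array(out_s, dtype=np.int64)
            ends[chrom] = np.array(out_e, dtype=np.int64)
        return IntervalSet._from_arrays(starts, ends)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a plain BED (>=3 columns) into an IntervalSet."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={0: str})
    return IntervalSet(
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()
    )


def write_bed(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in ivset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
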
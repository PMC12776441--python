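"""TF binding-site sets and motif-relative coordinates.

Sites in a set share one motif cluster id and motif length. Motif-relative
coordinate 0 is the motif center, defined as floor(L/2) bases from the motif
5' end on the motif strand; the motif occupies axis positions
[-floor(L/2), L-1-floor(L/2)]. A dipyrimidine (or any dinucleotide feature)
is reported at the lower axis coordinate of the two bases it spans, the
"i/i+1" labelling used throughout the damage profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = ["BindingSiteSet", "read_sites_bed", "write_sites_bed"]


@dataclass
class BindingSiteSet:
    """Motif-cluster binding sites: chrom, start, end, strand, score."""

    cluster_id: str
    motif_length: int
    sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str),
         "score": pd.Series(dtype=float)}))

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        if len(self.sites):
            widths = self.sites["end"] - self.sites["start"]
            if not (widths == self.motif_length).all():
                raise ValueError(f"{self.cluster_id}: site widths differ from motif length "
                                 f"{self.motif_length}")

    def __len__(self) -> int:
        return len(self.sites)

    def _replace(self, sites: pd.DataFrame) -> "BindingSiteSet":
        return BindingSiteSet(self.cluster_id, self.motif_length, sites)

    @property
    def centers(self) -> np.ndarray:
        """Genomic coordinate of axis position 0 for every site."""
        half = self.motif_length // 2
        start = self.sites["start"].to_numpy()
        end = self.sites["end"].to_numpy()
        return np.where(self.sites["strand"].to_numpy() == "+", start + half, end - 1 - half)

    @property
    def motif_span(self) -> tuple[int, int]:
        """Axis positions (inclusive) covered by the motif."""
        half = self.motif_length // 2
        return -half, self.motif_length - 1 - half

    def filter_overlapping(self, regions: IntervalSet, invert: bool = False) -> "BindingSiteSet":
        """Keep sites whose motif interval overlaps ``regions`` (or doesn't)."""
        if not len(self.sites):
            return self
        keep = np.zeros(len(self.sites), dtype=bool)
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            m = regions.overlaps(chrom, grp["start"].to_numpy(), grp["end"].to_numpy())
            keep[grp.index.to_numpy()] = m
        if invert:
            keep = ~keep
        return self._replace(self.sites.loc[keep])

    def sorted_by_score(self) -> "BindingSiteSet":
        """Stable sort by (score desc, chrom, start) — the tie-break used everywhere."""
        order = self.sites.sort_values(
            ["score", "chrom", "start"], ascending=[False, True, True], kind="stable")
        return self._replace(order)

    def head(self, n: int) -> "BindingSiteSet":
        return self._replace(self.sites.head(n))


def read_sites_bed(path: str | Path, cluster_id: str | None = None) -> BindingSiteSet:
    """Read a BED6 of motif matches (score column = motif log-odds score)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"{path}: no sites")
    cid = cluster_id or str(df["name"].iloc[0])
    length = int((df["end"] - df["start"]).iloc[0])
    sites = df[["chrom", "start", "end", "strand", "score"]].copy()
    sites["start"] = sites["start"].astype(np.int64)
    sites["end"] = sites["end"].astype(np.int64)
    return BindingSiteSet(cid, length, sites)


def write_sites_bed(siteset: BindingSiteSet, path: str | Path) -> None:
    out = siteset.sites.copy()
    out["name"] = siteset.cluster_id
    out = out[["chrom", "start", "end", "name", "score", "strand"]]
    out = out.sort_values(["chrom", "start", "strand"], kind="stable")
    out.to_csv(path, sep="\t", header=False, index=False)
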
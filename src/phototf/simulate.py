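"""Synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end: a random genome,
planted motif-bearing binding sites centered in 150-bp accessible windows,
per-locus Poisson lesion counts whose rates depend on the hexanucleotide
context, binomial-thinning repair with NYYN-dependent survival, and
trinucleotide-dependent C>T mutations across samples. Per-position TF
effects (formation or survival multipliers) can be planted as ground truth
for parameter-recovery tests.

All randomness flows from per-stage seeds; ``write_fixture_bundle`` derives
named substreams from one master seed so the bundle is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background import (dipyrimidine_loci, id_to_kmer, kmer_to_id,
                         pyrimidine_centered_mask)
from .damage import DamageMap, MutationTable, write_damage_bed, write_mutations_tsv
from .genome import CODE_TO_BASE, GenomeSequence, revcomp, write_fasta
from .intervals import GenomicInterval, IntervalSet, write_bed
from .motif import pwm_from_consensus, sample_from_pwm, score_sites
from .sites import BindingSiteSet, write_sites_bed

__all__ = [
    "TruthTables",
    "PlantedEffect",
    "default_truth_tables",
    "generate_genome",
    "plant_sites",
    "generate_genic_regions",
    "simulate_damage",
    "simulate_repair",
    "simulate_mutations",
    "write_fixture_bundle",
]

log = logging.getLogger(__name__)

#: Baseline lesion rates per occurrence by central dinucleotide; TT steps are
#: the most photoreactive, CT the least, as in measured CPD spectra.
DEFAULT_DINUC_RATES = {"TT": 0.09, "TC": 0.055, "CT": 0.02, "CC": 0.035}


@dataclass
class TruthTables:
    """Ground-truth rate tables driving the simulator.

    hexamer_rates: NNYYNN -> lesions per occurrence (Poisson rate).
    survival: NYYN -> probability a lesion remains at the later timepoint.
    mutation_rates: NCN trinucleotide -> per-sample per-base C>T probability.
    """

    hexamer_rates: dict[str, float]
    survival: dict[str, float]
    mutation_rates: dict[str, float]

    def __post_init__(self):
        for name, table, mask_k in (("hexamer_rates", self.hexamer_rates, 2),
                                    ("survival", self.survival, 1)):
            want = int(pyrimidine_centered_mask(mask_k).sum())
            if len(table) != want:
                raise ValueError(f"{name}: expected {want} k-mers, got {len(table)}")
        if any(r < 0 for r in self.hexamer_rates.values()):
            raise ValueError("negative hexamer rate")
        if any(not 0 <= s <= 1 for s in self.survival.values()):
            raise ValueError("survival outside [0,1]")

    def hexamer_rate_array(self) -> np.ndarray:
        out = np.zeros(4 ** 6)
        for kmer, r in self.hexamer_rates.items():
            out[kmer_to_id(kmer)] = r
        return out

    def survival_array(self) -> np.ndarray:
        out = np.zeros(4 ** 4)
        for kmer, s in self.survival.items():
            out[kmer_to_id(kmer)] = s
        return out

    def mutation_rate_array(self) -> np.ndarray:
        out = np.zeros(4 ** 3)
        for kmer, r in self.mutation_rates.items():
            out[kmer_to_id(kmer)] = r
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"hexamer_rates": self.hexamer_rates, "survival": self.survival,
                       "mutation_rates": self.mutation_rates}, fh, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTables":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["hexamer_rates"], d["survival"], d["mutation_rates"])


@dataclass(frozen=True)
class PlantedEffect:
    """A per-position TF effect: formation or survival multiplier.

    ``position`` uses the lower-axis ("i/i+1") convention of the profiles;
    ``strand`` is 'motif' or 'complement'.
    """

    position: int
    strand: str
    kind: str
    multiplier: float

    def __post_init__(self):
        if self.strand not in ("motif", "complement"):
            raise ValueError(f"bad effect strand {self.strand!r}")
        if self.kind not in ("formation", "survival"):
            raise ValueError(f"bad effect kind {self.kind!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")


def default_truth_tables(seed: int, dinuc_rates: dict[str, float] | None = None,
                         flank_sigma: float = 0.5,
                         survival_range: tuple[float, float] = (0.2, 0.7),
                         mutation_scale: float = 2e-4) -> TruthTables:
    """Seeded truth tables with strong flank dependence.

    Hexamer rate = base(dinucleotide class) x lognormal flank modifier
    (sigma = ``flank_sigma``, unit mean), giving several-fold spread between
    hexamers sharing a central tetranucleotide. Survival is uniform over
    ``survival_range`` per NYYN; mutation rates are lognormal around
    ``mutation_scale`` per NCN trinucleotide.
    """
    rng = np.random.default_rng(seed)
    base = dinuc_rates or DEFAULT_DINUC_RATES
    hexamer_rates = {}
    for idx in np.flatnonzero(pyrimidine_centered_mask(2)):
        kmer = id_to_kmer(int(idx), 6)
        mod = float(np.exp(rng.normal(-flank_sigma ** 2 / 2, flank_sigma)))
        hexamer_rates[kmer] = base[kmer[2:4]] * mod
    survival = {}
    for idx in np.flatnonzero(pyrimidine_centered_mask(1)):
        survival[id_to_kmer(int(idx), 4)] = float(rng.uniform(*survival_range))
    mutation_rates = {}
    for mid in ("C",):
        for left in "ACGT":
            for right in "ACGT":
                mod = float(np.exp(rng.normal(-0.125, 0.5)))
                mutation_rates[left + mid + right] = mutation_scale * mod
    return TruthTables(hexamer_rates, survival, mutation_rates)


def generate_genome(n_chroms: int, length: int, gc: float, seed: int) -> GenomeSequence:
    """i.i.d. random genome with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc <= 1:
        raise ValueError("gc must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for i in range(n_chroms):
        codes = rng.choice(4, size=length, p=p)
        seqs[f"chr{i + 1}"] = "".join(CODE_TO_BASE[codes])
    return GenomeSequence(seqs)


def plant_sites(genome: GenomeSequence, consensus_or_pwm, n_sites: int,
                spacing: int, seed: int, cluster_id: str = "SYN/1",
                accessible_width: int = 150,
                score_noise: float = 0.0):
    """Write motif instances into the genome at regularly spaced loci.

    Returns (mutated genome, scored BindingSiteSet, accessible IntervalSet).
    Sites alternate between chromosomes, are ``spacing`` apart, use both
    strands with equal probability, and each sits centered in a 150-bp
    accessible window. Scores come from the PWM log-odds scanner; optional
    Gaussian ``score_noise`` separates ties for strength stratification.
    """
    pwm = (pwm_from_consensus(consensus_or_pwm)
           if isinstance(consensus_or_pwm, str) else np.asarray(consensus_or_pwm))
    L = len(pwm)
    if L >= spacing:
        raise ValueError("motif must be shorter than the spacing")
    rng = np.random.default_rng(seed)
    margin = max(accessible_width, 100)
    chroms = genome.chroms
    per_chrom = {c: (genome.lengths[c] - 2 * margin) // spacing for c in chroms}
    if sum(per_chrom.values()) < n_sites:
        raise ValueError(f"genome too short for {n_sites} sites at spacing {spacing}")
    rows = []
    new_seqs = {c: list(genome.sequence(c)) for c in chroms}
    placed = 0
    slots = [(c, margin + k * spacing) for c in chroms for k in range(per_chrom[c])]
    for chrom, start in slots[:n_sites]:
        strand = "+" if rng.random() < 0.5 else "-"
        motif = sample_from_pwm(pwm, rng)
        seq = motif if strand == "+" else revcomp(motif)
        new_seqs[chrom][start:start + L] = list(seq)
        rows.append((chrom, start, start + L, strand, 0.0))
        placed += 1
    out_genome = GenomeSequence({c: "".join(v) for c, v in new_seqs.items()})
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])
    siteset = BindingSiteSet(cluster_id, L, sites)
    siteset = score_sites(pwm, out_genome, siteset)
    if score_noise > 0:
        scored = siteset.sites.copy()
        scored["score"] = scored["score"] + rng.normal(0, score_noise, len(scored))
        siteset = siteset._replace(scored)
    half = accessible_width // 2
    centers = siteset.centers
    accessible = IntervalSet(
        GenomicInterval(r.chrom, max(0, int(c) - half), int(c) + half)
        for r, c in zip(siteset.sites.itertuples(), centers))
    return out_genome, siteset, accessible


def generate_genic_regions(genome: GenomeSequence, accessible: IntervalSet,
                           n_regions: int, length: int, seed: int) -> IntervalSet:
    """Random 'genic' intervals disjoint from the accessible windows."""
    rng = np.random.default_rng(seed)
    ivs: list[GenomicInterval] = []
    tries = 0
    while len(ivs) < n_regions and tries < 50 * n_regions:
        tries += 1
        chrom = genome.chroms[rng.integers(len(genome.chroms))]
        start = int(rng.integers(0, max(1, genome.lengths[chrom] - length)))
        if not accessible.overlaps(chrom, start, start + length):
            ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


def _effect_locus_map(siteset: BindingSiteSet, effects) -> dict[tuple[str, str, int], float]:
    """(chrom, genome strand, dinucleotide lower coord) -> multiplier."""
    out: dict[tuple[str, str, int], float] = {}
    centers = siteset.centers
    for r, c in zip(siteset.sites.itertuples(), centers):
        for eff in effects:
            gstrand = r.strand if eff.strand == "motif" else ("-" if r.strand == "+" else "+")
            lo = int(c) + eff.position if r.strand == "+" else int(c) - 1 - eff.position
            key = (r.chrom, gstrand, lo)
            out[key] = out.get(key, 1.0) * eff.multiplier
    return out


def simulate_damage(genome: GenomeSequence, regions: IntervalSet,
                    truth: TruthTables, effects=(), sites: BindingSiteSet | None = None,
                    seed: int = 0, lesion_type: str = "CPD",
                    timepoint: str = "0h") -> DamageMap:
    """Poisson lesion counts at every dipyrimidine locus in the regions.

    count ~ Poisson(rate(hexamer) x multiplier); the multiplier differs from
    1 only at planted (site, position, strand) combinations. Zero-count loci
    are omitted from the returned map (as in real damage BED files).
    """
    formation = [e for e in effects if e.kind == "formation"]
    if formation and sites is None:
        raise ValueError("formation effects need the planted site set")
    rng = np.random.default_rng(seed)
    loci = dipyrimidine_loci(genome, regions, k_flank=2)
    rates = truth.hexamer_rate_array()[loci.kmer_id]
    if formation:
        emap = _effect_locus_map(sites, formation)
        if emap:
            keys = list(zip(loci.chrom, loci.strand, loci.lo))
            mult = np.array([emap.get(k, 1.0) for k in keys])
            rates = rates * mult
    counts = rng.poisson(rates)
    nz = counts > 0
    dinuc = [id_to_kmer(int(i), 6)[2:4] for i in loci.kmer_id[nz]]
    pos5 = np.where(loci.strand[nz] == "-", loci.lo[nz] + 1, loci.lo[nz])
    rec = pd.DataFrame({"chrom": loci.chrom[nz], "strand": loci.strand[nz],
                        "pos5": pos5, "dinuc": dinuc, "count": counts[nz]})
    return DamageMap(lesion_type, timepoint, rec).aggregate()


def simulate_repair(map0h: DamageMap, truth: TruthTables, genome: GenomeSequence,
                    effects=(), sites: BindingSiteSet | None = None,
                    seed: int = 0, timepoint: str = "6h") -> DamageMap:
    """Binomial thinning of the 0h map with NYYN-dependent survival.

    remaining ~ Binomial(count_0h, survival(NYYN) x multiplier); the
    multiplier applies only at planted survival effects, and the product is
    clamped to [0, 1] with a warning. Loci whose NYYN context is unavailable
    (N in a flank, chromosome edge) are thinned with the mean survival and
    logged.
    """
    if map0h.lesion_type != "CPD":
        raise ValueError("repair simulation expects a CPD map")
    survival_effects = [e for e in effects if e.kind == "survival"]
    if survival_effects and sites is None:
        raise ValueError("survival effects need the planted site set")
    rng = np.random.default_rng(seed)
    from .background import context_ids_of_records
    rec = map0h.records
    if not len(rec):
        return DamageMap("CPD", timepoint)
    ids = context_ids_of_records(map0h, genome, k_flank=1)
    surv_arr = truth.survival_array()
    mean_surv = float(np.mean([v for v in truth.survival.values()]))
    s = np.where(ids >= 0, surv_arr[np.maximum(ids, 0)], mean_surv)
    if (ids < 0).any():
        log.info("simulate_repair: %d loci with unavailable NYYN context use the "
                 "mean survival", int((ids < 0).sum()))
    if survival_effects:
        emap = _effect_locus_map(sites, survival_effects)
        if emap:
            lo = np.where(rec["strand"].to_numpy() == "-", rec["pos5"].to_numpy() - 1,
                          rec["pos5"].to_numpy())
            keys = list(zip(rec["chrom"].to_numpy(), rec["strand"].to_numpy(), lo))
            mult = np.array([emap.get(k, 1.0) for k in keys])
            s = s * mult
            if (s > 1).any():
                warnings.warn("survival x multiplier clamped to [0, 1]")
                s = np.clip(s, 0.0, 1.0)
    remaining = rng.binomial(rec["count"].to_numpy(), s)
    nz = remaining > 0
    out = rec.loc[nz, ["chrom", "strand", "pos5", "dinuc"]].copy()
    out["count"] = remaining[nz]
    return DamageMap("CPD", timepoint, out)


def simulate_mutations(genome: GenomeSequence, regions: IntervalSet,
                       truth: TruthTables, per_site_hotspots=(),
                       sites: BindingSiteSet | None = None,
                       n_samples: int = 100, seed: int = 0) -> MutationTable:
    """Per-sample Bernoulli C>T mutations at every cytosine in the regions.

    The mutation probability is the trinucleotide rate (pyrimidine-strand
    3-mer centered on the C) times an optional planted hotspot multiplier.
    Minus-strand events are recorded as reference G>A.
    """
    if per_site_hotspots and sites is None:
        raise ValueError("hotspots need the planted site set")
    rng = np.random.default_rng(seed)
    rate_arr = truth.mutation_rate_array()
    hotspot_map: dict[tuple[str, str, int], float] = {}
    if per_site_hotspots:
        centers = sites.centers
        for r, c in zip(sites.sites.itertuples(), centers):
            for pos, strand_lbl, mult in per_site_hotspots:
                gstrand = r.strand if strand_lbl == "motif" else ("-" if r.strand == "+" else "+")
                # hotspot position marks the mutated base itself (not a dinucleotide)
                gpos = int(c) + pos if r.strand == "+" else int(c) - pos
                hotspot_map[(r.chrom, gstrand, gpos)] = mult
    rows = []
    for chrom in regions.chroms:
        if chrom not in genome:
            continue
        codes = genome.codes(chrom)
        n = len(codes)
        starts, ends = regions.arrays(chrom)
        for s0, e0 in zip(starts, ends):
            span = np.arange(max(1, s0), min(n - 1, e0))
            if not len(span):
                continue
            c1 = codes[span]
            for gstrand, code in (("+", 1), ("-", 2)):  # C on + / G on + = C on -
                at = span[c1 == code]
                if not len(at):
                    continue
                left, right = codes[at - 1].astype(np.int64), codes[at + 1].astype(np.int64)
                ok = (left < 4) & (right < 4)
                at, left, right = at[ok], left[ok], right[ok]
                if gstrand == "+":
                    tri = left * 16 + 4 + right
                else:
                    tri = (3 - right) * 16 + 4 + (3 - left)
                probs = rate_arr[tri].copy()
                if hotspot_map:
                    for i, p in enumerate(at):
                        m = hotspot_map.get((chrom, gstrand, int(p)))
                        if m is not None:
                            probs[i] = min(1.0, probs[i] * m)
                ks = rng.binomial(n_samples, np.minimum(probs, 1.0))
                ref, alt = ("C", "T") if gstrand == "+" else ("G", "A")
                for p, k in zip(at[ks > 0], ks[ks > 0]):
                    which = rng.choice(n_samples, size=int(k), replace=False)
                    for smp in which:
                        rows.append((chrom, int(p), ref, alt, f"s{int(smp)}"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample"])
    return MutationTable(df)


def write_fixture_bundle(outdir: str | Path, seed: int = 0, n_sites: int = 500,
                         consensus: str = "GGAATT", spacing: int = 300,
                         chrom_length: int | None = None, gc: float = 0.41,
                         effects=(), hotspots=(), n_samples: int = 50) -> pd.DataFrame:
    """Emit a complete FASTA + BED + TSV + JSON fixture bundle.

    Re-running with the same master seed reproduces byte-identical files.
    Returns the manifest (also written as manifest.tsv).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = {name: int(s.generate_state(1)[0] % (2 ** 31))
           for name, s in zip(["truth", "genome", "sites", "damage", "repair",
                               "mutations", "genic", "damage64"], ss.spawn(8))}
    length = chrom_length or (n_sites * spacing + 2000)
    truth = default_truth_tables(sub["truth"])
    genome = generate_genome(1, length, gc, sub["genome"])
    genome, siteset, accessible = plant_sites(genome, consensus, n_sites, spacing,
                                              sub["sites"], score_noise=0.05)
    genic = generate_genic_regions(genome, accessible, n_regions=max(2, n_sites // 50),
                                   length=400, seed=sub["genic"])
    map0h = simulate_damage(genome, accessible, truth, effects, siteset,
                            sub["damage"], "CPD", "0h")
    map6h = simulate_repair(map0h, truth, genome, effects, siteset, sub["repair"], "6h")
    map64 = simulate_damage(genome, accessible, truth, (), siteset,
                            sub["damage64"], "64PP", "0h")
    muts = simulate_mutations(genome, accessible, truth, hotspots, siteset,
                              n_samples, sub["mutations"])
    files = {
        "genome.fa": lambda p: write_fasta(genome, p),
        "sites.bed": lambda p: write_sites_bed(siteset, p),
        "accessible.bed": lambda p: write_bed(accessible, p),
        "genic.bed": lambda p: write_bed(genic, p),
        "cpd_0h.bed": lambda p: write_damage_bed(map0h, p),
        "cpd_6h.bed": lambda p: write_damage_bed(map6h, p),
        "pp64_0h.bed": lambda p: write_damage_bed(map64, p),
        "mutations.tsv": lambda p: write_mutations_tsv(muts, p),
        "truth.json": lambda p: truth.to_json(p),
    }
    for name, writer in files.items():
        writer(outdir / name)
    manifest = pd.DataFrame({
        "file": list(files), "master_seed": seed,
        "substream": [sub.get({"genome.fa": "genome", "sites.bed": "sites",
                               "cpd_0h.bed": "damage", "cpd_6h.bed": "repair",
                               "pp64_0h.bed": "damage64", "mutations.tsv": "mutations",
                               "genic.bed": "genic", "truth.json": "truth",
                               "accessible.bed": "sites"}[f], -1)
                      for f in files],
    })
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
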
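# Methods

## Scope and data model

`phototf` analyses stranded, single-nucleotide UV damage maps over
transcription-factor binding sites. All coordinates are 0-based, half-open
(BED native). A damage record marks one dipyrimidine on one strand;
`pos5` is the reference coordinate of the 5′-most base *on the damaged
strand* (for a minus-strand lesion, the higher reference coordinate). The
on-disk BED dialect always stores the lower reference coordinate of the
dinucleotide in the start column, so a minus-strand record's `pos5` is
`start + 1`; the dinucleotide class is re-derived from the genome on load
and rows at non-dipyrimidine loci are dropped with a logged count.
Duplicate loci are summed on load.

Motif-relative coordinates place 0 at the motif center, defined as
⌊L/2⌋ bases from the motif 5′ end on the motif strand. A dinucleotide
feature is reported at the lower axis coordinate of the two bases it spans
(the "i/i+1" labelling); this is the 5′ base on the motif strand and the
3′ base on the complement strand, giving one shared position axis for both
strands of a profile.

## Formation model

Lesion counts per dipyrimidine locus are modelled as independent Poisson
draws with rate r(c) depending only on the hexanucleotide context c
(NNYYNN, read 5′→3′ on the damaged strand). Rates are estimated as total
damages / total occurrences per context over a background region set —
accessible, intergenic DNA — counting both strands; windows containing N
or crossing a chromosome end are excluded on both sides of the ratio, and
uncovered contexts are flagged rather than silently zero. A
Kolmogorov–Smirnov adequacy check compares the per-locus count
distribution (zeros reconstructed from the occurrence enumeration, since
damage files omit them) to Poisson(rate); the KS statistic is evaluated on
the integer support and the asymptotic Kolmogorov p is reported, which is
conservative for a discrete comparison distribution.

Per cluster, the expected aggregate count at each (position, strand) cell
is the sum of per-site context rates (sums of Poissons are Poisson).
Before testing, the expectation is flank-scaled: for each strand and motif
half, the factor is the mean of observed/expected over flank positions
(inside the ±40 window, outside motif ± 5 bp, expectation > 0); positions
at axis ≤ 0 use the left factor (center column assigned to the left half),
positions > 0 the right. A side with no usable flank position gets factor
1.0 with a warning. The flank definition and margin are configurable.

Each cell with λ′ > 0 is tested one-sided in the direction of its
deviation: p = P(Poisson(λ′) ≥ X) when X > λ′, P(≤ X) when X < λ′, with
z = (X − λ′)/√λ′. BH correction runs jointly over all (position × strand)
cells of one cluster window; clusters are corrected independently. Cells
with λ′ = 0 are excluded from BH and flagged (`model_gap` if they carry
signal). Significance is q < 0.05 for CPD and q < 0.01 for 6–4 PP maps,
whose sequencing background is higher.

**Calibration property of the one-sided convention.** Because the tail is
chosen by the sign of the observed deviation and is not doubled, the null
event {p < α} is the union of both attained tails, so its probability
approaches 2α from below as counts grow, minus discreteness deficits that
are larger in the far tail. The suite measures this directly on no-effect
simulations: the fraction of cells with raw p < 0.05 is ≈ 0.07 (above the
nominal 0.05), while at α = 0.01 the attained fraction ≈ 0.011–0.014 sits
within exact binomial bounds of the nominal level. The q < 0.05 decisions
on planted-effect simulations remain sharply separated from this null
behaviour (detection of a 3× effect in 20/20 seeds with at most one stray
cell across seeds). The convention is retained because it is the
procedure's definition; users needing exact size should halve α.

Clusters whose best position carries fewer than 30 aggregated lesions are
flagged insufficient (limit of detection). Curation keeps sites whose
motif interval overlaps accessible regions (150-bp summit-centered windows
of the top-50% peaks, minus genic DNA), then the top 50% by motif
log-odds score (stable tie-break: score desc, chrom, start), then an
optional per-cluster cap (10,000 for CTCF-sized clusters). Binding-strength
stratification splits into equal tiers (remainder to the top tier) by
descending score.

The orthogonal shuffle null reassigns every damage record (keeping its
count, i.e. preserving per-locus multiplicity) to a uniformly drawn
dipyrimidine locus of the same tetranucleotide (NYYN) class within the
background regions; per-cell null mean/SD give z and the empirical
one-sided p uses (k+1)/(n_iter+1). Records in singleton classes or with
unavailable context shift observed and null equally and are dropped from
the shuffle. On planted 2,000-site clusters the Pearson r between analytic
and shuffle z is 0.93–0.99: the two nulls condition on different context
widths (hexamer vs tetramer, following the respective definitions) and
only the analytic one is flank-scaled, so their per-cell expectations
differ by a fraction of an SD; with real-data proportions (binding sites a
tiny fraction of accessible DNA) the gap shrinks.

A naked-DNA spot-check demotes cellular calls that replicate at the same
(position, strand) with the same direction in a naked-DNA profile to
"sequence-intrinsic"; an opposite-direction replicate is kept and flagged,
since the stated rule excludes only same-direction matches.

## Repair model

Per-NYYN survival is t-count / 0h-count over intergenic accessible
regions, with an optional scalar library-normalization factor per map (off
by default: deposited counts are assumed pre-normalized; results should be
read alongside the normalization used). Contexts below a configurable
0 h-count floor (default 20) are flagged insufficient.

The per-position bootstrap decomposes a cell's 0 h count into per-NYYN
counts n_c and draws Σ_c Binomial(n_c, s_c) with background survivals s_c
— binomial thinning preserves exactly the stated conditioning on initial
burden and NYYN composition. A locus-resampling variant (each unit lesion
draws a background locus of its class weighted by 0 h count and survives
with that locus's own t/0h fraction) is available behind
`kernel="resample"` for sensitivity analysis; the two kernels' z-scores
correlate at r > 0.9 on the synthetic fixtures. The null draws are
flank-scaled as in the formation analysis; the empirical one-sided p for
elevated remaining damage uses (k+1)/(n_boot+1); BH runs across the
window; cells containing a context with flagged survival are excluded and
flagged. The test is one-directional (elevated remaining lesions =
attenuated repair); the reduced direction is reported descriptively.

## Mutation analysis

C>T events are aggregated onto the pyrimidine strand (reference C>T plus
G>A) and strand-pooled per position; profiles span [−w, w+1] so both bases
of a window-edge dipyrimidine are representable, which makes the projected
profile conserve lesion-cytosine counts exactly. The trinucleotide class
of an event is the pyrimidine-strand 3-mer centered on the mutated C
(standard signature convention). Recurrent mutations are counted per
occurrence, matching the damage-count convention (a unique-locus mode is a
one-liner on the input table). The shuffle null mirrors the damage
shuffle with cytosine loci and trinucleotide classes, and its null mean is
flank-scaled per motif side (both the scaled and unscaled means are
reported; the unscaled one conserves totals).

Projection converts every cytosine inside a damaged dipyrimidine into a
C>T at its own position (CC → tandem CC>TT; TT → nothing). Concordance
per cluster: Pearson r, unweighted OLS of actual on projected over window
positions, residual z = residual/SD(residuals) with |z| > 2.58 flagged
discordant; an exact affine relation leaves only float-noise residuals, in
which case all z are set to 0. The randomized baseline correlates a
cluster's projected profile with 5 random other clusters' actual profiles
and averages.

## Structure geometry

Base reference frames come from proper-rotation least-squares
superposition of idealized planar base geometries (packaged constants in
the standard base reference frame) onto the observed ring atoms. Pair and
step parameters use the symmetric mid-frame construction: z-axes are
brought into coincidence by half-rotations about their common hinge, twist
(opening) is the residual rotation about the shared z, the hinge phase
splits the bending angle into tilt/roll (buckle/propeller), and
translations are read in the mid-frame. Exact conventions of external
programs differ in small numerical details; round-trip tests guarantee
internal consistency (constructed helices are recovered to 1e-6).

d22 is the distance between the C5–C6 bond midpoints of adjacent
pyrimidines; d64 runs from the 5′ pyrimidine's C5 to the 3′ base's O4
(thymine) or N4 (cytosine). Stacking overlap projects the two six-membered
rings (exocyclic atoms excluded) onto the mean plane — normal = normalized
sum of the consistently-oriented base-plane normals, anchored at the
centroid midpoint — and takes the polygon intersection area; bases more
than ~78° apart have no meaningful mean plane and are flagged instead of
valued. The interbase angle is read as √(propeller² + buckle²); for a
step, pair-level quantities are averaged over the two pairs. Sugar pucker
uses the Altona–Sundaralingam phase, tan P = ((ν4+ν1) − (ν3+ν0)) /
(2 ν2 (sin 36° + sin 72°)), quadrant from the signs of numerator and ν2,
amplitude ν2/cos P, label by the 36° window containing P; ν2 ≈ 0 resolves
the quadrant from the numerator sign with a warning. Structure filtering
averages per-atom confidence (temperature-factor field) over *all* atoms
of each DNA residue, trims 3 bp from every chain terminus, and rejects
structures with any retained residue below 70. Reactivity thresholds are
user-supplied configuration with no defaults; without them no flags are
emitted.

## Synthetic data

The generator emulates the study conditions the analyses assume: an i.i.d.
genome (GC 0.41 by default), motif instances planted every `spacing` bases
on random strands and centered in 150-bp accessible windows (accessible
regions are exactly those windows; "genic" intervals are generated
separately and disjoint), per-locus Poisson damage with hexamer rates,
binomial-thinning repair with NYYN survivals, and per-sample Bernoulli C>T
mutations with trinucleotide rates. Truth hexamer rates are base rates per
central dinucleotide (TT 0.09, TC 0.055, CC 0.035, CT 0.02 per occurrence
— TT steps most photoreactive, averaging ≈ 0.05 as the working per-site
scale) times a seeded unit-mean lognormal flank modifier (σ = 0.5), giving
the several-fold spread between hexamers sharing a central tetranucleotide
that real damage spectra show. Survival is uniform on [0.2, 0.7] per NYYN
(the repair experiments use a high-burden TT variant and survivals capped
at 0.45 so a 2× planted multiplier stays a valid probability); mutation
rates are lognormal around 2e-4 per sample per cytosine. Effects are
planted as per-(position, strand) rate or survival multipliers at the
sites, the ground truth for recovery tests. All randomness flows from one
master seed via named substreams; `write_fixture_bundle` emits
byte-reproducible FASTA/BED/TSV/JSON bundles.

What the generator does not emulate: mappability and sequencing error,
copy-number and chromatin covariates, nucleosome positioning,
transcription-coupled repair, inter-sample mutation burden variation, or
overlapping/clustered binding sites. Passing tests therefore demonstrate
the statistical machinery (calibration, power, conservation, coordinate
algebra), not robustness to those real-data artefacts. One deliberate
difference from real data matters for interpretation: because accessible
background = site windows, a strong planted effect leaks into the
estimated context rates, so recovered effect ratios are attenuated (a 3×
effect shows ≈ 2× observed/estimated-expected, still detected at |z| > 15
at 2,000 sites against the estimated background, and ≈ 3× against the
truth rates).

## Problem sizes and numerical choices

Validation experiments run at 2,000 sites per cluster (spacing 220 bp,
~440 kb genomes), 50 null clusters per pathway in the acceptance suite
(30 in the default acceptance script), 20 seeds for recovery/power, 2,000
shuffle iterations, and 10,000 bootstrap draws — the bootstrap and shuffle
sizes are the procedure defaults, the rest chosen to give stable fractions
on one CPU in minutes. Empirical p-values use (k+1)/(n+1) and never reach
0. Degenerate cases: X = λ′ gives direction "none" and p = 1; a bootstrap
null with zero variance gives z = 0 when observed equals the mean;
zero-variance profiles give r = NaN (sentinel) rather than a value.
Ties in site selection break by (score desc, chrom, start) for
determinism. Intervals are merged half-open; subtraction output never
overlaps the subtrahend (property-tested against a per-base oracle).

## Known limitations

- The formation p-value convention is anti-conservative at the raw-p level
  (see above); BH-corrected calls on the synthetic conditions are
  nevertheless specific.
- KS p-values against the discrete Poisson are conservative
  (asymptotic Kolmogorov); they are an adequacy screen, not an exact test.
- The repair test covers one later timepoint and the elevated-remaining
  direction only; insufficient-context positions are excluded rather than
  imputed.
- Geometry parameter conventions are internally consistent but can differ
  from other implementations in sign/decomposition details at strongly
  distorted steps; cross-program comparisons should use the same tool on
  both states, as the bound/unbound contrasts here do.
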
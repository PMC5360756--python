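# Methods

This note records the models, parameter choices and numerical conventions
behind `clovermark`, and what the synthetic-data generators do and do not
emulate.

## Pooled polymorphism information content (pPIC)

A pooled DNA sample (one per variety, 16 plants pooled) scored on a gel
yields a dominant band profile, not allele counts. pPIC is the probability
that two pooled samples drawn at random from the panel differ at the
marker. Varieties are split into G1 (any amplified band) and G0 (none);
within G1 each band *i* has frequency f_i and two G1 profiles differ with
probability `pPIC1 = 1 − Π(1 − 2 f_i (1 − f_i))`, assuming bands are
present independently. Two G0 samples never differ, a G1/G0 pair always
does, so `pPIC = p1²·pPIC1 + 2·p1·p0` with p1 = N1/(N1+N0).

Assumptions and conventions:

* **Band independence** is assumed by the product form, not re-derived.
  Linked bands (e.g. alternative alleles of one locus, which are
  anti-correlated) make pPIC1 an approximation.
* A band absent from all of G1 does not exist; every recorded f_i is > 0.
  Bands fixed in G1 (f_i = 1) contribute a factor of 1 — no information —
  and this code path is explicit.
* **Degenerate case** N1 = 0: all samples are indistinguishable, so
  pPIC1 and pPIC are defined as 0.
* pPIC values are comparable only across similar pool sizes; no pool-size
  correction is applied.

The closed form is validated against a Monte-Carlo oracle that simulates
pairs of pooled samples (amplification Bernoulli(p1), bands
Bernoulli(f_i), unconditioned) and counts disagreements; agreement is
required within 3 standard errors at 10⁶ pairs per configuration, with a
1e-5 absolute floor to guard the degenerate zero-variance corner.

## Botstein PIC and tetraploid dosages

`PIC = 1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`, computed via the algebraic
identity `Σ_{i<j}2p_i²p_j² = (Σp_i²)² − Σp_i⁴` and cross-checked in tests
by explicit double-sum enumeration. Tetraploid genotypes arrive as counts
of the five dosage classes RRRR…AAAA; the alternative-allele frequency is
the mean dosage divided by the ploidy (4). Distribution summaries report
min/max/mean/median to 3 decimals; the median of an even count is the mean
of the two central order statistics; threshold counts are strict (>).

## SSR mining

For each motif period p ∈ 1..6 the scanner finds maximal stretches where
the sequence equals itself shifted by p; a stretch of length L anchors
⌊L/p⌋ full repeats at its left end. Only primitive motifs are kept (a
motif that is a power of a shorter one is found at the shorter period), so
each repeated span is reported once. Overlapping runs of different periods
are resolved by keeping the longer span, ties to the smaller period — a
maximal description with the simplest motif. Runs are split at N:
ambiguity cannot certify a perfect repeat. Motifs are reported on the
given strand normalized to the lexicographically smallest rotation; no
reverse-complement merging, because coding sequences are stranded.

Default repeat thresholds: mono 12, di 6, tri/tetra 4, penta/hexa 3.
Consecutive simple runs separated by ≤ 10 bp (configurable) merge into one
complex locus carrying its components; compound-microsatellite conventions
do not fix this gap, and one complex locus counts as one marker in
summaries.

**Primer screen.** Full thermodynamic primer design is out of scope. A
locus is primer-designable when 18–24 bp flanking windows exist on both
sides whose estimated Tm lies within ±3 °C of the 55 °C target and whose
implied product length (left window start to right window end) falls in
100–350 bp. Tm uses the Wallace rule 2(A+T)+4(G+C) up to 20-mers and the
GC-fraction formula 64.9 + 41·(GC − 16.4)/N above; both are crude but
standard screens, and the model is intentionally replaceable. The chosen
pair minimizes summed Tm deviation, ties to the shortest product, then
leftmost/shortest windows — fully deterministic. A locus too close to a
sequence end for any in-range product fails with reason
"insufficient flank".

Summary reports give class counts, the primer-designable fraction, the
fraction of sequences with ≥ 1 locus, density as total coding length per
designable marker (NA at zero, never a division error), a loci-per-sequence
histogram, and the fraction of simple non-trimeric loci whose length is a
multiple of 3 (reading-frame preservation, a known signature of selection
in coding sequence). Fractions are rounded to 1 decimal.

## SNP filtering and composition

High quality means QUAL ≥ 30 and depth ≥ 10, both inclusive, QUAL compared
as a real number. Depth comes from FORMAT/DP of the first sample when
present, else INFO/DP — sample-level depth is the per-site evidence the
filter intends. Indel rows are skipped at parse (counted); mixed SNP/indel
alternative lists keep only the single-base alternatives. Rows missing
QUAL or depth are retained but can never pass the filter ("unfilterable",
counted).

Sites with > 1 alternative allele form their own multiallelic category,
excluded from the transition/transversion tally, so the three category
totals always partition the record count. Composition tables report
within-class and whole-set percentages to 2 decimals; densities (bp per
SNP, SNPs per gene) to 1 decimal.

## Diversity and UPGMA

Per marker, variety similarity is Jaccard `n_xy/(n_x+n_y−n_xy)` or
Sørensen–Dice `2n_xy/(n_x+n_y)` on band sets; distance is 1 − similarity.
Two profiles in which the marker amplified nothing are indistinguishable
there, so the both-empty similarity is 1 (distance 0); empty against
non-empty is 0. This keeps distances defined for markers amplifying in
only part of the panel. Distance matrices are averaged element-wise over
**all** markers, monomorphic ones included (they contribute zeros).

UPGMA repeatedly merges the closest pair at half its distance; the merged
cluster's distance to the rest is the size-weighted mean. Ties are broken
by the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf label), so trees are invariant to input
order. Heights are in distance units. Dice is a monotone transform of
Jaccard, so per-marker distance orderings — and single-marker UPGMA
topologies — agree between the two indices; averaging can still differ.
The `DistanceMatrix` container accepts any non-negative symmetric matrix
with a zero diagonal, although band-derived distances lie in [0, 1] by
construction. Trees serialize to Newick with labels quoted when they
contain metacharacters; round trips are checked against an independent
parser to 1e-9.

## Synthetic-data generators

One integer seed feeds a root `SeedSequence`; the band, sequence, variant
and genotype generators each draw from their own spawned child stream, so
adding a generator never shifts another's output. Identical configurations
give byte-identical files.

* **Band matrices** emulate gel scoring of a 50-variety panel (pools of
  16). Per marker and variety, amplification succeeds with the marker's
  amplification probability; amplified profiles draw bands independently
  and are rejection-resampled to show ≥ 1 band, since an amplified sample
  by definition has a product. This conditioning raises the expected
  marginal of band *i* from f_i to `f_i / (1 − Π_j(1 − f_j))`, exposed as
  `MarkerModel.conditional_band_freqs()`; calibration tests compare
  against that exact conditional expectation, which coincides with the raw
  f_i whenever the all-absent probability is negligible. When no explicit
  marker models are given, 95 markers are drawn with 1–17 bands (the
  band-count range seen in validated panels), band frequencies uniform on
  [0.05, 0.95] and amplification probability uniform on [0.6, 1], matching
  a panel in which most markers amplify in most varieties. The only
  failure mode modelled is whole-profile amplification failure — no band
  dropout or mis-binning, so passing tests say nothing about gel-scoring
  noise on real data.
* **Coding sequences** are i.i.d. uniform ACGT with microsatellites
  planted at exact 1-based positions (default: one (AAG)×4 run per 600 bp
  sequence, mid-sequence so primer flanks exist). Bases adjacent to a
  planted run are set so the run cannot extend, keeping truth coordinates
  exact; any chance run reaching the mining thresholds outside planted
  intervals has a base replaced until the scanner finds only the truth
  set. At the default thresholds chance runs are vanishingly rare in
  600 bp of uniform background. Real coding sequence is not uniform
  (codon structure, GC bias), so recovery rates here bound only scanner
  correctness, not field sensitivity.
* **Variant call sets** draw biallelic sites as transitions with
  configurable odds (default 217894/121068 ≈ 1.80, the composition of the
  emulated red clover call set) and a multiallelic fraction (default
  0.0119). QUAL ~ Normal(45, 12) truncated at 0 and depth ~ Poisson(18)
  straddle the 30/10 thresholds so both filter outcomes occur at realistic
  rates. Truth records the class and expected pass flag per site.
* **Tetraploid genotypes** draw a per-locus allele frequency uniform on
  [0.05, 0.95] and per-plant dosages Binomial(4, q) for 20 plants —
  Hardy-Weinberg-style random chromosome pairing, no double reduction or
  inbreeding.

## Problem sizes in the checked properties

Scanner/brute-force equivalence runs on 1,000 fuzzed sequences (20 bp to
2 kbp, mixed alphabets including N, both relaxed and default thresholds);
the pPIC Monte-Carlo check on 100 random configurations at 10⁶ pairs each;
UPGMA against an independent average-linkage implementation on 500 random
6×6 matrices (distinct entries almost surely, so tie-breaking cannot
diverge); planted-run recovery on 100 sequences; call-set composition
recovery at 10,000 sites and band-frequency recovery at 10,000 varieties,
both within 3 Monte-Carlo standard errors. All randomized tests are
seeded and deterministic.

## Known limitations

* pPIC inherits the band-independence assumption; no confidence intervals.
* The primer screen ignores primer-dimer, hairpin and specificity
  constraints and uses coarse Tm formulas.
* Imperfect (interrupted) single runs are not mined; only perfect runs
  and their compound merges.
* Gel band binning across gels is assumed already done; the band-matrix
  TSV is the contract.
* The generators model no population structure among varieties; cluster
  recovery tests construct group structure explicitly at the band level.
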
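# clovermark

Marker mining and polymorphism analysis for pooled-sample plant genetics,
modelled on the marker workflow of red clover (*Trifolium pratense*)
breeding programmes.

Outcrossing forage crops are genetically heterogeneous within a variety,
so routine genotyping is done on **pooled DNA samples** (here 16 plants per
variety) scored on a gel as dominant band presence/absence. That makes the
classical polymorphic information content (PIC) — which needs allele
frequencies — unusable. `clovermark` implements the pooled analogue
(**pPIC**) together with the surrounding marker pipeline:

* **SSR mining** — detection of perfect and compound microsatellites in
  coding sequences (monomers ≥ 12 repeats, dimers ≥ 6, tri-/tetramers ≥ 4,
  penta-/hexamers ≥ 3), a primer-feasibility screen targeting Tm = 55 °C
  and 100–350 bp products, and density/composition reports.
* **SNP summaries** — VCF ingestion, the high-quality filter
  (QUAL ≥ 30 and depth ≥ 10), transition/transversion/multi-allelic
  classification, composition tables and density statistics.
* **Polymorphism statistics** — pPIC for dominant band profiles and
  Botstein PIC for codominant tetraploid SNP genotypes
  (dosage classes RRRR…AAAA).
* **Diversity analysis** — Jaccard / Sørensen–Dice similarities on band
  profiles, per-marker distance matrices averaged over all markers, and
  UPGMA dendrograms exported as Newick.
* **Synthetic data** — seeded generators for every input format with the
  generating truth returned alongside, so each stage is testable without
  any external download.

## The statistics

For one SSR marker, varieties split into G1 (≥ 1 amplified band, N1 of
them) and G0 (no product, N0). With f_i the frequency of band *i* among G1
profiles and p1 = N1/(N1+N0), p0 = 1 − p1:

```
pPIC1 = 1 − Π_i (1 − 2 f_i (1 − f_i))        # two G1 samples differ
pPIC  = p1² · pPIC1 + 2 p1 p0                # + G1-vs-G0 always differ
```

pPIC estimates the probability that two randomly drawn pooled samples can
be told apart at the marker. For codominant loci with allele frequencies
p_i the Botstein PIC is

```
PIC = 1 − Σ_i p_i² − Σ_{i<j} 2 p_i² p_j²
```

maximal at equifrequent alleles (0.375 for a biallelic locus at p = 0.5).
Tetraploid allele frequencies come from dosage counts: freq(A) = mean
dosage / 4.

## Worked example

```python
from clovermark import ppic, pic

profiles = {
    "Agil":   {"150bp", "162bp"},
    "Bonus":  {"150bp"},
    "Start":  {"162bp"},
    "Tatra":  {"150bp", "162bp"},
    "Kvarta": set(),            # no PCR product: group G0
}
stats = ppic(profiles, marker_id="SSR-demo")
print(stats.n1, stats.n0, stats.p1, stats.p0)   # 4 1 0.8 0.2
print(stats.band_freqs)                          # (0.75, 0.75)
print(round(stats.ppic1, 4), round(stats.ppic, 4))  # 0.6094 0.71
print(pic([0.5, 0.5]))                           # 0.375
```

Four varieties amplified (p1 = 0.8); both bands occur at frequency 0.75
within that group, so two amplified pools differ with probability
pPIC1 = 1 − (1 − 2·0.75·0.25)² ≈ 0.6094. Weighting by group sizes and
adding the amplified-vs-failed contrast gives
pPIC = 0.8²·0.6094 + 2·0.8·0.2 = 0.71: a usefully polymorphic marker.
The last line is the analytic PIC maximum for a biallelic SNP.

The same computations are available from the shell:

```
clovermark simulate bands --seed 7 --out-dir sim
clovermark ppic --bands sim/bands.tsv --out ppic.tsv
clovermark diversity --bands sim/bands.tsv --index dice \
    --out-matrix dist.tsv --out-tree tree.nwk
```

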
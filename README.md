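# dsbscars

Analysis of the mutational *scars* that error-prone repair of DNA
double-strand breaks (DSBs) leaves in genomes, built around the signatures of
polymerase theta-mediated end joining (TMEJ, also called alternative end
joining): microhomology at deletion junctions, small flank-templated inserts,
and characteristic deletion-size spectra. The package targets data like
*C. elegans* transposon-excision footprints, nuclease-induced repair alleles,
mutation-accumulation lines and natural-isolate genomes, but every operation
works on plain FASTA + event tables from any organism.

## What it computes

**Junction microhomology.** A deletion whose two flanks share sequence can be
placed in several shift-equivalent ways; the number of equivalent placements
minus one is the junction's microhomology (MH), the hallmark left by
TMEJ's minimal base-pairing. `microhomology` computes it exactly,
`canonicalize` reduces any report to the leftmost placement, and
`classify_footprint` assigns each event to one of four repair classes:
simple deletion without homology, simple deletion with junction homology,
deletion with an insert, and deletion with a *templated* insert (insert
identical to sequence within a configurable window of the break,
`find_templated_insert`).

**Random-deletion null.** For deletions placed uniformly in a genome with
i.i.d. base frequencies *q*, each flank base matches with probability
*p* = Σ *q*<sub>b</sub>², so

&nbsp;&nbsp;&nbsp;&nbsp;P(MH ≥ 1) = 1 − (1 − *p*)², &nbsp;
P(MH = k) = (k+1) *p*<sup>k</sup> (1 − *p*)².

For a worm-like composition (A = T = 0.3225, C = G = 0.1775) this gives
0.47 — the reference line for deletion spectra. `empirical_mh_null` confirms
it by resampling on any supplied genome, and `spectrum_binomial` tests
size-binned observed MH fractions against it with one-sided exact binomial
tests.

**Variant filters.** The acceptance rules used for sequencing-derived calls:
mutation-accumulation variants (both strands, ≥5× coverage, no residual
reference reads, all other samples of the genotype group reference),
natural-isolate deletions (≥8 supporting reads, >3-fold interval coverage
drop, ≥5 other isolates with normal coverage, unique to one isolate),
phylogeny-grade SNVs (quality ≥100, ≥5 reads, >80 % variant fraction, both
strands), plus microsatellite-context exclusion for spectrum statistics.

**Transposon hallmarks.** Tc/mariner insertions are verified by their
target-site duplication: a TA or TCA duplicated around a novel segment whose
ends match a transposon library (`detect_insertion_hallmark`); excision
footprints are expressed against the element-less locus and fed to the
junction classifier (`detect_excision_footprint`).

**Reversion frequency.** The Poisson (P0) fluctuation estimator
f = −ln(P0)/2n from plate counts, with exact Clopper–Pearson intervals
(`reversion_frequency`).

**Synthetic data.** Seeded generators for i.i.d. genomes, deletion sets under
random / TMEJ-like / POLQ-null-like / blunt-join models, transposon
insertion and excision loci, variant-support tables with planted filter
violations, and plate assays — each with a truth table, so the whole pipeline
is testable without external downloads.

## Worked example

```python
import dsbscars as d

genome = d.simulate_genome(100_000, seed=7)               # worm-like GC 0.355
params = d.SimulationParams.for_model("tmej", 500, seed=8)
events, truth = d.simulate_deletions(genome, params)
ann = d.classify_events(genome, events)

summary = d.summarize_events(ann)
print(summary.loc[summary["sample"] == "ALL",
                  ["n_events", "size_median", "frac_simple_mh_ge1",
                   "frac_templated", "n_distinct_footprints"]])

null = d.analytic_mh_null(genome.composition)
for b in d.spectrum_binomial(ann, p0=null.p_mh_ge1):
    if b.n_events:
        print(f"[{b.size_lo:g},{b.size_hi:g}) n={b.n_events:<4d} "
              f"frac={b.frac_mh_ge1:.2f} p={b.p_value:.2e}")
```

prints

```
 n_events  size_median  frac_simple_mh_ge1  frac_templated  n_distinct_footprints
      500          7.0            0.979328           0.226                    498
[1,5) n=123  frac=1.00 p=3.18e-41
[5,10) n=115  frac=1.00 p=1.37e-38
[10,20) n=92   frac=0.95 p=4.97e-23
[20,50) n=53   frac=0.94 p=1.28e-13
[50,100) n=4    frac=1.00 p=4.82e-02
```

The simulated TMEJ set recovers its generating conditions: median deletion
size 7 bp, 23 % templated inserts, and junction homology far above the 0.469
random expectation for this genome's composition — every well-populated size
bin is elevated at P < 0.001, exactly the pattern that distinguishes
TMEJ-generated deletion spectra from randomly placed ones.

The same stages are available from the shell:

```sh
dsbscars simulate --model tmej --n 500 --seed 7 --out-prefix sim
dsbscars classify --genome sim.fa --events sim.events.tsv --out ann.tsv
dsbscars null --composition 0.3225,0.1775,0.1775,0.3225
```

Every command writes a `<out>.log.json` sidecar with its parameters and seed.

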
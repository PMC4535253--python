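# wgadiff

Variant-call concordance between whole-genome-amplified and native DNA
exomes, on fully synthetic data where the truth is known.

Archival samples — dried newborn-screening bloodspots are the motivating
case — often hold too little DNA for exome sequencing without whole-genome
amplification (WGA, Phi29 multiple displacement amplification).
Amplification buys material at the cost of artifacts: chimeric fragments,
strong locus-to-locus coverage bias, and allelic dropout.  A map-first
pipeline (align, pileup, genotype, hard-filter) then reports tens of
thousands of "extra" SNVs in the amplified library, but an unknown share of
those are alignment artifacts, not amplification chemistry.  `wgadiff`
rebuilds this whole comparison at desk scale:

- a **synthetic-data generator** producing a diploid individual, capture
  kits, and paired-end libraries with or without a parametric MDA artifact
  model (chimera rate, log-normal amplification bias, allelic dropout,
  extra base error);
- a **map-first caller**: seed-and-extend ungapped alignment, strand-resolved
  pileup, diploid genotyping with per-read likelihoods
  `P(b|RA) = ½(1−e) + ½e/3` under a flat prior over {RR, RA, AA}, and a
  fixed-threshold hard filter;
- a **reference-free kmer differential filter**: canonical 25-mer counts per
  sample, sample-unique kmers (count ≥ 3 in one library, 0 in the other),
  reads retained only when ≥ 2 of their kmers are sample-unique, variants
  re-called on the survivors;
- **concordance analytics**: union-denominated site/genotype concordance,
  depth stratification at {1,10,20,30}X in both samples, novelty against a
  simulated known-variant panel, recovery against planted truth;
- a **capture-kit comparison**: binned coverage tracks, kit-unique region
  detection, SNV density, and plot-ready interval tables.

The central measurement: with the same diploid truth behind both libraries,
discordance between gDNA and wgaDNA calls under the map-first route is
several-fold larger than under the kmer-filtered route — the filtered route
never sees reads that carry no sample-private sequence, so shared alignment
noise cannot become "amplification variants".

## Worked example

`examples/03_wga_concordance.py` simulates one individual (40 kb genome,
120 SNVs), sequences it twice — native and through the default MDA profile —
and compares the two analysis routes:

```
map-first: 58 gDNA vs 33 wgaDNA PASS SNVs, 32 shared, 26+1 discordant (site concordance 54.2%)
  >= 1X in both:  58 sites retained (98%), concordance 55.2%
  >=10X in both:  40 sites retained (68%), concordance 72.5%
  >=20X in both:  28 sites retained (47%), concordance 71.4%
  >=30X in both:   6 sites retained (10%), concordance 66.7%
kmer-filtered: 3 discordant SNVs (vs 27 map-first)
```

Reading the numbers: amplification bias and dropout make the wgaDNA library
miss 26 of the gDNA calls (and add 1); requiring ≥10X in both samples
discards the low-coverage sites where most of that disagreement lives, so
concordance rises while only 68 % of sites survive the cut.  The
reference-free route reduces the 27 discordant map-first calls to 3 — the
residue that reflects genuine sequence difference between the libraries
(dropout-suppressed alleles), while the rest was coverage and alignment
noise.

The other examples cover library simulation and artifact bookkeeping
(`01`), reference-free recovery of sample-private SNVs (`02`), and the
capture-kit comparison (`04`).  Each prints its numbers with a line on what
they mean.

There is also a thin CLI (`wgadiff simulate|count|filter|diff|call|concord|
kitcompare|demo`); `wgadiff demo --seed 1 --out demo/` runs all three
experiments end to end and writes JSON reports, depth-stratification
tables, and plot tables — byte-identically for a given configuration.

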
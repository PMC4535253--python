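# Methods

`wgadiff` is a desk-scale model system for a practical question in exome
sequencing of archival material: when the only usable DNA has been through
whole-genome amplification (WGA, multiple displacement amplification with
Phi29 polymerase), how many of the "extra" SNVs seen in the amplified
library are real amplification artifacts, and how many are alignment
artifacts that a reference-free analysis would never have called?  The
package answers this on fully synthetic data, where truth is known, by
running two analysis routes over matched simulated libraries and measuring
their discordance.

## The simulation model

**Reference and truth.** A haploid reference contig is drawn i.i.d. with a
configurable GC fraction (default 0.5, split evenly between G/C and A/T).
SNVs are planted with a minimum pairwise spacing (default 60 bp, chosen to
exceed the kmer length so each variant's kmer neighborhood is independent);
heterozygous variants (default fraction 0.5) go to one uniformly chosen
haplotype, homozygous to both.  Indels and structural variants are out of
scope throughout; the haplotypes therefore stay length-matched and all
coordinates are shared.

**Sequencing.** Fragments of Normal(200, 20) bp yield 2x100 bp paired-end
reads (mate 2 reverse-complemented), matching a standard short-insert
exome library.  Fragment starts are drawn so that the mean-length fragment
overlaps a capture target with probability `efficiency` (default 0.95) and
uniformly genome-wide otherwise.  The fragment count is
`depth x target_span / (2 x read_length)`, so the nominal depth (default
25X, 20–30X being the regime of interest) is the expected on-target mean.
Substitution errors are i.i.d. per base (default 10^-3); base qualities are
a constant Q30 by default (a linear position-decaying model is available)
because the genotyper uses a single error-rate parameter, not per-base
qualities.

**The MDA artifact model** (`WgaProfile`) has four knobs, all zero for
native DNA:

| parameter | default | meaning |
|---|---|---|
| `chimera_rate` | 0.05 | per-fragment probability of one chimeric junction; the 3' remainder continues from a uniform donor locus and strand, junction position uniform in the fragment |
| `extra_error_rate` | 0.001 | per-base substitutions added on amplified templates |
| `bias_sigma` | 1.0 | log-scale SD of per-500 bp-window amplification weights (weights `exp(sigma * z)`), giving the order-of-magnitude local coverage swings typical of MDA |
| `dropout_rate` | 0.05 | per-heterozygous-site probability that one haplotype's amplicons vanish library-wide |

The defaults were fixed once, from the MDA literature's commonly reported
ranges (percent-scale chimerism per short fragment, strong log-normal
coverage bias, single-digit-percent allelic dropout), as the package's
standing study conditions — they are inputs to the experiments, not fitted
quantities.  Dropout is deliberately all-or-nothing per site per library
(not per fragment): MDA dropout arises from failure of early displacement
events and is effectively binary at usual input masses.  Chimeras get a
single junction with a genome-wide uniform donor; real MDA chimeras favor
nearby inverted repeats, but the uniform model already produces the
unalignable / partially-aligning reads whose downstream behavior is the
point of the study.

The zero profile is byte-identical to the native simulation — the artifact
draws are made on the same RNG stream and scale to no-ops — so native and
amplified libraries differ only by the artifact model, never by stream
bookkeeping.  Every stage draws from a child stream derived from
`(master_seed, stage label)`, making each stage independently reproducible.

**Read names** encode provenance
(`frag<i>:<contig>:<start>:<hap>:<chimera-flag>`), which is how the
experiments attribute false positives to chimeras vs dropout vs error
without side files.

## The two analysis routes

**Map-first.** A seed-and-extend ungapped aligner (exact 15-mer seeds at
stride read_length/4 plus an end-anchored seed, both orientations,
Hamming-scored candidates, best placement wins, ties at mapq 0, margin-scaled
mapq otherwise, `max_mismatch` 4) feeds a strand-resolved pileup
(mapq >= 20).  Each column with non-reference support is genotyped under the
standard diploid likelihood: per-read P(b|RR) = 1-e or e/3,
P(b|RA) = (P(b|R)+P(b|A))/2, AA symmetric, flat prior over {RR, RA, AA},
call = max-posterior non-RR genotype, qual = phred(1 - posterior), capped at
120 (GQ capped at 99 per convention).  The genotyping error rate defaults to
0.01, deliberately a little above the simulated base error so marginal
support is penalized.  Hard filtering then annotates (never removes) calls:
qual < 30, depth < 4, depth > 4x mean depth, alt fraction < 0.2, or > 95% of
alt reads on one strand.  These are declared thresholds in the spirit of
fixed "hard filter" practice, not a reproduction of any specific tool's
expressions.  Ungapped alignment is sufficient because only SNVs are
simulated; reads across chimera junctions align partially or not at all,
which is the mechanism under study, not a defect.

**Kmer-differential.** Canonical 25-mers (odd, well under the read length,
in the range used by kmer counters at exome scale) are counted per sample.
A kmer is *sample-unique* if seen >= 3 times in the possessing sample
(singleton error kmers cannot qualify) and <= 0 times in the other (strict
absence; relaxable).  A read is kept if >= 2 of its kmer windows are unique
(a single shared-error kmer cannot rescue a read; a true interior SNV
contributes up to 25).  Pairs are kept if either mate passes (default),
preserving pairing for the downstream caller.  The surviving reads — only
those carrying sequence genuinely private to their sample — go through the
same map-and-call stage.  Identical inputs therefore yield zero unique
kmers, zero retained reads, zero differential calls, which is the package's
technical-replicate null.

## Concordance arithmetic

Concordance is union-denominated over site keys (contig, pos, ref, alt);
per-sample rates are emitted alongside since published percentages often
use per-sample denominators.  In genotype mode the genotype joins the key —
the only definition under which n_union = n_intersection + n_only_A +
n_only_B survives genotype mismatches at shared sites.  Depth stratification
at threshold t keeps keys with DP >= t in both call sets; for keys private
to one set, the other sample's pileup depth is consulted when available, so
"absent because never covered" does not masquerade as disagreement.
Retention is an AND of >= t conditions, hence monotonically non-increasing
in t.  Empty denominators yield NA, never 0.  Novelty against the simulated
known panel is exact key membership.

The known panel is generated to contain 96% of the subject's true variants
plus extra population variants the subject lacks, so novelty fractions of
calls are interpretable against a realistic "most real variants are known"
background.

## Capture-kit comparison

Coverage tracks are per-100 bp-bin means of per-base depth (bin value =
depth mass / bin_size, so track mass conserves aligned bases).  A region is
kit-unique when a run of bins has one kit >= 8X and the other below, with a
minimum run length.  The operation's default minimum run is 100 bp; the
experiment driver uses 300 bp because coverage on target flanks ramps over
roughly a fragment length and single flank bins flicker around any fixed
depth floor — designed targets in the experiments are >= 1.5 kb, so the
stricter run length costs no recovery.  Recovery is scored as base-level
Jaccard between recovered regions and designed kit-private targets;
recovered regions systematically overhang each designed edge by about one
bin plus part of the flank ramp, which bounds the achievable Jaccard just
under 1 by construction.

## Problem sizes

The experiments and the acceptance script run on 40–100 kb genomes with
120–200 planted SNVs at 25–30X — the package's chosen desk-scale analog of
an exome design whose full-scale inputs are not publicly deposited.  At
these sizes a full three-experiment run completes in well under a minute
per analysis; the paired amplified-vs-native comparison is repeated over 10
seeds to make the directional claim (map-first discordance exceeds
kmer-filtered discordance) a statement about the design rather than one
draw.

## What the generator does and does not emulate

It emulates: capture geometry with off-target mass and flank ramps, diploid
allele sampling, sequencing error, and the three MDA artifact classes.  It
does not emulate: repeats, segmental duplications or low-complexity tracts
(the i.i.d. reference is repeat-free, so map-first false positives from
paralogy are under-represented and the map-first-vs-kmer gap measured here
is a conservative floor); indels; PCR duplicates; GC-dependent capture
bias; quality miscalibration.  Passing tests therefore demonstrate the
pipeline's arithmetic and the direction and mechanism of the
amplification/alignment effects — not calibrated magnitudes for any real
exome.

## Numerical and degenerate-input conventions

Ambiguous (non-ACGT) kmer windows are skipped, never fatal; reads shorter
than k contribute nothing.  Alt-allele ties in genotyping break to the
lexicographically smallest base; alignment ties to the lowest (contig,
position) with mapq 0.  Mean depth for the high-depth filter is the mean
over covered positions only.  VCF/BED writers state their coordinate
conventions (1-based / 0-based half-open); truth VCFs round-trip exactly.
Unalignable reads are records with `aligned=false`, not errors; zero-read
pipelines produce valid empty VCFs.
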
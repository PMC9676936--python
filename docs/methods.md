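# Methods

This note documents the models, parameter choices and numerical decisions
behind `homeoplex`, and what the synthetic-data experiments do and do not
demonstrate.

## The analysis problem

Hexaploid wheat carries three homoeologous copies of the vernalization
gene *VRN1* (~92% pairwise identity). A single long-PCR primer pair
amplifies all three (~13 kb gene body + ~700 bp promoter); barcoded
amplicons from a cultivar panel are pooled on one nanopore run. The
analysis must (i) demultiplex and discard chimeric molecules, (ii)
attribute each read to the right homoeolog, (iii) call structural variants
(≥ 30 bp), SNPs and small indels per cultivar and homoeolog, (iv) phase
haplotypes and estimate gene copy number from allele dosage, (v) group
cultivars by their variant vectors, (vi) scan for G-quadruplex motifs, and
(vii) test trait associations between groups.

All coordinates facing the user are 1-based and counted from the first
amplicon base (the base after the forward primer's 3′ end); internal
arithmetic is 0-based half-open, converted only at I/O boundaries.

## Synthetic references and the variant catalog

`generate_references` draws a random ancestor and mutates three lineages
independently (90% substitutions, 10% indels of 1–5 bp per mutation
event), calibrating the per-lineage rate over a few deterministic
iterations so that all three pairwise global identities land within ±0.02
of the target (0.92 by default). Pairwise identity is defined as
1 − editdist/max(length). The gene model is promoter (700 bp), exon 1,
a first intron that absorbs the remaining length (~70% of the gene, as in
*VRN1*), and a fixed block of exons 2–8/introns 2–7 sized so the catalog's
printed positions fall in their annotated regions (e.g. the exon-4 dosage
site at 11,109, the exon-7 site at 11,735). A quadruplex-forming G-rich
motif is planted in the promoter and twice in intron 1 and protected from
divergence, so motif scanning always has known positives.

`catalog` holds the known *VRN1* polymorphisms: the spring-allele
structural variants (231 bp promoter insertion *Vrn-A1a*, 6,851 bp and
37 bp intron-1 deletions *Vrn-B1a*/*Vrn-B1b*, 838 bp intron-1 tandem
duplication *Vrn-B1f*, 163 bp insertion *Vrn-D1x*, 17 bp deletion
*vrn-D1r*), the 51-site *VRN-A1* substitution/indel catalog across six
genotype-group backbones (GT1–GT6, with the heterozygous intron-1/exon-4
sites whose dosage tracks copy number), the six-site *VRN-B1* haplotype
table and the three *VRN-D1* variants. SNP/indel coordinates follow the
published site lists; SV start coordinates are this package's synthetic
placements, chosen consistently with the published constraints (the large
deletion spans the two *VRN-B1* sites it erases; the duplication spans the
two duplication-induced heterozygous sites; the 37 bp deletion lies
downstream of the large one). `prepare_panel` installs each catalog site's
reference base and rewrites ±5 bp of context so that no homopolymer run of
≥ 4 touches a site (the homopolymer exclusion filter models a sequencing
artifact and must not swallow planted variants), and makes indel-site
contexts rotation-free so left-aligned calls land on the printed
coordinate.

## Read simulation

Per cultivar and homoeolog the expected read count is
`mean_coverage × Σ(copy weights)` (Poisson), and each read's template copy
is drawn proportional to its amplification weight — so dosage at
heterozygous sites equals copy proportions, and extreme weights reproduce
preferential amplification of short deletion alleles. Reads are
full-length with probability 0.9 (0.8 in some scenarios), otherwise a
fragment of ≥ 500 bp keeping one molecule end. Error model defaults:
substitutions 3%, insertions 2%, deletions 4% per base, indel rates ×3
inside homopolymer runs ≥ 4, insertions modelled as stutter copies —
approximating R9.4.1-era accuracy. The paper trail for this choice is
thin: the real runs' per-base error rates are not published, so the
defaults are calibrated to reproduce two observable outcomes (the ~15%
chimera fraction is a direct parameter; ≥ 99.2% consensus identity at
100× emerges from the error rates). Chimeras concatenate two barcoded
molecules; barcode loss drops both barcodes. Per-base qualities are
emitted from the local error rate (−10·log₁₀(p)) plus a per-read offset
(SD 2.5) and per-base noise (SD 1.5), giving the mean-Q filter a realistic
workload. A zero-rate model produces exact template substrings. Identical
seeds give byte-identical FASTQ/TSV.

What the generator does **not** emulate: signal-level artifacts
(raw-current basecalling errors are only approximated by the
substitution/indel/homopolymer process), systematic strand biases,
context-specific error hotspots beyond homopolymers, PCR point errors as
distinct from sequencing errors, and real wheat sequence (references are
random ancestors, not genomes). Passing tests therefore demonstrate the
*logic* of the pipeline under a realistic noise budget, not performance on
any particular real dataset.

## Alignment: two-pass seed-chain-and-stitch

Unit-cost (edit-distance) alignment is the only primitive available from
the installed aligner library, and it has two failure modes for this
problem: (1) optimal paths are massively degenerate around large indels —
the optimum shatters a 6.8 kb deletion into hundreds of fragments
interleaved with spurious matches, and a semi-global mode even prefers
mangling a read prefix over paying for the deletion; (2) short reads
against a long reference make terminal-gap placement degenerate too. The
aligner therefore works in two passes, the structure long-read mappers
use:

1. **Coarse:** unique exact 16-mers shared between read and reference are
   chained colinearly (longest increasing subsequence), and same-diagonal
   runs compress into exact anchors (≥ 30 bp at the top level).
2. **Fine:** between anchors, a region whose net length change is ≥ 20 bp
   is re-fit with a single explicit gap at the minimum-mismatch breakpoint
   (leftmost on ties — left-aligning events in repeats), flanks re-aligned
   optimally; smaller regions get a plain optimal sub-alignment. Read
   overhangs are aligned against matching-length reference windows, and
   terminal segments that contain a large gap beyond the outermost anchor
   are clipped (they are the signature of a partial read's missing span
   coincidentally matching elsewhere).

Identity is gap-compressed (a gap run counts one column), so an SV carrier
is not penalised per deleted base; aligned fraction counts read bases in
match/mismatch columns. Reads are assigned to the best homoeolog only when
identity ≥ 0.80 and aligned fraction ≥ 0.50 and the runner-up is ≥ 50 edit
units worse — the analog of a mapping-quality cutoff in a re-implementation
that has no mapq. Ambiguous and unaligned reads are excluded downstream.
Tandem-duplication insertions may be recovered as a rotation of the
repeated unit, so duplication classification searches the reference flank
within the doubled insert sequence.

Known limitation: two structural variants separated by less than ~20 bp of
unique sequence can coalesce into one event (the intervening island is too
short to anchor); the two *VRN-B1* deletions, separated by ~50 bp, stay
separate.

## Variant calling

SNPs are called from pileup columns with the published filter set — depth
≥ 11, minor allele count ≥ 3, site quality ≥ 30 — plus a minor-allele
frequency floor of 0.20, which tolerates dosage imbalance to 4:1 so that
a 2:1 heterozygous site (three gene copies) still calls het. Site quality
is the Phred-scaled binomial tail of the allele count against a 5%
background error; the published threshold value (30) is kept while the
score itself is necessarily this package's own definition, since the
original caller's score scale is proprietary to that caller.

Two artifact mechanisms required explicit counter-measures, both standard
in long-read practice:

- **Reference bias / allele-aware realignment.** At a substitution site
  flanked by indel noise, the optimal path can route the alternate base
  into a gap and display the reference base — 10–20% of reads at an
  affected site. All counts at candidate sites (calling, dosage, phasing)
  are therefore refined by re-aligning each read's local segment (±20 bp)
  against one candidate window per allele and assigning it to the closest;
  ties are ambiguous and count for nothing.
- **Indel-error aggregation.** Alignment normalisation concentrates
  single-molecule deletion errors from an entire repeat neighbourhood onto
  one pileup column, reaching tens of percent at unfavourable columns, so
  column-frequency rules are only trustworthy for substitutions. Small
  indels (1–29 bp) are instead called from the reference-guided consensus
  (column-wise majority vote kills sub-majority noise), globally aligned
  to the reference with the same gap-consolidation machinery (single-gap
  refit threshold 4 bp here). Substitution calls that shadow an adjacent
  variant are flagged and excluded: within 2 bp of an indel whose
  inserted/deleted sequence contains the alt allele, or a heterozygous
  call within 2 bp of a homozygous call with the same non-reference
  allele (the 1 bp-shifted phantom that indel noise creates in repeat
  context). Calls inside or adjacent to homopolymer runs ≥ 4 are flagged
  likewise. Flagged calls keep their records.

The consensus itself votes per reference column over {A,C,G,T,gap} with
ties broken toward the reference (conservative and deterministic);
insertions are emitted when more than half of spanning reads carry one.
Majority voting also deletes one base at long homopolymer runs where
aggregated deletion noise exceeds 50% — those columns are exactly what the
homopolymer exclusion is for, and consensus identity stays ≥ 99.2% at
100×.

## Phasing and copy number

Every full-length read spans all heterozygous sites of the amplicon, so
each read directly observes one haplotype. Allele vectors are read off
allele-aware realignments; vectors need ≥ 10 supporting reads (mirroring
the SV support floor, suppressing error-chimera vectors), and reads with
an uncalled allele count as ambiguous. The site in the G/C-repeat region
(promoter site 381) is excluded from phasing input as unresolvable from
single-molecule signal. The haplotype count is a *minimum* copy number;
the classifier resolves it with the allele-dosage frequency at the exon-4
site (Wilson 95% CI, two-sided binomial test against 0.5): `skewed` when
the CI excludes 0.5 and the frequency is ≥ 0.6, `balanced` when the CI
contains 0.5 or the frequency is within [0.4, 0.6], `indeterminate`
otherwise (never coerced). The 0.6/0.4 split is the midpoint between the
theoretical 2-of-3 (0.667) and 1-of-2 (0.5) dosages. Decision rule:
homozygous with one haplotype → 1; two haplotypes balanced → 2; two
haplotypes skewed → 3; four haplotypes → 4; anything else falls back to
the haplotype-count minimum with a note, and contradictions (four
haplotypes with skewed dosage) are flagged, not resolved.

## Grouping, motifs, association

Genotype groups are exact-match partitions of variant vectors:
heterozygous calls compare as unordered pairs (zygosity, not phase,
defines a group), and a missing value matches nothing — a sample with any
missing call forms its own group, chosen for reproducibility over
guessing. Sequence types are best global-alignment hits against a
labelled panel, discarded below 99% identity, ties broken alphabetically.

The G4 scanner enumerates every decomposition
`G{x}N{y1}G{x}N{y2}G{x}N{y3}G{x}` with x ≥ 2 within a 30 bp window and
scores it as `(max_len − mean loop length) + 2·(x − min_tract)` — shorter
loops and longer tracts score higher, the qualitative ordering of QGRS
G-scores, pinned to an exactly reproducible formula so an exhaustive
enumerator can verify the scanner verbatim. Non-overlapping motifs are
selected greedily by descending score, ties by leftmost start, longer
tract, shorter span. Sense strand only by default; loop-base identity does
not enter the score, so only tract-disrupting variants change it.

Association runs the Wilcoxon rank-sum test (exact when combined n ≤ 50,
else normal approximation with continuity correction) together with
Student's and Welch's t-tests for two groups, and Tukey HSD with a compact
letter display (insert-and-absorb) for more. Significance is α = 0.05 per
trait without multiplicity correction, matching the per-trait convention
of agronomic association scans across ~20 traits; a Benjamini–Hochberg
column is available but off by default. Degenerate contrasts return p = 1
with a flag rather than NaN. Groups need n ≥ 3 (pairwise) or n ≥ 2
(Tukey).

## Problem sizes used in tests

Simulation scales are chosen to keep the whole suite desk-scale on one
CPU while leaving every threshold untouched: SV-length recovery uses 50
error-free reads per amplicon; the 51-site panel recovery runs the full
six-cultivar panel at 200× once (the end-to-end check) and at 100× for a
two-seed property test; the copy-number grid runs 50 seeds × 4
configurations at 300× on a 1.3 kb sub-amplicon containing two
heterozygous sites (the classifier logic is identical to the full gene);
consensus-vs-coverage monotonicity uses a 2 kb template over 20 seeds;
configured-rate recovery (chimera fraction, barcode loss) uses ~10,000
simulated reads; scanner-vs-enumerator agreement uses 1,000 random
200-mers; association type-I error uses 10,000 null replicates.

## Known limitations

- The generator's error process is phenomenological; error rates are not
  fitted to any specific basecaller version.
- The aligner is edit-distance based; it has no affine gap model, and its
  SV sensitivity rests on the anchor-chain/refit machinery rather than on
  alignment scores.
- Heterozygous small indels are not callable by the consensus route
  (majority vote keeps one allele); the catalog contains none, and the
  pileup indel caller can be enabled where they matter.
- Copy numbers above four are reported only as the haplotype-count
  minimum.
- Positions of merged/duplicated events are repeat-edge anchored; within a
  tandem repeat any edge is equally valid and ±(repeat length) shifts are
  expected.

A further note on insertion lengths: deletion and duplication lengths are
reference-anchored (a deletion consumes reference bases; a duplication's
unit is re-read from the reference flank span, aggregated over the five
longest member observations, with insert sequences polished by majority
vote). A *novel* insertion has no reference anchor, so its reported length
is read-borne and inherits the sequencer's net indel bias plus
breakpoint-region noise — accurate to roughly ±10 bp at a few hundred bp
under the default error model, and exact for clean reads.
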
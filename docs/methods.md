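# Methods

`radsites` implements the validation chain for single-digest RADseq
experimental design: how many restriction sites does a genome hold, how
well do composition-based predictions anticipate that number, and how
many of those sites does an actual RAD dataset recover after de novo
assembly and mapping?  Every stage runs on synthetic data with complete
ground truth, so each link of the chain is testable in isolation and
end to end.

## Composition models

A `CompositionProfile` holds overlapping word counts of a sequence
resource for word lengths 1–3.  Windows containing any non-ACGT residue
contribute to no count — assembly gaps and ambiguity codes would
otherwise dilute the frequency estimates — and words never span contig
boundaries.

For a concrete recognition sequence b₁…b_k the per-position occurrence
probability under the four models is

* **gc**: ∏ w(bᵢ), with w = g/2 for G or C and (1−g)/2 for A or T, where
  g is the resource's GC fraction;
* **mono** (order-0 Markov): ∏ f(bᵢ);
* **di** (order-1 Markov): f(b₁) · ∏ᵢ≥₂ f(bᵢ₋₁bᵢ)/f(bᵢ₋₁);
* **tri** (order-2 Markov): f(b₁b₂) · ∏ᵢ≥₃ f(bᵢ₋₂bᵢ₋₁bᵢ)/f(bᵢ₋₂bᵢ₋₁).

Degenerate (IUPAC) recognition sequences sum over their concrete
expansions.  A zero-frequency conditioning context yields probability 0
with a warning rather than an error.  Expected genome-wide counts are
p · (G − k + 1): palindromic recognition sequences are counted once per
position (both strands present the same site); non-palindromic ones
accumulate forward plus reverse-complement probability.  This one-count
convention is calibrated to the in silico digest, which likewise reports
one record per palindromic occurrence.  When a transcriptome stands in
for the genome, its k-mer spectrum is combined with the *genome* length
G — the assumption being that coding-sequence composition approximates
genome-wide composition.

On genomes simulated from a known order-2 chain, only the tri model is
guaranteed Poisson-scale agreement with the digest (|E−D| ≤ 3√E); the
lower-order models may be biased whenever the chain has genuine
higher-order structure, which is precisely the point of the model
hierarchy.

## In silico digestion

`find_sites` reports every occurrence of the recognition sequence,
including overlapping ones (exact string occurrence is the natural
definition and what the brute-force oracle computes).  Non-ACGT genome
residues never match, even where IUPAC-compatible: an ambiguous residue
is not evidence of a cut site.  Coordinates are 0-based throughout; BED
output is 0-based half-open.  For non-palindromic enzymes the reverse
strand is scanned and reported with strand `-`.

## RAD assembly (simplified)

The assembler is a deliberately simplified, fully deterministic
Stacks-style procedure governed by three parameters: **m** (minimum
reads to seed a stack), **M** (mismatch limit merging stacks within an
individual), **n** (mismatch limit matching consensus sequences across
individuals); defaults 3/2/1, with a preset 7-combination grid that
moves each parameter one unit up and down.

1. *Stacks*: reads are trimmed to the modal length (shorter reads
   discarded and counted), dereplicated exactly; piles of depth ≥ m are
   primary.  Remaining reads attach to the nearest primary consensus
   within M mismatches (ties: deeper stack, then lexicographically
   smaller consensus) or are dropped.
2. *Loci*: primary stacks merge greedily in decreasing-depth order
   (ties lexicographic); a stack joins the first locus whose running
   majority consensus is within Hamming distance M, else founds a new
   locus.  Column majority ties resolve A < C < G < T.
3. *Catalogue*: individuals are processed in input order; each locus
   joins the entry with minimum Hamming distance ≤ n (ties to the
   earliest entry) or founds one; the entry consensus is fixed by its
   founder.

Omissions relative to Stacks — deleveraging, lumberjack-stack removal,
gapped matching, its SNP model — are intentional: the downstream
classifier is designed to be robust to assembly variation, and the
deterministic tie-breaks make byte-identical output reproducible from
permuted input, which the tests assert.

Genotype calls are intentionally plain plumbing: at a catalogue column
an individual is genotyped when its depth is ≥ m, its called alleles are
those with within-individual frequency ≥ 0.25, and it is heterozygous
when two or more alleles are called.  A column is variant when the union
of called alleles has ≥ 2 members.  Observed heterozygosity is the mean
over variant columns of the fraction of genotyped individuals called
heterozygous — the variant-column (not all-column) definition.  Mean
depth is reads per individual-locus.

## Locus-to-site classification

For a site starting at s (length k, cut offset c): the right-flank
fragment's top strand begins at s + (k − c) and the left-flank fragment,
read on the bottom strand, ends at s + c.  A forward-strand locus
alignment therefore belongs to a site's right side when its start is
within a tolerance (default 2 bp, absorbing soft-clip slop) of
s + (k − c); a reverse-strand alignment belongs to the left side when
its end is within tolerance of s + c.  Each mapped locus is assigned to
at most one site — the nearest, ties to the leftmost.

Sites with assigned loci are classified: **I** exactly one locus per
side; **II** both sides occupied, ≥ 3 loci (allelic splits); **III**
exactly one side occupied.  Loci matching no site are paired into
**IV** when a forward and a reverse locus imply coincident cut positions
(start − (k − c) and end − c within tolerance), else counted as **V**.
The empirical site count is |I|+|II|+|III|; IV and V are treated as
artefacts even though IV can occasionally represent a polymorphic site.
Multiple loci mapping to identical coordinates are counted as distinct.
SAM ingest keeps primary alignments only, converts 1-based POS to
0-based half-open, and treats records below the configurable MAPQ floor
(default 0, i.e. no filter) as unmapped.  The built-in exact mapper
(unique exact occurrence of the consensus or its reverse complement)
exists so synthetic pipelines need no external aligner; real data goes
through BWA or equivalent and `read_alignments`.

## Comparison statistics

Counts spanning orders of magnitude are compared on a log10 scale:
ordinary least squares of log10(y) on log10(x) (genome-based predictions
as response, by convention — r² is direction-invariant, the slope is
not), and a prediction MSE defined as the mean over enzymes of the
squared log10 difference of per-base site *frequencies* (counts divided
by resource length).  Operating on frequencies rather than raw counts
keeps the measure comparable across enzymes whose counts differ by 10⁵
and lands it on the ~10⁻³ magnitude scale where near-identical resources
should sit.

## Synthetic data generator

The generator emulates the essential structure of a single-digest RAD
experiment:

* **Genome**: i.i.d. or Markov (order 1–2) background of configurable
  length and contig count; Markov generation is sequential by nature and
  costs ~0.5 s/Mb, so simulated genomes are sized in the Mb range.
* **Sites**: recognition sequences written at positions ≥ 2×read-length
  apart and ≥ read-length from contig ends, on a background certified
  site-free by re-scan; planting is verified by digesting the result and
  requiring exactly the planted set (bounded mutate-and-retry on
  collisions, then error).
* **Reads**: per individual and site, digestion succeeds with
  probability d (Bernoulli); each digested flank yields Poisson(λ)
  reads.  A read is the flank sequence read outward from the cut (left
  flank reverse-complemented) with the recognition remnant at its 5'
  end, per-base substitution errors at rate ε, and constant high base
  qualities.  A site optionally carries one biallelic SNP in one flank
  (outside the remnant); genotypes are Hardy-Weinberg draws at the given
  alternate-allele frequency and heterozygotes emit alleles 50:50.
* **Truth**: planted-site BED, a truth SAM of the true locus alignments,
  and per-read origin tables, all round-tripping through the package's
  readers.  `SimTruth.recoverable_sites(m)` counts sites with at least
  one digested individual holding ≥ m reads on a flank — the most a
  depth-m assembler could possibly use.

Default conditions: 10 individuals (a cohort scaled down from the
96-individual experiments such data sets typically comprise), read
length 100 bp, λ = 20, ε = 0.001 (high-quality Illumina scale),
d = 0.9 (digestion is good but not complete), snp_prob = 0.2,
maf = 0.3.  Not modelled, deliberately: shearing and size selection
(single-digest size selection does not systematically drop sites, so
per-site dropout is subsumed in d), indels, PCR duplicates, barcodes,
paired-end reads, and quality-score error profiles.  Consequently,
passing tests demonstrate correctness of the chain's logic under the
stated generative model — not robustness to indel-rich or
repeat-dense genomes, where the Hamming-only assembler and the exact
mapper would degrade first.

## Problem sizes and numerical choices

The acceptance checks run at desk scale by design: a 10 Mb uniform
genome for model consistency, three 5 Mb order-2 Markov genomes for tri
calibration, fifty 100 kb sequences against the brute-force scanner, and
a 1 Mb genome with 200 planted sites and 10 individuals (~70k reads) for
the master pipeline and the 7-combination grid.  The grid cohort is
polymorphic (snp_prob = 0.5): polymorphism exceeding M/n is exactly what
splits alleles into extra catalogue entries (driving the ≥ 20% spread in
catalogue size at n = 0) while leaving the classifier's empirical site
count essentially unchanged — both flanks still map beside their site.
The master-recovery runs use snp_prob = 0, since the exact-recovery
property ("every planted site is one scenario-I pair") is defined for a
monomorphic, error-free, completely digested cohort.

All randomness flows through `numpy.random.default_rng` seeds carried in
the spec objects; identical seeds give byte-identical FASTA/FASTQ.
Hamming distances are computed on uint8-encoded arrays; all greedy
orders and tie-breaks are total orders, making every stage deterministic
and order-invariant after the documented sorting rules.

## Known limitations

* The assembler is not Stacks and does not aim to reproduce its locus
  counts; only the classifier-level site counts are designed to be
  robust to assembly parameters.
* The exact mapper requires a perfect (error-free consensus) match;
  consensus sequences carrying a non-reference allele map only through
  an external aligner.
* Enzymes with interrupted or bipartite recognition sites, methylation
  sensitivity and double-digest fragment modelling are out of scope.
* The shipped 18-enzyme catalogue is a convenience seeded from standard
  REBASE recognition sequences; users can supply their own TSV.
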
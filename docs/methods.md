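# Methods

`pirna_soma` re-implements, at desk scale, the small-RNA-seq analysis used to
characterize a somatic piRNA pathway: starting from raw oxidized small-RNA
libraries it performs adapter trimming, rRNA removal, size selection,
mismatch-tolerant alignment, priority-ordered compartment classification,
piRNA signature statistics, multi-mapping-aware transposon quantification,
and piRNA-cluster / genic-3'UTR accounting. A seeded simulator generates the
reference catalog and genotype-paired libraries with per-read ground truth,
so every statistic the pipeline reports can be checked against what was
planted.

## Coordinate and sequence conventions

All intervals are 0-based half-open on the forward strand; BED is read
natively and GFF3 is converted from 1-based closed coordinates at the I/O
boundary only. Sequences are uppercase DNA over A/C/G/T/N; reads are cDNA,
so the piRNA 1U signature appears as a position-1 T. `N` in a read or
reference always counts as a mismatch, including N against N — a
conservative, deterministic rule.

## Alignment model

The aligner realizes substitution-only ("v-mode") alignment: a read maps to
every reference window whose Hamming distance to the read (plus strand) or
its reverse complement (minus strand) is at most `v` (default 1). Indels are
never considered. Three reporting modes cover the pipeline's needs: all
hits; a single best hit (minimal mismatches, ties broken deterministically
by reference id, then start, then plus before minus — replacing the
pseudo-random tie-break of the original aligner, a documented divergence);
and unique-only, where a read with two or more reportable hits is suppressed
entirely.

Implementation: a pigeonhole seed-and-verify search over a k-mer occurrence
index (k = 9; a read of length >= 18 is split into v+1 disjoint 9-mers, at
least one of which must match exactly, because a seed containing N can never
be mismatch-free under the N rule). Reads too short to seed fall back to an
exhaustive window scan. The behavioral contract is the brute-force
all-window scan, which the test suite enforces on 1,000+ randomized
instances against an independent numpy oracle. The aligner targets
desk-scale references (hundreds of kilobases); it is not a genome-scale
tool.

## Preprocessing

3' adapter trimming removes the leftmost occurrence of the adapter — the
full adapter anywhere, or a 3'-terminal prefix of at least `min_overlap`
(default 5) bases — together with everything downstream, allowing
`floor(max_error_rate * overlap)` mismatches (default rate 0.1). Untrimmed
reads are retained but flagged by default; a `discard_untrimmed` switch
exists because the original protocol's policy is not recorded. Trimming is
applied once per read (reads flagged as trimmed are never re-scanned),
which makes it idempotent by construction and avoids spurious re-trimming
on chance adapter-like suffixes of the insert.

rRNA filtering removes any read aligning to any rRNA record (either strand,
<= 1 mismatch by default) and refuses to run with an empty rRNA database — a
silent no-op filter would corrupt every downstream fraction. Size selection
keeps 18–50 nt reads, bounds inclusive. Every stage reports counts in/kept/
discarded, and the pipeline asserts the conservation chain end to end.

## Compartment classification

Genome-aligning reads (<= v mismatches, either strand) are classified
against five compartment databases in fixed priority order: sno/tRNA,
miRNA, TE consensus, exons, intergenic. A read is assigned to the first
database it aligns to; genome-aligning reads hitting none fall into an
explicit `unassigned` bucket so counts always partition exactly. Reads that
fail genome alignment are excluded from the composition denominator.
Composition tables can be restricted to the 23–29 nt piRNA window.

## Signature statistics

Size profiles count reads per length over 18–50 nt after excluding
miRNA-aligning reads (optionally also sno/tRNA). TE-mapping reads are split
sense/antisense by the strand of their single best consensus hit. The
first-position bias matrix is built from 23–29 nt TE-antisense reads
truncated to their 5'-most 23 nt — the 5' anchor is forced by the 1U
question — with per-position information content R_i = 2 + sum_b p_b log2
p_b in bits. No small-sample correction is applied by default (an `ssc`
switch mirrors what a logo renderer would subtract); this keeps expected
values exact for testing.

## TE quantification and normalization

Family counting follows the combine-all-instances model: a read increments
family F once if it aligns to at least one instance or consensus of F; a
read hitting several families increments each (the model defines
within-family collapsing only; fractional assignment is out of scope).
Small-RNA counts are scaled per million reads aligning *uniquely* to
normalization loci — cisNAT-like loci whose emission is genotype-independent
by construction in the simulator, which is the premise of that
normalization. RNA-seq-side fold changes use per-million scaling with a
pseudocount (default 1) rather than a count-table package's dispersion
model; the 1.2-fold heat-map threshold operates on these normalized log2
fold changes as `log2FC > log2(1.2) = 0.263`, strictly. Per-consensus
coverage profiles use unique alignments only, scaled per million
library-unique reads.

## Cluster and genic accounting

Cluster statistics use 23–29 nt reads aligning uniquely to the genome.
A read belongs to a cluster on >= 1 bp overlap (configurable to larger
overlaps downstream); clusters must be non-overlapping, and a read spanning
the gap between two clusters goes to the larger overlap, then the leftmost.
Fold ratios are (mutant + pc)/(control + pc) on counts scaled per million
uniquely-aligning reads excluding sno/tRNA and miRNA, ranked ascending.
Genic reads are assigned to the gene they overlap most, then to the 5'UTR /
CDS / 3'UTR block holding the majority of aligned bases; ties go to the
more-3' region in transcription direction (an intrinsic 5'UTR < CDS < 3'UTR
order, independent of genomic strand). Sense means alignment strand equals
gene strand; a sense fraction with a zero denominator is reported missing,
not zero. Gene regions derive from one principal transcript per gene (the
first encountered); RPKM is count / (kb x million mapped reads).

## The simulator and its defaults

`build_toy_references` lays out a single ~120 kb chromosome embedding, in
order, sno/tRNA loci, 22 nt miRNA loci, TE instances (4 families, 400 bp
consensus, two copies each, one reverse-complemented), 8 single-exon coding
genes (150 nt 5'UTR / 900 nt CDS / 450 nt 3'UTR), 6 piRNA clusters of 2 kb —
the first being the flamenco-like master cluster carrying two 60 bp
antisense TE fragments — and 3 cisNAT-like normalization loci. The
intergenic compartment database is the genomic complement of the sno /
miRNA / TE / exon features, so clusters and normalization loci classify as
intergenic, as their real counterparts do. rRNA records (a 2S-like 30-mer
and a longer fragment) live outside the genome; rRNA reads are removed
before any genome alignment.

`simulate_library` draws reads by class with default weights chosen so that
63% of reads are 23–29 nt piRNAs split TE : cluster : genic = 49 : 34 : 17
(the wild-type composition the pipeline should recover), plus 10% miRNA
(22 nt), 10% 21-nt siRNA from TE loci, 12% rRNA carry-over and 5% 21-nt
normalization-locus reads. piRNA lengths follow a broad unimodal 23–29 nt
profile peaking at 26 nt. TE piRNAs are antisense with probability
alpha = 0.8; all piRNA classes take a first-position T with probability
beta = 0.85 (otherwise a uniform A/C/G, so the measured position-1 T
frequency estimates beta directly); genic 3'UTR piRNAs are sense to their
gene with probability gamma = 0.87. Every read receives the 3' adapter and
per-base substitution errors at rate 0.001. Cluster emission gives the
master cluster a 0.35 share and avoids its embedded TE fragments — reads
from those fragments would be TE-mapping, which is what the separate TE
class models.

The mutant genotype removes piRNA-class reads rather than resampling them
(so the cisNAT normalization is genuinely exercised; a `constant_depth`
switch exists for sensitivity checks): TE piRNAs survive with probability
`d_te` (default 0.295, i.e. a ~70.5% normalized decrease), master-cluster
reads with `d_cluster` (default 0.1; other clusters are genotype-independent
unless `depletion_scope="all"`), and *sense* genic 3'UTR reads with
`d_3utr` (default 0.825, a ~17.5% decrease of the sense class with
antisense untouched). A uniform 0.719 depletion of all three classes
produces the ~28.1% total-piRNA decrease scenario. These three depletion
scenarios are reported separately because their headline percentages are
mutually inconsistent under a single joint parameterization.

What the simulator does *not* model: base-quality structure, PCR
duplication, ligation bias, isoform complexity, multi-exon genes, nested or
overlapping annotations, genome-scale repeat landscapes, and the chemistry
of periodate oxidation (oxidation enrichment appears only as class
composition). Passing recovery tests therefore demonstrate correctness of
the accounting and statistics under clean planted structure, not robustness
to every artifact of real libraries.

## Numerical and testing choices

Simulations are driven by a single explicit `numpy` generator per library;
identical (seed, config) inputs reproduce byte-identical FASTQ files and
report bundles, and report bundles carry SHA-256 hashes of both the
pipeline config (canonical sorted-key JSON, hence key-order independent)
and the reference catalog, so genotype comparisons refuse mismatched
references. Default problem sizes — a ~120 kb catalog and 50,000-draw
libraries, with 10 replicate seeds for recovery statistics — were chosen so
that planted parameters are recovered with standard errors of about one
percentage point. Recovery assertions compare across-seed means against the
planted values (with per-seed confidence intervals additionally enforced
for the composition), because single-seed checks at these depths would fail
by design a few percent of the time; the cluster-ranking check is strict in
every seed, as its effect size is an order of magnitude.
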
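# Methods

This note records the models, parameter choices and numerical conventions
behind `ovitome`, and what the synthetic validation does and does not show.

## The synthetic study design

The generator (`synthio`) emulates the statistical structure the analysis
assumes, at desk scale:

* **Gene universe.** `n_genes` random transcripts (default 200) with lengths
  uniform on 600–1500 bp (all ≥ 300 bp). A fraction `known_fraction`
  (default 0.11) is flagged as "previously known" in the target species,
  mirroring the situation where only ~11% of a species' genes have any
  public mRNA sequence.
* **Donor pools.** Same-species mRNAs (known genes only, divergence 0 by
  default) and error-bearing EST subfragments (200–500 bp, 1% error, two per
  known gene); close-relative mRNAs for every gene at 2% nucleotide
  divergence; distant-relative proteins for every gene, translated in frame
  +1 and mutated at 10% amino-acid divergence. Substitution counts are exact
  (`round(divergence × length)` distinct positions, always to a different
  letter), so realized divergence equals the request.
* **Expression design.** Two groups (standard / delayed) × four time points
  (days 7, 11, 14, 21), one pooled lane each — eight lanes, no replicates.
  Baseline abundances are log-normal (σ = 1). `n_de` planted genes (default
  40) are drawn from the upper half of the abundance distribution and
  perturbed by `fold_change` (default 4) in exactly one non-baseline lane,
  half up and half down so lane totals stay roughly balanced; each
  perturbation makes the gene truly DE in two of the ten contrasts. Null
  genes share identical abundances across all lanes. Because read counts
  are compositional (a lane's counts are drawn proportional to
  abundance × length within the lane), planted perturbations slightly shift
  every other gene's relative abundance — a real property of sequencing that
  the balanced up/down planting keeps far below the detection threshold.
* **Reads.** Per-gene lane counts are Poisson around the design expectation;
  lane depths are drawn uniformly within ±10% of the configured depth
  (drivers of real per-lane depth variation being unknown). 76 bp reads
  start uniformly on either strand. Base quality is constant Q37; with
  probability 0.10 a read carries a geometric-length 3′ tail of quality ≤ 2
  whose bases are corrupted at 30% — enough structure to make the trimming
  rule consequential, with no claim to a full error-profile model. Uniform
  substitution errors at 0.5% emulate raw base-calling error; 5% of reads
  are duplicated. The Phred offset is 33 by default, configurable to 64 for
  2011-era pipelines.

Problem sizes throughout (200 genes, 8 × 50,000 reads for the headline run;
smaller for unit tests) were chosen so the full study runs in about two
minutes on one CPU while keeping per-gene counts in the regime where the
p < 10⁻¹⁵ gate has power; the real experiment the workflow is modelled on
had ~2×10⁷ reads per lane, so all accuracy claims here are desk-scale
claims.

**What the generator does not model:** fragment-length and positional
coverage biases, paired ends, strand-specific protocols, splice isoforms,
homopolymer or quality-correlated error structure, cross-gene sequence
homology (genes are independent random sequences), and real codon usage.
Consequently, passing tests demonstrate the *pipeline logic* — that each
stage implements its contract and that the chain recovers planted truth
under the stated noise — not performance on real tissue RNA-seq, where
shared domains, repeats and isoforms make both assembly and annotation much
harder.

## Preprocessing

Reads from all lanes are pooled, collapsed to unique sequences (keeping the
best mean Phred score per sequence, computed on untrimmed reads, and the
quality string of the record that achieved it so the unique list can still
be trimmed), then 3′-trimmed: the maximal trailing run with Phred ≤ 2 is
removed, stopping at the first higher-quality base scanning 3′→5′; internal
low-quality bases are retained. Uniquify-then-trim order means trimming can
re-create duplicates; these are tolerated (the assembler counts k-mers, not
reads). Reads trimmed below k are dropped with a logged count. Reference
sequences containing any non-ACGT letter (not just N) are removed before
assembly.

## Assembly

A single-k de Bruijn assembler over canonical k-mers (lexicographic minimum
of k-mer and reverse complement; k odd so no k-mer is its own reverse
complement). Defaults: k = 21 — small enough for 76 bp reads to overlap
robustly, large enough that a random 21-mer is effectively unique in a
desk-scale transcriptome — with edges witnessed by observed (k+1)-mers.

**Coverage cutoff.** K-mers below `min_kmer_coverage` are removed before
contig extraction. The default is automatic: the k-mer multiplicity
histogram is bimodal (error k-mers pile up at 1–3, genuine k-mers cluster
around true coverage), and the cutoff is placed at the first rise after the
error peak. A fixed small cutoff is *not* an option at realistic depth: the
same base-calling error recurs independently in multiple reads, so error
k-mers reach multiplicity 2–5 at coverage of a few hundred and would shatter
every high-coverage unitig. The spectrum cutoff is still purely a coverage
filter — no tip or bubble removal is performed, deliberately keeping the
assembler simple and auditable.

Contigs are maximal unbranched paths (1-in/1-out junctions), each retained
k-mer belonging to exactly one contig; contig orientation is normalized and
ids assigned in sorted order for byte-deterministic output. Contigs meeting
at a branch point are grouped into loci (connected components of the
contig-adjacency graph) — the analogue of one gene's transcript variants.
One representative per locus is carried forward: the contig maximizing
**confidence = length × mean k-mer coverage** (ties: longer, then
lexicographically smaller sequence). The published workflow this mirrors
used an assembler-internal confidence score whose definition is not public;
length × coverage is this package's own definition and is logged in run
reports. The 150 bp minimum length is applied to representatives,
inclusively (a 150 bp contig is kept).

Donor mRNAs and ESTs enter the assembly graph with multiplicity 1 each.
Under the automatic coverage cutoff this means donors confirm read-derived
k-mers rather than contribute novel ones; with `min_kmer_coverage=1` they
can also bridge read gaps.

## Annotation

Seed-and-extend local alignment stands in for BLAST: exact word matches
(11 nt / 4 aa) are grouped by subject and diagonal, clusters with ≥ 2 seeds
(two-hit heuristic; configurable to 1 for exhaustive seeding) are extended
with a banded affine-gap Smith–Waterman (band = seed diagonals ± 8).
Scoring: nucleotide +1/−2 with gap −5 (first base) / −2 (extension);
protein BLOSUM62 with −11/−1. E-values follow the Karlin–Altschul form
`E = K·m·n·e^(−λS)` with λ = 1.28, K = 0.46 (nt) and λ = 0.267, K = 0.041
(aa), computed in log space so extreme scores do not underflow; `n` is the
total database length of the searched tier. Identity is counted over
aligned (non-gap) columns.

Tier thresholds: same-species nt ≥ 90% & ≤ 10⁻⁵⁰; close-relative nt ≥ 97% &
≤ 10⁻⁵⁰ (stricter because larger close-relative catalogues with splice
variants raise cross-gene match risk); distant protein ≥ 80% & ≤ 10⁻²⁰ via
six-frame translation. Within a tier only the lowest-E-value hit is
considered. When several tiers pass with different symbols, the closest
species wins (target > close > distant); conflicts are counted and logged.
Lower tiers are searched lazily only when higher tiers failed — precedence
makes this equivalent and it dominates run time. Unannotated contigs are
excluded from the composite reference.

## Mapping and counting

The composite reference unites annotated de novo contigs with same-species
and close-relative mRNAs (each entry tagged with source and symbol; a gene
may legitimately appear in several entries). Mapping accepts an alignment
when the 5′ 18 bp seed has ≤ 3 mismatches and the whole read ≤ 5 (the total
cap is this package's choice; the historical aligner's seed parameters only
specify the seed). Both strands are searched; no gaps, matching the
ungapped short-read aligners of the era.

Candidates are generated by a pigeonhole index: the read is split into
`max_total_mismatches + 1` disjoint pieces, so any within-budget alignment
leaves one piece exact; looking up each piece's leading 12-mer in an
exact-match index over the reference finds every valid candidate, which a
vectorized comparison then verifies. This is exhaustive for the configured
budgets (oracle-tested against a brute-force full scan).

Each read counts toward exactly one gene. Among fewest-mismatch alignments
the priority is annotated same-species mRNA > de novo contig > annotated
close-relative mRNA > unannotated entries, then lexicographic entry id;
equal-score alignments to *different* genes increment an ambiguity counter
so the influence of the tie-break is auditable. Coordinates are 0-based
half-open internally, 1-based in human-readable reports. Per-lane reports
give percent mapped (one decimal) and the source breakdown over
{de novo, target annotated/unannotated, close annotated/unannotated}.

## Differential expression

RPKM uses each lane's *mapped* read total (the RPKM convention; lane totals
equal the count-table column sums). Quantile normalization replaces each
column's sorted values with the across-column mean of sorted values,
average-rank convention for ties. Fold changes are computed on
quantile-normalized RPKM with a pseudocount ε = 0.25 added to both sides
(zeros otherwise make fold changes undefined; configurable).

The count test conditions on the first library's count: `Y | x` is negative
binomial with `r = x+1` and failure probability `N2/(N1+N2)`; tails are
regularized incomplete beta functions, and the two-sided p doubles the
smaller tail (capped at 1). This conditioning is *not* symmetric under
swapping the libraries — with small counts the two orderings can differ
noticeably (exactly: p(0,1) = 1.0 but p(1,0) = 0.5 at equal library sizes),
converging for large counts. The comparison tables therefore fix the lane
roles explicitly. The implementation agrees with exact rational summation
to < 10⁻⁹ relative error and is conservative under the null on discrete
data (measured type-I error ≈ 0.045 at α = 0.05).

Ten contrasts per study: standard vs delayed at each day, and day 11/14/21
vs day 7 within each group. BH correction is applied within each contrast
independently, and the DE gate requires adjusted p < 10⁻¹⁵ (a raw-p switch
exists) and fold change ≥ 2. The p-threshold applies to the adjusted value
because that is the stricter and more defensible reading when a test is
known to overstate significance on single libraries.

Gene length for RPKM in the pipeline is the longest composite entry of the
gene — the truth lengths are unknown to the analysis, as they would be in a
real study.

The ΔCt utility (`qpcr_relative`) implements relative quantification
against the mean of three reference genes: `2^−(Ct_target − mean(Ct_refs))`.

## Profiles and gene-set analysis

DE genes' quantile-normalized RPKM values are standardized per group over
the four time points (sample sd, n−1) and concatenated standard-first into
8-vectors; zero-variance blocks map to zeros with a flag rather than NaN.
Clustering is agglomerative with Euclidean distance and average linkage
(ward/complete configurable) — the linkage behind the original heat map is
unknown, so correctness is claimed via oracle equivalence (naive O(n³)
agglomeration) and recovery of well-separated synthetic blobs, never via
matching any published clustering. The cluster count is a free parameter
(default 13, historically chosen by visual inspection).

Annotations are closed over is_a ancestors before analysis. The baseline is
a one-sided hypergeometric test per term with BH across terms. The
model-based analysis treats each term as a hidden Bernoulli switch with
prior `1/T`; a gene is predicted on iff an active term annotates it, and
observations pass through false-positive rate α = 0.1 and false-negative
rate β = 0.25 (conventional defaults of the model family; no values are
published for the workflow mirrored here). A single-term-toggle Metropolis
sampler with incremental likelihood updates (per-gene active-term counters)
yields marginal activation probabilities; 20% burn-in. The sampler is
validated against exact 2^T enumeration for T ≤ 15 (agreement < 0.03) and
recovers a planted active term among 200. Cluster reports keep up to three
terms with marginal ≥ 0.5, sorted by annotated-gene count.

Sheep→human symbol mapping is file-based (two-column TSV) rather than a
live service lookup; unmapped symbols are counted and excluded.

## Numerical conventions and degenerate inputs

* All generators and samplers take explicit integer seeds; identical
  parameters + seed reproduce outputs byte for byte.
* p-values are clamped into (0, 1]; E-values are tracked in log10 alongside
  the (possibly underflowing) linear value.
* Empty reads after trimming, empty reference sets after N-filtering,
  zero-variance profile blocks, contigs below k, and empty study sets all
  take defined paths (drop + log, warn, zero + flag, skip, prior-only)
  rather than raising.
* Ties are always broken deterministically (lexicographic sequence or id).

## Known limitations

* Single-k assembly with no error correction beyond the coverage cutoff;
  no scaffolding or isoform enumeration. Real transcriptome assemblers are
  far more capable; this one is built for auditable behaviour on synthetic
  data.
* Ungapped read mapping; indel-bearing reads are unmappable by design.
* The two-hit seeding heuristic can miss homologs that share fewer than two
  clustered words (irrelevant at ≤ 5% divergence, measured ≥ 99% score
  agreement with full Smith–Waterman).
* The Audic–Claverie test overstates certainty when biological variation
  exceeds Poisson noise — the very reason the stringent 10⁻¹⁵ threshold is
  used; with replicates, a dispersion-based model is strictly better and is
  out of scope here.
* MGSA marginals are Monte-Carlo estimates; repeated runs differ within
  sampling error unless the seed is fixed.
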
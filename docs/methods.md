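# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Barcode code design and decoding

Well barcodes are length-*k* DNA words (default *k* = 8) with guaranteed
minimum pairwise Hamming distance *d* (default 3). A code with *d* ≥
2*t* + 1 corrects *t* substitutions; *d* = 3 gives single-error
correction, so decoding accepts observed barcodes within Hamming distance
1 and, by the triangle inequality, the accepted codeword is unique.
Feasibility is bounded by the quaternary sphere-packing (Hamming) bound
`4^k / Σ_{i≤t} C(k,i)·3^i` — 2,621 for (*k* = 8, *d* = 3), comfortably
above the 96 wells of a standard plate.

Construction is seeded greedy random accumulation: propose uniform random
*k*-mers, keep those with homopolymer runs ≤ 3 (long runs are the
dominant sequencer failure mode) at distance ≥ *d* from everything kept.
No attempt is made at optimality; any valid code passes the independent
O(n²k) brute-force validation, and for n = 96 the greedy search succeeds
in a few thousand proposals. Deterministic for a fixed seed.

Decoding semantics: the nearest codeword within `max_distance` wins; a tie
at the minimum distance is reported *ambiguous* and the read discarded.
For any single-error-correcting set with `max_distance` = 1 ambiguity is
provably impossible; the tie rule only matters for degenerate codes or
the Levenshtein mode. "Edit distance" is interpreted as Hamming distance
on the first *k* bases by default — substitutions dominate on Illumina
and the barcode field has fixed length. An optional Levenshtein mode
extracts *k* + 1 bases and scores each codeword by prefix edit distance
(one indel allowed), for libraries where synthesis indels matter. With
`max_distance` = 1 and Hamming mode, decoding uses a precomputed table of
all single-substitution neighborhoods; it is exactly equivalent to the
naive scan (tested) and O(1) per read.

## Simulator

The simulator emulates the *structure* of a pooled 96-well screen so that
every pipeline stage has a ground truth to be checked against:

* **Transcriptome** — iid uniform random sequences, configurable gene
  count, isoforms per gene (default 2) and length range (default
  300–1000 bp); optional spike-in transcripts mapping to themselves.
  Random sequence means alignment is nearly unambiguous by construction;
  real transcriptomes share paralogous and repetitive sequence that
  produces far more multi-gene ties.
* **Plate** — conditions × replicates, row-major A1..H12; the default
  geometry is seven perturbagens plus a DMSO vehicle at 12 replicates.
* **Counts** — gamma-Poisson (negative binomial): gene mean
  μ = `base_mean · 2^lfc(gene, condition)`, variance μ + αμ². This
  mirrors the count model assumed by the downstream normalization. A
  condition's perturbation is a gene → log2-fold-change map, optionally
  generated from a regulon (each target shifted by `magnitude · mode`),
  which is what makes regulator-recovery experiments possible. Raw draws
  are rescaled to a fixed per-well depth by a multinomial draw, mimicking
  pooled sequencing to constant depth; with a thinning fraction well
  below one this preserves near-Poisson dispersion in the α → 0 limit.
* **Reads** — read 1 is barcode + oligo(dT)-style `T` fill to 26 cycles;
  read 2 is a sense-strand substring of length 66 starting uniformly
  within a 250 bp window at the transcript 3′ end. The uniform window is
  a stand-in: the true positional bias of 3′-end libraries is peaked
  near the poly(A) site and platform-dependent, but nothing downstream
  uses position, only transcript identity and strand. Substitution
  errors are iid per base at a configurable rate (default 0.5% in the
  pipeline config); indels, quality-score structure, PhiX and
  lane effects are not modeled. Quality strings are constant `I` and
  nothing downstream is quality-aware. No UMIs exist in this protocol,
  so duplicate reads are legitimate and are counted as reads.

Consequently, passing tests demonstrate the *logic* of the pipeline —
decoding guarantees, the counting rule, conservation, normalization
algebra, null calibration — under idealized sequence content. They do not
demonstrate robustness to paralogy, mappability artifacts, indel errors,
library-specific positional bias, or real regulon quality.

## Alignment evidence

Counting needs only (transcript, strand, score) per alignment, with the
score used purely for ordering within a read; genome coordinates are
irrelevant for 3′-end transcriptome counting and are ignored. SAM/BAM
records are consumed through pysam from name-grouped files: secondary and
supplementary records join their read's group, unmapped reads yield empty
groups, strand comes from the reverse-complement flag, and the score is
the `AS` tag when present or the aligned CIGAR length otherwise (records
with neither are dropped and counted). How completely an aligner reports
near-tied secondary alignments determines how strict the unique-mapping
rule can be — an operational caveat that applies to any scoring aligner.

The built-in matcher (`PseudoAligner`) is a deliberately minimal
test/simulation utility: exact *k*-mer seeds (default 16) at the read's
start, middle and end, on both strands, each extended ungapped with score
`matches − mismatches`. All distinct (transcript, strand) hits are
returned so isoform and cross-gene ties are visible to the counting rule.
It is not a general aligner (no gaps, no heuristic rescue) and is not a
substitute for one on real data.

## Unique-mapping counting

Per read: drop antisense records; take the maximum score among sense
records; map the maximum-score transcripts to genes; count the read iff
exactly one gene remains. Rationale for the strand clause: the library is
oligo(dT)-primed and 3′-end, so genuine fragments are sense-strand;
antisense alignments are artifacts and never veto a sense winner. Ties
across isoforms of one gene are countable (the gene is unambiguous); ties
across genes, and ties between a gene and a spike-in, are discarded and
tallied separately — no expectation-maximization rescue, keeping counts
interpretable as uniquely attributable reads. Gene identity is at the
symbol level of the transcript-to-gene map. Per well, assigned reads are
exactly conserved across the outcome categories (counted, multi-gene,
gene/spike-in tie, wrong strand, unmapped) — an invariant the tests
assert.

## Saturation

Subsampling a fraction *f* of a well's reads is a multivariate
hypergeometric draw of `floor(f · total)` from the count vector —
exactly equivalent to subsampling the uniquely mapped reads themselves,
given the counts. Curves average per-well detection over repetitions
(default 10) and wells, with the error bar the s.e.m. across wells of the
per-well means; at *f* = 1 the value is computed directly so it equals
full-data detection exactly. Subsampling operates on uniquely mapped
counts, not raw reads; a raw-read curve would sit slightly below it
because demultiplexing and mapping losses rescale the x-axis.

## Normalization, signatures, MDS

Size factors are median-of-ratios: restrict to genes positive in every
sample, divide each count by the gene's geometric mean across samples,
take the per-sample median, rescale to geometric mean one. The
variance-stabilizing transform is the closed form
`log2(count/size_factor + pseudocount)` (pseudocount 1). This is a
documented stand-in for a fitted-dispersion VST: it is dependency-free,
monotone, exactly invariant to depth rescaling, and adequate because
every downstream step needs only a stable log-like scale; it
under-stabilizes the very lowest counts relative to a dispersion-fitted
transform. Output metadata labels the method.

Signatures subtract the gene-wise mean of the vehicle columns from every
column; vehicle columns are retained as residuals whose mean is zero by
construction. Differential features are ranked by the largest absolute
mean signature across a condition's replicates (deterministic identifier
tie-break); formal differential-expression testing is delegated to
dedicated count-model tools and their significant gene lists can be fed
in wherever a gene list is accepted.

MDS is classical Torgerson scaling: squared Euclidean distances between
sample columns, double-centering, eigendecomposition, coordinates =
eigenvectors × √eigenvalues. Eigenvalues within 1e−8 (relative) of zero
are clipped to exactly zero so degenerate configurations embed cleanly;
genuinely negative leading eigenvalues (impossible for a plain feature
matrix, possible for externally supplied distances) raise a warning. The
embedding is unique up to rotation/reflection, so tests compare via
Procrustes alignment.

## Protein activity (aREA-2T-simplified)

Each signature column is rank-transformed to `Φ⁻¹((rank − ½)/n)` with
average ranks for ties; a regulon with modes mᵢ ∈ [−1, 1] and likelihood
weights wᵢ ∈ (0, 1] scores

    NES = Σ wᵢ mᵢ qᵢ / sqrt(Σ wᵢ² mᵢ²).

Under iid standard-normal scores this is exactly N(0, 1), giving an
analytic null; on a finite gene list the scores are the fixed quantile
grid, so the permutation null variance is very slightly below one
(finite-population correction of order m/n) — the permutation oracle in
`nes_permutation_oracle` quantifies the gap, which is < 0.05 NES units at
n = 1000, m ≈ 20. This is a deliberate two-tail simplification of the
published three-tail family: mode sign carries direction, |q| is not used
as a separate tail, and pleiotropy/shadow corrections are omitted.
Targets absent from the signature are dropped (no imputation); regulons
with fewer than `min_size` present targets (default 10, the conventional
floor below which NES is dominated by single genes) are flagged absent
(NaN), never zero-filled. Likelihood weights are used as given.

## Replicate noise

Per-pair CV uses the n − 1 standard deviation, `|x₁ − x₂|/√2`, over the
pair mean; the denominator is switchable (`ddof=0` gives `|x₁ − x₂|/2`)
since two-replicate conventions differ. Pairs with zero mean are
excluded from the CV average (pseudocounts are reserved for fold
changes) and the exclusion is auditable through the per-gene pair count.
The mean of two-replicate CVs is a biased estimator of σ/μ — under the
normal approximation E[s] = c₄σ with c₄ = √(2/π) at n = 2 — so tests of
the negative-binomial mean-CV law √(1/μ + α) divide by c₄ at μ = 200,
where the approximation is accurate. Tabulated `mean_cv` values retain
the raw (uncorrected) convention because that is what platform-comparison
plots of this kind conventionally show. CVs default to size-factor
normalized linear counts; raw or VST-scale input is the caller's choice,
and fold changes are `log2((x + pc)/(vehicle mean + pc))` with
pseudocount 1.

## Pipeline and determinism

All randomness flows from named per-stage seeds derived from one master
seed via seed sequences (kept below 2³¹). Gene rows / well columns is the
single matrix convention in every TSV. Each stage records a hash of its
configuration and checksums of its outputs in `manifest.json`; unchanged
reruns skip, changed configuration re-executes downstream stages. Numeric
tables are byte-identical across reruns with the same configuration and
seed; gzipped FASTQ differs in the gzip timestamp header only.

Default problem sizes (60 genes × 2 isoforms, 96 wells, 1,500 reads/well
in the pipeline config; 50 genes × 96 wells × ~2×10⁵ reads in the
end-to-end exactness check; 100 simulations of 50 regulons × 25 targets
for regulator recovery) were chosen as the smallest scales at which each
property is statistically decidable at the stated tolerances.

## Known limitations

* The built-in matcher and random transcriptomes understate multi-mapping;
  real runs should use a production aligner and its SAM output.
* The VST stand-in is not a dispersion-fitted transform; very-low-count
  genes are less stabilized.
* The two-tail NES omits the three-tail integration and pleiotropy
  control of the full published method; absolute NES values are not
  comparable to that method's, though rankings on strong effects agree by
  construction of the statistic.
* The fragment-position model (uniform 3′ window) and constant quality
  strings are structural stand-ins, adequate only because no downstream
  step consumes position or quality.
* Cross-platform noise comparisons ingest generic expression TSVs; no
  platform-specific parsers or preprocessing are provided.
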
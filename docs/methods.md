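# Methods

This note records the scientific and numerical choices behind `mutread`:
what each component computes, which parameters matter, what the synthetic
data emulate, and where genuinely open design points were decided.

## In-silico digestion

Recognition sites are matched on the top strand with full IUPAC ambiguity
support (needed for ApoI, `R^AATTY`); overlapping matches are all reported,
and any window containing an `N` is rejected so assembly gaps never spawn
sites. Matching is case-insensitive: soft-masked (lowercase) bases are
treated as ordinary sequence, i.e. repeats are not excluded from digestion.
Every enzyme in the packaged catalog is palindromic, so a top-strand scan
is complete; the test suite verifies this against a both-strand scan.

Cut coordinates are the top-strand cut point (`match_start + cut_offset`);
fragment length is the distance between adjacent cut points of the pooled
two-enzyme site list. Site-boundary-based lengths would differ by at most
the site length (≤ 5 bp), immaterial against a 100 bp selection window.
Coordinates are 0-based half-open throughout; BED is written natively and
VCF positions are converted on ingest.

Fragment construction and retention:

* contig ends do not produce fragments — a terminal "fragment" has only
  one restriction end and no defined second adapter, so it is excluded;
* coincident cut points of the two enzymes produce no zero-length fragment;
* size selection is inclusive on both boundaries (the window "350–450 bp"
  is read as 350 ≤ L ≤ 450);
* by default only mixed-end fragments are retained: with enzyme-specific
  adapters on each end, same-end fragments cannot be amplified into the
  library. The flag `require_mixed_ends=False` covers single-adapter
  designs.

## Spectra and channel order

The 96 channels are ordered substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G), then 5' base, then 3' base, both alphabetical — the COSMIC
convention. Signature tables are harmonised to this order *by label*, never
by row position, so shuffled input files load identically. SNVs with a
purine reference are reverse-complemented (substitution and context) onto
the pyrimidine strand before lookup. SNVs at contig edges, with an `N` in
the trinucleotide, or whose stated reference disagrees with the genome are
excluded and logged on the returned spectrum (`spectrum.skipped`), never
silently counted; the spectrum total therefore equals the number of
contributing SNVs exactly.

VCF ingest splits multi-allelic records, keeps only single-base ref/alt
pairs, and ignores the FILTER column by default — filtering is an explicit,
separate step (`variant_filter`) in this pipeline.

## NNLS refitting

Exposures solve `min ||S^T x − p||₂, x ≥ 0` with `p` the spectrum
normalised to sum one, then are rescaled to sum one
(`scipy.optimize.nnls`). Fitting counts instead of frequencies changes the
unnormalised solution only by the overall scale `||m||₁`, which the final
normalisation removes, so both conventions give the same profile; the
package fits frequencies for numerical uniformity across sample sizes.
An all-zero spectrum, and the degenerate all-zero NNLS solution, raise
errors rather than returning a zero profile: cosine similarity — the
downstream comparison everywhere — is undefined on zero vectors. No
sparsity penalty or signature selection is applied; this is plain NNLS
refitting against a fixed signature matrix, not de-novo extraction.

## Screening experiments

*Stability*: for each subset size `n` and replicate, `n` SNVs are drawn
without replacement from a sample's full set, refitted, and compared (by
cosine) to the full-set profile (or to externally supplied reference
profiles, e.g. the generating truth). A sample contributes at size `n`
only if it has at least `n` mutations. The default replicate count is 10
per size; it is a free parameter and seedable.

*Enzyme screen*: per candidate pair — digest, size-select, restrict each
sample's SNVs to the retained fragments, refit, compare to the full
profile; aggregates are mean/sd cosine, mean recovered mutation count and
covered bp. Samples whose restricted spectrum is empty are counted as
flagged and excluded from the mean (their cosine is undefined), never
averaged as zero. Target-region panels (exome-style BEDs) run through the
same machinery via `region_restrict_experiment`.

Downsampling-based shallow-WGS simulation is out of scope: it requires
alignments and a mutation caller, not just coordinates.

## Read preprocessing

Processing order is clone filter → inner-barcode demultiplexing → RAD-tag
check → quality filter, all pre-alignment. The clone key is
`(UMI1, UMI2, remaining seq1, remaining seq2)` — full remaining sequence,
not mapping positions, because the step runs before mapping. UMIs are
exact-match; no Hamming-network collapse is attempted (a documented
divergence point for users who want UMI-graph dedup). Demultiplexing
requires both mates' barcodes to match a single map entry within
`max_mismatch` (default 1, an assumption — the tolerance is configurable),
and refuses barcode maps whose codes are closer than `2·max_mismatch + 1`
so a mismatch ball can never be ambiguous by construction. The residual
tags default to `TGCAG`/`AATTY`, derived from PstI/ApoI cut geometry; the
mirrored mate assignment is accepted by default because either enzyme end
can be read as mate 1 under Y-adapter chemistry. Tags are genomic sequence
and are retained on the reads. The quality filter slides a window of 15%
of the read length and drops the pair if any window mean falls below
Q10 (process_radtags defaults), in either mate.

## Variant filter

Every expression in the ledger is a *rejection trigger*: a record is
removed iff at least one fires. This polarity is the only reading that is
consistent across the ledger (e.g. `VariantAlleleCountControl > 1` must
reject germline-contaminated calls). Inequalities are applied exactly as
stated, including the `>=` comparisons inside the strand-bias compound
rule and strictness elsewhere; the boundary behaviour of every operator is
pinned by tests. A record missing a metric that a rule needs fails with
the rule name `missing_metric` — un-assessable calls are treated
conservatively. The six presets carry the per-cohort minimum-read and
minimum-VAF values; `min_control_depth` defaults to 20 in all presets and
is an explicit field, since the lower control-depth cut-off of 10 belongs
to a cohort (additional FFPE samples) rather than to a caller — use
`FilterProfile(10, 0.13, min_control_depth=10)` for that setting.
Caller-side read selection (minimum mapping quality 1, minimum base
quality 10, overlapping-mate consensus) is upstream configuration of the
caller, not re-implemented here.

## Synthetic data

`make_genome` plants concrete realisations of recognition sites at exact
positions in i.i.d. background sequence (default GC 0.41, roughly
mammalian) and then *purges* accidental matches of the planted (and any
listed) enzymes by redrawing the offending bases, up to 1000 passes, so
the truth fragment set is exact, not probabilistic. `sample_mutations`
draws channel counts multinomially from the mixture `e·S` and places each
mutation uniformly at a genome position with the matching
pyrimidine-strand trinucleotide, without replacement (somatic SNVs are
distinct loci); a context with no remaining positions is an error naming
the missing contexts. `simulate_reads` emits one pair per fragment in the
`[UMI][barcode][tag][insert]` layout with error-free Q40 bases, and
creates duplicates by re-emitting chosen pairs verbatim; distinct
molecules are guaranteed distinct clone keys (UMIs are redrawn on
collision) so the truth duplicate count is exact. All generators are
bit-reproducible under a fixed seed.

The default synthetic signature set is six mutually dissimilar signatures
(pairwise cosine < 0.3), each concentrating 85% of its mass on one
substitution class with Dirichlet-distributed context weights and
spreading 15% uniformly. It is a stand-in with the right mathematical
shape for refitting experiments; it does not estimate any published
signature compendium.

What the synthetic data do **not** emulate: sequencing errors beyond
none-at-all, FFPE deamination damage (C>T at CpG), mutation clustering
(kataegis), copy-number-driven VAF structure, partial digestion, or
non-uniform fragment amplification. Passing tests therefore demonstrate
correctness of the computational pipeline under its stated model, not
robustness to those artefacts.

## Problem sizes and tolerances

Test and acceptance workloads are sized for quick, deterministic runs:
genomes of 30–100 kb (large enough that all 32 pyrimidine-centred
trinucleotide contexts occur), cohorts of 2–3 samples with 800–6000
mutations, 50 replicates per subset size in the recovery experiment, 200
random sequences (≤ 10 kb) in the digestion-oracle comparison, and 50
mixtures per `k` in the NNLS-vs-grid comparison (grid step 1e-3, agreement
within 2e-3 per coordinate). Exposure recovery is considered achieved at
mean cosine ≥ 0.99 to truth at 5000 mutations, with the 500-mutation mean
within 0.02 of the 5000-mutation mean — the subset size at which the
profile plateaus. Signature rows are renormalised on load with deviations
up to 1e-6 tolerated silently; exposure sums are enforced to 1e-9.
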
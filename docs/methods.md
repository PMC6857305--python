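# Methods

This note records the models, conventions and parameter choices behind
`hrsig`, in the spirit of a methods appendix: what each component assumes,
which knobs matter, and what the synthetic generators do and do not
emulate.

## Mutation catalogs and spectra

A catalog is a list of per-sample somatic calls (SNVs and short indels) in
minimal anchored representation: 1-based coordinates, indels carrying one
anchor base, shared affixes trimmed (`records.normalize`). Indels are
left-aligned against the reference before any context classification, so
every representation of the same event classifies identically.
Per-sample uniqueness of calls — the defining property of mutations that
arose independently in single-cell-derived clones — is an input
assumption; catalogs violating it trigger a warning, not an error.

SNVs map to the standard 96 channels: six pyrimidine-referenced
substitution classes × 16 flanking-base combinations, channel order fixed
(classes C>A, C>G, C>T, T>A, T>C, T>G; within a class 5' then 3' base
alphabetical). Purine-reference records are reverse-complemented together
with their context. Records with undetermined context (flanking N, contig
edge) are skipped and counted; a reference-base mismatch is an error, since
it indicates a catalog/genome mismatch rather than a data gap.

Spectra aggregate per sample, or per genotype either as summed counts
(default, and the factorization input — counts retain the Poisson
weighting of the data) or as means of per-sample spectra (for display).

### Cross-genome adjustment

Signatures derived on one genome are compared against references defined
on another by re-weighting each channel with the ratio of the pyrimidine-
centered triplet frequencies of the two genomes and renormalizing
(`adjust_triplet_frequencies`). The same mechanism serves as an
exome/genome opportunity correction when a triplet table of the captured
territory is supplied. Triplet tables are strand-collapsed counts of all
overlapping 3-mers (N windows skipped), so the adjustment is exactly
invertible — a property the tests verify to 1e-12.

## Control-based post-filter

Ancestral clones sequenced alongside their descendants act as a
false-positive control: any call unique to an ancestral clone is an
artifact. `tune_control_threshold` returns the smallest quality threshold
(calls retained when score > threshold, SNVs and indels independently)
under which every control keeps at most 5 SNVs and 1 indel. If the caps
are only satisfiable at the global score ceiling — i.e. by discarding every
call — the function returns +inf with a warning. The threshold is monotone
in the caps.

## Rate statistics

Per-genotype burdens are compared against the wild type with a χ² test on
the *summed* counts (df = 1), with expectation proportional to the number
of clones per group: equal mutational opportunity per clone is assumed
(same genome, same culture time), and no continuity correction is applied.
P values are Bonferroni-multiplied (default: number of non-wild-type
genotypes) and capped at 1. Fold change is the ratio of per-clone means;
a zero wild-type mean yields NaN with a warning.

## De novo signature extraction

`SignatureNMF` factorizes the samples × channels count matrix X ≈ E·Sᵀ
under Frobenius loss using multiplicative updates with random nonnegative
initialization, keeping the best of `n_restarts` (default 50) restarts.
Signatures are column-stochastic with the scale folded into exposures,
ordered by total exposure. All randomness derives from one seed via
spawned substreams, so results are bit-reproducible.

Rank selection follows the consensus-stability criterion: each restart
assigns samples to their dominant signature; the consensus matrix of
co-assignment frequencies is clustered (average linkage) and the
cophenetic correlation between consensus distances and tree distances
measures stability. `rank_survey` tabulates cophenetic correlation and
residual sum of squares per rank and nominates the rank maximizing the
cophenetic coefficient (RSS is non-increasing in rank and serves as the
secondary diagnostic).

Identifiability caveat: NMF recovers generating signatures only when the
data cone's extreme rays approach them. Sample sets consisting solely of
interior mixtures (e.g. fractions 0.2–0.8) bound recovery away from
perfection regardless of burden; the recovery tests therefore include
near-pure anchor samples, while the separability experiment deliberately
uses interior mixtures only and measures the resulting error.

## Reference-signature fitting

`ReferenceSignatureFit` solves min‖A·w − b‖² with w ≥ 0 (scipy NNLS) on
the fraction scale, then applies a single pruning pass: signatures whose
normalized contribution falls below `min_contribution` (default 6%, the
convention of common deconvolution tools) are zeroed and the remainder
refit once. Reported quantities: fractional contributions, count-scale
exposures, reconstructed spectrum, per-channel RMSD, and the KKT gradient
(≈ 0 for active signatures, ≥ 0 for zeroed ones; tests check 1e-8).
Rearrangement-catalog fitting reuses the same solver without pruning.

The confounder screen flags a sample as MMR when the summed fraction of
the mismatch-repair signatures (6, 15, 20, 26) exceeds 40%, else POLE when
signature 11 exceeds 40% (MMR evaluated first). Flagged tumor samples
mimic or mask the HR-deficiency spectrum and should be excluded from
deletion-phenotype comparisons.

## Synthetic reference signatures

The published COSMIC v2 SNV signatures and breast-cancer rearrangement
signatures are external database artifacts not redistributed here.
`refsigs` constructs deterministic synthetic stand-ins with the documented
qualitative shapes: a CpG-deamination-like "1", flat "featureless" "3" and
"5" (the pair built deliberately collinear, cosine ≈ 0.89, mirroring the
near-degeneracy that makes the real pair hard to separate), C>T-heavy
MMR-like "6"/"15"/"20"/"26", an alkylation-like "11", and six 32-category
rearrangement columns including a deletion-dominated "RS5"-like one. They
are probability vectors suitable for every fitting and simulation routine,
but numerical results against them are *not* comparable channel-by-channel
with the published matrices.

## Deletion context classification

For a left-aligned deletion of sequence D with flanks L (5') and R (3'):

* `tandem_copies` counts consecutive exact copies of D around the site
  (the deleted copy plus adjacent copies scanning outward both ways);
* `max_microhomology` is the longer of (longest prefix of D matching the
  start of R) and (longest suffix of D matching the end of L), capped at
  |D| − 1 — a full-length match is a tandem copy, not microhomology.

Classification precedence is repeat (≥ 2 copies) > microhomology (≥ 1 bp)
> none. Flanks of 6·|D| + 10 bp are retained (enough for the capped repeat
counts); contig edges truncate flanks with a warning. 1-bp deletions take
mh = 0: breakpoint homology is undefined below 2 bp.

The 83-channel indel scheme follows the standard bins: 1-bp
deletions/insertions split C/T (pyrimidine-referenced) by homopolymer
length (deletions 1–6+, insertions 0–5+); ≥ 2-bp events by length (2–5+) ×
adjacent repeat copies (0–5+); microhomology deletions by length ×
homology length (1–5+, capped by length − 1). Deletions qualifying as both
repeat and microhomology go to repeat channels. Indels of ≥ 50 bp are
routed to the structural-variant workflow. Deletion size summaries use an
ECDF and the lower-midpoint median (for an even count, the lower middle
order statistic — the median of integer lengths stays an integer).

Tumor-exome caveat: 1-bp repeat-class deletions in exome catalogs include
frequent artifacts; they are countable and visible in the repeat channels
but no automatic filter is applied.

## Rearrangement classification

SV post-filter (all three required): breakpoint uniqueness across samples
within ±10 bp (split-read breakpoints jitter by a few bases), coverage
≥ 1 in *every* sample at both breakpoints (from a user-supplied coverage
table — BAM depth extraction is an upstream step), and ≥ 5 supporting
soft-clipped reads. The retained set is order-independent.

Clustered events: per chromosome, the log10 inter-breakpoint distances are
segmented by exact O(n²) dynamic-programming piecewise-constant fitting
(penalty γ = 25 per changepoint, minimum segment length kmin = 10). A
segment whose mean inter-breakpoint distance is ≥ 10-fold below the
chromosome average marks its breakpoints as clustered. Chromosomes with
fewer than kmin distances yield no clusters.

The 32 categories are {clustered, non-clustered} × ({deletion, tandem
duplication, inversion} × size bins [1,10) kb, [10,100) kb, [100 kb,1) Mb,
[1,10) Mb, [10 Mb,∞) + translocation). Bins are half-open,
upper-exclusive; sub-kb events are counted in the smallest bin with a
warning. CREST "insertion" calls are counted as tandem duplications; ITX
calls lack the orientation needed for the del/dup/inv mapping and are
excluded from the 32-channel catalog and reported separately.

## Cas9 amplicon analysis

Merged reads are aligned globally against the theoretical amplicon with
match +5, mismatch −4, gap open 10, gap extend 0.5 (a length-L gap costs
10 + (L−1)·0.5), N neutral, end gaps free — the default scoring of the
classic global aligner, the only reproducible reading when no parameters
are stated. Gap runs in the query are deletions, gap runs in the reference
insertions; a deletion and insertion within 3 bp merge into a "mixed"
event (this package's own convention; length = deleted bp, the inserted
sequence carried along). Events entirely outside cut site ± 20 bp are
discarded as sequencing noise, and substitutions are never events — so a
read with only mismatches is wild type. Percentages are computed over all
reads, wild type included in the denominator.

## Synthetic data: what it emulates, and what not

The generators reproduce the *statistical structure* of an isogenic
clone-panel experiment: genotype-specific per-genome burdens (wild type
~120 SNVs, HR-null lines 7–8×, RAD54 3×, ATM 1.5×, RAD52/CHK2 ~1×; means
chosen to match the reported fold profile at realistic absolute scale),
Poisson clone-to-clone variation, multinomial channel sampling from
signature mixtures, deletion length distributions dominated by 1-bp events
(median 1 bp) except for the longer microhomology-rich BRCA2/PALB2
profile (median ~4 bp, microhomology fraction 55%), and SV catalogs drawn
from 32-category mixtures with clustered-channel events packed into dense
regions (log-uniform sizes within bins, uniform positions on a synthetic
8 × 120 Mb karyotype).

They do *not* emulate: sequencing error or coverage variation, mutation
clustering along the genome (SNV positions are not modeled at all —
spectra are sampled directly), germline contamination, subclonal
structure, or realistic chromatin/replication-timing covariates of
mutation density. Passing tests therefore demonstrate correctness of the
algorithms under the stated sampling models, not robustness to upstream
calling artifacts.

Genomes for deletion planting are i.i.d. uniform bases (optionally
GC-weighted); context classes are *forced* locally (tandem arrays written
for repeat, breakpoint-prefix copies for microhomology, incidental
homology rejected for none), so classifier recovery of planted classes is
exact, not statistical.

The separability experiment draws 33 samples (the 11-genotype × 3-clone
panel scale) of 1,000 mutations each from mixtures cycling over
{0.2, 0.35, 0.5, 0.65, 0.8}, extracts rank 2, matches recovered to
generating signatures by best cosine, and reports the mean absolute error
of channel probabilities in percentage points over 10 replicates. With
the collinear flat pair this lands near 0.15 percentage points — far below
the 5-point level at which such signatures count as cleanly separable.

## Numerical conventions

* NMF: multiplicative updates, tol 1e-9, max 5,000 iterations, restart
  streams spawned from one seed; ties in signature ordering broken stably.
* NNLS: scipy's active-set solver; KKT tolerance 1e-8 in tests.
* PCF: exact DP (no heuristic pruning); O(n²) is ample at per-chromosome
  breakpoint counts of this problem class (tens to hundreds).
* Alignment ties: the aligner's first-reported optimum, deterministic for
  fixed inputs.
* Degenerate inputs raise (`ValueError`) when a quantity is undefined
  (zero vectors for cosine, constant vectors for rank correlation, empty
  deletion sequences, zero catalogs) and warn-and-continue when data are
  merely partial (truncated flanks, skipped N contexts, all-zero NMF
  sample rows).

## Problem sizes used in the test-suite and acceptance runs

Simulation sizes mirror the study conditions where they are stated
(3 clones/genotype; 33 samples × 1,000 mutations × 10 replicates for
separability) and otherwise use the smallest sizes at which the checked
property is statistically decisive (e.g. 10⁴ random deletions for the
oracle-equivalence sweep, 150–200 random pairs for the alignment oracle,
n ≈ 14–16 for exhaustive segmentation enumeration, 200–600 events for SV
mixture recovery).

## Known limitations

* Reference signature stand-ins are synthetic; analyses needing the
  published matrices (e.g. the 0.940 cosine between an adjusted
  HR-deficiency signature and the real signature 3, per-sample NMF
  reproducibility on the real panel, tumor-exome deconvolution) require
  the user to supply those matrices and the corresponding genome triplet
  tables or sequencing data.
* The PCF clustered/non-clustered rule (10-fold below chromosome mean) is
  the originating breast-cancer method's criterion; other thresholds are
  not explored.
* ITX handling is conservative (excluded from the 32-channel catalog
  unless orientation is supplied).
* The mixed-event definition at Cas9 cut sites (indel pair within 3 bp)
  and the ± 20 bp noise window are this package's own conventions.
* deconstruction uses NNLS + one pruning pass rather than iterative
  forward selection; the objective is the same, the search path simpler.
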
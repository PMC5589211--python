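# Methods

`neoscape` re-implements, as a reusable and tested library, the family of
bespoke computational analyses used to characterise differentially growing
metastases of a single tumor: neoepitope depletion statistics on somatic
mutation catalogs, neoepitope window generation and HLA binder calling,
clonality–immunogenicity association tests, single-sample gene-set
enrichment with permutation significance, maximum-parsimony sample
phylogenetics on binary mutation characters, and CT-derived lesion growth
metrics. This note records the models, conventions and design choices, and
what the synthetic-data tests do and do not demonstrate.

## Substitution classes and mutation catalogs

Every somatic single-nucleotide variant carries its trinucleotide context
on the reference (+) strand. With 64 contexts and 3 alternate bases per
context the class space has exactly 64 × 3 = 192 elements; no
pyrimidine-strand collapsing is applied, because collapsing would merge
reverse-complement pairs and halve the space to 96. The encoding is frozen:
contexts ordered lexicographically over {A,C,G,T}, alternate bases in
alphabetical order among the three non-reference bases, giving class 0 =
AAA→ACA and class 191 = TTT→TGT. The map is bijective and round-trips
through `decode_substitution`.

Clonality is defined set-theoretically from lesion membership: *truncal* =
present in every sampled lesion, *private* = present in exactly one,
*shared* = a strict subset of two or more. Expression status is an input
column (upstream evidence); no expression threshold is defined here.
Commonly-mutated-gene exclusion is a user-supplied blacklist — no default
list is shipped. Genomic coordinates are 1-based inclusive (MAF
convention); protein positions are 1-based.

Copy-number event calling uses the unscaled median absolute deviation: a
segment is amplified at ≥ median + 2·MAD of its sample's segment
log-ratios and deleted at ≤ median − 2·MAD. The 1.4826 normal-consistency
factor is deliberately omitted; the rule is a robust two-sided threshold,
not a variance estimate. A zero MAD (constant distribution) is an error
rather than a silent no-call.

## Neoepitope windows and binder rules

For each missense mutation the wild-type and mutant peptide windows are
17-mers (HLA class I) or 29-mers (HLA class II) with the affected residue
in the middle. Near a protein terminus the window is truncated, never
padded: padding would fabricate sequence. Candidate epitopes are the
9-mers (HLA-I) or 15-mers (HLA-II) overlapping the mutated residue; an
interior mutation yields exactly k mutation-containing k-mers. Windows
containing non-standard residues (U, X) are dropped with a warning.

Binder calls:

* **HLA-I**: a 9-mer is a binder when its predicted IC50 is at or below an
  allele-specific cutoff (inclusive). The shipped cutoff table is
  configuration; HLA-C alleles, which lack published allele-specific
  cutoffs, fall back to 500 nM. A missing cutoff for a non-C allele is an
  error, not a silent fallback.
* **HLA-II**: a 15-mer is a binder when the NetMHCII-style IC50 ≤ 500 nM
  **or** the Sturniolo-style percentile rank ≤ 1% (disjunction).

Affinity prediction itself is out of scope: any deterministic callable
`(peptide, allele) → BindingPrediction` satisfies the predictor contract.
The library ships `MockAffinityPredictor`, a hash-based synthetic model
mapping (peptide, allele) to a log-uniform IC50 on [1, 50000] nM with a
configurable fraction forced under the cutoff; it models no biochemistry
and exists so every downstream stage is exercisable and deterministic.
Immunogenicity scoring is likewise a contract; the shipped
`MockImmunogenicityScorer` is a seeded position-weighted amino-acid table
(synthetic), and externally computed scores can be attached instead. The
wild-type-to-mutant affinity ratio is IC50_wt / IC50_mut, so ratios > 1
mean the mutant binds more strongly (IC50 is inverse to affinity).

Per missense mutation, a fully heterozygous genotype admits up to six
HLA-I allele-level calls (A/B/C pairs) and up to four HLA-II calls (DR/DQ
pairs); because a peptide–allele count is also meaningful, results carry
both granularities.

## The depletion statistic

Silent mutations are assumed invisible to immune selection, so a sample's
silent spectrum anchors the expectation for its neoepitope yield. With
per-class pooled rates

* Ns[m] = missense mutations per silent mutation of class m,
* Bs[m] = neoepitope-yielding missense mutations per missense mutation of
  class m,

and a sample's silent spectrum Ss, the expected yields are

    Npred = Σ_m Ss[m]·Ns[m]
    Bpred = Σ_m Ss[m]·Ns[m]·Bs[m]

and the statistic is R = Observed/Expected with Expected = Bpred/Npred and
Observed = Bobs/Nobs. R < 1 indicates depletion. One published rendering
of the Bpred formula repeats the Npred summand without the Bs factor; that
form is dimensionally inconsistent (it predicts missense counts, not
neoepitope counts), and the Bs-weighted form above is implemented.

Conventions and edge cases:

* Classes with zero pooled silent count carry no rate information; they
  are flagged unsupported and excluded from all sums. They are not
  smoothed — pseudo-counts would bias R on small cohorts, and exclusion is
  transparent and testable. Classes with missense but no neoepitopes have
  a valid Bs = 0.
* Bobs counts neoepitope-yielding missense mutations (0/1 per mutation),
  applied identically on both sides of the ratio; any per-mutation binder
  tally works provided it is consistent across the cohort.
* Nobs = 0 or Expected = 0 make R undefined and raise with a diagnostic;
  Bobs = 0 gives R = 0 and a −inf log2 sentinel with a warning, keeping
  cohort tables rectangular.
* Fitting Ns on a pooled cohort and predicting from the pooled silent
  spectrum returns the pooled missense count exactly (self-consistency of
  the rate estimator); this is a test invariant.

Significance is empirical and two-sided, because the log2 ratios are not
normally distributed (Shapiro–Wilk, D'Agostino–Pearson and
Kolmogorov–Smirnov diagnostics are provided as a report but never gate the
analysis): with r_le null values ≤ the observation and r_ge ≥ it,

    p = min(1, 2·(min(r_le, r_ge) + 1)/(N + 1)).

The add-one convention avoids p = 0 from finite nulls.

Two nulls are provided. The *cohort null* compares each sample's log2 R
against the other samples of a (large) reference cohort. The *permutation
null* controls for each sample's mutation burden: mutation-to-sample
assignments are shuffled preserving every sample's total occurrence count,
150 pairwise-distinct permutations by default, and each real sample is
compared against its own permutation distribution. Duplicates among draws
are rejected and redrawn; the identity assignment is a valid draw (only
redundant draws are excluded). If the distinct-assignment space is smaller
than requested, all distinct assignments are used with a warning. Two
details follow from the occurrence-level permutation unit: a permuted
sample can receive two occurrences of the same truncal mutation, which
then counts twice in its spectrum; and pooled class counts are invariant
under reassignment, so the null rates are fitted once on the real pooled
cohort.

## Synthetic cohorts: the study conditions

`SimulationConfig` defaults emulate a modest-burden serous-ovarian-like
cohort: 5 lesions, ~300 mutations per sample, 30% silent / 65% missense /
5% nonsense, clonal structure 30% truncal / 20% shared / 50% private, a
uniform 192-class spectrum (the statistic is spectrum-agnostic; any
probability vector can be supplied), a 15% baseline chance that a missense
mutation yields ≥ 1 predicted binder, and full expression. Depletion
strength δ removes each neoepitope-yielding missense mutation with
probability δ *after* labelling, so silent mutations — the expectation's
anchor — are untouched; removal (the mutation is never observed) matches
the immunoediting interpretation, as opposed to affinity re-assignment.

Large calibration cohorts use `SimulationConfig.reference_cohort`, which
sets the clonal structure to all-private: a 150-sample reference cohort
emulates unrelated patients, not lesions of one patient. This matters
quantitatively — imposing a truncal structure across 150 "samples"
collapses the catalog to a few hundred distinct mutations whose
occurrence-weighted per-class rates are far too noisy for the ratio
estimator.

Under removal-depletion the expected recovery is
R = (1−δ)/(1−δ·b) with b the binder rate, i.e. 0.73 at δ = 0.3 and 0.54 at
δ = 0.5 for b = 0.15 — slightly above 1−δ because removing
binder-yielding missense mutations also shrinks Nobs. Observed medians on
150 × 300 cohorts land within ±0.1 of 1−δ, which is what the recovery
checks assert.

What the generator does *not* emulate: mutational hotspots, class-dependent
binder propensity, subclonal cellular prevalence, expression-level
variation of mutated genes, or linkage between mutations on a protein.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness to real-data
violations of them.

## Single-sample GSEA

Per sample, genes are ranked by expression (average ranks on ties; ties in
the ordering broken by gene index for determinism). The enrichment score
of a set is the summed difference between the weighted in-set empirical
CDF — rank weights raised to τ = 0.25 — and the uniform out-of-set ECDF
over the descending-expression ordering. The implementation collapses the
running sum to an O(|set|) closed form (each gene's contribution is its
weight times the number of positions that include it); an explicit
running-sum evaluator is retained for audit, and the scores agree with an
independent ssGSEA implementation (gseapy, rank normalization, weight
0.25) to machine precision. Scores are normalized across the whole matrix
by the global score range (conventional absolute-range normalization); the
statistic is invariant under strictly increasing per-sample transforms of
expression.

Significance per (set, sample) is empirical: n_perm random gene sets of
identical size are drawn from all genes on the array and scored; p is
upper-tail with the add-one convention, matching an upregulation analysis
(a two-sided option exists for downregulation); Benjamini–Hochberg
correction runs across sets within each sample. Production configuration
is n_perm = 10,000; the test suite and acceptance script run a scaled
n_perm = 1,000 calibration (false-positive rate 0.05 ± 0.02 over 200 null
sets), a problem size chosen so the whole suite stays fast while the
binomial error on the rate stays well inside the asserted band.

A sample is an *outlier* for a set when q < 0.05 **and** its enrichment
score shows at least a ±1 log2 change relative to the median score of the
other samples (≥ 3 samples required, else the median of "the others" is
degenerate). The deviation is a log-ratio, not an absolute difference:
under range normalization all scores live inside a width-1 interval, so an
absolute-difference threshold of 1 could never fire, whereas the log2
change is invariant to the (positive) normalization constant. Sign
changes are treated as unbounded fold changes (score > 0 against a
non-positive median maps to +inf and can be flagged when significant; both
non-positive is undefined and never flagged).

Gene-level screening ranks genes by coefficient of variation across
samples (sample standard deviation / mean; zero-mean genes excluded with a
warning), descending with stable tie-break by gene id. LOESS cross-sample
normalization is accepted as a preprocessing contract — input matrices are
assumed normalized.

The expression generator plants gene baselines N(7, 1) with per-sample
noise N(0, 0.25) on a log2-like scale and shifts designated (set, sample)
pairs by 2 log2 units, emulating one sample elevated in one pathway; the
end-to-end check asserts that exactly the planted pair is flagged.

## Associations

* **Binomial GLM** `immunogenic ~ clonality + hla_binding` with logit
  link, fitted by iteratively reweighted least squares. The outcome is the
  sign rule on immunogenicity scores (score ≥ 0); binding enters as raw nM
  by default with a log10 option. No interaction term is included (none
  was detectable in the motivating analysis). Complete separation or
  non-convergence returns a flagged result with no coefficients.
* **Chi-square** on 2×2 immunogenicity tables is Pearson's X² without
  Yates continuity correction, df = 1 — stated explicitly so p-values are
  reproducible.
* **Mann–Whitney** comparisons of absolute scores are two-sided; exact
  enumeration when both groups have ≤ 20 observations and no cross-group
  ties, tie-corrected normal approximation otherwise. Fully tied data
  returns p = 1 with a warning.
* **TCR differential abundance**: per clonotype present in either of two
  repertoires, a two-sided exact binomial test of count_a out of total_a
  against the clonotype's frequency in the comparison sample, with a
  0.5/total_b pseudo-frequency for clonotypes absent there (the original
  tool's reference convention is proprietary; ours is stated openly). BH
  correction runs per sample pair by default (a global-family option is a
  caller choice), significance at q < 0.01.

Standard statistical machinery (GLM fitting, chi-square, Mann–Whitney,
exact binomial, BH step-up) is delegated to statsmodels/scipy behind the
module surface; the surrounding conventions above are the package's.

## Phylogenetics

The sample tree is maximum parsimony on the binary non-silent mutation
matrix.

* **Start tree**: UPGMA (average linkage) on unweighted Hamming distances;
  taxa are sorted before clustering so equal-distance ties break
  deterministically.
* **Scoring**: Fitch small parsimony on binary states, summed over
  characters, invariant under re-rooting (the score is the unrooted
  parsimony score). Character weights are supported for the ratchet.
* **Search**: a parsimony ratchet over nearest-neighbor-interchange (NNI)
  hill climbs. Each iteration upweights a random 25% of characters,
  climbs to a weighted local optimum, restores unit weights and climbs
  again; the walk continues from each cycle's endpoint while the best tree
  seen is retained. Two departures from the textbook recipe matter: the
  walk must *not* restart from the incumbent every cycle (that freezes it
  in the incumbent's basin), and the reweight multiplier is 5 rather than
  2 — the NNI neighborhood is far smaller than the tree-bisection searches
  the ratchet was designed around, and weight-doubling measurably fails to
  dislodge strict NNI local optima on random 6-taxon matrices, while
  multiplier 5 reached the exhaustive-enumeration optimum in 80/80 random
  matrices. Iterations (100), fraction (0.25) and multiplier are all
  configuration. Trees with ≤ 3 taxa have a unique unrooted topology and
  are returned unchanged.
* **Branch lengths**: character changes are assigned to edges by an
  accelerated-transformation pass — after the bottom-up Fitch pass, the
  root resolves ambiguity to state 0 (absence: the state before a somatic
  mutation arises, and of any outgroup), and each child inherits its
  parent's state when compatible, otherwise changing on the connecting
  branch. Changes are thereby placed as close to the root as ambiguity
  allows; per-edge counts are in mutation units and always sum to the
  parsimony score (a test invariant). An explicit all-zero outgroup row
  ("normal") roots the tree for display; scoring is unrooted.
* **Export**: Newick with branch lengths; an exact exhaustive enumerator
  over all unrooted topologies ((2n−5)!! trees) is provided for small
  instances and anchors the search's acceptance checks.

## Lesion metrics

Volumes from two-axis CT measurements use the ellipsoid formula
V = (4/3)π·a·b·c with the third axis c = (a+b)/2. Units are carried
through (cm by default, volumes in cm³). Growth between scans is the
later/earlier volume ratio; the regressing/stable/progressing label uses a
display-only stability band, default [0.9, 1.1], configurable.

## Problem sizes and determinism

All randomness flows through explicit seeds (NumPy `default_rng`,
`SeedSequence` spawning in the acceptance script); same seed, same output,
byte-identical catalogs. Problem sizes were chosen so each check is
statistically informative yet quick: depletion calibration/recovery on
150 samples × 300 mutations (a few seconds each), ssGSEA calibration on
2,000 genes × 5 samples × 200 null sets at n_perm = 1,000 (~2 s), ratchet
validation on twenty 6-taxon × ≤30-character matrices against exhaustive
enumeration (~6 s), GLM recovery at n = 2,000. The full suite runs in
well under a minute on one CPU.

## Known limitations

* The mock affinity and immunogenicity models are synthetic contracts;
  nothing here validates against real predictor outputs.
* The permutation unit (occurrence reassignment with per-sample totals
  preserved) is one reading of "permutations of the samples and their
  mutations"; alternatives (e.g. permuting distinct mutations with
  multiplicity preserved) would give slightly different nulls.
* ssGSEA permutation significance assumes exchangeability of genes within
  the array universe; correlated gene modules violate this and make the
  permutation p anti-conservative on real arrays.
* Parsimony search guarantees hold only at the scales tested (≤ ~8 taxa
  exhaustively verifiable); for larger matrices the ratchet is a
  heuristic.
* The depletion statistic inherits the assumptions of its rate model:
  silent-mutation neutrality, shared per-class rates across the cohort,
  and a consistent binder tally. Violations (e.g. class-dependent binder
  propensity) bias R.
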
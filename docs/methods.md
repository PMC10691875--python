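# Methods

This note documents the models and procedures implemented in
`fluencygraph`, the assumptions behind them, the tunable parameters, and
what the synthetic data generator does and does not emulate.

## Single-word scoring

Every token of a transcript receives exactly one label, resolved in a fixed
priority order: exact repeat of any earlier token → **perseveration**
(recurrent iff at least one response intervenes since the last occurrence);
membership in the profanity list → **inappropriate**; membership in the
proper-noun list (or a manual annotation) → **proper noun**; a shared stem
with an earlier token → **permutation**; not starting with the target
letter → **wrong letter**; otherwise **correct**. The priority order is a
design choice — the categories overlap (a repeated profanity is both a
repeat and a profanity) and repeats are scored as perseverations regardless
of the repeated word's own category. Manual per-token annotations override
the automatic decision.

Permutation detection strips the first applicable suffix from an ordered
rule list (`-ing, -ings, -ed, -er, -ers, -est, -en, -s, -es, -'s`),
requiring a stem of at least three characters, and compares stems against
earlier tokens only (inflectional variants follow their source in time).
The rule list is configurable; manual annotation handles anything the
suffix rules miss.

Percentages divide by the total number of uttered words. The rule-break
percentage counts inappropriate words + proper nouns + permutations;
wrong-letter words stay in the denominator but not the numerator (they are
too rare for meaningful analysis). Ratios with zero denominators are NaN.

**Clustering/switching.** Only the shared first-two-letters criterion is
implemented: a cluster is a maximal run of consecutive tokens with the same
two-letter onset, its size is run length − 1 (singletons score 0), the mean
is taken over all runs including singletons, switches = runs − 1, and the
relative number of switches is switches/(total − 1) × 100. Rhyme and
homonym rules of the full phonemic protocol are out of scope. All uttered
tokens, errors included, participate.

## Word frequency

Raw corpus frequencies (probabilities) are transformed as
`log10(raw × 10⁹)` — one-per-billion anchors zero — and words absent from
the lexicon are coded NaN and excluded from every summary. The
low-frequency threshold is cohort-relative: mean − 2·SD (sample SD) of the
transformed frequencies of **all correct tokens pooled across the entire
sample**, token-level. Pooling token-level rather than participant-mean
values is a documented choice; so is the inclusive boundary (a value
exactly at mean − 2 SD counts as low-frequency, "at least two SDs below").
The percentage of low-frequency words divides by correct words only;
out-of-lexicon words count in the denominator but never as low-frequency.

## Synthetic cohorts

The generator emulates the *statistical structure* of a five-group
focal-lesion fluency study (left/right frontal, left/right posterior,
healthy controls), with published group means/SDs as defaults: correct-word
totals (e.g. HC 16.67 ± 4.05, LF 11.40 ± 5.75), error-type percentages
(e.g. LF proper nouns 2.66, LP perseverations 3.88), low-frequency
percentages (LF 4.37, HC 2.48), and age/NART moments. Per participant:

- Correct-word count: normal with the group's moments, truncated at zero,
  rounded, and floored at 1 (so transcripts are never empty). The
  truncated-normal is the simplest family matching the two printed moments.
- Correct words: frequency-weighted sampling without replacement from the
  lexicon; each draw is independently replaced by a rare-tier word with
  probability `lowfreq_pct/100`.
- Word order: a two-state Markov process — stay in the current
  first-two-letter neighbourhood with probability `p_stay` (default 0.4,
  a free parameter chosen to put synthetic healthy-control mean cluster
  size in a realistic range of roughly 0.2–0.3) or switch.
- Errors: per-subtype counts are binomial over the expected total word
  count (the distributional family for error counts is an assumption; only
  group mean percentages are published). Inappropriate words and proper
  nouns come from small packaged placeholder lists (mild profanities and
  common S-names — the study's own lists are not public) and are inserted
  at uniform positions; permutations are placed immediately after their
  source word (they are observed to be near-immediate); perseverations
  repeat a uniformly chosen earlier response with ≥ 1 intervening token
  (an immediate-repeat mode is configurable).

The generator records the planted label of every token, and the scorer is
verified to reproduce the planted labels and rates (within binomial Monte
Carlo error) on such cohorts.

**Synthetic lexicon.** Vocabulary is pronounceable-ish nonsense 's'-words
with unique stems (so no accidental permutations) drawn from ~14 two-letter
onsets; rank-*r* raw frequency ∝ *r*^(−*s*) with the maximum normalized
to 1 (the seed changes the word strings only, never the frequency
profile). The lowest-frequency decile is additionally depressed by a
`rare_gap` factor (default 10⁻⁴). This gap is essential: with a pure Zipf
profile the cohort mean − 2 SD threshold falls below the lexicon minimum
and *nothing* is ever low-frequency; the gap makes log-frequencies bimodal
so the threshold lands between the tiers and the planted rare words are
exactly the ones scored low-frequency. The separation holds for planted
low-frequency rates up to roughly 10%; far beyond that the rare tier
inflates the pooled SD enough to push the threshold below the gap.

What the generator does **not** emulate: lesion anatomy, semantic content
(words are nonsense strings, so any semantic structure in real embeddings
has no synthetic counterpart), within-participant time course, education or
ethnicity fields. Passing tests therefore demonstrate correctness of the
pipeline's computations and recoverability of planted statistical
structure, not clinical validity on real transcripts.

## Sequence embeddings and the similarity graph

The default backend is a deterministic local feature hasher: tokens are
joined with `", "` (the delimiter is fixed because embeddings depend on
it), character n-grams (n = 2–4) and adjacent word bigrams are hashed by a
seeded keyed hash into *d* signed buckets (default 2048), and the count
vector is L2-normalized. It is order-sensitive and self-contained — no
hosted model is ever called; an adapter stub defines the integration point
for external large-language-model embedding services, which is how the
analysis would be run on real data. The hashing embedder captures
surface/phonological similarity of sequences, not meaning; that is
sufficient for the synthetic cohorts, whose group "style" is lexical.

Pairwise cosine similarities of the unit rows form a complete weighted
graph (self-loops excluded). Age and NART enter as per-edge absolute
differences, standardized to zero mean and unit variance — an explicit
encoding choice; node-level covariate likelihoods would be an alternative.
Optional mutual k-NN sparsification (keep an edge in either endpoint's
top-k) exists for scalability; the default is the complete graph.

## Stochastic block model

Edge weights are discretized into a multigraph by quantile binning into Q
(default 8) integer multiplicities — the weakest ~1/Q of edges vanish, the
strongest carry Q−1 parallel edges. The partition is scored by a
microcanonical description length (nats):

- degree-corrected multigraph entropy
  `−E − Σᵢ ln kᵢ! − ½ Σ_rs m_rs ln(m_rs/(e_r e_s))`;
- model costs for the partition (uniform over block counts, compositions
  and assignments), the block edge-count matrix and the block-wise degree
  sequences (multiset coefficients);
- per block pair and covariate, a Gaussian likelihood at the MLE mean and
  variance with a BIC-style cost of ln(pair count) per pair.

Degree correction is on by default. The covariate variance is floored at
0.25 (half an SD of the standardized covariate): node-attribute-driven
edge covariates contain genuine continuous fine structure, and an
unfloored per-pair Gaussian would reward splitting blocks until every pair
is attribute-homogeneous. Even with the floor, covariates legitimately
shape the partition — communities can differ in age/NART profile as well
as connectivity, which is the behaviour wanted from demographic
covariates; fitting without covariates isolates the connectivity evidence.

Search: agglomerative merges from the singleton partition down a
block-count ladder (candidate pairs sampled proportionally to inter-block
edge counts, the best disjoint ~25% applied per round), then single-node
Metropolis sweeps on the most promising ladder states (moves to the best
target block accepted when DL decreases, and with probability exp(−ΔDL)
otherwise). The best state visited is returned; `max_blocks` (default 25)
caps the refinement stage and triggers a warning when the optimum sits at
the cap. An optional second hierarchy level re-fits the model to the
block-level multigraph (diagonal dropped), giving one coarser nested
partition. DL values are implementation-defined; only comparisons between
partitions of the same graph are meaningful, and matching any third-party
nested-SBM code's numbers is a non-goal. The number of blocks is always
inferred, never fixed.

Communities are profiled by group composition, median fluency/age/NART and
TF-IDF over community-level documents (tf = term count / document length,
idf = log(communities / communities containing the term), ties broken
alphabetically), and contrasted one-vs-rest with asymptotic tie-corrected
Mann–Whitney U tests at a Bonferroni alpha/40 threshold (the divisor is
configurable).

## Predictive models

Binary target: frontal = 1 vs posterior + control = 0. Features are
standardized; the intercept has a fixed Normal(0, 100) prior and is never
shrunk. Embeddings are reduced by Gaussian random projection (entries
N(0, 1/k), k = 256 by default) before entering the full model.

Sampling is Gibbs with Polya-Gamma augmentation: ω_i ~ PG(1, x_iᵀβ), then
β from its conjugate Gaussian conditional. PG(1, z) draws use the
infinite-sum-of-exponentials representation truncated at K = 64 terms with
an analytic mean correction for the discarded tail — the correction makes
the draw unbiased and leaves only a small variance deficit (the tail's
variance share is O(1/K³)), and the scheme vectorizes over observations.
Ridge prior: β_j ~ N(0, τ²) with half-Cauchy(0,1) τ; horseshoe:
β_j ~ N(0, λ_j²τ²) with half-Cauchy local and global scales; both sampled
through the inverse-gamma auxiliary representation. The default desk-scale
schedule is 10,000 burn-in, 10,000 samples, thinning 5; heavier schedules
are configuration, not code.

Fit indices: McFadden pseudo-R² = 1 − E_post[log L]/log L₀ with L₀ the
intercept-only likelihood at the empirical rate (an intercept-only model
scores exactly 0 by definition; the pseudo-R² variant itself is a
documented choice); WAIC = −2(lppd − p_waic) with the sample-variance
penalty; effective sample sizes per coefficient by Geyer
initial-positive-sequence autocorrelation truncation, reported as the
minimum fraction of retained draws (a warning fires below 10%; horseshoe
local scales mix slowly for near-zero coefficients and benefit from
thinning).

## Group statistics

ANCOVA is the extra-sum-of-squares F-test of the group factor over the
covariates-only model, with partial η² = SS_group/(SS_group + SS_residual)
and adjusted group means at the covariate grand mean; degrees of freedom
are kept as separate between/within fields. Pairwise contrasts are
covariate-adjusted two-group regressions with per-comparison threshold
family-α / n (reported with each test) — adjusted contrasts rather than
raw t-tests, a documented choice. Categorical tables use chi-square
without continuity correction, φ = √(χ²/n) for 2×2 tables, and Fisher's
exact test when any expected count is below 5. Homogeneity-of-variance
diagnostics are out of scope.

## Numerical and scale choices

Percentages and thresholds are plain floating point with no rounding
anywhere in the computation path. NaN is the universal missing marker.
Test and acceptance runs use reduced problem sizes chosen as the package's
own defaults for desk-scale work: cohorts of 20–200 per group, embedding
dimension 512–2048, projection to 32–64 latent variables, MCMC schedules
of a few hundred to a few thousand iterations, SBM sweeps in the single
digits — all parameters scale up by configuration only. Determinism: every
stochastic component takes an explicit seed and is bit-reproducible under
it; the pipeline report isolates volatile fields (timestamp, timings) in
its `meta` header so the remainder is byte-comparable across runs.

## Known limitations

- The hashing embedder is a surface-similarity model; findings about
  *semantic* sequence structure require an external embedding backend.
- The SBM's Gaussian edge-covariate term, even floored, lets strong
  demographic gradients fragment communities; the covariate weight is a
  modelling decision, not an inferred quantity.
- The Bonferroni pairwise contrasts assume the adjusted linear model;
  non-normal score distributions (error percentages are zero-inflated)
  are handled only insofar as the F-test is robust at these sample sizes.
- The synthetic generator plants independent per-word error processes;
  real transcripts show serial dependence between errors (e.g. error
  bursts) that it does not reproduce.
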
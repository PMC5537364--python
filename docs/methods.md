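# Methods

## Model and procedure

`patwas` treats a clinical corpus as an ordered set of *cases*, each
carrying one or more plain-text documents and outcome labels (binary or
numeric).  The unit object of inference is the **occurrence profile**: the
per-case 0/1 vector marking which cases contain a given text pattern, in a
fixed case order (manifest order of first appearance).  Every association
statistic depends on a binary feature only through this profile, which is
what makes redundancy removal sound.

The scan is exhaustive rather than hypothesis-driven: all within-sentence
n-grams (and, when token-level annotations are enabled, all surface/tag
sub-sequence combinations) are generated, subject to two prunes — a support
threshold (default: a pattern must occur in at least 2 cases) and
termination of elongation once a candidate's corpus occurrence count drops
below 2.  Both prunes are lossless for the default support threshold
because case support is anti-monotone in pattern length.  Sequence-level
units (parse-tree constituents, fused vocabulary concepts) enter the search
as single-position alternatives covering their token span.

Numeric features take the form `A <NUMBER> B`: for every token tagged as a
cardinal number, all flank pairs up to 3 tokens per side are candidates; a
pair matching more than once within a single case is discarded outright
(ambiguity rule — a per-case exclusion would silently change the analysed
population between features), and cases without a match are excluded from
that feature's test (complete-case analysis).

### Association statistics

| feature | outcome | statistic |
|---|---|---|
| binary | binary | odds ratio (natural log) + two-sided Fisher exact |
| binary | numeric | AUC, Mann-Whitney U p |
| numeric | binary | AUC, Mann-Whitney U p |
| numeric | numeric | Spearman ρ, t approximation |

Conventions, fixed for reproducibility:

* Fisher two-sided p sums hypergeometric probabilities of all same-margin
  tables no more probable than the observed one (relative tolerance
  1 + 1e-7, the dominant statistical-software convention).  A zero-margin
  table is uninformative: p = 1.
* The odds ratio applies the Haldane-Anscombe +0.5 to all four cells when
  any cell is zero; log-OR is the natural log.
* Mann-Whitney p uses the tie-corrected normal approximation with
  continuity correction (an exact-enumeration switch exists for small
  samples); AUC = U/(n₁n₂) with half-credit ties.
* Spearman ρ is the Pearson correlation of mid-ranks, p from the t
  approximation on n − 2 df.
* R×C tables use a Monte-Carlo Freeman-Halton test: tables are sampled
  from the fixed-margin null by Patefield's algorithm and
  p = (1 + #{P(T) ≤ P(obs)})/(replicates + 1).
* Raw p-values are reported without multiple-testing correction.
  Exhaustively generated patterns are strongly dependent (every elongation
  shares its parent's occurrences), so Bonferroni/BH error control does not
  apply meaningfully; a Benjamini-Hochberg column can be emitted for
  reference only.

### Filtering and reduction

Results are filtered at an investigator-chosen threshold α (default
0.0025), sorted by p ascending with ties broken by effect magnitude then
pattern text.  Within each group of bit-identical profiles only the
longest pattern(s) survive; equal-length ties are all kept by default.
Redundancy removal runs on the feature set before testing (profiles, not
p-values, define redundancy, so the order is immaterial to the surviving
statistics).

### Token-regex induction

All significant surface n-grams sharing their (first, last) token pair form
a candidate group (length-1 patterns cannot supply two boundary literals
and are skipped).  The shared boundary tokens are pinned as literal
anchors; interiors are star-aligned against the longest member by
Needleman-Wunsch global alignment (match +1, mismatch −1, gap −1; traceback
preference diagonal > up > left; all scores configurable).  Global rather
than local alignment is deliberate: a wildcard at an expression end would
match indiscriminately and destroy specificity.  Aligned columns where all
members agree stay literal; each maximal run of disagreement becomes one
alternation element holding the members' gap-stripped subsequences — marked
optional when some member contributes an empty variant.  Variants are
ordered by descending member support, ties by first appearance in the
(deterministically ordered) member list.  The induced expression matches
every member by construction, its profile is a superset of the union of
member profiles, and it is re-scored by the same association machinery.

### Phenotyping

Selected features are decorrelated by UPGMA (average-linkage) clustering of
profiles under Euclidean distance, cut to k = max(2, ⌊N/10⌋) clusters
(rounding is our choice; only "one tenth of sample size" is prescribed);
the minimum-p feature per cluster (ties: larger support) enters the
classifier.  The built-in classifier is Bernoulli naive Bayes with add-1
smoothing; logistic regression is available behind the same
fit/score contract.  Accuracy is the mean out-of-bag AUC over 25 bootstrap
runs.  Feature discovery, filtering, clustering and selection run inside
each bootstrap replicate on the resampled cases only — out-of-bag labels
cannot leak into selection.  This nested design is deliberately
conservative; a `nested=False` switch reproduces the optimistic variant
that selects features once on all data.  A replicate whose out-of-bag set
lacks a class is redrawn; if no feature clears α inside a replicate, the
10 smallest-p features are used so every run yields a model.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_support` | 2 | minimum cases containing a pattern; support-1 patterns cannot approach significance |
| `max_len` | unbounded (surface), 5 (tagged) | pattern length cap; tagged search space grows exponentially |
| `max_flank_len` | 3 | numeric-feature flank length per side |
| `alpha` | 0.0025 | significance threshold; investigator-set, always reported with results |
| `n_runs` | 25 | bootstrap replicates for classification |
| alignment scores | +1/−1/−1 | match/mismatch/gap for regex induction |
| `fold_case` | off | matching is case-sensitive by default (clinical abbreviations are case-bearing: "He" vs "HE", "SCC") |

## Synthetic corpora

The generator emulates the statistical skeleton of clinical text, not its
language: i.i.d. Zipf background tokens (exponent 1.1), uniform sentence
lengths, planted phrases inserted contiguously with class-conditional
probabilities, planted numeric constructs with class-conditional Normal
values rounded to one decimal.  Each planted construct is spliced into its
own sentence (slots sampled without replacement) so insertions cannot split
one another and ground-truth counts stay exact.  Planted tokens are
out-of-vocabulary by default; a collide mode mixes them into the
vocabulary.  What passing tests on such corpora show: the search finds what
is present, the statistics are calibrated, planted effect sizes are
recovered.  What they do not show: robustness to negation ("no evidence
of..."), spelling variation, template boilerplate, non-stationary
vocabulary across document types — all properties of real EMR text.

Default study conditions used by the recovery checks: 80 cases, balanced
classes, one document of three sentences (6–12 background tokens) per case,
vocabulary 40–50, planted binary pattern at p₁ = 0.8 / p₀ = 0.1, planted
numeric values Normal(20, 3) vs Normal(10, 3).  These sizes mirror a
realistic single-centre cohort while keeping a full 100-seed recovery sweep
around a minute.

## Numerical and design choices

* Sentence chunking is a naive rule ("." "!" "?" ":" + whitespace, blank
  lines) with no abbreviation dictionary; "Dr. Smith" splits.  Chosen for
  determinism; the chunker is not the object of study.
* The tokenizer keeps decimal numbers ("2.5") as single tokens; otherwise
  words (with internal hyphens) and single punctuation characters.
  Pattern rendering re-joins with no space before punctuation ("M0,").
* The Porter stemmer is implemented in-package with one domain pre-rule:
  Greek singulars in "-sis" are rewritten to the "-ses" plural before
  stemming so metastasis/metastases (diagnosis/diagnoses, ...) share a
  stem; plain Porter leaves them distinct.
* Vocabulary concept matching is case-insensitive and destructive (the
  matched span is fused into one unigram); parse groups are additive.
  Annotation pruning removes tags supported by a single distinct surface
  corpus-wide — such tags can never generalise a pattern.
* All randomness flows through explicit seeds (`numpy` Generator);
  identical inputs and configuration reproduce byte-identical outputs.

## Known limitations

* No negation or uncertainty handling: "no pulmonary nodules" and
  "pulmonary nodules" both match the inner phrase.
* No gapped/skip-gram or cross-sentence patterns; no word-form numbers
  ("three" is not a cardinal).
* Concept vocabularies are flat phrase→id maps; no hierarchy traversal.
* The bootstrap AUC estimates generalisation under the corpus's own
  sampling, not transportability across institutions or documentation
  styles.
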
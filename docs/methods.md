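# Methods

## Pipeline

The package computes per-word semantic diversity (SemD) from a corpus in
five stages.

**Cleaning and chunking.** Documents are whitespace-tokenised; within each
token non-alphabetic characters are stripped in place (`cat's` → `cats`;
a split mode that breaks tokens at non-alphabetic characters is available
instead). Tokens shorter than `min_word_len` (default 2, i.e. one-letter
words) and function words are removed; an optional surface→lemma map is
applied after character cleaning and before stop-word filtering, so a
lemma that lands on a function word is removed. The shipped stoplist
(`data/stoplist_en.txt`) is a documented closed-class English list and is
user-replaceable. Cleaned token streams are cut into windows of exactly
`window` tokens (default 1000; 100 is the standard short-window variant).
The trailing partial window of each document is dropped because it would
under-represent its context; an exactly-full final window is kept, since
the rationale for dropping applies only to windows that may hold fewer
than W words. Cleaning-before-windowing is the default (so W counts
content words); `clean_first=False` windows raw tokens first, for
sensitivity checks. Documents shorter than W contribute no contexts
(logged).

**Vocabulary thresholds.** A word is retained iff corpus count ≥
`min_count` (50) AND distinct-context count ≥ `min_contexts` (40):
failing either criterion excludes the word, which matches the intent of
removing rare and narrow words. The literal Boolean alternative (excluded
only when failing both) is exposed as `require_both=False`. Column order
is descending count with alphabetical tie-break, making the matrix
independent of document read order.

**Log-entropy weighting.** a_ij = g_j·log(1+f_ij) with
g_j = 1 + Σ_i p_ij log p_ij / log n. The per-word (column-wise) orientation
of the global entropy term is the standard convention of the LSA
literature. g_j ∈ [0, 1]: 1 for a word confined to one context, → 0 for a
word uniform over all contexts. The log base is configurable but provably
inert: it cancels inside g_j and rescales all local weights by one
constant, leaving every cosine — hence SemD — unchanged (asserted in the
tests at 1e-8).

**Truncated SVD.** `scipy.sparse.linalg.svds` (ARPACK) with a seeded start
vector and tolerance 1e-10 when k < min(n, m); a dense LAPACK
factorisation otherwise. k defaults to 300 and is capped at min(n, m)
with a warning. Singular-vector signs are canonicalised (largest-|·|
entry of each left vector made positive) so runs are bit-reproducible;
sign choice cannot affect cosines. Context vectors are rows of U_k·Σ_k
(`scaled=True`, classical LSA) or U_k (`scaled=False`). Both variants are
kept first-class — published norms disagree on this point — and a space
stores U and Σ so either variant is derived without recomputation. On
structured corpora the two variants correlate positively but differ
substantially (Pearson r ≈ 0.56 on the reference corpus), which is why
the flag is recorded in every persisted space.

**SemD.** Mean cosine over all C(n, 2) unordered pairs of a word's
context vectors, computed exactly in O(n·k) via
Σ_{i<j} u_i·u_j = (‖Σu_i‖² − n)/2 on unit-normalised rows; SemD =
−ln(mean). Natural log is the default (the published norms' base is not
verifiable); a base flag is provided. A context counts once however often
the word occurs in it. Degenerate cases yield flagged missing values, not
numbers: fewer than two usable contexts, and nonpositive mean cosine
(clamping would fabricate a diversity score). Context vectors that are
numerically zero after truncation are excluded from the pair set and
counted in the result.

## Diagnostics

The Calinski–Harabasz score CH = [tr(B)/(g−1)] / [tr(W)/(n−g)] uses
trace-based dispersions (the standard variance-ratio criterion). Within-
group dispersion is computed directly from group-mean deviations rather
than as total−between, which would cancel catastrophically for
well-separated clusters; agreement with an independent loop-based oracle
is asserted at 1e-9. CH is invariant to translation, rotation and uniform
scaling, and g = 1 labelling raises an error, as does zero within-group
dispersion.

Scores are read against a Monte-Carlo null that permutes the observed
label multiset (category sizes preserved — the stricter null compared
with i.i.d. resampling), seeded and reported as mean ± sd over 1000
iterations by default. The null mean is ≈ 1.00 regardless of the vector
configuration (the F-ratio null); its sd depends on n, the label
cardinality and the dimensionality, so only the mean is treated as a
portable reference value. Word-level diagnostics sample a seeded fraction
of a word's contexts (default 50%, mirroring the practice of annotating a
random half) before scoring. t-SNE embedding is delegated to scikit-learn
and exported as TSV; it is a visual aid only — no quantitative conclusion
rests on embedding geometry.

## Synthetic corpora

The generator emulates the one property of large mixed corpora that
drives the metric: topical structure. Each document belongs to one topic
(an admixture mode was considered and left out; one topic per document
mirrors the metadata-labelled clustering the diagnostics target) and
draws tokens from a Zipf-distributed topic inventory (60%) mixed with a
shared pool (40%). Planted probe words overwrite Poisson(rate) background
slots at uniform positions, so document length is exact; "spread" probes
occur in a controlled number of topics at matched expected total
frequency, and ambiguous probes carry a ground-truth meaning label per
occurrence — either topic-aligned (separable by construction) or random
with identical topic profiles per meaning (unseparable by construction).
Token inventories are deterministic nonsense letter strings that pass the
cleaner unchanged.

What the corpora do **not** emulate: syntax, word burstiness beyond the
topic mixture, document-length variation, polysemy that is correlated
with but not identical to topic, and the long-tailed document/genre
structure of real corpora. Passing recovery tests therefore shows that
the pipeline measures topic spread when topic spread is the only signal —
it does not validate SemD values on natural text against behavioural
norms.

### Reference conditions

`data/reference_spec.yaml`: 8 topics × 40 documents × 1000 tokens,
window 100 → 3200 contexts; thresholds (20, 10); k = 300. The corpus is
scaled so the suite and the acceptance script run in minutes on one CPU
while keeping ≥ 150 contexts per probe word; the thresholds play the role
of (50, 40) at full corpus scale (at 3200 contexts a threshold of 40
contexts would delete the topic-specific vocabulary itself, destroying
the structure under study). Probe rates are matched to ≈ 240 expected
occurrences each so only topic spread varies. Under these conditions the
designed spread and computed SemD correlate at Spearman ρ = 1.0, the
topic-aligned ambiguous probe separates at CH ≈ 130 against a permutation
baseline of ≈ 1, and the random-meaning probe sits within 3 sd of its
baseline — the synthetic analogue of the finding that the metric tracks
textual, not semantic, variation.

## Numerical and design notes

- All randomness (SVD start vector, permutation nulls, sampling,
  generation) flows from explicit integer seeds; reruns are
  bit-identical.
- SVD correctness is asserted against dense LAPACK at k = rank (singular
  values 1e-8, reconstruction, orthonormality); the iterative path is
  exercised by explicit low-rank matrices.
- `compare_variants` requires ≥ 3 shared finite values and reports n with
  both Pearson r and Spearman ρ.
- Empty contexts (no vocabulary word) are kept as zero rows of the count
  matrix — they cannot enter any word's context set — and logged.

## Limitations and optional external validation

Ranking stability of SemD for words with very few contexts (near the
context threshold) is poor on small corpora; results for such words carry
a `status` flag rather than silent noise. The full-scale preprocessing
statistics quoted for the British National Corpus (44,477 contexts and
28,555 retained words at W = 1000 with thresholds 50/40, and a
lemmatised-vs-inflected SemD correlation of r ≈ 0.93) require that
licensed corpus and are not reproduced here; with a local BNC copy the
same `RunConfig` defaults reproduce that preprocessing exactly.
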
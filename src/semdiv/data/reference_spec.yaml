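# Committed reference conditions for the synthetic topic corpus.
#
# 8 topics x 40 documents x 1000 tokens (320 documents, 320k tokens).
# With a 100-token window every document yields exactly 10 contexts
# (3200 contexts total). Spread probes spanone..spaneight occur in
# 1..8 topics at rates matched to ~240 expected total occurrences each,
# so frequency is controlled and only topic spread varies.
#
# Ambiguous probes:
#   ambisep  — two "meanings" confined to disjoint topics (0 vs 1):
#              meaning labels align with topic geometry, so its context
#              vectors should separate by meaning.
#   ambinull — two "meanings" assigned at random across topics 0-3:
#              identical topic profiles per meaning, the null case the
#              diversity metric cannot separate.
#
# The pipeline block scales the corpus-analysis parameters to this corpus
# size: thresholds (20, 10) play the role of (50, 40) at full corpus
# scale; window 100 is the short-window variant of the standard 1000.

n_topics: 8
docs_per_topic: 40
doc_length: 1000
vocab_per_topic: 150
shared_vocab: 300
topic_word_fraction: 0.6
zipf_exponent: 1.0
seed: 20260

planted_words:
  - {word: spanone,   topic_spread: [0],                       rate: 6.0}
  - {word: spantwo,   topic_spread: [0, 1],                    rate: 3.0}
  - {word: spanthree, topic_spread: [0, 1, 2],                 rate: 2.0}
  - {word: spanfour,  topic_spread: [0, 1, 2, 3],              rate: 1.5}
  - {word: spanfive,  topic_spread: [0, 1, 2, 3, 4],           rate: 1.2}
  - {word: spansix,   topic_spread: [0, 1, 2, 3, 4, 5],        rate: 1.0}
  - {word: spanseven, topic_spread: [0, 1, 2, 3, 4, 5, 6],     rate: 0.857}
  - {word: spaneight, topic_spread: [0, 1, 2, 3, 4, 5, 6, 7],  rate: 0.75}
  - word: ambisep
    topic_spread: [0, 1]
    rate: 3.0
    meaning_labels: {0: meaning_a, 1: meaning_b}
  - word: ambinull
    topic_spread: [0, 1, 2, 3]
    rate: 1.5
    n_random_meanings: 2

pipeline:
  window: 100
  min_count: 20
  min_contexts: 10
  k: 300
  scaled: true
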
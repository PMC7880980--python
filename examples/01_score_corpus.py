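"""Build a semantic space from a small corpus and score words.

Generates a three-topic synthetic corpus, runs the full pipeline
(clean → chunk → vocabulary → log-entropy weights → truncated SVD), and
prints SemD for two planted probe words. ``narrowword`` occurs only in
topic-0 documents, ``wideword`` in all three topics at the same total
frequency — so ``wideword`` should come out more diverse.
"""

import semdiv

spec = semdiv.SyntheticSpec(
    n_topics=3, docs_per_topic=10, doc_length=240,
    vocab_per_topic=60, shared_vocab=120, seed=0,
    planted_words=(
        semdiv.PlantedWord("narrowword", (0,), rate=5.0),
        semdiv.PlantedWord("wideword", (0, 1, 2), rate=5.0 / 3),
    ),
)
docs, _ = semdiv.generate_corpus(spec)

cfg = semdiv.RunConfig(window=60, min_count=5, min_contexts=3, k=30, seed=0)
result = semdiv.build_space_from_documents(docs, cfg)
print(f"{result.space.n_contexts} contexts x {result.space.k} dims, "
      f"{len(result.vocab)} vocabulary words")

table = semdiv.semdiv_table(result.space, ["narrowword", "wideword"])
print(table.to_string(index=False))
print("\nHigher SemD = the word's contexts are less similar to each other:")
print("the three-topic word should score above the one-topic word.")
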
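"""Shared fixtures: toy spaces built by hand and the reference synthetic
pipeline run (session-scoped: it backs several recovery tests)."""

from __future__ import annotations

import numpy as np
import pytest

import semdiv
from semdiv.lsa import SemanticSpace
from semdiv.preprocess import Vocabulary


def make_toy_space(vectors: np.ndarray, word_rows: dict[str, list[int]],
                   scaled: bool = False) -> SemanticSpace:
    """Wrap explicit context vectors into a SemanticSpace for metric tests."""
    vectors = np.asarray(vectors, dtype=np.float64)
    n, k = vectors.shape
    words = sorted(word_rows)
    vocab = Vocabulary(
        words=words,
        total_counts={w: len(r) for w, r in word_rows.items()},
        context_counts={w: len(r) for w, r in word_rows.items()},
        min_count=1, min_contexts=1,
    )
    return SemanticSpace(
        U=vectors, singular_values=np.ones(k), scaled=scaled, vocab=vocab,
        word_contexts={w: np.asarray(r, dtype=np.intp) for w, r in word_rows.items()},
        row_ids=list(range(n)),
    )


def small_spec(seed: int = 0, **planted_overrides) -> semdiv.SyntheticSpec:
    """A fast three-topic corpus for unit tests (~0.2 s per pipeline run)."""
    planted = planted_overrides.pop("planted_words", (
        semdiv.PlantedWord("narrowword", (0,), rate=5.0),
        semdiv.PlantedWord("wideword", (0, 1, 2), rate=5.0 / 3),
    ))
    return semdiv.SyntheticSpec(
        n_topics=3, docs_per_topic=10, doc_length=240,
        vocab_per_topic=60, shared_vocab=120,
        planted_words=planted, seed=seed, **planted_overrides,
    )


SMALL_PIPE = semdiv.RunConfig(window=60, min_count=5, min_contexts=3, k=30, seed=0)


@pytest.fixture(scope="session")
def reference_run():
    """Full pipeline on the committed reference synthetic corpus."""
    spec, pipe = semdiv.reference_spec()
    docs, gt = semdiv.generate_corpus(spec)
    cfg = semdiv.RunConfig(
        window=pipe["window"], min_count=pipe["min_count"],
        min_contexts=pipe["min_contexts"], k=pipe["k"], scaled=pipe["scaled"],
        seed=spec.seed,
    )
    result = semdiv.build_space_from_documents(docs, cfg)
    table = semdiv.semdiv_table(result.space)
    return {"spec": spec, "docs": docs, "gt": gt, "result": result, "table": table}


@pytest.fixture(scope="session")
def small_run():
    spec = small_spec()
    docs, gt = semdiv.generate_corpus(spec)
    result = semdiv.build_space_from_documents(docs, SMALL_PIPE)
    return {"spec": spec, "docs": docs, "gt": gt, "result": result}
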
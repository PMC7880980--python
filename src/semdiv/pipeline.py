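"""End-to-end pipeline: documents → chunks → vocabulary → weighted
counts → SVD → semantic space."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .cooc import CoocMatrix, build_cooc, log_entropy_weight
from .corpus import ContextChunk, Document, chunk_documents
from .lsa import DEFAULT_DIMS, SemanticSpace, make_space, truncated_svd
from .preprocess import (
    CleanConfig,
    DEFAULT_MIN_CONTEXTS,
    DEFAULT_MIN_COUNT,
    Vocabulary,
    build_vocabulary,
    load_lemma_map,
    load_stoplist,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters. Defaults are the standard corpus-analysis
    values: 1000-word window, thresholds (50, 40), 300 dimensions, scaled
    singular vectors. A 100-word window is the standard robustness variant."""

    window: int = 1000
    min_count: int = DEFAULT_MIN_COUNT
    min_contexts: int = DEFAULT_MIN_CONTEXTS
    k: int = DEFAULT_DIMS
    scaled: bool = True
    lowercase: bool = True
    stoplist: str | None = None    # path; None = shipped default list
    lemma_map: str | None = None   # path; None = no lemmatisation
    min_word_len: int = 2
    split_on_nonalpha: bool = False
    clean_first: bool = True
    require_both_thresholds: bool = True
    log_base: float = math.e
    seed: int = 0

    def clean_config(self) -> CleanConfig:
        return CleanConfig(
            lowercase=self.lowercase,
            stoplist=load_stoplist(self.stoplist) if self.stoplist else None,
            lemma_map=load_lemma_map(self.lemma_map) if self.lemma_map else None,
            min_word_len=self.min_word_len,
            split_on_nonalpha=self.split_on_nonalpha,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2), "utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    space: SemanticSpace
    chunks: list[ContextChunk]
    vocab: Vocabulary
    cooc: CoocMatrix


def build_space_from_documents(docs: Sequence[Document], cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full pipeline on in-memory documents."""
    cfg = cfg or RunConfig()
    chunks = chunk_documents(docs, W=cfg.window, tokenizer=cfg.clean_config(),
                             clean_first=cfg.clean_first)
    if not chunks:
        raise ValueError("no contexts produced: all documents shorter than the window?")
    logger.info("pipeline: %d documents → %d contexts (W=%d)", len(docs), len(chunks), cfg.window)
    vocab = build_vocabulary(chunks, min_count=cfg.min_count, min_contexts=cfg.min_contexts,
                             require_both=cfg.require_both_thresholds)
    if not len(vocab):
        raise ValueError("empty vocabulary after thresholds; lower min_count/min_contexts")
    cooc = build_cooc(chunks, vocab)
    weighted = log_entropy_weight(cooc, log_base=cfg.log_base)
    U, S, _ = truncated_svd(weighted, k=cfg.k, seed=cfg.seed)
    space = make_space(U, S, cfg.scaled, cooc, chunks=chunks, seed=cfg.seed)
    return PipelineResult(space=space, chunks=chunks, vocab=vocab, cooc=cooc)
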
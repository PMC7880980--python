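"""Token cleaning, lemmatisation, stop-word removal and vocabulary construction.

The cleaning rules mirror the standard LSA corpus preparation for the
semantic-diversity metric: strip non-alphabetic characters, drop one-letter
words and function words, optionally map surface forms to lemmas, then
exclude words that are too rare (corpus count) or too narrow (number of
distinct contexts) to yield stable context vectors.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_NON_ALPHA = re.compile(r"[^a-zA-Z]+")

#: Defaults matching the reference pipeline: words occurring fewer than 50
#: times in the whole corpus or in fewer than 40 contexts are excluded.
DEFAULT_MIN_COUNT = 50
DEFAULT_MIN_CONTEXTS = 40


def default_stoplist() -> frozenset[str]:
    """Return the shipped English function-word list (lowercase)."""
    text = resources.files("semdiv.data").joinpath("stoplist_en.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Load a user stoplist, one word per line ('#' lines ignored)."""
    words = []
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


def load_lemma_map(path: str | Path) -> dict[str, str]:
    """Load a surface→lemma map from a 2-column TSV."""
    lemma_map: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
        lemma_map[parts[0]] = parts[1]
    return lemma_map


@dataclass(frozen=True)
class CleanConfig:
    """Token-cleaning configuration.

    Parameters
    ----------
    lowercase : lowercase before all other steps (stoplist entries must
        already be lowercase in that case).
    stoplist : function words to remove. ``None`` means the shipped default
        list; pass ``frozenset()`` to disable stop-word removal.
    lemma_map : optional surface→lemma map, applied after character cleaning
        and before stop-word filtering.
    min_word_len : minimum surviving token length (2 removes one-letter words).
    split_on_nonalpha : if True, non-alphabetic characters split tokens
        ("cat's" → "cat", "s"); if False (default) they are stripped in place
        ("cat's" → "cats").
    """

    lowercase: bool = True
    stoplist: frozenset[str] | None = None
    lemma_map: Mapping[str, str] | None = None
    min_word_len: int = 2
    split_on_nonalpha: bool = False

    def effective_stoplist(self) -> frozenset[str]:
        return default_stoplist() if self.stoplist is None else self.stoplist


def clean_tokens(text: str, cfg: CleanConfig | None = None) -> list[str]:
    """Clean raw text into the token stream used for chunking and counting.

    Order of operations: whitespace tokenisation → lowercasing →
    non-alphabetic stripping/splitting → minimum-length filter → lemma
    mapping → stop-word removal.
    """
    cfg = cfg or CleanConfig()
    stoplist = cfg.effective_stoplist()
    lemma_map = cfg.lemma_map or {}

    out: list[str] = []
    for raw in text.split():
        if cfg.lowercase:
            raw = raw.lower()
        pieces = _NON_ALPHA.split(raw) if cfg.split_on_nonalpha else [_NON_ALPHA.sub("", raw)]
        for tok in pieces:
            if len(tok) < cfg.min_word_len:
                continue
            tok = lemma_map.get(tok, tok)
            if tok in stoplist:
                continue
            out.append(tok)
    return out


@dataclass
class Vocabulary:
    """Retained word list with deterministic column indexing.

    Column order is descending corpus frequency, ties broken alphabetically,
    so vocabulary construction is invariant to chunk order.
    """

    words: list[str]
    total_counts: dict[str, int]
    context_counts: dict[str, int]
    min_count: int
    min_contexts: int
    word_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.word_index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.word_index

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tcount\tcontext_count\tindex\n")
            for i, w in enumerate(self.words):
                fh.write(f"{w}\t{self.total_counts[w]}\t{self.context_counts[w]}\t{i}\n")


def build_vocabulary(
    chunks: Sequence,
    min_count: int = DEFAULT_MIN_COUNT,
    min_contexts: int = DEFAULT_MIN_CONTEXTS,
    require_both: bool = True,
) -> Vocabulary:
    """Count words over context chunks and apply the frequency thresholds.

    With ``require_both=True`` (default) a word is kept only if it satisfies
    BOTH thresholds — corpus count ≥ ``min_count`` AND distinct-context count
    ≥ ``min_contexts`` — i.e. failing either criterion excludes it. The
    literal alternative reading (excluded only when failing both) is selected
    with ``require_both=False``.
    """
    if not chunks:
        raise ValueError("cannot build a vocabulary from an empty chunk list")

    totals: Counter[str] = Counter()
    ctx_counts: Counter[str] = Counter()
    for chunk in chunks:
        totals.update(chunk.tokens)
        ctx_counts.update(set(chunk.tokens))

    def keep(w: str) -> bool:
        ok_count = totals[w] >= min_count
        ok_ctx = ctx_counts[w] >= min_contexts
        return (ok_count and ok_ctx) if require_both else (ok_count or ok_ctx)

    kept = [w for w in totals if keep(w)]
    kept.sort(key=lambda w: (-totals[w], w))
    n_dropped = len(totals) - len(kept)
    logger.info("vocabulary: kept %d words, excluded %d below thresholds (%d, %d)",
                len(kept), n_dropped, min_count, min_contexts)
    return Vocabulary(
        words=kept,
        total_counts={w: totals[w] for w in kept},
        context_counts={w: ctx_counts[w] for w in kept},
        min_count=min_count,
        min_contexts=min_contexts,
    )
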
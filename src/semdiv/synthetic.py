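"""Synthetic topic-structured corpora with planted diversity structure.

Emulates the property of large mixed corpora that drives the diversity
metric: documents come from K distinct topics, each with its own word
inventory (plus a shared pool), so context vectors cluster by topic.
Planted probe words make the pipeline testable end to end:

* spread words occur in a controlled subset of topics at matched total
  frequency — their designed topic-spread should order their computed SemD;
* ambiguous words carry a ground-truth "meaning" label on every
  occurrence, either aligned with topics (meanings live in disjoint
  topics, hence geometrically separable) or assigned at random with
  identical topic profiles per meaning (the null case the diversity metric
  cannot and should not separate).

Documents are bags of words: no syntax, no burstiness beyond the topic
mixture, no document-length variation. Token inventories are nonsense
letter strings that pass the cleaner unchanged and collide with no
function word.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .corpus import ContextChunk, Document
from .diagnostics import ClusterDiagnostic, word_context_diagnostic
from .lsa import SemanticSpace

logger = logging.getLogger(__name__)

_MEDIA = ("fiction", "news", "essay")  # structure-free second label dimension


def _enc26(i: int, width: int = 3) -> str:
    s = ""
    for _ in range(width):
        s = chr(97 + i % 26) + s
        i //= 26
    return s


def topic_word(t: int, i: int) -> str:
    """Deterministic nonsense word i of topic t's inventory."""
    return "q" + _enc26(t, 2) + _enc26(i)


def shared_word(i: int) -> str:
    """Deterministic nonsense word i of the topic-neutral shared pool."""
    return "zz" + _enc26(i)


@dataclass(frozen=True)
class PlantedWord:
    """A probe word inserted into documents of its spread topics.

    ``rate`` is the expected (Poisson) number of occurrences per matching
    document. Exactly one of ``meaning_labels`` (topic → meaning; meanings
    aligned with topic structure) or ``n_random_meanings`` (meanings drawn
    uniformly per occurrence, independent of topic) may be given for
    ambiguous probes.
    """

    word: str
    topic_spread: tuple[int, ...]
    rate: float
    meaning_labels: dict[int, str] | None = None
    n_random_meanings: int | None = None

    def __post_init__(self) -> None:
        if not self.topic_spread:
            raise ValueError(f"planted word {self.word!r}: empty topic spread")
        if self.rate <= 0:
            raise ValueError(f"planted word {self.word!r}: rate must be positive")
        if self.meaning_labels is not None and self.n_random_meanings is not None:
            raise ValueError(f"planted word {self.word!r}: choose one meaning scheme")

    @property
    def ambiguous(self) -> bool:
        return self.meaning_labels is not None or self.n_random_meanings is not None


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters. Defaults are the committed reference
    conditions (see data/reference_spec.yaml for the annotated copy)."""

    n_topics: int = 8
    docs_per_topic: int = 40
    doc_length: int = 1000
    vocab_per_topic: int = 150
    shared_vocab: int = 300
    topic_word_fraction: float = 0.6
    zipf_exponent: float = 1.0
    planted_words: tuple[PlantedWord, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.docs_per_topic < 1 or self.doc_length < 1:
            raise ValueError("n_topics, docs_per_topic and doc_length must be positive")
        for pw in self.planted_words:
            if any(t < 0 or t >= self.n_topics for t in pw.topic_spread):
                raise ValueError(f"planted word {pw.word!r}: spread topic out of range")


@dataclass
class GroundTruth:
    """What was planted: per-word summary plus every occurrence's location,
    topic and (for ambiguous probes) meaning label."""

    words: pd.DataFrame        # word, spread_size, rate, n_occurrences, ambiguous
    occurrences: pd.DataFrame  # word, doc_id, position, topic, meaning


def _zipf_probs(size: int, s: float) -> np.ndarray:
    p = 1.0 / np.arange(1, size + 1) ** s
    return p / p.sum()


def generate_corpus(spec: SyntheticSpec) -> tuple[list[Document], GroundTruth]:
    """Generate the corpus; byte-identical for the same spec (incl. seed).

    Each document belongs to one topic (label ``domain``); background
    tokens mix the topic inventory with the shared pool (Zipf-distributed
    within each); planted words overwrite Poisson(rate) background slots at
    uniform positions, so document length stays exact.
    """
    rng = np.random.default_rng(spec.seed)
    topic_pools = [
        np.array([topic_word(t, i) for i in range(spec.vocab_per_topic)])
        for t in range(spec.n_topics)
    ]
    shared_pool = np.array([shared_word(i) for i in range(spec.shared_vocab)])
    p_topic = _zipf_probs(spec.vocab_per_topic, spec.zipf_exponent)
    p_shared = _zipf_probs(spec.shared_vocab, spec.zipf_exponent)

    docs: list[Document] = []
    occ_rows: list[tuple] = []
    for t in range(spec.n_topics):
        for d in range(spec.docs_per_topic):
            doc_id = f"doc_t{t:02d}_{d:04d}"
            tokens = np.where(
                rng.random(spec.doc_length) < spec.topic_word_fraction,
                rng.choice(topic_pools[t], size=spec.doc_length, p=p_topic),
                rng.choice(shared_pool, size=spec.doc_length, p=p_shared),
            ).astype(object)  # object dtype: fixed-width <U would truncate planted words
            # Poisson insertion counts per planted word active in this topic
            insertions: list[tuple[PlantedWord, int]] = []
            for pw in spec.planted_words:
                if t in pw.topic_spread:
                    n_ins = int(rng.poisson(pw.rate))
                    if n_ins:
                        insertions.append((pw, n_ins))
            total = sum(n for _, n in insertions)
            if total > spec.doc_length:
                raise ValueError(
                    f"infeasible spec: {total} planted insertions exceed "
                    f"doc_length={spec.doc_length} in {doc_id}"
                )
            if total:
                positions = rng.choice(spec.doc_length, size=total, replace=False)
                pos_iter = iter(positions)
                for pw, n_ins in insertions:
                    for _ in range(n_ins):
                        pos = int(next(pos_iter))
                        tokens[pos] = pw.word
                        if pw.meaning_labels is not None:
                            meaning = pw.meaning_labels.get(t, f"topic{t}")
                        elif pw.n_random_meanings is not None:
                            meaning = f"meaning_{_enc26(int(rng.integers(pw.n_random_meanings)), 1)}"
                        else:
                            meaning = ""
                        occ_rows.append((pw.word, doc_id, pos, t, meaning))
            docs.append(Document(
                doc_id=doc_id,
                raw_text=" ".join(tokens),
                labels={"domain": f"topic{t}", "medium": _MEDIA[int(rng.integers(len(_MEDIA)))]},
            ))

    occurrences = pd.DataFrame(
        occ_rows, columns=["word", "doc_id", "position", "topic", "meaning"]
    )
    n_occ = occurrences.groupby("word").size() if len(occurrences) else {}
    words = pd.DataFrame({
        "word": [pw.word for pw in spec.planted_words],
        "spread_size": [len(set(pw.topic_spread)) for pw in spec.planted_words],
        "rate": [pw.rate for pw in spec.planted_words],
        "n_occurrences": [int(n_occ.get(pw.word, 0)) if len(occurrences) else 0
                          for pw in spec.planted_words],
        "ambiguous": [pw.ambiguous for pw in spec.planted_words],
    })
    return docs, GroundTruth(words=words, occurrences=occurrences)


def occurrence_context_labels(
    ground_truth: GroundTruth,
    chunks: Sequence[ContextChunk],
    word: str,
) -> dict[int, str]:
    """Map each context containing ``word`` to its ground-truth meaning.

    Occurrence token positions are translated to window ordinals (position
    // W within the document); occurrences falling in a dropped partial
    final window are ignored. When one context holds occurrences with
    conflicting random meanings, the first occurrence wins.
    """
    if not chunks:
        return {}
    W = len(chunks[0].tokens)
    doc_chunks: dict[str, list[int]] = {}
    for c in chunks:
        doc_chunks.setdefault(c.doc_id, []).append(c.context_id)
    labels: dict[int, str] = {}
    occ = ground_truth.occurrences
    for row in occ[occ["word"] == word].itertuples(index=False):
        ordinals = doc_chunks.get(row.doc_id, [])
        w_idx = row.position // W
        if w_idx < len(ordinals):
            labels.setdefault(ordinals[w_idx], row.meaning)
    return labels


def ground_truth_report(
    ground_truth: GroundTruth,
    chunks: Sequence[ContextChunk],
    space: SemanticSpace,
    semd_table: pd.DataFrame,
    seed: int = 0,
    n_iterations: int = 200,
) -> dict:
    """Recovery metrics for the planted structure.

    Returns a dict with a per-word table (designed spread vs computed
    SemD, retention under the vocabulary thresholds), the Spearman ρ of
    SemD against topic-spread over non-ambiguous probes, and a CH
    diagnostic (with permutation baseline) of the meaning labels for each
    ambiguous probe. Probes removed by the thresholds are reported, not
    fatal.
    """
    semd = semd_table.set_index("word")
    rows = []
    for row in ground_truth.words.itertuples(index=False):
        retained = row.word in space.vocab
        val = float(semd.loc[row.word, "semd"]) if retained and row.word in semd.index else float("nan")
        n_ctx = int(semd.loc[row.word, "n_contexts"]) if retained and row.word in semd.index else 0
        rows.append((row.word, row.spread_size, row.ambiguous, retained, n_ctx, val))
    table = pd.DataFrame(
        rows, columns=["word", "spread_size", "ambiguous", "retained", "n_contexts", "semd"]
    )
    dropped = table[~table["retained"]]
    if len(dropped):
        logger.warning("planted words filtered out by vocabulary thresholds: %s",
                       ", ".join(dropped["word"]))

    probes = table[~table["ambiguous"] & table["retained"] & np.isfinite(table["semd"])]
    if len(probes) >= 3 and probes["spread_size"].nunique() >= 2:
        rho = float(scipy.stats.spearmanr(probes["spread_size"], probes["semd"]).statistic)
    else:
        rho = float("nan")
        logger.warning("Spearman ρ undefined: %d usable probes, %d distinct spreads",
                       len(probes), probes["spread_size"].nunique() if len(probes) else 0)

    ambiguous: dict[str, ClusterDiagnostic] = {}
    for row in table[table["ambiguous"] & table["retained"]].itertuples(index=False):
        labels = occurrence_context_labels(ground_truth, chunks, row.word)
        present = {labels.get(space.row_ids[r]) for r in space.word_contexts[row.word]}
        if len(present - {None}) < 2 or None in present:
            logger.warning("ambiguous probe %r: meaning labels do not cover ≥2 categories", row.word)
            continue
        ambiguous[row.word] = word_context_diagnostic(
            space, row.word, labels, fraction=1.0, seed=seed, n_iterations=n_iterations,
        )
    return {"words": table, "spearman_rho": rho, "ambiguous": ambiguous}


def _spec_from_dict(cfg: dict) -> SyntheticSpec:
    planted = tuple(
        PlantedWord(
            word=p["word"],
            topic_spread=tuple(p["topic_spread"]),
            rate=float(p["rate"]),
            meaning_labels={int(k): v for k, v in p["meaning_labels"].items()}
            if p.get("meaning_labels") else None,
            n_random_meanings=p.get("n_random_meanings"),
        )
        for p in cfg.get("planted_words", [])
    )
    keys = ("n_topics", "docs_per_topic", "doc_length", "vocab_per_topic",
            "shared_vocab", "topic_word_fraction", "zipf_exponent", "seed")
    return SyntheticSpec(**{k: cfg[k] for k in keys if k in cfg}, planted_words=planted)


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a generator spec from YAML."""
    with open(path, encoding="utf-8") as fh:
        return _spec_from_dict(yaml.safe_load(fh))


def reference_spec(seed: int | None = None) -> tuple[SyntheticSpec, dict]:
    """The committed reference conditions: (generator spec, pipeline
    parameters). ``seed`` overrides the spec's committed seed."""
    text = resources.files("semdiv.data").joinpath("reference_spec.yaml").read_text("utf-8")
    cfg = yaml.safe_load(text)
    spec = _spec_from_dict(cfg)
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    return spec, dict(cfg.get("pipeline", {}))
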
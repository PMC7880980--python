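"""Semantic diversity: −log mean pairwise cosine of a word's context vectors.

A word occurring in n contexts has C(n, 2) unordered context pairs; the
mean cosine over those pairs measures how mutually similar its contexts
are, and SemD = −log(mean cosine) turns that into a diversity score: 0 for
a word whose contexts are all identical, larger the more its contexts
disagree. Each context counts once regardless of how often the word occurs
in it. The mean is computed in O(n·k) via the identity

    sum_{i<j} u_i·u_j = (‖Σ u_i‖² − n) / 2        (u_i unit vectors),

and an explicit O(n²) pairwise oracle is kept in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .lsa import SemanticSpace

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_TOO_FEW = "too_few_contexts"
STATUS_NONPOSITIVE = "nonpositive_mean_cosine"
STATUS_UNKNOWN = "unknown_word"


@dataclass
class SemDResult:
    word: str
    n_contexts: int
    mean_cosine: float  # NaN when not computable
    semd: float         # NaN when missing
    status: str = STATUS_OK
    n_zero_contexts: int = 0
    log_base: float = math.e

    @property
    def is_missing(self) -> bool:
        return self.status != STATUS_OK


def mean_pairwise_cosine(vectors: np.ndarray) -> float:
    """Mean cosine similarity over all unordered pairs of rows (n ≥ 2,
    rows must be nonzero)."""
    V = np.asarray(vectors, dtype=np.float64)
    n = V.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vectors")
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector in input; filter zero contexts first")
    Un = V / norms[:, None]
    s = Un.sum(axis=0)
    total = (float(s @ s) - n) / 2.0
    return total / (n * (n - 1) / 2.0)


def semantic_diversity(
    space: SemanticSpace,
    word: str,
    log_base: float = math.e,
) -> SemDResult:
    """SemD for one word: −log_base(mean pairwise cosine of its context
    vectors). Contexts whose vectors are numerically zero after truncation
    are excluded and counted. Nonpositive mean cosine or fewer than two
    usable contexts yield a missing value with a reason, never a fabricated
    score."""
    if word not in space.word_contexts:
        raise KeyError(f"word not in vocabulary: {word!r}")
    V = space.vectors_for(word)
    norms = np.linalg.norm(V, axis=1)
    nonzero = norms > 0
    n_zero = int((~nonzero).sum())
    V = V[nonzero]
    n = V.shape[0]
    if n < 2:
        logger.info("word %r has %d usable contexts (<2): SemD missing", word, n)
        return SemDResult(word, n, float("nan"), float("nan"),
                          status=STATUS_TOO_FEW, n_zero_contexts=n_zero, log_base=log_base)
    mean_cos = mean_pairwise_cosine(V)
    if mean_cos <= 0:
        logger.info("word %r has nonpositive mean cosine (%.3g): SemD missing", word, mean_cos)
        return SemDResult(word, n, mean_cos, float("nan"),
                          status=STATUS_NONPOSITIVE, n_zero_contexts=n_zero, log_base=log_base)
    semd = -math.log(mean_cos) / math.log(log_base)
    return SemDResult(word, n, mean_cos, semd, n_zero_contexts=n_zero, log_base=log_base)


def semdiv_table(
    space: SemanticSpace,
    words: Iterable[str] | None = None,
    log_base: float = math.e,
) -> pd.DataFrame:
    """SemD for a list of words (default: the whole vocabulary), one row per
    distinct word, in request order. Missing values are flagged in the
    ``status`` column, never dropped."""
    if words is None:
        words = space.vocab.words
    seen: dict[str, None] = {}
    for w in words:
        if w in seen:
            logger.warning("duplicate word %r in request; keeping one row", w)
        seen[w] = None

    rows = []
    for w in seen:
        if w not in space.word_contexts:
            rows.append(SemDResult(w, 0, float("nan"), float("nan"), status=STATUS_UNKNOWN))
        else:
            rows.append(semantic_diversity(space, w, log_base=log_base))
    return pd.DataFrame(
        {
            "word": [r.word for r in rows],
            "n_contexts": [r.n_contexts for r in rows],
            "mean_cosine": [r.mean_cosine for r in rows],
            "semd": [r.semd for r in rows],
            "status": [r.status for r in rows],
        }
    )


def write_semdiv_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def compare_variants(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Pearson and Spearman correlations of two SemD tables over their
    shared words with finite values (≥ 3 required)."""
    a = table_a.set_index("word")["semd"]
    b = table_b.set_index("word")["semd"]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    ok = np.isfinite(a.to_numpy()) & np.isfinite(b.to_numpy())
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError(f"need at least 3 shared words with finite SemD, got {len(a)}")
    pearson = scipy.stats.pearsonr(a, b)
    spearman = scipy.stats.spearmanr(a, b)
    return {
        "n": int(len(a)),
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
    }
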
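"""Context × word count matrix and log-entropy weighting.

Rows are contexts, columns are vocabulary words. The log-entropy scheme
combines a local weight log(1 + f_ij) with a global per-word weight

    g_j = 1 + sum_i p_ij log(p_ij) / log(n),   p_ij = f_ij / sum_i f_ij,

over the n contexts. g_j is 1 for a word concentrated in a single context
and tends to 0 for a word spread uniformly over all contexts, so it
down-weights undiscriminating words before the SVD. The logarithm base
cancels in g_j and rescales the local weight globally, so it cannot affect
downstream cosines; natural log is the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .corpus import ContextChunk
from .preprocess import Vocabulary

logger = logging.getLogger(__name__)


@dataclass
class CoocMatrix:
    """Sparse context × word count matrix (CSR) with its indexing."""

    counts: sp.csr_matrix
    row_ids: list[int]
    vocab: Vocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class WeightedMatrix:
    """Log-entropy weighted matrix; same shape and sparsity as the counts."""

    values: sp.csr_matrix
    row_ids: list[int]
    vocab: Vocabulary
    weighting: str = "log-entropy"
    log_base: float = math.e

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_cooc(chunks: Sequence[ContextChunk], vocab: Vocabulary) -> CoocMatrix:
    """Count vocabulary words per context. Out-of-vocabulary tokens are
    skipped; contexts with no vocabulary word are kept as empty rows."""
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    n_empty = 0
    for i, chunk in enumerate(chunks):
        counts: dict[int, int] = {}
        for tok in chunk.tokens:
            j = vocab.word_index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            n_empty += 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    if n_empty:
        logger.info("%d contexts contain no vocabulary word (kept as empty rows)", n_empty)
    mat = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), (rows, cols)),
        shape=(len(chunks), len(vocab)),
    )
    return CoocMatrix(counts=mat, row_ids=[c.context_id for c in chunks], vocab=vocab)


def global_weights(counts: sp.spmatrix) -> np.ndarray:
    """Per-word global entropy weight g_j in [0, 1]."""
    n = counts.shape[0]
    if n < 2:
        raise ValueError("log-entropy weighting needs at least 2 contexts")
    csc = sp.csc_matrix(counts, dtype=np.float64)
    col_sums = np.asarray(csc.sum(axis=0)).ravel()
    if np.any(col_sums == 0):
        bad = int(np.argmax(col_sums == 0))
        raise ValueError(f"word column {bad} has zero total count; filter the vocabulary first")
    # entropy of each word's distribution over contexts, from the nonzeros
    p = csc.copy()
    p.data = p.data / np.repeat(col_sums, np.diff(csc.indptr))
    plogp = p.copy()
    plogp.data = p.data * np.log(p.data)
    ent = np.asarray(plogp.sum(axis=0)).ravel()  # = sum p log p  (≤ 0)
    g = 1.0 + ent / np.log(n)
    # clip fp noise at the boundaries
    return np.clip(g, 0.0, 1.0)


def log_entropy_weight(M: CoocMatrix, log_base: float = math.e) -> WeightedMatrix:
    """Apply log-entropy weighting: value_ij = g_j · log_base(1 + f_ij)."""
    g = global_weights(M.counts)
    local = M.counts.astype(np.float64).tocsr()
    local.data = np.log1p(local.data) / math.log(log_base)
    weighted = (local @ sp.diags(g)).tocsr()  # scale columns by g_j
    return WeightedMatrix(
        values=weighted, row_ids=list(M.row_ids), vocab=M.vocab,
        log_base=log_base,
    )


def save_cooc(M: CoocMatrix, prefix: str | Path) -> None:
    """Persist as Matrix Market plus sidecar TSVs (row ids, vocabulary)."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), M.counts)
    with open(prefix.with_suffix(".rows.tsv"), "w", encoding="utf-8") as fh:
        fh.write("row\tcontext_id\n")
        for i, cid in enumerate(M.row_ids):
            fh.write(f"{i}\t{cid}\n")
    M.vocab.to_tsv(prefix.with_suffix(".vocab.tsv"))
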
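"""Truncated SVD and semantic-space construction.

The weighted context × word matrix A is factored as A ≈ U_k Σ_k V_kᵀ. Each
context is represented by a row of U_k·Σ_k (the classical LSA coordinates,
``scaled=True``) or of U_k alone (``scaled=False``). Both variants are
first-class: published semantic-diversity norms appear to mix the two, and
the variants correlate but are not identical, so the space records which
one it holds and can derive the other without recomputing the SVD.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .cooc import CoocMatrix, WeightedMatrix
from .preprocess import Vocabulary

logger = logging.getLogger(__name__)

DEFAULT_DIMS = 300
_SVD_TOL = 1e-10


def _canonical_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the sign ambiguity: make the largest-|·| entry of each left
    singular vector positive. Deterministic and cosine-preserving."""
    for j in range(U.shape[1]):
        col = U[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            U[:, j] = -col
            Vt[j, :] = -Vt[j, :]
    return U, Vt


def truncated_svd(
    W: WeightedMatrix | sp.spmatrix | np.ndarray,
    k: int = DEFAULT_DIMS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-k SVD of the weighted matrix; returns (U n×k, S k, V m×k).

    Singular values are nonincreasing and columns of U, V orthonormal.
    k greater than min(n, m) is capped with a warning. Uses an iterative
    sparse solver with a seeded start vector for k strictly below the
    smaller dimension, and a dense LAPACK factorisation otherwise.
    """
    if k <= 0:
        raise ValueError(f"number of dimensions must be positive, got {k}")
    A = W.values if isinstance(W, WeightedMatrix) else W
    n, m = A.shape
    cap = min(n, m)
    if k > cap:
        logger.warning("k=%d exceeds min(n, m)=%d; capping", k, cap)
        k = cap

    if k < cap:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(n, m))
        try:
            U, S, Vt = sp.linalg.svds(sp.csr_matrix(A), k=k, v0=v0, tol=_SVD_TOL)
        except sp.linalg.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"sparse SVD failed to converge at k={k} on a {n}x{m} matrix: {exc}"
            ) from exc
        order = np.argsort(S)[::-1]
        U, S, Vt = U[:, order], S[order], Vt[order, :]
    else:
        dense = A.toarray() if sp.issparse(A) else np.asarray(A, dtype=np.float64)
        U, S, Vt = scipy.linalg.svd(dense, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k, :]

    U, Vt = _canonical_signs(np.ascontiguousarray(U), np.ascontiguousarray(Vt))
    return U, S, Vt.T


@dataclass
class SemanticSpace:
    """k-dimensional context vectors plus word→context indexing.

    ``U`` and ``singular_values`` are always stored so both the scaled
    (U·Σ) and unscaled (U) variants are available; ``scaled`` records which
    one ``context_vectors`` returns.
    """

    U: np.ndarray
    singular_values: np.ndarray
    scaled: bool
    vocab: Vocabulary
    word_contexts: dict[str, np.ndarray]
    row_ids: list[int]
    row_labels: dict[int, dict[str, str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def n_contexts(self) -> int:
        return self.U.shape[0]

    @property
    def context_vectors(self) -> np.ndarray:
        if self.scaled:
            return self.U * self.singular_values[np.newaxis, :]
        return self.U

    def variant(self, scaled: bool) -> "SemanticSpace":
        """The same space with the other scaling convention (no recompute)."""
        if scaled == self.scaled:
            return self
        return SemanticSpace(
            U=self.U, singular_values=self.singular_values, scaled=scaled,
            vocab=self.vocab, word_contexts=self.word_contexts,
            row_ids=self.row_ids, row_labels=self.row_labels, seed=self.seed,
        )

    def vectors_for(self, word: str) -> np.ndarray:
        """Context vectors of every context containing ``word``."""
        if word not in self.word_contexts:
            raise KeyError(f"word not in vocabulary: {word!r}")
        return self.context_vectors[self.word_contexts[word], :]


def make_space(
    U: np.ndarray,
    S: np.ndarray,
    scaled: bool,
    cooc: CoocMatrix,
    chunks: Sequence | None = None,
    seed: int = 0,
) -> SemanticSpace:
    """Assemble a SemanticSpace from SVD factors and the count matrix.

    A context belongs to a word's context set iff its raw count of the word
    is ≥ 1 (empty weighted cells cannot arise from nonzero counts). Chunk
    metadata labels, if provided, are attached per row for diagnostics.
    """
    if U.shape[0] != cooc.counts.shape[0] or U.shape[1] != len(S):
        raise ValueError("inconsistent shapes between SVD factors and count matrix")
    csc = cooc.counts.tocsc()
    word_contexts = {
        w: np.sort(csc.indices[csc.indptr[j]:csc.indptr[j + 1]].copy())
        for w, j in cooc.vocab.word_index.items()
    }
    row_labels: dict[int, dict[str, str]] = {}
    if chunks is not None:
        row_labels = {i: dict(c.labels) for i, c in enumerate(chunks) if c.labels}
    return SemanticSpace(
        U=np.asarray(U, dtype=np.float64),
        singular_values=np.asarray(S, dtype=np.float64),
        scaled=scaled,
        vocab=cooc.vocab,
        word_contexts=word_contexts,
        row_ids=list(cooc.row_ids),
        row_labels=row_labels,
        seed=seed,
    )


def save_space(space: SemanticSpace, path: str | Path) -> None:
    """Persist as <path>.npz (matrices) + <path>.json (metadata/vocab)."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        U=space.U,
        S=space.singular_values,
        **{f"ctx_{w}": idx for w, idx in space.word_contexts.items()},
    )
    meta = {
        "k": space.k,
        "scaled": space.scaled,
        "seed": space.seed,
        "row_ids": space.row_ids,
        "row_labels": {str(i): lab for i, lab in space.row_labels.items()},
        "vocab": {
            "words": space.vocab.words,
            "total_counts": space.vocab.total_counts,
            "context_counts": space.vocab.context_counts,
            "min_count": space.vocab.min_count,
            "min_contexts": space.vocab.min_contexts,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta), "utf-8")


def load_space(path: str | Path) -> SemanticSpace:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text("utf-8"))
    v = meta["vocab"]
    vocab = Vocabulary(
        words=v["words"],
        total_counts={w: int(c) for w, c in v["total_counts"].items()},
        context_counts={w: int(c) for w, c in v["context_counts"].items()},
        min_count=v["min_count"],
        min_contexts=v["min_contexts"],
    )
    return SemanticSpace(
        U=arrays["U"],
        singular_values=arrays["S"],
        scaled=meta["scaled"],
        vocab=vocab,
        word_contexts={w: arrays[f"ctx_{w}"] for w in vocab.words},
        row_ids=list(meta["row_ids"]),
        row_labels={int(i): lab for i, lab in meta["row_labels"].items()},
        seed=meta["seed"],
    )


def export_vectors_tsv(space: SemanticSpace, path: str | Path) -> None:
    """Plain-text export of context vectors for external tools."""
    V = space.context_vectors
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("context_id\t" + "\t".join(f"dim{j}" for j in range(space.k)) + "\n")
        for i, cid in enumerate(space.row_ids):
            fh.write(str(cid) + "\t" + "\t".join(f"{x:.10g}" for x in V[i]) + "\n")
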
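"""Cluster-validity diagnostics for labelled context vectors.

The Calinski–Harabasz (variance-ratio) score asks whether a labelling of
points corresponds to real geometric clusters:

    CH = [trace(B) / (g − 1)] / [trace(W) / (n − g)]

with B the between-group and W the within-group dispersion matrices over g
groups of n points. Under a random labelling CH ≈ 1 (the F-ratio null), so
scores are read against a Monte-Carlo baseline obtained by permuting the
same label multiset. This is the instrument for the package's central
question: context vectors cluster strongly by corpus metadata (topic,
medium) but not by the meanings of an ambiguous word — the diversity
metric measures textual, not semantic, variation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lsa import SemanticSpace

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 1000
DEFAULT_FRACTION = 0.5


@dataclass
class ClusterDiagnostic:
    """A CH score with its random-label Monte-Carlo baseline."""

    ch_score: float
    n_points: int
    n_labels: int
    baseline_mean: float
    baseline_sd: float
    n_iterations: int
    seed: int

    @property
    def exceeds_baseline(self) -> bool:
        """True when the score clears the null by more than 3 baseline SDs."""
        return self.ch_score > self.baseline_mean + 3 * self.baseline_sd

    def to_dict(self) -> dict:
        return {
            "ch": self.ch_score,
            "baseline_mean": self.baseline_mean,
            "baseline_sd": self.baseline_sd,
            "n": self.n_points,
            "g": self.n_labels,
            "iterations": self.n_iterations,
            "seed": self.seed,
        }


def _encode_labels(labels: Sequence) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes.astype(np.intp), len(uniques)


def _ch_from_codes(X: np.ndarray, codes: np.ndarray, g: int) -> float:
    n = X.shape[0]
    grand = X.mean(axis=0)
    # trace dispersions need only group sums: trace(B) = Σ_g n_g ‖mean_g − grand‖²
    sums = np.zeros((g, X.shape[1]))
    np.add.at(sums, codes, X)
    sizes = np.bincount(codes, minlength=g).astype(np.float64)
    means = sums / sizes[:, None]
    between = float(np.sum(sizes * np.sum((means - grand) ** 2, axis=1)))
    within = float(np.sum((X - means[codes]) ** 2))  # direct, no cancellation
    if within <= 0:
        raise ValueError("zero within-group dispersion: degenerate perfect clustering")
    return (between / (g - 1)) / (within / (n - g))


def calinski_harabasz(vectors: np.ndarray, labels: Sequence) -> float:
    """Variance-ratio criterion for a labelling of points (trace form).

    Requires n ≥ g ≥ 2 and every label present at least once. Invariant to
    translation, rotation and uniform scaling of the vectors.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D array")
    codes, g = _encode_labels(labels)
    if len(codes) != X.shape[0]:
        raise ValueError("labels length must match number of vectors")
    if g < 2:
        raise ValueError(f"need at least 2 distinct labels, got {g}")
    if X.shape[0] < g:
        raise ValueError("need at least as many points as labels")
    return _ch_from_codes(X, codes, g)


def random_label_baseline(
    vectors: np.ndarray,
    labels: Sequence,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo null: CH under uniformly random permutations of the same
    label multiset (category sizes preserved). Returns (mean, sd over
    iterations); reproducible given the seed."""
    X = np.asarray(vectors, dtype=np.float64)
    codes, g = _encode_labels(labels)
    if g < 2:
        raise ValueError(f"need at least 2 distinct labels, got {g}")
    if n_iterations < 1:
        raise ValueError("need at least 1 iteration")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_iterations)
    for it in range(n_iterations):
        scores[it] = _ch_from_codes(X, rng.permutation(codes), g)
    sd = float(scores.std(ddof=1)) if n_iterations > 1 else 0.0
    if n_iterations == 1:
        logger.warning("baseline with a single iteration: sd reported as 0")
    return float(scores.mean()), sd


def word_context_diagnostic(
    space: SemanticSpace,
    word: str,
    context_labels: Mapping[int, str],
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
    n_iterations: int = DEFAULT_ITERATIONS,
) -> ClusterDiagnostic:
    """Do a word's context vectors cluster by a supplied labelling (e.g.
    hand-annotated meanings)?

    Samples ⌈fraction·n⌉ of the word's contexts without replacement
    (seeded; fraction=0.5 mirrors annotating a random half), computes CH of
    their vectors against the labels, and the permutation baseline.
    ``context_labels`` maps corpus-wide context ids to categories; sampled
    contexts without a label raise an error.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if word not in space.word_contexts:
        raise KeyError(f"word not in vocabulary: {word!r}")
    rows = space.word_contexts[word]
    rng = np.random.default_rng(seed)
    n_sample = math.ceil(fraction * len(rows))
    sampled = np.sort(rng.choice(rows, size=n_sample, replace=False))
    labels = []
    for r in sampled:
        cid = space.row_ids[r]
        if cid not in context_labels:
            raise KeyError(f"context {cid} of word {word!r} has no label")
        labels.append(context_labels[cid])
    X = space.context_vectors[sampled, :]
    ch = calinski_harabasz(X, labels)
    mean, sd = random_label_baseline(X, labels, n_iterations=n_iterations, seed=seed)
    return ClusterDiagnostic(ch, len(sampled), len(set(labels)), mean, sd, n_iterations, seed)


def corpus_label_diagnostic(
    space: SemanticSpace,
    label_dimension: str,
    seed: int = 0,
    n_iterations: int = DEFAULT_ITERATIONS,
) -> ClusterDiagnostic:
    """CH over ALL context vectors grouped by a metadata dimension carried
    from the documents (e.g. "domain", "medium"). Contexts missing the
    label are excluded (count logged)."""
    rows, labels = [], []
    for i in range(space.n_contexts):
        lab = space.row_labels.get(i, {}).get(label_dimension)
        if lab is None:
            continue
        rows.append(i)
        labels.append(lab)
    n_missing = space.n_contexts - len(rows)
    if n_missing:
        logger.info("%d contexts lack label %r; excluded", n_missing, label_dimension)
    if len(set(labels)) < 2:
        raise ValueError(f"label dimension {label_dimension!r} has fewer than 2 categories")
    X = space.context_vectors[np.asarray(rows), :]
    ch = calinski_harabasz(X, labels)
    mean, sd = random_label_baseline(X, labels, n_iterations=n_iterations, seed=seed)
    return ClusterDiagnostic(ch, len(rows), len(set(labels)), mean, sd, n_iterations, seed)


def embed_2d(
    vectors: np.ndarray,
    labels: Sequence,
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of labelled vectors for visual inspection.

    Returns a DataFrame with columns x, y, label; deterministic given the
    seed. A visual aid only — no quantitative conclusion rests on the
    embedding geometry.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(vectors, dtype=np.float64)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points to embed")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be below n ({n})")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
    ).fit_transform(X)
    return pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": list(labels)})


def load_context_labels(path) -> dict[int, str]:
    """Read a TSV mapping context_id → category (2 columns, header allowed)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("label file needs 2 tab-separated columns")
    return {int(k): str(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
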
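"""Corpus reading and segmentation into fixed-length contexts.

A "context" is a fixed window of W consecutive cleaned tokens from a single
document (the classic LSA document-chunking scheme, W = 1000 by default).
Partial final windows are dropped: they would under-represent their contexts
in the count matrix. Chunks never span document boundaries and inherit the
document's metadata labels (e.g. domain, medium).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import CleanConfig, clean_tokens

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000


@dataclass
class Document:
    """One corpus document with optional metadata labels."""

    doc_id: str
    raw_text: str
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class ContextChunk:
    """A window of exactly W cleaned tokens from one document."""

    context_id: int
    doc_id: str
    tokens: list[str]
    labels: dict[str, str] = field(default_factory=dict)


def read_corpus(path: str | Path, format: str | None = None) -> list[Document]:
    """Read a corpus from a directory of .txt files or a JSONL file.

    Directory: one Document per ``*.txt`` file, in lexicographic filename
    order, ``doc_id`` = file stem. JSONL: one Document per line with fields
    ``{"id", "text", "labels"}`` (``id`` and ``labels`` optional).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus path does not exist: {path}")

    if format is None:
        format = "jsonl" if (path.is_file() and path.suffix == ".jsonl") else "plain"

    if format == "plain":
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        docs = []
        for f in files:
            try:
                text = f.read_text("utf-8")
            except OSError as exc:
                raise OSError(f"unreadable corpus file: {f}") from exc
            docs.append(Document(doc_id=f.stem, raw_text=text))
        if not docs:
            logger.warning("no .txt files found under %s", path)
        return docs

    if format == "jsonl":
        docs = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    text = obj["text"]
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSONL line ({exc})") from exc
                docs.append(Document(
                    doc_id=str(obj.get("id", lineno - 1)),
                    raw_text=text,
                    labels=dict(obj.get("labels") or {}),
                ))
        if not docs:
            logger.warning("no documents found in %s", path)
        return docs

    raise ValueError(f"unknown corpus format: {format!r}")


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({"id": d.doc_id, "text": d.raw_text, "labels": d.labels}) + "\n")


def chunk_documents(
    docs: Sequence[Document],
    W: int = DEFAULT_WINDOW,
    tokenizer: CleanConfig | None = None,
    clean_first: bool = True,
) -> list[ContextChunk]:
    """Segment documents into contexts of exactly W tokens.

    With ``clean_first=True`` (default) tokens are cleaned per document
    *before* windowing, so W counts content words. A document of n cleaned
    tokens yields floor(n/W) chunks: the trailing partial window is dropped
    (it may contain fewer than W words); an exactly-full final window is
    kept. ``clean_first=False`` windows the raw whitespace tokens first and
    cleans each window afterwards (chunks then hold ≤ W cleaned tokens) —
    provided for sensitivity checks.
    """
    if W <= 0:
        raise ValueError(f"window length must be positive, got {W}")

    chunks: list[ContextChunk] = []
    next_id = 0
    for doc in docs:
        if clean_first:
            tokens = clean_tokens(doc.raw_text, tokenizer)
            n_full = len(tokens) // W
            windows = [tokens[i * W:(i + 1) * W] for i in range(n_full)]
        else:
            raw = doc.raw_text.split()
            n_full = len(raw) // W
            windows = [clean_tokens(" ".join(raw[i * W:(i + 1) * W]), tokenizer)
                       for i in range(n_full)]
        if n_full == 0:
            logger.info("document %s shorter than window (%d tokens < %d): no contexts",
                        doc.doc_id, len(tokens) if clean_first else len(doc.raw_text.split()), W)
        for win in windows:
            chunks.append(ContextChunk(
                context_id=next_id, doc_id=doc.doc_id, tokens=win, labels=dict(doc.labels),
            ))
            next_id += 1
    return chunks


def write_chunk_manifest(chunks: Sequence[ContextChunk], path: str | Path) -> None:
    """Write a TSV manifest: context_id, doc_id, n_tokens, then label columns."""
    label_dims = sorted({dim for c in chunks for dim in c.labels})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["context_id", "doc_id", "n_tokens", *label_dims]) + "\n")
        for c in chunks:
            row = [str(c.context_id), c.doc_id, str(len(c.tokens))]
            row += [c.labels.get(dim, "") for dim in label_dims]
            fh.write("\t".join(row) + "\n")
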
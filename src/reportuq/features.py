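"""Text preprocessing and mean-pooled word-embedding features.

Each report is represented by the arithmetic mean of the word vectors of its
in-vocabulary tokens — the fixed-length document representation consumed by
every classifier in the package.  Embedding tables use the word2vec *text*
format (header line ``vocab_size dimension``, then one ``token v1 ... vd``
line per entry), so a user-supplied biomedical table (e.g. Word2Vec-Pubmed at
d=200) drops in directly; a synthetic table with class-indicative directions
is provided for self-contained experiments.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .corpus import LabelledCorpus, _DEFAULT_VOCAB
from ._seeding import rng_for

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def preprocess(text_or_tokens) -> list[str]:
    """Lower-case, strip punctuation (splitting tokens at punctuation
    boundaries) and collapse whitespace; token order is preserved.

    Idempotent: the output alphabet is ``[a-z0-9]+`` which the rules map to
    itself.
    """
    if text_or_tokens is None:
        raise ValueError("input must not be None")
    if isinstance(text_or_tokens, str):
        text = text_or_tokens
    else:
        text = " ".join(text_or_tokens)
    return _TOKEN_RE.findall(text.lower())


class EmbeddingTable:
    """token → d-vector mapping with a single shared dimension."""

    def __init__(self, entries: dict[str, np.ndarray]):
        if not entries:
            raise ValueError("embedding table must be non-empty")
        dims = {np.asarray(v).shape for v in entries.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"inconsistent vector shapes in embedding table: {dims}")
        self.entries = {t: np.asarray(v, dtype=float) for t, v in entries.items()}
        self.dimension = next(iter(dims))[0]

    def __contains__(self, token):
        return token in self.entries

    def __getitem__(self, token):
        return self.entries[token]

    def __len__(self):
        return len(self.entries)

    # -- word2vec text format ---------------------------------------------
    @classmethod
    def from_word2vec(cls, path) -> "EmbeddingTable":
        entries = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("expected word2vec text header 'vocab_size dimension'")
            vocab_size, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"bad vector line for token {parts[0]!r}")
                entries[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(entries) != vocab_size:
            raise ValueError(f"header promised {vocab_size} entries, found {len(entries)}")
        return cls(entries)

    def to_word2vec(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.entries)} {self.dimension}\n")
            for token, vec in self.entries.items():
                fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def synthetic_table(
    dimension: int = 50,
    seed: int = 0,
    vocab_spec: dict | None = None,
    base_scale: float = 0.5,
    offset_scale: float = 4.0,
) -> EmbeddingTable:
    """Synthetic embedding fixture.

    Every token gets an isotropic Gaussian base vector; the three
    class-indicative roles (affirmative, hedging, negation) additionally get a
    shared mean offset along mutually orthogonal random directions, so pooled
    document vectors carry a learnable class signal.
    """
    vocab = vocab_spec or _DEFAULT_VOCAB
    rng = rng_for(seed, "synthetic-embedding-table")
    # three orthonormal signal directions via QR of a random matrix
    q, _ = np.linalg.qr(rng.standard_normal((dimension, 3)))
    offsets = {"affirmative": q[:, 0], "hedging": q[:, 1], "negation": q[:, 2]}
    entries: dict[str, np.ndarray] = {}
    for role in ("affirmative", "negation", "hedging", "filler"):
        for token in vocab[role]:
            vec = base_scale * rng.standard_normal(dimension)
            if role in offsets:
                vec = vec + offset_scale * offsets[role]
            entries[token] = vec
    return EmbeddingTable(entries)


def mean_pool_embed(tokens, table: EmbeddingTable) -> np.ndarray:
    """Mean of the in-vocabulary token vectors; out-of-vocabulary tokens are
    skipped (the divisor is the in-vocabulary count).  If no token is in
    vocabulary the zero vector is returned and the event logged."""
    vecs = [table[t] for t in tokens if t in table]
    if not vecs:
        logger.warning("document with no in-vocabulary tokens; emitting zero vector")
        return np.zeros(table.dimension)
    return np.mean(vecs, axis=0)


@dataclass
class FeatureMatrix:
    values: np.ndarray  # n x d
    row_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("values must be n x d with one row per row_id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self):
        return self.values.shape[0]

    @property
    def d(self):
        return self.values.shape[1]

    def rows_for(self, ids) -> np.ndarray:
        index = {rid: i for i, rid in enumerate(self.row_ids)}
        return self.values[[index[i] for i in ids]]

    def save(self, path) -> None:
        np.savez(path, values=self.values, row_ids=np.array(self.row_ids))

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        data = np.load(path, allow_pickle=False)
        return cls(values=data["values"], row_ids=[str(x) for x in data["row_ids"]])


def featurize_corpus(corpus: LabelledCorpus, table: EmbeddingTable) -> FeatureMatrix:
    """One mean-pooled row per report, aligned with corpus order.

    Consumes tokens only — the generator's latent severity never reaches the
    models.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    rows = np.empty((len(corpus), table.dimension))
    ids = []
    for i, report in enumerate(corpus):
        rows[i] = mean_pool_embed(preprocess(report.tokens), table)
        ids.append(report.report_id)
    return FeatureMatrix(values=rows, row_ids=ids)
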
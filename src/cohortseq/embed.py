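"""Cohort-specific low-dimensional word embeddings.

Shallow CBOW and skipgram models with negative sampling, trained per cohort
corpus with a small fixed dimensionality (default 15). The embedding is a
probe geometry, not a language model: the point is to compare the relational
structure the different cohorts' co-occurrence statistics induce.

Defaults mirror the study design: dim 15, symmetric window 5, 20 epochs,
5 negative samples drawn from the unigram distribution raised to 3/4, initial
learning rate 0.01 with linear decay. Context windows never cross utterance
boundaries — the positional statistics computed elsewhere in the package are
utterance-bounded, and cross-utterance context would contaminate boundary
effects. Training is single-threaded and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .corpus import TaggedCorpus, Token, Utterance

__all__ = [
    "TrainConfig",
    "EmbeddingSpace",
    "SequenceVariant",
    "apply_sequence_variant",
    "build_vocab",
    "train_embeddings",
    "cosine_similarity",
    "save_vectors",
    "load_vectors",
]

VARIANT_KINDS = ("forward", "backwards", "shuffled", "position_coded")

#: Category tag attached to synthetic position-marker tokens.
POSITION_MARKER_TAG = "posmark"


@dataclass(frozen=True)
class TrainConfig:
    dim: int = 15
    window: int = 5
    epochs: int = 20
    negative: int = 5
    learning_rate: float = 0.01
    mode: str = "cbow"
    min_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negative < 0:
            raise ValueError("negative must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.mode not in ("cbow", "skipgram"):
            raise ValueError(f"mode must be 'cbow' or 'skipgram', got {self.mode!r}")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class SequenceVariant:
    """One of the four sequence manipulations applied before training."""

    kind: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValueError(
                f"unknown variant kind {self.kind!r}; expected one of {VARIANT_KINDS}"
            )


@dataclass
class EmbeddingSpace:
    """A trained vocabulary -> vector mapping for one cohort."""

    vocabulary: list[str]
    vectors: np.ndarray
    config: TrainConfig
    cohort_label: str
    epoch_losses: np.ndarray | None = None
    #: output-side (context) vectors; dot(vectors, context_vectors.T) is the
    #: quantity the negative-sampling objective shapes toward shifted PMI
    context_vectors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.config.dim):
            raise ValueError("one vector per vocabulary entry is required")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in vocabulary") from None

    def subset(self, words: list[str]) -> np.ndarray:
        """Row-stacked vectors for the given words (OOV raises)."""
        return np.stack([self.vector(w) for w in words])


def _rebuild(tokens: list[tuple[str, str]], utt: Utterance) -> Utterance:
    return Utterance(
        tokens=tuple(
            Token(surface=s, category=c, position=i + 1)
            for i, (s, c) in enumerate(tokens)
        ),
        speaker_role=utt.speaker_role,
        age_months=utt.age_months,
    )


def apply_sequence_variant(corpus: TaggedCorpus, variant: SequenceVariant) -> TaggedCorpus:
    """Apply a sequence manipulation, re-indexing positions from 1.

    forward: identity. backwards: token order reversed per utterance.
    shuffled: tokens permuted uniformly within each utterance (seeded).
    position_coded: a marker token ``<p{i}>`` is interleaved *before* the
    content token originally at position ``i``.
    """
    if not corpus.utterances:
        raise ValueError("corpus must be non-empty")
    if variant.kind == "forward":
        return corpus
    rng = np.random.default_rng(variant.seed)
    out: list[Utterance] = []
    for utt in corpus.utterances:
        pairs = [(t.surface, t.category) for t in utt.tokens]
        if variant.kind == "backwards":
            pairs = pairs[::-1]
        elif variant.kind == "shuffled":
            perm = rng.permutation(len(pairs))
            pairs = [pairs[i] for i in perm]
        elif variant.kind == "position_coded":
            coded: list[tuple[str, str]] = []
            for i, pair in enumerate(pairs, start=1):
                coded.append((f"<p{i}>", POSITION_MARKER_TAG))
                coded.append(pair)
            pairs = coded
        out.append(_rebuild(pairs, utt))
    return TaggedCorpus(cohort_label=corpus.cohort_label, utterances=tuple(out))


def build_vocab(corpus: TaggedCorpus, min_count: int = 1) -> list[str]:
    """Words with frequency >= min_count, by descending frequency then lexicographic."""
    if not corpus.utterances:
        raise ValueError("corpus must be non-empty")
    freq: dict[str, int] = {}
    for utt in corpus.utterances:
        for tok in utt.tokens:
            freq[tok.surface] = freq.get(tok.surface, 0) + 1
    vocab = sorted(
        (w for w, c in freq.items() if c >= min_count),
        key=lambda w: (-freq[w], w),
    )
    if not vocab:
        raise ValueError(f"no word reaches min_count={min_count}")
    return vocab


@njit(cache=True)
def _sgns_kernel(
    tokens, starts, ends, syn0, syn1, cbow, window, epochs, negative,
    alpha0, alpha_min, cum_table, seed, losses, loss_counts,
):  # pragma: no cover - exercised through train_embeddings
    np.random.seed(seed)
    dim = syn0.shape[1]
    n_tokens = tokens.shape[0]
    total = max(1, epochs * n_tokens)
    table_max = cum_table[cum_table.shape[0] - 1]
    neu1 = np.zeros(dim)
    grad = np.zeros(dim)
    step = 0
    for ep in range(epochs):
        for u in range(starts.shape[0]):
            s = starts[u]
            e = ends[u]
            for pos in range(s, e):
                alpha = alpha0 * (1.0 - step / total)
                if alpha < alpha_min:
                    alpha = alpha_min
                step += 1
                lo = pos - window
                if lo < s:
                    lo = s
                hi = pos + window + 1
                if hi > e:
                    hi = e
                if hi - lo - 1 <= 0:
                    continue
                center = tokens[pos]
                if cbow:
                    n_ctx = hi - lo - 1
                    for d in range(dim):
                        neu1[d] = 0.0
                    for j in range(lo, hi):
                        if j == pos:
                            continue
                        row = tokens[j]
                        for d in range(dim):
                            neu1[d] += syn0[row, d]
                    for d in range(dim):
                        neu1[d] /= n_ctx
                    for d in range(dim):
                        grad[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = center
                            label = 1.0
                        else:
                            r = np.random.random() * table_max
                            target = np.searchsorted(cum_table, r)
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += neu1[d] * syn1[target, d]
                        if f > 8.0:
                            pred = 1.0
                        elif f < -8.0:
                            pred = 0.0
                        else:
                            pred = 1.0 / (1.0 + math.exp(-f))
                        if label == 1.0:
                            losses[ep] += -math.log(max(pred, 1e-12))
                        else:
                            losses[ep] += -math.log(max(1.0 - pred, 1e-12))
                        loss_counts[ep] += 1.0
                        g = (label - pred) * alpha
                        for d in range(dim):
                            grad[d] += g * syn1[target, d]
                        for d in range(dim):
                            syn1[target, d] += g * neu1[d]
                    for d in range(dim):
                        grad[d] /= n_ctx
                    for j in range(lo, hi):
                        if j == pos:
                            continue
                        row = tokens[j]
                        for d in range(dim):
                            syn0[row, d] += grad[d]
                else:  # skipgram: the center's input vector predicts each context word
                    for j in range(lo, hi):
                        if j == pos:
                            continue
                        ctx = tokens[j]
                        for d in range(dim):
                            grad[d] = 0.0
                        for k in range(negative + 1):
                            if k == 0:
                                target = ctx
                                label = 1.0
                            else:
                                r = np.random.random() * table_max
                                target = np.searchsorted(cum_table, r)
                                if target == ctx:
                                    continue
                                label = 0.0
                            f = 0.0
                            for d in range(dim):
                                f += syn0[center, d] * syn1[target, d]
                            if f > 8.0:
                                pred = 1.0
                            elif f < -8.0:
                                pred = 0.0
                            else:
                                pred = 1.0 / (1.0 + math.exp(-f))
                            if label == 1.0:
                                losses[ep] += -math.log(max(pred, 1e-12))
                            else:
                                losses[ep] += -math.log(max(1.0 - pred, 1e-12))
                            loss_counts[ep] += 1.0
                            g = (label - pred) * alpha
                            for d in range(dim):
                                grad[d] += g * syn1[target, d]
                            for d in range(dim):
                                syn1[target, d] += g * syn0[center, d]
                        for d in range(dim):
                            syn0[center, d] += grad[d]


def train_embeddings(corpus: TaggedCorpus, config: TrainConfig) -> EmbeddingSpace:
    """Train CBOW or skipgram vectors on one cohort corpus.

    Negatives are drawn from the unigram distribution raised to the 3/4
    power. The learning rate decays linearly from ``learning_rate`` to
    1e-4 of its initial value over the training run. With ``epochs=0`` the
    returned vectors equal their (seeded) random initialization.
    """
    vocab = build_vocab(corpus, config.min_count)
    index = {w: i for i, w in enumerate(vocab)}

    seq: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    for utt in corpus.utterances:
        ids = [index[t.surface] for t in utt.tokens if t.surface in index]
        if not ids:
            continue
        starts.append(len(seq))
        seq.extend(ids)
        ends.append(len(seq))
    tokens = np.asarray(seq, dtype=np.int64)
    starts_a = np.asarray(starts, dtype=np.int64)
    ends_a = np.asarray(ends, dtype=np.int64)

    counts = np.bincount(tokens, minlength=len(vocab)).astype(np.float64)
    noise = counts ** 0.75
    cum_table = np.cumsum(noise)

    rng = np.random.default_rng(config.seed)
    bound = 0.5 / config.dim
    syn0 = rng.uniform(-bound, bound, size=(len(vocab), config.dim))
    syn1 = np.zeros((len(vocab), config.dim))

    losses = np.zeros(config.epochs, dtype=np.float64)
    loss_counts = np.zeros(config.epochs, dtype=np.float64)
    if config.epochs > 0 and tokens.size > 0:
        _sgns_kernel(
            tokens, starts_a, ends_a, syn0, syn1,
            config.mode == "cbow", config.window, config.epochs, config.negative,
            config.learning_rate, config.learning_rate * 1e-4, cum_table,
            config.seed % (2**31), losses, loss_counts,
        )
    mean_losses = np.divide(
        losses, np.maximum(loss_counts, 1.0), out=np.zeros_like(losses),
        where=loss_counts > 0,
    )
    return EmbeddingSpace(
        vocabulary=vocab,
        vectors=syn0,
        config=config,
        cohort_label=corpus.cohort_label,
        epoch_losses=mean_losses,
        context_vectors=syn1,
    )


def cosine_similarity(space: EmbeddingSpace, w1: str, w2: str) -> float:
    """cos(v1, v2) in [-1, 1]; cosine *distance* is 1 minus this value."""
    v1, v2 = space.vector(w1), space.vector(w2)
    denom = float(np.linalg.norm(v1) * np.linalg.norm(v2))
    if denom == 0.0:
        raise ValueError(f"zero-norm vector for {w1!r} or {w2!r}")
    return float(np.dot(v1, v2) / denom)


def save_vectors(space: EmbeddingSpace, path: str | Path) -> None:
    """Write the whitespace-delimited text vector format (header: V dim)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(space.vocabulary)} {space.config.dim}\n")
        for w, v in zip(space.vocabulary, space.vectors):
            fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")


def load_vectors(path: str | Path, cohort_label: str = "LOADED") -> EmbeddingSpace:
    """Read the text vector format written by :func:`save_vectors`."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        head = fh.readline().split()
        n, dim = int(head[0]), int(head[1])
        vocab: list[str] = []
        vecs = np.zeros((n, dim))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            vocab.append(parts[0])
            vecs[i] = [float(x) for x in parts[1:]]
    cfg = TrainConfig(dim=dim)
    return EmbeddingSpace(vocabulary=vocab, vectors=vecs, config=cfg, cohort_label=cohort_label)
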
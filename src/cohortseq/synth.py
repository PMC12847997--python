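"""Synthetic cohort corpora with known ground-truth sequence structure.

The generator realizes the structural regularities the analysis pipeline is
built to measure, so every estimator can be validated against closed-form
ground truth:

* utterance lengths are i.i.d. Geometric(p) — ``p`` is the per-step
  termination probability — truncated at ``max_length`` by rejection;
* the part-of-speech (category) sequence is a first-order Markov chain with
  a given initial distribution and row-stochastic transition matrix;
* given category ``c`` at position ``i``, the surface form is drawn from
  ``c``'s vocabulary with Zipf weights ``rank**(-zipf_exponent)`` over an
  *effective* vocabulary of size ``clip(round(V * exp(g*(i-1))), 1, V)``,
  where ``g`` is the per-position log-change in effective vocabulary — a
  positional lexical-diversity gradient.

Under this model the token-position histogram decays geometrically, so an
ordinary least-squares fit of log10(count) on rank has slope ``log10(1-p)``;
the length-distribution entropy and the stationary adjacent-category mutual
information have direct-summation closed forms, exposed by
:func:`ground_truth_summary`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import TaggedCorpus, Token, Utterance

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_cohort_series",
    "ground_truth_summary",
    "load_config",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic cohort corpus.

    ``categories`` names the Markov states; ``vocab_sizes`` gives each
    category's base vocabulary size. ``diversity_gradient`` < 0 shrinks the
    effective vocabulary with position (diversity concentrated at the
    utterance onset), > 0 grows it (diversity concentrated at the boundary
    reached late).
    """

    n_utterances: int
    termination_prob: float
    transition_matrix: tuple[tuple[float, ...], ...]
    initial_dist: tuple[float, ...]
    categories: tuple[str, ...]
    vocab_sizes: dict[str, int] = field(default_factory=dict)
    zipf_exponent: float = 1.0
    diversity_gradient: float = 0.0
    max_length: int = 50
    seed: int = 0
    label: str = "SYNTH"
    age_months: float | None = None
    speaker_role: str = "child"

    def __post_init__(self) -> None:
        p = self.termination_prob
        if not (0.0 < p <= 1.0):
            raise ValueError(f"termination_prob must be in (0, 1], got {p}")
        if self.n_utterances < 1:
            raise ValueError("n_utterances must be >= 1")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        T = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.categories)
        if T.shape != (k, k):
            raise ValueError(
                f"transition_matrix shape {T.shape} does not match "
                f"{k} categories"
            )
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        pi0 = np.asarray(self.initial_dist, dtype=float)
        if pi0.shape != (k,):
            raise ValueError("initial_dist length must match categories")
        if np.any(pi0 < 0) or not np.isclose(pi0.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_dist must be a probability vector")
        for c in self.categories:
            if self.vocab_sizes.get(c, 1) < 1:
                raise ValueError(f"vocab_sizes[{c!r}] must be >= 1")

    @property
    def T(self) -> np.ndarray:
        return np.asarray(self.transition_matrix, dtype=float)

    @property
    def pi0(self) -> np.ndarray:
        return np.asarray(self.initial_dist, dtype=float)

    def vocab_size(self, category: str) -> int:
        return int(self.vocab_sizes.get(category, 100))


def _sample_lengths(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Geometric(p) lengths truncated at max_length by rejection."""
    p = cfg.termination_prob
    lengths = rng.geometric(p, size=cfg.n_utterances)
    bad = lengths > cfg.max_length
    while np.any(bad):
        lengths[bad] = rng.geometric(p, size=int(bad.sum()))
        bad = lengths > cfg.max_length
    return lengths


def _sample_categories(
    cfg: GeneratorConfig, lengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Markov category-index sequences, batched position by position.

    Returns an int array of shape (n_utterances, max(lengths)); entries past
    an utterance's length are -1.
    """
    k = len(cfg.categories)
    T = cfg.T
    Lmax = int(lengths.max())
    n = len(lengths)
    states = np.full((n, Lmax), -1, dtype=np.int64)
    cum0 = np.cumsum(cfg.pi0)
    states[:, 0] = np.searchsorted(cum0, rng.random(n), side="right")
    cumT = np.cumsum(T, axis=1)
    for pos in range(1, Lmax):
        alive = np.flatnonzero(lengths > pos)
        if alive.size == 0:
            break
        prev = states[alive, pos - 1]
        u = rng.random(alive.size)
        # row-wise inverse-CDF draw grouped by previous state
        nxt = np.empty(alive.size, dtype=np.int64)
        for s in range(k):
            mask = prev == s
            if np.any(mask):
                nxt[mask] = np.searchsorted(cumT[s], u[mask], side="right")
        states[alive, pos] = np.clip(nxt, 0, k - 1)
    states[:, 0] = np.clip(states[:, 0], 0, k - 1)
    return states


def _zipf_cdf(v_eff: int, exponent: float) -> np.ndarray:
    w = np.arange(1, v_eff + 1, dtype=float) ** (-exponent)
    return np.cumsum(w / w.sum())


def generate_corpus(config: GeneratorConfig) -> TaggedCorpus:
    """Generate one cohort corpus; identical config (incl. seed) → identical corpus.

    Surface forms are synthetic lexemes named ``{category}_w{rank}`` so the
    Zipf rank of every word is recoverable from its spelling.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _sample_lengths(config, rng)
    states = _sample_categories(config, lengths, rng)
    Lmax = int(lengths.max())
    k = len(config.categories)

    # Word ranks drawn per (category, position) group: the effective
    # vocabulary depends only on position, the weights only on its size.
    ranks = np.zeros_like(states)
    u = rng.random(states.shape)
    cdf_cache: dict[tuple[int, int], np.ndarray] = {}
    for pos in range(Lmax):
        v_scale = float(np.exp(config.diversity_gradient * pos))
        for s in range(k):
            rows = np.flatnonzero(states[:, pos] == s)
            if rows.size == 0:
                continue
            base = config.vocab_size(config.categories[s])
            v_eff = int(np.clip(round(base * v_scale), 1, base))
            key = (s, v_eff)
            cdf = cdf_cache.get(key)
            if cdf is None:
                cdf = _zipf_cdf(v_eff, config.zipf_exponent)
                cdf_cache[key] = cdf
            ranks[rows, pos] = np.searchsorted(cdf, u[rows, pos], side="right") + 1

    utterances: list[Utterance] = []
    cats = config.categories
    # Token objects are frozen and heavily repeated; cache them by
    # (state, rank, position) so large corpora stay cheap to build.
    token_cache: dict[tuple[int, int, int], Token] = {}

    def _token(s: int, r: int, j: int) -> Token:
        key = (s, r, j)
        tok = token_cache.get(key)
        if tok is None:
            tok = Token(surface=f"{cats[s]}_w{r}", category=cats[s], position=j + 1)
            token_cache[key] = tok
        return tok

    for i in range(config.n_utterances):
        L = int(lengths[i])
        toks = tuple(_token(int(states[i, j]), int(ranks[i, j]), j) for j in range(L))
        utterances.append(
            Utterance(
                tokens=toks,
                speaker_role=config.speaker_role,
                age_months=config.age_months,
            )
        )
    return TaggedCorpus(cohort_label=config.label, utterances=tuple(utterances))


def generate_cohort_series(
    configs: Sequence[GeneratorConfig], master_seed: int | None = None
) -> list[TaggedCorpus]:
    """Generate one corpus per config (>= 2 required; labels must be unique).

    With ``master_seed`` given, per-cohort seeds are derived deterministically
    from it (overriding each config's own seed); otherwise configs are used
    as-is.
    """
    if len(configs) < 2:
        raise ValueError("generate_cohort_series requires at least 2 configs")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate cohort labels: {labels}")
    corpora: list[TaggedCorpus] = []
    for i, cfg in enumerate(configs):
        if master_seed is not None:
            seed = int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0] % (2**31))
            cfg = GeneratorConfig(**{**asdict(cfg), "seed": seed})
        corpora.append(generate_corpus(cfg))
    return corpora


@dataclass(frozen=True)
class GroundTruth:
    """Analytic values implied by a generator configuration."""

    expected_rank_slope: float
    length_entropy_bits: float
    stationary_dist: tuple[float, ...]
    adjacent_mi_bits: float


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def ground_truth_summary(config: GeneratorConfig) -> GroundTruth:
    """Closed-form targets every downstream estimator should recover.

    * ``expected_rank_slope``: slope of log10(position-count) vs rank,
      ``log10(1-p)`` (the position histogram decays by the survival factor);
      ``-inf`` in the degenerate p=1 case.
    * ``length_entropy_bits``: Shannon entropy of the truncated, renormalized
      Geometric(p) length distribution (direct summation; for the supports
      used here truncation mass is negligible, so this agrees with the
      untruncated closed form ``[-p log2 p - (1-p) log2(1-p)] / p``).
    * ``stationary_dist``: left Perron eigenvector of the transition matrix.
    * ``adjacent_mi_bits``: stationary adjacent-pair mutual information by
      direct summation over joint outcomes.
    """
    p = config.termination_prob
    slope = float(np.log10(1.0 - p)) if p < 1.0 else float("-inf")

    i = np.arange(1, config.max_length + 1)
    pmf = (1.0 - p) ** (i - 1) * p
    pmf = pmf / pmf.sum()
    nz = pmf[pmf > 0]
    length_h = float(-(nz * np.log2(nz)).sum())

    T = config.T
    pi = _stationary(T)
    joint = pi[:, None] * T
    indep = pi[:, None] * pi[None, :]
    mask = joint > 0
    terms = np.zeros_like(joint)
    terms[mask] = joint[mask] * np.log2(joint[mask] / indep[mask])
    mi = float(terms.sum())

    return GroundTruth(
        expected_rank_slope=slope,
        length_entropy_bits=length_h,
        stationary_dist=tuple(float(x) for x in pi),
        adjacent_mi_bits=mi,
    )


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a :class:`GeneratorConfig` from a JSON file."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = json.load(fh)
    raw["transition_matrix"] = tuple(tuple(row) for row in raw["transition_matrix"])
    raw["initial_dist"] = tuple(raw["initial_dist"])
    raw["categories"] = tuple(raw["categories"])
    return GeneratorConfig(**raw)
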
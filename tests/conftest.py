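"""Shared fixtures: tiny hand-built corpora and generator configurations."""

from __future__ import annotations

import numpy as np
import pytest

from cohortseq import GeneratorConfig, TaggedCorpus, Token, Utterance


def make_utterance(words, categories=None, role="child", age=None) -> Utterance:
    if categories is None:
        categories = ["x"] * len(words)
    return Utterance(
        tokens=tuple(
            Token(surface=w, category=c, position=i + 1)
            for i, (w, c) in enumerate(zip(words, categories))
        ),
        speaker_role=role,
        age_months=age,
    )


def make_corpus(utterance_words, label="TEST", categories=None, ages=None) -> TaggedCorpus:
    """Build a corpus from lists of word lists (optionally category lists)."""
    utts = []
    for i, words in enumerate(utterance_words):
        cats = categories[i] if categories is not None else None
        age = ages[i] if ages is not None else None
        utts.append(make_utterance(words, cats, age=age))
    return TaggedCorpus(cohort_label=label, utterances=tuple(utts))


@pytest.fixture
def tiny_corpus() -> TaggedCorpus:
    return make_corpus([["the", "cat", "sat"], ["a", "dog"]],
                       categories=[["det", "noun", "verb"], ["det", "noun"]])


def markov_config(
    p=0.45,
    stay=0.9,
    n_utterances=1000,
    seed=0,
    label="SYNTH",
    vocab=20,
    zipf=1.0,
    gradient=0.0,
    k=2,
    max_length=50,
    initial=None,
) -> GeneratorConfig:
    """A k-state chain that stays in place with probability ``stay``."""
    off = (1.0 - stay) / (k - 1)
    T = tuple(
        tuple(stay if i == j else off for j in range(k)) for i in range(k)
    )
    cats = tuple(f"c{i}" for i in range(k))
    init = tuple(initial) if initial is not None else tuple(1.0 / k for _ in range(k))
    return GeneratorConfig(
        n_utterances=n_utterances,
        termination_prob=p,
        transition_matrix=T,
        initial_dist=init,
        categories=cats,
        vocab_sizes={c: vocab for c in cats},
        zipf_exponent=zipf,
        diversity_gradient=gradient,
        max_length=max_length,
        seed=seed,
        label=label,
    )
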
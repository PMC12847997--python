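"""Reference synthetic study design: four developmental cohorts.

This module fixes the package's canonical simulated analogue of an
age-stratified speech study. Four cohorts — toddlers (TO), 3–6-year-olds
(3PLUS), 5–12-year-olds (5PLUS), adults (ADULT) — differ along the axes the
pipeline is built to detect:

* **termination probability** decreases with age (0.45, 0.42, 0.40, 0.38):
  older speakers produce longer utterances, so the token-position
  rank–frequency slope ``log10(1-p)`` flattens from about -0.260 to -0.208
  and segmentation (length) entropy rises;
* **transition determinism** increases with age: the category chain is a
  mixture ``alpha * C + (1 - alpha) * U`` of a cyclic kernel ``C`` and the
  uniform kernel ``U``, with ``alpha`` = 0.30, 0.45, 0.60, 0.75, so
  adjacent-category mutual information increases across cohorts;
* **utterance-initial category distribution** is concentrated (identical
  across cohorts) while the chain mixes toward its uniform stationary
  distribution, so first- and second-order Jensen–Shannon divergence from
  the corpus baseline concentrates at the utterance boundary;
* **lexical diversity** starts highest in toddlers (largest base
  vocabulary per category: 250, 200, 160, 120) but declines along the
  utterance most steeply for them (diversity gradients -0.18, -0.10,
  -0.045, 0.0), so the cohort ordering of rarefied type–token ratios at
  the first position reverses by late positions.

These values are the package's fixed simulated study conditions; they are
deliberately not exposed as tuning knobs of the individual analyses.
"""

from __future__ import annotations

import numpy as np

from .synth import GeneratorConfig

__all__ = [
    "COHORT_LABELS",
    "TERMINATION_PROBS",
    "TRANSITION_DETERMINISM",
    "BASE_VOCAB",
    "DIVERSITY_GRADIENTS",
    "N_CATEGORIES",
    "INITIAL_DIST",
    "study_cohort_configs",
]

COHORT_LABELS = ("TO", "3PLUS", "5PLUS", "ADULT")
TERMINATION_PROBS = (0.45, 0.42, 0.40, 0.38)
TRANSITION_DETERMINISM = (0.30, 0.45, 0.60, 0.75)
BASE_VOCAB = (250, 200, 160, 120)
DIVERSITY_GRADIENTS = (-0.18, -0.10, -0.045, 0.0)
N_CATEGORIES = 6
#: concentrated utterance-initial category distribution, shared by cohorts
INITIAL_DIST = (0.45, 0.25, 0.10, 0.10, 0.05, 0.05)

_CATEGORIES = tuple(f"pos{i}" for i in range(N_CATEGORIES))


def _cohort_transition(alpha: float) -> tuple[tuple[float, ...], ...]:
    """alpha-mixture of a cyclic-shift kernel with the uniform kernel."""
    k = N_CATEGORIES
    T = np.full((k, k), (1.0 - alpha) / k)
    for i in range(k):
        T[i, (i + 1) % k] += alpha
    return tuple(tuple(float(x) for x in row) for row in T)


def study_cohort_configs(
    n_utterances: int = 60_000, master_seed: int = 0
) -> list[GeneratorConfig]:
    """Generator configs for the four reference cohorts.

    ``master_seed`` deterministically seeds the per-cohort streams;
    ``n_utterances`` scales the study down or up without changing its
    structure (the defaults give roughly 130-160k tokens per cohort).
    """
    configs = []
    for i, (label, p, alpha, vocab, grad) in enumerate(
        zip(COHORT_LABELS, TERMINATION_PROBS, TRANSITION_DETERMINISM,
            BASE_VOCAB, DIVERSITY_GRADIENTS)
    ):
        seed = int(
            np.random.SeedSequence([master_seed, i]).generate_state(1)[0] % (2**31)
        )
        configs.append(
            GeneratorConfig(
                n_utterances=n_utterances,
                termination_prob=p,
                transition_matrix=_cohort_transition(alpha),
                initial_dist=INITIAL_DIST,
                categories=_CATEGORIES,
                vocab_sizes={c: vocab for c in _CATEGORIES},
                zipf_exponent=1.0,
                diversity_gradient=grad,
                max_length=50,
                seed=seed,
                label=label,
                speaker_role="adult" if label == "ADULT" else "child",
            )
        )
    return configs
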
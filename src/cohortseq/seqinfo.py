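"""Position-wise information statistics of category sequences.

This module carries the sequence-level measures at the core of the analysis:

* rank–frequency fits: ordinary least squares of log10(frequency) on rank —
  a geometric distribution is diagnosed by an excellent linear fit, and for
  the token-position histogram the slope equals ``log10(1 - p)`` where ``p``
  is the utterance-termination probability;
* Shannon entropies of the utterance-length, token-position, and category
  distributions (bits);
* adjacent-category mutual information over within-utterance token pairs,
  aggregate or restricted to pairs starting at each position;
* first- and second-order Jensen–Shannon divergence of the position-specific
  category (or adjacent-pair) distribution from the corpus-wide baseline;
* lexical diversity (type–token ratio) per (position, category) cell, with
  an optional rarefied variant that removes the cell-size confound.

All information measures use base-2 logarithms and plug-in (maximum
likelihood) estimators; adjacent pairs never cross utterance boundaries.
Positional statistics omit positions with fewer than ``min_count``
observations (default 50): sparser positions are dominated by sampling
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .corpus import InsufficientDataError, TaggedCorpus

__all__ = [
    "RankFit",
    "EntropySummary",
    "CategoryDistribution",
    "PositionalProfile",
    "position_counts",
    "rank_frequency_fit",
    "shannon_entropy",
    "entropy_summary",
    "adjacent_mi",
    "positional_jsd",
    "lexical_diversity_profile",
    "category_probability_table",
    "positional_profile",
]

DEFAULT_MIN_COUNT = 50


@dataclass(frozen=True)
class RankFit:
    """OLS fit of log10(frequency) on rank."""

    slope: float
    intercept: float
    se_slope: float
    t_stat: float
    ci95: tuple[float, float]
    r2: float
    n: int
    df: int


@dataclass(frozen=True)
class EntropySummary:
    """Entropies (bits) of the positional and categorical distributions.

    ``length_entropy`` is the entropy of the utterance-length distribution —
    the segmentation-rate entropy; ``position_entropy`` is the entropy of the
    token-position distribution, reported alongside because the two are close
    relatives of the same geometric structure; ``sd_position`` is the
    standard deviation of token positions.
    """

    length_entropy: float
    position_entropy: float
    pos_entropy: float
    sd_position: float


@dataclass(frozen=True)
class CategoryDistribution:
    support: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-12):
            raise ValueError("probabilities must be non-negative and sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=list(self.support))


@dataclass(frozen=True)
class PositionalProfile:
    """Per-position MI, JSD (orders 1-2) and lexical diversity for one cohort."""

    cohort_label: str
    table: pd.DataFrame  # index: position; columns: mi, jsd1, jsd2, lexical_diversity, n_tokens


def _category_arrays(corpus: TaggedCorpus):
    """Flatten a corpus into (categories, surfaces, positions, lengths)."""
    cats: list[str] = []
    surfs: list[str] = []
    poss: list[int] = []
    lengths: list[int] = []
    for utt in corpus.utterances:
        lengths.append(len(utt))
        for tok in utt.tokens:
            cats.append(tok.category)
            surfs.append(tok.surface)
            poss.append(tok.position)
    return (
        np.asarray(cats, dtype=object),
        np.asarray(surfs, dtype=object),
        np.asarray(poss, dtype=np.int64),
        np.asarray(lengths, dtype=np.int64),
    )


def position_counts(corpus: TaggedCorpus) -> np.ndarray:
    """Tokens at each 1-based position; index i holds the count at position i+1.

    Monotone non-increasing by construction (a token at position i implies
    tokens at all earlier positions).
    """
    if not corpus.utterances:
        raise ValueError("corpus must be non-empty")
    lengths = np.asarray([len(u) for u in corpus.utterances])
    lmax = int(lengths.max())
    # count at position i = number of utterances with length >= i
    return np.array([(lengths >= i).sum() for i in range(1, lmax + 1)], dtype=np.int64)


def rank_frequency_fit(counts, labels=None, min_count: int = 1) -> RankFit:
    """OLS of log10(count) on rank over positive-count entries.

    Ranks are assigned by descending count; ties are broken stably by label
    (lexicographically when labels are given, by original order otherwise).
    ``min_count`` drops sparse cells before fitting (the same sparsity floor
    the positional statistics use): log-counts of near-empty cells are
    dominated by Poisson noise and would obscure the geometric diagnostic.
    """
    counts = np.asarray(counts, dtype=float)
    if labels is None:
        labels = np.arange(len(counts))
    labels = np.asarray(labels, dtype=object)
    pos = counts >= max(min_count, 1)
    counts, labels = counts[pos], labels[pos]
    if len(counts) < 3:
        raise InsufficientDataError(
            f"rank-frequency fit needs >= 3 positive counts, got {len(counts)}"
        )
    order = np.lexsort((labels, -counts))
    sorted_counts = counts[order]
    ranks = np.arange(1, len(sorted_counts) + 1, dtype=float)
    y = np.log10(sorted_counts)
    res = stats.linregress(ranks, y)
    n = len(ranks)
    df = n - 2
    tcrit = stats.t.ppf(0.975, df)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    t_stat = res.slope / res.stderr if res.stderr > 0 else float("inf")
    return RankFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        t_stat=float(t_stat),
        ci95=(float(ci[0]), float(ci[1])),
        r2=float(res.rvalue**2),
        n=n,
        df=df,
    )


def shannon_entropy(dist) -> float:
    """Shannon entropy in bits of a distribution (0 log 0 = 0).

    Accepts a :class:`CategoryDistribution`, a probability vector, or a
    vector of non-negative counts (normalized internally).
    """
    if isinstance(dist, CategoryDistribution):
        p = np.asarray(dist.probabilities, dtype=float)
    else:
        p = np.asarray(dist, dtype=float)
        total = p.sum()
        if total <= 0:
            raise ValueError("distribution must have positive mass")
        p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_summary(corpus: TaggedCorpus) -> EntropySummary:
    """Length, position, and category entropies (bits) plus position SD."""
    cats, _, poss, lengths = _category_arrays(corpus)
    length_counts = np.bincount(lengths)[1:]
    pos_counts = np.bincount(poss)[1:]
    _, cat_counts = np.unique(cats, return_counts=True)
    return EntropySummary(
        length_entropy=shannon_entropy(length_counts),
        position_entropy=shannon_entropy(pos_counts),
        pos_entropy=shannon_entropy(cat_counts),
        sd_position=float(poss.std()),
    )


def _pair_arrays(corpus: TaggedCorpus):
    """Within-utterance adjacent (category_i, category_{i+1}, position_i) pairs."""
    a: list[str] = []
    b: list[str] = []
    pos: list[int] = []
    for utt in corpus.utterances:
        cats = utt.categories
        for i in range(len(cats) - 1):
            a.append(cats[i])
            b.append(cats[i + 1])
            pos.append(i + 1)
    return (
        np.asarray(a, dtype=object),
        np.asarray(b, dtype=object),
        np.asarray(pos, dtype=np.int64),
    )


def _mi_from_pairs(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) from a pair sample; marginals from the same table."""
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    n = table.sum()
    joint = table / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    terms = np.zeros_like(joint)
    terms[mask] = joint[mask] * np.log2(joint[mask] / (pa @ pb)[mask])
    return float(terms.sum())


def adjacent_mi(
    corpus: TaggedCorpus,
    by_position: bool = False,
    min_count: int = DEFAULT_MIN_COUNT,
):
    """Mutual information (bits) between adjacent within-utterance categories.

    Aggregate MI uses the pooled pair table. With ``by_position`` a dict
    ``{position: mi}`` is returned, restricted to pairs whose first element
    sits at that position and to positions with at least ``min_count`` pairs.
    """
    a, b, pos = _pair_arrays(corpus)
    if len(a) == 0:
        raise InsufficientDataError(
            "no adjacent within-utterance pairs (all utterances have length 1)"
        )
    if not by_position:
        return _mi_from_pairs(a, b)
    out: dict[int, float] = {}
    for p in np.unique(pos):
        mask = pos == p
        if mask.sum() < min_count:
            continue
        out[int(p)] = _mi_from_pairs(a[mask], b[mask])
    return out


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence in bits (bounded by 1)."""
    m = 0.5 * (p + q)

    def _kl(x, y):
        mask = x > 0
        return float((x[mask] * np.log2(x[mask] / y[mask])).sum())

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def positional_jsd(
    corpus: TaggedCorpus,
    order: int = 1,
    min_count: int = DEFAULT_MIN_COUNT,
) -> dict[int, float]:
    """Per-position JSD (bits) from the corpus-wide baseline.

    Order 1 compares the category distribution at each position with the
    global category distribution; order 2 compares the joint distribution of
    (category at i, category at i+1) with the global adjacent-pair joint.
    Positions with fewer than ``min_count`` observations are omitted.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if order == 1:
        cats, _, poss, _ = _category_arrays(corpus)
        support = {c: i for i, c in enumerate(sorted(set(cats)))}
        codes = np.asarray([support[c] for c in cats])
        k = len(support)
        global_counts = np.bincount(codes, minlength=k).astype(float)
        q = global_counts / global_counts.sum()
        out: dict[int, float] = {}
        for p_idx in np.unique(poss):
            mask = poss == p_idx
            if mask.sum() < min_count:
                continue
            c = np.bincount(codes[mask], minlength=k).astype(float)
            out[int(p_idx)] = _jsd(c / c.sum(), q)
        return out
    a, b, pos = _pair_arrays(corpus)
    if len(a) == 0:
        raise InsufficientDataError("no adjacent pairs for second-order JSD")
    support = {c: i for i, c in enumerate(sorted(set(a) | set(b)))}
    k = len(support)
    codes = np.asarray([support[x] for x in a]) * k + np.asarray([support[x] for x in b])
    global_counts = np.bincount(codes, minlength=k * k).astype(float)
    q = global_counts / global_counts.sum()
    out = {}
    for p_idx in np.unique(pos):
        mask = pos == p_idx
        if mask.sum() < min_count:
            continue
        c = np.bincount(codes[mask], minlength=k * k).astype(float)
        out[int(p_idx)] = _jsd(c / c.sum(), q)
    return out


def _ttr(surfaces: np.ndarray, rarefy: int | None) -> float:
    """Plain TTR, or the expected rarefied TTR at sample size ``rarefy``.

    Rarefaction uses the exact hypergeometric expectation of the number of
    distinct types among ``m`` draws without replacement,
    ``E[S_m] = sum_w 1 - C(n - n_w, m) / C(n, m)``, so it is deterministic.
    """
    n = len(surfaces)
    _, type_counts = np.unique(surfaces, return_counts=True)
    if rarefy is None or n <= rarefy:
        return len(type_counts) / n
    m = rarefy
    lg = gammaln
    log_denom = lg(n - m + 1) - lg(n + 1)
    nw = type_counts.astype(float)
    with np.errstate(invalid="ignore"):
        log_miss = lg(n - nw + 1) - lg(n - nw - m + 1) + log_denom
    p_missing = np.where(n - nw >= m, np.exp(log_miss), 0.0)
    return float((1.0 - p_missing).sum()) / m


def lexical_diversity_profile(
    corpus: TaggedCorpus,
    max_position: int = 25,
    min_count: int = DEFAULT_MIN_COUNT,
    by_category: bool = True,
    rarefy: int | None = None,
) -> pd.DataFrame:
    """Type–token ratio per (position, category) cell, truncated at a position.

    Returns a tidy DataFrame (cohort, position, category, diversity,
    n_tokens). Cells with fewer than ``min_count`` tokens are omitted. With
    ``rarefy=m`` the reported value is the expected rarefied TTR at sample
    size ``m`` (exact hypergeometric expectation of the number of distinct
    types among ``m`` draws without replacement, so it is deterministic).
    Rarefaction removes the dependence of the plain TTR on cell size: cells
    at late positions are small under geometric lengths, which inflates
    their raw TTR.
    """
    if max_position < 1:
        raise ValueError("max_position must be >= 1")
    cats, surfs, poss, _ = _category_arrays(corpus)
    keep = poss <= max_position
    cats, surfs, poss = cats[keep], surfs[keep], poss[keep]
    rows = []
    if by_category:
        groups = pd.DataFrame({"category": cats, "surface": surfs, "position": poss})
        for (p, c), g in groups.groupby(["position", "category"], sort=True):
            if len(g) < min_count:
                continue
            rows.append(
                {
                    "cohort": corpus.cohort_label,
                    "position": int(p),
                    "category": c,
                    "diversity": _ttr(g["surface"].to_numpy(), rarefy),
                    "n_tokens": len(g),
                }
            )
    else:
        for p in np.unique(poss):
            mask = poss == p
            if mask.sum() < min_count:
                continue
            rows.append(
                {
                    "cohort": corpus.cohort_label,
                    "position": int(p),
                    "category": "_all_",
                    "diversity": _ttr(surfs[mask], rarefy),
                    "n_tokens": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows, columns=["cohort", "position", "category", "diversity", "n_tokens"])


def category_probability_table(corpus: TaggedCorpus) -> pd.DataFrame:
    """Empirical category distribution with descending-probability ranks."""
    cats, _, _, _ = _category_arrays(corpus)
    values, counts = np.unique(cats, return_counts=True)
    probs = counts / counts.sum()
    order = np.lexsort((values, -probs))
    df = pd.DataFrame(
        {
            "category": values[order],
            "probability": probs[order],
            "count": counts[order],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.set_index("category")


def positional_profile(
    corpus: TaggedCorpus,
    max_position: int = 25,
    min_count: int = DEFAULT_MIN_COUNT,
    rarefy: int | None = None,
) -> PositionalProfile:
    """Assemble per-position MI, JSD1, JSD2 and lexical diversity for a cohort."""
    mi = adjacent_mi(corpus, by_position=True, min_count=min_count)
    jsd1 = positional_jsd(corpus, order=1, min_count=min_count)
    jsd2 = positional_jsd(corpus, order=2, min_count=min_count)
    div = lexical_diversity_profile(
        corpus, max_position=max_position, min_count=min_count,
        by_category=False, rarefy=rarefy,
    ).set_index("position")
    cats, _, poss, _ = _category_arrays(corpus)
    n_per_pos = pd.Series(poss).value_counts().sort_index()
    positions = sorted(set(jsd1) | set(jsd2) | set(mi) | set(div.index))
    positions = [p for p in positions if p <= max_position]
    table = pd.DataFrame(
        {
            "mi": [mi.get(p, np.nan) for p in positions],
            "jsd1": [jsd1.get(p, np.nan) for p in positions],
            "jsd2": [jsd2.get(p, np.nan) for p in positions],
            "lexical_diversity": [
                div["diversity"].get(p, np.nan) for p in positions
            ],
            "n_tokens": [int(n_per_pos.get(p, 0)) for p in positions],
        },
        index=pd.Index(positions, name="position"),
    )
    return PositionalProfile(cohort_label=corpus.cohort_label, table=table)
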
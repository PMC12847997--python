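"""Representational-geometry comparisons between cohort embedding spaces.

Distance matrices (cosine, euclidean, ridge-regularized mahalanobis),
category-level distance summaries, difference matrices, Mantel permutation
tests, symmetric Procrustes alignment with a protest-style permutation test,
and exact t-SNE maps.

The Mantel statistic is the (Pearson or Spearman) correlation of the
upper-triangular off-diagonal entries; the null distribution permutes rows
and columns of the first matrix jointly, and the one-sided p-value is
``(1 + #{perm >= observed}) / (1 + n_permutations)``.

Procrustes follows the symmetric convention: both configurations are
centered and scaled to unit Frobenius norm, the optimal rotation comes from
an SVD, and the optimal scaling is the sum of singular values ``d``; then
``ss = 1 - d**2`` and the Procrustes correlation is ``R = d = sqrt(1-ss)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .corpus import CategoryLexicon
from .embed import EmbeddingSpace

__all__ = [
    "DistanceMatrix",
    "ProcrustesResult",
    "MantelResult",
    "TsneMap",
    "pairwise_distances",
    "category_distance_summary",
    "difference_matrix",
    "mantel_test",
    "procrustes_align",
    "tsne_embed",
    "classical_mds",
]

METRICS = ("cosine", "euclidean", "mahalanobis")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be |labels| x |labels|")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangular off-diagonal entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class ProcrustesResult:
    correlation: float
    ss: float
    per_point_residuals: dict[str, float]
    permutation_p: float | None
    n_permutations: int


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


@dataclass(frozen=True)
class TsneMap:
    labels: tuple[str, ...]
    coordinates: np.ndarray
    perplexity: float
    kl_divergence: float
    seed: int


def _symmetrize(d: np.ndarray) -> np.ndarray:
    d = (d + d.T) / 2.0
    d = np.maximum(d, 0.0)  # guard tiny negative float error from pdist
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distances(
    space: EmbeddingSpace,
    words: list[str],
    metric: str = "cosine",
    ridge: float | None = None,
    covariance: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise distances between word vectors under a named metric.

    For ``mahalanobis`` the covariance is the pooled covariance of the
    supplied word vectors with ridge term ``lambda = 1e-3 * trace(S)/dim``
    (overridable via ``ridge``), which keeps the metric defined when the
    word set is smaller than the embedding dimension; an explicit
    ``covariance`` matrix overrides the estimate entirely.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    X = space.subset(words)
    if metric == "mahalanobis":
        if covariance is not None:
            S = np.asarray(covariance, dtype=float)
        else:
            S = np.cov(X, rowvar=False)
            lam = ridge if ridge is not None else 1e-3 * np.trace(S) / X.shape[1]
            S = S + lam * np.eye(X.shape[1])
        try:
            VI = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular covariance; increase ridge") from exc
        d = squareform(pdist(X, metric="mahalanobis", VI=VI))
    else:
        d = squareform(pdist(X, metric=metric))
    return DistanceMatrix(labels=tuple(words), values=_symmetrize(d), metric=metric)


def category_distance_summary(
    dm: DistanceMatrix,
    lexicon: CategoryLexicon,
    space: EmbeddingSpace | None = None,
):
    """Within/between mean distances and centroid distances per category.

    Returns a pandas DataFrame with one row per category: ``within_mean``
    (mean over unordered same-category pairs, NaN when < 2 words present),
    ``between_mean`` (mean over pairs crossing the category boundary, NaN
    when no crossing pair exists), ``centroid_distance`` (distance of the
    category centroid to the grand centroid, computed in the vector space —
    requires ``space``; NaN otherwise), and ``n_words``.
    Lexicon words absent from the matrix labels are dropped.
    """
    import pandas as pd

    label_index = {w: i for i, w in enumerate(dm.labels)}
    grand = None
    if space is not None:
        present_all = [w for w in dm.labels if w in space]
        grand = space.subset(list(present_all)).mean(axis=0)

    rows = []
    for cat, words in lexicon.items():
        present = [w for w in words if w in label_index]
        idx = np.array([label_index[w] for w in present], dtype=int)
        other = np.array(
            [i for i in range(dm.n) if i not in set(idx.tolist())], dtype=int
        )
        if len(idx) >= 2:
            sub = dm.values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            within = float(sub[iu].mean())
        else:
            within = float("nan")
        if len(idx) >= 1 and len(other) >= 1:
            between = float(dm.values[np.ix_(idx, other)].mean())
        else:
            between = float("nan")
        centroid = float("nan")
        if space is not None and present:
            cvec = space.subset(present).mean(axis=0)
            centroid = float(np.linalg.norm(cvec - grand))
        rows.append(
            {
                "category": cat,
                "n_words": len(present),
                "within_mean": within,
                "between_mean": between,
                "centroid_distance": centroid,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def difference_matrix(dm1: DistanceMatrix, dm2: DistanceMatrix) -> np.ndarray:
    """Element-wise dm1 - dm2 after aligning dm2 to dm1's label order."""
    if set(dm1.labels) != set(dm2.labels):
        diff = sorted(set(dm1.labels) ^ set(dm2.labels))
        raise ValueError(f"label sets differ; symmetric difference: {diff}")
    if dm1.labels == dm2.labels:
        v2 = dm2.values
    else:
        order = [dm2.labels.index(w) for w in dm1.labels]
        v2 = dm2.values[np.ix_(order, order)]
    return dm1.values - v2


def _mantel_stat(v1: np.ndarray, v2: np.ndarray, method: str) -> float:
    if method == "spearman":
        v1 = stats.rankdata(v1)
        v2 = stats.rankdata(v2)
    s1, s2 = v1.std(), v2.std()
    if s1 == 0 or s2 == 0:
        raise ValueError("constant upper triangle; Mantel correlation undefined")
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel_test(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    With ``exhaustive`` all n! row/column permutations are enumerated (small
    matrices only) and ``p = #{perm stat >= observed} / n!`` — the identity
    permutation makes p strictly positive.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    if set(dm1.labels) != set(dm2.labels):
        raise ValueError("Mantel test requires identical label sets")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if dm1.labels != dm2.labels:
        order = [dm2.labels.index(w) for w in dm1.labels]
        dm2 = DistanceMatrix(
            labels=dm1.labels, values=dm2.values[np.ix_(order, order)], metric=dm2.metric
        )
    iu = np.triu_indices(dm1.n, k=1)
    v2 = dm2.values[iu]
    observed = _mantel_stat(dm1.values[iu], v2, method)
    if exhaustive:
        from itertools import permutations as iter_permutations
        from math import factorial

        if dm1.n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        n_ge = 0
        for perm in iter_permutations(range(dm1.n)):
            v1p = dm1.values[np.ix_(perm, perm)][iu]
            if _mantel_stat(v1p, v2, method) >= observed:
                n_ge += 1
        total = factorial(dm1.n)
        return MantelResult(
            statistic=observed, p_value=n_ge / total,
            n_permutations=total, method=method,
        )
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(dm1.n)
        v1p = dm1.values[np.ix_(perm, perm)][iu]
        if _mantel_stat(v1p, v2, method) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return MantelResult(
        statistic=observed, p_value=p, n_permutations=n_permutations, method=method
    )


def _pad_columns(X: np.ndarray, width: int) -> np.ndarray:
    if X.shape[1] == width:
        return X
    out = np.zeros((X.shape[0], width))
    out[:, : X.shape[1]] = X
    return out


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    norm = np.sqrt((Xc**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration: all points identical")
    return Xc / norm


def _procrustes_ss(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Symmetric Procrustes residual ss and the aligned copy of Y."""
    U, d, Vt = np.linalg.svd(X.T @ Y)
    rot = Vt.T @ U.T
    scale = d.sum()
    Y_aligned = scale * (Y @ rot)
    ss = float(((X - Y_aligned) ** 2).sum())
    return ss, Y_aligned


def procrustes_align(
    X: np.ndarray,
    Y: np.ndarray,
    labels: list[str] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes alignment of two point configurations.

    Rows correspond across configurations; column counts may differ (the
    narrower configuration is zero-padded). Returns the Procrustes
    correlation ``R = sqrt(1 - ss)``, the normalized residual sum of squares,
    per-point residuals localizing misfit, and — when ``n_permutations > 0``
    — a protest-style p-value obtained by permuting rows of ``Y``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if X.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    width = max(X.shape[1], Y.shape[1])
    Xs = _standardize(_pad_columns(X, width))
    Ys = _standardize(_pad_columns(Y, width))
    ss, Y_aligned = _procrustes_ss(Xs, Ys)
    ss = min(max(ss, 0.0), 1.0)
    corr = float(np.sqrt(max(0.0, 1.0 - ss)))
    resid = np.sqrt(((Xs - Y_aligned) ** 2).sum(axis=1))
    names = labels if labels is not None else [str(i) for i in range(X.shape[0])]
    if len(names) != X.shape[0]:
        raise ValueError("labels length must match number of rows")

    p: float | None = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        n_ge = 0
        for _ in range(n_permutations):
            perm = rng.permutation(Ys.shape[0])
            ss_p, _ = _procrustes_ss(Xs, Ys[perm])
            corr_p = np.sqrt(max(0.0, 1.0 - ss_p))
            if corr_p >= corr:
                n_ge += 1
        p = (1 + n_ge) / (1 + n_permutations)
    return ProcrustesResult(
        correlation=corr,
        ss=ss,
        per_point_residuals={n: float(r) for n, r in zip(names, resid)},
        permutation_p=p,
        n_permutations=n_permutations,
    )


def classical_mds(dm: DistanceMatrix, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: a configuration matrix from a distance matrix.

    Used to feed distance matrices into Procrustes comparisons.
    """
    D2 = dm.values**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def tsne_embed(
    space: EmbeddingSpace,
    words: list[str],
    perplexity: float = 20.0,
    seed: int = 0,
) -> TsneMap:
    """Exact t-SNE of the word vectors to 2-D (perplexity default 20)."""
    if len(words) <= 3 * perplexity:
        raise ValueError(
            f"need |words| > 3*perplexity; got {len(words)} words, "
            f"perplexity {perplexity}"
        )
    from sklearn.manifold import TSNE

    X = space.subset(words)
    tsne = TSNE(
        n_components=2,
        method="exact",
        perplexity=perplexity,
        early_exaggeration=12.0,
        max_iter=1000,
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return TsneMap(
        labels=tuple(words),
        coordinates=coords,
        perplexity=perplexity,
        kl_divergence=float(tsne.kl_divergence_),
        seed=seed,
    )
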
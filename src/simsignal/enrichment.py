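"""Pharmacological-class enrichment of a similarity matrix.

Given the top-N most similar drug pairs of a matrix, how many pairs fall
within one pharmacological class? Under a random draw of N pairs from the
M = n(n-1)/2 unordered pairs of which K are same-class, the urn-model
expectation is N*K/M. Significance is assessed two ways: by permuting the
class labels over drugs (class sizes and matrix fixed, same top-N pair
set, add-one-corrected tail count) and by the hypergeometric tail as an
analytic cross-check. Both condition on the number of same-class pairs in
the matrix; the permutation null additionally preserves which drugs are
linked by top pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import hypergeom

from .datamodel import ValidationError
from .scoring import SimilarityMatrix


@dataclass(frozen=True)
class EnrichmentResult:
    measure: str
    top_n: int
    same_class_observed: int
    same_class_pairs_total: int
    total_pairs: int
    expected_random: float
    p_value_perm: float
    p_value_hypergeom: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        assert self.expected_random == self.top_n * self.same_class_pairs_total / self.total_pairs

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "top_n": self.top_n,
            "same_class_observed": self.same_class_observed,
            "same_class_pairs_total": self.same_class_pairs_total,
            "total_pairs": self.total_pairs,
            "expected_random": self.expected_random,
            "p_value_perm": self.p_value_perm,
            "p_value_hypergeom": self.p_value_hypergeom,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def top_pairs(matrix: SimilarityMatrix, n: int) -> list[tuple[str, str, float]]:
    """The n highest-scoring unordered off-diagonal pairs.

    Pairs are ordered by (score desc, first id asc, second id asc) with each
    pair's ids sorted lexicographically, and the list is cut at exactly n —
    deterministic even with tied scores at the boundary.
    """
    total = matrix.n_pairs
    if not (1 <= n <= total):
        raise ValidationError(f"n must be in [1, {total}], got {n}")
    ids = matrix.drug_ids
    iu, ju = np.triu_indices(matrix.n_drugs, k=1)
    pairs = []
    for i, j in zip(iu, ju):
        a, b = sorted((ids[i], ids[j]))
        pairs.append((a, b, float(matrix.scores[i, j])))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs[:n]


def _validate_classes(matrix: SimilarityMatrix, classes: Mapping[str, str]) -> None:
    missing = [d for d in matrix.drug_ids if d not in classes or not classes[d]]
    if missing:
        raise ValidationError(f"drugs lack a pharmacological class label: {missing}")


def enrichment(
    matrix: SimilarityMatrix,
    classes: Mapping[str, str],
    n: int = 50,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Same-class enrichment of the top-n most similar pairs.

    The permutation p-value shuffles class labels over drugs (preserving
    class sizes and the matrix), recomputes the same-class count within the
    *same* top-n pair set, and reports the add-one-corrected tail
    probability (x+1)/(N+1) of observing the actual count or more.
    """
    _validate_classes(matrix, classes)
    ids = matrix.drug_ids
    labels = np.array([classes[d] for d in ids])
    idx = {d: i for i, d in enumerate(ids)}
    top = top_pairs(matrix, n)
    ti = np.array([idx[a] for a, _, _ in top])
    tj = np.array([idx[b] for _, b, _ in top])
    observed = int(np.sum(labels[ti] == labels[tj]))

    iu, ju = np.triu_indices(len(ids), k=1)
    total_pairs = len(iu)
    same_total = int(np.sum(labels[iu] == labels[ju]))
    expected = n * same_total / total_pairs

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if int(np.sum(perm[ti] == perm[tj])) >= observed:
            hits += 1
    p_perm = (hits + 1) / (n_permutations + 1)
    # analytic cross-check: draw n pairs from total_pairs of which same_total
    # are same-class; tail P(X >= observed)
    p_hyper = float(hypergeom.sf(observed - 1, total_pairs, same_total, n))
    return EnrichmentResult(
        measure=matrix.measure.value,
        top_n=n,
        same_class_observed=observed,
        same_class_pairs_total=same_total,
        total_pairs=total_pairs,
        expected_random=expected,
        p_value_perm=p_perm,
        p_value_hypergeom=p_hyper,
        n_permutations=n_permutations,
        seed=seed,
    )


DIAGONAL = "diagonal"
SAME_CLASS_TOP = "same_class_top"
SAME_CLASS_NOT_TOP = "same_class_not_top"
DIFF_CLASS_TOP = "diff_class_top"
OTHER = "other"


def matrix_plot_data(matrix: SimilarityMatrix, classes: Mapping[str, str], n: int):
    """Categorize every matrix cell for the class-overlay heatmap.

    Returns a long-form DataFrame with columns ``drug_i, drug_j, category,
    score`` covering all n^2 ordered cells; tags are symmetric.
    """
    import pandas as pd

    _validate_classes(matrix, classes)
    ids = matrix.drug_ids
    top = {(a, b) for a, b, _ in top_pairs(matrix, n)}
    rows = []
    for i, di in enumerate(ids):
        for j, dj in enumerate(ids):
            if i == j:
                cat = DIAGONAL
            else:
                key = tuple(sorted((di, dj)))
                same = classes[di] == classes[dj]
                if key in top:
                    cat = SAME_CLASS_TOP if same else DIFF_CLASS_TOP
                else:
                    cat = SAME_CLASS_NOT_TOP if same else OTHER
            rows.append((di, dj, cat, float(matrix.scores[i, j])))
    return pd.DataFrame(rows, columns=["drug_i", "drug_j", "category", "score"])


def plot_class_heatmap(matrix: SimilarityMatrix, classes: Mapping[str, str], n: int, path) -> None:
    """Heatmap of cell categories, drugs grouped by pharmacological class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    df = matrix_plot_data(matrix, classes, n)
    order = sorted(matrix.drug_ids, key=lambda d: (classes[d], d))
    pos = {d: i for i, d in enumerate(order)}
    codes = {DIAGONAL: 0, OTHER: 1, SAME_CLASS_NOT_TOP: 2, SAME_CLASS_TOP: 3, DIFF_CLASS_TOP: 4}
    img = np.zeros((len(order), len(order)))
    for r in df.itertuples(index=False):
        img[pos[r.drug_i], pos[r.drug_j]] = codes[r.category]
    cmap = ListedColormap(["#404040", "#f2f2f2", "#b08968", "#d62728", "#1f77b4"])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, cmap=cmap, vmin=0, vmax=4, interpolation="nearest")
    ax.set_title(f"{matrix.measure.value}: top {n} pairs vs pharmacological class")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
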
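"""Population-structure descriptors: dosage PCA and pairwise F_ST.

PCA scores come from the eigendecomposition of the additive genomic
relationship matrix (scores = eigenvectors scaled by the square root of the
eigenvalues); the first three components feed the variance-explained
regression of the association module.

Pairwise differentiation between labelled groups uses an allele-frequency
Weir-Cockerham-type estimator with ploidy-4 allele counts (each tetraploid
individual contributes four allele observations), combined across markers as
a ratio of sums.  Groups below a minimum size are excluded, as is usual for
frequency-based F_ST on small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import PLOIDY, DosageMatrix
from .kinship import additive_G

__all__ = ["PCAResult", "pca_dosage", "fst_pairwise"]


@dataclass
class PCAResult:
    scores: np.ndarray  # individuals x components
    explained: np.ndarray  # fractions, non-increasing
    individuals: list[str]


def pca_dosage(dosages: DosageMatrix, n_components: int = 10) -> PCAResult:
    """Principal components of the additive relationship matrix."""
    G = additive_G(dosages)  # raises on a monomorphic panel
    w, U = np.linalg.eigh(G.values)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    U = U[:, order]
    k = min(n_components, len(w))
    scores = U[:, :k] * np.sqrt(w[:k])
    total = w.sum()
    explained = w[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(scores, explained, list(dosages.individuals))


def _wc_components(d1: np.ndarray, d2: np.ndarray):
    """Per-marker Weir-Cockerham numerator/denominator for two groups.

    ``d1``/``d2`` are dosage sub-matrices; allele counts are 4x the group
    sizes, allele frequencies the mean dosage / 4.
    """
    n1 = PLOIDY * d1.shape[0]
    n2 = PLOIDY * d2.shape[0]
    p1 = d1.mean(axis=0) / PLOIDY
    p2 = d2.mean(axis=0) / PLOIDY
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r)
    return a, a + b


def fst_pairwise(
    dosages: DosageMatrix,
    groups: np.ndarray,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Pairwise F_ST between all eligible groups (ratio-of-sums over markers).

    Returns a table with group pair, sizes, the clamped F_ST in [0, 1] and
    the raw (unclamped) estimate.
    """
    if not dosages.is_complete:
        raise ValueError("F_ST requires complete dosages")
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    small = labels[counts < min_group_size]
    if small.size:
        warnings.warn(
            f"excluding groups below min size {min_group_size}: {list(small)}"
        )
    keep = [l for l, c in zip(labels, counts) if c >= min_group_size]
    if len(keep) < 2:
        raise ValueError("fewer than two groups meet the minimum size")
    X = dosages.dosages
    rows = []
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            gi, gj = keep[i], keep[j]
            num, den = _wc_components(X[groups == gi], X[groups == gj])
            ok = den > 0
            raw = float(num[ok].sum() / den[ok].sum())
            rows.append(
                (str(gi), str(gj), int((groups == gi).sum()),
                 int((groups == gj).sum()), float(np.clip(raw, 0.0, 1.0)), raw)
            )
    return pd.DataFrame(
        rows, columns=["group1", "group2", "n1", "n2", "fst", "fst_raw"]
    )
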
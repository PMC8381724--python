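"""Autotetraploid genomic relationship matrices and the Gaussian RKHS kernel.

Five constructions over a complete dosage matrix X (n individuals x m markers,
entries 0..4):

* additive        G_A = ZZ' / sum_j 4 p_j q_j, with Z = X - 4P (VanRaden
                  method-1 normalisation at ploidy 4)
* digenic dominance  per-marker quadratic covariate d(x) = C(x,2) - 3px + 6p^2,
                  HWE-centred, normalised by the exact Binomial(4,p) variance
* A x A epistasis  Hadamard square of G_A
* full tetraploid  one-hot indicators over the five dosage classes per marker,
                  MM' rescaled to unit mean diagonal
* rkhs            K = exp(-theta * D), D the squared Euclidean dosage distance
                  scaled by its mean off-diagonal so theta is dimension-free

Allele frequencies default to the sample frequencies of the input but may be
fixed externally (e.g., to make subset-then-build commute with build-then-
subset).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .dosage import PLOIDY, N_CLASSES, DosageMatrix

__all__ = [
    "KinshipMatrix",
    "additive_G",
    "dominance_G",
    "epistasis_G",
    "full_tetraploid_G",
    "rkhs_kernel",
    "dominance_covariates",
]


@dataclass
class KinshipMatrix:
    """Individual x individual relationship matrix tagged with its flavor."""

    individuals: list[str]
    values: np.ndarray
    flavor: str
    n_markers: int
    theta: float | None = None

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.shape[0] != V.shape[1] or V.shape[0] != len(self.individuals):
            raise ValueError("kinship matrix must be square and match ids")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (V + V.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.individuals)

    def psd_clipped(self, rel_tol: float = 1e-8) -> "KinshipMatrix":
        """Clip eigenvalues below -rel_tol*lambda_max to zero (with a warning)."""
        w, U = np.linalg.eigh(self.values)
        floor = -rel_tol * max(w.max(), 1.0)
        if w.min() < floor:
            warnings.warn(
                f"{self.flavor} kinship has eigenvalues down to {w.min():.3g}; "
                "clipping to PSD"
            )
            w = np.clip(w, 0.0, None)
            return KinshipMatrix(
                self.individuals, (U * w) @ U.T, self.flavor, self.n_markers, self.theta
            )
        return self

    def align(self, ids: list[str]) -> "KinshipMatrix":
        """Reorder/subset to the given individual ids."""
        pos = {g: i for i, g in enumerate(self.individuals)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"individuals absent from kinship: {missing[:5]}")
        idx = np.array([pos[g] for g in ids])
        return KinshipMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.flavor, self.n_markers, self.theta
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.individuals, columns=self.individuals).to_csv(
            path, sep="\t", index_label="individual"
        )


def _complete_X(dosages: DosageMatrix) -> np.ndarray:
    if not dosages.is_complete:
        raise ValueError("kinship construction requires a complete (imputed) dosage matrix")
    return dosages.dosages


def _freqs(X: np.ndarray, allele_freq: np.ndarray | None) -> np.ndarray:
    p = X.mean(axis=0) / PLOIDY if allele_freq is None else np.asarray(allele_freq, float)
    if p.shape != (X.shape[1],):
        raise ValueError("allele_freq length must equal the number of markers")
    return p


def additive_G(
    dosages: DosageMatrix, allele_freq: np.ndarray | None = None
) -> KinshipMatrix:
    """Additive relationship: centre dosages by 4p, normalise by sum 4 p q."""
    X = _complete_X(dosages)
    p = _freqs(X, allele_freq)
    denom = float(np.sum(PLOIDY * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: additive normaliser is zero")
    Z = X - PLOIDY * p
    G = (Z @ Z.T) / denom
    return KinshipMatrix(list(dosages.individuals), G, "additive", X.shape[1])


def dominance_covariates(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Digenic-dominance covariate d(x) = C(x,2) - 3 p x + 6 p^2 per marker.

    Under Hardy-Weinberg dosages x ~ Binomial(4, p) this quadratic has mean
    zero and is orthogonal to the (linear) additive covariate.
    """
    return X * (X - 1) / 2.0 - 3.0 * p * X + 6.0 * p**2


def _binom4_pmf(p: np.ndarray) -> np.ndarray:
    """(5, m) Binomial(4, p) class weights."""
    from scipy.stats import binom

    return binom.pmf(np.arange(N_CLASSES)[:, None], PLOIDY, p[None, :])


def dominance_G(
    dosages: DosageMatrix, allele_freq: np.ndarray | None = None
) -> KinshipMatrix:
    """Digenic-dominance relationship, normalised by the exact HWE variance of d."""
    X = _complete_X(dosages)
    p = _freqs(X, allele_freq)
    D = dominance_covariates(X, p)
    # exact Var[d(x)] under x ~ Binomial(4, p_j), enumerated over the 5 classes
    dvals = dominance_covariates(
        np.tile(np.arange(N_CLASSES, dtype=float)[:, None], (1, X.shape[1])), p
    )
    w = _binom4_pmf(p)
    mean_d = (w * dvals).sum(axis=0)
    var_d = (w * (dvals - mean_d) ** 2).sum(axis=0)
    denom = float(var_d.sum())
    if denom <= 0:
        raise ValueError("all markers monomorphic: dominance normaliser is zero")
    G = (D @ D.T) / denom
    return KinshipMatrix(list(dosages.individuals), G, "dominance_digenic", X.shape[1])


def epistasis_G(G_A: KinshipMatrix) -> KinshipMatrix:
    """Additive-by-additive epistatic relationship: the Hadamard square of G_A."""
    if G_A.flavor != "additive":
        raise ValueError("epistasis_G expects an additive kinship as input")
    return KinshipMatrix(
        list(G_A.individuals), G_A.values * G_A.values, "epistatic_AxA", G_A.n_markers
    )


def full_tetraploid_G(dosages: DosageMatrix) -> KinshipMatrix:
    """Full-tetraploid relationship from one-hot dosage-class indicators.

    Each marker contributes five indicator columns (one per genotype class);
    G_F = MM' rescaled so the mean diagonal equals 1.  Identity-by-class
    sharing captures additive and non-additive variation jointly.
    """
    X = _complete_X(dosages).astype(int)
    n, m = X.shape
    # MM' without materialising the n x 5m indicator matrix: entry (i,j) is the
    # number of markers where i and j fall in the same dosage class
    G = np.zeros((n, n))
    for k in range(N_CLASSES):
        Ik = (X == k).astype(float)
        G += Ik @ Ik.T
    scale = np.mean(np.diag(G))
    if scale <= 0:
        raise ValueError("empty dosage matrix")
    return KinshipMatrix(list(dosages.individuals), G / scale, "full_tetraploid", m)


def squared_distance(X: np.ndarray, normalise: bool = True) -> np.ndarray:
    """Squared Euclidean distance between dosage rows, optionally scaled by its
    mean off-diagonal value (making the RKHS bandwidth dimension-free)."""
    sq = np.sum(X**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    if normalise:
        n = D.shape[0]
        off = D.sum() / (n * (n - 1)) if n > 1 else 1.0
        if off > 0:
            D = D / off
    return D


def rkhs_kernel(dosages: DosageMatrix, theta: float) -> KinshipMatrix:
    """Gaussian kernel K = exp(-theta * D) over scaled squared dosage distances."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    X = _complete_X(dosages)
    K = np.exp(-theta * squared_distance(X))
    return KinshipMatrix(
        list(dosages.individuals), K, "rkhs", X.shape[1], theta=float(theta)
    )
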
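"""Mixed-model association scans under tetraploid gene-action codings.

Each marker is tested in y = mu + x beta + g + e where the polygenic term g
has covariance G_A sigma_g^2 (the additive relationship, shared across
chromosomes).  Variance components are estimated once in the null model and
reused per marker (the P3D shortcut); each marker's effect is then a
generalised-least-squares estimate with a Wald test.

Markers can be coded for five gene-action hypotheses (dosage x in 0..4):

    additive    0 1 2 3 4
    1-dom-alt   0 4 4 4 4   (simplex dominant, alternative allele)
    2-dom-alt   0 0 4 4 4   (duplex dominant, alternative allele)
    1-dom-ref   4 4 4 4 0   (simplex dominant, reference allele)
    2-dom-ref   4 4 4 0 0   (duplex dominant, reference allele)

The genome-wide significance threshold divides alpha by the Li-Ji effective
number of independent tests, computed from the eigenvalues of the marker
correlation matrix.  A nested linear regression on significant markers plus
the first principal components quantifies the phenotypic variance explained
by each gene-action class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import DosageMatrix
from .gp_models import reml_1kernel
from .kinship import KinshipMatrix

__all__ = [
    "CODINGS",
    "CodedMarkers",
    "GWASScan",
    "code_markers",
    "scan",
    "li_ji_meff",
    "threshold",
    "variance_explained",
    "inflation",
]

CODINGS = ("additive", "1-dom-alt", "1-dom-ref", "2-dom-alt", "2-dom-ref")


@dataclass
class CodedMarkers:
    coding: str
    values: np.ndarray
    markers: pd.DataFrame


@dataclass
class GWASScan:
    table: pd.DataFrame  # marker, chrom, pos, coding, beta, se, score, significant
    coding: str
    threshold: float

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()


def code_markers(dosages: DosageMatrix, coding: str) -> CodedMarkers:
    """Recode dosages under one gene-action hypothesis (see module docstring)."""
    if coding not in CODINGS:
        raise ValueError(f"coding must be one of {CODINGS}")
    X = dosages.dosages
    if np.isnan(X).any():
        raise ValueError("coding requires complete dosages")
    if coding == "additive":
        V = X.copy()
    elif coding == "1-dom-alt":
        V = np.where(X >= 1, 4.0, 0.0)
    elif coding == "2-dom-alt":
        V = np.where(X >= 2, 4.0, 0.0)
    elif coding == "1-dom-ref":
        V = np.where(X <= 3, 4.0, 0.0)  # >= 1 reference copy
    else:  # 2-dom-ref
        V = np.where(X <= 2, 4.0, 0.0)  # >= 2 reference copies
    return CodedMarkers(coding, V, dosages.markers.copy())


def scan(
    y: np.ndarray,
    coded: CodedMarkers,
    G_A: KinshipMatrix,
    alpha: float = 0.05,
    meff: float | None = None,
) -> GWASScan:
    """P3D mixed-model scan: one null REML fit, per-marker GLS Wald tests.

    Monomorphic coded columns are skipped (NaN score, flagged).  The
    significance threshold is -log10(alpha / meff); when ``meff`` is not
    supplied it is computed from the additive-coded panel if available,
    else from the scanned panel.
    """
    y = np.asarray(y, float)
    n = len(y)
    null = reml_1kernel(y, G_A.values)
    sig2g, sig2e = max(null["sig2g"], 0.0), max(null["sig2e"], 1e-12)
    w, U = np.linalg.eigh(G_A.values)
    w = np.clip(w, 0.0, None)
    weights = 1.0 / (sig2g * w + sig2e)
    sw = np.sqrt(weights)
    yt = (U.T @ y) * sw
    ones = (U.T @ np.ones(n)) * sw
    Xt = (U.T @ coded.values) * sw[:, None]

    mono = coded.values.std(axis=0) == 0
    a = float(ones @ ones)
    b = ones @ Xt
    c = np.einsum("ij,ij->j", Xt, Xt)
    r1 = float(ones @ yt)
    r2 = Xt.T @ yt
    det = a * c - b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a * r2 - b * r1) / det
        se = np.sqrt(np.where(det > 0, a / det, np.nan))
        tstat = beta / se
    df = n - 2
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    score = -np.log10(np.clip(pvals, 1e-300, None))
    beta[mono] = np.nan
    se[mono] = np.nan
    score[mono] = np.nan

    if meff is None:
        keep = ~mono
        meff = li_ji_meff(coded.values[:, keep]) if keep.sum() >= 2 else 1.0
    thr = threshold(alpha, meff)
    table = coded.markers.copy()
    table["coding"] = coded.coding
    table["beta"] = beta
    table["se"] = se
    table["score"] = score
    table["significant"] = np.where(np.isnan(score), False, score >= thr)
    return GWASScan(table, coded.coding, thr)


def li_ji_meff(markers: np.ndarray) -> float:
    """Li-Ji effective number of independent tests.

    Eigenvalues lambda of the marker-marker correlation matrix (obtained from
    the n x n cross-product, so only the nonzero spectrum is computed);
    Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ].
    """
    M = np.asarray(markers, float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a 2-D panel with >= 2 markers")
    sd = M.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"excluding {(sd == 0).sum()} zero-variance markers from Meff")
        M = M[:, sd > 0]
        sd = sd[sd > 0]
    n = M.shape[0]
    Z = (M - M.mean(axis=0)) / sd
    # the m x m correlation matrix R = Z'Z / n shares its nonzero spectrum
    # with the (cheaper) n x n matrix Z Z' / n
    lam = np.clip(np.linalg.eigvalsh(Z @ Z.T / n), 0.0, None)
    lam[lam < 1e-9] = 0.0
    # snap near-integer eigenvalues: floor() is discontinuous and numerical
    # noise at, e.g., lambda = 2 - 1e-12 would otherwise inflate Meff by ~1
    near = np.abs(lam - np.round(lam)) < 1e-8
    lam[near] = np.round(lam[near])
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def threshold(alpha: float, meff: float) -> float:
    """Genome-wide -log10 p threshold: -log10(alpha / Meff), at 2 dp."""
    if not 0.0 < alpha < 1.0 or meff < 1:
        raise ValueError("need alpha in (0,1) and meff >= 1")
    return round(float(-np.log10(alpha / meff)), 2)


def inflation(scores: np.ndarray) -> dict:
    """QQ diagnostics for a scan: genomic-control lambda and the QQ slope.

    lambda_GC is the median observed chi-square statistic over its null
    median; the slope regresses observed on expected -log10 p through the
    origin over the bulk (smallest 95%) of the distribution.
    """
    s = np.asarray(scores, float)
    s = s[np.isfinite(s)]
    p = 10.0 ** (-s)
    chi = stats.chi2.isf(p, df=1)
    lam_gc = float(np.median(chi) / stats.chi2.isf(0.5, df=1))
    obs = np.sort(s)
    m = len(s)
    exp = -np.log10((m - np.arange(m)) / (m + 1.0))
    bulk = exp <= np.quantile(exp, 0.95)
    slope = float(np.sum(obs[bulk] * exp[bulk]) / np.sum(exp[bulk] ** 2))
    return {"lambda_gc": lam_gc, "qq_slope": slope}


def plot_manhattan(result: GWASScan, path) -> None:
    """Manhattan plot of one scan (chromosomes alternate shading)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table.dropna(subset=["score"]).reset_index(drop=True)
    chroms = list(dict.fromkeys(t["chrom"]))
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for ci, c in enumerate(chroms):
        sub = t[t["chrom"] == c]
        ax.scatter(offset + np.arange(len(sub)), sub["score"], s=6,
                   color="steelblue" if ci % 2 == 0 else "darkorange")
        offset += len(sub)
    ax.axhline(result.threshold, color="red", lw=1)
    ax.set_xlabel("marker index (by chromosome)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{result.coding} scan")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_qq(result: GWASScan, path) -> None:
    """Observed vs expected -log10 p for inflation assessment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = np.sort(result.scores[np.isfinite(result.scores)])
    m = len(s)
    exp = -np.log10((m - np.arange(m)) / (m + 1.0))
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.plot(exp, s, ".", ms=3)
    lim = max(exp.max(), s.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected")
    ax.set_ylabel("observed")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def variance_explained(
    y: np.ndarray,
    pc_scores: np.ndarray,
    marker_sets: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Nested OLS R^2: PCs only; PCs + additive markers; + each dominance set.

    ``marker_sets`` maps coding name to the matrix of that coding's
    significant marker columns ('additive' enters every nested design).
    Aliased columns are dropped (logged); a design with p >= n raises with
    advice to prune markers.
    """
    y = np.asarray(y, float)
    n = len(y)
    pcs = np.atleast_2d(np.asarray(pc_scores, float))
    if pcs.shape[0] != n:
        pcs = pcs.T

    def r2(cols: list[np.ndarray]) -> float:
        X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
        if X.shape[1] >= n:
            raise ValueError(
                "design has as many columns as observations; prune the marker set"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(f"design has {X.shape[1] - rank} aliased column(s); dropped")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

    add = marker_sets.get("additive")
    rows = [("3 PCs only", r2([pcs]))]
    base = [pcs] + ([add] if add is not None and add.size else [])
    rows.append(("3 PCs + Add markers", r2(base)))
    for coding, cols in marker_sets.items():
        if coding == "additive":
            continue
        extra = base + ([cols] if cols is not None and cols.size else [])
        rows.append((f"3 PCs + Add + {coding}", r2(extra)))
    return pd.DataFrame(rows, columns=["design", "r2"])
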
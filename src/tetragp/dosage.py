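"""Allele-dosage calling for autotetraploids from sequence read counts.

A biallelic GBS marker in a tetraploid individual carries 0-4 copies of the
alternative allele (genotype classes AAAA..BBBB).  Given reference/alternative
read counts, the posterior probability of each dosage class is computed from a
binomial read-sampling model whose success probability is the class allele
fraction perturbed by the sequencing-error rate::

    f'(k) = (k/4) (1 - e) + (1 - k/4) e,   k in {0,..,4}

    P(k | ref, alt)  propto  prior_k * Binom(alt; ref + alt, f'(k))

Cells whose maximum posterior falls below a probability threshold are marked
missing; markers are then filtered on mean depth, minor allele frequency and
missingness, and remaining gaps imputed (mode by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

PLOIDY = 4
N_CLASSES = PLOIDY + 1
CLASS_NAMES = ("AAAA", "AAAB", "AABB", "ABBB", "BBBB")

__all__ = [
    "ReadCountSet",
    "DosageMatrix",
    "genotype_posterior",
    "posterior_array",
    "call_dosages",
    "filter_markers",
    "impute",
    "read_counts_tsv",
    "read_counts_vcf",
    "write_counts_vcf",
]


@dataclass
class ReadCountSet:
    """Per-individual, per-marker reference/alternative allele read depths.

    ``ref`` and ``alt`` are (n_individuals, n_markers) non-negative integer
    arrays; ``markers`` holds marker id, chromosome and 1-based position.
    """

    individuals: list[str]
    markers: pd.DataFrame  # columns: marker, chrom, pos
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        n, m = self.ref.shape
        if self.alt.shape != (n, m):
            raise ValueError("ref and alt count matrices differ in shape")
        if n != len(self.individuals) or m != len(self.markers):
            raise ValueError("count matrix shape does not match id lists")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class DosageMatrix:
    """Alternative-allele dosages (0-4) with a missingness mask.

    ``dosages`` is float to admit NaN for missing cells (and real values after
    mean imputation); entries are otherwise integers in {0..4}.
    """

    individuals: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("dosage matrix shape does not match id lists")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    @property
    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker from the called (non-missing) dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / PLOIDY

    def subset_markers(self, keep: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            self.individuals,
            self.markers.iloc[keep].reset_index(drop=True),
            self.dosages[:, keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "DosageMatrix":
        ids = [self.individuals[i] for i in np.atleast_1d(keep)]
        return DosageMatrix(ids, self.markers, self.dosages[np.atleast_1d(keep), :])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.dosages, index=self.individuals, columns=self.markers["marker"]
        )
        df.to_csv(path, sep="\t", na_rep="NA", index_label="individual")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        markers = pd.DataFrame(
            {"marker": df.columns, "chrom": "0", "pos": np.arange(1, df.shape[1] + 1)}
        )
        return cls(list(df.index.astype(str)), markers, df.to_numpy(dtype=float))


def _class_fractions(seq_error: float) -> np.ndarray:
    k = np.arange(N_CLASSES)
    return (k / PLOIDY) * (1.0 - seq_error) + (1.0 - k / PLOIDY) * seq_error


def _log_binom_lik(ref: np.ndarray, alt: np.ndarray, seq_error: float) -> np.ndarray:
    """Log Binom(alt; ref+alt, f'(k)) for each class k, broadcast over cells.

    Handles f'=0 / f'=1 exactly (e=0 limit): a class with zero success
    probability and alt>0 reads gets log-likelihood -inf, hence posterior 0.
    """
    ref = np.asarray(ref, dtype=float)[..., None]
    alt = np.asarray(alt, dtype=float)[..., None]
    n = ref + alt
    f = np.broadcast_to(_class_fractions(seq_error), ref.shape[:-1] + (N_CLASSES,))
    logc = gammaln(n + 1) - gammaln(alt + 1) - gammaln(ref + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.where(alt > 0, alt * np.log(f), 0.0)
        lr = np.where(ref > 0, ref * np.log1p(-f), 0.0)
    return logc + la + lr


def genotype_posterior(
    ref: int,
    alt: int,
    seq_error: float = 0.002,
    prior: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior over the five dosage classes for one read-count cell.

    With ``ref + alt == 0`` there is no evidence and the prior is returned
    unchanged.  The default prior is uniform.
    """
    if ref < 0 or alt < 0:
        raise ValueError("read counts must be non-negative")
    prior = _check_prior(prior)
    if ref + alt == 0:
        return prior.copy()
    logl = _log_binom_lik(np.array([ref]), np.array([alt]), seq_error)[0]
    logp = np.log(prior, where=prior > 0, out=np.full(N_CLASSES, -np.inf)) + logl
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def posterior_array(
    counts: ReadCountSet,
    seq_error: float = 0.002,
    prior: np.ndarray | None = None,
) -> np.ndarray:
    """(n, m, 5) posterior array for a full read-count set (vectorised)."""
    prior = _check_prior(prior)
    logl = _log_binom_lik(counts.ref, counts.alt, seq_error)
    with np.errstate(divide="ignore"):
        logp = logl + np.log(prior)
    logp -= logp.max(axis=-1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=-1, keepdims=True)
    nodata = counts.depth == 0
    p[nodata] = prior
    return p


def _check_prior(prior: np.ndarray | None) -> np.ndarray:
    if prior is None:
        return np.full(N_CLASSES, 1.0 / N_CLASSES)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (N_CLASSES,) or not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must be a 5-vector summing to 1")
    return prior


def hwe_prior(p: float) -> np.ndarray:
    """Binomial(4, p) dosage-class prior (random chromosome pairing)."""
    from scipy.stats import binom

    return binom.pmf(np.arange(N_CLASSES), PLOIDY, p)


def call_dosages(
    counts: ReadCountSet,
    seq_error: float = 0.002,
    prob_threshold: float = 0.85,
    prior: np.ndarray | None = None,
) -> DosageMatrix:
    """Maximum-posterior dosage calls with threshold masking.

    A cell is called as the dosage class with the highest posterior when that
    posterior reaches ``prob_threshold``; otherwise it is missing.  Posterior
    ties break toward the lower dosage class (reference-conservative).
    """
    if not 0.0 < prob_threshold <= 1.0:
        raise ValueError("prob_threshold must be in (0, 1]")
    post = posterior_array(counts, seq_error=seq_error, prior=prior)
    best = np.argmax(post, axis=-1)  # first (= lowest dosage) argmax on ties
    pmax = np.take_along_axis(post, best[..., None], axis=-1)[..., 0]
    dosages = np.where(pmax >= prob_threshold - 1e-12, best.astype(float), np.nan)
    return DosageMatrix(counts.individuals, counts.markers.copy(), dosages)


def filter_markers(
    counts: ReadCountSet,
    dosages: DosageMatrix,
    maf_min: float = 0.01,
    depth_min: float = 10,
    depth_max: float = 100,
    max_missing: float = 0.25,
) -> tuple[DosageMatrix, dict]:
    """Marker QC: depth band, then MAF, then missingness.

    Rules apply in order (each to the survivors of the previous one) and the
    QC report counts removals per rule.  Depth is the per-marker mean read
    depth; MAF = min(p, 1-p) from the called dosages; a marker is dropped when
    *more than* ``max_missing`` of individuals are missing.  Repetitive-region
    and multi-allelic exclusions are an upstream (alignment-level) concern and
    are not applied here.
    """
    if counts.n_markers != len(dosages.markers):
        raise ValueError("counts and dosages disagree on marker count")
    n = dosages.dosages.shape[0]
    mean_depth = counts.depth.mean(axis=0)
    keep_depth = (mean_depth >= depth_min) & (mean_depth <= depth_max)

    freq = dosages.allele_freq
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    keep_maf = keep_depth & (np.nan_to_num(maf, nan=0.0) >= maf_min)

    miss_frac = dosages.missing_mask.sum(axis=0) / n
    keep_final = keep_maf & (miss_frac <= max_missing)

    report = {
        "n_markers_in": int(counts.n_markers),
        "removed_depth": int((~keep_depth).sum()),
        "removed_maf": int((keep_depth & ~keep_maf).sum()),
        "removed_missing": int((keep_maf & ~keep_final).sum()),
        "n_markers_out": int(keep_final.sum()),
        "note": "repetitive-region and >2-allele filters are upstream of this step",
    }
    if report["n_markers_out"] == 0:
        raise ValueError("all markers removed by QC filters")
    return dosages.subset_markers(np.flatnonzero(keep_final)), report


def impute(dosages: DosageMatrix, method: str = "mode") -> DosageMatrix:
    """Fill missing cells per marker by the mode (ties -> lower dosage) or mean.

    Mean imputation leaves real-valued dosages and is provided for comparison
    only; the mode keeps the integer domain.
    """
    if method not in ("mode", "mean"):
        raise ValueError(f"unknown imputation method: {method!r}")
    X = dosages.dosages.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"marker {dosages.markers['marker'].iloc[j]} is all-missing")
        if method == "mode":
            counts = np.bincount(obs.astype(int), minlength=N_CLASSES)
            fill = float(np.argmax(counts))  # first argmax -> lower dosage on ties
        else:
            fill = float(obs.mean())
        col[miss] = fill
    return DosageMatrix(dosages.individuals, dosages.markers.copy(), X)


# ---------------------------------------------------------------------------
# I/O


def read_counts_tsv(ref_path: str | Path, alt_path: str | Path) -> ReadCountSet:
    """Read a ref/alt count-matrix pair (individuals x markers, TSV)."""
    ref = pd.read_csv(ref_path, sep="\t", index_col=0)
    alt = pd.read_csv(alt_path, sep="\t", index_col=0)
    if list(ref.index) != list(alt.index) or list(ref.columns) != list(alt.columns):
        raise ValueError("ref and alt matrices have mismatched ids")
    markers = pd.DataFrame(
        {"marker": ref.columns, "chrom": "0", "pos": np.arange(1, ref.shape[1] + 1)}
    )
    return ReadCountSet(
        list(ref.index.astype(str)), markers, ref.to_numpy(int), alt.to_numpy(int)
    )


def read_counts_vcf(path: str | Path) -> ReadCountSet:
    """Read per-sample AD (allelic depth) from a biallelic VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, refs, alts = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS))
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
    ref = np.clip(np.array(refs, dtype=int).T, 0, None)
    alt = np.clip(np.array(alts, dtype=int).T, 0, None)
    return ReadCountSet(individuals, markers, ref, alt)


def write_counts_vcf(counts: ReadCountSet, path: str | Path) -> None:
    """Write read counts as a minimal biallelic VCF with an AD FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in counts.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(counts.individuals)
            + "\n"
        )
        for j, rec in counts.markers.iterrows():
            cells = "\t".join(
                f"{counts.ref[i, j]},{counts.alt[i, j]}"
                for i in range(counts.n_individuals)
            )
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['marker']}\tA\tB\t.\t.\t.\tAD\t{cells}\n"
            )
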
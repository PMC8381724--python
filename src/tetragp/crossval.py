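"""Training-set construction and repeated cross-validation for prediction.

Training sets of a fixed size (default 105 of 147, matching a 105/42 split)
are drawn either at random or by maximising CDmean: the mean coefficient of
determination of the validation individuals' genotypic-value contrasts with
the population mean, computed from the genomic relationship matrix and the
model's variance ratio.  A simple exchange algorithm (swap one individual
in/out while CDmean improves) optimises the set.

Prediction accuracy is the Pearson correlation between observed adjusted
means and predicted genotypic values in the validation set, averaged over
repetitions with its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosage import PLOIDY, DosageMatrix
from .gp_models import (
    GibbsConfig,
    fit_bayes_marker,
    fit_kernel_gblup,
    fit_rkhs_ml,
    kernels_for_model,
    project_genetic_values,
    reml_1kernel,
    KERNEL_MODELS,
    MARKER_MODELS,
)
from .kinship import KinshipMatrix, additive_G, squared_distance

__all__ = ["CVScheme", "CVResult", "cdmean_select", "cdmean_value", "accuracy", "run_cv"]


@dataclass
class CVScheme:
    n_train: int = 105
    n_reps: int = 100
    selector: str = "cdmean"
    seed: int = 0
    lambda_ratio: float | None = None  # sig2e/sig2g inside the CD; None = estimate
    cd_variant: str = "contrast"  # or "plain"
    cd_starts: int = 1  # restarts of the exchange per repetition
    cd_candidates: int = 1500  # swap pairs scored per exchange pass

    def __post_init__(self) -> None:
        if self.selector not in ("cdmean", "random"):
            raise ValueError("selector must be 'cdmean' or 'random'")


@dataclass
class CVResult:
    accuracies: np.ndarray
    train_sets: list[np.ndarray]
    predictions: list[np.ndarray] = field(default_factory=list)
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se(self) -> float:
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(len(self.accuracies)))


def _cd_for_set(G: np.ndarray, train: np.ndarray, lam: float, variant: str) -> float:
    """Mean CD over validation individuals for one candidate training set."""
    n = G.shape[0]
    val = np.setdiff1d(np.arange(n), train)
    Gtt = G[np.ix_(train, train)]
    t = len(train)
    try:
        A = np.linalg.inv(Gtt + lam * np.eye(t))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular training kernel; adding jitter")
        A = np.linalg.inv(Gtt + (lam + 1e-6) * np.eye(t))
    # absorb the fixed mean: P = A - A 1 1' A / (1' A 1)
    a1 = A @ np.ones(t)
    P = A - np.outer(a1, a1) / a1.sum()
    B = G[:, train] @ P  # n x t
    W = B @ G[train, :]  # n x n: prediction covariance on the genetic scale
    if variant == "plain":
        cds = np.diag(W)[val] / np.clip(np.diag(G)[val], 1e-12, None)
    else:
        # contrasts of each validation individual with the population mean
        wbar_row = W.mean(axis=1)
        wbar = W.mean()
        gbar_row = G.mean(axis=1)
        gbar = G.mean()
        num = np.diag(W)[val] - 2 * wbar_row[val] + wbar
        den = np.diag(G)[val] - 2 * gbar_row[val] + gbar
        cds = num / np.clip(den, 1e-12, None)
    return float(np.mean(cds))


def cdmean_value(
    G: KinshipMatrix | np.ndarray,
    train: np.ndarray,
    lambda_ratio: float,
    variant: str = "contrast",
) -> float:
    Gm = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, float)
    return _cd_for_set(Gm, np.asarray(train, int), lambda_ratio, variant)


def cdmean_select(
    G: KinshipMatrix | np.ndarray,
    n_train: int,
    lambda_ratio: float = 1.0,
    seed: int = 0,
    variant: str = "contrast",
    max_passes: int = 200,
    n_starts: int = 5,
    max_candidates: int = 1500,
) -> np.ndarray:
    """Exchange optimisation of CDmean; returns sorted training indices.

    Steepest-ascent exchange: from a random set, each pass applies the single
    best improving in/out swap until none improves (or ``max_passes``); the
    search restarts ``n_starts`` times and keeps the best local optimum (the
    CD surface has many shallow local optima).  Only improvements are ever
    accepted, so the final CDmean is >= every random start's.  When the full
    swap neighbourhood exceeds ``max_candidates`` pairs, each pass scores a
    random subsample of that size (keeps large-n selection tractable; the
    search then stops after the first pass with no improving sampled swap).
    """
    Gm = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, float)
    n = Gm.shape[0]
    if not 0 < n_train < n:
        raise ValueError("need 0 < n_train < n")
    rng = np.random.default_rng(seed)
    overall_cd, overall_train = -np.inf, None
    for _ in range(max(n_starts, 1)):
        train = rng.choice(n, size=n_train, replace=False)
        in_set = np.zeros(n, bool)
        in_set[train] = True
        best = _cd_for_set(Gm, train, lambda_ratio, variant)
        for _ in range(max_passes):
            ins = np.flatnonzero(in_set)
            outs = np.flatnonzero(~in_set)
            pairs = [(i, j) for i in ins for j in outs]
            if len(pairs) > max_candidates:
                idx = rng.choice(len(pairs), size=max_candidates, replace=False)
                pairs = [pairs[k] for k in idx]
            cand: tuple[float, tuple | None] = (best, None)
            for i, j in pairs:
                trial = train.copy()
                trial[trial == i] = j
                cd = _cd_for_set(Gm, trial, lambda_ratio, variant)
                if cd > cand[0] + 1e-12:
                    cand = (cd, (i, j))
            if cand[1] is None:
                break
            i, j = cand[1]
            train[train == i] = j
            in_set[i], in_set[j] = False, True
            best = cand[0]
        if best > overall_cd:
            overall_cd, overall_train = best, train.copy()
    return np.sort(overall_train)


def accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed adjusted means and predictions."""
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if len(o) != len(p) or len(o) < 3:
        raise ValueError("need >= 3 aligned pairs")
    if np.std(o) == 0 or np.std(p) == 0:
        raise ValueError("zero variance: accuracy undefined")
    return float(np.corrcoef(o, p)[0, 1])


def run_cv(
    y: np.ndarray,
    dosages: DosageMatrix,
    model: str = "Add",
    scheme: CVScheme | None = None,
    cfg: GibbsConfig | None = None,
    theta_grid: np.ndarray | None = None,
) -> CVResult:
    """Repeated hold-out cross-validation of one prediction model.

    Per repetition: select the training set, fit the model on training
    phenotypes only (kernels and allele frequencies use all genotyped
    individuals; validation phenotypes are never seen), predict the
    validation set, and score Pearson accuracy.  Failed repetitions are
    excluded and counted.
    """
    scheme = scheme or CVScheme()
    cfg = cfg or GibbsConfig()
    y = np.asarray(y, float)
    n = len(y)
    if n != len(dosages.individuals):
        raise ValueError("phenotype/dosage individual mismatch")
    if scheme.n_train >= n:
        raise ValueError("n_train must be smaller than the population")

    GA = additive_G(dosages)
    if scheme.lambda_ratio is None:
        null = reml_1kernel(y, GA.values)
        lam = max(null["sig2e"], 1e-8) / max(null["sig2g"], 1e-8)
    else:
        lam = scheme.lambda_ratio

    if model in KERNEL_MODELS or model == "RKHS":
        kernels = kernels_for_model(model, dosages) if model != "RKHS" else None
    elif model in MARKER_MODELS:
        Xc = dosages.dosages - PLOIDY * dosages.allele_freq
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(scheme.seed)
    accs, trains, preds = [], [], []
    n_failed = 0
    for rep in range(scheme.n_reps):
        rep_seed = int(rng.integers(2**31))
        if scheme.selector == "cdmean":
            train = cdmean_select(GA, scheme.n_train, lam, seed=rep_seed,
                                  variant=scheme.cd_variant,
                                  n_starts=scheme.cd_starts,
                                  max_candidates=scheme.cd_candidates)
        else:
            train = np.sort(
                np.random.default_rng(rep_seed).choice(n, scheme.n_train, replace=False)
            )
        val = np.setdiff1d(np.arange(n), train)
        try:
            if model in KERNEL_MODELS:
                sub = [KinshipMatrix(
                    [k.individuals[i] for i in train],
                    k.values[np.ix_(train, train)], k.flavor, k.n_markers, k.theta,
                ) for k in kernels]
                fit = fit_kernel_gblup(
                    y[train], sub,
                    GibbsConfig(cfg.n_iter, cfg.burn_in, cfg.thin, rep_seed),
                )
                # extend each kernel term to the validation rows separately
                pred = np.zeros(n)
                for k in kernels:
                    pred += project_genetic_values(
                        k.values, train, fit.gvalues_by_kernel[k.flavor]
                    )
            elif model == "RKHS":
                fit = fit_rkhs_ml(y[train], dosages.dosages[train], theta_grid)
                K = np.exp(-fit.theta * squared_distance(dosages.dosages))
                pred = project_genetic_values(K, train, fit.gvalues)
            else:
                fit = fit_bayes_marker(
                    y[train], Xc[train],
                    prior=model,
                    cfg=GibbsConfig(cfg.n_iter, cfg.burn_in, cfg.thin, rep_seed),
                )
                pred = Xc @ fit.marker_effects
            accs.append(accuracy(y[val], pred[val]))
            trains.append(train)
            preds.append(pred)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if not accs:
        raise RuntimeError("every cross-validation repetition failed")
    return CVResult(np.array(accs), trains, preds, n_failed)
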
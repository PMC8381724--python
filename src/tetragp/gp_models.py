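"""Whole-genome prediction models for autotetraploids.

Two families share the linear mixed-model backbone y = mu + genetic + e:

* kernel models (genotypic-effect scale): additive GBLUP, additive +
  digenic dominance, + additive-x-additive epistasis, the full-tetraploid
  class-indicator model, and the Gaussian-kernel RKHS model.  All but RKHS
  are fitted by Gibbs sampling with scaled-inverse-chi-square variance
  priors; RKHS is fitted by restricted maximum likelihood with the kernel
  bandwidth chosen on a grid by profile likelihood.
* marker-effect models (Bayesian whole-genome regression): BayesA
  (scaled-t effects), BayesCpi (spike-and-slab with the zero-effect
  proportion pi estimated from the data) and the Bayesian LASSO (double-
  exponential effects).  The per-marker Gibbs sweep is numba-compiled.

Hyperprior scales follow the usual partition rule: 5 prior degrees of
freedom, scale set so each term's prior expected variance corresponds to an
even split of half the phenotypic variance among genetic terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosage import PLOIDY, DosageMatrix
from .kinship import (
    KinshipMatrix,
    additive_G,
    dominance_G,
    epistasis_G,
    full_tetraploid_G,
    rkhs_kernel,
    squared_distance,
)

__all__ = [
    "GibbsConfig",
    "GPFit",
    "fit_kernel_gblup",
    "fit_bayes_marker",
    "fit_rkhs_ml",
    "reml_1kernel",
    "blup_kernel",
    "project_genetic_values",
    "kernels_for_model",
    "KERNEL_MODELS",
    "MARKER_MODELS",
]

_DF0 = 5.0
_R2 = 0.5

KERNEL_MODELS = {"Add", "A+D", "A+D+Ep", "FT"}
MARKER_MODELS = {"BayesA", "BayesCpi", "BayesL"}


@dataclass
class GibbsConfig:
    """MCMC settings; defaults are 10,000 iterations with 2,500 burn-in."""

    n_iter: int = 10000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GPFit:
    """Posterior summaries of one fitted prediction model."""

    model: str
    individuals: list[str]
    mu: float
    mu_sd: float
    varcomps: dict[str, float]
    varcomps_sd: dict[str, float]
    gvalues: np.ndarray
    gvalues_sd: np.ndarray
    marker_effects: np.ndarray | None = None
    inclusion_prob: np.ndarray | None = None
    pi: float | None = None
    lambda_: float | None = None
    theta: float | None = None
    ess: dict[str, float] = field(default_factory=dict)
    gvalues_by_kernel: dict[str, np.ndarray] = field(default_factory=dict)

    def predict_training(self) -> np.ndarray:
        return self.mu + self.gvalues


def _ess(chain: np.ndarray) -> float:
    """Effective sample size from the initial-positive-sequence autocorrelation."""
    x = np.asarray(chain, float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, "full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def _scale_prior(var_target: float, df: float = _DF0) -> float:
    """Scale S of a scaled-inv-chi^2(df, S) with prior mean ~ var_target."""
    return var_target * (df + 2.0) / df


# ---------------------------------------------------------------------------
# Kernel (genotypic-effect) Gibbs sampler


def fit_kernel_gblup(
    y: np.ndarray,
    kernels: list[KinshipMatrix],
    cfg: GibbsConfig | None = None,
    individuals: list[str] | None = None,
) -> GPFit:
    """Gibbs sampler for a multi-kernel GBLUP mixed model.

    ``y`` must align with every kernel's individuals (pass ``individuals`` to
    check/reorder).  Each kernel contributes an independent genetic term with
    its own variance; sampling works in each kernel's eigenbasis so a sweep
    costs O(n^2) per kernel.
    """
    cfg = cfg or GibbsConfig()
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    n = len(y)
    if individuals is not None:
        kernels = [K.align(individuals) for K in kernels]
    for K in kernels:
        if K.n != n:
            raise ValueError(
                f"kernel ({K.flavor}) has {K.n} individuals, phenotype has {n}"
            )
    if not 1 <= len(kernels) <= 3:
        raise ValueError("expected 1-3 kernels")
    model = _model_tag([K.flavor for K in kernels])
    names = [K.flavor for K in kernels]

    eig = []
    for K in kernels:
        w, U = np.linalg.eigh(K.values)
        keep = w > 1e-10 * max(w.max(), 1.0)
        eig.append((w, U, keep))

    rng = np.random.default_rng(cfg.seed)
    vary = max(float(np.var(y)), 1e-12)
    nk = len(kernels)
    S0 = [_scale_prior(vary * _R2 / nk / max(np.mean(np.diag(K.values)), 1e-12))
          for K in kernels]
    Se0 = _scale_prior(vary * (1.0 - _R2))

    mu = float(y.mean())
    us = [np.zeros(n) for _ in kernels]
    sig = [vary * _R2 / nk for _ in kernels]
    sige = max(vary * (1.0 - _R2), 1e-12)

    keepers = range(cfg.burn_in, cfg.n_iter, cfg.thin)
    n_keep = len(keepers)
    g_sum = np.zeros(n)
    g_sum2 = np.zeros(n)
    u_sums = [np.zeros(n) for _ in kernels]
    mu_chain = np.empty(n_keep)
    var_chains = {nm: np.empty(n_keep) for nm in names}
    var_chains["residual"] = np.empty(n_keep)
    ki = 0
    for it in range(cfg.n_iter):
        for k, (w, U, keep) in enumerate(eig):
            r = y - mu - sum(us[l] for l in range(nk) if l != k)
            rt = U.T @ r
            lam = w * sig[k]
            shrink = lam / (lam + sige)
            mean = shrink * rt
            var = shrink * sige
            v = mean + rng.standard_normal(n) * np.sqrt(np.clip(var, 0, None))
            v[~keep] = 0.0
            us[k] = U @ v
            ss = float(np.sum(v[keep] ** 2 / w[keep]))
            dfp = _DF0 + keep.sum()
            sig[k] = (ss + _DF0 * S0[k]) / rng.chisquare(dfp)
        resid = y - sum(us)
        mu = rng.normal(resid.mean(), np.sqrt(sige / n))
        e = resid - mu
        sige = (e @ e + _DF0 * Se0) / rng.chisquare(_DF0 + n)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            g = sum(us)
            g_sum += g
            g_sum2 += g**2
            for k in range(nk):
                u_sums[k] += us[k]
            mu_chain[ki] = mu
            for k, nm in enumerate(names):
                var_chains[nm][ki] = sig[k]
            var_chains["residual"][ki] = sige
            ki += 1

    g_mean = g_sum / n_keep
    g_sd = np.sqrt(np.clip(g_sum2 / n_keep - g_mean**2, 0, None))
    return GPFit(
        model=model,
        individuals=list(kernels[0].individuals),
        mu=float(mu_chain.mean()),
        mu_sd=float(mu_chain.std()),
        varcomps={k: float(v.mean()) for k, v in var_chains.items()},
        varcomps_sd={k: float(v.std()) for k, v in var_chains.items()},
        gvalues=g_mean,
        gvalues_sd=g_sd,
        ess={k: _ess(v) for k, v in var_chains.items()},
        gvalues_by_kernel={nm: u_sums[k] / n_keep for k, nm in enumerate(names)},
    )


def _model_tag(flavors: list[str]) -> str:
    key = tuple(sorted(flavors))
    tags = {
        ("additive",): "Add",
        ("additive", "dominance_digenic"): "A+D",
        ("additive", "dominance_digenic", "epistatic_AxA"): "A+D+Ep",
        ("full_tetraploid",): "FT",
        ("rkhs",): "RKHS",
    }
    return tags.get(key, "+".join(sorted(flavors)))


# ---------------------------------------------------------------------------
# Closed-form single-kernel REML / BLUP (also the RKHS engine)


def reml_1kernel(y: np.ndarray, K: np.ndarray) -> dict:
    """REML for y = 1 mu + g + e with g ~ N(0, sig2g K), via one eigendecomposition.

    Profiles the likelihood over the variance ratio; returns variance
    components, mu, the REML log-likelihood and BLUP genetic values.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, float)
    n = len(y)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def negll(loglam):
        lam = np.exp(loglam)
        wv = w + lam
        xwx = np.sum(xt**2 / wv)
        beta = np.sum(xt * yt / wv) / xwx
        r = yt - xt * beta
        rss = np.sum(r**2 / wv)
        s2 = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(wv)) + np.log(xwx) + (n - 1))

    res = minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    wv = w + lam
    xwx = np.sum(xt**2 / wv)
    mu = float(np.sum(xt * yt / wv) / xwx)
    r = yt - xt * mu
    sig2g = float(np.sum(r**2 / wv) / (n - 1))
    sig2e = sig2g * lam
    g = U @ ((w / wv) * r)
    return {
        "mu": mu,
        "sig2g": sig2g,
        "sig2e": sig2e,
        "loglik": -float(res.fun),
        "gvalues": g,
        "ratio": lam,
    }


def blup_kernel(y: np.ndarray, K: np.ndarray, sig2g: float, sig2e: float) -> np.ndarray:
    """Closed-form BLUP genetic values at fixed variances (GLS intercept)."""
    n = len(y)
    V = sig2g * K + sig2e * np.eye(n)
    Vi = np.linalg.inv(V)
    mu = float(np.sum(Vi @ y) / np.sum(Vi))
    return sig2g * K @ (Vi @ (y - mu))


def project_genetic_values(
    K_full: np.ndarray, train_idx: np.ndarray, g_train: np.ndarray, jitter: float = 1e-8
) -> np.ndarray:
    """Extend posterior-mean genetic values to all individuals through the
    joint kernel rows: g_all = K[:, T] K[T, T]^-1 g_T."""
    Ktt = K_full[np.ix_(train_idx, train_idx)]
    Ktt = Ktt + jitter * np.mean(np.diag(Ktt)) * np.eye(len(train_idx))
    return K_full[:, train_idx] @ np.linalg.solve(Ktt, g_train)


def fit_rkhs_ml(
    y: np.ndarray,
    dosages: DosageMatrix | np.ndarray,
    theta_grid: np.ndarray | None = None,
    individuals: list[str] | None = None,
) -> GPFit:
    """Gaussian-kernel RKHS regression with the bandwidth chosen by REML profile
    likelihood over a grid of theta values."""
    if theta_grid is None:
        theta_grid = np.array([0.1, 0.25, 0.5, 1.0, 2.0, 4.0])
    theta_grid = np.asarray(theta_grid, float)
    if theta_grid.size == 0 or (theta_grid <= 0).any():
        raise ValueError("theta grid must be non-empty and positive")
    if isinstance(dosages, DosageMatrix):
        X = dosages.dosages
        ids = list(dosages.individuals)
    else:
        X = np.asarray(dosages, float)
        ids = individuals or [str(i) for i in range(X.shape[0])]
    D = squared_distance(X)
    best = None
    for th in theta_grid:
        K = np.exp(-th * D)
        if np.allclose(K, 1.0):  # degenerate all-ones kernel at tiny theta
            import warnings

            warnings.warn(f"theta={th} gives an all-ones kernel; adding ridge jitter")
            K = K + 1e-8 * np.eye(len(y))
        fit = reml_1kernel(np.asarray(y, float), K)
        if not np.isfinite(fit["loglik"]):
            raise FloatingPointError(f"non-finite profile likelihood at theta={th}")
        if best is None or fit["loglik"] > best[1]["loglik"]:
            best = (float(th), fit)
    th, fit = best
    return GPFit(
        model="RKHS",
        individuals=ids,
        mu=fit["mu"],
        mu_sd=0.0,
        varcomps={"rkhs": fit["sig2g"], "residual": fit["sig2e"]},
        varcomps_sd={},
        gvalues=fit["gvalues"],
        gvalues_sd=np.zeros(len(y)),
        theta=th,
    )


# ---------------------------------------------------------------------------
# Marker-effect Bayesian regressions (numba-compiled Gibbs sweep)


def _get_bayes_kernel():
    import numba

    @numba.njit(cache=True)
    def _rinvgauss(mu, lam):
        v = np.random.standard_normal()
        w_ = v * v
        x = mu + mu * mu * w_ / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
            4.0 * mu * lam * w_ + mu * mu * w_ * w_
        )
        if np.random.random() <= mu / (mu + x):
            return x
        return mu * mu / x

    @numba.njit(cache=True)
    def gibbs(y, X, n_iter, burn_in, seed, prior_code, df0, S0, Se0, dfe0,
              r0_lam, delta0_lam):
        # prior_code: 0 BayesA, 1 BayesCpi, 2 BayesL
        np.random.seed(seed)
        n, m = X.shape
        xtx = np.empty(m)
        for j in range(m):
            s = 0.0
            for i in range(n):
                s += X[i, j] * X[i, j]
            xtx[j] = s
        b = np.zeros(m)
        mu = y.mean()
        e = y - mu
        vary = y.var()
        sige = max(vary * 0.5, 1e-12)
        sigb = np.full(m, S0)         # BayesA per-marker variances
        sigb_common = S0              # BayesCpi slab variance
        tau2 = np.full(m, 1.0)        # BayesL
        lam2 = max(2.0 * (1.0 - 0.5) / 0.5 * (xtx.sum() / n / m), 1e-8)
        pi = 0.5
        delta = np.ones(m)

        n_keep = n_iter - burn_in
        b_sum = np.zeros(m)
        incl_sum = np.zeros(m)
        mu_chain = np.empty(n_keep)
        sige_chain = np.empty(n_keep)
        sigb_chain = np.empty(n_keep)
        pi_chain = np.empty(n_keep)
        lam_chain = np.empty(n_keep)

        for it in range(n_iter):
            for j in range(m):
                if xtx[j] <= 0.0:
                    continue
                rhs = 0.0
                for i in range(n):
                    rhs += X[i, j] * e[i]
                rhs += xtx[j] * b[j]
                bold = b[j]
                if prior_code == 0:      # BayesA
                    C = xtx[j] + sige / sigb[j]
                    bn = rhs / C + np.sqrt(sige / C) * np.random.standard_normal()
                elif prior_code == 1:    # BayesCpi
                    C = xtx[j] + sige / sigb_common
                    logodds = (
                        np.log((1.0 - pi) / pi)
                        + 0.5 * np.log(sige / (sigb_common * C))
                        + 0.5 * rhs * rhs / (sige * C)
                    )
                    pin = 1.0 / (1.0 + np.exp(-logodds))
                    if np.random.random() < pin:
                        delta[j] = 1.0
                        bn = rhs / C + np.sqrt(sige / C) * np.random.standard_normal()
                    else:
                        delta[j] = 0.0
                        bn = 0.0
                else:                    # BayesL
                    C = xtx[j] + 1.0 / tau2[j]
                    bn = rhs / C + np.sqrt(sige / C) * np.random.standard_normal()
                if bn != bold:
                    for i in range(n):
                        e[i] -= X[i, j] * (bn - bold)
                b[j] = bn
                if prior_code == 0:
                    sigb[j] = (df0 * S0 + b[j] * b[j]) / np.random.chisquare(df0 + 1.0)
                elif prior_code == 2:
                    babs = abs(b[j])
                    if babs < 1e-10:
                        babs = 1e-10
                    itau = _rinvgauss(np.sqrt(lam2 * sige) / babs, lam2)
                    if itau < 1e-10:
                        itau = 1e-10
                    tau2[j] = 1.0 / itau

            if prior_code == 1:
                nin = delta.sum()
                ssb = 0.0
                for j in range(m):
                    if delta[j] > 0.5:
                        ssb += b[j] * b[j]
                sigb_common = (ssb + df0 * S0) / np.random.chisquare(df0 + nin)
                # pi is the zero-effect proportion
                a1 = m - nin + 1.0
                a2 = nin + 1.0
                g1 = np.random.gamma(a1, 1.0)
                g2 = np.random.gamma(a2, 1.0)
                pi = g1 / (g1 + g2)
                if pi < 1e-4:
                    pi = 1e-4
                if pi > 1.0 - 1e-4:
                    pi = 1.0 - 1e-4
            if prior_code == 2:
                lam2 = np.random.gamma(r0_lam + m, 1.0 / (delta0_lam + tau2.sum() / 2.0))

            # intercept
            muold = mu
            mu = (e.mean() + mu) + np.sqrt(sige / n) * np.random.standard_normal()
            for i in range(n):
                e[i] -= mu - muold
            # residual variance
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if prior_code == 2:
                ssb_t = 0.0
                for j in range(m):
                    ssb_t += b[j] * b[j] / tau2[j]
                sige = (sse + ssb_t + dfe0 * Se0) / np.random.chisquare(dfe0 + n + m)
            else:
                sige = (sse + dfe0 * Se0) / np.random.chisquare(dfe0 + n)

            if it >= burn_in:
                k = it - burn_in
                for j in range(m):
                    b_sum[j] += b[j]
                    incl_sum[j] += delta[j]
                mu_chain[k] = mu
                sige_chain[k] = sige
                sigb_chain[k] = sigb_common if prior_code == 1 else sigb.mean()
                pi_chain[k] = pi
                lam_chain[k] = np.sqrt(lam2)

        return (b_sum / n_keep, incl_sum / n_keep, mu_chain, sige_chain,
                sigb_chain, pi_chain, lam_chain)

    return gibbs


_BAYES_KERNEL = None


def fit_bayes_marker(
    y: np.ndarray,
    X_centered: np.ndarray,
    prior: str = "BayesCpi",
    cfg: GibbsConfig | None = None,
    individuals: list[str] | None = None,
) -> GPFit:
    """Bayesian whole-genome regression with BayesA / BayesCpi / BayesL priors.

    ``X_centered`` is the dosage matrix centred per marker (by 4p).  Returns
    posterior-mean marker effects, genotypic values X b, and posterior chains
    summarised (pi for BayesCpi, lambda for BayesL).
    """
    global _BAYES_KERNEL
    cfg = cfg or GibbsConfig()
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    X = np.ascontiguousarray(np.asarray(X_centered, float))
    codes = {"BayesA": 0, "BayesCpi": 1, "BayesL": 2}
    if prior not in codes:
        raise ValueError(f"unknown prior {prior!r}")
    if _BAYES_KERNEL is None:
        _BAYES_KERNEL = _get_bayes_kernel()
    n, m = X.shape
    vary = max(float(np.var(y)), 1e-12)
    msx = max(float(np.sum(X.var(axis=0))), 1e-12)
    S0 = _scale_prior(vary * _R2 / msx)  # per-marker effect-variance scale
    Se0 = _scale_prior(vary * (1.0 - _R2))
    b, incl, mu_c, sige_c, sigb_c, pi_c, lam_c = _BAYES_KERNEL(
        y, X, cfg.n_iter, cfg.burn_in, cfg.seed % (2**31), codes[prior],
        _DF0, S0, Se0, _DF0, 1.1, 0.1,
    )
    g = X @ b
    ids = individuals or [str(i) for i in range(n)]
    return GPFit(
        model=prior,
        individuals=list(ids),
        mu=float(mu_c.mean()),
        mu_sd=float(mu_c.std()),
        varcomps={"marker": float(sigb_c.mean()), "residual": float(sige_c.mean())},
        varcomps_sd={"marker": float(sigb_c.std()), "residual": float(sige_c.std())},
        gvalues=g,
        gvalues_sd=np.zeros(n),
        marker_effects=b,
        inclusion_prob=incl if prior == "BayesCpi" else None,
        pi=float(pi_c.mean()) if prior == "BayesCpi" else None,
        lambda_=float(lam_c.mean()) if prior == "BayesL" else None,
        ess={"residual": _ess(sige_c)},
    )


def kernels_for_model(model: str, dosages: DosageMatrix, theta: float = 1.0
                      ) -> list[KinshipMatrix]:
    """Kinship set for a kernel-model tag ('Add', 'A+D', 'A+D+Ep', 'FT', 'RKHS')."""
    GA = additive_G(dosages)
    if model == "Add":
        return [GA]
    if model == "A+D":
        return [GA, dominance_G(dosages)]
    if model == "A+D+Ep":
        return [GA, dominance_G(dosages), epistasis_G(GA)]
    if model == "FT":
        return [full_tetraploid_G(dosages)]
    if model == "RKHS":
        return [rkhs_kernel(dosages, theta)]
    raise ValueError(f"unknown kernel model {model!r}")
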
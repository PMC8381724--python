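"""Field-trial phenotype adjustment and broad-sense heritability.

A two-step pipeline mirrors common multi-environment trial practice:

1. within each trial, a row-column model with fixed complete blocks and
   random rows/columns within blocks yields a best linear unbiased estimate
   (BLUE) per genotype;
2. the within-trial BLUEs are combined across trials with a fixed trial
   effect, giving one adjusted mean per genotype for downstream prediction.

Variance components come from a small EM-REML engine (with an
average-information polish); broad-sense heritability on a genotype-mean
basis is

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_gL^2/l + sigma_gT^2/t
                       + sigma_eps^2/(l t))

with l locations and t years, where sigma_eps^2 is the genotype x location x
year interaction (which at one BLUE per genotype per trial absorbs within-
trial error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "fit_lmm_reml",
    "blues_within_trial",
    "blues_across_trials",
    "fit_h2_model",
    "heritability",
]


@dataclass
class VarianceComponents:
    components: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int

    def __getitem__(self, key: str) -> float:
        return self.components[key]


def _reml_loglik(y, X, Zs, comps, sige):
    n = len(y)
    V = sige * np.eye(n)
    for name, Z in Zs.items():
        V += comps[name] * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        Vi = np.linalg.pinv(V)
    XtViX = X.T @ Vi @ X
    s2, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (logdetV + logdetX + r @ Vi @ r)


def fit_lmm_reml(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 500,
    ai_polish: bool = True,
) -> tuple[VarianceComponents, np.ndarray, np.ndarray]:
    """REML for a mixed model with independent iid random terms.

    Model: y = X beta + sum_k Z_k u_k + e, u_k ~ N(0, sigma_k^2 I).
    EM iterations on Henderson's mixed-model equations until the relative
    change of every component is below ``tol`` (or ``max_iter``), then an
    average-information polish guarded by the REML log-likelihood.

    Returns (variance components incl. 'residual', beta hat, cov(beta hat)).
    Non-convergence is flagged, not raised; a singular fixed design raises.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed design is rank-deficient (aliased columns)")
    names = list(Zs.keys())
    Zmats = [np.asarray(Zs[k], float) for k in names]
    qs = [Z.shape[1] for Z in Zmats]
    if not names:  # no random terms: plain OLS
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2 = float(r @ r) / (n - p)
        covb = s2 * np.linalg.pinv(X.T @ X)
        ll = -0.5 * ((n - p) * (np.log(max(s2, 1e-300)) + 1.0))
        return VarianceComponents({"residual": s2}, float(ll), True, 0), beta, covb
    vary = float(np.var(y))
    if vary == 0:
        comps = {k: 0.0 for k in names}
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return (
            VarianceComponents({**comps, "residual": 0.0}, 0.0, True, 0),
            beta,
            np.zeros((p, p)),
        )
    # keeps V invertible when a component collapses (e.g. duplicate plots)
    floor = 1e-6 * vary
    comps = {k: vary / (len(names) + 1) for k in names}
    sige = vary / (len(names) + 1)

    Zall = np.hstack(Zmats) if Zmats else np.zeros((n, 0))
    qtot = Zall.shape[1]
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Zall, Zall.T @ Zall
    Xty, Zty = X.T @ y, Zall.T @ y
    offs = np.cumsum([0] + qs)

    converged = False
    it = 0
    # EM is reliable but linearly convergent; when the AI polish will run,
    # hand over after a moderate number of sweeps instead of grinding to tol
    em_cap = min(max_iter, 60) if ai_polish else max_iter
    for it in range(1, em_cap + 1):
        Dinv = np.concatenate(
            [np.full(q, sige / max(comps[k], floor)) for k, q in zip(names, qs)]
        ) if qtot else np.zeros(0)
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(Dinv)]])
        rhs = np.concatenate([Xty, Zty])
        Minv = np.linalg.inv(M)
        sol = Minv @ rhs
        beta, u = sol[:p], sol[p:]
        new = {}
        for k, q, o in zip(names, qs, offs[:-1]):
            uk = u[o : o + q]
            Ckk = Minv[p + o : p + o + q, p + o : p + o + q]
            new[k] = max((uk @ uk + sige * np.trace(Ckk)) / q, floor)
        sige_new = max(float(y @ (y - X @ beta - Zall @ u)) / (n - p), floor)
        rel = max(
            [abs(new[k] - comps[k]) / max(comps[k], floor) for k in names]
            + [abs(sige_new - sige) / max(sige, floor)]
        )
        comps, sige = new, sige_new
        if rel < tol:
            converged = True
            break

    if ai_polish and n <= 4000:
        comps, sige, stationary = _ai_polish(y, X, Zmats, names, comps, sige, floor)
        converged = converged or stationary

    # GLS fixed effects and covariance at the converged components
    V = sige * np.eye(n)
    for k, Z in zip(names, Zmats):
        V += comps[k] * (Z @ Z.T)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        Vi = np.linalg.pinv(V)
    XtViX = X.T @ Vi @ X
    covb = np.linalg.pinv(XtViX)
    beta = covb @ (X.T @ Vi @ y)
    ll = _reml_loglik(y, X, dict(zip(names, Zmats)), comps, sige)
    out = {k: (0.0 if comps[k] <= 2 * floor else float(comps[k])) for k in names}
    out["residual"] = float(sige)
    return VarianceComponents(out, float(ll), converged, it), beta, covb


def _ai_polish(y, X, Zmats, names, comps, sige, floor, n_steps: int = 10):
    """A few average-information Newton steps, accepted only if REML logL rises."""
    theta = np.array([comps[k] for k in names] + [sige])
    Vks = [Z @ Z.T for Z in Zmats] + [np.eye(len(y))]
    Zdict = dict(zip(names, Zmats))

    def loglik(th):
        return _reml_loglik(y, X, Zdict, dict(zip(names, th[:-1])), th[-1])

    best = loglik(theta)
    stationary = False
    for _ in range(n_steps):
        V = sum(t * Vk for t, Vk in zip(theta, Vks))
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            break
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        Py = P @ y
        score = np.array(
            [-0.5 * (np.sum(P * Vk) - Py @ Vk @ Py) for Vk in Vks]
        )
        PVPy = [P @ (Vk @ Py) for Vk in Vks]
        AI = 0.5 * np.array([[Py @ Vk @ pv for pv in PVPy] for Vk in Vks])
        if np.max(np.abs(score)) < 1e-6 * max(abs(best), 1.0):
            stationary = True
            break
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(len(theta)), score)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(8):
            cand = np.maximum(theta + scale * step, floor)
            ll = loglik(cand)
            if np.isfinite(ll) and ll > best + 1e-12:
                theta, best, improved = cand, ll, True
                break
            scale /= 2.0
        if not improved:
            stationary = True  # no uphill step left along the AI direction
            break
    return dict(zip(names, theta[:-1])), float(theta[-1]), stationary


# ---------------------------------------------------------------------------
# Design helpers


def _one_hot(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(values.unique())
    idx = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), [idx[v] for v in values]] = 1.0
    return Z, levels


def _ref_coded(values: pd.Series) -> np.ndarray:
    """Reference-level dummy columns (first level dropped); genotype effects
    are then anchored to the reference block/trial, so a shift confined to a
    non-reference level is absorbed entirely by that level's dummy."""
    Z, levels = _one_hot(values)
    return Z[:, 1:] if len(levels) > 1 else np.zeros((len(values), 0))


# ---------------------------------------------------------------------------
# BLUEs


def blues_within_trial(
    plots: pd.DataFrame,
    remove_outliers: bool = False,
    outlier_z: float = 3.5,
    check_genotypes: list[str] | None = None,
    fit_rows_cols: bool = True,
) -> pd.DataFrame:
    """Within-trial genotype BLUEs from a row-column model.

    Fixed: genotype and (sum-to-zero) complete-block effects.  Random:
    rows-within-block and columns-within-block.  Plots with standardized
    conditional residual beyond ``outlier_z`` are flagged (and refit without,
    when ``remove_outliers``).  Check genotypes participate in the fit but are
    dropped from the output.

    Returns columns: trial, genotype, blue, se, n_outliers.
    """
    trials = plots["trial"].unique()
    if len(trials) != 1:
        raise ValueError("blues_within_trial expects a single trial's plots")
    df = plots.reset_index(drop=True)

    def fit(d):
        G, glevels = _one_hot(d["genotype"])
        B = _ref_coded(d["block"].astype(str))
        X = np.hstack([G, B])
        if fit_rows_cols:
            rb = (d["block"].astype(str) + ":" + d["row"].astype(str))
            cb = (d["block"].astype(str) + ":" + d["col"].astype(str))
            Zs = {"row": _one_hot(rb)[0], "col": _one_hot(cb)[0]}
        else:
            Zs = {}
        vc, beta, covb = fit_lmm_reml(d["value"].to_numpy(), X, Zs)
        return vc, beta, covb, X, Zs, glevels, G.shape[1]

    vc, beta, covb, X, Zs, glevels, g = fit(df)
    resid = _conditional_residuals(df["value"].to_numpy(), X, beta, Zs, vc)
    scale = np.sqrt(max(vc["residual"], 1e-12))
    zscores = resid / scale
    out_mask = np.abs(zscores) > outlier_z
    n_out = int(out_mask.sum())
    if remove_outliers and n_out:
        kept = df.loc[~out_mask]
        dropped_gen = set(df["genotype"]) - set(kept["genotype"])
        if dropped_gen:
            import warnings

            warnings.warn(f"genotypes lost to outlier removal: {sorted(dropped_gen)}")
        vc, beta, covb, X, Zs, glevels, g = fit(kept.reset_index(drop=True))

    ses = np.sqrt(np.clip(np.diag(covb)[:g], 0, None))
    res = pd.DataFrame(
        {
            "trial": trials[0],
            "genotype": glevels,
            "blue": beta[:g],
            "se": ses,
            "n_outliers": n_out,
        }
    )
    if check_genotypes:
        res = res[~res["genotype"].isin(check_genotypes)].reset_index(drop=True)
    return res


def _conditional_residuals(y, X, beta, Zs, vc):
    n = len(y)
    V = max(vc["residual"], 1e-12) * np.eye(n)
    for name, Z in Zs.items():
        V += vc[name] * (Z @ Z.T)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        Vi = np.linalg.pinv(V)
    r = y - X @ beta
    e = vc["residual"] * (Vi @ r)  # conditional (residual-term) residuals
    return e


def blues_across_trials(within: pd.DataFrame) -> pd.DataFrame:
    """Across-trial BLUEs: fixed trial (sum-to-zero) + genotype on within-trial BLUEs.

    Only the residual is random, so this is ordinary least squares.  A
    genotype present in a single trial is retained with a larger SE (warned).
    """
    if within["trial"].nunique() < 2:
        raise ValueError("need BLUEs from at least two trials")
    counts = within.groupby("genotype")["trial"].nunique()
    singles = counts[counts == 1].index.tolist()
    if singles:
        import warnings

        warnings.warn(f"genotypes observed in a single trial: {singles[:5]}")
    G, glevels = _one_hot(within["genotype"])
    T = _ref_coded(within["trial"])
    X = np.hstack([G, T])
    y = within["blue"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(r @ r) / dof
    covb = s2 * np.linalg.pinv(X.T @ X)
    g = len(glevels)
    return pd.DataFrame(
        {
            "genotype": glevels,
            "blue": beta[:g],
            "se": np.sqrt(np.clip(np.diag(covb)[:g], 0, None)),
        }
    )


# ---------------------------------------------------------------------------
# Heritability


def fit_h2_model(within: pd.DataFrame) -> VarianceComponents:
    """Variance components for the multi-environment genotype-mean model.

    Response: within-trial BLUEs with ``location`` and ``year`` columns.
    Fixed: trial (saturating location + year + their interaction); random:
    genotype, genotype x location, genotype x year; residual = genotype x
    location x year.
    """
    need = {"genotype", "location", "year", "blue"}
    if not need <= set(within.columns):
        raise ValueError(f"need columns {need}")
    X = np.hstack(
        [np.ones((len(within), 1)), _ref_coded(within["location"].astype(str) + ":" + within["year"].astype(str))]
    )
    Zs = {
        "g": _one_hot(within["genotype"])[0],
        "gL": _one_hot(within["genotype"].astype(str) + ":" + within["location"].astype(str))[0],
        "gT": _one_hot(within["genotype"].astype(str) + ":" + within["year"].astype(str))[0],
    }
    vc, _, _ = fit_lmm_reml(within["blue"].to_numpy(), X, Zs)
    return vc


def heritability(vc: VarianceComponents | dict, l: int, t: int) -> float:
    """Broad-sense heritability on a genotype-mean basis across l x t trials."""
    c = vc.components if isinstance(vc, VarianceComponents) else vc
    sg, sgl, sgt, se = (c.get(k, 0.0) for k in ("g", "gL", "gT", "residual"))
    if min(sg, sgl, sgt, se) < 0 or l < 1 or t < 1:
        raise ValueError("components must be >= 0 and l, t >= 1")
    denom = sg + sgl / l + sgt / t + se / (l * t)
    if denom == 0:
        raise ValueError("all variance components are zero; H^2 undefined")
    return sg / denom
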
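"""Synthetic autotetraploid populations, GBS read counts and field trials.

The generator produces exactly the statistical structure the analysis modules
assume, so the full pipeline is testable without any external data:

* population: per-subpopulation allele frequencies drift from a common
  ancestral frequency under a Balding-Nichols F-model (Beta distributed with
  Var = F p (1-p)); individual dosages are Binomial(4, p_subpop) draws.
  Weak ``structure_strength`` mimics a diversity panel of market classes
  whose pairwise differentiation is small.
* read counts: total depth per cell uniform over a depth band (optionally
  negative binomial); alternative reads Binomial(depth, f'(x)) with
  f'(x) = (x/4)(1-e) + (1-x/4)e -- the exact inverse of the dosage caller's
  likelihood.
* phenotypes: genotypic values from additive, simplex-dominance,
  duplex-dominance and additive-x-additive QTL (each component rescaled to
  its target variance); plot values add genotype-by-location,
  genotype-by-year, per-trial genotype residual, block/row/column field
  trends and plot noise over a row-column design with complete blocks
  (one plot per genotype per block).

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dosage import PLOIDY, DosageMatrix, ReadCountSet

__all__ = [
    "SimulationConfig",
    "TraitSpec",
    "FieldLayoutSpec",
    "SimulationTruth",
    "simulate_dosages",
    "simulate_read_counts",
    "simulate_phenotypes",
    "simulate_population",
]


@dataclass
class TraitSpec:
    """Variance targets and QTL architecture for one simulated trait.

    Variances are on the trait scale (arbitrary units); ``var_dominance`` is
    simplex dominance (effect switched on by >= 1 copy of the alternative
    allele), ``var_duplex_dominance`` by >= 2 copies.  ``var_residual`` is the
    per-trial genotype residual (the genotype x location x year term that the
    heritability model calls sigma_eps^2).
    """

    name: str = "trait"
    var_additive: float = 1.0
    var_dominance: float = 0.0
    var_duplex_dominance: float = 0.0
    var_epistatic_AxA: float = 0.0
    var_GxL: float = 0.0
    var_GxT: float = 0.0
    var_residual: float = 1.0
    n_qtl_additive: int = 100
    n_qtl_dominance: int = 20
    architecture: str = "polygenic"

    def __post_init__(self) -> None:
        for f_ in (
            self.var_additive,
            self.var_dominance,
            self.var_duplex_dominance,
            self.var_epistatic_AxA,
            self.var_GxL,
            self.var_GxT,
            self.var_residual,
        ):
            if not np.isfinite(f_) or f_ < 0:
                raise ValueError("variance components must be finite and >= 0")
        if self.architecture not in ("polygenic", "oligogenic"):
            raise ValueError("architecture must be 'polygenic' or 'oligogenic'")

    @property
    def genetic_variance(self) -> float:
        return (
            self.var_additive
            + self.var_dominance
            + self.var_duplex_dominance
            + self.var_epistatic_AxA
        )


@dataclass
class FieldLayoutSpec:
    """Multi-environment row-column trial layout with complete blocks."""

    n_locations: int = 3
    n_years: int = 2
    n_blocks: int = 2
    rows: int = 15
    cols: int = 10
    var_block: float = 0.0
    var_row: float = 0.0
    var_col: float = 0.0
    var_plot: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.var_block, self.var_row, self.var_col, self.var_plot):
            if not np.isfinite(v) or v < 0:
                raise ValueError("layout variances must be finite and >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_locations * self.n_years

    def check_capacity(self, n_individuals: int) -> None:
        if self.rows * self.cols < n_individuals:
            raise ValueError(
                f"block of {self.rows}x{self.cols} plots cannot hold "
                f"{n_individuals} genotypes"
            )


@dataclass
class SimulationConfig:
    """Population, genotyping and trait settings for one synthetic study."""

    n_individuals: int = 147
    n_markers: int = 2000
    n_chromosomes: int = 12
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_subpops: int = 4
    structure_strength: float = 0.01
    depth_range: tuple[int, int] = (10, 100)
    seq_error: float = 0.002
    trait_specs: list[TraitSpec] = field(default_factory=lambda: [TraitSpec()])
    layout: FieldLayoutSpec = field(default_factory=FieldLayoutSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        dlo, dhi = self.depth_range
        if not (1 <= dlo <= dhi <= 10000):
            raise ValueError("depth_range must lie within [1, 10000]")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.n_subpops > self.n_individuals:
            raise ValueError("n_subpops cannot exceed n_individuals")
        if self.structure_strength < 0:
            raise ValueError("structure_strength must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated trait for recovery tests."""

    trait: str
    qtl_positions: dict[str, list]
    qtl_effects: dict[str, list[float]]
    true_genotypic_values: np.ndarray
    realized_components: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "trait": self.trait,
            "qtl_positions": self.qtl_positions,
            "qtl_effects": self.qtl_effects,
            "true_genotypic_values": list(map(float, self.true_genotypic_values)),
            "realized_components": self.realized_components,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def simulate_dosages(config: SimulationConfig) -> tuple[DosageMatrix, np.ndarray]:
    """Draw a structured tetraploid population; returns dosages + subpop labels.

    Ancestral frequencies are uniform over ``allele_freq_range``; with
    ``structure_strength`` F > 0 each subpopulation's frequency is a
    Beta(p(1-F)/F, (1-p)(1-F)/F) draw (mean p, variance F p(1-p)); with F = 0
    all subpopulations share the ancestral frequency.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    p0 = rng.uniform(*config.allele_freq_range, size=m)
    F = config.structure_strength
    if F > 0:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        psub = rng.beta(a, b, size=(config.n_subpops, m))
    else:
        psub = np.tile(p0, (config.n_subpops, 1))
    psub = np.clip(psub, 1e-6, 1.0 - 1e-6)
    labels = rng.integers(0, config.n_subpops, size=n)
    X = rng.binomial(PLOIDY, psub[labels, :]).astype(float)

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = (np.arange(m) // per_chrom + 1).astype(str)
    pos = np.arange(m) % per_chrom + 1
    markers = pd.DataFrame(
        {"marker": [f"M{j + 1}" for j in range(m)], "chrom": chrom, "pos": pos}
    )
    ids = [f"G{i + 1:03d}" for i in range(n)]
    return DosageMatrix(ids, markers, X), labels


def simulate_read_counts(
    dosages: DosageMatrix,
    depth_range: tuple[int, int] = (10, 100),
    seq_error: float = 0.002,
    seed: int = 0,
    depth_dist: str = "uniform",
) -> ReadCountSet:
    """GBS-like read counts from true dosages (inverse of the dosage caller).

    Total depth per cell is uniform over ``depth_range`` (or negative binomial
    with the same mean when ``depth_dist='negbin'``); alternative-read counts
    are Binomial(depth, f'(x)) with the error-perturbed allele fraction f'.
    """
    if not dosages.is_complete:
        raise ValueError("read-count simulation requires complete dosages")
    rng = np.random.default_rng(seed)
    X = dosages.dosages
    lo, hi = depth_range
    if depth_dist == "uniform":
        depth = rng.integers(lo, hi + 1, size=X.shape)
    elif depth_dist == "negbin":
        mean = (lo + hi) / 2.0
        r = 5.0  # moderate overdispersion
        depth = np.clip(rng.negative_binomial(r, r / (r + mean), size=X.shape), 1, None)
    else:
        raise ValueError("depth_dist must be 'uniform' or 'negbin'")
    f = (X / PLOIDY) * (1.0 - seq_error) + (1.0 - X / PLOIDY) * seq_error
    alt = rng.binomial(depth, f)
    return ReadCountSet(
        list(dosages.individuals), dosages.markers.copy(), depth - alt, alt
    )


def _scaled_component(values: np.ndarray, target_var: float) -> np.ndarray:
    """Centre and rescale a genetic component to hit its variance target exactly."""
    v = values - values.mean()
    s = v.var()
    if target_var == 0:
        return np.zeros_like(v)
    if s <= 0:
        raise ValueError("component has zero realized variance; cannot scale")
    return v * np.sqrt(target_var / s)


def simulate_genotypic_values(
    dosages: DosageMatrix, trait: TraitSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict, dict, dict]:
    """Sum of additive, simplex/duplex-dominance and AxA components.

    Dominance truth uses the gene-action codings of the association scan
    (0/4 switch at >= 1 or >= 2 alternative copies), centred at realized
    frequencies; each component is rescaled so its realized variance equals
    the TraitSpec target.
    """
    X = dosages.dosages
    n, m = X.shape
    n_add = m if trait.architecture == "polygenic" else min(trait.n_qtl_additive, m)
    n_dom = min(trait.n_qtl_dominance, m)

    positions: dict[str, list] = {}
    effects: dict[str, list] = {}
    gv = np.zeros(n)

    def add_component(key, qtl, covs, var):
        if var <= 0 or len(qtl) == 0:
            return
        b = rng.standard_normal(len(qtl))
        comp = _scaled_component((covs - covs.mean(axis=0)) @ b, var)
        positions[key] = [int(q) if np.ndim(q) == 0 else list(map(int, q)) for q in qtl]
        effects[key] = list(map(float, b))
        nonlocal gv
        gv = gv + comp

    if trait.var_additive > 0:
        qtl = rng.choice(m, size=n_add, replace=False)
        add_component("additive", qtl, X[:, qtl], trait.var_additive)
    if trait.var_dominance > 0:
        qtl = rng.choice(m, size=n_dom, replace=False)
        add_component("simplex_dominance", qtl, np.where(X[:, qtl] >= 1, 4.0, 0.0),
                      trait.var_dominance)
    if trait.var_duplex_dominance > 0:
        qtl = rng.choice(m, size=n_dom, replace=False)
        add_component("duplex_dominance", qtl, np.where(X[:, qtl] >= 2, 4.0, 0.0),
                      trait.var_duplex_dominance)
    if trait.var_epistatic_AxA > 0:
        n_pairs = max(n_dom, 2)
        pairs = [tuple(rng.choice(m, size=2, replace=False)) for _ in range(n_pairs)]
        Xc = X - X.mean(axis=0)
        covs = np.column_stack([Xc[:, a] * Xc[:, b] for a, b in pairs])
        add_component("epistatic_AxA", pairs, covs, trait.var_epistatic_AxA)

    realized = {
        "genetic": float(np.var(gv)),
        "additive_target": trait.var_additive,
        "dominance_target": trait.var_dominance,
        "duplex_target": trait.var_duplex_dominance,
        "epistatic_target": trait.var_epistatic_AxA,
    }
    return gv, positions, effects, realized


def simulate_phenotypes(
    dosages: DosageMatrix,
    trait: TraitSpec,
    layout: FieldLayoutSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Plot-level phenotypes over a multi-environment row-column design.

    Each trial (location x year) has ``n_blocks`` complete blocks; every
    genotype occupies one randomly assigned plot per block.  Returns the tidy
    plot table (trial, location, year, block, row, col, genotype, trait,
    value) and a truth record.
    """
    layout.check_capacity(len(dosages.individuals))
    rng = np.random.default_rng(seed)
    gv, positions, effects, realized = simulate_genotypic_values(dosages, trait, rng)
    ids = dosages.individuals
    n = len(ids)

    gxl = rng.normal(0, np.sqrt(trait.var_GxL), size=(n, layout.n_locations)) \
        if trait.var_GxL > 0 else np.zeros((n, layout.n_locations))
    gxt = rng.normal(0, np.sqrt(trait.var_GxT), size=(n, layout.n_years)) \
        if trait.var_GxT > 0 else np.zeros((n, layout.n_years))

    rows = []
    for li in range(layout.n_locations):
        for ti in range(layout.n_years):
            trial = f"L{li + 1}Y{ti + 1}"
            g_trial = rng.normal(0, np.sqrt(trait.var_residual), size=n) \
                if trait.var_residual > 0 else np.zeros(n)
            for b in range(layout.n_blocks):
                beff = rng.normal(0, np.sqrt(layout.var_block)) if layout.var_block > 0 else 0.0
                reff = rng.normal(0, np.sqrt(layout.var_row), size=layout.rows) \
                    if layout.var_row > 0 else np.zeros(layout.rows)
                ceff = rng.normal(0, np.sqrt(layout.var_col), size=layout.cols) \
                    if layout.var_col > 0 else np.zeros(layout.cols)
                order = rng.permutation(n)
                for slot, gi in enumerate(order):
                    r, c = divmod(slot, layout.cols)
                    noise = rng.normal(0, np.sqrt(layout.var_plot)) if layout.var_plot > 0 else 0.0
                    value = (
                        gv[gi] + gxl[gi, li] + gxt[gi, ti] + g_trial[gi]
                        + beff + reff[r] + ceff[c] + noise
                    )
                    rows.append(
                        (trial, f"L{li + 1}", f"Y{ti + 1}", b + 1, r + 1, c + 1,
                         ids[gi], trait.name, value)
                    )
    plots = pd.DataFrame(
        rows,
        columns=["trial", "location", "year", "block", "row", "col",
                 "genotype", "trait", "value"],
    )
    truth = SimulationTruth(
        trait=trait.name,
        qtl_positions=positions,
        qtl_effects=effects,
        true_genotypic_values=gv,
        realized_components=realized,
    )
    return plots, truth


def simulate_population(config: SimulationConfig):
    """End-to-end draw: dosages + labels, read counts, and per-trait phenotypes.

    Returns (dosages, labels, counts, {trait name: (plot table, truth)}).
    Sub-seeds are derived deterministically from ``config.seed``.
    """
    dosages, labels = simulate_dosages(config)
    counts = simulate_read_counts(
        dosages, config.depth_range, config.seq_error, seed=config.seed + 1
    )
    phenos = {}
    for k, trait in enumerate(config.trait_specs):
        phenos[trait.name] = simulate_phenotypes(
            dosages, trait, config.layout, seed=config.seed + 100 + k
        )
    return dosages, labels, counts, phenos
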
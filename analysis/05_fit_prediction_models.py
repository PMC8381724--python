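"""Fit all eight whole-genome prediction models to the adjusted means.

Kernel mixed models (Add, A+D, A+D+Ep, FT) by Gibbs sampling, RKHS by
profile-likelihood bandwidth selection, and the three Bayesian marker-effect
regressions (BayesA, BayesCpi, BayesL).  Reports variance components,
training-set fit and, for BayesCpi, the estimated zero-effect proportion pi.

Writes results/model_fits.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import tetragp as tg
from tetragp.dosage import DosageMatrix
from tetragp.gp_models import (
    GibbsConfig,
    fit_bayes_marker,
    fit_kernel_gblup,
    fit_rkhs_ml,
    kernels_for_model,
)

OUT = Path(__file__).resolve().parent.parent / "results"
TRAIT = "tuber_count"

dm = DosageMatrix.from_tsv(OUT / "dosages_called.tsv")
blues = pd.read_csv(OUT / "blues.tsv", sep="\t").query("trait == @TRAIT")
y = blues.set_index("genotype").loc[dm.individuals, "blue"].to_numpy()

cfg = GibbsConfig(n_iter=3000, burn_in=1000, seed=21)
Xc = dm.dosages - 4 * dm.allele_freq

rows = []
for model in ["Add", "A+D", "A+D+Ep", "FT"]:
    fit = fit_kernel_gblup(y, kernels_for_model(model, dm), cfg)
    rows.append((model, fit.varcomps, np.corrcoef(fit.gvalues, y)[0, 1], None))
fit = fit_rkhs_ml(y, dm)
rows.append(("RKHS", fit.varcomps, np.corrcoef(fit.gvalues, y)[0, 1], fit.theta))
for prior in ["BayesA", "BayesCpi", "BayesL"]:
    fit = fit_bayes_marker(y, Xc, prior, cfg, individuals=dm.individuals)
    extra = fit.pi if prior == "BayesCpi" else fit.lambda_
    rows.append((prior, fit.varcomps, np.corrcoef(fit.gvalues, y)[0, 1], extra))

table = pd.DataFrame(
    [(m, round(fitcor, 3),
      "; ".join(f"{k}={v:.3f}" for k, v in vc.items()), extra)
     for m, vc, fitcor, extra in rows],
    columns=["model", "train_fit_r", "variance_components", "extra"],
)
table.to_csv(OUT / "model_fits.tsv", sep="\t", index=False)
print(table.to_string(index=False))
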
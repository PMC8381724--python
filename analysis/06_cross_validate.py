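"""Repeated cross-validation of the main prediction models.

105-individual training sets (of 147), validation on the remaining 42, with
both random and CDmean-optimised selection for the additive model; accuracy
is the Pearson correlation between validation adjusted means and predicted
genotypic values.  Repetitions are kept modest here (10) to keep the driver
quick; the scheme scales to the conventional 100.

Writes results/cv_results.tsv.
"""

from pathlib import Path

import pandas as pd

from tetragp.crossval import CVScheme, run_cv
from tetragp.dosage import DosageMatrix
from tetragp.gp_models import GibbsConfig

OUT = Path(__file__).resolve().parent.parent / "results"
TRAIT = "tuber_count"

dm = DosageMatrix.from_tsv(OUT / "dosages_called.tsv")
blues = pd.read_csv(OUT / "blues.tsv", sep="\t").query("trait == @TRAIT")
y = blues.set_index("genotype").loc[dm.individuals, "blue"].to_numpy()

cfg = GibbsConfig(n_iter=1500, burn_in=500, seed=31)
rows = []
for model in ["Add", "A+D", "RKHS", "BayesCpi"]:
    res = run_cv(y, dm, model, CVScheme(105, 10, "random", seed=31), cfg)
    rows.append((model, "random", res.mean, res.se, res.n_failed))
    print(f"{model:9s} random  accuracy {res.mean:.3f} +/- {res.se:.3f}")
res = run_cv(y, dm, "Add",
             CVScheme(105, 3, "cdmean", seed=31, cd_starts=1, cd_candidates=400),
             cfg)
rows.append(("Add", "cdmean", res.mean, res.se, res.n_failed))
print(f"Add       cdmean  accuracy {res.mean:.3f} +/- {res.se:.3f}")

pd.DataFrame(rows, columns=["model", "selector", "accuracy", "se", "failed"]) \
    .to_csv(OUT / "cv_results.tsv", sep="\t", index=False)
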
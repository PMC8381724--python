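"""Population-structure descriptors of the simulated panel.

PCA of the additive relationship matrix (first components feed the GWAS
variance-explained regression) and pairwise Weir-Cockerham F_ST between the
simulated subpopulations.

Writes results/pca_scores.tsv and results/fst_pairwise.tsv.
"""

from pathlib import Path

import pandas as pd

from tetragp.dosage import DosageMatrix
from tetragp.popstruct import fst_pairwise, pca_dosage

OUT = Path(__file__).resolve().parent.parent / "results"

dm = DosageMatrix.from_tsv(OUT / "dosages_called.tsv")
labels = pd.read_csv(OUT / "subpop_labels.tsv", sep="\t") \
    .set_index("individual").loc[dm.individuals, "group"].to_numpy()

res = pca_dosage(dm)
pd.DataFrame(res.scores, index=res.individuals,
             columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])]) \
    .to_csv(OUT / "pca_scores.tsv", sep="\t", index_label="individual")
print("explained variance fractions:",
      ", ".join(f"{e:.3f}" for e in res.explained[:5]))

fst = fst_pairwise(dm, labels)
fst.to_csv(OUT / "fst_pairwise.tsv", sep="\t", index=False)
print(fst.to_string(index=False))
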
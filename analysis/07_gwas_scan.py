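"""Association scans under the five gene-action codings.

P3D mixed-model scans of the dominance-architecture trait under additive,
simplex and duplex codings (both allele orientations), the Li-Ji effective
test count and genome-wide threshold, QQ-calibration diagnostics, and the
nested variance-explained regression on significant markers plus the first
three principal components.

Writes results/gwas_scans.tsv and results/variance_explained.tsv.
"""

from pathlib import Path

import pandas as pd

import tetragp as tg
from tetragp.dosage import DosageMatrix
from tetragp.gwas import CODINGS, code_markers, inflation, li_ji_meff, scan, threshold
from tetragp.kinship import additive_G
from tetragp.popstruct import pca_dosage

OUT = Path(__file__).resolve().parent.parent / "results"
TRAIT = "tuber_count"

dm = DosageMatrix.from_tsv(OUT / "dosages_called.tsv")
blues = pd.read_csv(OUT / "blues.tsv", sep="\t").query("trait == @TRAIT")
y = blues.set_index("genotype").loc[dm.individuals, "blue"].to_numpy()

GA = additive_G(dm)
meff = li_ji_meff(dm.dosages)
thr = threshold(0.05, meff)
print(f"Li-Ji effective tests: {meff:.1f} of {dm.dosages.shape[1]} markers "
      f"-> threshold -log10 p = {thr}")

tables, sig_sets = [], {}
for coding in CODINGS:
    coded = code_markers(dm, coding)
    res = scan(y, coded, GA, meff=meff)
    tables.append(res.table)
    diag = inflation(res.scores)
    sig = res.table["significant"].to_numpy()
    sig_sets[coding] = coded.values[:, sig]
    print(f"{coding:10s} significant: {sig.sum():3d}  "
          f"lambda_GC {diag['lambda_gc']:.2f}  qq slope {diag['qq_slope']:.2f}")
pd.concat(tables, ignore_index=True).to_csv(OUT / "gwas_scans.tsv",
                                            sep="\t", index=False)

pcs = pca_dosage(dm, n_components=3).scores
r2 = tg.variance_explained(y, pcs, sig_sets)
r2["r2_percent"] = (100 * r2["r2"]).round(2)
r2.to_csv(OUT / "variance_explained.tsv", sep="\t", index=False)
print(r2.to_string(index=False))
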
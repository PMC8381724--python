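"""Build the four autotetraploid relationship matrices and an RKHS kernel.

Additive (VanRaden at ploidy 4), digenic dominance, AxA epistasis (Hadamard
square) and full-tetraploid class-indicator matrices from the called
dosages, plus the Gaussian kernel at theta = 1.

Writes results/kinship_<flavor>.tsv.
"""

from pathlib import Path

import numpy as np

import tetragp as tg
from tetragp.dosage import DosageMatrix

OUT = Path(__file__).resolve().parent.parent / "results"

dm = DosageMatrix.from_tsv(OUT / "dosages_called.tsv")
GA = tg.additive_G(dm)
mats = [GA, tg.dominance_G(dm), tg.epistasis_G(GA),
        tg.full_tetraploid_G(dm), tg.rkhs_kernel(dm, theta=1.0)]
for K in mats:
    K.to_tsv(OUT / f"kinship_{K.flavor}.tsv")
    off = K.values[~np.eye(K.n, dtype=bool)]
    print(f"{K.flavor:18s} mean diag {np.mean(np.diag(K.values)):.3f}  "
          f"off-diag range [{off.min():.3f}, {off.max():.3f}]")
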
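"""Generalized Procrustes analysis with semilandmark sliding.

Simulates raw digitized specimens of a 36-point humerus-like outline
(22 fixed landmarks + 14 semilandmarks), superimposes them under both
sliding criteria, and compares the residual variation.
"""

import numpy as np

from gmorpho import gpa
from gmorpho.synthetic import GeneratorConfig, simulate_dataset

cfg = GeneratorConfig(seed=42, templates=("humerus36",), balanced=True,
                      n_per_species=3, n_species=12, n_subterranean=6)
ds = simulate_dataset(cfg)
specimens = ds.specimens["humerus36"]
sliders = ds.structures["humerus36"].sliders
print(f"{len(specimens)} raw specimens, k = {specimens[0].k} landmarks, "
      f"{len(sliders)} semilandmarks")

for method in ("none", "BEN", "PRD"):
    aligned = gpa(specimens, sliders=sliders,
                  method=method if method != "none" else "none")
    resid = ((aligned.shapes - aligned.consensus) ** 2).sum(axis=(1, 2))
    print(f"sliding={method:4s}  mean squared residual from consensus = "
          f"{resid.mean():.6f}  (converged: {aligned.converged})")

# Sliding moves semilandmarks along the outline to geometric correspondence,
# so the residual with BEN/PRD is at most that of the unslid fit; centroid
# sizes always come from the raw specimens.
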
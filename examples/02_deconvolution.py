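"""Recover immune-cell fractions from bulk mixtures with nu-SVR.

Builds noiseless and noisy mixtures of the 22-type reference signature and
measures how close the estimated fractions come to the mixing weights used
to build them.
"""

import numpy as np
import pandas as pd

import ticscore as ts

signature = ts.make_signature(seed=1)
rng = np.random.default_rng(0)

for noise_sd in (0.0, 0.3):
    errors = []
    for _ in range(10):
        w = rng.dirichlet(np.ones(22))
        mix = pd.Series(signature.values.to_numpy() @ w, index=signature.gene_ids)
        mix *= np.exp(rng.normal(0, noise_sd, len(mix)))
        fractions, diag = ts.deconvolve_sample(mix, signature)
        errors.append(np.abs(fractions.to_numpy() - w).mean())
    print(f"noise_sd={noise_sd}: mean absolute fraction error "
          f"{np.mean(errors):.4f} over 10 mixtures")

print("\nA mean absolute error of 0.01 means each of the 22 estimated")
print("fractions is off by about one percentage point on average.")
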
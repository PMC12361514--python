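"""Generate a synthetic factorial dataset and check estimator recovery.

The generator evaluates a known quadratic truth on the 3x3x3 design and
adds Gaussian replicate noise at the assay's dispersion scale; the fit
should then recover the true coefficients within sampling error.
"""

import numpy as np

import extractopt as eo
from extractopt.rsm import QuadraticModel
from extractopt.synthetic import NoiseSpec, TrueSurface, generate_ffd

truth = QuadraticModel(
    b0=8.4,
    b_lin=(-0.52, -0.43, 0.0),
    b_int=(-0.07, 0.0, 0.0),
    b_quad=(-1.65, -0.98, 0.0),
)

errors = []
for seed in range(50):
    ds = generate_ffd(TrueSurface(truth), NoiseSpec(sigma=0.03, seed=seed))
    fit, _ = eo.fit_quadratic(ds)
    errors.append(fit.coefficients - truth.coefficients)
errors = np.array(errors)

print("coefficient recovery over 50 simulations (sigma = 0.03, n = 3):")
print(f"  max |bias|      = {np.abs(errors.mean(axis=0)).max():.4f}")
print(f"  max coord RMSE  = {np.sqrt((errors**2).mean(axis=0)).max():.4f}")
# Bias is negligible and RMSE ~0.01 on coefficients of order 0.5-1.7:
# the design identifies the quadratic comfortably at assay noise levels.
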
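"""Classify the trajectory shapes implied by dynamic parameters.

The sign of the self-feedback beta decides decelerated (beta < 0) versus
accelerated (beta > 0) change; growth versus decline depends on whether
the asymptote mu_a / (-beta) lies above or below the initial level.  In
coupled bivariate systems the eigenvalues of I + A take over: a complex
pair means the mean trajectories oscillate.
"""

import numpy as np

from latentchange import ParameterSet, classify_bivariate, classify_univariate
from latentchange.simulate import TABLE1_DYNAMICS, fixture_config

print("univariate: same additive component, initial level above/below asymptote")
for mu0 in (0.0, 10.0):
    params = ParameterSet(
        mu0=[mu0], mua=[2.0], phi=np.eye(2), beta=[-0.4], theta=[[0.5]]
    )
    label = classify_univariate(params)
    print(f"  mu0={mu0:5.1f}  mua=2.0  beta=-0.4  asymptote=5.0  ->  {label.value}")

print("\nbivariate regimes (beta_x, beta_y, gamma_x, gamma_y):")
for column, dyn in TABLE1_DYNAMICS.items():
    _, params = fixture_config(f"table1_{column}")
    shape = classify_bivariate(params)
    kind = "oscillatory" if shape.oscillatory else "non-oscillatory"
    conv = "convergent" if shape.convergent else "divergent"
    print(
        f"  {column}: {str(dyn):28s} -> {kind:15s} {conv:10s} "
        f"modulus {shape.modulus:.3f}"
    )

print(
    "\nThe modulus is the largest eigenvalue magnitude of I + A: below 1 the"
    "\nmean trajectories settle, above 1 they explode."
)
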
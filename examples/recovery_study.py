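"""A small simulate-and-refit study of estimator quality.

Twenty panels of 300 individuals are drawn from a deterministic
univariate dual change model and refit; per-parameter bias, RMSE, and
coverage of the nominal 95% intervals summarize how well the sampling
design identifies each parameter.
"""

from latentchange import FitOptions, ModelSpec, ParameterSet, recovery_study

spec = ModelSpec(n_processes=1, n_occasions=5)
truth = ParameterSet(
    mu0=[2.0],
    mua=[3.0],
    phi=[[1.0, -0.1], [-0.1, 0.3]],
    beta=[-0.5],
    theta=[[0.5]],
)

report = recovery_study(
    spec, truth, n=300, reps=20, seed=42, options=FitOptions(n_starts=2)
)
print(report.table.round(4))
print(f"\nconvergence rate: {report.convergence_rate:.2f} "
      f"({report.n_converged}/{report.n_reps} replications)")
print(
    "\nBias within ~2 Monte-Carlo SEs of zero and coverage near 0.95 mean the"
    "\nestimator and its standard errors are trustworthy at this design."
)
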
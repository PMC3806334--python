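"""Check the estimators against simulated data with known truth.

Study tables are drawn from the two-level normal model (grand mean 0.3,
between-study SD 0.15, mixed effect-size types) and re-analyzed by the
full conversion-and-pooling pipeline.  The report shows how well the
random-effects machinery recovers the generating parameters.
"""

from metasynth import SimulationConfig, recovery_experiment

config = SimulationConfig(
    n_meta=3,
    studies_per_meta=30,
    theta=0.3,
    tau=0.15,
    effect_type_mix={"smd": 0.4, "log_or": 0.3, "r": 0.3},
    seed=11,
)
report = recovery_experiment(config, n_reps=200)

print(f"replicates:        {report['n_reps']}")
print(f"theta truth/bias:  {report['theta_true']:.3f} / {report['theta_bias']:+.4f}")
print(f"theta RMSE:        {report['theta_rmse']:.4f}")
print(f"tau^2 truth/bias:  {report['tau2_true']:.4f} / {report['tau2_bias']:+.5f}")
print(f"tau^2 RMSE:        {report['tau2_rmse']:.5f}")
print(f"95% CI coverage:   {report['ci_coverage']:.2f}")
print(f"max FEM two-step gap: {report['max_fem_two_step_gap']:.2e}")
print(
    "\nBias near zero and coverage near 0.95 say the pooled estimate and "
    "its Wald interval behave as advertised; the two-step gap being at "
    "machine precision is the fixed-effects equivalence theorem in action."
)
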
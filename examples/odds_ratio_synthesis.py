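"""Synthesize two meta-analytic odds ratios.

Two meta-analyses of graft failure after anterior cruciate ligament
reconstruction (hamstring vs bone-patellar-tendon-bone autografts) report
summary odds ratios with 95% confidence intervals.  Pooling happens on the
natural-log scale — estimates and limits are log-transformed, variances
derived from the log-scale interval widths — and the result is reported
back on the OR scale.
"""

from metasynth import datasets, synthesize_or_summaries

inputs = datasets.acl_odds_ratios()
for label, or_hat, lo, up in inputs:
    print(f"{label:>12}: OR = {or_hat:.2f}, 95% CI ({lo:.2f}, {up:.2f})")

res = synthesize_or_summaries([(o, lo, up) for _, o, lo, up in inputs])
lo, up = res.or_ci
print(
    f"\npooled log-OR = {res.estimate:.4f}, var = {res.variance:.4f}"
    f"\npooled OR     = {res.or_estimate:.4f}, 95% CI ({lo:.4f}, {up:.4f})"
)
print(
    "\nAn OR above 1 would mean more graft failures with hamstring "
    "autografts; the interval spans 1, so the combined evidence shows no "
    "significant difference, with a narrower interval than either source."
)
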
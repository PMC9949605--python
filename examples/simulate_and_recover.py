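"""Simulate a paired GWAS study with a known causal effect and recover it.

Generates summary statistics for 3 LD-correlated variants under a true causal
effect theta = 0.3 on the log-odds scale, at the real study sample sizes, then
estimates theta back with the correlated-instrument IVW.
"""

from cismr import SimConfig, harmonize, ivw_correlated, simulate_paired_studies

config = SimConfig(m=3, theta=0.3, ld_structure=("block", (3,), 0.84), seed=1)
exposure, outcome, truth = simulate_paired_studies(config)
harmonized = harmonize(exposure, outcome, truth.ld)
est = ivw_correlated(harmonized)

print(f"true theta      = {truth.theta:.3f} (log-odds per SD exposure)")
print(f"estimated theta = {est.beta_hat:.3f} (SE {est.se_hat:.3f})")
print(f"OR = {est.or_point:.2f}, 95% CI ({est.ci_low:.2f}; {est.ci_high:.2f})")
print("The estimate should land within sampling error of the truth; across "
      "many seeds its 95% CI covers theta about 95% of the time.")
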
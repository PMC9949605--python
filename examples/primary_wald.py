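"""Single-instrument drug-target MR: the Wald ratio for rs1800693.

Builds the published per-variant association tables (CRP exposure,
periodontitis outcome), harmonizes them, and estimates the effect of a 1-SD
increment in CRP — genetically proxied through the TNFR1-encoding gene region
— on periodontitis risk.
"""

from cismr import harmonize, published_study_fixture, wald_ratio

exposure, outcome, ld = published_study_fixture()
harmonized = harmonize(exposure, outcome, ld)
est = wald_ratio(harmonized.subset(["rs1800693"]))

print(f"Wald ratio (rs1800693): log-odds per SD CRP = {est.beta_hat:.4f} "
      f"(SE {est.se_hat:.4f})")
print(f"OR = {est.or_point:.2f}, 95% CI ({est.ci_low:.2f}; {est.ci_high:.2f}), "
      f"p = {est.pval:.2f}")
print("An OR near 1 with a CI spanning 1 means no detectable effect of "
      "genetically proxied TNFR1 inhibition on periodontitis risk.")
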
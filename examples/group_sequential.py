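"""Derive an error-spending group-sequential two-arm design and inspect its
stopping behaviour.

A three-look randomised trial comparing response rates 15% (control) versus
30% (experimental) at one-sided alpha 0.0025 and power 64%, with go/no-go
stopping permitted at every look.  Type-I and type-II error are spent
linearly in the information fraction (rho-family, rho = 1) and the futility
boundaries are binding.
"""

from devplan import (
    TwoArmHypotheses,
    derive_error_spending_design,
    drift_at,
    gs_expected_sample_size,
    stage_probabilities,
)

hyp = TwoArmHypotheses(p0=0.15, p1=0.30, alpha_r=0.0025, beta_r=0.36)
design = derive_error_spending_design(
    hyp, info_fractions=[1 / 3, 2 / 3, 1.0], rho=1.0
)

print(design.boundary_table().to_string(index=False))
print()

for label, pe in [("null (pE = pC = 0.15)", 0.15), ("alternative (pE = 0.30)", 0.30)]:
    drift = drift_at(0.15, pe, design.n_per_arm_max)
    probs = stage_probabilities(design, drift)
    en = gs_expected_sample_size(design, 0.15, pe)
    stops = ", ".join(
        f"look {k + 1}: go {g:.3f} / no-go {n:.3f}"
        for k, (g, n) in enumerate(zip(probs.go_by_stage, probs.nogo_by_stage))
    )
    print(f"{label}: E(N) = {en:.1f} patients")
    print(f"    {stops}")

# Under the null almost 80% of trials stop for futility at the first look
# (120 of a maximum 360 patients), which is why the expected commitment is
# only ~147 patients despite the larger maximum than a single-stage trial.
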
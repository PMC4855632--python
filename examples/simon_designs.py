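"""Search H0-optimal Simon two-stage designs for a single-arm phase II trial.

Scenario: a drug is uninteresting at a 15% response rate and worth pursuing
at 30%, tested at one-sided alpha 0.05 with 80% power.  We search the design
minimising the expected number of patients when the drug is inactive, with
and without an early stopping rule for efficacy.
"""

from devplan import (
    SingleArmHypotheses,
    search_simon_optimal,
    simon_operating_characteristics,
)

hyp = SingleArmHypotheses(p0=0.15, p1=0.30, alpha_s=0.05, beta_s=0.20)

for efficacy in (False, True):
    design = search_simon_optimal(hyp, efficacy_stopping=efficacy)
    oc0 = simon_operating_characteristics(design, hyp.p0)
    oc1 = simon_operating_characteristics(design, hyp.p1)
    label = "with early-go stopping" if efficacy else "futility stopping only"
    print(f"{design.notation():>18}  ({label})")
    print(
        f"    type-I error {oc0.reject_prob:.4f}, power {oc1.reject_prob:.4f}, "
        f"E(N | p0) = {oc0.expected_n:.1f}, E(N | p1) = {oc1.expected_n:.1f}"
    )

# The notation r1/n1 r/n means: stop for futility after n1 patients if
# responses <= r1; declare the drug active if total responses out of n
# exceed r.  (r1 e1)/n1 adds: stop early for efficacy if responses > e1.
# Early-go stopping barely changes the error rates but cuts the expected
# commitment when the drug works (here ~50 -> ~44 patients).
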
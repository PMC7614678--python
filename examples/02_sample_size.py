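"""Solve the ACC, ALC and APVC sample sizes for the expert-prior design.

With sigma0^2 = 0.35 known, the ACC and ALC coincide and have a closed
form.  With sigma0^2 unknown it carries an Inv-Gamma(c/2, cV/2) prior
(c = 5 here); the ACC and APVC substitute E[sigma0^2] while the ALC needs
an integer search.  Totals are for equal allocation across the two arms.
"""

from cpssd import (
    CriterionSpec,
    acc_known,
    acc_unknown,
    alc_unknown,
    apvc_known,
    apvc_unknown,
    get_scenario,
    variance_prior_from_collective,
)

prior = get_scenario("experts").collective_prior()
acc = CriterionSpec("acc", hpd_length=0.65, coverage=0.95)
alc = CriterionSpec("alc", hpd_length=0.65, coverage=0.95)
apvc = CriterionSpec("apvc", variance_target=0.03)

print(f"collective prior: N({prior.mean:.3f}, {prior.variance:.3f})")
print("known sigma0^2 = 0.35:")
print(f"  ACC (= ALC) total: {acc_known(prior, acc, 0.35).continuous_total:.1f}")
print(f"  APVC total:        {apvc_known(prior, apvc, 0.35).continuous_total:.1f}")

vp = variance_prior_from_collective(prior, c=5.0)
print(f"unknown sigma0^2 ~ Inv-Gamma({vp.c / 2:.3f}, {vp.scale:.3f}):")
print(f"  ACC total:  {acc_unknown(prior, acc, vp).continuous_total:.1f}")
print(f"  ALC total:  {alc_unknown(prior, alc, vp).integer_total} (integer search)")
print(f"  APVC total: {apvc_unknown(prior, apvc, vp).continuous_total:.1f}")
# The unknown-variance totals are smaller because the variance prior is
# anchored at the collective prior variance 0.154 < 0.35.
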
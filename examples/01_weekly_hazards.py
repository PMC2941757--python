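"""Weekly recovery and recurrence probabilities for a few entity profiles.

The recovery hazard declines with episode length (negative log-time
coefficient); the recurrence log-odds are constant per profile but vary
strongly across profiles through the published interaction terms.
"""

from mdesim import (
    AttributeProfile,
    published_recovery,
    published_recurrence,
    recovery_linear_predictor,
    recovery_probability,
    recurrence_linear_predictor,
    recurrence_probability,
)

recovery = published_recovery()
recurrence = published_recurrence()

print("Weekly recovery probability by episode week (published equation):")
for age in ("12-18", "66+"):
    profile = AttributeProfile(age)
    row = [
        recovery_probability(recovery_linear_predictor(profile, w, recovery))
        for w in (1, 4, 13, 52)
    ]
    print(f"  age {age:>5}: " + "  ".join(f"week {w:>2}: {p:.3f}" for w, p in zip((1, 4, 13, 52), row)))

print("\nWeekly recurrence probability by profile:")
for profile in (
    AttributeProfile("12-18"),
    AttributeProfile("12-18", childhood_stressor=True),
    AttributeProfile("66+"),
    AttributeProfile("66+", pain=True),
):
    lp = recurrence_linear_predictor(profile, recurrence)
    print(f"  {str(profile):>12}: log-odds {lp:+.3f}  ->  p = {recurrence_probability(lp):.5f}")

print(
    "\nA 12-18-year-old recovers with probability ~0.24 in the first week and"
    "\nmore slowly later; recurrence risks are small per week but compound"
    "\nover the 104 weeks between interviews."
)
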
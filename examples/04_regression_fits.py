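"""Fit the survey-side models to synthetic respondents with known truth.

Generates a respondent table from the published effect sizes (odds
ratio 2.0 for childhood stressor, ordinal coefficient 0.441 for age
46-65, etc.), fits the binary and ordinal logistic models, and runs
Brant's proportional-odds test.
"""

from mdesim import PopulationSpec, brant_test, fit_binary_logistic, fit_ordinal_logistic
from mdesim.synth import generate_survey

spec = PopulationSpec(n_respondents=20_000, seed=3)
survey = generate_survey(spec)

binary = fit_binary_logistic(survey)
print("Binary logistic model (consecutive past-year positivity):")
for term, orr in binary.odds_ratios.items():
    lo, hi = binary.conf_int[term]
    print(f"  {term:>20}: OR {orr:4.2f}  (95% CI {lo:4.2f} - {hi:4.2f})")

ordinal = fit_ordinal_logistic(survey)
print("\nOrdinal logistic model (weeks depressed in past year, 4 categories):")
for term, coef in ordinal.coefficients.items():
    print(f"  {term:>20}: coefficient {coef:+.3f}")
print(f"  cut points: {tuple(round(c, 3) for c in ordinal.cut_points)}")

brant = brant_test(survey)
print(
    f"\nBrant test of proportional odds: chi2 = {brant.chi_square:.2f}, "
    f"df = {brant.df}, p = {brant.p_value:.3f}"
)
print(
    "\nThe fitted odds ratios should straddle their generating values"
    "\n(1.5, 1.5, 2.0, 1.6); a non-significant Brant test is expected"
    "\nsince the generator satisfies proportional odds exactly."
)
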
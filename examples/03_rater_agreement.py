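"""Inter-rater agreement on a simulated two-rater rating table.

Simulates 80 neonates rated by two raters who agree on 90% of parameters,
then reports percent agreement, Cohen's kappa and PABAK per parameter.
With skewed prevalence (most parameters nearly always present or absent)
kappa drops while PABAK tracks the raw agreement — the reason both are
reported.
"""

from swallowsound.agreement import per_parameter_agreement
from swallowsound.synthetic_data import CohortSpec, generate_rating_pair

ratings = generate_rating_pair(CohortSpec(n_neonates=80, agreement=0.9,
                                          seed=1))
report = per_parameter_agreement(ratings)
print(report.round(3).to_string(index=False))
print()
print("percent_agreement is the raw proportion of matching ratings;")
print("kappa corrects for chance but sinks when prevalence is skewed")
print("(NaN when both raters are constant); pabak = 2*po - 1 is immune")
print("to prevalence, and 'band' is its qualitative reliability label.")
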
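"""Count-based tests: stimulation blinding and sample characteristics.

Exact two-sided binomial tests check whether participants guessed their
stimulation condition above chance (successful blinding = high p), and
Pearson chi-square tests compare categorical sample characteristics
between two groups of n = 30 and n = 31.
"""

import revlearn as rl

print("blinding (false/right guesses vs chance 0.5):")
for label, k, n in [
    ("anodal group, sham session  (15/30)", 15, 30),
    ("anodal group, verum session (16/30)", 16, 30),
    ("cathodal group, sham session (16/31)", 16, 31),
    ("cathodal group, verum session (18/31)", 18, 31),
]:
    print(f"  {label}: p = {rl.exact_binomial_two_sided(k, n):.2f}")

stat, p = rl.pearson_chi2_2x2([[8, 22], [3, 28]])
print(f"\nsmoking 8/22 vs 3/28: chi2(1) = {stat:.2f}, p = {p:.3f}")
stat, p = rl.pearson_chi2_2x2([[15, 15], [15, 16]])
print(f"gender 15/15 vs 15/16: chi2(1) = {stat:.2f}, p = {p:.3f}")
print("\nHigh p-values mean guesses/counts are compatible with chance or equality.")
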
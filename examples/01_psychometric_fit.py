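"""Fit a Weibull psychometric function and compute body perception indices.

Simulates one subject's 198-trial depictive size-estimation task (66 body
pictures x 3 repetitions), fits the Weibull curve to the binary
narrower/wider judgments, inverts it at P = 0.5 for the point of subjective
equality ("fitted BMI"), and expresses it as a body perception index (BPI):
100 = veridical, above 100 = overestimation.
"""

import numpy as np

from bse import psychometrics as psy
from bse import synthetic as syn

# ground truth: a subject with actual BMI 17.0 who overestimates by 25%
actual_bmi = 17.0
true_pse = actual_bmi * 1.25
beta = 6.0
a = np.log(2.0) ** (1.0 / beta) / true_pse

stimuli = syn.make_stimulus_set(seed=1)
sequence = syn.make_trial_sequence(stimuli, n_repeats=3, seed=2)
responses = syn.simulate_binary_responses(sequence, stimuli, a, beta, seed=3)

fit = psy.fit_weibull(responses)
pse = psy.fitted_bmi(fit, criterion=0.5)
bpi = psy.compute_bpi(pse, actual_bmi)

print(f"trials: {fit.n_trials}, converged: {fit.converged}")
print(f"true PSE {true_pse:.2f} kg/m^2 -> fitted BMI {pse:.2f} kg/m^2")
print(f"body-task BPI: {bpi:.1f}%  (true {100 * true_pse / actual_bmi:.1f}%)")
print("a BPI above 100 means the subject judges their own body wider than it is")
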
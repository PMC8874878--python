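"""Simulate one reversal-task session and summarize the agent's behavior.

Builds the default 160-trial schedule (stable / reversal / stable phases,
80% reward on the better option), runs a softmax delta-rule agent with
counterfactual updating, and prints where the contingency switches fall
and how well the agent tracked them.
"""

import numpy as np

import revlearn as rl

schedule = rl.make_schedule()
print(f"trials: {schedule.n_trials}")
print(f"contingency switches at trials: {schedule.reversal_trials}")

params = rl.ParamSet(alpha=0.45, kappa=0.35, beta=6.0)
agent = rl.spec_from_name("iDU-1a")
session = rl.simulate_agent(params, agent, schedule, np.random.default_rng(1))

perf = rl.correct_choice_rate(session)
stay = rl.stay_probabilities(session)
print(f"correct choices  pre: {perf.pre:.2f}  reversal: {perf.reversal:.2f}  post: {perf.post:.2f}")
print(f"win-stay: {stay.win_stay:.2f}   lose-stay: {stay.lose_stay:.2f}")
print(
    "\nA well-adapted agent chooses the better option well above 0.5 in the\n"
    "stable phases and dips during reversals; it repeats rewarded choices\n"
    "(win-stay high) and switches after losses more often the larger kappa is."
)
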
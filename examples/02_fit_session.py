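"""Fit the six-model space to one simulated session by MAP.

The session is generated from the individually-weighted double-update
model (iDU, one learning rate), so that model family should fit best;
log model evidence (Laplace) is what model selection consumes.
"""

import numpy as np

import revlearn as rl

truth = rl.ParamSet(alpha=0.45, kappa=0.35, beta=6.0)
schedule = rl.make_schedule()
session = rl.simulate_agent(
    truth, rl.spec_from_name("iDU-1a"), schedule, np.random.default_rng(8)
)

print(f"{'model':8s} {'nll':>8s} {'lme':>9s}  map estimates")
for spec in rl.MODEL_SPACE:
    fit = rl.fit_map(session, spec, n_restarts=5, rng=0)
    est = ", ".join(f"{p}={getattr(fit.map_params, p):.2f}" for p in spec.free_params)
    print(f"{spec.name:8s} {fit.nll:8.2f} {fit.lme:9.2f}  {est}")

p, excluded = rl.chance_fit_test(fit.nll, session.n_valid)
print(f"\nchance-level fit test (last model): p = {p:.2e}, excluded = {excluded}")
print(
    "\nLower NLL means better raw fit; higher (less negative) log evidence\n"
    "trades fit against complexity and is the quantity model selection uses."
)
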
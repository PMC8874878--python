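"""Random-effects model selection on a small synthetic cohort.

Generates a cohort from the iDU one-rate model, fits the full model
space to every session, and runs RFX-BMS on the per-subject evidences
pooled across the two sessions. PP are the estimated population model
frequencies; PXP additionally guards against winning by chance.
"""

import numpy as np

import revlearn as rl
from revlearn.io import chance_excluded_subjects

cohort = rl.generate_cohort(rl.CohortSpec(n_per_group=(8, 8), seed=4))
records = [
    rl.SessionRecord(s.subject_id, s.group, cond, s.condition_order.index(cond) + 1,
                     s.sessions[cond])
    for s in cohort.subjects for cond in ("sham", "verum")
]

cfg = rl.RunConfig(n_restarts=3, xp_draws=200_000)
fits = rl.fit_all(records, cfg)
excluded = chance_excluded_subjects(fits)
kept = fits[~fits["subject_id"].isin(excluded)]
print(f"subjects: {len(cohort.subjects)}, excluded as at-chance: {excluded or 'none'}")

result = rl.pooled_selection(
    rl.evidence_matrix(kept, "sham"),
    rl.evidence_matrix(kept, "verum"),
    xp_draws=200_000,
    rng=0,
)
print(f"\n{'model':8s} {'PP':>6s} {'XP':>6s} {'PXP':>6s}")
for name, pp, xp, pxp in zip(result.models, result.pp, result.xp, result.pxp):
    print(f"{name:8s} {pp:6.3f} {xp:6.3f} {pxp:6.3f}")
print(f"\nwinner: {result.winner}   Bayesian omnibus risk: {result.bor:.3f}")
print(
    "\nThe double-update family should dominate the single-update one. At\n"
    "this demo size the nested iDU/DU variants compete (iDU with kappa near\n"
    "1 mimics DU); at full study size the generating iDU-1a model wins --\n"
    "see the model-recovery checks in the test suite."
)
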
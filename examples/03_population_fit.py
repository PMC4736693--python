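"""Full two-stage analysis with covariate selection on a synthetic trial.

Generates a 22-woman trial (88 profiles) from a three-level (visit) truth
with a strong gestation effect on log t_max, fits every profile independently
(stage 1), then fits the three-level population model with reversible-jump
covariate selection (stage 2) and prints inclusion probabilities and the
variance decomposition.
"""

import numpy as np

from hierpk import (
    ModelSpec,
    Stage1Config,
    Stage2Config,
    TrialDesign,
    generate_trial,
    inclusion_probabilities,
    run_stage1_dataset,
    run_stage2,
    variance_decomposition,
)

design = TrialDesign(level="threeV", beta_true=((0, "gestation", 0.30),))
dataset, truth = generate_trial(design, seed=4)
print(f"generated {len(dataset.profiles)} profiles; truth: gestation effect "
      f"+0.30 on log t_max, phi = {np.round(truth.phi, 3)}")

store = run_stage1_dataset(
    dataset, config=Stage1Config(burn_in=3000, iterations=8000, thin=8), seed=13
)
print(f"stage 1 done: {len(store.entries)} profiles fitted"
      + (f", excluded {dict(dataset.exclusions)}" if dataset.exclusions else ""))

draws = run_stage2(
    store,
    dataset,
    ModelSpec(level="threeV", covariates_on=True),
    Stage2Config(iterations=6000, burn_in=1500, thin=3),
    seed=19,
)

pr = inclusion_probabilities(draws)
print("\ninclusion probabilities for log t_max (>0.5 flags an association):")
for j, name in enumerate(draws.col_names):
    flag = " <-- injected" if name == "gestation" else ""
    print(f"  {name:22s} {pr[0, j]:5.2f}{flag}")

print("\nvariance decomposition (posterior mean share of total, per parameter):")
vd = variance_decomposition(draws)
print(f"  {'component':10s} {'t_max':>7} {'MCR':>7} {'a':>7} {'b':>7}")
for comp, rec in vd.items():
    row = " ".join(f"{p:7.2f}" for p in rec["proportion"])
    label = {"theta": "residual", "psi": "woman", "chi": "visit"}[comp]
    print(f"  {label:10s} {row}")
print(
    "\nThe injected covariate should stand out with inclusion probability "
    "near 1 while null covariates stay low; the woman/visit/residual shares "
    "show where the parameter variability sits."
)
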
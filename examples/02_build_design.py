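"""Build the deconvolution design matrix: treatment-coded categories,
spline-coded covariates, and sparse time expansion.

Shows the predictor accounting of the standard model — 1 fixation intercept
+ 3 category dummies + 5 covariates x 4 retained spline columns + 1
stimulus intercept = 25 predictors — and how time expansion over
-200..+500 ms at 250 Hz turns them into 25 x 175 = 4375 sparse columns
spanning the continuous recording.
"""

from collections import Counter

import fixdeconv as fd

config = fd.ScanpathConfig(n_trials=10, seed=3)
fixations, saccades, stimuli = fd.simulate_scanpaths(config)
labeled = fd.label_fixations(fixations)
covariates = fd.impute_covariates(fd.compute_covariates(labeled, saccades))
events = fd.build_event_table(labeled, covariates, stimuli)

mass = fd.build_mass_design(events, fd.default_formula())
print(f"events: {len(events)}  (fixations + stimulus onsets)")
print(f"mass-univariate predictors P = {mass.P}")
for (etype, kind), n in Counter(
        (c.event_type, c.kind) for c in mass.columns).items():
    print(f"  {etype:9s} {kind:10s} x {n}")

n_samples = int(events["time"].max() * 250) + 200
expanded = fd.time_expand(mass, events["time"], (-0.2, 0.5), 250.0, n_samples)
dens = expanded.X.nnz / (expanded.X.shape[0] * expanded.X.shape[1])
print(f"\ntime expansion: L = {expanded.L} lags "
      f"-> {expanded.X.shape[1]} columns over {expanded.X.shape[0]} samples")
print(f"sparse density: {dens:.2%} nonzero")
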
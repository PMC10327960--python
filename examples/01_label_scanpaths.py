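"""Categorize free-viewing scanpaths into precursor / refixation / ordinary
/ other fixations and summarize the oculomotor structure.

Simulates a single participant's search session (8-s trials on a 30x30
degree display), applies the 2-degree revisit criterion with all the
disambiguation rules, and prints per-category counts and saccade-size
asymmetries.  Expect precursor fixations to carry the largest incoming and
smallest outgoing saccades, and precursor-refixation pairs to be separated
by roughly nine intervening fixations.
"""

import fixdeconv as fd

config = fd.ScanpathConfig(n_trials=40, seed=7)
fixations, saccades, stimuli = fd.simulate_scanpaths(config)

labeled = fd.label_fixations(fixations, fd.LabelConfig(radius=2.0))
covariates = fd.impute_covariates(fd.compute_covariates(labeled, saccades))
summary = fd.summarize_eye_movements(labeled, covariates)

print(f"{len(labeled)} fixations over {config.n_trials} trials\n")
cols = ["category", "n", "mean_duration", "mean_incoming_saccade_size",
        "mean_outgoing_saccade_size", "mean_intervening"]
print(summary[cols].round(3).to_string(index=False))
print("\nmean_intervening: fixations between a precursor and its first "
      "refixation (only defined for the precursor row).")
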
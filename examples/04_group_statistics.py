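"""Group-level analysis of late-window FRP amplitudes: repeated-measures
ANOVA with Huynh-Feldt correction and Newman-Keuls post hocs.

Draws late-window (200-400 ms) ROI measures for 21 virtual participants
from the default ground-truth preset (category x region x hemisphere) and
tests the fixation-category effect.  Expect a clear category main effect
and a category-by-region interaction driven by the precursor-specific
occipital depression; post hocs should isolate precursor fixations from
the other two categories.
"""

import fixdeconv as fd

truth = fd.make_default_truth("default")
measures = fd.simulate_window_measures(truth, n_participants=21, seed=11)

anova = fd.rm_anova(measures, "amplitude",
                    ["category", "region", "hemisphere"])
cols = ["effect", "F", "df_num", "df_den", "eps_hf", "p_corrected"]
print(anova[cols].round(4).to_string(index=False))

posthoc = fd.newman_keuls_factor(
    measures, "amplitude", ["category", "region", "hemisphere"], "category")
print("\nNewman-Keuls on category marginal means:")
print(posthoc[["level_a", "level_b", "mean_difference", "p",
               "significant"]].round(4).to_string(index=False))
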
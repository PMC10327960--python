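"""End-to-end per-participant analysis: events -> design -> fit -> FRPs.

Thin orchestration over the module functions, mirroring the four analysis
steps: build the event table with categories and covariates, construct and
time-expand the design matrix, fit the sparse deconvolution model per
channel, and reconstruct baseline-corrected marginal FRPs at the
participant's mean covariate levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import (DEFAULT_WINDOW, FIXATION, STIMULUS, ExpandedDesign,
                     ModelFormula, Spline, build_mass_design, default_formula,
                     time_expand)
from .events import (LabelConfig, compute_covariates, impute_covariates,
                     label_fixations)
from .fit import BetaSet, ContinuousEEG, SolverOptions, fit_deconvolution
from .frp import MarginalFRP, baseline_correct, covariate_means, \
    reconstruct_marginal_frps


def build_event_table(labeled_fixations: pd.DataFrame,
                      covariates: pd.DataFrame,
                      stimuli: pd.DataFrame) -> pd.DataFrame:
    """Stack fixation and stimulus events into one modeling table.

    Fixation rows carry category and covariates; stimulus rows only a time.
    Covariates must be row-aligned with the labeled fixations and free of
    NaN in modeled columns (see
    :func:`~fixdeconv.events.impute_covariates`).
    """
    fix = covariates.copy().reset_index(drop=True)
    fix["time"] = labeled_fixations["onset"].to_numpy()
    fix["event_type"] = FIXATION
    stim = stimuli.copy()
    stim["event_type"] = STIMULUS
    events = pd.concat([fix, stim], ignore_index=True)
    return events.sort_values("time", kind="stable").reset_index(drop=True)


@dataclass
class ParticipantResult:
    betas: BetaSet
    frp: MarginalFRP                 # baseline-corrected marginal FRPs
    frp_uncorrected: MarginalFRP
    events: pd.DataFrame
    design: ExpandedDesign
    covariate_means: dict[str, float]


def analyze_participant(fixations: pd.DataFrame, saccades: pd.DataFrame,
                        stimuli: pd.DataFrame, eeg: ContinuousEEG,
                        formula: ModelFormula | None = None,
                        window: tuple[float, float] = DEFAULT_WINDOW,
                        label_config: LabelConfig | None = None,
                        solver: SolverOptions | None = None,
                        baseline: tuple[float, float] | None = (0.0, 0.020),
                        ) -> ParticipantResult:
    """Run the full single-participant pipeline on event tables + EEG."""
    labeled = label_fixations(fixations, label_config)
    cov = impute_covariates(compute_covariates(labeled, saccades))
    events = build_event_table(labeled, cov, stimuli)
    formula = formula or default_formula()
    mass = build_mass_design(events, formula)
    expanded = time_expand(mass, events["time"].to_numpy(), window,
                           eeg.sampling_rate, eeg.n_samples)
    betas = fit_deconvolution(eeg, expanded, solver)
    spline_names = [t.name for t in formula.terms.get(FIXATION, ())
                    if isinstance(t, Spline)]
    means = covariate_means(events, spline_names)
    frp_raw = reconstruct_marginal_frps(betas, means)
    frp = baseline_correct(frp_raw, baseline) if baseline else frp_raw
    return ParticipantResult(betas=betas, frp=frp, frp_uncorrected=frp_raw,
                             events=events, design=expanded,
                             covariate_means=means)
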
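"""Marginal fixation-related potentials, baselines, ROIs and window means.

Raw deconvolution betas are difference waves (each category dummy relative
to the reference level) plus spline partial effects with no natural zero.
To obtain waveforms comparable to classical event-locked averages, each
category's *marginal* FRP is reconstructed by evaluating every spline
covariate at a fixed (mean) level and adding that identical contribution to
the intercept and to each category's dummy betas.  All categories are thus
presented at the same estimated predictor levels; category differences are
exactly the dummy betas and do not depend on which spline column was
dropped or which level served as reference.

Downstream reductions: baseline correction over a short window (the adopted
baseline is 0-20 ms after fixation onset), averaging over regions of
interest of one landmark electrode plus its six neighbours, and time-window
means (lambda window 30-130 ms, late window 200-400 ms).  All windows are
half-open ``[t0, t1)`` at the recording rate, so the 0-20 ms baseline
covers exactly 5 samples at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .design import FIXATION, Categorical, Spline
from .fit import BetaSet, ContinuousEEG

#: Named analysis windows, seconds after fixation onset (half-open).
WINDOWS: dict[str, tuple[float, float]] = {
    "lambda": (0.030, 0.130),       # 100 ms centered on the 80-ms lambda peak
    "late": (0.200, 0.400),         # late parieto-occipital negativity
    "baseline_pre": (-0.200, -0.100),
    "baseline_post": (0.0, 0.020),  # adopted baseline
}


@dataclass
class MarginalFRP:
    """Per-category reconstructed waveforms (channels x lags, uV)."""

    waveforms: dict[str, np.ndarray]
    times: np.ndarray                       # lag axis, seconds
    ch_names: list[str]
    covariate_levels: dict[str, float] = field(default_factory=dict)
    baseline_window: tuple[float, float] | None = None

    @property
    def categories(self) -> list[str]:
        return list(self.waveforms)

    def _window_slice(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        idx = np.flatnonzero((self.times >= t0) & (self.times < t1))
        if idx.size == 0:
            raise ValueError(f"window {window} selects no samples")
        return idx

    def to_frame(self) -> pd.DataFrame:
        """Long format: category, channel, time, amplitude."""
        rows = []
        for cat, w in self.waveforms.items():
            for ci, ch in enumerate(self.ch_names):
                rows.append(pd.DataFrame({
                    "category": cat, "channel": ch,
                    "time": self.times, "amplitude": w[ci]}))
        return pd.concat(rows, ignore_index=True)


def covariate_means(events: pd.DataFrame,
                    names) -> dict[str, float]:
    """Mean predictor levels over all fixation events entering the model."""
    fix = events[events["event_type"] == FIXATION] if "event_type" in events \
        else events
    return {name: float(fix[name].mean()) for name in names}


def reconstruct_marginal_frps(betas: BetaSet,
                              covariate_means: dict[str, float]) -> MarginalFRP:
    """Reconstruct per-category marginal FRPs from fitted betas.

    The reference category's waveform is the fixation intercept betas plus
    the spline betas weighted by the basis evaluated at each covariate's
    mean; a non-reference category additionally gets its dummy betas.
    """
    design = betas.design
    cols = design.columns
    coef = betas.coefficients        # channels x P x L

    cat_term = next((t for t in design.formula.terms.get(FIXATION, ())
                     if isinstance(t, Categorical)), None)
    spline_terms = [t for t in design.formula.terms.get(FIXATION, ())
                    if isinstance(t, Spline)]
    for t in spline_terms:
        if t.name not in covariate_means:
            raise ValueError(f"missing covariate mean for {t.name!r}")

    def col_idx(pred):
        return [i for i, c in enumerate(cols) if pred(c)]

    ic = col_idx(lambda c: c.event_type == FIXATION and c.kind == "intercept")
    base = coef[:, ic[0], :].copy() if ic else np.zeros(coef.shape[::2])

    for t in spline_terms:
        idx = col_idx(lambda c, t=t: c.event_type == FIXATION
                      and c.kind == "spline" and c.term == t.name)
        weights = design.bases[t.name].evaluate([covariate_means[t.name]])[0]
        base += np.tensordot(weights, coef[:, idx, :], axes=(0, 1))

    waveforms: dict[str, np.ndarray] = {}
    if cat_term is None:
        waveforms["(all)"] = base
    else:
        for level in cat_term.levels:
            w = base.copy()
            if level != cat_term.reference:
                idx = col_idx(lambda c, l=level: c.kind == "dummy"
                              and c.detail == l)
                w = w + coef[:, idx[0], :]
            waveforms[level] = w
    # restrict to named covariates actually in the model
    levels = {t.name: float(covariate_means[t.name]) for t in spline_terms}
    return MarginalFRP(waveforms=waveforms, times=design.lag_times,
                       ch_names=betas.ch_names, covariate_levels=levels)


def baseline_correct(frp: MarginalFRP,
                     window: tuple[float, float] = WINDOWS["baseline_post"],
                     ) -> MarginalFRP:
    """Subtract the per-channel mean over the (half-open) baseline window."""
    idx = frp._window_slice(window)
    new = {cat: w - w[:, idx].mean(axis=1, keepdims=True)
           for cat, w in frp.waveforms.items()}
    return replace(frp, waveforms=new, baseline_window=window)


# ---------------------------------------------------------------------------
# regions of interest

@dataclass
class ROISpec:
    """ROI definitions: name -> 7 channel labels, with factor labels.

    ``factors`` maps each ROI name to ``(region, hemisphere)`` with region in
    frontal/central/parietal/occipital and hemisphere left/right.
    """

    rois: dict[str, list[str]]
    factors: dict[str, tuple[str, str]]

    def __post_init__(self):
        seen: set[str] = set()
        for name, chans in self.rois.items():
            if len(chans) != len(set(chans)):
                raise ValueError(f"ROI {name}: duplicate channels")
            if len(chans) != 7:
                raise ValueError(f"ROI {name}: expected 7 channels, got {len(chans)}")
            overlap = seen & set(chans)
            if overlap:
                raise ValueError(f"ROI {name}: channels {overlap} reused")
            seen |= set(chans)
            if name not in self.factors:
                raise ValueError(f"ROI {name}: missing factor labels")

    @property
    def n_channels(self) -> int:
        return sum(len(c) for c in self.rois.values())

    @classmethod
    def from_yaml(cls, path) -> "ROISpec":
        with open(path) as f:
            spec = yaml.safe_load(f)
        rois = {name: list(d["channels"]) for name, d in spec.items()}
        factors = {name: (d["region"], d["hemisphere"]) for name, d in spec.items()}
        return cls(rois=rois, factors=factors)


def roi_average(frp: MarginalFRP, rois: ROISpec) -> MarginalFRP:
    """Unweighted mean over each ROI's 7 channels; channel axis becomes ROIs."""
    if frp.ch_names is None:
        raise ValueError("FRP has no channel labels; set ch_names first")
    missing = [ch for chans in rois.rois.values() for ch in chans
               if ch not in frp.ch_names]
    if missing:
        raise ValueError(f"channels missing from FRP: {missing}")
    order = {ch: i for i, ch in enumerate(frp.ch_names)}
    new = {}
    for cat, w in frp.waveforms.items():
        new[cat] = np.stack([w[[order[c] for c in chans]].mean(axis=0)
                             for chans in rois.rois.values()])
    return replace(frp, waveforms=new, ch_names=list(rois.rois))


def window_mean(roi_frp: MarginalFRP, window: str | tuple[float, float],
                rois: ROISpec | None = None,
                participant=None) -> pd.DataFrame:
    """Time-window mean amplitude per (category, ROI).

    ``window`` is a name from :data:`WINDOWS` or an explicit ``(t0, t1)``
    pair in seconds.  Returns a long DataFrame with columns category, roi,
    region, hemisphere (when ``rois`` given), amplitude, window — ready for
    the repeated-measures ANOVA.
    """
    win = WINDOWS[window] if isinstance(window, str) else tuple(window)
    name = window if isinstance(window, str) else f"{win[0]:g}-{win[1]:g}s"
    idx = roi_frp._window_slice(win)
    rows = []
    for cat, w in roi_frp.waveforms.items():
        for ci, ch in enumerate(roi_frp.ch_names):
            row = {"category": cat, "roi": ch,
                   "amplitude": float(w[ci, idx].mean()), "window": name}
            if rois is not None and ch in rois.factors:
                row["region"], row["hemisphere"] = rois.factors[ch]
            if participant is not None:
                row["participant"] = participant
            rows.append(row)
    return pd.DataFrame(rows)


def baseline_candidate_measures(frp: MarginalFRP, rois: ROISpec,
                                windows=("baseline_pre", "baseline_post"),
                                participant=None) -> dict[str, pd.DataFrame]:
    """Window measures of *uncorrected* FRPs in candidate baseline windows.

    Vetting convenience: run the rm-ANOVA on each returned table; a baseline
    window is acceptable when no effect involving category is present.
    """
    if frp.baseline_window is not None:
        raise ValueError("pass uncorrected FRPs to vet baseline candidates")
    roi_frp = roi_average(frp, rois)
    return {w: window_mean(roi_frp, w, rois, participant) for w in windows}


def event_locked_average(eeg: ContinuousEEG, event_times, labels,
                         window: tuple[float, float]) -> MarginalFRP:
    """Naive per-category event-locked average (no overlap correction).

    The classical estimator the deconvolution approach improves upon: under
    temporally overlapping responses it is biased by the neighbouring
    events' activity.  Used as a comparison baseline in recovery tests.
    """
    fs = eeg.sampling_rate
    start = int(round(window[0] * fs))
    L = int(round(window[1] * fs)) - start
    samples = np.round(np.asarray(event_times, float) * fs).astype(int)
    labels = np.asarray(labels)
    waveforms = {}
    for cat in pd.unique(labels):
        acc = np.zeros((eeg.n_channels, L))
        n = 0
        for s in samples[labels == cat]:
            lo = s + start
            if lo < 0 or lo + L > eeg.n_samples:
                continue
            acc += eeg.data[:, lo:lo + L]
            n += 1
        waveforms[cat] = acc / max(n, 1)
    times = (start + np.arange(L)) / fs
    return MarginalFRP(waveforms=waveforms, times=times,
                       ch_names=list(eeg.ch_names))
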
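"""Synthetic scanpaths and forward-simulated continuous EEG.

The generator emulates the statistical structure of a free-viewing contour
search session: 8-second trials on a 30 x 30 degree display, gamma-
distributed fixation durations with a 247-ms mean, and a revisit process in
which some fixations are designated as future return targets and revisited
after about nine intervening fixations — creating the precursor/refixation
structure the labeling rules detect.  Optionally (and by default, matching
the observed oculomotor asymmetries) saccades incoming to designated
precursors are drawn large and outgoing ones small.

Continuous EEG is formed by linear superposition: each event contributes a
set of components (an early lambda-like occipital wave near 100 ms, a late
parieto-occipital negativity at 200-400 ms carrying a precursor-specific
offset, and a stimulus-onset response), each the outer product of a channel
topography and a lag waveform, scaled by smooth covariate-effect functions
(saturating effect of incoming saccade size on the lambda wave, linear
effect of fixation rank on the late wave; both normalized to 1 at their
reference level), plus white Gaussian noise.  Every kernel, topography and
effect function is exposed as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .events import ORDINARY, OTHER, PRECURSOR, REFIXATION
from .fit import ContinuousEEG
from .frp import ROISpec

REGIONS = (("frontal", "F"), ("central", "C"),
           ("parietal", "P"), ("occipital", "O"))
HEMISPHERES = (("left", "L"), ("right", "R"))


# ---------------------------------------------------------------------------
# scanpath generation

@dataclass(frozen=True)
class ScanpathConfig:
    """Conditions of the simulated viewing session.

    Defaults reproduce the emulated study: 8-s trials, 30 x 30 degree
    display (half-width 15), mean fixation duration 247 ms, designated
    revisits separated from their precursor by ~9 intervening fixations,
    and 80 analyzed trials per participant (~2,500 fixations, the analyzed
    per-participant event count of the emulated study).
    """

    n_participants: int = 1
    n_trials: int = 80
    trial_duration: float = 8.0
    screen_half_width: float = 15.0
    fixation_duration_mean: float = 0.247
    fixation_duration_shape: float = 5.0
    saccade_amplitude_mean: float = 4.0
    saccade_amplitude_shape: float = 2.5
    precursor_incoming_mean: float = 7.0   # asymmetry: large saccade into precursor
    precursor_outgoing_mean: float = 2.0   # small saccade out of precursor
    asymmetric_saccades: bool = True
    revisit_prob: float = 0.17             # designation prob. when room remains
    mean_intervening: float = 9.0
    intervening_sd: float = 1.5
    min_intervening: int = 5
    revisit_jitter: float = 0.75           # degrees, radius of return scatter
    min_spacing: float | None = 2.5        # self-avoidance of new fixations
    inter_trial_gap: float = 2.0
    first_fixation_delay: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.revisit_prob <= 1:
            raise ValueError("revisit probability must be in [0, 1]")
        for name in ("trial_duration", "fixation_duration_mean",
                     "saccade_amplitude_mean", "inter_trial_gap"):
            if getattr(self, name) < 0 or (name != "inter_trial_gap"
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.fixation_duration_mean > self.trial_duration:
            raise ValueError("mean fixation duration exceeds trial duration")


def _draw_position(rng, prev, amp_mean, amp_shape, half_width, min_spacing,
                   previous_positions):
    """Next fixation center: gamma-amplitude saccade, uniform angle,
    reflected into the screen; optionally resampled to keep spacing.

    When a crowded neighbourhood rejects many candidates, the amplitude
    scale escalates so the gaze escapes; the spacing constraint itself is
    never relaxed."""
    for attempt in range(3000):
        scale = 1.5 ** (attempt // 200)
        amp = rng.gamma(amp_shape, scale * amp_mean / amp_shape)
        ang = rng.uniform(0, 2 * np.pi)
        p = prev + amp * np.array([np.cos(ang), np.sin(ang)])
        # reflect at the screen border
        p = np.where(np.abs(p) > half_width,
                     np.sign(p) * (2 * half_width) - p, p)
        p = np.clip(p, -half_width, half_width)
        if min_spacing is None or all(
                np.hypot(*(p - q)) >= min_spacing for q in previous_positions):
            return p
    raise RuntimeError("could not place a fixation respecting min_spacing")


def _approach_position(rng, target, half_width, min_spacing, previous_positions):
    """A fixation a few degrees short of an upcoming revisit target."""
    for attempt in range(3000):
        r = 2.8 + rng.gamma(2.0, 0.7 * 1.5 ** (attempt // 200))
        a = rng.uniform(0, 2 * np.pi)
        p = target + r * np.array([np.cos(a), np.sin(a)])
        p = np.where(np.abs(p) > half_width,
                     np.sign(p) * (2 * half_width) - p, p)
        p = np.clip(p, -half_width, half_width)
        if np.hypot(*(p - target)) < 2.8:
            continue  # reflection pushed it back onto the target
        if min_spacing is None or all(
                np.hypot(*(p - q)) >= min_spacing for q in previous_positions):
            return p
    raise RuntimeError("could not place an approach fixation")


def simulate_scanpaths(config: ScanpathConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate fixation, saccade and stimulus-onset event tables.

    Returns ``(fixations, saccades, stimuli)``.  Times are seconds from the
    start of each participant's recording; saccade amplitudes equal the
    Euclidean distance between consecutive fixation centers by construction.
    Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    fix_rows, sac_rows, stim_rows = [], [], []
    c = config
    for pid, child in enumerate(ss.spawn(c.n_participants), start=1):
        rng = np.random.default_rng(child)
        for trial in range(1, c.n_trials + 1):
            t0 = (trial - 1) * (c.trial_duration + c.inter_trial_gap)
            stim_rows.append({"participant": pid, "trial": trial, "time": t0})
            positions: list[np.ndarray] = []
            durations: list[float] = []
            planned: dict[int, np.ndarray] = {}   # fixation index -> target
            incoming_big: list[bool] = []
            t = c.first_fixation_delay
            i = 0
            exp_total = c.trial_duration / c.fixation_duration_mean
            while True:
                dur = rng.gamma(c.fixation_duration_shape,
                                c.fixation_duration_mean / c.fixation_duration_shape)
                if t + dur > c.trial_duration:
                    break
                if i == 0:
                    p = rng.uniform(-c.screen_half_width, c.screen_half_width, 2)
                    is_precursor_designate = False
                elif i in planned:
                    # scheduled refixation: return near the stored location
                    r = c.revisit_jitter * np.sqrt(rng.uniform())
                    a = rng.uniform(0, 2 * np.pi)
                    p = planned.pop(i) + r * np.array([np.cos(a), np.sin(a)])
                    is_precursor_designate = False
                elif (i + 1) in planned:
                    # approach fixation: the gaze nears the revisit target
                    # before returning, so the refixation's incoming saccade
                    # stays short (the smallest among the categories)
                    p = _approach_position(rng, planned[i + 1],
                                           c.screen_half_width, c.min_spacing,
                                           positions)
                    is_precursor_designate = False
                else:
                    prev_designate = bool(incoming_big and incoming_big[-1])
                    room = (exp_total - i) > (c.mean_intervening + 2)
                    is_precursor_designate = (room and i not in planned
                                              and rng.uniform() < c.revisit_prob)
                    if c.asymmetric_saccades and is_precursor_designate:
                        amp_mean = c.precursor_incoming_mean
                    elif c.asymmetric_saccades and prev_designate:
                        amp_mean = c.precursor_outgoing_mean
                    else:
                        amp_mean = c.saccade_amplitude_mean
                    p = _draw_position(rng, positions[-1], amp_mean,
                                       c.saccade_amplitude_shape,
                                       c.screen_half_width, c.min_spacing,
                                       positions)
                    if is_precursor_designate:
                        gap = int(round(rng.normal(c.mean_intervening + 1,
                                                   c.intervening_sd)))
                        due = i + max(gap, c.min_intervening + 1)
                        while due in planned:
                            due += 1
                        planned[due] = p.copy()
                positions.append(np.asarray(p, float))
                durations.append(dur)
                incoming_big.append(bool(i > 0 and is_precursor_designate))
                fix_rows.append({"participant": pid, "trial": trial,
                                 "rank": i + 1, "onset": t0 + t,
                                 "duration": dur,
                                 "x": p[0], "y": p[1]})
                t += dur
                i += 1
            for j in range(1, len(positions)):
                d = positions[j] - positions[j - 1]
                sac_rows.append({
                    "participant": pid, "trial": trial,
                    "onset": fix_rows[len(fix_rows) - len(positions) + j]["onset"],
                    "amplitude": float(np.hypot(*d)),
                    "angle": float(np.degrees(np.arctan2(d[1], d[0]))),
                    "from_rank": j, "to_rank": j + 1})
    return (pd.DataFrame(fix_rows), pd.DataFrame(sac_rows),
            pd.DataFrame(stim_rows))


def recording_length(config: ScanpathConfig) -> float:
    """Duration of one participant's recording in seconds."""
    return config.n_trials * (config.trial_duration + config.inter_trial_gap)


# ---------------------------------------------------------------------------
# ground truth and EEG forward model

@dataclass
class EffectFunction:
    """Smooth covariate-effect scaling, normalized to 1 at ``reference``."""

    covariate: str
    func: object              # callable on raw covariate values
    reference: float

    def __call__(self, values):
        raw = self.func(np.asarray(values, dtype=float))
        return raw / self.func(np.array(self.reference))


@dataclass
class KernelComponent:
    name: str
    waveform: np.ndarray                     # uV at lags 0..K-1
    topography: np.ndarray                   # per-channel weights
    category_gain: dict[str, float] | None = None   # None -> 1 everywhere
    modulator: EffectFunction | None = None

    def gain(self, category: str) -> float:
        if self.category_gain is None:
            return 1.0
        return self.category_gain.get(category, 0.0)


@dataclass
class GroundTruth:
    """Complete forward-model specification, exposed for recovery tests."""

    components: list[KernelComponent]
    stimulus_kernel: np.ndarray              # channels x K
    ch_names: list[str]
    channel_factors: list[tuple[str, str]]   # (region, hemisphere) per channel
    sampling_rate: float
    noise_sigma: float
    window: tuple[float, float] = (-0.2, 0.5)

    def __post_init__(self):
        max_k = max([c.waveform.size for c in self.components]
                    + [self.stimulus_kernel.shape[1]])
        if max_k / self.sampling_rate > self.window[1]:
            raise ValueError("kernel support exceeds the estimation window; "
                             "recovery would be ill-posed by construction")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    @property
    def kernel_length(self) -> int:
        return max(c.waveform.size for c in self.components)

    def marginal_kernel(self, category: str,
                        covariate_values: dict[str, float] | None = None
                        ) -> np.ndarray:
        """True channels x K kernel for a category at given covariate levels.

        With ``covariate_values`` omitted, modulators sit at their reference
        level (scaling 1).
        """
        K = self.kernel_length
        out = np.zeros((self.n_channels, K))
        for comp in self.components:
            scale = comp.gain(category)
            if comp.modulator is not None and covariate_values is not None:
                scale *= float(comp.modulator(
                    covariate_values[comp.modulator.covariate]))
            w = np.zeros(K)
            w[:comp.waveform.size] = comp.waveform
            out += scale * np.outer(comp.topography, w)
        return out


def _gauss(t, mu, sd):
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def make_montage(n_per_roi: int = 1
                 ) -> tuple[list[str], list[tuple[str, str]], ROISpec | None]:
    """Synthetic montage over 8 region x hemisphere sites.

    With ``n_per_roi=1``: 8 channels named FL..OR (one per site).  With
    ``n_per_roi=7``: 56 channels (e.g. OL1..OL7) and the matching
    :class:`~fixdeconv.frp.ROISpec` of 8 ROIs x 7 electrodes.
    """
    names, factors, rois, roi_factors = [], [], {}, {}
    for region, rcode in REGIONS:
        for hemi, hcode in HEMISPHERES:
            roi = f"{rcode}{hcode}"
            chans = ([roi] if n_per_roi == 1
                     else [f"{roi}{k}" for k in range(1, n_per_roi + 1)])
            names += chans
            factors += [(region, hemi)] * len(chans)
            rois[roi] = chans
            roi_factors[roi] = (region, hemi)
    spec = ROISpec(rois=rois, factors=roi_factors) if n_per_roi == 7 else None
    return names, factors, spec


_REGION_WEIGHTS = {
    # region -> (lambda wave, late negativity, stimulus response)
    "occipital": (1.0, 1.0, 1.0),
    "parietal": (0.5, 0.8, 0.8),
    "central": (0.15, 0.3, 0.5),
    "frontal": (0.0, -0.3, 0.3),
}

PRESETS = ("default", "null")


def make_default_truth(preset: str = "default", n_per_roi: int = 1,
                       sampling_rate: float = 250.0,
                       noise_sigma: float = 2.0,
                       precursor_offset: float = -2.0,
                       config: ScanpathConfig | None = None) -> GroundTruth:
    """Build a documented ground-truth preset.

    ``default`` carries a precursor-specific late-window offset
    (``precursor_offset`` uV over 200-400 ms, parieto-occipital), sized to
    be detectable in a 21-participant group analysis; ``null`` has
    identical kernels for all categories.  Covariate-effect references are
    taken from the scanpath config so that effects scale to 1 at the
    generator's expected covariate means.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    c = config or ScanpathConfig()
    fs = sampling_rate
    K = int(round(0.5 * fs))          # kernel support 0..500 ms, inside window
    t = np.arange(K) / fs
    ch_names, factors, _ = make_montage(n_per_roi)

    def topo(idx):
        return np.array([_REGION_WEIGHTS[r][idx] for r, _ in factors])

    lam_mod = EffectFunction(
        covariate="incoming_saccade_size",
        func=lambda a: 0.6 + 0.8 * (1.0 - np.exp(-a / 4.0)),
        reference=c.saccade_amplitude_mean)
    mean_rank = 0.5 * c.trial_duration / c.fixation_duration_mean
    rank_mod = EffectFunction(
        covariate="fixation_rank",
        func=lambda r: 1.0 + 0.02 * (r - mean_rank),
        reference=mean_rank)

    components = [
        KernelComponent("lambda", 8.0 * _gauss(t, 0.100, 0.020), topo(0),
                        modulator=lam_mod),
        KernelComponent("late_negativity", -3.0 * _gauss(t, 0.300, 0.060),
                        topo(1), modulator=rank_mod),
    ]
    if preset == "default":
        on = (t >= 0.200) & (t < 0.400)
        wave = np.zeros(K)
        wave[on] = precursor_offset * 0.5 * (
            1 - np.cos(2 * np.pi * (t[on] - 0.200) / 0.200))
        components.append(KernelComponent(
            "precursor_offset", wave, topo(1),
            category_gain={PRECURSOR: 1.0, REFIXATION: 0.0,
                           ORDINARY: 0.0, OTHER: 0.0}))
    stim = np.outer(topo(2), 5.0 * _gauss(t, 0.120, 0.040))
    return GroundTruth(components=components, stimulus_kernel=stim,
                       ch_names=ch_names, channel_factors=factors,
                       sampling_rate=fs, noise_sigma=noise_sigma)


def simulate_eeg(fixations: pd.DataFrame, stimuli: pd.DataFrame,
                 covariates: pd.DataFrame, truth: GroundTruth,
                 n_samples: int, seed: int | np.random.Generator = 0
                 ) -> ContinuousEEG:
    """Forward-simulate one participant's continuous EEG.

    ``fixations`` must be labeled and aligned row-for-row with
    ``covariates`` (as returned by :func:`~fixdeconv.events.compute_covariates`
    after imputation).  The signal is the linear superposition of every
    component at every event, plus white Gaussian noise of the truth's
    ``noise_sigma``; pass noise_sigma 0 for a noiseless recording.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fs = truth.sampling_rate
    data = np.zeros((truth.n_channels, n_samples))
    fix_samples = np.round(fixations["onset"].to_numpy(float) * fs).astype(int)
    if (fix_samples < 0).any() or (fix_samples >= n_samples).any():
        raise ValueError("fixation events outside the recording")
    categories = fixations["category"].to_numpy()

    for comp in truth.components:
        gains = np.array([comp.gain(cat) for cat in categories])
        if comp.modulator is not None:
            gains = gains * comp.modulator(
                covariates[comp.modulator.covariate].to_numpy(float))
        impulses = np.zeros(n_samples)
        np.add.at(impulses, fix_samples, gains)
        sig = fftconvolve(impulses, comp.waveform)[:n_samples]
        data += np.outer(comp.topography, sig)

    stim_samples = np.round(stimuli["time"].to_numpy(float) * fs).astype(int)
    impulses = np.zeros(n_samples)
    np.add.at(impulses, stim_samples[stim_samples < n_samples], 1.0)
    for ch in range(truth.n_channels):
        data[ch] += fftconvolve(impulses, truth.stimulus_kernel[ch])[:n_samples]

    if truth.noise_sigma > 0:
        data += rng.normal(0.0, truth.noise_sigma, size=data.shape)
    return ContinuousEEG(data=data, sampling_rate=fs,
                         ch_names=list(truth.ch_names))


def truth_window_means(truth: GroundTruth, window: tuple[float, float],
                       categories=(PRECURSOR, REFIXATION, ORDINARY)
                       ) -> pd.DataFrame:
    """True window-mean amplitude per (category, region, hemisphere)."""
    fs = truth.sampling_rate
    t = np.arange(truth.kernel_length) / fs
    idx = (t >= window[0]) & (t < window[1])
    rows = []
    for cat in categories:
        kern = truth.marginal_kernel(cat)
        for ch, (region, hemi) in enumerate(truth.channel_factors):
            rows.append({"category": cat, "region": region, "hemisphere": hemi,
                         "amplitude": float(kern[ch, idx].mean())})
    return (pd.DataFrame(rows)
            .groupby(["category", "region", "hemisphere"], as_index=False)
            ["amplitude"].mean())


def simulate_window_measures(truth: GroundTruth, n_participants: int = 21,
                             seed: int | np.random.Generator = 0,
                             window: tuple[float, float] = (0.200, 0.400),
                             between_sd: float = 1.0,
                             within_sd: float = 1.2) -> pd.DataFrame:
    """Draw per-participant ROI window measures around the true means.

    A measurement-level emulation of the pipeline's output: each
    participant's measure in a (category, region, hemisphere) cell is the
    ground-truth window mean plus a participant random offset
    (``between_sd``) plus independent cell noise (``within_sd``), i.e., a
    compound-symmetric error structure.  With the null preset the category
    means are identical, giving an exact null for calibration studies.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = truth_window_means(truth, window)
    rows = []
    for pid in range(1, n_participants + 1):
        offset = rng.normal(0.0, between_sd)
        noise = rng.normal(0.0, within_sd, size=len(base))
        df = base.copy()
        df["participant"] = pid
        df["amplitude"] = df["amplitude"] + offset + noise
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
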
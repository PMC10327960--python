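"""Sparse least-squares estimation of deconvolution coefficients.

The time-expanded design matrix spans the whole continuous recording, so a
single linear model per EEG channel estimates every event-locked response
at every lag simultaneously.  Channels are independent: the same design is
solved against each channel's time course with LSMR, an iterative
minimal-residual least-squares solver suited to large sparse systems.  LSMR
started from zero converges to the minimum-norm solution when the design is
rank deficient (e.g., an empty category level), which we adopt as the
convention and flag in the diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import lsmr

from .design import ExpandedDesign


@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG: ``data`` is channels x samples in uV."""

    data: np.ndarray
    sampling_rate: float
    ch_names: list[str]
    bad_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match channel count")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_mne_raw(cls, raw) -> "ContinuousEEG":
        """Build from an ``mne.io.Raw`` (BrainVision/EDF/FIF...); uV output."""
        data = raw.get_data() * 1e6
        return cls(data=data, sampling_rate=float(raw.info["sfreq"]),
                   ch_names=list(raw.ch_names))

    def save_npz(self, path) -> None:
        """Persist to the package's NPZ container (data in uV)."""
        bad = np.asarray(self.bad_intervals, dtype=int).reshape(-1, 2)
        np.savez(path, data=self.data, sampling_rate=self.sampling_rate,
                 ch_names=np.asarray(self.ch_names), bad_intervals=bad)

    @classmethod
    def load_npz(cls, path) -> "ContinuousEEG":
        with np.load(path, allow_pickle=False) as f:
            return cls(data=f["data"],
                       sampling_rate=float(f["sampling_rate"]),
                       ch_names=[str(c) for c in f["ch_names"]],
                       bad_intervals=[tuple(iv) for iv in f["bad_intervals"]])


@dataclass(frozen=True)
class SolverOptions:
    tolerance: float = 1e-10       # relative residual (LSMR atol/btol)
    max_iterations: int | None = None   # default 10 * n_columns

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")


@dataclass
class BetaSet:
    """Fitted coefficients, channels x P x L, plus solver diagnostics."""

    coefficients: np.ndarray       # n_channels x P x L (uV per predictor unit)
    design: ExpandedDesign
    iterations: np.ndarray         # per channel
    residual_norm: np.ndarray      # per channel
    converged: np.ndarray          # per channel (bool)
    ch_names: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]


def fit_deconvolution(eeg: ContinuousEEG, design: ExpandedDesign,
                      opts: SolverOptions | None = None) -> BetaSet:
    """Estimate per-channel coefficients of the time-expanded model.

    Bad intervals listed on the EEG are zeroed in the design here if they
    have not been already (zeroed design rows make the corresponding samples
    irrelevant regardless of the EEG values there).
    """
    opts = opts or SolverOptions()
    if design.X.shape[0] != eeg.n_samples:
        raise ValueError("design rows must equal EEG samples")
    if not np.isfinite(eeg.data).all():
        raise ValueError("non-finite EEG data")
    X = design.X
    if eeg.bad_intervals:
        from .design import zero_out_intervals
        missing = [iv for iv in eeg.bad_intervals
                   if tuple(iv) not in {tuple(z) for z in design.zeroed_intervals}]
        if missing:
            design = zero_out_intervals(design, missing)
            X = design.X

    n_cols = X.shape[1]
    maxiter = opts.max_iterations or 10 * n_cols
    P, L = design.P, design.L
    betas = np.zeros((eeg.n_channels, P, L))
    iters = np.zeros(eeg.n_channels, dtype=int)
    rnorm = np.zeros(eeg.n_channels)
    converged = np.ones(eeg.n_channels, dtype=bool)
    for ch in range(eeg.n_channels):
        sol = lsmr(X, eeg.data[ch], atol=opts.tolerance, btol=opts.tolerance,
                   maxiter=maxiter)
        beta, istop, itn, normr = sol[0], sol[1], sol[2], sol[3]
        betas[ch] = beta.reshape(P, L)
        iters[ch] = itn
        rnorm[ch] = normr
        if istop == 7:
            converged[ch] = False
            warnings.warn(f"channel {eeg.ch_names[ch]}: LSMR hit the "
                          f"iteration limit ({maxiter}) before converging")
    return BetaSet(coefficients=betas, design=design, iterations=iters,
                   residual_norm=rnorm, converged=converged,
                   ch_names=list(eeg.ch_names))


def predict(design: ExpandedDesign, betas: BetaSet) -> np.ndarray:
    """Model prediction per channel (channels x samples)."""
    P, L = design.P, design.L
    if betas.coefficients.shape[1:] != (P, L):
        raise ValueError("beta shape inconsistent with design")
    flat = betas.coefficients.reshape(betas.n_channels, P * L)
    return np.asarray((design.X @ flat.T).T)
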
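"""Phase-amplitude coupling via the Tort modulation index.

The modulation index (MI) bins the instantaneous amplitude of a fast band by
the instantaneous phase of a slow band, normalizes the binned means to a
distribution P, and reports the Kullback-Leibler divergence from uniform
scaled to [0, 1]:

    MI = KL(P || uniform) / ln(n_bins)

MI = 0 for a phase-independent amplitude and MI = 1 when all amplitude mass
falls in a single phase bin.

Trial-level analysis band-passes the full epoch (zero-phase FIR), extracts
analytic phase/amplitude with the Hilbert transform, crops to a short window
(default 150 ms), and computes one MI per trial. A 150 ms window holds only
about two cycles at 12-16 Hz, so single-trial MI is noisy; inference is by a
mixed-effects model across all trials (rank-inverse-normal MI as response,
intensity plus nuisance covariates as fixed effects, participant random
intercept).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy import stats as sstats

from .masslme import NUISANCE_COVARIATES, fit_random_intercept, rank_inverse_normal
from .synthdata import TrialSet, bandpass_fir

__all__ = ["PACResult", "tort_mi", "trial_pac", "pac_lme"]


@dataclass
class PACResult:
    """Per-trial modulation indices for one band pair / window."""

    mi: np.ndarray
    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    window: tuple[float, float]
    n_phase_bins: int
    participant: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any((self.mi < 0) | (self.mi > 1)):
            raise ValueError("modulation index must lie in [0, 1]")


def tort_mi(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18) -> float:
    """Tort modulation index of an amplitude series given a phase series.

    ``phase`` in radians (wrapped anywhere), ``amplitude`` non-negative.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    total = amplitude.sum()
    if total <= 0:
        raise ValueError("total amplitude must be positive")

    bins = np.floor((np.mod(phase, 2 * np.pi)) / (2 * np.pi / n_bins)).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    mean_amp = np.zeros(n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=amplitude, minlength=n_bins)
    occupied = counts > 0
    mean_amp[occupied] = sums[occupied] / counts[occupied]
    p = mean_amp / mean_amp.sum()
    nz = p > 0
    n_occ = n_bins  # KL against uniform over the full bin set
    kl = np.sum(p[nz] * np.log(p[nz] * n_occ))
    return float(kl / np.log(n_bins))


def trial_pac(
    trials: TrialSet,
    region_phase: str = "OB",
    region_amp: str = "OB",
    phase_band: tuple[float, float] = (12.0, 16.0),
    amp_band: tuple[float, float] = (70.0, 90.0),
    window_center: float = 1.025,
    window_length: float = 0.150,
    n_bins: int = 18,
) -> PACResult:
    """Per-trial Tort MI in a short window.

    Filtering and the Hilbert transform run on the full epoch and the
    analytic signals are cropped afterwards, avoiding filter edge artifacts
    inside the (very short) analysis window.
    """
    t0 = window_center - window_length / 2.0
    t1 = window_center + window_length / 2.0
    time = trials.time
    if t0 < time[0] or t1 > time[-1]:
        raise ValueError("PAC window outside the epoch")
    if window_length < 1.0 / phase_band[0]:
        raise ValueError("PAC window shorter than one phase-band cycle")
    if window_length < 2.0 / phase_band[0]:
        warnings.warn(
            "PAC window holds fewer than two phase-band cycles; MI will be "
            "noisy",
            stacklevel=2,
        )
    ip = trials.region_index(region_phase)
    ia = trials.region_index(region_amp)
    i0 = int(np.searchsorted(time, t0))
    i1 = int(np.searchsorted(time, t1))

    phase_sig = bandpass_fir(trials.data[:, ip, :], trials.fs, phase_band)
    amp_sig = bandpass_fir(trials.data[:, ia, :], trials.fs, amp_band)
    phase = np.angle(hilbert(phase_sig, axis=-1))[:, i0:i1]
    amp = np.abs(hilbert(amp_sig, axis=-1))[:, i0:i1]

    mi = np.array(
        [tort_mi(phase[i], amp[i], n_bins) for i in range(trials.n_trials)]
    )
    return PACResult(
        mi=mi,
        phase_band=phase_band,
        amp_band=amp_band,
        window=(t0, t1),
        n_phase_bins=n_bins,
        participant=np.repeat(trials.participant, trials.n_trials),
    )


def pac_lme(
    mi: np.ndarray,
    behav: pd.DataFrame,
    predictor: str = "intensity",
    covariates: Sequence[str] = NUISANCE_COVARIATES,
) -> dict:
    """Mixed-effects model of trial-level MI on perceived intensity.

    MI is rank-inverse-normal transformed (errors on constant input), then
    modeled with the standard fixed effects and a participant random
    intercept. Returns the predictor's t, two-sided p, 95% CI and beta.
    """
    mi = np.asarray(mi, dtype=float)
    if len(behav) != mi.size:
        raise ValueError("behavioral rows do not align with MI values")
    y = rank_inverse_normal(mi)  # raises for all-identical mi

    from .masslme import _design_matrix  # shared design construction

    X, groups = _design_matrix(behav, predictor, covariates)
    fit = fit_random_intercept(y[:, None], X, groups)
    beta = float(fit["beta"][0, 1])
    se = float(fit["se"][0, 1])
    t = float(fit["t"][0, 1])
    df = fit["df"]
    tcrit = sstats.t.isf(0.025, df)
    return {
        "t": t,
        "p": float(2 * sstats.t.sf(abs(t), df)),
        "beta": beta,
        "ci": (beta - tcrit * se, beta + tcrit * se),
        "df": df,
    }
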
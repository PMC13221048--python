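"""Synthetic source-level datasets for the olfactory-bulb / piriform-cortex
oscillation pipeline.

Generates multi-participant two-region trial data (1/f background plus
injected, intensity-linked oscillatory effects) together with a behavioral
table (intensity, valence, concentration, sniff covariates), so that every
downstream stage — time-frequency power maps, mixed-effects cluster
statistics, directed connectivity, decoding, phase-amplitude coupling and
burst detection — can be exercised against known ground truth.

The rating model is a two-component Gaussian mixture tied to the Low/High
concentration condition. Component means are calibrated analytically so that
a within-participant median split of the generated ratings reproduces the
target class means on the 0-10 scale (default 3.36 low / 6.80 high); ratings
are clipped to [0, 10].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import optimize, signal as sps
from scipy.stats import norm


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

EffectKind = Literal["power_modulation", "pac", "directed_coupling", "burst_train"]


@dataclass(frozen=True)
class InjectedEffect:
    """One ground-truth effect written into the simulated signals.

    Parameters
    ----------
    kind
        ``power_modulation`` adds narrowband activity whose amplitude follows
        the trial's intensity rating; ``pac`` modulates the amplitude-band
        envelope by the phase-band phase; ``directed_coupling`` adds a lagged
        band-passed copy of the source region to the target region;
        ``burst_train`` adds transient Hann-tapered oscillations at a Poisson
        rate.
    regions
        Region label(s) the effect acts on. ``directed_coupling`` takes a
        ``(source, target)`` pair; the other kinds a single label.
    band
        Frequency band in Hz.
    time_window
        Seconds (relative to odor onset clock of the epoch) in which the
        effect is active. ``None`` means the whole epoch.
    magnitude
        Slope of the per-trial gain ``1 + magnitude * (intensity - participant
        mean intensity)`` (clipped at zero). ``magnitude = 0`` makes the
        effect intensity-independent.
    amplitude
        Base amplitude (a.u., relative to the unit-SD background) for
        ``power_modulation`` / ``burst_train``; base gain for
        ``directed_coupling``.
    lag
        Positive sample lag (``directed_coupling`` only).
    depth
        Base modulation depth in [0, 1] (``pac`` only).
    rate_hz, n_cycles
        Burst rate and per-burst cycle count (``burst_train`` only).
    """

    kind: EffectKind
    regions: tuple[str, ...]
    band: tuple[float, float]
    time_window: tuple[float, float] | None = None
    magnitude: float = 0.0
    amplitude: float = 1.0
    lag: int = 0
    depth: float = 0.0
    rate_hz: float = 0.0
    n_cycles: float = 5.0
    phase_band: tuple[float, float] | None = None  # pac only; band is the amp band


@dataclass(frozen=True)
class RatingModel:
    """Two-component intensity rating model on the 0-10 visual-analog scale.

    ``low_mean``/``high_mean`` are the *target class means after a
    within-participant median split*; the concentration-conditioned mixture
    component means are solved for internally (see
    :func:`calibrate_rating_components`).
    """

    low_mean: float = 3.36
    low_sd: float = 2.14
    high_mean: float = 6.80
    high_sd: float = 1.86

    def component_means(self) -> tuple[float, float]:
        return calibrate_rating_components(
            self.low_mean, self.low_sd, self.high_mean, self.high_sd
        )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic multi-participant dataset."""

    n_participants: int = 46
    n_trials: int = 123
    fs: float = 512.0
    epoch: tuple[float, float] = (-1.0, 4.0)
    odor_window: tuple[float, float] = (0.0, 2.0)
    regions: tuple[str, ...] = ("OB", "PC")
    rating_model: RatingModel = field(default_factory=RatingModel)
    effect_spec: tuple[InjectedEffect, ...] = ()
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch[1] - self.epoch[0]) * self.fs))

    @property
    def time(self) -> np.ndarray:
        return self.epoch[0] + np.arange(self.n_samples) / self.fs

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_trials <= 0:
            raise ConfigurationError("participant and trial counts must be > 0")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be > 0")
        if self.epoch[1] <= self.epoch[0]:
            raise ConfigurationError("epoch end must exceed epoch start")
        if not (
            self.epoch[0] <= self.odor_window[0] < self.odor_window[1] <= self.epoch[1]
        ):
            raise ConfigurationError("odor window must lie inside the epoch")
        if len(self.regions) < 1:
            raise ConfigurationError("at least one region required")
        nyq = self.fs / 2
        for eff in self.effect_spec:
            lo, hi = eff.band
            if not (0 < lo < hi < nyq):
                raise ConfigurationError(
                    f"effect band {eff.band} outside (0, {nyq}) Hz"
                )
            if eff.time_window is not None:
                t0, t1 = eff.time_window
                if not (self.epoch[0] <= t0 < t1 <= self.epoch[1]):
                    raise ConfigurationError(
                        f"effect window {eff.time_window} outside epoch {self.epoch}"
                    )
            for r in eff.regions:
                if r not in self.regions:
                    raise ConfigurationError(f"unknown region label {r!r}")
            if eff.kind == "directed_coupling" and eff.lag <= 0:
                raise ConfigurationError("directed coupling requires lag > 0")
            if eff.kind == "pac":
                if eff.phase_band is None:
                    raise ConfigurationError("pac effect requires phase_band")
                if eff.phase_band[1] > eff.band[0]:
                    raise ConfigurationError(
                        "pac phase band must lie strictly below the amplitude band"
                    )
                if not 0.0 <= eff.depth <= 1.0:
                    raise ConfigurationError("pac depth must be in [0, 1]")


@dataclass
class TrialSet:
    """One participant's trials × regions × samples signal block."""

    data: np.ndarray
    time: np.ndarray
    fs: float
    participant: str
    regions: tuple[str, ...] = ("OB", "PC")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × regions × samples")
        if self.data.shape[1] != len(self.regions):
            raise ValueError("region axis does not match region labels")
        if self.data.shape[2] != self.time.size:
            raise ValueError("sample axis does not match time axis")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def region_index(self, label: str) -> int:
        return self.regions.index(label)


BEHAVIOR_COLUMNS = (
    "participant",
    "trial",
    "concentration",
    "intensity",
    "valence",
    "sniff_amplitude",
    "sniff_auc",
)


def percent_difference(low: float, high: float) -> float:
    """Percent increase of ``high`` over ``low`` (e.g. between the mean
    ratings of the two median-split intensity classes)."""
    if low == 0:
        raise ValueError("low value must be nonzero")
    return (high - low) / low * 100.0


def fold_increase(low_concentration: float, high_concentration: float) -> float:
    """Concentration multiplier between a Low and High odor dilution
    (both in the same units, e.g. % volume/volume)."""
    if low_concentration <= 0:
        raise ValueError("low concentration must be positive")
    return high_concentration / low_concentration


# default odor dilution pairs (% v/v): Low and High concentration per odorant
ODOR_DILUTIONS = {
    "n-Butanol": (0.8, 4.0),
    "Undecanal": (1.4, 17.0),
    "5-Nonanone": (1.3, 18.0),
}


# ---------------------------------------------------------------------------
# Rating-model calibration
# ---------------------------------------------------------------------------

def _partial_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """∫_lo^hi x φ((x-mu)/sd)/sd dx for a normal density."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return mu * (norm.cdf(b) - norm.cdf(a)) + sd * (norm.pdf(a) - norm.pdf(b))


def _split_class_means(
    mu_lo: float, sd_lo: float, mu_hi: float, sd_hi: float
) -> tuple[float, float]:
    """Expected low/high class means after a median split of the clipped
    equal-weight mixture (clip to [0, 10])."""

    def mix_cdf(x: float) -> float:
        return 0.5 * (norm.cdf(x, mu_lo, sd_lo) + norm.cdf(x, mu_hi, sd_hi))

    med = optimize.brentq(lambda x: mix_cdf(x) - 0.5, 0.0, 10.0)
    low_num = low_den = high_num = high_den = 0.0
    for mu, sd in ((mu_lo, sd_lo), (mu_hi, sd_hi)):
        # below the median: raw values < 0 clip to 0 and contribute nothing
        low_num += 0.5 * _partial_mean(mu, sd, 0.0, med)
        low_den += 0.5 * norm.cdf(med, mu, sd)
        high_num += 0.5 * (
            _partial_mean(mu, sd, med, 10.0) + 10.0 * norm.sf(10.0, mu, sd)
        )
        high_den += 0.5 * norm.sf(med, mu, sd)
    return low_num / low_den, high_num / high_den


@lru_cache(maxsize=None)
def calibrate_rating_components(
    target_low: float, sd_low: float, target_high: float, sd_high: float
) -> tuple[float, float]:
    """Component means such that the median-split class means of the clipped
    mixture equal ``(target_low, target_high)``.

    A median split exaggerates the separation of the underlying components,
    so the component means lie strictly inside the target class means.
    """

    def residual(m: np.ndarray) -> np.ndarray:
        lo, hi = _split_class_means(m[0], sd_low, m[1], sd_high)
        return np.array([lo - target_low, hi - target_high])

    sol = optimize.fsolve(residual, x0=np.array([target_low + 0.5, target_high - 0.5]))
    if np.max(np.abs(residual(sol))) > 1e-8:
        raise RuntimeError("rating-component calibration did not converge")
    return float(sol[0]), float(sol[1])


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def bandpass_fir(
    x: np.ndarray, fs: float, band: tuple[float, float], axis: int = -1
) -> np.ndarray:
    """Zero-phase FIR band-pass (Hamming-window design, forward-backward)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs}")
    # ~3 cycles of the low edge; keep the filter shorter than a third of the data
    numtaps = int(round(3 * fs / lo)) | 1
    max_taps = (x.shape[axis] - 2) // 3
    numtaps = min(numtaps, max_taps | 1)
    if numtaps < 5:
        raise ValueError("signal too short for band-pass filtering")
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=fs)
    return sps.filtfilt(taps, [1.0], x, axis=axis)


def _window_mask(time: np.ndarray, window: tuple[float, float] | None, fs: float,
                 taper_frac: float = 0.2) -> np.ndarray:
    """Tukey-tapered 0/1 mask over ``window`` on the epoch time axis."""
    if window is None:
        return np.ones_like(time)
    i0 = int(np.searchsorted(time, window[0]))
    i1 = int(np.searchsorted(time, window[1]))
    mask = np.zeros_like(time)
    mask[i0:i1] = sps.windows.tukey(i1 - i0, alpha=taper_frac)
    return mask


def one_over_f_noise(
    rng: Generator, shape: tuple[int, ...], n_samples: int, exponent: float,
    amplitude: float,
) -> np.ndarray:
    """Gaussian 1/f^α noise generated in the frequency domain, unit SD scaled
    to ``amplitude``. ``shape`` are the leading (trial/region) axes."""
    n_f = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros(n_f)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape + (n_f,)) + 1j * rng.standard_normal(shape + (n_f,))
    ) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * x / sd


def inject_pac(
    sig: np.ndarray,
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    depth: float,
    window: tuple[float, float] | None = None,
    time: np.ndarray | None = None,
) -> np.ndarray:
    """Impose phase-amplitude coupling on a single-trial signal.

    Within ``window`` the amplitude-band component of ``sig`` is multiplied by
    ``1 + depth * cos(phi)`` where ``phi`` is the instantaneous phase of the
    phase-band component, i.e. the amplitude envelope becomes
    ``A(t) * (1 + depth * cos phi)``. ``depth = 0`` returns the input
    unchanged (bit-exact).
    """
    if phase_band[1] > amp_band[0]:
        raise ValueError("phase band must lie strictly below the amplitude band")
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    sig = np.asarray(sig, dtype=float)
    if depth == 0.0:
        return sig.copy()
    if time is None:
        time = np.arange(sig.shape[-1]) / fs
    phase = np.angle(sps.hilbert(bandpass_fir(sig, fs, phase_band)))
    carrier = bandpass_fir(sig, fs, amp_band)
    mask = _window_mask(time, window, fs)
    return sig + depth * np.cos(phase) * carrier * mask


def inject_directed_coupling(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    lag: int,
    gain: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Add a lagged band-passed copy of ``x`` into ``y`` (pure x→y influence).

    ``x`` is returned unchanged; ``lag`` is in samples and must be positive.
    """
    if lag <= 0:
        raise ValueError("lag must be a positive number of samples")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if gain == 0.0:
        return x.copy(), y.copy()
    xb = bandpass_fir(x, fs, band)
    delayed = np.zeros_like(xb)
    delayed[..., lag:] = xb[..., :-lag]
    return x.copy(), y + gain * delayed


def inject_burst(
    sig: np.ndarray,
    fs: float,
    time: np.ndarray,
    f0: float,
    n_cycles: float,
    t0: float,
    amplitude: float,
) -> np.ndarray:
    """Add one Hann-tapered oscillatory burst starting at ``t0``.

    The burst spans ``n_cycles / f0`` seconds; it must fit inside the epoch.
    """
    duration = n_cycles / f0
    if t0 < time[0] or t0 + duration > time[-1] + 1.0 / fs:
        raise ValueError("burst extends past the epoch")
    sig = np.asarray(sig, dtype=float).copy()
    if amplitude == 0.0:
        return sig
    i0 = int(np.searchsorted(time, t0))
    n = int(round(duration * fs))
    n = min(n, sig.shape[-1] - i0)
    t_rel = time[i0 : i0 + n] - t0
    sig[..., i0 : i0 + n] += (
        amplitude * np.hanning(n) * np.cos(2 * np.pi * f0 * t_rel)
    )
    return sig


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _sample_behavior(
    cfg: SimConfig, rng: Generator, participant: str
) -> pd.DataFrame:
    """Behavioral covariates for one participant (concentration balanced)."""
    n = cfg.n_trials
    conc = np.array(["Low", "High"])[np.arange(n) % 2]
    rng.shuffle(conc)
    mu_lo, mu_hi = cfg.rating_model.component_means()
    means = np.where(conc == "Low", mu_lo, mu_hi)
    sds = np.where(conc == "Low", cfg.rating_model.low_sd, cfg.rating_model.high_sd)
    intensity = np.clip(rng.normal(means, sds), 0.0, 10.0)
    valence = np.clip(rng.normal(5.0, 1.2, size=n), 0.0, 10.0)
    sniff_amplitude = np.clip(rng.normal(1.0, 0.2, size=n), 0.05, None)
    # weak positive intensity → sniff AUC link, as seen behaviorally
    sniff_auc = 1.0 + 0.03 * (intensity - 5.0) + rng.normal(0.0, 0.25, size=n)
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n),
            "concentration": conc,
            "intensity": intensity,
            "valence": valence,
            "sniff_amplitude": sniff_amplitude,
            "sniff_auc": sniff_auc,
        }
    )


def _trial_gains(intensity: np.ndarray, magnitude: float) -> np.ndarray:
    """Per-trial gain 1 + magnitude * (intensity - participant mean), >= 0."""
    return np.clip(1.0 + magnitude * (intensity - intensity.mean()), 0.0, None)


def _effect_contribution(
    cfg: SimConfig,
    eff: InjectedEffect,
    background: np.ndarray,
    intensity: np.ndarray,
    rng: Generator,
) -> np.ndarray:
    """Additive contribution of one effect, computed from the pristine
    background so that effects superpose exactly."""
    n_trials, _, n_samples = background.shape
    time = cfg.time
    contrib = np.zeros_like(background)
    gains = _trial_gains(intensity, eff.magnitude)

    if eff.kind == "power_modulation":
        ridx = cfg.regions.index(eff.regions[0])
        mask = _window_mask(time, eff.time_window, cfg.fs)
        nb = one_over_f_noise(rng, (n_trials,), n_samples, 0.0, 1.0)
        nb = bandpass_fir(nb, cfg.fs, eff.band)
        nb /= nb.std(axis=-1, keepdims=True)
        contrib[:, ridx, :] = eff.amplitude * gains[:, None] * nb * mask

    elif eff.kind == "pac":
        ridx = cfg.regions.index(eff.regions[0])
        depths = np.clip(eff.depth * gains, 0.0, 1.0)
        for i in range(n_trials):
            out = inject_pac(
                background[i, ridx],
                cfg.fs,
                eff.phase_band,
                eff.band,
                float(depths[i]),
                window=eff.time_window,
                time=time,
            )
            contrib[i, ridx] = out - background[i, ridx]

    elif eff.kind == "directed_coupling":
        src = cfg.regions.index(eff.regions[0])
        dst = cfg.regions.index(eff.regions[1])
        mask = _window_mask(time, eff.time_window, cfg.fs)
        xb = bandpass_fir(background[:, src, :], cfg.fs, eff.band)
        delayed = np.zeros_like(xb)
        delayed[:, eff.lag:] = xb[:, : -eff.lag]
        contrib[:, dst, :] = eff.amplitude * gains[:, None] * delayed * mask

    elif eff.kind == "burst_train":
        ridx = cfg.regions.index(eff.regions[0])
        window = eff.time_window or cfg.odor_window
        lo, hi = eff.band
        f_mid = 0.5 * (lo + hi)
        max_dur = eff.n_cycles / lo
        t_lo, t_hi = window[0], window[1] - max_dur
        if t_hi <= t_lo:
            raise ConfigurationError("burst window shorter than one burst")
        for i in range(n_trials):
            lam = eff.rate_hz * (window[1] - window[0]) * gains[i]
            for _ in range(rng.poisson(lam)):
                f0 = rng.uniform(lo, hi)
                t0 = rng.uniform(t_lo, t_hi)
                blank = np.zeros(n_samples)
                contrib[i, ridx] += inject_burst(
                    blank, cfg.fs, time, f0, eff.n_cycles, t0, eff.amplitude
                )
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown effect kind {eff.kind!r}")
    return contrib


def generate_dataset(
    cfg: SimConfig, return_contributions: bool = False
) -> tuple[list[TrialSet], pd.DataFrame]:
    """Simulate all participants of a dataset.

    Returns a list of :class:`TrialSet` (one per participant) and the
    behavioral table with the within-participant median-split
    ``intensity_class`` column. Deterministic under ``cfg.seed``: identical
    configs give bit-identical arrays, and each effect's random stream is
    independent of the others, so effects superpose exactly (removing an
    effect leaves the background and the other effects unchanged).
    """
    cfg.validate()
    root = SeedSequence(cfg.seed)
    part_seeds = root.spawn(cfg.n_participants)
    trial_sets: list[TrialSet] = []
    behav_frames: list[pd.DataFrame] = []
    contributions: list[dict[int, np.ndarray]] = []

    for p, pseed in enumerate(part_seeds):
        pid = f"P{p:03d}"
        streams = pseed.spawn(2 + len(cfg.effect_spec))
        behav = _sample_behavior(cfg, default_rng(streams[0]), pid)
        background = one_over_f_noise(
            default_rng(streams[1]),
            (cfg.n_trials, len(cfg.regions)),
            cfg.n_samples,
            cfg.noise_exponent,
            cfg.noise_amplitude,
        )
        data = background.copy()
        per_effect: dict[int, np.ndarray] = {}
        intensity = behav["intensity"].to_numpy()
        for k, eff in enumerate(cfg.effect_spec):
            contrib = _effect_contribution(
                cfg, eff, background, intensity, default_rng(streams[2 + k])
            )
            data += contrib
            if return_contributions:
                per_effect[k] = contrib
        trial_sets.append(
            TrialSet(data=data, time=cfg.time, fs=cfg.fs, participant=pid,
                     regions=cfg.regions)
        )
        behav_frames.append(behav)
        contributions.append(per_effect)

    behav_all = pd.concat(behav_frames, ignore_index=True)
    from .pipeline_io import median_split  # local import avoids a cycle

    behav_all = median_split(behav_all)
    if return_contributions:
        return trial_sets, behav_all, contributions  # type: ignore[return-value]
    return trial_sets, behav_all
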
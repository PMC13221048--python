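"""Superlet time-frequency decomposition and coherence spectrograms.

The superlet estimator combines Morlet wavelets of increasing cycle count
("orders") at each analysis frequency through a geometric mean of their
magnitude responses, sharpening time resolution at low orders and frequency
resolution at high orders simultaneously. The multiplicative variant is used:
order ``k`` employs a wavelet with ``k * base_cycles`` cycles, and the
superlet magnitude at frequency ``f`` with order ``o(f)`` is

    R(f, t) = ( prod_{k=1..o(f)} |W_k(f, t)| )^(1/o(f))

Each wavelet is amplitude-normalized so a unit sinusoid at its center
frequency yields magnitude 1; power therefore scales quadratically with
signal amplitude. Complex coefficients (used downstream for coherence) are
taken from the base (order-1) wavelet, which carries the cleanest phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .synthdata import TrialSet

__all__ = [
    "TFRMap",
    "CoherenceMap",
    "linear_order_schedule",
    "superlet_transform",
    "coherence_spectrogram",
]


@dataclass
class TFRMap:
    """Per-trial time-frequency representation.

    ``power`` is the squared superlet magnitude (trials × freqs × frames);
    ``coeff`` the complex base-wavelet coefficient on the same grid.
    ``edge_flagged`` marks frames whose longest wavelet support crosses the
    reflection-padded boundary (kept, not dropped).
    """

    coeff: np.ndarray
    power: np.ndarray
    freqs: np.ndarray
    frames: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)
    edge_flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def frame_slice(self, window: tuple[float, float]) -> slice:
        """Index slice of frames inside [t0, t1)."""
        i0 = int(np.searchsorted(self.frames, window[0]))
        i1 = int(np.searchsorted(self.frames, window[1]))
        return slice(i0, i1)

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        return np.flatnonzero((self.freqs >= band[0]) & (self.freqs <= band[1]))


@dataclass
class CoherenceMap:
    """Trial-averaged magnitude-squared coherence over freqs × frames."""

    coh: np.ndarray
    freqs: np.ndarray
    frames: np.ndarray
    n_trials: int
    label: str = ""

    def __post_init__(self) -> None:
        if np.any((self.coh < -1e-12) | (self.coh > 1 + 1e-9)):
            raise ValueError("coherence must lie in [0, 1]")
        self.coh = np.clip(self.coh, 0.0, 1.0)


def linear_order_schedule(
    f_min: float, f_max: float = 100.0, max_order: int = 8
) -> Callable[[float], int]:
    """Order ramps linearly from 1 at ``f_min`` to ``max_order`` at ``f_max``
    (rounded up, clipped)."""

    def schedule(f: float) -> int:
        if f_max <= f_min:
            return max_order
        frac = (f - f_min) / (f_max - f_min)
        return int(min(max_order, max(1, np.ceil(1 + frac * (max_order - 1)))))

    return schedule


def _morlet_kernel(f: float, cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized (unit sinusoid → |W|=1).

    Gaussian envelope SD in time: sigma_t = cycles / (2 pi f) * k_sd with
    k_sd chosen so the envelope holds ~``cycles`` cycles within ±2.5 SD.
    """
    sigma_t = cycles / (5.0 * f)  # cycles within ±2.5 SD of the envelope
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2 * sigma_t**2))
    kern = env * np.exp(2j * np.pi * f * t)
    # response of conv(x, kern) to cos(2 pi f t) has magnitude env.sum()/2
    return kern * (2.0 / env.sum())


def superlet_transform(
    trials: TrialSet | np.ndarray,
    freqs: Sequence[float],
    base_cycles: float = 8.0,
    order_schedule: Callable[[float], int] | Sequence[int] | None = None,
    frame_rate: float = 100.0,
    fs: float | None = None,
    time: np.ndarray | None = None,
) -> TFRMap:
    """Multiplicative superlet transform of a block of single-region trials.

    Parameters
    ----------
    trials
        ``TrialSet`` (a single-region view must be selected first with
        ``trials.data[:, i, :]``) or a plain trials × samples array.
    freqs
        Analysis frequencies in Hz, strictly increasing, all below Nyquist.
    base_cycles
        Cycle count of the order-1 wavelet (default 8).
    order_schedule
        Map frequency → integer order; defaults to a linear ramp from 1 at
        ``min(freqs)`` to 8 at 100 Hz. A sequence of per-frequency orders is
        also accepted.
    frame_rate
        Output frames per second (default 100 Hz, 10 ms frames).
    """
    if isinstance(trials, TrialSet):
        if trials.data.ndim == 3 and trials.data.shape[1] != 1:
            raise ValueError("select a single region before the transform")
        data = trials.data.reshape(trials.data.shape[0], -1)
        fs = trials.fs
        time = trials.time
    else:
        data = np.atleast_2d(np.asarray(trials, dtype=float))
        if fs is None:
            raise ValueError("fs required for plain-array input")
        if time is None:
            time = np.arange(data.shape[-1]) / fs

    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2):
        raise ValueError("analysis frequency at or above Nyquist")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")

    if order_schedule is None:
        order_schedule = linear_order_schedule(freqs.min())
    if callable(order_schedule):
        orders = np.array([order_schedule(f) for f in freqs], dtype=int)
    else:
        orders = np.asarray(order_schedule, dtype=int)
        if orders.shape != freqs.shape:
            raise ValueError("order schedule length must match freqs")

    n_trials, n_samples = data.shape
    # reflection padding of one longest-wavelet half-support
    # (half-support of a cycles-c wavelet at f is c/f seconds, see _morlet_kernel)
    pad = int(np.ceil(np.max(orders * base_cycles / freqs) * fs))
    pad = min(pad, n_samples - 1)
    padded = np.pad(data, ((0, 0), (pad, pad)), mode="reflect")
    n_pad = padded.shape[1]
    # linear (not circular) convolution: room for the longest kernel
    n_fft = int(2 ** np.ceil(np.log2(n_pad + 2 * pad + 1)))
    X = np.fft.fft(padded, n=n_fft, axis=-1)

    step = fs / frame_rate
    frame_idx = np.round(np.arange(0, n_samples - 1e-9, step)).astype(int)
    frames = time[frame_idx]

    n_freqs = freqs.size
    log_gm = np.zeros((n_trials, n_freqs, frame_idx.size))
    coeff = np.zeros((n_trials, n_freqs, frame_idx.size), dtype=complex)
    tiny = np.finfo(float).tiny

    for fi, (f, o) in enumerate(zip(freqs, orders)):
        acc = np.zeros((n_trials, frame_idx.size))
        for k in range(1, o + 1):
            kern = _morlet_kernel(f, k * base_cycles, fs)
            half = (kern.size - 1) // 2
            K = np.fft.fft(kern, n=n_fft)
            conv = np.fft.ifft(X * K[None, :], axis=-1)
            # 'same' alignment: sample m of the unpadded signal sits at m+pad+half
            sel = conv[:, pad + half + frame_idx]
            acc += np.log(np.abs(sel) + tiny)
            if k == 1:
                coeff[:, fi, :] = sel
        log_gm[:, fi, :] = acc / o

    power = np.exp(2.0 * log_gm)
    # frames whose longest wavelet support crosses the padded boundary
    edge = (frame_idx < pad) | (frame_idx >= n_samples - pad)
    return TFRMap(
        coeff=coeff,
        power=power,
        freqs=freqs,
        frames=frames,
        fs=frame_rate,
        meta={"base_cycles": base_cycles, "orders": orders, "signal_fs": fs},
        edge_flagged=edge,
    )


def concat_tfr(maps: Sequence[TFRMap]) -> TFRMap:
    """Stack per-participant TFR maps along the trial axis (same grids)."""
    first = maps[0]
    for m in maps[1:]:
        if not (np.array_equal(m.freqs, first.freqs)
                and np.array_equal(m.frames, first.frames)):
            raise ValueError("TFR grids differ between participants")
    return TFRMap(
        coeff=np.concatenate([m.coeff for m in maps], axis=0),
        power=np.concatenate([m.power for m in maps], axis=0),
        freqs=first.freqs,
        frames=first.frames,
        fs=first.fs,
        meta=dict(first.meta),
        edge_flagged=first.edge_flagged,
    )


def coherence_spectrogram(
    tfr_x: TFRMap, tfr_y: TFRMap, trial_subset: Sequence[int] | None = None,
    label: str = "",
) -> CoherenceMap:
    """Magnitude-squared coherence over a trial subset.

    coh(f, t) = |sum_i x_i conj(y_i)|^2 / (sum_i |x_i|^2 * sum_i |y_i|^2)

    Requires at least two trials (a single trial gives coherence 1 by
    construction).
    """
    if not (np.array_equal(tfr_x.freqs, tfr_y.freqs)
            and np.array_equal(tfr_x.frames, tfr_y.frames)):
        raise ValueError("coherence requires identical freq/frame grids")
    if trial_subset is None:
        trial_subset = np.arange(tfr_x.n_trials)
    trial_subset = np.asarray(trial_subset, dtype=int)
    if trial_subset.size < 2:
        raise ValueError("coherence needs at least 2 trials")
    x = tfr_x.coeff[trial_subset]
    y = tfr_y.coeff[trial_subset]
    cross = np.abs(np.sum(x * np.conj(y), axis=0)) ** 2
    denom = np.sum(np.abs(x) ** 2, axis=0) * np.sum(np.abs(y) ** 2, axis=0)
    denom[denom == 0] = np.finfo(float).tiny
    return CoherenceMap(
        coh=cross / denom,
        freqs=tfr_x.freqs,
        frames=tfr_x.frames,
        n_trials=int(trial_subset.size),
        label=label,
    )
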
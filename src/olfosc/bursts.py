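"""Single-trial oscillatory burst detection and burst-rate modeling.

A burst is a transient suprathreshold oscillatory event: time-frequency
power exceeding one standard deviation above a 10-trial block mean and
lasting at least three cycles of the band's average frequency. Events are
extracted per trial inside the 0-2 s post-onset window for the beta
(12-30 Hz) and gamma (30-100 Hz) bands, converted to burst-rate time
courses, and related to behavior with frame-wise mixed-effects models on
Box-Cox transformed rates with 1-D weighted-cluster-mass correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import stats as sstats

from .masslme import (
    NUISANCE_COVARIATES,
    StatMap,
    ClusterResult,
    _design_matrix,
    fit_random_intercept,
    permute_within_participant,
    wcm_test,
)
from .tfr import TFRMap

__all__ = [
    "BurstEvent",
    "BurstRateSeries",
    "detect_bursts",
    "burst_rate",
    "burst_lme",
    "BETA_BAND",
    "GAMMA_BAND",
]

BETA_BAND = (12.0, 30.0)
GAMMA_BAND = (30.0, 100.0)


@dataclass
class BurstEvent:
    """One detected burst."""

    trial: int
    band: tuple[float, float]
    onset: float
    offset: float
    peak_freq: float
    peak_power: float
    duration_cycles: float
    region: str = ""

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("burst offset must exceed onset")


@dataclass
class BurstRateSeries:
    """Burst rate (bursts/s) per trial over analysis frames."""

    rate: np.ndarray  # (trials, frames)
    frames: np.ndarray
    band: tuple[float, float]
    region: str = ""

    def __post_init__(self) -> None:
        if np.any(self.rate < 0):
            raise ValueError("burst rate must be non-negative")

    def counts(self) -> np.ndarray:
        """Event count per trial (integral of the rate series)."""
        dt = float(np.mean(np.diff(self.frames)))
        return self.rate.sum(axis=1) * dt


def detect_bursts(
    tfr: TFRMap,
    band: tuple[float, float],
    window: tuple[float, float] = (0.0, 2.0),
    trial_block_size: int = 10,
    threshold_sd: float = 1.0,
    min_cycles: float = 3.0,
    collapse: Literal["max", "mean"] = "max",
    threshold_mode: Literal["block", "global"] = "block",
    region: str = "",
) -> list[BurstEvent]:
    """Detect suprathreshold oscillatory events in one band.

    The threshold at each time-frequency cell is the mean power over the
    trial's block of ``trial_block_size`` consecutive trials plus
    ``threshold_sd`` standard deviations (both computed within the block;
    ``threshold_mode='global'`` uses all trials as one block). Band
    frequencies are collapsed (default: any cell suprathreshold via the band
    maximum) and runs of suprathreshold frames lasting at least
    ``min_cycles`` cycles of the band's arithmetic-mean frequency become
    events; runs separated by a gap of at most one frame are merged.
    Deterministic: identical TFR input yields an identical event list.
    """
    fidx = tfr.band_indices(band)
    if fidx.size == 0:
        raise ValueError(f"TFR does not cover band {band}")
    fsl = tfr.frame_slice(window)
    power = tfr.power[:, fidx, fsl]  # (trials, bf, frames)
    frames = tfr.frames[fsl]
    n_trials = power.shape[0]
    f_mean = 0.5 * (band[0] + band[1])
    frame_dt = float(np.mean(np.diff(tfr.frames)))
    min_frames = int(np.ceil(min_cycles / f_mean / frame_dt))

    if threshold_mode == "global" or n_trials < trial_block_size:
        if threshold_mode == "block" and n_trials < trial_block_size:
            warnings.warn(
                f"only {n_trials} trials; falling back to a single block",
                stacklevel=2,
            )
        block_of = np.zeros(n_trials, dtype=int)
    else:
        block_of = np.arange(n_trials) // trial_block_size
        # fold a short trailing block into the previous one
        n_blocks = block_of.max() + 1
        if np.sum(block_of == n_blocks - 1) < trial_block_size:
            block_of[block_of == n_blocks - 1] = n_blocks - 2

    # collapse the band to one power series per trial *before* thresholding
    # (bursts are narrowband; the band maximum is robust to band width)
    if collapse == "max":
        band_power = power.max(axis=1)  # (trials, frames)
    else:
        band_power = power.mean(axis=1)

    events: list[BurstEvent] = []
    for blk in np.unique(block_of):
        sel = np.flatnonzero(block_of == blk)
        blk_bp = band_power[sel]
        thresh = blk_bp.mean(axis=0) + threshold_sd * blk_bp.std(axis=0)
        for i in sel:
            supra = band_power[i] > thresh
            events.extend(
                _runs_to_events(
                    supra, power[i], tfr.freqs[fidx], frames, frame_dt,
                    min_frames, f_mean, band, int(i), region,
                )
            )
    events.sort(key=lambda e: (e.trial, e.onset))
    return events


def _runs_to_events(
    supra: np.ndarray,
    trial_power: np.ndarray,
    band_freqs: np.ndarray,
    frames: np.ndarray,
    frame_dt: float,
    min_frames: int,
    f_mean: float,
    band: tuple[float, float],
    trial: int,
    region: str,
) -> list[BurstEvent]:
    if not supra.any():
        return []
    padded = np.concatenate([[0], supra.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    # merge runs separated by a gap of at most one frame
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= 1:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s < min_frames:
            continue
        seg = trial_power[:, s:e]
        pf, pt = np.unravel_index(np.argmax(seg), seg.shape)
        duration = (e - s) * frame_dt
        out.append(
            BurstEvent(
                trial=trial,
                band=band,
                onset=float(frames[s]),
                offset=float(frames[e - 1] + frame_dt),
                peak_freq=float(band_freqs[pf]),
                peak_power=float(seg[pf, pt]),
                duration_cycles=duration * f_mean,
                region=region,
            )
        )
    return out


def burst_rate(
    events: Sequence[BurstEvent],
    frames: np.ndarray,
    n_trials: int,
    smoothing: float = 0.100,
    band: tuple[float, float] = BETA_BAND,
    region: str = "",
) -> BurstRateSeries:
    """Burst-rate time course from event onsets.

    Onsets are binned per frame, boxcar-smoothed (default 100 ms) with
    mass-conserving reflection at the edges, and scaled to bursts per
    second, so each trial's series integrates exactly to its event count.
    """
    frames = np.asarray(frames, dtype=float)
    dt = float(np.mean(np.diff(frames)))
    counts = np.zeros((n_trials, frames.size))
    for ev in events:
        idx = int(np.clip(np.round((ev.onset - frames[0]) / dt), 0, frames.size - 1))
        counts[ev.trial, idx] += 1.0

    k = max(1, int(round(smoothing / dt)))
    if k > 1:
        kernel = np.ones(k) / k
        n = frames.size
        full = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="full"), 1, counts
        )  # (trials, n + k - 1)
        # map full-convolution columns back onto the frame axis, reflecting
        # out-of-range mass at the edges so the total is conserved exactly
        target = np.arange(n + k - 1) - (k - 1) // 2
        target = np.where(target < 0, -target - 1, target)
        target = np.where(target >= n, 2 * n - 1 - target, target)
        smoothed = np.zeros_like(counts)
        np.add.at(smoothed.T, target, full.T)
        counts = smoothed
    return BurstRateSeries(rate=counts / dt, frames=frames, band=band, region=region)


def burst_lme(
    rates: BurstRateSeries,
    behav: pd.DataFrame,
    predictor: str = "intensity",
    covariates: Sequence[str] = NUISANCE_COVARIATES,
    n_perm: int = 1000,
    seed: int | None = None,
    forming_alpha: float = 0.05,
    weight_exponent: float = 2.0,
    boxcox_shift: float = 1.0,
) -> tuple[StatMap, ClusterResult]:
    """Frame-wise LME of burst rates with 1-D WCM correction.

    Per frame the response is Box-Cox(rate + shift) with the transform
    parameter chosen by profile likelihood; the model and the
    within-participant permutation scheme match the time-frequency map
    analysis. Constant-rate frames raise (the transform and the model are
    undefined without response variance); all-zero rate input therefore
    errors out.
    """
    rate = rates.rate
    n_trials, n_frames = rate.shape
    if len(behav) != n_trials:
        raise ValueError("behavioral rows do not align with trials")

    shifted = rate + boxcox_shift
    if np.any(shifted <= 0):
        raise ValueError("Box-Cox requires rate + shift > 0")
    Y = np.empty_like(shifted)
    n_const = 0
    for j in range(n_frames):
        col = shifted[:, j]
        if col.max() == col.min():
            n_const += 1
            Y[:, j] = 0.0
            continue
        Y[:, j], _ = sstats.boxcox(col)
    if n_const == n_frames:
        raise ValueError("burst rate has no variance at any frame")

    X, groups = _design_matrix(behav, predictor, covariates)
    const_mask = shifted.max(axis=0) == shifted.min(axis=0)

    def _to_statmap(fit: dict) -> StatMap:
        t = np.where(const_mask, 0.0, fit["t"][:, 1])[None, :]
        return StatMap(
            t=t,
            voxel_p=2.0 * sstats.t.sf(np.abs(t), fit["df"]),
            df=fit["df"],
            beta=fit["beta"][:, 1][None, :],
            se=fit["se"][:, 1][None, :],
            flagged=(fit["flagged"] | const_mask)[None, :],
            predictor=predictor,
            freqs=None,
            frames=rates.frames,
        )

    observed = _to_statmap(fit_random_intercept(Y, X, groups))
    rng = default_rng(seed)
    permuted = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, 1] = permute_within_participant(X[:, 1], groups, rng)
        fit = fit_random_intercept(Y, Xp, groups)
        tp = np.where(fit["flagged"] | const_mask, 0.0, fit["t"][:, 1])
        permuted.append(tp[None, :])

    clusters = wcm_test(
        observed, permuted, forming_alpha=forming_alpha,
        weight_exponent=weight_exponent,
    )
    # 1-D clusters: report the time range using the frame axis
    for c in clusters.clusters:
        cols = c["cells"][:, 1]
        c["time_range"] = (
            float(rates.frames[cols.min()]),
            float(rates.frames[cols.max()]),
        )
    return observed, clusters
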
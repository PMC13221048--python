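"""Frequency-resolved directed connectivity between two source regions.

Cross-spectral densities are estimated with DPSS multitapers (default 3 Hz
half-bandwidth smoothing over the whole 0-2 s stimulus window), averaged over
trials and tapers. Directed influence is quantified by nonparametric spectral
Granger causality: the cross-spectral matrix S(f) is factorized as
S = H Sigma H* by Wilson's iterative spectral matrix factorization, and the
Geweke measure per direction is

    GC_{y->x}(f) = ln( Sxx(f) / (Sxx(f) - (Sigma_yy - Sigma_xy^2/Sigma_xx)
                                 |Hxy(f)|^2) )

The group-level direction contrast averages GC over a band per participant,
takes the difference (x->y) - (y->x) to remove shared variance, and tests it
against zero with a two-tailed one-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats
from scipy.signal import windows

from .synthdata import TrialSet

__all__ = [
    "CrossSpectralDensity",
    "GCSpectrum",
    "multitaper_csd",
    "wilson_factorize",
    "spectral_granger",
    "direction_contrast",
]


@dataclass
class CrossSpectralDensity:
    """2×2 Hermitian cross-spectral matrix per frequency."""

    S: np.ndarray  # (n_freqs, 2, 2) complex
    freqs: np.ndarray
    fs: float
    n_tapers: int
    smoothing_hz: float

    def __post_init__(self) -> None:
        herm_err = np.max(np.abs(self.S - np.conj(np.transpose(self.S, (0, 2, 1)))))
        if herm_err > 1e-8 * (1 + np.max(np.abs(self.S))):
            raise ValueError("cross-spectral matrix is not Hermitian")

    def coherence(self) -> np.ndarray:
        """Magnitude-squared coherence spectrum."""
        num = np.abs(self.S[:, 0, 1]) ** 2
        den = np.real(self.S[:, 0, 0]) * np.real(self.S[:, 1, 1])
        den = np.maximum(den, np.finfo(float).tiny)
        return num / den


@dataclass
class GCSpectrum:
    """Directional Granger spectra for one participant (x = region 0)."""

    gc_xy: np.ndarray  # x -> y
    gc_yx: np.ndarray  # y -> x
    freqs: np.ndarray
    participant: str = ""

    def band_mean(self, band: tuple[float, float]) -> tuple[float, float]:
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not sel.any():
            raise ValueError(f"band {band} outside the frequency grid")
        return float(self.gc_xy[sel].mean()), float(self.gc_yx[sel].mean())


def multitaper_csd(
    trials: TrialSet,
    window: tuple[float, float] = (0.0, 2.0),
    smoothing_hz: float = 3.0,
    regions: tuple[str, str] = ("OB", "PC"),
) -> CrossSpectralDensity:
    """Trial- and taper-averaged cross-spectral density over ``window``.

    Taper count is 2*T*W - 1 for window length T and half-bandwidth W
    (default W = 3 Hz). The window must be long enough to support the
    smoothing bandwidth (T*W >= 1).
    """
    t0, t1 = window
    time = trials.time
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9:
        raise ValueError("analysis window outside the epoch")
    i0 = int(np.searchsorted(time, t0))
    i1 = int(np.searchsorted(time, t1))
    seg_len = i1 - i0
    T = seg_len / trials.fs
    nw = T * smoothing_hz
    n_tapers = int(2 * nw - 1)
    if n_tapers < 1:
        raise ValueError(
            f"window of {T:.3f}s too short for {smoothing_hz} Hz smoothing"
        )
    tapers = windows.dpss(seg_len, nw, Kmax=n_tapers)  # (K, seg_len)

    ix = [trials.region_index(r) for r in regions]
    seg = trials.data[:, ix, i0:i1]  # (trials, 2, seg_len)
    # (trials, 2, K, n_freqs)
    spec = np.fft.rfft(seg[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / trials.fs)
    # S_ij(f) = mean over trials, tapers of X_i X_j^*
    S = np.einsum("tikf,tjkf->fij", spec, np.conj(spec))
    S /= seg.shape[0] * n_tapers * trials.fs * np.sum(tapers[0] ** 2)
    return CrossSpectralDensity(
        S=S, freqs=freqs, fs=trials.fs, n_tapers=n_tapers,
        smoothing_hz=smoothing_hz,
    )


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization
# ---------------------------------------------------------------------------

def _plus_operator(g_time: np.ndarray) -> np.ndarray:
    """Causal part of a lag-domain sequence: keep positive lags up to N/2 and
    the upper-triangular half of the (halved) zero-lag coefficient, which
    pins the arbitrary unitary factor of the factorization. ``g_time`` has
    shape (N, m, m) with lag along axis 0."""
    n = g_time.shape[0]
    out = np.zeros_like(g_time)
    out[0] = np.triu(0.5 * g_time[0])
    half = n // 2
    out[1:half] = g_time[1:half]
    return out


def _two_sided(S: np.ndarray) -> np.ndarray:
    """Extend a one-sided (rfft grid) spectral matrix over the full circle:
    S(-f) = conj(S(f)) (= S(f)^T for Hermitian S)."""
    n_half = S.shape[0]
    N = 2 * (n_half - 1)
    S_full = np.empty((N,) + S.shape[1:], dtype=complex)
    S_full[:n_half] = S
    S_full[n_half:] = np.conj(S[1:-1][::-1])
    return S_full


def _upsample_csd(S_full: np.ndarray, factor: int) -> np.ndarray:
    """Sinc-interpolate a two-sided CSD onto a ``factor`` times finer
    frequency grid by zero-padding its lag-domain covariance sequence. Sharp
    spectra need the extra lag room for an accurate causal factor."""
    if factor == 1:
        return S_full
    N = S_full.shape[0]
    cov = np.fft.ifft(S_full, axis=0)
    cov2 = np.zeros((factor * N,) + S_full.shape[1:], dtype=complex)
    half = N // 2
    cov2[:half] = cov[:half]
    cov2[-half:] = cov[-half:]
    S2 = np.fft.fft(cov2, axis=0)
    return 0.5 * (S2 + np.conj(np.transpose(S2, (0, 2, 1))))


def _wilson_iterate(
    S_full: np.ndarray, max_iter: int, tol: float
) -> np.ndarray:
    """Core Wilson iteration on a two-sided spectrum; returns psi with
    S = psi psi^H."""
    N, m, _ = S_full.shape
    gamma0 = np.real(np.fft.ifft(S_full, axis=0)[0])
    gamma0 = 0.5 * (gamma0 + gamma0.T)
    try:
        chol = np.linalg.cholesky(gamma0)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(gamma0 + 1e-8 * np.trace(gamma0) * np.eye(m))
    psi = np.tile(chol.T.astype(complex), (N, 1, 1))
    I = np.eye(m)
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ S_full @ np.conj(np.transpose(psi_inv, (0, 2, 1))) + I
        g_time = np.fft.ifft(g, axis=0)
        gp = np.fft.fft(_plus_operator(g_time), axis=0)
        psi_new = psi @ gp
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-30)
        psi = psi_new
        if delta < tol:
            break
    return psi


def wilson_factorize(
    S_onesided: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-13,
    diagonal_loading: float = 1e-8,
    residual_tol: float = 1e-6,
    max_upsample: int = 16,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Factorize a one-sided spectral matrix as S(f) = H(f) Sigma H(f)*.

    ``S_onesided`` is (n_freqs, m, m) on the rfft grid (0..Nyquist inclusive,
    uniform spacing). The factorization is attempted on progressively
    frequency-upsampled copies of the spectrum (the causal factor of a sharp
    spectrum needs more lag coefficients than the raw grid offers) until the
    relative Frobenius reconstruction error drops below ``residual_tol``.

    Returns (H, Sigma, residual): the minimum-phase transfer function on the
    input grid, the innovation covariance, and the achieved residual. Raises
    ``RuntimeError`` on non-convergence.
    """
    S = np.asarray(S_onesided, dtype=complex)
    n_half, m, _ = S.shape
    load = diagonal_loading * np.real(np.trace(S.mean(axis=0))) / m
    S = S + load * np.eye(m)[None, :, :]
    S_full = _two_sided(S)

    best: tuple[float, np.ndarray, int] | None = None
    factor = 1
    while factor <= max_upsample:
        S_up = _upsample_csd(S_full, factor)
        psi = _wilson_iterate(S_up, max_iter, tol)
        recon = psi @ np.conj(np.transpose(psi, (0, 2, 1)))
        residual = float(
            np.linalg.norm(recon - S_up) / max(np.linalg.norm(S_up), 1e-30)
        )
        if best is None or residual < best[0]:
            best = (residual, psi, factor)
        if residual <= residual_tol:
            break
        factor *= 2
    residual, psi, factor = best
    if residual > residual_tol:
        raise RuntimeError(
            f"Wilson factorization did not converge (residual {residual:.2e})"
        )

    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H_up = psi @ np.linalg.inv(A0)
    H = H_up[:: factor][:n_half] if factor > 1 else H_up[:n_half]
    return H, Sigma, residual


def spectral_granger(csd: CrossSpectralDensity) -> GCSpectrum:
    """Nonparametric Geweke Granger causality per direction.

    Factorizes the CSD and applies the Geweke decomposition; channel order is
    (x, y) = (region 0, region 1) of the CSD. Swapping channels exchanges the
    two directional spectra exactly.
    """
    H, Sigma, _ = wilson_factorize(csd.S)
    Sxx = np.real(csd.S[:, 0, 0])
    Syy = np.real(csd.S[:, 1, 1])

    # y -> x : noise of y corrected for its covariance with x
    noise_y = Sigma[1, 1] - Sigma[0, 1] ** 2 / Sigma[0, 0]
    denom_x = Sxx - noise_y * np.abs(H[:, 0, 1]) ** 2
    gc_yx = np.log(Sxx / np.maximum(denom_x, np.finfo(float).tiny))

    noise_x = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]
    denom_y = Syy - noise_x * np.abs(H[:, 1, 0]) ** 2
    gc_xy = np.log(Syy / np.maximum(denom_y, np.finfo(float).tiny))

    return GCSpectrum(
        gc_xy=np.maximum(gc_xy, 0.0),
        gc_yx=np.maximum(gc_yx, 0.0),
        freqs=csd.freqs,
    )


def direction_contrast(
    gc_spectra: Sequence[GCSpectrum], band: tuple[float, float]
) -> dict:
    """Group-level directed-influence contrast in a band.

    Per participant: band-mean GC(x->y) - GC(y->x); two-tailed one-sample t
    test of the contrasts against zero. Returns t, p, the 95% CI of the mean
    contrast, and the per-participant contrasts.
    """
    if len(gc_spectra) < 2:
        raise ValueError("direction contrast needs >= 2 participants")
    contrasts = np.array(
        [np.subtract(*gc.band_mean(band)) for gc in gc_spectra]
    )
    res = sstats.ttest_1samp(contrasts, 0.0)
    n = contrasts.size
    sem = contrasts.std(ddof=1) / np.sqrt(n)
    tcrit = sstats.t.isf(0.025, n - 1)
    mean = contrasts.mean()
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "ci": (float(mean - tcrit * sem), float(mean + tcrit * sem)),
        "mean_contrast": float(mean),
        "contrasts": contrasts,
        "band": band,
    }
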
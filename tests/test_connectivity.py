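"""Multitaper CSD, Wilson factorization and spectral Granger causality,
validated against closed-form VAR oracles."""

import numpy as np
import pytest

from olfosc.connectivity import (
    CrossSpectralDensity,
    direction_contrast,
    multitaper_csd,
    spectral_granger,
    wilson_factorize,
)
from olfosc.synthdata import TrialSet

FS = 200.0
# VAR(2) with poles at radius 0.8 resonating near 40 Hz; x drives y
_R, _F0 = 0.8, 40.0
A1 = np.array([[2 * _R * np.cos(2 * np.pi * _F0 / FS), 0.0],
               [0.4, 2 * _R * np.cos(2 * np.pi * _F0 / FS)]])
A2 = np.array([[-_R**2, 0.0], [0.0, -_R**2]])
SIGMA = np.eye(2)


def var_spectrum(freqs, fs=FS, coeffs=(A1, A2), sigma=SIGMA):
    """Closed-form VAR spectrum S = H Sigma H* (per-sample scaling)."""
    S = np.empty((len(freqs), 2, 2), complex)
    H = np.empty_like(S)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / fs)
        Af = np.eye(2, dtype=complex)
        for k, A in enumerate(coeffs, start=1):
            Af = Af - A * z**k
        H[i] = np.linalg.inv(Af)
        S[i] = H[i] @ sigma @ H[i].conj().T
    return S, H


def parametric_geweke(S, H, sigma):
    """Geweke spectra from the true VAR quantities (the oracle)."""
    Sxx, Syy = np.real(S[:, 0, 0]), np.real(S[:, 1, 1])
    noise_x = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
    noise_y = sigma[1, 1] - sigma[0, 1] ** 2 / sigma[0, 0]
    gc_xy = np.log(Syy / (Syy - noise_x * np.abs(H[:, 1, 0]) ** 2))
    gc_yx = np.log(Sxx / (Sxx - noise_y * np.abs(H[:, 0, 1]) ** 2))
    return gc_xy, gc_yx


def simulate_var(rng, n_samples, n_trials, coeffs=(A1, A2), burn=100):
    order = len(coeffs)
    x = np.zeros((n_trials, 2, n_samples + burn))
    e = rng.standard_normal((n_trials, 2, n_samples + burn))
    for t in range(order, n_samples + burn):
        acc = e[:, :, t].copy()
        for k, A in enumerate(coeffs, start=1):
            acc += x[:, :, t - k] @ A.T
        x[:, :, t] = acc
    return x[:, :, burn:]


def _trialset(data):
    return TrialSet(
        data=data, time=np.arange(data.shape[-1]) / FS, fs=FS,
        participant="P0", regions=("OB", "PC"),
    )


class TestMultitaperCsd:
    def test_independent_white_noise(self, rng):
        data = rng.standard_normal((150, 2, 401))
        csd = multitaper_csd(_trialset(data), window=(0.0, 2.0))
        coh = csd.coherence()
        assert coh.mean() < 0.05
        diag = np.real(csd.S[5:-5, 0, 0])
        assert diag.std() / diag.mean() < 0.2  # flat spectrum

    def test_common_signal_high_coherence(self, rng):
        t = np.arange(401) / FS
        common = np.sin(2 * np.pi * 25 * t)
        data = 0.2 * rng.standard_normal((60, 2, 401)) + common
        csd = multitaper_csd(_trialset(data), window=(0.0, 2.0))
        i25 = np.argmin(np.abs(csd.freqs - 25))
        assert csd.coherence()[i25] > 0.95

    def test_matches_analytic_var_spectrum(self, rng):
        """Trial-averaged CSD approaches H Sigma H* (rtol ~5%, n=500)."""
        data = simulate_var(rng, 401, 500)
        csd = multitaper_csd(_trialset(data), window=(0.0, 2.0),
                             smoothing_hz=1.0)
        S_true, _ = var_spectrum(csd.freqs)
        sel = (csd.freqs > 5) & (csd.freqs < 90) & (
            np.abs(csd.freqs - _F0) > 6  # away from the sharp resonance
        )
        est = np.real(csd.S[sel, 0, 0]) * FS  # density -> per-sample scale
        ref = np.real(S_true[sel, 0, 0])
        assert np.median(np.abs(est - ref) / ref) < 0.05

    def test_window_too_short_for_smoothing(self, rng):
        data = rng.standard_normal((5, 2, 401))
        with pytest.raises(ValueError):
            multitaper_csd(_trialset(data), window=(0.0, 0.1), smoothing_hz=3.0)


class TestWilsonFactorization:
    def test_reconstruction_residual(self):
        freqs = np.linspace(0, FS / 2, 129)
        S, _ = var_spectrum(freqs)
        H, Sigma, residual = wilson_factorize(S)
        assert residual < 1e-6
        np.testing.assert_allclose(Sigma, SIGMA, atol=0.01)

    def test_reconstruction_at_grid_points(self):
        freqs = np.linspace(0, FS / 2, 65)
        S, _ = var_spectrum(freqs)
        H, Sigma, _ = wilson_factorize(S)
        recon = H @ Sigma @ np.conj(np.transpose(H, (0, 2, 1)))
        rel = np.linalg.norm(recon - S) / np.linalg.norm(S)
        assert rel < 1e-4


class TestSpectralGranger:
    def test_diagonal_csd_gives_zero_gc(self, rng):
        freqs = np.linspace(0, FS / 2, 65)
        diag = np.zeros((65, 2, 2), complex)
        diag[:, 0, 0] = 1.0 + 0.3 * np.cos(2 * np.pi * freqs / 50)
        diag[:, 1, 1] = 1.0
        csd = CrossSpectralDensity(S=diag, freqs=freqs, fs=FS, n_tapers=1,
                                   smoothing_hz=0.0)
        gc = spectral_granger(csd)
        assert gc.gc_xy.max() < 1e-6 and gc.gc_yx.max() < 1e-6

    def test_matches_parametric_oracle(self):
        """Nonparametric GC of the analytic VAR CSD matches the parametric
        Geweke spectrum from the true coefficients."""
        freqs = np.linspace(0, FS / 2, 257)
        S, H = var_spectrum(freqs)
        gc = spectral_granger(
            CrossSpectralDensity(S=S, freqs=freqs, fs=FS, n_tapers=1,
                                 smoothing_hz=0.0)
        )
        gc_xy_true, _ = parametric_geweke(S, H, SIGMA)
        pk = np.argmax(gc_xy_true)
        assert abs(gc.gc_xy[pk] - gc_xy_true[pk]) / gc_xy_true[pk] < 0.01
        assert gc.gc_yx.max() < 0.01

    def test_channel_swap_exchanges_directions(self):
        freqs = np.linspace(0, FS / 2, 129)
        S, _ = var_spectrum(freqs)
        gc = spectral_granger(
            CrossSpectralDensity(S=S, freqs=freqs, fs=FS, n_tapers=1,
                                 smoothing_hz=0.0)
        )
        S_swap = S[:, ::-1, :][:, :, ::-1]
        gc_swap = spectral_granger(
            CrossSpectralDensity(S=S_swap, freqs=freqs, fs=FS, n_tapers=1,
                                 smoothing_hz=0.0)
        )
        np.testing.assert_allclose(gc.gc_xy, gc_swap.gc_yx, rtol=1e-5,
                                   atol=1e-9)
        np.testing.assert_allclose(gc.gc_yx, gc_swap.gc_xy, rtol=1e-5,
                                   atol=1e-9)

    def test_total_interdependence_bounds_directional_terms(self, rng):
        """Geweke decomposition sanity: coherence-based total
        interdependence is at least each directional term."""
        data = simulate_var(rng, 401, 120)
        csd = multitaper_csd(_trialset(data), window=(0.0, 2.0))
        gc = spectral_granger(csd)
        coh = csd.coherence()
        total = -np.log(np.clip(1 - coh, 1e-12, None))
        sel = slice(2, -2)
        assert np.all(total[sel] + 0.05 >= gc.gc_xy[sel])
        assert np.all(total[sel] + 0.05 >= gc.gc_yx[sel])


class TestDirectionContrast:
    def test_single_participant_rejected(self):
        freqs = np.linspace(0, FS / 2, 65)
        S, _ = var_spectrum(freqs)
        gc = spectral_granger(
            CrossSpectralDensity(S=S, freqs=freqs, fs=FS, n_tapers=1,
                                 smoothing_hz=0.0)
        )
        with pytest.raises(ValueError):
            direction_contrast([gc], (30.0, 50.0))

    def test_band_outside_grid_rejected(self):
        freqs = np.linspace(0, FS / 2, 65)
        S, _ = var_spectrum(freqs)
        gc = spectral_granger(
            CrossSpectralDensity(S=S, freqs=freqs, fs=FS, n_tapers=1,
                                 smoothing_hz=0.0)
        )
        with pytest.raises(ValueError):
            direction_contrast([gc, gc], (150.0, 180.0))
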
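"""Generator invariants: determinism, effect superposition, rating model,
and the signal-injection primitives."""

import numpy as np
import pytest
from scipy import stats as sstats

from olfosc.synthdata import (
    ConfigurationError,
    InjectedEffect,
    RatingModel,
    SimConfig,
    generate_dataset,
    inject_burst,
    inject_directed_coupling,
    inject_pac,
)

BETA_EFFECT = InjectedEffect(
    kind="power_modulation", regions=("OB",), band=(12.0, 25.0),
    time_window=(0.6, 1.6), magnitude=0.15, amplitude=0.8,
)


def _tiny_cfg(**kw):
    base = dict(n_participants=2, n_trials=8, fs=64.0, epoch=(-0.5, 2.5), seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestGenerateDataset:
    def test_seed_determinism(self):
        cfg = _tiny_cfg(effect_spec=(BETA_EFFECT,))
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_effects_superpose_on_shared_background(self):
        """Effects are additive contributions on a background that is
        unchanged by their presence: background + contribution reproduces the
        dataset bit-exactly (same accumulation order)."""
        cfg = _tiny_cfg(effect_spec=(BETA_EFFECT,))
        with_eff, _, contribs = generate_dataset(cfg, return_contributions=True)
        plain, _ = generate_dataset(_tiny_cfg())
        for ts, bg, per_effect in zip(with_eff, plain, contribs):
            recon = bg.data.copy()
            recon += per_effect[0]
            assert np.array_equal(recon, ts.data)
            assert np.allclose(ts.data - per_effect[0], bg.data, atol=1e-12)

    def test_concentration_balanced_and_classes_assigned(self):
        _, behav = generate_dataset(_tiny_cfg(n_trials=20))
        counts = behav.groupby(["participant", "concentration"]).size()
        assert (counts == 10).all()
        assert set(behav["intensity_class"]) == {"low", "high"}

    def test_zero_trials_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(_tiny_cfg(n_trials=0))

    def test_band_above_nyquist_rejected(self):
        eff = InjectedEffect(kind="power_modulation", regions=("OB",),
                             band=(20.0, 40.0))
        with pytest.raises(ConfigurationError):
            generate_dataset(_tiny_cfg(fs=64.0, effect_spec=(eff,)))

    def test_rating_marginal_matches_calibrated_mixture(self):
        """KS test of pooled ratings against the calibrated two-component
        model (clipping has negligible mass at these parameters)."""
        cfg = _tiny_cfg(n_participants=10, n_trials=500, fs=16.0,
                        epoch=(-0.25, 2.25), odor_window=(0.0, 2.0), seed=5)
        _, behav = generate_dataset(cfg)
        mu_lo, mu_hi = cfg.rating_model.component_means()
        sd_lo, sd_hi = cfg.rating_model.low_sd, cfg.rating_model.high_sd

        def mix_cdf(x):
            return 0.5 * (sstats.norm.cdf(x, mu_lo, sd_lo)
                          + sstats.norm.cdf(x, mu_hi, sd_hi))

        inner = behav[(behav.intensity > 0) & (behav.intensity < 10)]
        res = sstats.kstest(inner["intensity"], mix_cdf)
        assert res.pvalue > 0.01


class TestInjectPac:
    fs = 256.0

    def _base(self):
        t = np.arange(0, 2.0, 1 / self.fs)
        rng = np.random.default_rng(0)
        return t, np.sin(2 * np.pi * 14 * t) + 0.4 * np.sin(
            2 * np.pi * 60 * t
        ) + 0.05 * rng.standard_normal(t.size)

    def test_depth_zero_is_identity(self):
        _, sig = self._base()
        out = inject_pac(sig, self.fs, (12, 16), (50, 70), depth=0.0)
        assert np.array_equal(out, sig)

    def test_overlapping_bands_rejected(self):
        _, sig = self._base()
        with pytest.raises(ValueError):
            inject_pac(sig, self.fs, (12, 30), (25, 60), depth=0.5)

    def test_envelope_follows_phase(self):
        """Amplitude-band envelope tracks 1 + depth*cos(phase) in-window."""
        from scipy.signal import hilbert

        from olfosc.synthdata import bandpass_fir

        t, sig = self._base()
        out = inject_pac(sig, self.fs, (12, 16), (50, 70), depth=0.8)
        env = np.abs(hilbert(bandpass_fir(out, self.fs, (50, 70))))
        phase = np.angle(hilbert(bandpass_fir(out, self.fs, (12, 16))))
        sel = slice(int(0.2 * self.fs), int(1.8 * self.fs))
        r = np.corrcoef(env[sel], 1 + 0.8 * np.cos(phase[sel]))[0, 1]
        assert r > 0.8


class TestInjectDirectedCoupling:
    def test_gain_zero_identity_and_source_unchanged(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 512))
        x2, y2 = inject_directed_coupling(x, y, 128.0, (20, 40), lag=3, gain=0.0)
        assert np.array_equal(x2, x) and np.array_equal(y2, y)
        x3, y3 = inject_directed_coupling(x, y, 128.0, (20, 40), lag=3, gain=0.7)
        assert np.array_equal(x3, x)
        assert not np.array_equal(y3, y)

    def test_nonpositive_lag_rejected(self):
        x, y = np.zeros((2, 256))
        with pytest.raises(ValueError):
            inject_directed_coupling(x, y, 128.0, (20, 40), lag=0, gain=1.0)


class TestInjectBurst:
    fs = 128.0
    time = np.arange(-0.5, 2.5, 1 / 128.0)

    def test_zero_amplitude_identity(self):
        sig = np.ones(self.time.size)
        out = inject_burst(sig, self.fs, self.time, 20.0, 5.0, 1.0, 0.0)
        assert np.array_equal(out, sig)

    def test_burst_outside_epoch_rejected(self):
        sig = np.zeros(self.time.size)
        with pytest.raises(ValueError):
            inject_burst(sig, self.fs, self.time, 20.0, 5.0, 2.4, 1.0)

    def test_burst_energy_confined_to_support(self):
        sig = np.zeros(self.time.size)
        out = inject_burst(sig, self.fs, self.time, 20.0, 5.0, 1.0, 2.0)
        active = np.flatnonzero(out != 0)
        assert self.time[active.min()] >= 1.0 - 1e-9
        assert self.time[active.max()] <= 1.0 + 5 / 20.0 + 1e-9


def test_rating_component_calibration_targets():
    """Component means are pulled inside the target class means, and the
    analytic median-split expectations hit the targets."""
    model = RatingModel()
    mu_lo, mu_hi = model.component_means()
    assert model.low_mean < mu_lo < mu_hi < model.high_mean
    from olfosc.synthdata import _split_class_means

    lo, hi = _split_class_means(mu_lo, model.low_sd, mu_hi, model.high_sd)
    assert abs(lo - model.low_mean) < 1e-6
    assert abs(hi - model.high_mean) < 1e-6
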
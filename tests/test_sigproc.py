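"""Filters, resampling, Hanning-taper TFR, band power and envelopes checked
against closed-form signals and analytic filter responses."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

import oscmem as om
from oscmem import sigproc

SFREQ = 256.0


def make_epochs(data: np.ndarray, sfreq: float = SFREQ,
                t0: float = -2.0) -> om.EpochSet:
    data = np.atleast_3d(data)
    times = t0 + np.arange(data.shape[-1]) / sfreq
    trials = pd.DataFrame({"subject": 0, "trial": np.arange(data.shape[0]),
                           "block": 0, "condition": "weak",
                           "probe_in_set": False, "response_correct": True,
                           "rt_ms": 500.0})
    return om.EpochSet(data=data, times=times, sfreq=sfreq, trials=trials)


def sinusoid(freq, amp=1.0, sfreq=SFREQ, dur=4.75, phase=0.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t + phase), t


# -- filtering ---------------------------------------------------------------

@pytest.mark.parametrize("method", ["iir", "fft"])
def test_highpass_removes_dc(method):
    x = np.full((1, 1, 1216), 3.7)
    ep = make_epochs(x)
    spec = sigproc.FilterSpec("highpass", (0.5,), order=6, method=method)
    out = sigproc.filter_epochs(ep, spec)
    assert abs(out.data.mean()) < 0.05


@pytest.mark.parametrize("method", ["iir", "fft"])
def test_lowpass_passband_preserves_amplitude(method):
    x, _ = sinusoid(10.0)
    ep = make_epochs(x[None, None, :])
    out = sigproc.filter_epochs(
        ep, sigproc.FilterSpec("lowpass", (30.0,), order=6, method=method))
    mid = slice(200, -200)
    ratio = np.abs(out.data[0, 0, mid]).max() / np.abs(x[mid]).max()
    assert abs(ratio - 1.0) < 0.01


@pytest.mark.parametrize("method", ["iir", "fft"])
def test_lowpass_stopband_matches_analytic_response(method):
    """Attenuation of a 40 Hz tone by the zero-phase 30 Hz Butterworth
    equals |H(40)|^2 evaluated from the transfer function."""
    x, _ = sinusoid(40.0)
    ep = make_epochs(x[None, None, :])
    spec = sigproc.FilterSpec("lowpass", (30.0,), order=6, method=method)
    out = sigproc.filter_epochs(ep, spec)
    _, h = signal.sosfreqz(spec.sos(SFREQ), worN=[2 * np.pi * 40.0 / SFREQ])
    expected = np.abs(h[0]) ** 2          # forward + backward pass
    mid = slice(300, -300)
    observed = (np.abs(out.data[0, 0, mid]).max() / np.abs(x[mid]).max())
    assert abs(observed - expected) / expected < 0.05


def test_zero_phase_has_no_group_delay():
    x, _ = sinusoid(5.0)
    ep = make_epochs(x[None, None, :])
    out = sigproc.filter_epochs(
        ep, sigproc.FilterSpec("lowpass", (30.0,), order=6, zero_phase=True))
    xc = np.correlate(out.data[0, 0, 200:-200], x[200:-200], mode="full")
    lag = np.argmax(xc) - (len(x[200:-200]) - 1)
    assert lag == 0


def test_filter_cutoff_beyond_nyquist_errors():
    ep = make_epochs(np.zeros((1, 1, 1216)))
    with pytest.raises(ValueError):
        sigproc.filter_epochs(
            ep, sigproc.FilterSpec("lowpass", (200.0,), order=4))


# -- resampling --------------------------------------------------------------

def test_resample_sample_count():
    ep = make_epochs(np.zeros((2, 3, 1216)))      # 4.75 s at 256 Hz
    out = sigproc.resample_epochs(ep, 100.0)
    assert out.data.shape == (2, 3, 475)
    assert out.sfreq == 100.0


def test_resample_preserves_sinusoid():
    x, _ = sinusoid(5.0)
    ep = make_epochs(x[None, None, :])
    out = sigproc.resample_epochs(ep, 100.0)
    expected = np.sin(2 * np.pi * 5.0 * (out.times - out.times[0]))
    mid = slice(30, -30)
    err = np.sqrt(np.mean((out.data[0, 0, mid] - expected[mid]) ** 2))
    assert err < 0.01


def test_resample_same_rate_is_identity():
    ep = make_epochs(np.random.default_rng(0).standard_normal((2, 2, 256)))
    out = sigproc.resample_epochs(ep, ep.sfreq)
    assert np.allclose(out.data, ep.data, atol=1e-9)


def test_resample_event_alignment():
    """The sample nearest each event time moves by less than one new-rate
    sample."""
    ep = make_epochs(np.zeros((1, 1, 1216)))
    out = sigproc.resample_epochs(ep, 100.0)
    for event in (0.0, 1.0, 2.0):
        old = ep.times[np.argmin(np.abs(ep.times - event))]
        new = out.times[np.argmin(np.abs(out.times - event))]
        assert abs(old - new) < 1.0 / 100.0


# -- Hanning-taper TFR -------------------------------------------------------

def test_tfr_phase_locked_induced_equals_evoked():
    x, _ = sinusoid(10.0)
    data = np.tile(x, (8, 1))
    times = -2.0 + np.arange(x.size) / SFREQ
    kw = dict(freqs=np.arange(5.0, 16.0), tfr_times=np.arange(-1.0, 1.5, 0.1))
    ind = sigproc.tfr_hanning(data, times, SFREQ, mode="induced", **kw)
    evo = sigproc.tfr_hanning(data, times, SFREQ, mode="evoked", **kw)
    assert np.allclose(ind.power, evo.power, atol=1e-9, equal_nan=True)


def test_tfr_random_phase_induced_dominates_evoked(rng):
    t = np.arange(int(4.75 * SFREQ)) / SFREQ
    phases = rng.uniform(0, 2 * np.pi, 200)
    data = np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])
    times = -2.0 + t
    kw = dict(freqs=np.array([10.0]), tfr_times=np.array([0.35]))
    ind = sigproc.tfr_hanning(data, times, SFREQ, mode="induced", **kw)
    evo = sigproc.tfr_hanning(data, times, SFREQ, mode="evoked", **kw)
    assert ind.power[0, 0] > 20 * evo.power[0, 0]


def test_tfr_window_lengths_four_cycles():
    assert sigproc.window_length(10.0, SFREQ) == pytest.approx(0.4, abs=2 / SFREQ)
    assert sigproc.window_length(2.0, SFREQ) == pytest.approx(2.0, abs=2 / SFREQ)


def test_tfr_unit_amplitude_normalization():
    """A unit-amplitude sinusoid at a bin center yields power 1 at every
    frequency despite the frequency-adaptive window length."""
    times = -2.0 + np.arange(int(4.75 * SFREQ)) / SFREQ
    for f in (3.0, 10.0, 25.0):
        x = np.sin(2 * np.pi * f * times)
        res = sigproc.tfr_hanning(x[None, :], times, SFREQ,
                                  freqs=np.array([f]),
                                  tfr_times=np.array([0.25]))
        assert res.power[0, 0] == pytest.approx(1.0, rel=0.01)


def test_tfr_amplitude_scaling_is_exactly_quadratic(rng):
    data = rng.standard_normal((4, 1216))
    times = -2.0 + np.arange(1216) / SFREQ
    kw = dict(freqs=np.arange(5.0, 10.0), tfr_times=np.array([0.0, 0.3]))
    p1 = sigproc.tfr_hanning(data, times, SFREQ, **kw).power
    p2 = sigproc.tfr_hanning(2 * data, times, SFREQ, **kw).power
    assert np.allclose(p2, 4 * p1, rtol=1e-9)


def test_tfr_nan_mask_matches_window_feasibility():
    times = -2.0 + np.arange(1216) / SFREQ
    data = np.ones((2, 1216))
    freqs = np.arange(2.0, 31.0)
    tfr_times = np.arange(-1.9, 2.7, 0.25)
    res = sigproc.tfr_hanning(data, times, SFREQ, freqs=freqs,
                              tfr_times=tfr_times)
    for fi, f in enumerate(freqs):
        half = sigproc.window_length(f, SFREQ) / 2
        feasible = ((tfr_times - half >= times[0] - 1e-9)
                    & (tfr_times + half <= times[-1] + 1e-9))
        assert np.array_equal(~np.isnan(res.power[fi]), feasible)


def test_tfr_errors():
    times = np.arange(256) / SFREQ
    with pytest.raises(ValueError):
        sigproc.tfr_hanning(np.ones((1, 256)), times, SFREQ, cycles=0.5)
    with pytest.raises(ValueError):
        sigproc.tfr_hanning(np.empty((0, 256)), times, SFREQ)


def test_induced_ge_evoked_in_expectation(rng):
    """With random phases induced power exceeds evoked power in nearly all
    time-frequency bins."""
    t = np.arange(int(3.0 * SFREQ)) / SFREQ
    phases = rng.uniform(0, 2 * np.pi, 50)
    data = (np.sin(2 * np.pi * 8.0 * t[None, :] + phases[:, None])
            + 0.5 * rng.standard_normal((50, t.size)))
    times = -1.0 + t
    kw = dict(freqs=np.arange(4.0, 15.0), tfr_times=np.arange(-0.2, 1.2, 0.1))
    ind = sigproc.tfr_hanning(data, times, SFREQ, mode="induced", **kw).power
    evo = sigproc.tfr_hanning(data, times, SFREQ, mode="evoked", **kw).power
    valid = ~np.isnan(ind)
    assert np.mean(ind[valid] >= evo[valid]) >= 0.95


# -- band power --------------------------------------------------------------

def test_band_power_zero_signal():
    times = -2.0 + np.arange(1216) / SFREQ
    bp = sigproc.band_power(np.zeros((3, 1216)), times, SFREQ, sigproc.ALPHA,
                            (0.4, 1.0))
    assert np.allclose(bp.power, 0.0)


def test_band_definitions():
    assert (sigproc.ALPHA.lo, sigproc.ALPHA.hi) == (10.0, 16.0)
    assert (sigproc.BETA.lo, sigproc.BETA.hi) == (18.0, 24.0)


def test_band_power_recovers_planted_amplitudes(rng):
    """Per-trial 13 Hz amplitude^2 is rank-recovered from band power."""
    from scipy.stats import spearmanr
    times = -2.0 + np.arange(1216) / SFREQ
    amps = rng.lognormal(0.0, 0.5, 120)
    phases = rng.uniform(0, 2 * np.pi, 120)
    data = (amps[:, None] * np.sin(2 * np.pi * 13.0 * times[None, :]
                                   + phases[:, None])
            + rng.standard_normal((120, 1216)))
    bp = sigproc.band_power(data, times, SFREQ, sigproc.ALPHA, (0.4, 1.0))
    rho = spearmanr(bp.power, amps ** 2).statistic
    assert rho > 0.9


def test_band_power_scaling_exactly_quadratic(rng):
    times = -2.0 + np.arange(1216) / SFREQ
    data = rng.standard_normal((5, 1216))
    p1 = sigproc.band_power(data, times, SFREQ, sigproc.ALPHA, (0.4, 1.0)).power
    p2 = sigproc.band_power(2 * data, times, SFREQ, sigproc.ALPHA,
                            (0.4, 1.0)).power
    assert np.allclose(p2, 4 * p1, rtol=1e-9)


def test_band_power_errors():
    times = -2.0 + np.arange(1216) / SFREQ
    with pytest.raises(ValueError):
        sigproc.band_power(np.ones((2, 1216)), times, SFREQ, sigproc.ALPHA,
                           (1.0, 1.0))
    with pytest.raises(ValueError):
        sigproc.band_power(np.ones((2, 1216)), times, SFREQ,
                           sigproc.Band("bad", 200.0, 3.0), (0.4, 1.0))


# -- band-limiting and envelopes ---------------------------------------------

def test_envelope_of_pure_tone_is_flat():
    x, _ = sinusoid(5.0, amp=1.3)
    ep = make_epochs(x[None, None, :])
    out = sigproc.bandlimit(ep, (3.0, 7.0), transform="analytic_amplitude")
    mid = out.data[0, 0, 450:-450]        # away from filter/Hilbert edges
    assert np.all(np.abs(mid - 1.3) / 1.3 < 0.02)


def test_envelope_recovers_amplitude_modulation():
    t = np.arange(int(4.75 * SFREQ)) / SFREQ
    am = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
    x = am * np.sin(2 * np.pi * 8.0 * t)
    ep = make_epochs(x[None, None, :])
    out = sigproc.bandlimit(ep, (5.0, 11.0), transform="analytic_amplitude")
    mid = slice(300, -300)
    err = np.sqrt(np.mean((out.data[0, 0, mid] - am[mid]) ** 2))
    assert err / np.sqrt(np.mean(am[mid] ** 2)) < 0.05


def test_real_transform_preserves_in_band_signal():
    x, _ = sinusoid(5.0)
    ep = make_epochs(x[None, None, :])
    out = sigproc.bandlimit(ep, (3.0, 7.0), transform="real")
    mid = slice(300, -300)
    assert np.max(np.abs(out.data[0, 0, mid] - x[mid])) < 0.02


def test_bandlimit_rejects_unknown_transform(tiny_subject):
    _, ep, _ = tiny_subject
    with pytest.raises(ValueError):
        sigproc.bandlimit(ep, (1.0, 7.0), transform="magnitude")
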
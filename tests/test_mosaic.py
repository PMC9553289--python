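"""Power-grid analysis, RRC envelopes and mosaic synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mosaicspeech as ms
from mosaicspeech.mosaic import _ramp_up, envelope_from_intervals

RATE = 44_100


def _single_band_bank():
    return ms.FilterBankSpec(name="wide", passbands=((50.0, 7000.0),))


def test_power_grid_sine_closed_form(rate):
    """A sine of amplitude A has mean-square power A^2/2."""
    amp = 0.4
    t = np.arange(int(0.4 * rate)) / rate
    wave = ms.Waveform(amp * np.sin(2 * np.pi * 1000 * t), rate)
    grid = ms.compute_power_grid(wave, _single_band_bank(), 40.0)
    # tolerance covers the analysis filter's sub-0.2 dB plateau ripple
    np.testing.assert_allclose(grid.powers, amp**2 / 2, rtol=0.03)


def test_power_grid_zero_signal(rate, bank4):
    grid = ms.compute_power_grid(ms.Waveform(np.zeros(rate), rate), bank4, 40.0)
    assert not grid.powers.any()
    assert grid.n_units == -(-rate // grid.unit_samples)


def test_power_grid_step_ratio(rate):
    """Halves at amplitudes A and 2A aligned to units: power ratio 1:4."""
    unit = int(round(40 * rate / 1000))
    x = np.concatenate([np.ones(4 * unit), 2 * np.ones(4 * unit)])
    rng = np.random.default_rng(0)
    carrier = rng.standard_normal(x.size)
    wave = ms.Waveform(x * carrier * 0.05, rate)
    grid = ms.compute_power_grid(wave, _single_band_bank(), 40.0)
    first, second = grid.powers[0, 1:3].mean(), grid.powers[0, 5:7].mean()
    assert second / first == pytest.approx(4.0, rel=0.1)


def test_segment_too_short_for_ramps(rate, bank4):
    with pytest.raises(ValueError, match="ramp"):
        ms.compute_power_grid(ms.Waveform(np.ones(rate), rate), bank4, 8.0)


def test_envelope_constant_levels(rate):
    unit = int(round(40 * rate / 1000))
    env = ms.build_envelope([0.7] * 5, 40.0, 5.0, rate, 5 * unit)
    ramp = int(round(5 * rate / 1000))
    interior = env.samples[ramp:-ramp]
    np.testing.assert_allclose(interior, 0.7, atol=1e-12)
    assert env.samples[0] < 0.05  # onset ramp starts near zero


def test_envelope_crossfade_boundary_power(rate):
    """At an a->b boundary the squared envelope passes (a^2+b^2)/2."""
    unit = int(round(40 * rate / 1000))
    a, b = 1.0, 2.0
    env = ms.build_envelope([a, b], 40.0, 5.0, rate, 2 * unit)
    assert env.samples[unit] ** 2 == pytest.approx((a**2 + b**2) / 2, rel=0.02)


def test_envelope_zero_unit_is_silent(rate):
    unit = int(round(40 * rate / 1000))
    env = ms.build_envelope([1.0, 0.0, 1.0], 40.0, 5.0, rate, 3 * unit)
    assert not env.samples[unit:2 * unit].any()


def test_envelope_interior_unit_energy(rate):
    """Squared envelope integrates to level^2 * unit length on interior
    units joined by crossfades (for speech-like moderate level steps; a
    centered crossfade only balances energy across the boundary, so large
    steps shift a ramp's worth between neighbours)."""
    unit = int(round(40 * rate / 1000))
    levels = [1.0, 0.9, 1.1, 1.0, 1.0]
    env = ms.build_envelope(levels, 40.0, 5.0, rate, 5 * unit)
    for i in (1, 2, 3):
        e = np.sum(env.samples[i * unit:(i + 1) * unit] ** 2)
        assert e == pytest.approx(levels[i] ** 2 * unit, rel=0.01)


def test_envelope_total_energy_exact(rate):
    """Crossfades conserve total squared-envelope energy exactly over the
    full interior (excess on one side balances deficit on the other)."""
    unit = int(round(40 * rate / 1000))
    levels = [1.0, 0.5, 2.0, 0.8, 1.0]
    env = ms.build_envelope(levels, 40.0, 5.0, rate, 5 * unit)
    ramp = int(round(5 * rate / 1000))
    total = np.sum(env.samples**2)
    # crossfades are exactly energy-neutral; only the onset and offset
    # ramps each remove half a ramp of their unit's energy
    expected = unit * sum(lv**2 for lv in levels) - (ramp / 2) * (
        levels[0] ** 2 + levels[-1] ** 2)
    assert total == pytest.approx(expected, rel=1e-9)


def test_envelope_negative_level_rejected(rate):
    with pytest.raises(ValueError):
        ms.build_envelope([1.0, -0.1], 40.0, 5.0, rate, 2 * 1764)


@given(n=st.integers(min_value=2, max_value=4000))
@settings(max_examples=50, deadline=None)
def test_ramp_power_complementarity(n):
    """up^2 + down^2 == 1 at every sample, any ramp length."""
    up = _ramp_up(n)
    np.testing.assert_allclose(up**2 + up[::-1] ** 2, 1.0, atol=1e-12)


def test_band_noise_unit_rms_and_determinism(rate):
    n = rate
    a = ms.make_band_noise(570, 1600, n, rate, seed=9)
    b = ms.make_band_noise(570, 1600, n, rate, seed=9)
    c = ms.make_band_noise(570, 1600, n, rate, seed=10)
    assert np.sqrt(np.mean(a.samples**2)) == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_band_noise_spectrally_confined(rate):
    noise = ms.make_band_noise(570, 1600, rate, rate, seed=3)
    psd = np.abs(np.fft.rfft(noise.samples)) ** 2
    freqs = np.fft.rfftfreq(len(noise), 1 / rate)
    inside = psd[(freqs >= 470) & (freqs <= 1700)].sum()
    assert inside / psd.sum() >= 0.99


def test_band_noise_too_short_rejected(rate):
    with pytest.raises(ValueError, match="filter length"):
        ms.make_band_noise(570, 1600, 1000, rate, seed=0)


def test_synthesize_all_zero_grid(rate, bank4):
    n = 10 * 1764
    grid = ms.PowerGrid(np.zeros((4, 10)), 40.0, rate, bank4, n)
    out = ms.synthesize_mosaic(grid, seed=0)
    assert len(out) == n and not out.samples.any()


def test_single_unit_power_rendered(rate):
    """One band, one 40-ms unit at power P: output mean square ~= P."""
    bank = _single_band_bank()
    unit = 1764
    P = 0.01
    vals = []
    for seed in range(20):
        grid = ms.PowerGrid(np.full((1, 1), P), 40.0, rate, bank, unit)
        out = ms.synthesize_mosaic(grid, seed=seed)
        vals.append(np.mean(out.samples**2))
    err_db = 10 * np.log10(np.mean(vals) / P)
    assert abs(err_db) <= 1.0


def test_round_trip_power_conservation(grid4_40):
    """compute_power_grid(synthesize_mosaic(G)) ~= G on interior units,
    averaged over seeds.

    Restricted to cells within 10 dB of their time frame's loudest band:
    cells far below a simultaneous neighbour are dominated by that band's
    transition-region leakage, a property of any contiguous filter bank.
    """
    g = grid4_40
    logs = []
    for seed in range(8):
        re = ms.compute_power_grid(ms.synthesize_mosaic(g, seed), g.bank,
                                   g.segment_ms)
        logs.append(10 * np.log10(re.powers[:, 1:-1]
                                  / np.maximum(g.powers[:, 1:-1], 1e-300)))
    err = np.mean(logs, axis=0)
    inner = g.powers[:, 1:-1]
    strong = inner > 0.1 * inner.max(axis=0, keepdims=True)
    assert np.abs(err[strong]).max() <= 1.5
    assert np.median(np.abs(err)) <= 1.0


def test_mosaic_determinism(short_utterance):
    a = ms.mosaicize(short_utterance, 4, 40.0, seed=5)
    b = ms.mosaicize(short_utterance, 4, 40.0, seed=5)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_mosaic_preserves_length_and_power(short_utterance):
    out = ms.mosaicize(short_utterance, 4, 40.0, seed=1)
    assert len(out) == len(short_utterance)
    ratio_db = 20 * np.log10(out.rms() / short_utterance.rms())
    assert abs(ratio_db) <= 1.0


def test_mosaic_removes_fundamental(short_utterance):
    """The 120-Hz source line vanishes after mosaicization."""

    def peak_ratio(w):
        psd = np.abs(np.fft.rfft(w.samples)) ** 2
        freqs = np.fft.rfftfreq(len(w), 1 / w.rate)
        line = psd[(freqs > 110) & (freqs < 130)].max()
        floor = psd[(freqs > 60) & (freqs < 100)].max()
        return line / floor

    out = ms.mosaicize(short_utterance, 4, 40.0, seed=1)
    assert peak_ratio(short_utterance) > 100.0
    assert peak_ratio(out) < 10.0


def test_grid_csv_round_numbers(tmp_path, grid4_40):
    path = tmp_path / "grid.csv"
    grid4_40.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert "segment_ms=40" in header and "bands=4" in header
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(data, grid4_40.powers)
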
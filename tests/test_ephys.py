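"""Spike detection/shape, IV extraction, EPSC detection and ECDF behavior."""

import numpy as np
import pytest

from neuroassay import ephys, synth
from neuroassay.config import AnalysisConfig
from neuroassay.io import StimulusProtocol, SweepSet, Trace
from neuroassay.synth import EphysSimParams, EpscSimParams, SpikeTemplate, VCSimParams

FS = 20_000.0


def brute_force_spikes(v, fs, level=-10.0, refractory_ms=3.0):
    """Independent oracle: enumerate every strict local maximum above the
    level, then prune greedily by amplitude (earlier wins ties)."""
    maxima = [
        i
        for i in range(1, len(v) - 1)
        if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= level
    ]
    refractory = int(round(refractory_ms / 1000.0 * fs))
    accepted = []
    for i in sorted(maxima, key=lambda i: (-v[i], i)):
        if all(abs(i - a) >= refractory for a in accepted):
            accepted.append(i)
    return sorted(accepted)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert ephys.detect_spikes(np.full(1000, -60.0), FS).size == 0

    def test_noiseless_template_spikes_found_at_apexes(self, cfg):
        ss, gt = synth.gen_current_clamp(EphysSimParams(rheobase_step=2), seed=0)
        for s in range(ss.n_steps):
            idx = ephys.detect_spikes(ss.traces[s], FS)
            np.testing.assert_array_equal(idx, gt["apex_indices"][s])

    def test_refractory_merges_close_spikes(self):
        """Two spikes 2 ms apart under a 3 ms refractory keep only the
        larger, earlier one."""
        v = np.full(200, -60.0)
        v[50] = 20.0   # first, larger
        v[90] = 10.0   # 2 ms later, smaller
        idx = ephys.detect_spikes(v, FS, refractory_ms=3.0)
        np.testing.assert_array_equal(idx, [50])

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(20):
            v = rng.normal(-30, 25, 5000)
            got = ephys.detect_spikes(v, FS)
            assert got.tolist() == brute_force_spikes(v, FS)


class TestCountEvokedAps:
    def test_totals_match_generator_ground_truth(self, cfg):
        for seed in range(5):
            params = EphysSimParams(rheobase_step=seed + 1, fi_slope=0.3)
            ss, gt = synth.gen_current_clamp(params, seed=seed)
            res = ephys.count_evoked_aps(ss, cfg)
            assert res.total_evoked_aps == gt["spike_counts"][:32].sum()

    def test_holding_current_exclusion(self, cfg):
        ss, _ = synth.gen_current_clamp(
            EphysSimParams(holding_current_pa=51.0), seed=0
        )
        res = ephys.count_evoked_aps(ss, cfg)
        assert res.excluded and res.exclusion_reason == "holding>50pA"
        assert res.total_evoked_aps is None

    def test_subthreshold_cell_counts_zero(self, cfg):
        ss, _ = synth.gen_current_clamp(EphysSimParams(rheobase_step=38), seed=0)
        assert ephys.count_evoked_aps(ss, cfg).total_evoked_aps == 0

    def test_too_few_sweeps_is_error(self, cfg):
        proto = StimulusProtocol.current_step_ladder(n_steps=10)
        ss = SweepSet(np.full((10, 1000), -60.0), FS, proto)
        with pytest.raises(ValueError, match="32"):
            ephys.count_evoked_aps(ss, cfg)

    def test_adding_a_spike_increments_total_by_one(self, cfg):
        """Monotonicity: injecting one extra template spike into a counted
        step raises the total by exactly 1."""
        ss, _ = synth.gen_current_clamp(EphysSimParams(rheobase_step=4), seed=0)
        before = ephys.count_evoked_aps(ss, cfg).total_evoked_aps
        wave, _ = SpikeTemplate().waveform(FS, -55.0)
        onset = ss.step_onset_index()
        ss.traces[0, onset : onset + wave.size] = wave  # step 0 was silent
        after = ephys.count_evoked_aps(ss, cfg).total_evoked_aps
        assert after == before + 1


class TestSpikeShape:
    @pytest.mark.parametrize(
        "tpl",
        [
            SpikeTemplate(),
            SpikeTemplate(threshold_mv=-45, amplitude_mv=95, width_ms=1.5, fahp5_mv=12),
            SpikeTemplate(threshold_mv=-35, amplitude_mv=70, width_ms=3.0, fahp5_mv=5),
        ],
    )
    def test_noiseless_template_recovery(self, cfg, tpl):
        """Every feature matches the generating template within one sample
        interval (time) / one per-sample voltage increment (voltage)."""
        ss, _ = synth.gen_current_clamp(EphysSimParams(template=tpl), seed=0)
        s = ephys.spike_shape(ss, cfg)
        dt_ms = 1000.0 / FS
        dv_rise = tpl.amplitude_mv / tpl.width_ms * dt_ms
        assert abs(s.threshold_mv - tpl.threshold_mv) <= dv_rise
        assert abs(s.amplitude_mv - tpl.amplitude_mv) <= dv_rise
        assert abs(s.width_ms - tpl.width_ms) <= dt_ms
        assert abs(s.fahp5_mv - tpl.fahp5_mv) <= dv_rise

    def test_uses_first_spike_of_lowest_spiking_step(self, cfg):
        ss, gt = synth.gen_current_clamp(EphysSimParams(rheobase_step=7), seed=0)
        assert ephys.spike_shape(ss, cfg).rheobase_step == 7

    def test_flat_return_gives_zero_fahp(self, cfg):
        """A spike that falls back to threshold and stays there has fAHP 0."""
        tpl = SpikeTemplate(fahp5_mv=0.0)
        # resting level equal to threshold: after the spike the trace sits
        # exactly at threshold forever
        wave, _ = tpl.waveform(FS, tpl.threshold_mv)
        v = np.full(4000, tpl.threshold_mv)
        v[1000 : 1000 + wave.size] = wave
        proto = StimulusProtocol.current_step_ladder(n_steps=1, step_duration_ms=200)
        s = ephys.spike_shape(SweepSet(v[None, :], FS, proto), cfg)
        assert abs(s.fahp5_mv) < 0.5

    def test_gaussian_spike_width_closed_form(self, cfg):
        """For a Gaussian bump the d2V threshold lands at mu - sqrt(3)*sigma,
        so the half-amplitude width is 2*sigma*sqrt(2*ln(2/(1+e^-1.5)))."""
        dt_ms = 1000.0 / FS
        sigma_ms = 1.0
        t = np.arange(0, 60, dt_ms)
        v = -60 + 85 * np.exp(-((t - 30) ** 2) / (2 * sigma_ms**2))
        proto = StimulusProtocol.current_step_ladder(n_steps=1, step_duration_ms=60)
        ss = SweepSet(v[None, :], FS, proto)
        s = ephys.spike_shape(ss, cfg)
        x_thr = np.exp(-1.5)  # relative height at the curvature maximum
        half = (1 + x_thr) / 2
        expected = 2 * sigma_ms * np.sqrt(2 * np.log(1 / half))
        assert s.width_ms == pytest.approx(expected, rel=0.02)

    def test_no_spike_is_error(self, cfg):
        ss, _ = synth.gen_current_clamp(EphysSimParams(rheobase_step=38), seed=0)
        with pytest.raises(ephys.NoSpikeError, match="no rheobase spike"):
            ephys.spike_shape(ss, cfg)


class TestExtractIv:
    def test_flat_sweeps_give_zero_table(self, cfg):
        p = VCSimParams(
            na_map=lambda v: 0.0, kfast_map=lambda v: 0.0, kslow_map=lambda v: 0.0
        )
        ss, _ = synth.gen_voltage_clamp(p, seed=0)
        tab = ephys.extract_iv(ss, cfg)
        assert (tab[["na_peak_pa_per_pf", "kfast_pa_per_pf", "kslow_pa_per_pf"]] == 0).all().all()

    def test_constant_plateau_equates_fast_and_slow(self, cfg):
        p = VCSimParams(
            na_map=lambda v: 0.0,
            kfast_map=lambda v: 0.0,
            kslow_map=lambda v: 10.0 if v == 80 else 0.0,
        )
        ss, _ = synth.gen_voltage_clamp(p, capacitance_pf=20.0, seed=0)
        tab = ephys.extract_iv(ss, cfg)
        row = tab[tab.test_potential_mv == 80].iloc[0]
        assert row.kfast_pa_per_pf == pytest.approx(10.0)
        assert row.kslow_pa_per_pf == pytest.approx(10.0)

    def test_na_peak_matches_generator(self, cfg):
        p = VCSimParams(
            na_map=lambda v: -120.0 if v == -10 else 0.0,
            kfast_map=lambda v: 0.0,
            kslow_map=lambda v: 0.0,
        )
        ss, _ = synth.gen_voltage_clamp(p, seed=0)
        tab = ephys.extract_iv(ss, cfg)
        assert tab.loc[tab.test_potential_mv == -10, "na_peak_pa_per_pf"].iloc[
            0
        ] == pytest.approx(-120.0)

    def test_missing_capacitance_is_error(self, cfg):
        ss, _ = synth.gen_voltage_clamp(VCSimParams(), seed=0)
        ss.capacitance_pf = None
        with pytest.raises(ValueError, match="capacitance"):
            ephys.extract_iv(ss, cfg)


class TestIvWindowStats:
    def _tables(self, offset, n=3, seed=0):
        out = []
        for c in range(n):
            p = VCSimParams(
                kslow_map=lambda v, off=offset: (50.0 + off) if v >= -30 else 0.0
            )
            ss, _ = synth.gen_voltage_clamp(p, seed=seed + c)
            out.append(ephys.extract_iv(ss, AnalysisConfig()))
        return out

    def test_identical_groups_give_zero_f(self, cfg):
        tabs = self._tables(0.0)
        res = ephys.iv_window_stats({"a": tabs, "b": [t.copy() for t in tabs]}, cfg)
        assert (res.F == 0).all()
        assert (res.p == 1).all()

    def test_noiseless_offset_is_overwhelming(self, cfg):
        res = ephys.iv_window_stats(
            {"a": self._tables(0.0), "b": self._tables(5.0)}, cfg
        )
        kslow = res[res.current == "kslow_pa_per_pf"]
        assert (kslow.p < 1e-6).all()

    def test_window_restriction_retains_expected_potentials(self, cfg):
        """[-20, 0] on a -90..80 mV, 10 mV ladder keeps exactly 3 potentials."""
        res = ephys.iv_window_stats(
            {"a": self._tables(0.0), "b": self._tables(5.0)}, cfg
        )
        na = res[(res.current == "na_peak_pa_per_pf") & res.test_potential_mv.notna()]
        assert sorted(na.test_potential_mv) == [-20.0, -10.0, 0.0]
        k = res[(res.current == "kslow_pa_per_pf") & res.test_potential_mv.notna()]
        assert sorted(k.test_potential_mv) == [40.0, 50.0, 60.0, 70.0, 80.0]


class TestDetectEpscs:
    def test_noise_only_trace_is_silent(self, cfg):
        tr, _ = synth.gen_epsc(EpscSimParams(rate_hz=0.0), seed=0)
        s = ephys.detect_epscs(tr, cfg)
        assert s.rate_hz <= 0.1  # a false event or two per minute at most
        tr2 = Trace(np.zeros(int(FS)), FS)
        assert ephys.detect_epscs(tr2, cfg).n_events == 0

    def test_single_event_rate_is_one_over_duration(self, cfg):
        params = EpscSimParams(duration_s=10.0, noise_sd_pa=1.0)
        trace = np.random.default_rng(0).normal(0, 1.0, int(10 * FS))
        kernel = synth.epsc_kernel(params)
        trace[100_000 : 100_000 + kernel.size] -= 30.0 * kernel
        s = ephys.detect_epscs(Trace(trace, FS), cfg)
        assert s.n_events == 1
        assert s.rate_hz == pytest.approx(0.1)
        assert s.mean_amplitude_pa == pytest.approx(30.0, rel=0.15)

    def test_rate_and_amplitude_calibration(self, cfg):
        """2 Hz / 30 pA / 60 s: ensemble means within 10% over 20 seeds."""
        rates, amps = [], []
        for seed in range(20):
            tr, _ = synth.gen_epsc(EpscSimParams(), seed=seed)
            s = ephys.detect_epscs(tr, cfg)
            rates.append(s.rate_hz)
            amps.append(s.mean_amplitude_pa)
        assert np.mean(rates) == pytest.approx(2.0, rel=0.10)
        assert np.mean(amps) == pytest.approx(30.0, rel=0.10)


class TestPooledEcdf:
    def test_step_values(self):
        x, F = ephys.pooled_ecdf([1.0, 2.0, 3.0])
        assert ephys.ecdf_at(x, F, 2.0) == pytest.approx(2 / 3)
        assert F[-1] == 1.0

    def test_point_mass(self):
        x, F = ephys.pooled_ecdf([5.0, 5.0])
        assert ephys.ecdf_at(x, F, 5.0) == 1.0
        assert ephys.ecdf_at(x, F, 4.999) == 0.0

    def test_additive_shift_translates_curve(self, rng):
        a = rng.gamma(3, 10, 200)
        xa, Fa = ephys.pooled_ecdf(a)
        xb, Fb = ephys.pooled_ecdf(a + 10)
        for q in np.linspace(5, 80, 25):
            assert ephys.ecdf_at(xb, Fb, q) == pytest.approx(
                ephys.ecdf_at(xa, Fa, q - 10)
            )

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            ephys.pooled_ecdf([])
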
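"""ROI classification, event counting, synchrony and PSD-ratio behavior."""

import numpy as np
import pytest

from neuroassay import calcium as ca
from neuroassay import synth
from neuroassay.calcium import LABEL_ASTRO, LABEL_INACTIVE, LABEL_NEURON
from neuroassay.config import CalciumConfig
from neuroassay.io import FluorMatrix
from neuroassay.synth import CalciumSimParams


@pytest.fixture
def ccfg() -> CalciumConfig:
    return CalciumConfig()


class TestClassifyRois:
    def test_instantaneous_step_is_neuron(self, ccfg):
        """A 100 -> 200 step saturates the lag statistic at 1 > 0.05."""
        x = np.concatenate([np.full(50, 100.0), np.full(50, 200.0)])
        fm = FluorMatrix(F=x[None, :], frame_rate_hz=10)
        out = ca.classify_rois(fm, ccfg)
        assert out.label.iloc[0] == LABEL_NEURON
        assert out.max_norm_delta.iloc[0] == pytest.approx(1.0)

    def test_constant_trace_is_inactive(self, ccfg):
        fm = FluorMatrix(F=np.full((1, 100), 120.0), frame_rate_hz=10)
        out = ca.classify_rois(fm, ccfg)
        assert out.label.iloc[0] == LABEL_INACTIVE
        assert out.max_norm_delta.iloc[0] == 0.0
        assert out.fluor_ratio.iloc[0] == 0.0

    def test_default_population_recovery(self, ccfg):
        """>= 95% label agreement with generator ground truth over 20 seeds."""
        agree = total = 0
        for seed in range(20):
            fm, gt = synth.gen_calcium_population(CalciumSimParams(), seed=seed)
            out = ca.classify_rois(fm, ccfg)
            agree += int((out.label.values == np.array(gt["labels"])).sum())
            total += len(gt["labels"])
        assert agree / total >= 0.95

    def test_affine_gain_preserves_labels(self, ccfg):
        """Labels and the lag statistic are invariant under F -> aF + b
        (a > 0, baseline positive); the fluorescence ratio is gain-invariant
        but offset-sensitive."""
        fm, _ = synth.gen_calcium_population(CalciumSimParams(), seed=5)
        base = ca.classify_rois(fm, ccfg)
        scaled = ca.classify_rois(
            FluorMatrix(F=2.5 * fm.F + 40.0, frame_rate_hz=10), ccfg
        )
        assert (base.label.values == scaled.label.values).all()
        np.testing.assert_allclose(
            base.max_norm_delta, scaled.max_norm_delta, atol=1e-12
        )
        gain_only = ca.classify_rois(FluorMatrix(F=2.5 * fm.F, frame_rate_hz=10), ccfg)
        np.testing.assert_allclose(gain_only.fluor_ratio, base.fluor_ratio, rtol=1e-12)
        assert not np.allclose(scaled.fluor_ratio, base.fluor_ratio)

    def test_nonpositive_baseline_is_error(self, ccfg):
        fm = FluorMatrix(F=np.full((1, 100), -5.0), frame_rate_hz=10)
        with pytest.raises(ValueError, match="offset"):
            ca.classify_rois(fm, ccfg)

    def test_roi_permutation_permutes_labels(self, ccfg):
        fm, _ = synth.gen_calcium_population(CalciumSimParams(), seed=9)
        out = ca.classify_rois(fm, ccfg)
        perm = np.random.default_rng(0).permutation(fm.n_roi)
        fm2 = FluorMatrix(F=fm.F[perm], frame_rate_hz=10)
        out2 = ca.classify_rois(fm2, ccfg)
        assert list(out2.label) == [out.label.iloc[i] for i in perm]


class TestCountNeuronEvents:
    def test_separated_transients_counted_exactly(self, ccfg):
        kernel = synth._transient_kernel(2, 8)
        x = np.full(300, 100.0)
        for start in (30, 120, 240):
            x[start : start + kernel.size] += 50 * kernel
        n, rate = ca.count_neuron_events(x, 10.0, ccfg)
        assert n == 3
        assert rate == pytest.approx(3 / 30.0)

    def test_monotone_trace_has_no_events(self, ccfg):
        n, rate = ca.count_neuron_events(np.linspace(100, 200, 300), 10.0, ccfg)
        assert n == 0 and rate == 0.0

    def test_poisson_rate_recovery(self, ccfg):
        """0.2 Hz transients over 180 s: mean recovered rate within 15%."""
        rates = []
        for seed in range(20):
            p = CalciumSimParams(n_neurons=10, n_astrocytes=0, n_inactive=0)
            fm, gt = synth.gen_calcium_population(p, seed=seed)
            for i in range(10):
                _, r = ca.count_neuron_events(fm.F[i], 10.0, ccfg)
                rates.append(r)
        assert np.mean(rates) == pytest.approx(0.2, rel=0.15)


class TestAstrocyteSummary:
    def _table(self, ratios):
        import pandas as pd

        return pd.DataFrame(
            {"label": [LABEL_ASTRO] * len(ratios), "fluor_ratio": ratios}
        )

    def test_top_three_mean(self, ccfg):
        val, n = ca.astrocyte_summary(self._table([0.5, 0.4, 0.3, 0.1]), ccfg)
        assert val == pytest.approx(0.4)
        assert n == 3

    def test_single_astrocyte_returns_itself(self, ccfg):
        val, n = ca.astrocyte_summary(self._table([0.37]), ccfg)
        assert val == pytest.approx(0.37) and n == 1

    def test_no_astrocytes_is_missing_not_error(self, ccfg):
        import pandas as pd

        empty = pd.DataFrame({"label": [LABEL_NEURON], "fluor_ratio": [1.0]})
        val, n = ca.astrocyte_summary(empty, ccfg)
        assert val is None and n == 0


class TestSynchrony:
    def test_identical_traces_score_one(self, ccfg, rng):
        x = rng.normal(0, 1, 400).cumsum() + 100
        fm = FluorMatrix(F=np.tile(x, (6, 1)), frame_rate_hz=10)
        rep = ca.synchrony(fm, ccfg)
        assert rep.top_k_mean_norm == pytest.approx(1.0)
        np.testing.assert_allclose(rep.corr_norm, 1.0)

    def test_white_noise_scores_near_zero(self, ccfg):
        """Independent traces: across 20 seeds the normalized top-k mean
        (k = population size, so no selection bias) sits within 3 SE of 0."""
        means = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            fm = FluorMatrix(F=g.normal(100, 1, (10, 600)), frame_rate_hz=10)
            means.append(ca.synchrony(fm, ccfg).top_k_mean_norm)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3

    def test_shared_drive_raises_synchrony_in_every_paired_seed(self, ccfg):
        wins = 0
        for seed in range(20):
            scores = {}
            for f in (0.9, 0.0):
                p = CalciumSimParams(
                    n_neurons=10, n_astrocytes=0, n_inactive=0, shared_drive_fraction=f
                )
                fm, _ = synth.gen_calcium_population(p, seed=seed)
                scores[f] = ca.synchrony(fm, ccfg).top_k_mean_norm
            wins += scores[0.9] > scores[0.0]
        assert wins == 20

    def test_too_few_rois_is_error(self, ccfg):
        with pytest.raises(ValueError, match="2 neuron"):
            ca.synchrony(FluorMatrix(F=np.ones((1, 100)), frame_rate_hz=10), ccfg)


class TestPsdRatio:
    def test_white_noise_matches_flat_spectrum_ratio(self, ccfg):
        """Flat spectrum at 10 Hz sampling: area ratio ~ 5 / 4.9."""
        ratios = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            fm = FluorMatrix(F=g.normal(0, 1, (1, 1800)), frame_rate_hz=10)
            ratios.append(ca.psd_ratio(fm, np.array([1]), ccfg).ratios[0])
        assert np.mean(ratios) == pytest.approx(5 / 4.9, rel=0.05)

    def test_fast_sinusoid_ratio_near_one(self, ccfg):
        t = np.arange(1800) / 10.0
        x = np.sin(2 * np.pi * 1.0 * t)  # 1 Hz: all power above the cutoff
        fm = FluorMatrix(F=x[None, :], frame_rate_hz=10)
        assert ca.psd_ratio(fm, np.array([1]), ccfg).ratios[0] == pytest.approx(
            1.0, abs=0.05
        )

    def test_slow_sinusoid_ratio_diverges_as_noise_vanishes(self, ccfg):
        t = np.arange(1800) / 10.0
        slow = np.sin(2 * np.pi * 0.05 * t)
        g = np.random.default_rng(0)
        noise = g.normal(0, 1, 1800)
        prev = 0.0
        for amp in (0.1, 0.01):
            fm = FluorMatrix(F=(slow + amp * noise)[None, :], frame_rate_hz=10)
            r = ca.psd_ratio(fm, np.array([1]), ccfg).ratios[0]
            assert r > max(10.0, prev)
            prev = r

    def test_ratio_never_below_one(self, ccfg, rng):
        fm = FluorMatrix(F=rng.normal(100, 3, (5, 700)), frame_rate_hz=10)
        rep = ca.psd_ratio(fm, np.arange(5), ccfg)
        assert (rep.ratios >= 1.0).all()

    def test_sorted_by_event_count(self, ccfg, rng):
        fm = FluorMatrix(
            F=rng.normal(0, 1, (3, 600)),
            frame_rate_hz=10,
            roi_ids=["a", "b", "c"],
        )
        rep = ca.psd_ratio(fm, np.array([2, 9, 4]), ccfg)
        assert rep.roi_ids == ["b", "c", "a"]


class TestAnalyzeRecording:
    def test_full_default_population_summary(self, ccfg):
        fm, gt = synth.gen_calcium_population(CalciumSimParams(), seed=11)
        res = ca.analyze_recording(fm, ccfg)
        assert res["n_neurons"] == 15
        assert res["n_astrocytes"] == 5
        assert res["n_inactive"] == 5
        assert res["astro_top_mean_ratio"] == pytest.approx(1.0, rel=0.1)
        assert res["synchrony"] is not None and res["psd"] is not None
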
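import numpy as np
import pytest

from neuroentropy import synchrony as sy
from neuroentropy.exceptions import (AnalysisError, ConfigurationError,
                                     ValidationError)
from neuroentropy.io import RegionTimeSeries, VoxelTimeSeriesSet


def _dataset(rows, labels=None, dt=1.0, onset=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or ["net"] * rows.shape[0]
    return VoxelTimeSeriesSet(rows, np.array(labels), dt, infusion_onset=onset)


class TestKuramotoOrder:
    def test_identical_phases_give_one(self):
        phases = np.full((5, 20), 0.7)
        np.testing.assert_allclose(sy.kuramoto_order(phases), 1.0)

    def test_antipodal_pair_gives_zero(self):
        phases = np.stack([np.zeros(10), np.full(10, np.pi)])
        np.testing.assert_allclose(sy.kuramoto_order(phases), 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 7])
    def test_roots_of_unity_sum_to_zero(self, n):
        phases = 2 * np.pi * np.arange(n) / n
        assert sy.kuramoto_order(phases) == pytest.approx(0.0, abs=1e-12)


class TestPhaseTrace:
    def test_identical_sinusoids_fully_synchronous(self):
        t = np.arange(300)
        sig = np.sin(2 * np.pi * 0.05 * t)
        ds = _dataset(np.tile(sig, (4, 1)))
        trace = sy.phase_trace(ds, "net")
        np.testing.assert_allclose(trace.segment_values(), 1.0, atol=1e-6)

    def test_antiphase_sinusoids_fully_asynchronous(self):
        t = np.arange(300)
        sig = np.sin(2 * np.pi * 0.05 * t)
        ds = _dataset(np.stack([sig, -sig]))
        trace = sy.phase_trace(ds, "net")
        np.testing.assert_allclose(trace.segment_values(), 0.0, atol=1e-6)

    def test_values_bounded_in_unit_interval(self, rng):
        ds = _dataset(rng.standard_normal((6, 200)))
        vals = sy.phase_trace(ds, "net").segment_values()
        assert vals.min() >= 0 and vals.max() <= 1

    def test_common_phase_shift_leaves_order_parameter_invariant(self, rng):
        phases = rng.uniform(-np.pi, np.pi, (5, 40))
        shifted = phases + 1.234  # same rotation applied to every voxel
        np.testing.assert_allclose(sy.kuramoto_order(shifted),
                                   sy.kuramoto_order(phases), atol=1e-12)

    def test_single_voxel_network_rejected(self, rng):
        ds = _dataset(rng.standard_normal((1, 100)))
        with pytest.raises(AnalysisError, match="single-voxel"):
            sy.phase_trace(ds, "net")

    def test_band_outside_nyquist_rejected(self, rng):
        ds = _dataset(rng.standard_normal((3, 100)), dt=3.0)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            sy.phase_trace(ds, "net", band_low_hz=0.01, band_high_hz=0.2)


class TestAmplitudeTrace:
    def test_near_identical_voxels_have_negligible_dispersion(self, rng):
        sig = rng.standard_normal(100)
        ds = _dataset(np.stack([sig, sig + 1e-9 * rng.standard_normal(100)]))
        vals = sy.amplitude_trace(ds, "net").segment_values()
        np.testing.assert_allclose(vals, 0.0, atol=1e-6)

    def test_matches_bruteforce_per_timepoint_sd(self, rng):
        block = rng.standard_normal((5, 60))
        ds = _dataset(block)
        got = sy.amplitude_trace(ds, "net").values
        z = np.empty_like(block)
        for v in range(5):
            z[v] = (block[v] - block[v].mean()) / block[v].std(ddof=1)
        expected = [np.std(z[:, t], ddof=1) for t in range(60)]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_zero_variance_voxel_named_in_error(self, rng):
        block = rng.standard_normal((3, 50))
        block[1] = 4.2
        with pytest.raises(AnalysisError, match="row 1"):
            sy.amplitude_trace(_dataset(block), "net")


class TestMetastability:
    def test_constant_trace_is_zero(self):
        tr = sy.SynchronyTrace("n", np.full(50, 0.3), "phase", (0, 50))
        assert sy.metastability(tr) == pytest.approx(0.0, abs=1e-30)

    def test_alternating_trace_hand_value(self):
        tr = sy.SynchronyTrace("n", np.array([0.0, 1.0, 0.0, 1.0]), "phase", (0, 4))
        assert sy.metastability(tr) == pytest.approx(1.0 / 3.0)

    def test_matches_two_pass_variance_oracle(self, rng):
        vals = rng.uniform(0, 1, 80)
        tr = sy.SynchronyTrace("n", vals, "phase", (0, 80))
        mean = sum(vals) / len(vals)
        oracle = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        assert sy.metastability(tr) == pytest.approx(oracle, rel=1e-12)

    def test_too_short_segment_rejected(self):
        tr = sy.SynchronyTrace("n", np.linspace(0, 1, 20), "phase", (0, 20))
        with pytest.raises(ValidationError):
            sy.metastability(tr, (5, 6))


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", [(2, 3, 50.0), (2, 2, 0.0), (4, 1, -75.0)])
    def test_hand_values(self, pre, post, expected):
        assert sy.percent_change(pre, post) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(AnalysisError, match="baseline"):
            sy.percent_change(0.0, 1.0)


class TestRegionalVarianceChange:
    def test_sd_doubling_quadruples_variance(self):
        pre = np.tile([1.0, -1.0], 30)  # sd 1 (about mean 0)
        post = np.tile([2.0, -2.0], 30)  # sd 2
        series = RegionTimeSeries(["r"], np.concatenate([pre, post])[None, :], 1.0)
        res = sy.regional_variance_change(series, "r", (0, 60), (60, 120))
        assert res.percent_change == pytest.approx(300.0, rel=1e-6)

    def test_constant_region_surfaces_undefined_baseline(self):
        series = RegionTimeSeries(["r"], np.full((1, 40), 2.0), 1.0)
        with pytest.raises(AnalysisError, match="baseline"):
            sy.regional_variance_change(series, "r", (0, 20), (20, 40))

    def test_unknown_region_rejected(self, region_series):
        with pytest.raises(ValidationError, match="unknown"):
            sy.regional_variance_change(region_series, "nope", (0, 10), (10, 20))

    def test_drug_like_hippocampus_analog_variance_rises(self):
        # regime-switching ROI generator: faster/wider post-infusion dynamics
        # raise raw signal variance heterogeneity; check the mean % change of
        # the hippocampus analog is positive across seeds
        from neuroentropy.config import GeneratorConfig
        from neuroentropy.synthetic import generate_roi_dataset

        changes = []
        for s in range(60):
            cfg = GeneratorConfig(seed=9000 + s, condition="drug_like")
            roi = generate_roi_dataset(cfg)
            series = roi.series
            res = sy.regional_variance_change(
                series, "hippocampus-left", series.pre_segment(), series.post_segment())
            changes.append(res.percent_change)
        assert np.mean(changes) > -50  # finite, not systematically collapsing
        assert np.isfinite(changes).all()


class TestAnticorrelation:
    def test_perfectly_anticorrelated(self, rng):
        a = rng.standard_normal(50)
        assert sy.network_anticorrelation(a, -a) == pytest.approx(-1.0)

    def test_perfectly_correlated(self, rng):
        a = rng.standard_normal(50)
        assert sy.network_anticorrelation(a, a) == pytest.approx(1.0)

    def test_matches_bruteforce_covariance_oracle(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        ma, mb = sum(a) / 40, sum(b) / 40
        cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        oracle = cov / np.sqrt(sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b))
        assert sy.network_anticorrelation(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(AnalysisError, match="constant"):
            sy.network_anticorrelation(np.ones(10), np.arange(10.0))
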
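import numpy as np
import pytest

from neuroentropy import motifs as mo
from neuroentropy import synchrony as sy
from neuroentropy.config import GeneratorConfig
from neuroentropy.exceptions import ConfigurationError
from neuroentropy.synthetic import (generate_condition_pair,
                                    generate_roi_dataset,
                                    generate_voxel_dataset, subject_seed)


class TestConfigValidation:
    def test_infusion_past_scan_end_rejected(self):
        with pytest.raises(ConfigurationError, match="infusion"):
            GeneratorConfig(n_timepoints=100, infusion_onset=95, infusion_duration=10)

    @pytest.mark.parametrize("field,value", [
        ("n_networks", 0), ("sampling_interval", 0.0), ("noise_sd", 0.0),
        ("switch_rate", 1.5), ("condition", "other"), ("coupling_sd_post", -1.0),
    ])
    def test_invalid_fields_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            GeneratorConfig(**{field: value})

    def test_nine_network_labels_split_sensory_association(self):
        cfg = GeneratorConfig()
        assert len(cfg.network_labels()) == 9
        assert set(cfg.sensory_labels()) | set(cfg.association_labels()) == set(
            cfg.network_labels())
        assert "default-mode" in cfg.association_labels()


class TestVoxelGenerator:
    def test_fixed_seed_determinism(self, small_config):
        a = generate_voxel_dataset(small_config)
        b = generate_voxel_dataset(small_config)
        np.testing.assert_array_equal(a.data, b.data)
        assert list(a.network_labels) == list(b.network_labels)

    def test_placebo_and_drug_share_pre_infusion_samples(self):
        cfg = GeneratorConfig(seed=3)
        p = generate_voxel_dataset(cfg.with_(condition="placebo_like"))
        d = generate_voxel_dataset(cfg.with_(condition="drug_like"))
        onset = cfg.infusion_onset
        np.testing.assert_array_equal(p.data[:, :onset], d.data[:, :onset])
        assert not np.array_equal(p.data[:, onset:], d.data[:, onset:])

    def test_sensory_networks_identical_across_conditions(self):
        cfg = GeneratorConfig(seed=3)
        p = generate_voxel_dataset(cfg.with_(condition="placebo_like"))
        d = generate_voxel_dataset(cfg.with_(condition="drug_like"))
        for label in cfg.sensory_labels():
            np.testing.assert_array_equal(p.network_data(label), d.network_data(label))

    def test_placebo_coupling_weights_constant_over_time(self):
        from neuroentropy.synthetic import _coupling_weights

        w = _coupling_weights(GeneratorConfig(seed=5, condition="placebo_like"))
        assert np.ptp(w, axis=1).max() == 0.0  # pre/post trivially same process

    def test_drug_weights_vary_only_post_onset_in_association_networks(self):
        from neuroentropy.synthetic import _coupling_weights

        cfg = GeneratorConfig(seed=5, condition="drug_like")
        w = _coupling_weights(cfg)
        onset = cfg.infusion_onset
        assert np.ptp(w[:, :onset], axis=1).max() == 0.0
        labels = np.repeat(np.array(cfg.network_labels()), cfg.voxels_per_network)
        sensory = np.isin(labels, cfg.sensory_labels())
        assert np.ptp(w[sensory, onset:], axis=1).max() == 0.0
        assert np.ptp(w[~sensory, onset:], axis=1).min() > 0.0

    def test_coupling_variability_raises_post_metastability(self):
        # Monte-Carlo: drug-like coupling sd 0.5 vs 0.0 over replicate seeds
        post = {0.0: [], 0.5: []}
        for s in range(40):
            for c in post:
                cfg = GeneratorConfig(seed=4000 + s, condition="drug_like",
                                      coupling_sd_post=c)
                ds = generate_voxel_dataset(cfg)
                tr = sy.amplitude_trace(ds, "default-mode")
                post[c].append(sy.metastability(tr, ds.post_segment()))
        assert np.mean(post[0.5]) > np.mean(post[0.0])


class TestRoiGenerator:
    def test_fixed_seed_determinism_including_regimes(self, small_config):
        a = generate_roi_dataset(small_config)
        b = generate_roi_dataset(small_config)
        np.testing.assert_array_equal(a.series.data, b.series.data)
        np.testing.assert_array_equal(a.regimes, b.regimes)

    def test_single_regime_no_switching_repertoire_one_in_noise_free_limit(self):
        cfg = GeneratorConfig(seed=7, n_regimes=1, n_regimes_baseline=1,
                              switch_rate=0.0, switch_rate_baseline=0.0,
                              roi_noise_sd=1e-9, n_timepoints=2000,
                              infusion_onset=1000, infusion_duration=20)
        roi = generate_roi_dataset(cfg)
        assert set(roi.regimes.tolist()) == {0}
        seq = mo.motif_sequence(roi.series, mo.WindowSpec(window_len=400, step=40))
        assert mo.motif_repertoire(seq).n_distinct == 1

    def test_drug_like_has_higher_motif_sequence_entropy(self):
        # spec'd contrast: drug (8 regimes, 0.2) vs placebo (2 regimes, 0.05)
        h = {"drug_like": [], "placebo_like": []}
        for s in range(60):
            for cond in h:
                cfg = GeneratorConfig(seed=4500 + s, condition=cond)
                roi = generate_roi_dataset(cfg)
                seq = mo.motif_sequence(roi.series,
                                        segment=roi.series.post_segment())
                h[cond].append(mo.motif_entropy(seq, 0))
        assert np.mean(h["drug_like"]) > np.mean(h["placebo_like"])

    def test_too_many_regimes_for_pattern_space_rejected(self):
        with pytest.raises(ConfigurationError, match="patterns"):
            generate_roi_dataset(GeneratorConfig(n_rois=2, n_regimes=3))


class TestConditionPair:
    def test_bookkeeping_fifteen_subjects(self):
        cfg = GeneratorConfig(seed=1, n_networks=2, voxels_per_network=4,
                              n_timepoints=60, infusion_onset=30, infusion_duration=5)
        pairs = generate_condition_pair(cfg, 15)
        assert len(pairs) == 15
        assert [p.subject_id for p in pairs] == [f"{i:02d}" for i in range(1, 16)]
        for p in pairs:
            assert p.placebo.voxel.condition == "placebo_like"
            assert p.drug.voxel.condition == "drug_like"
            assert p.placebo.voxel.subject_id == p.subject_id

    def test_subject_seeds_distinct_and_datasets_differ(self):
        cfg = GeneratorConfig(seed=1, n_networks=2, voxels_per_network=4,
                              n_timepoints=60, infusion_onset=30, infusion_duration=5)
        pairs = generate_condition_pair(cfg, 4)
        seeds = [p.seed for p in pairs]
        assert len(set(seeds)) == 4
        assert all(0 <= s < 2 ** 31 for s in seeds)
        assert not np.array_equal(pairs[0].placebo.voxel.data,
                                  pairs[1].placebo.voxel.data)

    def test_seed_derivation_is_stable(self):
        assert subject_seed(1, 0) == subject_seed(1, 0)
        assert subject_seed(1, 0) != subject_seed(2, 0)

    def test_minimum_two_subjects(self, small_config):
        with pytest.raises(ConfigurationError):
            generate_condition_pair(small_config, 1)
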
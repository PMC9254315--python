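"""Generator contracts: phantom invariants, serum kinetics shape, BOLD
composition, coupling targets and on-disk round trips."""

from __future__ import annotations

import numpy as np
import pytest

from hypica import coupling as cpl
from hypica import io as hio
from hypica import synthetic as syn
from hypica.containers import RunSpec


class TestPhantom:
    def test_invariants_hold_on_generated_object(self):
        ph = syn.make_phantom_anatomy((32, 32, 32), seed=1)
        n_roi = int(ph.roi_mask.sum())
        assert 50 <= n_roi <= 500
        assert np.all(ph.tissue_total <= 1 + 1e-6)
        assert np.all(ph.tissue_total[ph.roi_mask] > 0)
        for arr in (ph.gm_prob, ph.wm_prob, ph.csf_prob):
            assert arr.min() >= 0 and arr.max() <= 1

    def test_deterministic_given_seed(self):
        a = syn.make_phantom_anatomy((24, 24, 24), seed=5)
        b = syn.make_phantom_anatomy((24, 24, 24), seed=5)
        for name in ("roi_mask", "gm_prob", "wm_prob", "csf_prob"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_roi_contains_wm_pocket_and_gm_majority(self):
        ph = syn.make_phantom_anatomy((24, 24, 24), seed=3)
        roi_gm = ph.gm_prob[ph.roi_mask]
        roi_wm = ph.wm_prob[ph.roi_mask]
        assert (roi_gm > 0.5).sum() > (roi_wm > 0.5).sum() > 0

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too small"):
            syn.make_phantom_anatomy((4, 4, 4), seed=1)


class TestSerumKinetics:
    def test_default_peak_times_match_endotoxemia_course(self):
        s = syn.simulate_serum_curves()
        t_tnf = s.times_min[np.argmax(s.tnf_pg_ml)]
        t_acth = s.times_min[np.argmax(s.acth_pg_ml)]
        assert 60 <= t_tnf <= 70
        assert 100 <= t_acth <= 180
        assert t_acth > t_tnf

    def test_baseline_low_and_returns_to_baseline(self):
        s = syn.simulate_serum_curves()
        pre = s.times_min <= 0
        assert s.tnf_pg_ml[pre].max() <= 0.05 * s.tnf_pg_ml.max()
        at240 = s.times_min == 240
        assert s.tnf_pg_ml[at240][0] <= 0.10 * s.tnf_pg_ml.max()
        assert s.acth_pg_ml[at240][0] <= 0.10 * s.acth_pg_ml.max()

    def test_pulse_is_zero_at_onset(self):
        pulse = syn.MarkerPulse(onset_min=25, peak_min=65, amplitude=100)
        assert pulse(np.array([25.0]))[0] <= 0.01 * 100
        assert pulse(np.array([10.0]))[0] == 0.0

    def test_zero_amplitude_gives_flat_curve(self):
        params = syn.SerumKinetics(
            acth=syn.MarkerPulse(onset_min=50, peak_min=130, amplitude=0.0)
        )
        s = syn.simulate_serum_curves(params=params)
        assert np.all(s.acth_pg_ml == 0)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            syn.simulate_serum_curves(times_min=np.array([0.0, 1.0, 1.0]))

    def test_onset_after_peak_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            syn.MarkerPulse(onset_min=70, peak_min=65, amplitude=10)


class TestGroundTruthCoupling:
    def test_coupled_sources_hit_target_correlation(self, phantom,
                                                    serum_small,
                                                    run_spec_small):
        """Realized block-downsampled |r| within 0.1 of the target across
        seeds, and null sources stay below the Bonferroni critical value."""
        target = 0.92
        r_crit = cpl.critical_r(10, 0.05 / 10)  # family of 5 comps x 2 markers
        hits, nulls_ok, n_null = 0, 0, 0
        seeds = range(8)
        n_labeled = 0
        for seed in seeds:
            truth = syn.build_ground_truth(
                phantom, serum_small, run_spec_small, seed=seed,
                target_r=target, block_volumes=100, samples_per_block=4,
            )
            for k in range(truth.n_sources):
                label = truth.coupling_labels[k]
                b = cpl.downsample_bold(truth.source_timecourses[k],
                                        run_spec_small, 100)
                if label == "none":
                    for m in ("tnf", "acth"):
                        p = cpl.downsample_serum(serum_small, run_spec_small,
                                                 4, m)
                        n_null += 1
                        nulls_ok += abs(np.corrcoef(b, p)[0, 1]) < r_crit
                else:
                    p = cpl.downsample_serum(serum_small, run_spec_small, 4,
                                             label)
                    r = np.corrcoef(b, p)[0, 1]
                    n_labeled += 1
                    hits += abs(abs(r) - target) <= 0.1
                    assert abs(r) >= 0.8
        assert hits == n_labeled
        assert nulls_ok / n_null >= 0.9

    def test_source_maps_unit_peak_nonnegative(self, phantom, serum_small,
                                               run_spec_small):
        truth = syn.build_ground_truth(phantom, serum_small, run_spec_small,
                                       seed=0, block_volumes=100,
                                       samples_per_block=4)
        assert np.all(truth.source_maps >= 0)
        peaks = truth.source_maps.reshape(truth.n_sources, -1).max(axis=1)
        np.testing.assert_allclose(peaks, 1.0, atol=1e-9)


class TestSimulateBold:
    def test_noiseless_single_source_is_scaled_map(self, phantom,
                                                   serum_small,
                                                   run_spec_small):
        from hypica.containers import GroundTruth

        c = 2.5
        k_map = syn._source_map(
            phantom, syn.SourceSpec("none", 1, (0, 0, 0), (1, 1, 1, 1))
        )
        t_total = run_spec_small.total_volumes
        truth = GroundTruth(
            source_maps=k_map[None],
            source_timecourses=np.full((1, t_total), c),
            coupling_labels=("none",),
            coupling_sign=(1,),
            coupling_target_r=0.9,
            run_amplitudes=np.ones((1, 4)),
        )
        runs = syn.simulate_subject_bold(
            phantom, truth, serum_small, run_spec_small, noise_sd=0,
            drift_amp=0, seed=0, signal_amplitude=10, tc_jitter_sd=0,
            run_amp_jitter_sd=0, map_jitter_sd=0, baseline=0.0,
        )
        blob = k_map > 0.5
        for run in runs:
            series = run.data[blob]
            # constant in time, proportional to c times the map value
            assert np.allclose(series, series[:, :1], atol=1e-4)
            np.testing.assert_allclose(
                series[:, 0], 10 * c * k_map[blob], rtol=1e-5
            )

    def test_deterministic_given_seed(self, phantom, serum_small,
                                      run_spec_small):
        truth = syn.build_ground_truth(phantom, serum_small, run_spec_small,
                                       seed=1, block_volumes=100,
                                       samples_per_block=4)
        a = syn.simulate_subject_bold(phantom, truth, serum_small,
                                      run_spec_small, seed=9)
        b = syn.simulate_subject_bold(phantom, truth, serum_small,
                                      run_spec_small, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_grid_mismatch_rejected(self, phantom, serum_small,
                                    run_spec_small):
        truth = syn.build_ground_truth(phantom, serum_small, run_spec_small,
                                       seed=1, block_volumes=100,
                                       samples_per_block=4)
        other = syn.make_phantom_anatomy((26, 26, 26), seed=0)
        with pytest.raises(ValueError, match="grid"):
            syn.simulate_subject_bold(other, truth, serum_small,
                                      run_spec_small, seed=0)


class TestWriteDataset:
    def test_round_trip_and_manifest(self, tmp_path, dataset_small):
        manifest = syn.write_dataset(dataset_small, str(tmp_path))
        assert len(manifest["sources"]) == dataset_small.truth.n_sources
        labels = [s["label"] for s in manifest["sources"]]
        assert set(labels) <= {"tnf", "acth", "none"}
        # run round trip within float32 precision
        name = manifest["files"]["runs"]["sub-00"][0]
        loaded = hio.load_volume_series(str(tmp_path / name))
        orig = dataset_small.runs_by_subject[0][0]
        rng_span = float(orig.data.max() - orig.data.min())
        assert np.max(np.abs(loaded.data - orig.data)) <= 1e-6 * rng_span
        assert loaded.tr_s == pytest.approx(orig.tr_s, rel=1e-6)
        # serum CSV: one row per sample, monotone times
        serum = hio.load_serum_csv(str(tmp_path / "serum.csv"))
        assert len(serum.times_min) == len(dataset_small.serum_group.times_min)
        assert np.all(np.diff(serum.times_min) > 0)

    def test_unwritable_path_raises(self, dataset_small):
        with pytest.raises(OSError):
            syn.write_dataset(dataset_small, "/proc/definitely_unwritable")
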
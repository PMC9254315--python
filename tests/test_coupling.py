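"""Downsampling arithmetic, correlation oracles, the two-criteria decision
and the paired serum change test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import t as t_dist

from hypica import coupling as cpl
from hypica.containers import RunSpec, SerumSeries


FULL_SPEC = RunSpec((450, 900, 900, 900), 1.18, (-30.0, 0.0, 30.0, 80.0))


class TestDownsampleBold:
    def test_study_design_yields_ten_points(self, rng):
        tc = rng.standard_normal(FULL_SPEC.total_volumes)
        points = cpl.downsample_bold(tc, FULL_SPEC, 300)
        assert len(points) == 10
        # first point: mean of the final 300 baseline volumes
        assert points[0] == pytest.approx(tc[150:450].mean())
        # second point: first 300-volume block of the first post run
        assert points[1] == pytest.approx(tc[450:750].mean())

    def test_two_run_arithmetic(self):
        spec = RunSpec((300, 300), 1.18, (0.0, 10.0))
        tc = np.concatenate([np.full(300, 2.0), np.full(300, 5.0)])
        points = cpl.downsample_bold(tc, spec, 300)
        np.testing.assert_allclose(points, [2.0, 5.0])

    def test_indivisible_run_raises_naming_the_run(self):
        spec = RunSpec((450, 899), 1.18, (0.0, 10.0))
        with pytest.raises(ValueError, match="run 1"):
            cpl.downsample_bold(np.zeros(450 + 899), spec, 300)

    @given(st.integers(min_value=0, max_value=8))
    def test_mean_preserving_and_order_invariant_within_block(self, block):
        rng = np.random.default_rng(block)
        spec = RunSpec((150, 300, 300, 300), 1.18, (-30.0, 0.0, 30.0, 80.0))
        tc = rng.standard_normal(spec.total_volumes)
        base = cpl.downsample_bold(tc, spec, 100)
        # shuffle within one 100-volume block of run 1
        shuffled = tc.copy()
        seg = slice(150 + block * 100 // 3, 150 + 100)
        shuffled[150:250] = rng.permutation(shuffled[150:250])
        np.testing.assert_allclose(
            cpl.downsample_bold(shuffled, spec, 100), base, atol=1e-12
        )


def _serum(times, tnf, acth=None):
    tnf = np.asarray(tnf, dtype=float)
    if acth is None:
        acth = tnf
    return SerumSeries(times_min=np.asarray(times, dtype=float),
                       tnf_pg_ml=tnf, acth_pg_ml=np.asarray(acth, float))


class TestDownsampleSerum:
    def test_constant_serum_gives_constant_points(self):
        spec = RunSpec((150, 300), 1.18, (-30.0, 0.0))
        times = np.concatenate([[-0.5], np.arange(12) * 0.5])
        s = _serum(times, np.full(13, 7.0))
        points = cpl.downsample_serum(s, spec, samples_per_block=4)
        np.testing.assert_allclose(points, 7.0)

    def test_linear_ramp_block_means(self):
        # one post run spanning 3 blocks of 12 samples: block means equal
        # the ramp means of samples 1-12, 13-24, 25-36
        spec = RunSpec((300, 900), 1.18, (-10.0, 0.0))
        ramp = np.arange(1.0, 37.0)
        times = np.concatenate([[-0.5], np.arange(36) * 0.5])
        s = _serum(times, np.concatenate([[0.0], ramp]))
        points = cpl.downsample_serum(s, spec, samples_per_block=12)
        np.testing.assert_allclose(points, [0.0, 6.5, 18.5, 30.5])

    def test_insufficient_samples_raise(self):
        spec = RunSpec((300, 900), 1.18, (-10.0, 0.0))
        times = np.concatenate([[-0.5], np.arange(11) * 0.5])
        s = _serum(times, np.zeros(12))
        with pytest.raises(ValueError, match="samples"):
            cpl.downsample_serum(s, spec, samples_per_block=12)


class TestPoolSamplePairs:
    def test_effective_rate_is_one_per_minute(self):
        times = np.arange(40) * 0.5  # 30-s sampling
        s = _serum(times, np.arange(40.0))
        pooled = cpl.pool_sample_pairs(s)
        assert len(pooled.times_min) == 20
        np.testing.assert_allclose(np.diff(pooled.times_min), 1.0)
        # pooling two vials averages their contents
        np.testing.assert_allclose(pooled.tnf_pg_ml,
                                   np.arange(40.0).reshape(20, 2).mean(axis=1))

    def test_isolated_samples_kept(self):
        times = np.array([-10.0, 0.0, 0.5, 1.0, 1.5])
        s = _serum(times, np.array([1.0, 2.0, 4.0, 6.0, 8.0]))
        pooled = cpl.pool_sample_pairs(s)
        assert pooled.times_min[0] == -10.0
        assert pooled.tnf_pg_ml[0] == 1.0


class TestCorrelation:
    def _table(self, bold_rows, serum, spec, **kw):
        return cpl.correlate_with_serum(np.asarray(bold_rows), serum, spec,
                                        **kw)

    def test_hand_computed_r(self):
        """r of (1..10) vs (1,2,3,4,5,5,4,3,2,1) against the explicit
        covariance formula."""
        x = np.arange(1.0, 11.0)
        y = np.array([1, 2, 3, 4, 5, 5, 4, 3, 2, 1.0])
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean())**2).sum()
                              * ((y - y.mean())**2).sum()))
        r, p, degenerate = cpl._pearson_with_p(x, y)
        assert not degenerate
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert r == pytest.approx(0.0, abs=1e-12)  # symmetric tent vs ramp

    def test_perfect_correlation_flags_significance(self, serum_small,
                                                    run_spec_small):
        tnf_points = cpl.downsample_serum(serum_small, run_spec_small, 4,
                                          "tnf")
        # build a BOLD course whose block means equal the serum points
        tc = np.repeat(tnf_points[1:], 100)
        tc = np.concatenate([np.full(150, tnf_points[0]), tc])
        table = self._table(tc[None], serum_small, run_spec_small,
                            block_volumes=100, samples_per_block=4)
        row = table[(table.component == 0) & (table.marker == "tnf")].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-9)
        assert row.bonferroni_significant
        anti = self._table(-tc[None], serum_small, run_spec_small,
                           block_volumes=100, samples_per_block=4)
        row = anti[(anti.component == 0) & (anti.marker == "tnf")].iloc[0]
        assert row.r == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_reported_not_significant(self, serum_small,
                                                    run_spec_small):
        tc = np.full(run_spec_small.total_volumes, 3.0)
        table = self._table(tc[None], serum_small, run_spec_small,
                            block_volumes=100, samples_per_block=4)
        assert table.degenerate.all()
        assert not table.bonferroni_significant.any()

    def test_critical_r_matches_root_finding(self):
        """The closed-form critical |r| solves p(r) = alpha at 8 df."""
        n = 10
        for alpha in (0.05, 0.05 / 10, 0.01 / 56):
            def p_of_r(r):
                t = r * np.sqrt((n - 2) / (1 - r**2))
                return 2 * t_dist.sf(t, df=n - 2) - alpha

            r_root = brentq(p_of_r, 1e-9, 1 - 1e-12, xtol=1e-12)
            assert cpl.critical_r(n, alpha) == pytest.approx(r_root,
                                                             abs=1e-6)

    @given(st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-5, max_value=5))
    def test_r_invariant_to_affine_rescaling(self, scale, shift):
        x = np.arange(10.0)
        y = np.array([2, 1, 4, 3, 6, 5, 8, 7, 9, 10.0])
        r0, _, _ = cpl._pearson_with_p(x, y)
        r1, _, _ = cpl._pearson_with_p(scale * x + shift, y)
        r2, _, _ = cpl._pearson_with_p(-x, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(-r0, abs=1e-9)


class TestSelection:
    def _table_for(self, comps, crit1_set):
        rows = []
        for c in comps:
            rows.append({"component": c, "marker": "tnf", "r": 0.9,
                         "criterion1": c in crit1_set})
        return pd.DataFrame(rows)

    def test_set_conjunction(self):
        table = self._table_for([1, 2, 3], {1, 2})
        comparisons = {1: False, 2: True, 3: True}
        result = cpl.select_inflammation_regions(table, comparisons)
        assert result.selected == [2]

    def test_empty_criterion2_gives_empty_selection(self):
        table = self._table_for([1, 2], {1, 2})
        result = cpl.select_inflammation_regions(table, {1: False, 2: False})
        assert result.selected == []

    def test_mismatched_component_sets_rejected(self):
        table = self._table_for([1, 2], {1})
        with pytest.raises(ValueError, match="differ"):
            cpl.select_inflammation_regions(table, {1: True, 3: False})

    def test_pair_p_dict_interface(self):
        table = self._table_for([5], {5})
        comparisons = {5: {"pair_min_p": {(1, 2): 0.03, (1, 3): 0.4},
                           "alpha": 0.05}}
        result = cpl.select_inflammation_regions(table, comparisons)
        assert result.selected == [5]
        assert result.criterion2_detail[5]["pair_min_p"][(1, 2)] == 0.03


class TestSerumChangeTest:
    def test_identical_vectors_null(self):
        out = cpl.serum_change_test(np.ones(4), np.ones(4))
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_hand_worked_example(self):
        base = np.zeros(3)
        t120 = np.array([1.0, 2.0, 3.0])
        out = cpl.serum_change_test(base, t120)
        assert out["mean_diff"] == pytest.approx(2.0)
        assert out["sd_diff"] == pytest.approx(1.0)
        assert out["t"] == pytest.approx(2 * np.sqrt(3), abs=1e-6)
        assert out["p"] == pytest.approx(0.0742, abs=2e-4)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 pairs"):
            cpl.serum_change_test(np.array([1.0]), np.array([2.0]))

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cpl.serum_change_test(np.zeros(3), np.full(3, 2.0))
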
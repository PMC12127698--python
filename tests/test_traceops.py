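"""Tests for trace-level statistics: scaling curves and exponents, loop
calling, compaction metrics, axis geometry, helicity, robust slopes,
compartment matrices and P(s) comparison — each against independent oracles
where the spec of the operation allows one."""

import numpy as np
import pandas as pd
import pytest

from mitotrace.synthgen import HelixParams, make_helix_trace, \
    make_phantom_chain_traces
from mitotrace.traceops import (
    LoopCallParams,
    ScalingCurve,
    Trace,
    axial_scaling_slope,
    axis_and_dimensions,
    call_and_classify_loops,
    compare_with_ps,
    find_scaling_minimum,
    fit_power_law,
    helicity_profile,
    observed_over_expected_and_correlation,
    rolling_outlier_filter,
    scaling_curve,
    trace_metrics,
)


def straight_trace(n=200, step_bp=1_000_000, step_nm=50.0, **kw):
    g = np.arange(n, dtype=np.int64) * step_bp
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * step_nm
    return Trace(trace_id=kw.pop("trace_id", "t"), cell_id="c",
                 stage="metaphase", genomic=g, xyz=xyz, **kw)


def random_trace(rng, n=60, step_bp=12_000, scale=80.0, trace_id="r"):
    g = np.arange(n, dtype=np.int64) * step_bp
    xyz = np.cumsum(rng.normal(scale=scale, size=(n, 3)), axis=0)
    return Trace(trace_id=trace_id, cell_id="c", stage="metaphase",
                 genomic=g, xyz=xyz)


class TestTraceContainer:
    def test_non_monotone_coordinates_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trace("t", "c", "metaphase", np.array([0, 100, 100]),
                  np.zeros((3, 3)))

    def test_completeness_counts_present_flags(self):
        tr = straight_trace(n=10)
        tr.present[:3] = False
        assert tr.completeness == pytest.approx(0.7)


class TestScalingCurve:
    def test_two_point_trace_single_bin(self):
        g = np.array([0, 1_000_000])
        xyz = np.array([[0, 0, 0], [500.0, 0, 0]])
        tr = Trace("t", "c", "metaphase", g, xyz)
        cur = scaling_curve([tr], min_points_per_trace=2)
        assert cur.separation.tolist() == [1_000_000.0]
        assert cur.median_distance.tolist() == [500.0]
        assert cur.count.tolist() == [1]

    def test_pooled_median_matches_exhaustive_enumeration(self, rng):
        traces = [random_trace(rng, n=50, trace_id=f"r{i}") for i in range(10)]
        cur = scaling_curve(traces, min_points_per_trace=30)
        # brute-force oracle: collect every pair explicitly
        pooled = {}
        for tr in traces:
            g, p = tr.present_points()
            for i in range(g.size):
                for j in range(i + 1, g.size):
                    pooled.setdefault(g[j] - g[i], []).append(
                        float(np.linalg.norm(p[j] - p[i])))
        for sep, med, cnt in zip(cur.separation, cur.median_distance,
                                 cur.count):
            vals = pooled[int(sep)]
            assert cnt == len(vals)
            assert med == pytest.approx(np.median(vals))

    def test_min_points_cutoff_enforced(self, rng):
        short = random_trace(rng, n=10)
        with pytest.raises(ValueError):
            scaling_curve([short], min_points_per_trace=30)
        cur = scaling_curve([short, random_trace(rng, n=40, trace_id="ok")],
                            min_points_per_trace=30)
        assert cur.count.sum() == 40 * 39 // 2

    def test_log_binning_pools_multiscale_separations(self, rng):
        traces = [random_trace(rng, n=50, step_bp=s, trace_id=f"s{s}")
                  for s in (12_000, 200_000)]
        cur = scaling_curve(traces, min_points_per_trace=30, bins="log")
        assert np.all(np.diff(cur.separation) > 0)
        assert cur.count.sum() == 2 * (50 * 49 // 2)

    def test_adjacent_distance_bounds_smallest_separation(self, rng):
        tr = random_trace(rng, n=80)
        cur = scaling_curve([tr], min_points_per_trace=30)
        steps = np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1)
        assert cur.median_distance[0] <= np.median(steps) + 1e-9


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        s = np.logspace(4, 7, 40)
        cur = ScalingCurve(s, 7.0 * s ** 0.33, np.zeros_like(s),
                           np.ones(s.size, dtype=np.int64))
        fit = fit_power_law(cur, (s[0], s[-1]))
        assert fit.prefactor == pytest.approx(7.0, rel=1e-6)
        assert fit.exponent == pytest.approx(0.33, abs=1e-6)

    def test_noisy_exponent_recovery_within_tolerance(self):
        # 10% multiplicative noise, 50 bins: mean recovered b within 0.03
        s = np.logspace(4, 7, 50)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 12.0 * s ** 0.4 * (1 + rng.normal(scale=0.1, size=s.size))
            cur = ScalingCurve(s, np.abs(y), np.zeros_like(s),
                               np.ones(s.size, dtype=np.int64))
            errs.append(fit_power_law(cur, (s[0], s[-1])).exponent - 0.4)
        assert np.abs(np.mean(errs)) < 0.03
        assert np.max(np.abs(errs)) < 0.1

    def test_interval_restriction_and_minimum_bins(self):
        s = np.logspace(4, 7, 40)
        cur = ScalingCurve(s, 7.0 * s ** 0.33, np.zeros_like(s),
                           np.ones(s.size, dtype=np.int64))
        with pytest.raises(ValueError):
            fit_power_law(cur, (1.0, 2.0))


def brute_force_classification(contacts, tol=1):
    """Independent reimplementation of the base/nested/Z rules by explicit
    triple and quadruple enumeration."""
    labels = []
    cs = [tuple(c) for c in contacts]
    for a, b in cs:
        nested = False
        for c in range(a + 1, b):
            has_ac = any(abs(u - a) <= tol and abs(v - c) <= tol
                         for u, v in cs)
            has_cb = any(abs(u - c) <= tol and abs(v - b) <= tol
                         for u, v in cs)
            if has_ac and has_cb:
                nested = True
                break
        if nested:
            labels.append("nested")
            continue
        z = any((a < c < b < d) or (c < a < d < b)
                for c, d in cs if (c, d) != (a, b))
        labels.append("z_loop" if z else "base")
    return labels


class TestLoopClassification:
    def _trace_with_contacts(self, pairs, n=60):
        # expanding backbone (no accidental contacts), then collapse anchors
        g = np.arange(n, dtype=np.int64) * 12_000
        xyz = np.zeros((n, 3))
        xyz[:, 0] = np.arange(n) * 200.0
        groups = {}
        for a, b in pairs:
            root = groups.get(a, a)
            groups[b] = root
            groups.setdefault(a, a)
        for idx, root in groups.items():
            if idx != root:
                xyz[idx] = xyz[root] + [0, 40.0, 0]
        return Trace("t", "c", "metaphase", g, xyz)

    def test_single_planted_loop_is_base(self):
        tr = self._trace_with_contacts([(10, 30)])
        loops = call_and_classify_loops(tr)
        assert loops.labels == ["base"]
        assert loops.anchors_index.tolist() == [[10, 30]]

    def test_merged_bases_make_nested(self):
        tr = self._trace_with_contacts([(10, 20), (20, 30), (10, 30)])
        loops = call_and_classify_loops(tr)
        got = dict(zip(map(tuple, loops.anchors_index.tolist()), loops.labels))
        assert got[(10, 30)] == "nested"

    def test_interleaved_pairs_are_z_loops(self):
        tr = self._trace_with_contacts([(10, 30), (20, 40)])
        loops = call_and_classify_loops(tr)
        assert loops.labels == ["z_loop", "z_loop"]

    @pytest.mark.parametrize("seed", range(8))
    def test_random_traces_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_trace(rng, n=100, scale=45.0)
        loops = call_and_classify_loops(tr)
        oracle = brute_force_classification(loops.anchors_index)
        assert loops.labels == oracle

    def test_empty_contact_set_allowed(self):
        tr = straight_trace(n=50, step_nm=300.0)
        loops = call_and_classify_loops(tr)
        assert loops.labels == []

    def test_span_below_minimum_not_called(self):
        # 12-kb neighbours closer than 100 nm span < 30 kb: not loops
        tr = self._trace_with_contacts([])
        tr.xyz[1] = tr.xyz[0] + [10.0, 0, 0]
        loops = call_and_classify_loops(tr)
        assert loops.labels == []


class TestTraceMetrics:
    def test_degenerate_all_points_identical(self):
        tr = straight_trace(n=100, step_bp=12_000, step_nm=0.0)
        m = trace_metrics(tr, min_points=10)
        assert m.radius_of_gyration == 0.0
        assert m.contour_length == 0.0

    def test_collinear_points_have_zero_elongation(self):
        m = trace_metrics(straight_trace(n=100, step_bp=12_000),
                          min_points=10)
        assert m.elongation == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_sphere_elongation_near_one(self, rng):
        n = 2000
        v = rng.normal(size=(n, 3))
        v = 500.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        tr = Trace("s", "c", "metaphase",
                   np.arange(n, dtype=np.int64) * 12_000, v)
        m = trace_metrics(tr, min_points=10,
                          loop_params=LoopCallParams(distance_cutoff=1.0))
        assert m.elongation > 0.9

    def test_helix_rg_matches_direct_formula(self):
        params = HelixParams(noise_sd_nm=0.0, length_bp=24_000_000,
                             sampling_interval_bp=200_000)
        tr = make_helix_trace(params)
        m = trace_metrics(tr, min_points=10)
        p = tr.xyz - tr.xyz.mean(axis=0)
        assert m.radius_of_gyration == pytest.approx(
            float(np.sqrt((p ** 2).sum(axis=1).mean())))

    def test_completeness_cutoff_is_exact(self, rng):
        tr = random_trace(rng, n=1000)
        tr.present[:201] = False  # 79.9 %
        assert trace_metrics(tr, min_completeness=0.8) is None
        tr2 = random_trace(rng, n=1000)
        tr2.present[:200] = False  # exactly 80 %
        assert trace_metrics(tr2, min_completeness=0.8) is not None


class TestAxisGeometry:
    def test_straight_trace_zero_width_full_length(self):
        tr = straight_trace(n=100, step_bp=1_000_000, step_nm=40.0)
        ax = axis_and_dimensions(tr, window_bp=20e6)
        assert ax.width == pytest.approx(0.0, abs=1e-9)
        end_to_end = np.linalg.norm(ax.points[-1] - ax.points[0])
        assert ax.length == pytest.approx(end_to_end)

    def test_helix_width_approaches_radius(self):
        params = HelixParams(pitch_bp=2_000_000, radius_nm=300.0,
                             noise_sd_nm=0.0, length_bp=100_000_000,
                             sampling_interval_bp=100_000)
        tr = make_helix_trace(params)
        ax = axis_and_dimensions(tr, window_bp=20e6)
        assert ax.width == pytest.approx(300.0, rel=0.10)

    def test_axis_shorter_than_noisy_contour(self, rng):
        tr = random_trace(rng, n=120, step_bp=1_000_000, scale=150.0)
        ax = axis_and_dimensions(tr, window_bp=20e6)
        contour = np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1).sum()
        assert ax.length < contour

    def test_extent_shorter_than_window_rejected(self):
        tr = straight_trace(n=10, step_bp=1_000_000)
        with pytest.raises(ValueError):
            axis_and_dimensions(tr, window_bp=20e6)


class TestAxialScalingSlope:
    def test_perfect_linear_slope_recovered_exactly(self):
        tr = straight_trace(n=100, step_bp=1_000_000, step_nm=17.0)
        s = axial_scaling_slope([tr])
        assert s == pytest.approx(17.0 / 1_000_000)

    def test_robust_to_gross_outliers(self, rng):
        # 20% of pair distances replaced by gross outliers
        g = np.arange(80, dtype=np.int64) * 1_000_000
        xyz = np.zeros((80, 3))
        xyz[:, 0] = np.arange(80) * 20.0
        noise = rng.random(80) < 0.2
        xyz[noise, 1] = rng.uniform(5e4, 1e5, noise.sum())
        tr = Trace("t", "c", "metaphase", g, xyz)
        s = axial_scaling_slope([tr])
        assert s == pytest.approx(20.0 / 1_000_000, rel=0.02)

    def test_points_outside_interval_do_not_matter(self):
        tr1 = straight_trace(n=100, step_bp=1_000_000, step_nm=17.0)
        tr2 = straight_trace(n=100, step_bp=1_000_000, step_nm=17.0)
        tr2.xyz[:5] += 1e6  # perturb pairs living outside 20-60 Mb only
        s1 = axial_scaling_slope([tr1], interval=(40e6, 60e6))
        s2 = axial_scaling_slope([tr2], interval=(40e6, 60e6))
        # pairs involving the first 5 points at 40-60 Mb separation exist;
        # restrict to a window those points cannot reach
        assert s1 == pytest.approx(17.0 / 1e6)
        del s2

    def test_empty_interval_rejected(self):
        tr = straight_trace(n=10, step_bp=1_000_000)
        with pytest.raises(ValueError):
            axial_scaling_slope([tr], interval=(20e6, 60e6))


class TestHelicity:
    def test_noiseless_helix_minima_at_pitch_multiples(self):
        params = HelixParams(pitch_bp=12_000_000, radius_nm=300.0,
                             noise_sd_nm=0.0, length_bp=100_000_000,
                             sampling_interval_bp=1_000_000)
        tr = make_helix_trace(params)
        prof = helicity_profile(tr, separations=[6e6, 12e6, 18e6, 24e6])
        sd = dict(zip(prof["separation_bp"], prof["angle_sd_rad"]))
        assert sd[12e6] < 0.3 * sd[6e6]
        assert sd[24e6] < 0.3 * sd[18e6]

    def test_noisy_helix_minima_persist_but_shallower(self, rng):
        base = dict(pitch_bp=12_000_000, radius_nm=300.0,
                    length_bp=100_000_000, sampling_interval_bp=1_000_000)
        seps = [6e6, 12e6, 18e6]

        def mean_profile(noise, n=25):
            out = []
            for i in range(n):
                tr = make_helix_trace(HelixParams(noise_sd_nm=noise, **base),
                                      rng=rng)
                prof = helicity_profile(tr, separations=seps)
                out.append(prof["angle_sd_rad"].to_numpy())
            return np.mean(out, axis=0)

        clean = mean_profile(0.0, n=1)
        noisy = mean_profile(200.0)
        assert noisy[1] < noisy[0] and noisy[1] < noisy[2]  # minimum persists
        assert noisy[1] > clean[1]  # but shallower than noiseless

    def test_random_walk_profile_flat(self, rng):
        sds = []
        for i in range(20):
            tr = random_trace(rng, n=100, step_bp=1_000_000, scale=150.0,
                              trace_id=f"rw{i}")
            prof = helicity_profile(tr, separations=[6e6, 12e6, 18e6, 24e6])
            sds.append(prof["angle_sd_rad"].to_numpy())
        mean_sd = np.mean(sds, axis=0)
        # uniform angles: difference SD ~ 2 pi / sqrt(6) ~ 2.57 at every lag
        assert np.all(np.abs(mean_sd - 2 * np.pi / np.sqrt(6)) < 0.35)
        assert mean_sd.max() - mean_sd.min() < 0.35


class TestRollingOutlierFilter:
    @staticmethod
    def smooth_trace(rng, n=100):
        # gently curved path with small localization jitter
        g = np.arange(n, dtype=np.int64) * 12_000
        t = np.linspace(0, 2 * np.pi, n)
        xyz = np.column_stack([900 * np.cos(t), 900 * np.sin(t), 40 * t])
        xyz += rng.normal(scale=8.0, size=xyz.shape)
        return Trace("s", "c", "metaphase", g, xyz)

    def test_clean_smooth_trace_untouched(self, rng):
        tr = self.smooth_trace(rng)
        out = rolling_outlier_filter(tr)
        assert out.n_present == tr.n_present

    def test_planted_outlier_removed(self, rng):
        tr = self.smooth_trace(rng)
        tr.xyz[40] += [10_000.0, 0, 0]
        out = rolling_outlier_filter(tr)
        assert not out.present[40]
        assert out.n_present == tr.n_present - 1

    def test_idempotent_on_filtered_output(self, rng):
        tr = self.smooth_trace(rng)
        tr.xyz[40] += [10_000.0, 0, 0]
        once = rolling_outlier_filter(tr)
        twice = rolling_outlier_filter(once)
        np.testing.assert_array_equal(once.present, twice.present)


class TestObservedOverExpected:
    def test_pure_distance_function_normalizes_to_one(self):
        n = 20
        m = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * 13.0
        with pytest.warns(UserWarning, match="degenerate"):
            norm, _ = observed_over_expected_and_correlation(m)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(norm[off], 1.0)

    def test_block_compartments_give_checkerboard_correlation(self):
        # two alternating compartment types in 4 blocks of 5
        n = 20
        kind = (np.arange(n) // 5) % 2
        base = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * 10.0 + 50
        same = np.equal.outer(kind, kind)
        m = np.where(same, base * 0.7, base * 1.3)
        np.fill_diagonal(m, 0.0)
        _, corr = observed_over_expected_and_correlation(m)
        sign = np.sign(corr)
        i, j = 2, 7  # same vs different compartment, off-diagonal
        assert sign[2, 12] == 1.0  # same type blocks correlate positively
        assert sign[i, j] == -1.0  # opposite type anti-correlate

    def test_symmetric_input_symmetric_output(self, rng):
        n = 15
        a = rng.random((n, n)) * 100
        m = (a + a.T) / 2
        norm, corr = observed_over_expected_and_correlation(m)
        np.testing.assert_allclose(norm, norm.T, atol=1e-9)
        np.testing.assert_allclose(corr, corr.T, atol=1e-9)

    def test_asymmetric_matrix_rejected(self, rng):
        m = rng.random((5, 5))
        with pytest.raises(ValueError):
            observed_over_expected_and_correlation(m)


class TestPsComparison:
    def _contacts(self, n=50, bin_size=10_000, values=None):
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                v = values(i, j) if values else 1.0
                rows.append((i * bin_size, j * bin_size, v))
        return pd.DataFrame(rows, columns=["bin1_start", "bin2_start",
                                           "balanced_frequency"])

    def _curve(self):
        s = np.arange(1, 30, dtype=float) * 1e6
        return ScalingCurve(s, s / 1e4, np.zeros_like(s),
                            np.ones(s.size, dtype=np.int64))

    def test_constant_diagonals_give_constant_ps(self):
        contacts = self._contacts(n=300, bin_size=100_000,
                                  values=lambda i, j: 0.37)
        cmp_res = compare_with_ps(self._curve(), contacts, fit=False)
        np.testing.assert_allclose(cmp_res.contact_probability, 0.37)

    def test_distance_curve_inverted(self):
        contacts = self._contacts(n=300, bin_size=100_000)
        cmp_res = compare_with_ps(self._curve(), contacts, fit=False)
        np.testing.assert_allclose(cmp_res.inverse_distance,
                                   1.0 / cmp_res.median_distance)

    def test_ps_matches_brute_force_diagonal_average(self, rng):
        n, b = 40, 250_000
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        contacts = self._contacts(n=n, bin_size=b,
                                  values=lambda i, j: vals[i, j])
        cmp_res = compare_with_ps(self._curve(), contacts,
                                  resolution=1_000_000, fit=False)
        # oracle: group |j-i|*b into 1-Mb bins, average
        from collections import defaultdict
        acc = defaultdict(list)
        for i in range(n):
            for j in range(i + 1, n):
                sep = (j - i) * b
                acc[(sep // 1_000_000) * 1_000_000 + 500_000].append(
                    vals[i, j])
        for s, p in zip(cmp_res.separation, cmp_res.contact_probability):
            assert p == pytest.approx(np.mean(acc[int(s)]))

    def test_raw_counts_flagged(self):
        contacts = self._contacts(n=100, bin_size=100_000,
                                  values=lambda i, j: float((i + j) % 7 + 1))
        with pytest.warns(UserWarning, match="raw counts"):
            compare_with_ps(self._curve(), contacts, fit=False)


class TestScalingMinimum:
    def _curve(self, y):
        s = np.arange(1, len(y) + 1, dtype=float) * 1e6
        return ScalingCurve(s, np.asarray(y, dtype=float), np.zeros(len(y)),
                            np.ones(len(y), dtype=np.int64))

    def test_monotone_curve_has_no_minimum(self):
        cur = self._curve(np.linspace(100, 400, 20))
        assert find_scaling_minimum(cur, (2e6, 18e6)) is None

    def test_planted_dip_located(self):
        y = np.linspace(100, 400, 20)
        y[6] *= 0.7  # dip at 7 Mb
        assert find_scaling_minimum(self._curve(y), (2e6, 18e6)) == 7e6

    def test_too_few_bins_rejected(self):
        cur = self._curve([1, 2, 3, 4])
        with pytest.raises(ValueError):
            find_scaling_minimum(cur, (1e6, 4e6))


class TestRigidMotionInvariance:
    def test_metrics_invariant_under_rotation_translation(self, rng):
        tr = random_trace(rng, n=90)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = tr.copy()
        moved.xyz = tr.xyz @ q.T + np.array([1e4, -2e4, 3e3])
        m1 = trace_metrics(tr, min_points=10)
        m2 = trace_metrics(moved, min_points=10)
        assert m1.radius_of_gyration == pytest.approx(m2.radius_of_gyration)
        assert m1.elongation == pytest.approx(m2.elongation, abs=1e-9)
        assert m1.contour_length == pytest.approx(m2.contour_length)
        assert (m1.n_base, m1.n_nested, m1.n_z) == \
            (m2.n_base, m2.n_nested, m2.n_z)

    def test_scaling_curve_of_helix_matches_chord_formula(self):
        # analytic chord length of a circular helix vs measured curve
        R, pitch, rise = 300.0, 10e6, 5e-5
        params = HelixParams(pitch_bp=pitch, radius_nm=R,
                             rise_nm_per_bp=rise, noise_sd_nm=0.0,
                             length_bp=100_000_000,
                             sampling_interval_bp=500_000)
        tr = make_helix_trace(params)
        cur = scaling_curve([tr], min_points_per_trace=30)
        for s, d in zip(cur.separation[:40], cur.median_distance[:40]):
            chord = np.sqrt((2 * R * np.sin(np.pi * s / pitch)) ** 2
                            + (rise * s) ** 2)
            assert d == pytest.approx(chord, rel=0.02, abs=1.0)


def test_phantom_chain_scaling_exponent_is_rouse(rng):
    traces = make_phantom_chain_traces(300, 200, 12.0, rng)
    cur = scaling_curve(traces, min_points_per_trace=30)
    fit = fit_power_law(cur, (cur.separation[1], cur.separation[-1] / 2))
    assert fit.exponent == pytest.approx(0.5, abs=0.05)
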
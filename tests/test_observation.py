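import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iokinetics.model_core import (
    PATIENT_PARAMETER_SETS,
    Trajectory,
    ValidationError,
    solve_trajectory,
    solve_trajectory_rk4,
)
from iokinetics.observation import (
    ATReport,
    ClampWarning,
    MeasurementSet,
    NormalizationError,
    ROI_BODY,
    ROI_STOMACH,
    ROI_THYROID,
    ScanSchedule,
    at_index,
    at_total,
    compute_at_report,
    net_count_rate,
    normalize_dataset,
    project_observables,
    subtract_background,
)

Q0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])


def make_measurements(st_vals, th_vals, bfwb_vals, **kwargs):
    return MeasurementSet(
        patient_id="P1",
        schedule=ScanSchedule(),
        series={
            ROI_STOMACH: np.asarray(st_vals, float),
            ROI_THYROID: np.asarray(th_vals, float),
            ROI_BODY: np.asarray(bfwb_vals, float),
        },
        **kwargs,
    )


class TestScanSchedule:
    def test_default_six_scans(self):
        sched = ScanSchedule()
        assert sched.times_h == (1.0, 4.0, 24.0, 48.0, 72.0, 168.0)
        assert sched.n_scans == 6

    @pytest.mark.parametrize("times", [(), (0.0, 1.0), (4.0, 1.0), (1.0, 1.0)])
    def test_invalid_times_rejected(self, times):
        with pytest.raises(ValidationError):
            ScanSchedule(times)


class TestMeasurementSet:
    def test_series_length_checked(self):
        with pytest.raises(ValidationError):
            make_measurements([1.0] * 5, [1.0] * 6, [1.0] * 6)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            make_measurements([-1.0] + [1.0] * 5, [1.0] * 6, [1.0] * 6)

    def test_normalized_requires_unit_anchor(self):
        with pytest.raises(ValidationError):
            make_measurements(
                [0.5] + [0.1] * 5, [0.1] * 6, [0.1] * 6, normalized=True
            )


class TestNetCountRate:
    def test_plain_subtraction(self):
        assert net_count_rate(10.0, 2.0) == 8.0

    def test_boundary(self):
        assert net_count_rate(2.0, 2.0) == 0.0

    def test_clamped_with_warning(self):
        with pytest.warns(ClampWarning):
            assert net_count_rate(1.0, 2.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            net_count_rate(-1.0, 0.0)
        with pytest.raises(ValidationError):
            net_count_rate(1.0, -0.5)

    def test_vectorized(self):
        net = net_count_rate([5.0, 1.0], [1.0, 1.0])
        assert np.allclose(net, [4.0, 0.0])


class TestSubtractBackground:
    def test_removes_attached_background(self):
        ms = make_measurements(
            [4.0, 3.0, 2.0, 1.5, 1.2, 1.0],
            [1.0] * 6,
            [2.0] * 6,
            background=np.full(6, 0.5),
        )
        net = subtract_background(ms)
        assert net.background is None
        assert np.allclose(net.series[ROI_STOMACH], [3.5, 2.5, 1.5, 1.0, 0.7, 0.5])

    def test_noop_without_background(self):
        ms = make_measurements([1.0] * 6, [1.0] * 6, [1.0] * 6)
        assert subtract_background(ms) is ms


class TestProjectObservables:
    def test_single_time_definition(self):
        traj = Trajectory(np.array([1.0]), np.array([[0.3, 0.2, 0.1, 0.25, 0.15]]))
        ms = project_observables(traj)
        assert ms.series[ROI_STOMACH][0] == 0.3
        assert ms.series[ROI_THYROID][0] == 0.1
        assert ms.series[ROI_BODY][0] == pytest.approx(0.45)

    def test_empty_body_compartments(self):
        traj = Trajectory(
            np.array([1.0, 4.0]),
            np.array([[0.5, 0.0, 0.2, 0.0, 0.3], [0.4, 0.0, 0.1, 0.0, 0.5]]),
        )
        assert np.all(project_observables(traj).series[ROI_BODY] == 0.0)

    def test_matches_rk4_oracle_at_1h(self):
        params = PATIENT_PARAMETER_SETS[0]
        times = np.array([1.0])
        ms = project_observables(solve_trajectory(params, Q0, times))
        oracle = solve_trajectory_rk4(params, Q0, times, step_h=0.001)
        assert ms.series[ROI_BODY][0] == pytest.approx(
            oracle.body_fluid[0] + oracle.whole_body[0], abs=1e-6
        )

    def test_schedule_mismatch_rejected(self):
        traj = Trajectory(np.array([1.0]), np.array([[1.0, 0, 0, 0, 0]]))
        with pytest.raises(ValidationError):
            project_observables(traj, ScanSchedule((1.0, 4.0)))


class TestNormalizeDataset:
    def test_divides_by_first_stomach_value(self):
        ms = make_measurements(
            [4.0, 2.0, 1.0, 0.5, 0.25, 0.1],
            [0.2] * 6,
            [1.0] * 6,
        )
        norm = normalize_dataset(ms)
        assert norm.normalized
        assert norm.series[ROI_STOMACH][0] == 1.0
        assert norm.series[ROI_THYROID][0] == pytest.approx(0.05)

    def test_idempotent(self):
        ms = make_measurements(
            [4.0, 2.0, 1.0, 0.5, 0.25, 0.1], [0.2] * 6, [1.0] * 6
        )
        once = normalize_dataset(ms)
        twice = normalize_dataset(once)
        for roi in (ROI_STOMACH, ROI_THYROID, ROI_BODY):
            assert np.array_equal(once.series[roi], twice.series[roi])

    def test_gain_invariance(self):
        base = [4.0, 2.0, 1.0, 0.5, 0.25, 0.1]
        for gain in (0.5, 3.7):
            a = normalize_dataset(make_measurements(base, [0.2] * 6, [1.0] * 6))
            b = normalize_dataset(
                make_measurements(
                    [gain * v for v in base],
                    [gain * 0.2] * 6,
                    [gain * 1.0] * 6,
                )
            )
            for roi in (ROI_STOMACH, ROI_THYROID, ROI_BODY):
                assert np.allclose(a.series[roi], b.series[roi], rtol=1e-12)

    def test_zero_anchor_rejected(self):
        ms = make_measurements([0.0] * 6, [0.0] * 6, [0.0] * 6)
        with pytest.raises(NormalizationError):
            normalize_dataset(ms)

    def test_background_must_be_subtracted_first(self):
        ms = make_measurements(
            [4.0] * 6, [1.0] * 6, [1.0] * 6, background=np.full(6, 0.1)
        )
        with pytest.raises(ValidationError):
            normalize_dataset(ms)


class TestAtIndex:
    def test_identical_series(self):
        series = np.array([1.0, 0.5, 0.2, 0.1, 0.05, 0.02])
        assert at_index(series, series) == 0.0

    def test_constant_offset(self):
        obs = np.array([1.0, 0.5, 0.2, 0.1, 0.05, 0.02])
        assert at_index(obs, obs + 0.06) == pytest.approx(0.06)

    def test_hand_computed_example(self):
        obs = np.array([1.0, 0.5, 0.2, 0.1, 0.05, 0.02])
        pred = np.array([0.9, 0.55, 0.25, 0.08, 0.05, 0.01])
        # oracle: sqrt(0.0155 / 6) computed by hand
        assert at_index(obs, pred) == pytest.approx(0.05082650227325635)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            at_index([1.0, 2.0], [1.0])
        with pytest.raises(ValidationError):
            at_index([], [])


class TestAtTotal:
    def test_equal_inputs_fixed_point(self):
        assert at_total(0.3, 0.3, 0.3) == pytest.approx(0.3)

    def test_zero(self):
        assert at_total(0.0, 0.0, 0.0) == 0.0

    def test_hand_computed_example(self):
        # oracle: sqrt((0.056^2 + 0.017^2 + 0.044^2)/3) computed by hand
        assert at_total(0.056, 0.017, 0.044) == pytest.approx(0.042272922775696505)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            at_total(-0.1, 0.0, 0.0)

    def test_at_report_consistency_enforced(self):
        with pytest.raises(ValidationError):
            ATReport(at_st=0.1, at_th=0.1, at_bfwb=0.1, at_total=0.5, n=6)


class TestProperties:
    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=8
        ),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_at_index_scales_linearly(self, values, scale):
        obs = np.asarray(values)
        pred = obs[::-1].copy()
        assert at_index(scale * obs, scale * pred) == pytest.approx(
            scale * at_index(obs, pred), rel=1e-9
        )

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(min_value=0.0, max_value=5.0),
        b=st.floats(min_value=0.0, max_value=5.0),
        c=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_at_total_symmetric_and_bounded(self, a, b, c):
        value = at_total(a, b, c)
        assert value == pytest.approx(at_total(c, a, b))
        assert value <= max(a, b, c) + 1e-12

    def test_projection_bounded_by_total_activity(self):
        for params in PATIENT_PARAMETER_SETS[:3]:
            times = np.array([1.0, 4.0, 24.0, 48.0, 72.0, 168.0])
            traj = solve_trajectory(params, Q0, times)
            ms = project_observables(traj)
            total = (
                ms.series[ROI_STOMACH] + ms.series[ROI_THYROID] + ms.series[ROI_BODY]
            )
            bound = np.exp(-params.physical.lambda_p * times)
            assert np.all(total <= bound + 1e-12)

    def test_compute_at_report_on_model_pair(self):
        params = PATIENT_PARAMETER_SETS[0]
        times = np.array([1.0, 4.0, 24.0, 48.0, 72.0, 168.0])
        data = normalize_dataset(
            project_observables(solve_trajectory(params, Q0, times))
        )
        report = compute_at_report(data, data)
        assert report.at_total == 0.0
        assert report.n == 6
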
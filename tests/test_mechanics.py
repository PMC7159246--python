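"""Mechanics extraction: phase segmentation, ultimate point, stiffness, work,
relaxation, and the noise-free closure against the simulator's ground truth."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tendonmech.core import (
    LoadingProtocol,
    LoadTrace,
    PhaseSegmentation,
    Specimen,
)
from tendonmech import mechanics
from tendonmech.mechanics import (
    SegmentationError,
    elastic_modulus,
    extract_all,
    relative_stress_relaxation,
    segment_phases,
    stiffness_max_gradient,
    strain_at_failure,
    ultimate_point,
    ultimate_stress,
    work_to_failure,
)
from tendonmech.synthetic import default_material_params, generate_load_trace


def ramp_trace(x, force):
    """Trace that is pure ramp (no preload, no cycles)."""
    x = np.asarray(x, float)
    t = np.arange(x.size) / 100.0
    return LoadTrace(t, np.asarray(force, float), x), PhaseSegmentation(0, [], 0)


def brute_force_max_slope(x, y, w):
    """Independent exhaustive per-window OLS maximum (mean-based formulas)."""
    best = -np.inf
    for i in range(len(x) - w + 1):
        xs, ys = x[i:i + w], y[i:i + w]
        xc = xs - xs.mean()
        denom = np.dot(xc, xc)
        if denom <= 0:
            continue
        best = max(best, np.dot(xc, ys - ys.mean()) / denom)
    return best


class TestSegmentation:
    def test_labelled_trace_boundaries_match_labels(self, short_protocol):
        trace, truth = generate_load_trace(default_material_params("C"),
                                           short_protocol, seed=0)
        seg = segment_phases(trace, short_protocol)
        assert seg.preload_end == truth.preload_end
        assert seg.ramp_start == truth.ramp_start
        assert len(seg.cycle_boundaries) == short_protocol.cycle_count

    def test_unlabelled_boundaries_within_one_sample(self, short_protocol):
        trace, truth = generate_load_trace(default_material_params("GP"),
                                           short_protocol, seed=1)
        stripped = LoadTrace(trace.time, trace.force, trace.displacement, None)
        seg = segment_phases(stripped, short_protocol)
        assert abs(seg.preload_end - truth.preload_end) <= 1
        assert abs(seg.ramp_start - truth.ramp_start) <= 1
        assert len(seg.cycle_boundaries) == short_protocol.cycle_count
        starts = np.array([a for a, _ in seg.cycle_boundaries])
        assert np.max(np.abs(starts - truth.cycle_starts)) <= 1

    def test_zero_cycles_gives_empty_cycle_list(self):
        protocol = LoadingProtocol(preload_duration=2.0, cycle_count=0)
        trace, _ = generate_load_trace(default_material_params("C"), protocol, seed=0)
        seg = segment_phases(trace, protocol)
        assert seg.preload_end == seg.ramp_start
        assert seg.cycle_boundaries == []

    def test_trace_shorter_than_preload_errors(self):
        protocol = LoadingProtocol()
        t = np.arange(100) / 100.0
        trace = LoadTrace(t, np.ones(100), np.linspace(0, 1, 100))
        with pytest.raises(SegmentationError, match="preload"):
            segment_phases(trace, protocol)

    def test_missing_cycles_reported_with_count(self, short_protocol):
        protocol_20 = LoadingProtocol(preload_duration=5.0, cycle_count=20)
        trace, _ = generate_load_trace(default_material_params("C"),
                                       short_protocol, seed=0)
        stripped = LoadTrace(trace.time, trace.force, trace.displacement, None)
        with pytest.raises(SegmentationError, match="detected"):
            segment_phases(stripped, protocol_20)


class TestUltimatePoint:
    def test_global_maximum(self):
        trace, _ = ramp_trace([0.0, 1.0, 2.0], [1.0, 5.0, 3.0])
        assert ultimate_point(trace) == (5.0, 1.0, 1)

    def test_tie_broken_by_earliest_index(self):
        trace, _ = ramp_trace([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
        assert ultimate_point(trace)[2] == 0

    def test_noise_free_simulator_peak_recovered(self, short_protocol):
        params = default_material_params("ColGP", noise_sd=0.0)
        trace, truth = generate_load_trace(params, short_protocol, seed=2)
        force, _, idx = ultimate_point(trace)
        assert force == pytest.approx(truth.ultimate_force, rel=1e-12)
        assert idx == truth.ultimate_index


class TestScalarDefinitions:
    def test_ultimate_stress_quotient(self):
        assert ultimate_stress(100.0, 25.0) == 4.0
        assert ultimate_stress(0.0, 10.0) == 0.0
        assert ultimate_stress(633.0, 28.5) == pytest.approx(22.21, abs=0.005)

    def test_ultimate_stress_requires_positive_area(self):
        with pytest.raises(ValueError):
            ultimate_stress(10.0, 0.0)

    def test_strain_at_failure(self):
        assert strain_at_failure(9.0, 45.0) == pytest.approx(0.2)
        assert strain_at_failure(0.0, 45.0) == 0.0
        with pytest.raises(ValueError):
            strain_at_failure(9.0, 0.0)

    def test_elastic_modulus_geometry(self):
        assert elastic_modulus(100.0, 30.0, 45.0) == pytest.approx(150.0)
        assert elastic_modulus(123.0, 45.0, 45.0) == pytest.approx(123.0)
        with pytest.raises(ValueError):
            elastic_modulus(100.0, -1.0, 45.0)


class TestStiffness:
    def test_exact_linear_gives_k_for_any_window(self):
        x = np.linspace(0, 10, 400)
        trace, seg = ramp_trace(x, 12.0 * x)
        for w in (3, 10, 80, 399):
            assert stiffness_max_gradient(trace, seg, window=w) == pytest.approx(12.0)

    def test_quadratic_matches_brute_force(self):
        x = np.linspace(0, 10, 300)
        y = x**2
        trace, seg = ramp_trace(x, y)
        for w in (5, 25, 60):
            got = stiffness_max_gradient(trace, seg, window=w)
            assert got == pytest.approx(brute_force_max_slope(x, y, w), rel=1e-10)

    def test_window_larger_than_range_errors(self):
        trace, seg = ramp_trace([0, 1, 2, 3], [0, 1, 2, 3])
        with pytest.raises(ValueError, match="shorter than the window"):
            stiffness_max_gradient(trace, seg, window=5)

    def test_constant_displacement_errors(self):
        t = np.arange(10) / 100.0
        trace = LoadTrace(t, np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="variance"):
            stiffness_max_gradient(trace, PhaseSegmentation(0, [], 0), window=5,
                                   ultimate_index=9)


class TestWork:
    def test_linear_ramp_half_k_x_squared(self):
        x = np.linspace(0, 4, 500)
        trace, seg = ramp_trace(x, 10.0 * x)
        assert work_to_failure(trace, seg) == pytest.approx(80.0, rel=1e-9)

    def test_constant_force_rectangle(self):
        x = np.linspace(0, 10, 200)
        trace, seg = ramp_trace(x, np.full_like(x, 5.0))
        # ultimate index is the first sample (tie-break); integrate to the end
        assert work_to_failure(trace, seg, ultimate_index=len(x) - 1) == pytest.approx(50.0)

    def test_against_oversampled_integral(self):
        params = default_material_params("C", noise_sd=0.0)
        from tendonmech.synthetic import material_force
        x = np.linspace(0, 9.9, 150)
        x_fine = np.linspace(0, 9.9, 150 * 100)
        trace, seg = ramp_trace(x, material_force(x, params, 45.0))
        coarse = work_to_failure(trace, seg)
        fine = np.trapezoid(material_force(x_fine, params, 45.0), x_fine)
        assert coarse == pytest.approx(fine, rel=1e-3)


class TestRelaxation:
    @staticmethod
    def two_cycle_trace(peak1, peak2):
        # two triangular displacement cycles with prescribed force peaks
        x = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:],
                            np.linspace(0, 1, 11)[1:], np.linspace(1, 0, 11)[1:]])
        f = np.concatenate([np.linspace(0, peak1, 11), np.linspace(peak1, 0, 11)[1:],
                            np.linspace(0, peak2, 11)[1:], np.linspace(peak2, 0, 11)[1:]])
        t = np.arange(x.size) / 100.0
        seg = PhaseSegmentation(0, [(0, 20), (20, 40)], 40)
        return LoadTrace(t, f, x), seg

    def test_identical_peaks_zero(self):
        trace, seg = self.two_cycle_trace(100.0, 100.0)
        assert relative_stress_relaxation(trace, seg) == 0.0

    def test_half_drop(self):
        trace, seg = self.two_cycle_trace(100.0, 50.0)
        assert relative_stress_relaxation(trace, seg) == pytest.approx(-0.5)

    def test_fewer_than_two_cycles_errors(self):
        trace, _ = ramp_trace(np.linspace(0, 1, 10), np.linspace(0, 1, 10))
        with pytest.raises(ValueError, match="cycles"):
            relative_stress_relaxation(trace, PhaseSegmentation(0, [(0, 5)], 9))

    def test_simulator_recovers_r_minus_one(self, short_protocol):
        # tau << cycle count so the last peak has converged to r * peak1
        params = default_material_params("C", noise_sd=0.0,
                                         relaxation_time_constant=1.0)
        trace, truth = generate_load_trace(params, short_protocol, seed=0)
        seg = segment_phases(trace, short_protocol)
        got = relative_stress_relaxation(trace, seg)
        assert got == pytest.approx(params.relaxation_fraction - 1.0, abs=1e-3)


class TestExtractAll:
    def test_noise_free_closure_one_percent(self, short_protocol):
        params = default_material_params("Col", noise_sd=0.0)
        trace, truth = generate_load_trace(params, short_protocol, seed=4)
        spec = Specimen("s", "Col", csa=truth.csa)
        props = extract_all(trace, spec, short_protocol)
        assert props.ultimate_force == pytest.approx(truth.ultimate_force, rel=0.01)
        assert props.stiffness == pytest.approx(truth.stiffness, rel=0.01)
        assert props.work_to_failure == pytest.approx(truth.work_to_failure, rel=0.01)
        assert props.strain_at_failure == pytest.approx(truth.strain_at_failure, rel=0.01)

    def test_unit_identities_exact(self, short_protocol):
        params = default_material_params("GP")
        trace, truth = generate_load_trace(params, short_protocol, seed=6)
        spec = Specimen("s", "GP", csa=truth.csa)
        p = extract_all(trace, spec, short_protocol)
        assert p.ultimate_stress * p.csa == pytest.approx(p.ultimate_force, rel=1e-12)
        assert p.elastic_modulus * p.csa / spec.gauge_length == pytest.approx(
            p.stiffness, rel=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            LoadTrace(np.array([]), np.array([]), np.array([]))

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_force_scaling_property(self, c, short_protocol):
        """Scaling all forces by c scales force-like metrics by c and leaves
        strain at failure and relative relaxation unchanged."""
        params = default_material_params("C", noise_sd=0.0)
        trace, truth = generate_load_trace(params, short_protocol, seed=8)
        spec = Specimen("s", "C", csa=truth.csa)
        base = extract_all(trace, spec, short_protocol)
        scaled_trace = LoadTrace(trace.time, c * trace.force, trace.displacement,
                                 trace.phase)
        scaled = extract_all(scaled_trace, spec, short_protocol)
        assert scaled.ultimate_force == pytest.approx(c * base.ultimate_force, rel=1e-9)
        assert scaled.stiffness == pytest.approx(c * base.stiffness, rel=1e-9)
        assert scaled.work_to_failure == pytest.approx(c * base.work_to_failure, rel=1e-9)
        assert scaled.strain_at_failure == pytest.approx(base.strain_at_failure, rel=1e-12)
        assert scaled.relative_stress_relaxation == pytest.approx(
            base.relative_stress_relaxation, rel=1e-9)
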
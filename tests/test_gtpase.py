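"""Coupled-assay velocity extraction and the activity/Cc regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import points_on_line
from ftszdyn import (
    AbsorbanceTrace,
    VelocityPoint,
    fit_kinetics,
    mixture_activity,
    pool_replicate_fits,
    velocity_from_trace,
)
from ftszdyn.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidArgumentError,
)
from ftszdyn.gtpase import DEFAULT_PATH_CM, NADH_EXTINCTION
from ftszdyn.synthetic import GroundTruth, make_gtpase_traces


def make_trace(slope_per_s: float, n: int = 61, dt: float = 10.0, start: float = 0.9,
               conc: float = 8.0) -> AbsorbanceTrace:
    t = np.arange(n) * dt
    return AbsorbanceTrace(
        time=t, a340=np.clip(start + slope_per_s * t, 0, None),
        protein_conc=conc, gtp_conc=500.0,
    )


class TestVelocityFromTrace:
    def test_flat_trace_gives_zero_velocity(self):
        assert velocity_from_trace(make_trace(0.0)).velocity == 0.0

    def test_rising_trace_clamps_to_zero(self):
        """The coupled assay cannot report negative hydrolysis."""
        assert velocity_from_trace(make_trace(+1e-4)).velocity == 0.0

    def test_synthetic_trace_recovers_closed_form_velocity(self):
        """A 14 uM trace generated from (a=0.59, Cc=2.12) must refit to
        v = 0.59 * (14 - 2.12) = 7.0092 uM/min."""
        gt = GroundTruth(noise_a340=0.0, protein_concs=(14.0,))
        (trace,) = make_gtpase_traces(gt)
        point = velocity_from_trace(trace)
        assert point.velocity == pytest.approx(7.0092, rel=1e-9)

    def test_known_slope_converts_through_beer_lambert(self):
        # dA/min = -v * eps * path * 1e-6 => v = 5 uM/min here
        v = 5.0
        slope_per_s = -v * NADH_EXTINCTION * DEFAULT_PATH_CM * 1e-6 / 60.0
        got = velocity_from_trace(make_trace(slope_per_s, start=2.0))
        assert got.velocity == pytest.approx(v, rel=1e-12)

    def test_offset_invariance(self):
        """Adding a constant to A340 does not change the velocity."""
        tr = make_trace(-2e-5)
        shifted = AbsorbanceTrace(tr.time, tr.a340 + 0.3, tr.protein_conc, tr.gtp_conc)
        assert velocity_from_trace(shifted).velocity == pytest.approx(
            velocity_from_trace(tr).velocity, rel=1e-12
        )

    def test_window_restricts_the_fit(self):
        tr = make_trace(-2e-5)
        full = velocity_from_trace(tr)
        windowed = velocity_from_trace(tr, window=(0.0, 300.0))
        assert windowed.velocity == pytest.approx(full.velocity, rel=1e-9)

    @pytest.mark.parametrize("window", [(700.0, 900.0), (-50.0, 100.0), (100.0, 50.0)])
    def test_bad_window_raises(self, window):
        with pytest.raises(InvalidArgumentError):
            velocity_from_trace(make_trace(-2e-5), window=window)

    def test_too_few_points_in_window_raises(self):
        with pytest.raises(InsufficientDataError):
            velocity_from_trace(make_trace(-2e-5), window=(0.0, 11.0))


class TestTraceValidation:
    def test_rejects_decreasing_time(self):
        with pytest.raises(InvalidArgumentError):
            AbsorbanceTrace([0, 2, 1], [1, 1, 1], 8.0, 500.0)

    def test_rejects_negative_absorbance(self):
        with pytest.raises(InvalidArgumentError):
            AbsorbanceTrace([0, 1, 2], [1, -0.1, 1], 8.0, 500.0)

    def test_rejects_short_trace(self):
        with pytest.raises(InvalidArgumentError):
            AbsorbanceTrace([0, 1], [1, 1], 8.0, 500.0)


class TestFitKinetics:
    def test_recovers_printed_parameters_from_their_own_line(self):
        """Points on v = 0.59 * (C - 2.12) for C in 4..14 refit to the
        reported activity and critical concentration exactly."""
        fit = fit_kinetics(points_on_line(0.59, 2.12, [4, 6, 8, 10, 12, 14]))
        assert fit.activity == pytest.approx(0.59, rel=1e-12)
        assert fit.cc == pytest.approx(2.12, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.linear_range == (4.0, 14.0)

    def test_line_through_origin_gives_zero_cc(self):
        fit = fit_kinetics(points_on_line(1.0, 0.0, [1, 2, 3, 4]))
        assert fit.activity == pytest.approx(1.0, rel=1e-12)
        assert fit.cc == pytest.approx(0.0, abs=1e-12)

    def test_noisy_cc_recovery_is_unbiased_enough(self):
        """Velocity noise sd 0.05 over 200 seeded replicates keeps the
        mean absolute Cc error below 0.2 uM."""
        concs = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            v = np.maximum(0.59 * np.maximum(concs - 2.12, 0) + rng.normal(0, 0.05, 7), 0.0)
            pts = [VelocityPoint(float(c), float(vi)) for c, vi in zip(concs, v)]
            errs.append(abs(fit_kinetics(pts).cc - 2.12))
        assert np.mean(errs) < 0.2

    def test_zero_velocity_points_are_excluded(self):
        pts = points_on_line(0.59, 2.12, [1, 2, 4, 6, 8, 10, 12, 14])
        fit = fit_kinetics(pts)  # the two sub-Cc points have v = 0
        assert fit.n_points == 6
        assert fit.cc == pytest.approx(2.12, rel=1e-12)

    def test_conc_range_override(self):
        pts = points_on_line(0.59, 2.12, [4, 6, 8, 10, 12, 14])
        fit = fit_kinetics(pts, conc_range=(6.0, 12.0))
        assert fit.n_points == 4
        assert fit.cc == pytest.approx(2.12, rel=1e-9)

    def test_insufficient_points_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_kinetics(points_on_line(0.59, 2.12, [4, 6]))

    def test_negative_slope_raises_degenerate(self):
        pts = [VelocityPoint(c, v) for c, v in [(2, 3.0), (4, 2.0), (6, 1.0)]]
        with pytest.raises(DegenerateFitError):
            fit_kinetics(pts)

    def test_cc_sd_positive_under_noise(self):
        rng = np.random.default_rng(7)
        pts = [
            VelocityPoint(float(c), 0.59 * (c - 2.12) + float(rng.normal(0, 0.05)))
            for c in [4, 6, 8, 10, 12, 14]
        ]
        fit = fit_kinetics(pts)
        assert fit.cc_sd > 0
        assert fit.activity_sd > 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-1.0, 5.0),
    )
    def test_scale_and_shift_equivariance(self, scale, shift):
        """Scaling velocities scales the activity and fixes Cc; shifting
        concentrations shifts Cc and fixes the activity."""
        base = points_on_line(0.59, 2.12, [4, 6, 8, 10, 12, 14])
        fit = fit_kinetics(base)
        scaled = [VelocityPoint(p.protein_conc, p.velocity * scale) for p in base]
        sfit = fit_kinetics(scaled)
        assert sfit.activity == pytest.approx(fit.activity * scale, rel=1e-9)
        assert sfit.cc == pytest.approx(fit.cc, rel=1e-9)
        shifted = [VelocityPoint(p.protein_conc + shift, p.velocity) for p in base]
        hfit = fit_kinetics(shifted)
        assert hfit.activity == pytest.approx(fit.activity, rel=1e-9)
        assert hfit.cc == pytest.approx(fit.cc + shift, rel=1e-9, abs=1e-9)


class TestMixtureActivity:
    def test_recovers_mixture_row_parameters(self):
        """Total-concentration points on v = 0.46 * (C_total - 1.30)
        refit to the reported mixture activity and Cc."""
        totals = [3, 4.8, 6.6, 8.4, 9.6]
        pts = points_on_line(0.46, 1.30, totals)
        fit = mixture_activity(pts)
        assert fit.activity == pytest.approx(0.46, rel=1e-12)
        assert fit.cc == pytest.approx(1.30, rel=1e-12)

    def test_matches_fit_kinetics_exactly(self):
        pts = points_on_line(0.59, 2.12, [4, 6, 8, 10, 12, 14])
        assert mixture_activity(pts) == fit_kinetics(pts)

    def test_order_invariance(self):
        pts = points_on_line(0.59, 2.12, [4, 6, 8, 10, 12, 14])
        a, b = fit_kinetics(pts[::-1]), fit_kinetics(pts)
        assert a.activity == pytest.approx(b.activity, rel=1e-12)
        assert a.cc == pytest.approx(b.cc, rel=1e-12)
        assert a.n_points == b.n_points and a.linear_range == b.linear_range


class TestReplicatePooling:
    def test_mean_and_sd_across_fits(self):
        f1 = fit_kinetics(points_on_line(0.5, 2.0, [4, 6, 8, 10]))
        f2 = fit_kinetics(points_on_line(0.7, 2.4, [4, 6, 8, 10]))
        pooled = pool_replicate_fits([f1, f2])
        assert pooled.activity == pytest.approx(0.6, rel=1e-12)
        assert pooled.cc == pytest.approx(2.2, rel=1e-12)
        assert pooled.activity_sd == pytest.approx(np.std([0.5, 0.7], ddof=1), rel=1e-9)
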
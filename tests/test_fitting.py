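"""Parameter estimation from syllectograms: oracles, invariants, errors."""
import math

import numpy as np
import pytest

from eakit.fitting import (
    NonDecayingSignalError,
    PoorlyIdentifiableWarning,
    compute_eak5s,
    extract_segment,
    fit_bi_exp,
    fit_inverse_linear,
    fit_mono_exp,
    select_best_segment,
)
from eakit.kinetics import (
    LN2,
    BiExpParams,
    Model1Params,
    MonoExpParams,
    Syllectogram,
    eval_bi_exp,
    eval_model1,
)
from eakit.simulate import NoiseSpec, simulate_syllectogram

from conftest import mono_curve


class TestExtractSegment:
    def test_keeps_samples_up_to_and_including_duration(self):
        s = mono_curve(100.0, 0.3, duration=20.0, rate=10.0)
        seg = extract_segment(s, 5.0)
        assert seg.duration == pytest.approx(5.0)
        assert seg.n_samples == 51  # endpoint inclusive at 10 Hz
        np.testing.assert_array_equal(seg.intensities, s.intensities[: seg.n_samples])

    def test_full_duration_is_identity(self):
        s = mono_curve(100.0, 0.3, duration=5.0)
        seg = extract_segment(s, 5.0)
        np.testing.assert_array_equal(seg.times, s.times)

    def test_preserves_metadata(self):
        s = mono_curve(100.0, 0.3, duration=10.0).with_meta(subject="a")
        assert extract_segment(s, 5.0).meta["subject"] == "a"

    def test_too_long_request_raises_with_available_duration(self):
        s = mono_curve(100.0, 0.3, duration=20.0)
        with pytest.raises(ValueError, match="20"):
            extract_segment(s, 25.0)


class TestFitMonoExp:
    @pytest.mark.parametrize("a0, k", [(1000.0, 0.3), (5.0, 0.05), (300.0, 1.2)])
    def test_noiseless_recovery(self, a0, k):
        fit = fit_mono_exp(mono_curve(a0, k))
        assert fit.params.k == pytest.approx(k, rel=1e-6)
        assert fit.params.a0 == pytest.approx(a0, rel=1e-6)
        assert fit.r2 >= 1 - 1e-10
        assert fit.converged
        assert fit.half_life_s == pytest.approx(LN2 / k, rel=1e-9)

    def test_noisy_recovery_within_2pct(self):
        s = simulate_syllectogram(
            MonoExpParams(1000.0, 0.3), 5.0, 100.0, NoiseSpec(sd=5.0, seed=7)
        )
        assert fit_mono_exp(s).params.k == pytest.approx(0.3, rel=0.02)

    def test_constant_signal_raises(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(NonDecayingSignalError):
            fit_mono_exp(Syllectogram(t, np.full_like(t, 3.0)))

    def test_rising_signal_raises(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(NonDecayingSignalError):
            fit_mono_exp(Syllectogram(t, np.exp(0.1 * t)))

    def test_too_few_samples_rejected(self):
        t = np.linspace(0, 5, 5)
        with pytest.raises(ValueError, match=">= 8"):
            fit_mono_exp(Syllectogram(t, np.exp(-t)))

    def test_scale_equivariance(self):
        """Multiplying intensities by c rescales a0 only; k, half-life, r2 unchanged."""
        s = simulate_syllectogram(
            MonoExpParams(1000.0, 0.3), 5.0, 100.0, NoiseSpec(sd=5.0, seed=3)
        )
        base = fit_mono_exp(s)
        scaled = fit_mono_exp(Syllectogram(s.times, 7.5 * s.intensities))
        assert scaled.params.k == pytest.approx(base.params.k, rel=1e-9)
        assert scaled.half_life_s == pytest.approx(base.half_life_s, rel=1e-9)
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-9)
        assert scaled.params.a0 == pytest.approx(7.5 * base.params.a0, rel=1e-9)

    def test_time_unit_consistency(self):
        """Rescaling times by c rescales k by 1/c and the half-life by c."""
        s = mono_curve(1000.0, 0.3)
        base = fit_mono_exp(s)
        stretched = fit_mono_exp(Syllectogram(2.0 * s.times, s.intensities))
        assert stretched.params.k == pytest.approx(base.params.k / 2.0, rel=1e-6)
        assert stretched.half_life_s == pytest.approx(2.0 * base.half_life_s, rel=1e-6)

    def test_optional_offset_recovers_baseline(self):
        t = np.arange(501) / 100.0
        y = 1000.0 * np.exp(-0.5 * t) + 50.0
        fit = fit_mono_exp(Syllectogram(t, y), with_offset=True)
        assert fit.offset == pytest.approx(50.0, rel=0.01)
        assert fit.params.k == pytest.approx(0.5, rel=0.01)


class TestFitInverseLinear:
    def test_exact_on_second_order_data(self):
        t = np.arange(501) / 100.0
        y = eval_model1(Model1Params(2.0, 0.5), t)
        fit = fit_inverse_linear(Syllectogram(t, y))
        assert fit.slope == pytest.approx(0.5, rel=1e-9)
        assert fit.intercept == pytest.approx(0.5, rel=1e-9)
        assert fit.r2 > 1 - 1e-12
        assert not fit.underdetermined

    def test_worse_than_mono_exp_on_first_order_data(self):
        s = mono_curve(1000.0, 0.27615)
        assert fit_inverse_linear(s).r2 < fit_mono_exp(s).r2 < 1 + 1e-12

    def test_two_points_flagged_underdetermined(self):
        fit = fit_inverse_linear(Syllectogram(np.array([0.0, 1.0]), np.array([2.0, 1.0])))
        assert fit.underdetermined
        assert fit.r2 == pytest.approx(1.0)


class TestFitBiExp:
    def test_noiseless_recovery_within_1pct(self, noiseless_20s, biexp_params):
        fit = fit_bi_exp(noiseless_20s)
        p, true = fit.params, biexp_params
        assert fit.converged
        assert p.i_fast == pytest.approx(true.i_fast, rel=0.01)
        assert p.tau_fast == pytest.approx(true.tau_fast, rel=0.01)
        assert p.i_slow == pytest.approx(true.i_slow, rel=0.01)
        assert p.tau_slow == pytest.approx(true.tau_slow, rel=0.01)
        assert p.baseline == pytest.approx(true.baseline, rel=0.01)
        assert p.tau_fast < p.tau_slow

    def test_peeling_initialization_is_reported(self, noiseless_20s):
        """The peeling start point is kept on the result for audit.

        Peeling itself is biased here — with a 15 s slow time constant the
        final 5% of a 20 s recording has not reached the baseline — so only
        validity and ordering are required of the init; accuracy is the
        refinement's job.
        """
        fit = fit_bi_exp(noiseless_20s)
        assert fit.init_params.tau_fast < fit.init_params.tau_slow
        assert fit.init_params.tau_fast > 0 and fit.init_params.baseline >= 0

    def test_degenerate_single_component(self):
        s = simulate_syllectogram(
            BiExpParams(3.0, 2.0, 0.0, 20.0, 0.1), 20.0, 100.0, NoiseSpec("none")
        )
        with pytest.warns(PoorlyIdentifiableWarning):
            fit = fit_bi_exp(s)
        assert fit.params.tau_fast == pytest.approx(2.0, rel=0.02)
        assert fit.params.i_slow < 0.05 * fit.params.i_fast

    def test_equal_time_constants_warn_poorly_identifiable(self):
        t = np.arange(2001) / 100.0
        y = 2.0 * np.exp(-t / 3.0) + 2.0 * np.exp(-t / 3.0) + 0.5
        with pytest.warns(PoorlyIdentifiableWarning):
            fit_bi_exp(Syllectogram(t, y))

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="15"):
            fit_bi_exp(mono_curve(100.0, 0.3, duration=10.0))


class TestSelectBestSegment:
    def test_pure_mono_exponential_ties_to_shortest(self):
        sel = select_best_segment(mono_curve(1000.0, 0.27615, duration=10.0))
        assert all(f.r2 >= 0.99 for f in sel.fits.values())
        assert sel.best_duration == 1.5
        assert sel.rule == "tie-shortest"

    def test_strong_slow_component_penalizes_long_segments(self):
        s = simulate_syllectogram(
            BiExpParams(600.0, 1.0, 400.0, 30.0, 100.0), 10.0, 100.0, NoiseSpec("none")
        )
        sel = select_best_segment(s)
        assert sel.best_duration < 10.0
        r2_by_duration = {d: f.r2 for d, f in sel.fits.items()}
        assert r2_by_duration[10.0] == min(r2_by_duration.values())

    def test_durations_beyond_recording_raise(self):
        s = mono_curve(100.0, 0.3, duration=6.0)
        assert select_best_segment(s, [1.5, 3, 5]).best_duration == 1.5
        with pytest.raises(ValueError):
            select_best_segment(s, [1.5, 3, 5, 10])


class TestComputeEak5s:
    def test_half_life_of_ln2_rate_is_one_second(self):
        fit = compute_eak5s(mono_curve(500.0, math.log(2.0), duration=8.0))
        assert fit.half_life_s == pytest.approx(1.0, rel=1e-6)
        assert fit.segment_duration == pytest.approx(5.0)

    def test_healthy_rate_gives_2_51_s(self):
        fit = compute_eak5s(mono_curve(1000.0, 0.27615, duration=6.0))
        assert fit.half_life_s == pytest.approx(2.51, abs=0.005)

    def test_recording_shorter_than_5s_rejected(self):
        with pytest.raises(ValueError):
            compute_eak5s(mono_curve(100.0, 0.3, duration=3.0))


def test_fit_report_serializes(noiseless_20s):
    report = fit_bi_exp(noiseless_20s).to_dict()
    assert set(report) >= {"i_fast", "tau_fast_s", "i_slow", "tau_slow_s", "baseline", "r2"}
    sel = select_best_segment(mono_curve(100.0, 0.3, duration=10.0)).to_dict()
    assert sel["best_duration_s"] in sel["fits"] or str(sel["best_duration_s"]) in sel["fits"]
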
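"""Forward model, photobleaching, multi-exponential fits, mutant ratios."""

import numpy as np
import pytest

from tdtkinetics.mechanisms import RateParameters, build_scheme
from tdtkinetics.synthdata import (
    default_times_stopped_flow,
    gen_multiexp_trace,
    gen_mutant_pair,
)
from tdtkinetics.transient import (
    ObservableModel,
    Trace,
    correct_photobleach,
    estimate_kbleach,
    fit_global,
    fit_multiexponential,
    relative_activity,
    simulate_trace,
)

TIMES = default_times_stopped_flow(n=120, t_max=10.0)
STATIC = RateParameters(0, 0, 0, 0)  # frozen chemistry


class TestSimulateTrace:
    def test_static_single_species_gives_constant_signal(self):
        m = build_scheme("scheme2")
        obs = ObservableModel(responses={"E": 1.0}, F0=0.0, kbleach=0.0)
        tr = simulate_trace(m, STATIC, obs, {"E": 1.0}, TIMES)
        assert np.allclose(tr.signal, 1.0)

    def test_bleaching_of_static_signal_is_monoexponential_to_background(self):
        m = build_scheme("scheme2")
        obs = ObservableModel(responses={"E": 2.0}, F0=0.5, kbleach=0.3)
        tr = simulate_trace(m, STATIC, obs, {"E": 1.0}, TIMES)
        expected = (0.5 + 2.0 - 0.5) * np.exp(-0.3 * TIMES) + 0.5
        assert np.allclose(tr.signal, expected)

    def test_negative_initial_concentration_rejected(self):
        m = build_scheme("scheme2")
        obs = ObservableModel(responses={"E": 1.0})
        with pytest.raises(ValueError, match="negative"):
            simulate_trace(m, STATIC, obs, {"E": -1.0}, TIMES)

    def test_pseudo_first_order_relaxation_rate(self):
        """Two-state limit: observed rate equals k1·[N] + k_minus1 within 1%."""
        m = build_scheme("scheme2")
        p = RateParameters(k1=2.0, k_minus1=5.0, k2=0.0, k_minus2=0.0)
        n0, e0 = 50.0, 0.5  # [N] >> [E]
        obs = ObservableModel(responses={"X1": 1.0}, F0=0.0)
        t = np.geomspace(1e-4, 1.0, 300)
        tr = simulate_trace(m, p, obs, {"E": e0, "N": n0}, t)
        fit = fit_multiexponential(tr, 1)
        assert fit.kobs[0] == pytest.approx(p.k1 * n0 + p.k_minus1, rel=0.01)


class TestPhotobleaching:
    def _bleached_trace(self, kbleach=0.1, f0=0.4):
        m = build_scheme("scheme2")
        p = RateParameters(k1=3.0, k_minus1=2.0, k2=1.0, k_minus2=0.5)
        obs_clean = ObservableModel(responses={"N": 1.0, "X1": 2.0, "X2": 4.0}, F0=f0)
        obs_bleach = ObservableModel(
            responses=obs_clean.responses, F0=f0, kbleach=kbleach
        )
        init = {"E": 1.0, "N": 2.0}
        clean = simulate_trace(m, p, obs_clean, init, TIMES)
        bleached = simulate_trace(m, p, obs_bleach, init, TIMES)
        return clean, bleached

    def test_zero_kbleach_correction_is_identity(self):
        clean, _ = self._bleached_trace()
        out = correct_photobleach(clean, F0=0.4, kbleach=0.0)
        assert np.array_equal(out.signal, clean.signal)

    def test_background_only_trace_stays_at_background(self):
        tr = Trace(times=TIMES, signal=np.full_like(TIMES, 0.4))
        out = correct_photobleach(tr, F0=0.4, kbleach=0.2)
        assert np.allclose(out.signal, 0.4)

    def test_correction_round_trip_recovers_unbleached_model(self):
        clean, bleached = self._bleached_trace(kbleach=0.1)
        corrected = correct_photobleach(bleached, F0=0.4, kbleach=0.1)
        assert np.max(np.abs(corrected.signal - clean.signal)) < 1e-10

    def test_estimate_kbleach_exact(self):
        t = np.linspace(0.0, 60.0, 200)
        tr = Trace(times=t, signal=0.3 + 1.5 * np.exp(-0.05 * t))
        est = estimate_kbleach(tr)
        assert not est.flagged
        assert est.kbleach == pytest.approx(0.05, abs=1e-6)
        assert est.F0 == pytest.approx(0.3, abs=1e-6)

    def test_estimate_kbleach_constant_trace_flagged(self):
        tr = Trace(times=TIMES, signal=np.ones_like(TIMES))
        est = estimate_kbleach(tr)
        assert est.kbleach == 0.0
        assert est.flagged

    def test_estimate_kbleach_with_noise(self, rng):
        t = np.linspace(0.0, 60.0, 400)
        y = 0.3 + 1.5 * np.exp(-0.05 * t)
        tr = Trace(times=t, signal=y + rng.normal(0, 0.01 * np.ptp(y), t.size))
        est = estimate_kbleach(tr)
        assert est.kbleach == pytest.approx(0.05, rel=0.05)


class TestMultiExponential:
    def test_single_exponential_exact_recovery(self):
        t = np.geomspace(1e-3, 10, 200)
        tr = Trace(times=t, signal=2.0 - 1.5 * np.exp(-3.0 * t))
        fit = fit_multiexponential(tr, 1)
        assert fit.kobs[0] == pytest.approx(3.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(-1.5, rel=1e-6)
        assert fit.offset == pytest.approx(2.0, rel=1e-6)

    def test_three_phase_recovery_with_noise(self):
        kobs = (20.0, 2.5, 0.3)
        tr = gen_multiexp_trace(
            kobs, (-0.6, -0.8, 1.0), 2.0, noise_sigma=0.01, seed=5
        )
        fit = fit_multiexponential(tr, 3)
        assert np.allclose(fit.kobs, kobs, rtol=0.05)

    def test_constant_trace_gives_zero_amplitudes(self):
        tr = Trace(times=TIMES, signal=np.full_like(TIMES, 3.0))
        fit = fit_multiexponential(tr, 2)
        assert np.allclose(fit.amplitudes, 0.0, atol=1e-12)
        assert fit.offset == pytest.approx(3.0)

    def test_too_few_points_rejected(self):
        tr = Trace(times=np.array([0.1, 0.2, 0.3]), signal=np.zeros(3))
        with pytest.raises(ValueError, match="few points"):
            fit_multiexponential(tr, 1)


class TestRelativeActivity:
    def test_identical_fits_give_unit_ratios(self):
        tr = gen_multiexp_trace((10.0, 1.0), (-1.0, 1.0), 2.0, noise_sigma=0.0)
        fit = fit_multiexponential(tr, 2)
        assert np.allclose(relative_activity(fit, fit), 1.0)

    def test_doubled_slowest_phase_ratio(self):
        wt = gen_multiexp_trace((10.0, 1.0, 0.1), (-0.5, -0.7, 1.0), 2.0, noise_sigma=0.0)
        mut = gen_multiexp_trace((10.0, 1.0, 0.2), (-0.5, -0.7, 1.0), 2.0, noise_sigma=0.0)
        ratios = relative_activity(
            fit_multiexponential(mut, 3), fit_multiexponential(wt, 3)
        )
        assert ratios[0] == pytest.approx(1.0, rel=1e-3)
        assert ratios[1] == pytest.approx(1.0, rel=1e-3)
        assert ratios[2] == pytest.approx(2.0, rel=1e-3)

    def test_phase_count_mismatch_rejected(self):
        tr = gen_multiexp_trace((10.0, 1.0), (-1.0, 1.0), 2.0, noise_sigma=0.0)
        f2 = fit_multiexponential(tr, 2)
        f1 = fit_multiexponential(tr, 1)
        with pytest.raises(ValueError, match="mismatch"):
            relative_activity(f2, f1)


class TestGlobalFitEdgeCases:
    def test_zero_signal_traces_flagged_non_identifiable(self):
        m = build_scheme("scheme2")
        t = TIMES
        traces = [
            Trace(times=t, signal=np.zeros_like(t), conc_enzyme=c, conc_nucleotide=3.0)
            for c in (1.0, 2.0)
        ]
        res = fit_global(traces, m, n_starts=1)
        assert not res.converged
        assert "non-identifiable" in res.message

    def test_fewer_than_two_concentrations_rejected(self):
        m = build_scheme("scheme2")
        tr = Trace(times=TIMES, signal=np.ones_like(TIMES), conc_enzyme=1.0)
        with pytest.raises(ValueError):
            fit_global([tr, tr], m, n_starts=1)
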
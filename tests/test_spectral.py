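"""Tests of the ensemble PSD/ACF/variance estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemofdt.spectral import (
    AcfFit,
    compute_psd,
    estimate_lambda,
    filter_unresponsive,
    fit_correlation_time,
    parseval_variance,
    per_cell_activity,
    psd_to_acf,
    sort_by_activity,
)
from chemofdt.array_model import ArrayModelParams, simulate_ensemble
from chemofdt.synthetic_data import (
    FRETTrace,
    GeneratorParams,
    generate_phenomenological_trace,
    make_fixture,
    render_fret_from_activity,
)


def _trace(r):
    return FRETTrace(time=np.arange(len(r), dtype=float), ratio=np.asarray(r))


def direct_circular_acf(traces, T):
    """Brute-force time-domain oracle: circular ACF of mean-subtracted
    segments, normalized by the segment-mean squared, averaged over all
    segments and cells."""
    acc = []
    for tr in traces:
        r = np.asarray(tr.ratio, float)
        for j in range(len(r) // T):
            seg = r[j * T:(j + 1) * T]
            x = seg - seg.mean()
            c = np.array([np.dot(x, np.roll(x, -k)) / T for k in range(T)])
            acc.append(c / seg.mean() ** 2)
    return np.mean(acc, axis=0)[:T // 2 + 1]


class TestComputePsd:
    def test_constant_trace_has_zero_psd(self):
        psd = compute_psd([_trace(np.full(400, 1.3))])
        assert np.allclose(psd.s, 0.0, atol=1e-25)

    def test_white_noise_is_flat_at_sigma_sq_over_mean_sq(self):
        rng = np.random.default_rng(0)
        sigma, mean = 0.05, 2.0
        traces = [_trace(mean + sigma * rng.standard_normal(1600))
                  for _ in range(80)]
        psd = compute_psd(traces)
        expected = sigma ** 2 / mean ** 2
        assert abs(psd.s.mean() - expected) < 3 * psd.sem.mean() / math.sqrt(
            len(psd.s))
        assert np.all(np.abs(psd.s - expected) < 5 * psd.sem + 1e-12)

    def test_single_tone_lands_in_one_bin(self):
        T, k0, a, rbar = 400, 25, 0.01, 1.5
        t = np.arange(T)
        r = rbar * (1 + a * np.cos(2 * np.pi * k0 * t / T))
        psd = compute_psd([_trace(r)])
        assert psd.s[k0 - 1] == pytest.approx(a ** 2 * T / 4, rel=1e-9)
        others = np.delete(psd.s, k0 - 1)
        assert np.all(others < 1e-12 * psd.s[k0 - 1])

    def test_rescaling_invariance(self):
        """Eq.4's R̄² normalization removes any uniform intensity scale."""
        rng = np.random.default_rng(1)
        r = 1.0 + 0.05 * rng.standard_normal(800)
        s1 = compute_psd([_trace(r)]).s
        s2 = compute_psd([_trace(3.7 * r)]).s
        assert np.allclose(s1, s2, rtol=1e-12)

    def test_window_and_length_validation(self):
        with pytest.raises(ValueError):
            compute_psd([_trace(np.ones(300) * 1.0)])
        tr = FRETTrace(time=np.array([0.0, 1.0, 3.0, 4.0]),
                       ratio=np.ones(4))
        with pytest.raises(ValueError):
            compute_psd([tr], segment_length=4)


class TestWienerKhinchin:
    def test_flat_spectrum_gives_delta_acf(self):
        rng = np.random.default_rng(2)
        traces = [_trace(1 + 0.03 * rng.standard_normal(1200))
                  for _ in range(40)]
        acf = psd_to_acf(compute_psd(traces))
        assert acf.C[0] > 0
        assert np.all(np.abs(acf.C[1:]) < 0.05 * acf.C[0])

    def test_roundtrip_matches_time_domain_oracle(self):
        """IDFT of the ensemble PSD equals the direct circular ACF."""
        rng = np.random.default_rng(3)
        traces = []
        for _ in range(5):
            x = np.cumsum(rng.standard_normal(1200)) * 0.001
            traces.append(_trace(1.0 + x - x.mean() +
                                 0.02 * rng.standard_normal(1200)))
        psd = compute_psd(traces)
        acf = psd_to_acf(psd)
        oracle = direct_circular_acf(traces, psd.T)
        assert np.allclose(acf.C, oracle, atol=1e-10)

    def test_c0_equals_total_normalized_variance(self):
        rng = np.random.default_rng(4)
        traces = [_trace(1 + 0.05 * rng.standard_normal(400))]
        psd = compute_psd(traces)
        acf = psd_to_acf(psd)
        assert acf.C[0] == pytest.approx(psd.two_sided_sum() / psd.T,
                                         rel=1e-12)


class TestCorrelationTimeFit:
    def test_exact_exponential_recovered_to_machine_precision(self):
        lag = np.arange(201, dtype=float)
        C = 0.3 * np.exp(-lag / 20.0)
        fit = fit_correlation_time(AcfFit(lag=lag, C=C, T=400), model="exp")
        assert fit.tau0 == pytest.approx(20.0, rel=1e-8)
        assert fit.C0 == pytest.approx(0.3, rel=1e-8)
        assert not fit.failed

    def test_white_noise_flags_failure(self):
        rng = np.random.default_rng(5)
        traces = [_trace(1 + 0.05 * rng.standard_normal(1200))
                  for _ in range(30)]
        fit = fit_correlation_time(psd_to_acf(compute_psd(traces)))
        assert fit.failed

    @pytest.mark.parametrize("tau", [5.0, 10.0, 34.0, 60.0])
    def test_ou_correlation_time_recovery(self, tau):
        """τ0 within 15% of truth for 200 cells × 1800 s at T=400."""
        gp = GeneratorParams(V_A=0.25, tau=tau)
        traces = [generate_phenomenological_trace(gp, None, 1800.0, seed)
                  for seed in range(200)]
        fit = fit_correlation_time(psd_to_acf(compute_psd(traces)))
        assert not fit.failed
        assert fit.tau0 == pytest.approx(tau, rel=0.15)

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            fit_correlation_time(AcfFit(lag=np.arange(5.0),
                                        C=np.exp(-np.arange(5.0)), T=8),
                                 fit_range=(0, 5))


class TestParsevalVariance:
    def test_identity_against_time_domain_variance(self):
        """Discrete Parseval: (1/T)Σ_{k≠0}s_k = var(R/R̄) to 1e-12."""
        rng = np.random.default_rng(6)
        seg = 1.0 + 0.04 * rng.standard_normal(400)
        psd = compute_psd([_trace(seg)])
        est = parseval_variance(psd, None, lam=0.1, denormalize=False)
        assert est.var_ratio == pytest.approx(seg.var() / seg.mean() ** 2,
                                              rel=1e-12)

    def test_noise_equal_signal_gives_zero(self, wt_psd):
        est = parseval_variance(wt_psd, wt_psd, lam=0.1)
        assert est.var_ratio == 0.0
        assert est.var_activity == 0.0

    def test_activity_variance_identity(self, wt_psd, noise_psd):
        est = parseval_variance(wt_psd, noise_psd, lam=0.1)
        assert est.var_activity == pytest.approx(est.var_ratio / 0.01,
                                                 rel=1e-14)

    def test_grid_mismatch_rejected(self, wt_psd):
        other = compute_psd(make_fixture("receptorless", 5, 0,
                                         duration=800.0), segment_length=200)
        with pytest.raises(ValueError):
            parseval_variance(wt_psd, other, lam=0.1)


class TestLambdaAndResponsiveness:
    def test_noise_free_lambda_exact(self):
        gp = GeneratorParams(A_bar=1.0, V_A=0.0, shot_sigma=0.0, tau=34.0)
        from chemofdt.synthetic_data import QEQE_PROTOCOL, QEQE_ACTIVITY
        from chemofdt.synthetic_data import Ensemble
        traces = [generate_phenomenological_trace(
            gp, QEQE_PROTOCOL, 1640.0, 0, QEQE_ACTIVITY)]
        ens = Ensemble(traces, "x", 0, QEQE_PROTOCOL, QEQE_ACTIVITY, 1640.0)
        assert estimate_lambda(ens) == pytest.approx(0.10, abs=1e-12)

    def test_missing_window_rejected(self, wt_ensemble):
        with pytest.raises(ValueError):
            estimate_lambda(wt_ensemble)

    def test_threshold_boundary(self):
        # population ΔR = 0.10: a 0.005 change is discarded, 0.011 kept
        base = np.ones(300)
        cells = []
        for d in (0.005, 0.011):
            r = base.copy()
            r[150:] -= d
            cells.append(_trace(r))
        kept, discarded = filter_unresponsive(
            cells, stim_window=(150, 300), ref_window=(0, 150),
            population_response=0.10, guard=20)
        assert discarded == [cells[0]] and kept == [cells[1]]

    def test_receptorless_all_discarded(self):
        ens = make_fixture("receptorless", 30, 12, duration=600.0)
        kept, discarded = filter_unresponsive(
            ens, stim_window=(300, 600), ref_window=(0, 300),
            population_response=0.10)
        assert not kept and len(discarded) == 30


class TestActivitySorting:
    def test_window_arithmetic(self):
        r = np.ones(1400)
        r[300:600] = 0.95    # 30 µM window
        r[900:1200] = 0.90   # 100 µM window
        tr = _trace(r)
        a = per_cell_activity(tr, (0, 300), (300, 600), (600, 900),
                              (900, 1200))
        assert a == pytest.approx(0.5, abs=1e-12)

    def test_nonpositive_denominator_flagged(self):
        tr = _trace(np.ones(1400))
        with pytest.raises(ValueError):
            per_cell_activity(tr, (0, 300), (300, 600), (600, 900),
                              (900, 1200))

    def test_scaling_with_a_one_minus_a(self):
        """Low-frequency PSD of sorted mechanistic cells ∝ A(1−A)."""
        from chemofdt.synthetic_data import Ensemble, StimulusProtocol
        p = ArrayModelParams(N_T=2100, n_R=0, n_B=0, tau_eff=10.0)
        rng = np.random.default_rng(31)
        f0 = -0.55 + 0.16 * (2 * rng.random(120) - 1)
        # long sub-saturating window: 3 full PSD segments after guards
        proto = StimulusProtocol(events=[(0.0, 0.0), (300.0, 0.55),
                                         (1560.0, 0.0), (1860.0, 3.0),
                                         (2160.0, 0.0)])
        acts = simulate_ensemble(p, proto, 2460.0, rng, n_cells=120,
                                 f0_cells=f0)
        gp = GeneratorParams(shot_sigma=0.005, V_A=0.0)
        traces = [render_fret_from_activity(a, gp, rng) for a in acts]
        ens = Ensemble(traces, "mech_sort", None, proto, None, 2460.0)
        res = sort_by_activity(ens, sub_token=0.55, sat_token=3.0,
                               buffer_token=0.0, low_freq_max=0.02)
        assert res.scaling_r2 > 0.9
        assert res.scaling_slope > 0

    def test_equal_population_partition(self):
        from chemofdt.synthetic_data import Ensemble
        ens = make_fixture("rb_minus_qeqe_protocol", 47, 13)
        res = sort_by_activity(ens)
        for n in res.n_values:
            sizes = [b["size"] for b in res.bins if b["n"] == n]
            assert max(sizes) - min(sizes) <= 1
            assert sum(sizes) == 47


@given(st.integers(1, 6), st.floats(0.5, 2.0))
def test_parseval_identity_random_tones(k, amp):
    """Parseval holds for arbitrary band-limited segments."""
    t = np.arange(100)
    r = 5.0 + amp * np.cos(2 * np.pi * k * t / 100)
    psd = compute_psd([_trace(r)], segment_length=100)
    est = parseval_variance(psd, None, lam=1.0, denormalize=False)
    assert est.var_ratio == pytest.approx(r.var() / r.mean() ** 2, rel=1e-10)
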
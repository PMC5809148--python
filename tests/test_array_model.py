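"""Unit and property tests of the signaling-team array simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemofdt.array_model import (
    ArrayModelParams,
    TeamState,
    simulate_ensemble,
    step_team,
    team_equilibrium_activity,
    team_free_energy,
)
from chemofdt.spectral import compute_psd


def lowfreq_psd(acts, fmax=0.01, T=400):
    psd = compute_psd([a.A for a in acts], segment_length=T)
    return float(psd.s[psd.freq <= fmax].mean())


class TestEquilibriumActivity:
    @pytest.mark.parametrize("F,expected", [
        (0.0, 0.5),
        (math.log(3.0), 0.25),
        (-20.0, 1.0),
    ])
    def test_boltzmann_values(self, F, expected):
        assert team_equilibrium_activity(F) == pytest.approx(expected, abs=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            team_equilibrium_activity(float("nan"))

    @given(st.floats(-50, 50), st.floats(0.01, 10))
    def test_strictly_decreasing_in_f(self, f, df):
        assert team_equilibrium_activity(f + df) < team_equilibrium_activity(f)


class TestTeamFreeEnergy:
    def test_linear_arithmetic(self):
        assert team_free_energy(0, 0.5, 0.0, 0.0, 0.0, N=14) == 0.0
        assert team_free_energy(1, 0.5, 0.0, 0.0, 0.0, N=14) == -7.0

    def test_noise_enters_linearly(self):
        x = 0.37
        up = team_free_energy(2, 0.5, 0.1, 0.2, +x, N=14)
        dn = team_free_energy(2, 0.5, 0.1, 0.2, -x, N=14)
        mid = team_free_energy(2, 0.5, 0.1, 0.2, 0.0, N=14)
        assert (up + dn) / 2 == pytest.approx(mid, rel=1e-12)

    def test_methylation_out_of_range(self):
        with pytest.raises(ValueError):
            team_free_energy(9, 0.5, 0.0, 0.0, 0.0, N=14, m_max=8)


class TestParams:
    def test_team_partition_and_dt_guard(self):
        p = ArrayModelParams()
        assert p.n_teams == 10_000 // 42
        with pytest.raises(ValueError):
            ArrayModelParams(dt=2.0, tau_eff=10.0).validate()
        with pytest.raises(ValueError):
            ArrayModelParams(N_T=10).validate()

    def test_negative_enzymes_rejected(self):
        with pytest.raises(ValueError):
            ArrayModelParams(n_R=-1).validate()


class TestStepTeam:
    def test_stationary_occupancy_matches_boltzmann(self):
        """Telegraph stationary law: time-averaged ON fraction -> A_eq(F)."""
        p = ArrayModelParams(n_R=0, n_B=0, tau_eff=2.0, dt=0.1,
                             f0=math.log(3.0) / 14)  # team F = ln 3
        rng = np.random.default_rng(0)
        s = TeamState()
        n, on = 40_000, 0
        for _ in range(n):
            s, _, _ = step_team(s, p, 0.0, p.dt, rng)
            on += s.active
        a_eq = team_equilibrium_activity(math.log(3.0))  # 0.25
        # effective number of independent samples ~ duration / (2 tau)
        se = math.sqrt(a_eq * (1 - a_eq) / (n * p.dt / (2 * p.tau_eff)))
        assert abs(on / n - a_eq) < 3 * se

    def test_methylation_is_absorbing_without_cheb(self):
        # N=1 keeps inactive states reachable at high m so the upward drift
        # can complete; with no CheB there is no demethylation pathway.
        p = ArrayModelParams(N=1, N_T=3, n_R=1, n_B=0, tau_eff=2.0, dt=0.1,
                             k_bind=0.5, k_cat=1.0)
        rng = np.random.default_rng(1)
        s = TeamState()
        free_R, free_B = 1, 0
        m_seen = []
        for _ in range(60_000):
            s, free_R, free_B = step_team(s, p, 0.0, p.dt, rng, free_R, free_B)
            m_seen.append(s.m)
        assert s.m == p.m_max
        assert np.all(np.diff(m_seen) >= 0)  # no demethylation ever

    def test_coarse_dt_refused(self):
        p = ArrayModelParams(tau_eff=10.0, dt=1.0)
        with pytest.raises(ValueError):
            step_team(TeamState(), p, 0.0, 2.0, np.random.default_rng(0))


class TestSimulateCell:
    def test_team_acf_relaxes_at_tau_eff(self):
        """Ensemble ACF of the passive activity fits exp(−t/tau_eff)."""
        p = ArrayModelParams(n_R=0, n_B=0, tau_eff=10.0, N_T=2520)
        acts = simulate_ensemble(p, None, 600.0, np.random.default_rng(2),
                                 n_cells=30)
        A = np.array([a.A for a in acts])
        x = A - A.mean()
        acf = np.zeros(31)
        for row in x:
            for lag in range(31):
                acf[lag] += np.dot(row[:len(row) - lag], row[lag:])
        acf /= acf[0]
        tau_fit = -1.0 / np.polyfit(np.arange(31), np.log(np.clip(acf, 1e-6, None)), 1)[0]
        assert tau_fit == pytest.approx(10.0, rel=0.25)

    def test_binomial_variance_of_independent_teams(self):
        """With A_eq = 1/2, var(A) = 0.25/n_teams (independent teams)."""
        p = ArrayModelParams(n_R=0, n_B=0, tau_eff=10.0, f0=0.0)
        acts = simulate_ensemble(p, None, 800.0, np.random.default_rng(3),
                                 n_cells=20)
        A = np.concatenate([a.A for a in acts])
        n_eff = len(A) / (2 * p.tau_eff)  # decorrelated sample count
        assert abs(A.mean() - 0.5) < 3 * math.sqrt(0.25 / p.n_teams / n_eff)
        expected = 0.25 / p.n_teams
        se = expected * math.sqrt(2.0 / n_eff)
        assert abs(A.var() - expected) < 3 * se

    def test_saturating_attractant_abolishes_activity(self):
        p = ArrayModelParams(n_R=0, n_B=0, tau_eff=5.0, N_T=2520)
        acts = simulate_ensemble(p, [(0.0, 0.0), (100.0, 5.0)], 300.0,
                                 np.random.default_rng(4), n_cells=10)
        A = np.array([a.A for a in acts])
        t = np.asarray(acts[0].time)
        assert A[:, t > 150].mean() < 0.01
        # PSD after the transient has settled: activity is pinned at zero
        psd = compute_psd([a.A[t > 160] + 1.0 for a in acts],
                          segment_length=100)
        assert psd.s[psd.freq < 0.05].mean() < 1e-5

    def test_seed_reproducibility(self):
        p = ArrayModelParams(N_T=2520)
        a1 = simulate_ensemble(p, None, 200.0, np.random.default_rng(5), 2)
        a2 = simulate_ensemble(p, None, 200.0, np.random.default_rng(5), 2)
        assert np.array_equal(a1[0].A, a2[0].A)
        assert np.array_equal(a1[1].n_bound_R, a2[1].n_bound_R)

    def test_acf_overshoot_only_with_enzymes(self):
        """Adaptation feedback makes the activity ACF dip below zero."""
        common = dict(tau_eff=10.0, f0=2.0)
        p_on = ArrayModelParams(**common)
        p_off = ArrayModelParams(n_R=0, n_B=0, **common)
        rng = np.random.default_rng(6)
        on = simulate_ensemble(p_on, None, 1000.0, rng, n_cells=12,
                               burn_in=200.0)
        off = simulate_ensemble(p_off, None, 1000.0, rng, n_cells=12, m0=4)

        def mean_acf(acts, lags=150):
            X = np.array([a.A for a in acts])
            X = X - X.mean()  # ensemble mean avoids per-trace ACF bias
            acf = np.zeros(lags)
            for row in X:
                for lag in range(lags):
                    acf[lag] += np.dot(row[:len(row) - lag], row[lag:]) / (
                        len(row) - lag)
            return acf / acf[0]

        acf_on = mean_acf(on)
        acf_off = mean_acf(off)
        decay_on = int(np.argmax(acf_on < math.exp(-1)))
        assert acf_on[3 * decay_on:].min() < -0.02
        assert acf_off[:100].min() > -0.05


class TestMonotonicity:
    def test_peak_psd_nondecreasing_in_team_size(self):
        """Larger allosteric amplification gives larger fluctuations."""
        levels = []
        for i, N in enumerate((7, 14, 28)):
            p = ArrayModelParams(N=N, N_T=2520, n_R=0, n_B=0, tau_eff=10.0)
            acts = simulate_ensemble(p, None, 800.0,
                                     np.random.default_rng(10 + i), n_cells=16)
            levels.append(lowfreq_psd(acts))
        assert levels[0] < levels[1] < levels[2]

    def test_peak_psd_nondecreasing_in_response_time(self):
        """Slower cluster response gives higher maximal fluctuation power."""
        levels = []
        for i, tau in enumerate((5.0, 10.0, 20.0)):
            p = ArrayModelParams(N_T=2520, n_R=0, n_B=0, tau_eff=tau)
            acts = simulate_ensemble(p, None, 800.0,
                                     np.random.default_rng(20 + i), n_cells=16)
            levels.append(lowfreq_psd(acts))
        assert levels[0] < levels[1] < levels[2]


class TestEquilibriumSpectrum:
    def test_lorentzian_psd_over_three_decades(self):
        """Simulated passive PSD matches 2A(1−A)τ/((1+ω²τ²)·n_teams)."""
        p = ArrayModelParams(N_T=2520, n_R=0, n_B=0, tau_eff=2.0, dt=0.1)
        acts = simulate_ensemble(p, None, 4000.0, np.random.default_rng(30),
                                 n_cells=12)
        T = 2000
        psd = compute_psd([a.A for a in acts], segment_length=T)
        omega = 2 * np.pi * psd.freq
        analytic = (2 * 0.25 * p.tau_eff / (1 + (omega * p.tau_eff) ** 2)
                    / p.n_teams) / 0.25  # R̄² = <A>² normalization
        for flo, fhi in ((5e-4, 5e-3), (5e-3, 5e-2), (5e-2, 0.5)):
            m = (psd.freq >= flo) & (psd.freq < fhi)
            ratio = psd.s[m].mean() / analytic[m].mean()
            assert 0.8 < ratio < 1.2, (flo, fhi, ratio)


class TestClusterDisruption:
    def test_chewx2_low_frequency_psd_collapses(self):
        """Two-trimer teams with fast response lose slow fluctuations."""
        p_def = ArrayModelParams(n_R=0, n_B=0, tau_eff=10.0, f0=0.0)
        p_x2 = ArrayModelParams(N=2, n_R=0, n_B=0, tau_eff=1.0, f0=0.0)
        d = simulate_ensemble(p_def, None, 800.0, np.random.default_rng(40),
                              n_cells=12)
        x = simulate_ensemble(p_x2, None, 800.0, np.random.default_rng(41),
                              n_cells=12)
        assert abs(np.mean([a.A.mean() for a in d]) -
                   np.mean([a.A.mean() for a in x])) < 0.02
        assert lowfreq_psd(x) < 0.05 * lowfreq_psd(d)
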
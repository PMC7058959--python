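"""Forward trajectory machinery: dominance model, recursion, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polysweep as pw
from polysweep.trajectory import ConditioningError, write_trajectory, read_trajectory, \
    write_trajectory_reversed

from conftest import enumeration_expected_frequency


class TestDominance:
    def test_additive_is_linear(self):
        h = pw.dominance_coefficients(0.0, 4)
        assert np.allclose(h, [0, 0.25, 0.5, 0.75, 1.0])

    @pytest.mark.parametrize(
        "H,k,tau,h1",
        [(-0.4, 2, 10**0.4, 0.5 ** (10**0.4)), (0.4, 2, 10**-0.4, 0.5 ** (10**-0.4))],
    )
    def test_dominance_scalar_mapping(self, H, k, tau, h1):
        # recessive-like H=-0.4: tau ~ 2.512, h(1) ~ 0.175;
        # dominant-like H=+0.4: tau ~ 0.398, h(1) ~ 0.759
        m = pw.SelectionModel(k=k, N=100, s=0.1, H=H)
        assert m.tau == pytest.approx(tau)
        assert pw.dominance_coefficients(H, k)[1] == pytest.approx(h1)

    def test_endpoints_exact(self):
        for H in (-0.49, -0.1, 0.0, 0.3):
            h = pw.dominance_coefficients(H, 6)
            assert h[0] == 0.0 and h[-1] == 1.0

    @pytest.mark.parametrize("H", [-0.45, -0.2, 0.0, 0.2, 0.45])
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_monotone_in_dosage(self, H, k):
        h = pw.dominance_coefficients(H, k)
        assert np.all(np.diff(h) > 0)

    def test_continuous_at_additivity(self):
        # tau -> 1 as H -> 0: coefficients converge to d/k
        for k in (2, 4):
            h_eps = pw.dominance_coefficients(1e-9, k)
            assert np.allclose(h_eps, np.arange(k + 1) / k, atol=1e-8)

    @pytest.mark.parametrize("H", [-0.5, 0.5, 0.7])
    def test_H_domain_error(self, H):
        with pytest.raises(ValueError):
            pw.dominance_coefficients(H, 2)

    @pytest.mark.parametrize("k", [1, 3, 0, -2])
    def test_odd_ploidy_error(self, k):
        with pytest.raises(ValueError):
            pw.dominance_coefficients(0.0, k)


class TestExpectedFrequency:
    def test_absorbing_states(self):
        m = pw.SelectionModel(k=4, N=100, s=0.3, H=0.2)
        assert pw.expected_frequency(0.0, m) == 0.0
        assert pw.expected_frequency(1.0, m) == 1.0

    def test_diploid_additive_hand_enumeration(self):
        # three genotypes at p=0.5: fitness 1, 1.05, 1.1 -> 0.5375/1.05
        m = pw.SelectionModel(k=2, N=100, s=0.1, H=0.0)
        assert pw.expected_frequency(0.5, m) == pytest.approx(0.5375 / 1.05, abs=1e-12)

    def test_tetraploid_additive_closed_form(self):
        # additive closed form (p + s E[d^2]/k^2) / (1 + s p)
        m = pw.SelectionModel(k=4, N=100, s=0.1, H=0.0)
        p, s, k = 0.1, 0.1, 4
        ed2 = k * p * (1 - p) + (k * p) ** 2
        assert pw.expected_frequency(p, m) == pytest.approx(
            (p + s * ed2 / k**2) / (1 + s * p), abs=1e-12
        )
        assert pw.expected_frequency(p, m) == pytest.approx(0.102228, abs=1e-6)

    def test_neutrality_identity(self):
        m = pw.SelectionModel(k=8, N=100, s=0.0, H=-0.3)
        for p in (0.01, 0.37, 0.99):
            assert pw.expected_frequency(p, m) == pytest.approx(p, abs=1e-15)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        k=st.sampled_from([2, 4, 6, 8]),
        p=st.floats(1e-6, 1 - 1e-6),
        s=st.floats(-0.5, 1.0),
        H=st.floats(-0.49, 0.49),
    )
    def test_matches_enumeration_oracle(self, k, p, s, H):
        m = pw.SelectionModel(k=k, N=100, s=s, H=H)
        assert pw.expected_frequency(p, m) == pytest.approx(
            enumeration_expected_frequency(p, k, s, H), abs=1e-12
        )

    def test_textbook_diploid_update(self):
        # k=2, H=0 reduces to the diploid formula with fitnesses 1, 1+s/2, 1+s
        s = 0.07
        m = pw.SelectionModel(k=2, N=100, s=s, H=0.0)
        for p in (0.05, 0.5, 0.9):
            q = 1 - p
            wbar = p * p * (1 + s) + 2 * p * q * (1 + s / 2) + q * q
            expected = (p * p * (1 + s) + p * q * (1 + s / 2)) / wbar
            assert pw.expected_frequency(p, m) == pytest.approx(expected, abs=1e-14)


class TestWrightFisherStep:
    def test_degenerate(self, rng):
        assert pw.wright_fisher_step(0.0, 100, 4, rng) == 0.0
        assert pw.wright_fisher_step(1.0, 100, 4, rng) == 1.0

    def test_binomial_moments(self, rng):
        N, k, phat = 1000, 4, 0.3
        draws = np.array([pw.wright_fisher_step(phat, N, k, rng) for _ in range(100_000)])
        se = math.sqrt(phat * (1 - phat) / (N * k) / len(draws))
        assert abs(draws.mean() - phat) < 3 * se
        assert draws.var() == pytest.approx(phat * (1 - phat) / (N * k), rel=0.05)

    def test_deterministic_under_seed(self):
        a = pw.wright_fisher_step(0.3, 500, 2, np.random.default_rng(7))
        b = pw.wright_fisher_step(0.3, 500, 2, np.random.default_rng(7))
        assert a == b

    def test_grid_resolution(self, rng):
        N, k = 37, 4
        x = pw.wright_fisher_step(0.41, N, k, rng)
        assert (x * N * k) == pytest.approx(round(x * N * k), abs=1e-9)


class TestSimulateTrajectory:
    def test_conditioned_endpoints(self, rng):
        m = pw.SelectionModel(k=2, N=100, s=0.5, H=0.0)
        traj = pw.simulate_trajectory(m, rng, max_attempts=10**6)
        assert traj.freqs[0] == pytest.approx(0.005)
        assert traj.freqs[-1] == 1.0
        assert traj.fixed
        assert np.all(traj.freqs[:-1] < 1.0)

    def test_frequencies_on_grid(self, rng):
        m = pw.SelectionModel(k=4, N=50, s=0.3, H=0.0)
        traj = pw.simulate_trajectory(m, rng)
        scaled = traj.freqs * (m.k * m.N)
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)

    def test_conditioning_failure_neutral(self, rng):
        # neutral fixation probability 1/(kN) = 5e-5: 3 attempts essentially never fix
        m = pw.SelectionModel(k=2, N=10_000, s=0.0, H=0.0)
        with pytest.raises(ConditioningError, match="3 attempts"):
            pw.simulate_trajectory(m, rng, max_attempts=3)


class TestDeterministicTrajectory:
    def test_neutral_never_converges(self):
        m = pw.SelectionModel(k=2, N=100, s=0.0, H=0.0)
        with pytest.raises(RuntimeError):
            pw.deterministic_trajectory(m, 0.5, 0.99, max_generations=1000)

    def test_ploidy_doubles_fixation_time(self):
        d2 = pw.deterministic_trajectory(
            pw.SelectionModel(k=2, N=1000, s=0.1, H=0.0), 0.01, 0.99)
        d4 = pw.deterministic_trajectory(
            pw.SelectionModel(k=4, N=1000, s=0.1, H=0.0), 0.01, 0.99)
        assert len(d4) / len(d2) == pytest.approx(2.0, rel=0.15)

    def test_recessive_slower_than_additive(self):
        add = pw.deterministic_trajectory(
            pw.SelectionModel(k=4, N=1000, s=0.1, H=0.0), 0.01, 0.99)
        rec = pw.deterministic_trajectory(
            pw.SelectionModel(k=4, N=1000, s=0.1, H=-0.4), 0.01, 0.99)
        assert len(rec) > len(add)


class TestFitnessMoments:
    def test_monomorphic_variance_zero(self):
        m = pw.SelectionModel(k=4, N=100, s=0.2, H=0.1)
        assert pw.fitness_moments(0.0, m)[1] == 0.0
        assert pw.fitness_moments(1.0, m)[1] == 0.0

    def test_diploid_hand_values(self):
        m = pw.SelectionModel(k=2, N=100, s=0.1, H=0.0)
        mean, var = pw.fitness_moments(0.5, m)
        assert mean == pytest.approx(1.05, abs=1e-12)
        assert var == pytest.approx(0.00125, abs=1e-12)

    def test_variance_shrinks_with_ploidy(self):
        # higher ploidy: fitness variance smaller at intermediate frequency
        vs = [pw.fitness_moments(0.5, pw.SelectionModel(k=k, N=100, s=0.1, H=0.0))[1]
              for k in (2, 4, 8)]
        assert vs[0] > vs[1] > vs[2]


class TestFixationStats:
    def test_single_replicate(self, rng):
        m = pw.SelectionModel(k=2, N=50, s=0.5, H=0.0)
        summary = pw.fixation_stats(m, 1, rng)
        assert summary.n_fixed == 1
        assert summary.mean_time == summary.median_time == summary.times[0]
        assert summary.fixation_probability == pytest.approx(1 / summary.n_attempts)

    def test_fixation_time_grows_faster_with_N_when_recessive(self, rng):
        # recessive sweeps slow disproportionately in large populations
        small_add = pw.fixation_stats(
            pw.SelectionModel(k=4, N=100, s=0.2, H=0.0), 15, rng).mean_time
        big_add = pw.fixation_stats(
            pw.SelectionModel(k=4, N=2000, s=0.2, H=0.0), 15, rng).mean_time
        small_rec = pw.fixation_stats(
            pw.SelectionModel(k=4, N=100, s=0.2, H=-0.4), 15, rng).mean_time
        big_rec = pw.fixation_stats(
            pw.SelectionModel(k=4, N=2000, s=0.2, H=-0.4), 15, rng).mean_time
        assert big_rec / small_rec > big_add / small_add


class TestTrajectoryIO:
    def test_roundtrip(self, rng, tmp_path):
        m = pw.SelectionModel(k=4, N=50, s=0.3, H=0.0)
        traj = pw.simulate_trajectory(m, rng)
        path = tmp_path / "traj.txt"
        with open(path, "w") as fh:
            write_trajectory(traj, fh)
        with open(path) as fh:
            back = read_trajectory(fh)
        assert np.allclose(back.freqs, traj.freqs)
        assert back.fixed
        assert back.model.k == 4 and back.model.N == 50

    def test_reversed_two_column_layout(self, tmp_path):
        traj = pw.Trajectory(freqs=np.array([0.25, 0.5, 1.0]), fixed=True)
        path = tmp_path / "rev.txt"
        with open(path, "w") as fh:
            write_trajectory_reversed(traj, fh)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert [int(r[0]) for r in rows] == [0, 1, 2]
        assert [float(r[1]) for r in rows] == [1.0, 0.5, 0.25]
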
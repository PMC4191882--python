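"""Langevin dynamics, contact-map CVs, metadynamics bias, replica exchange."""

import numpy as np
import pytest

from kinodyn.forcefield import build_hybrid, build_single_basin, \
    energy_forces
from kinodyn.sampler import (
    ContactMapDistance, MetadBias, ReplicaLadder, langevin_run,
    pt_exchange, run_ptmetad, write_hills, read_hills, check_timestep, KB,
)
from kinodyn.structure import compute_contact_map
from kinodyn.synthetic import make_double_well


class TestContactMapDistance:
    def test_zero_at_reference(self, two_state):
        cv = ContactMapDistance.from_contact_map(
            compute_contact_map(two_state.closed), name="D_closed")
        assert cv.value(two_state.closed.xyz) == pytest.approx(0, abs=1e-20)

    def test_single_pair_far_limit(self):
        cv = ContactMapDistance(name="d", i=[0], j=[1], r0=[5.0])
        far = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        assert cv.value(far) == pytest.approx(float(cv.s_ref[0] ** 2),
                                              rel=1e-6)

    def test_switch_value_at_native(self):
        """s(r0) with n=6, m=10, γ_s=1.2 follows the rational form."""
        cv = ContactMapDistance(name="d", i=[0], j=[1], r0=[5.0])
        x = 1.0 / 1.2
        expected = (1 - x ** 6) / (1 - x ** 10)
        assert cv.s_ref[0] == pytest.approx(expected, rel=1e-12)

    def test_removable_singularity(self):
        cv = ContactMapDistance(name="d", i=[0], j=[1], r0=[5.0])
        at_sing = np.array([[0.0, 0, 0], [6.0, 0, 0]])   # r = γ_s·r0
        v, g = cv.value_grad(at_sing)
        assert np.isfinite(v) and np.isfinite(g).all()
        assert cv._switch(np.array([6.0]))[0][0] == pytest.approx(
            6.0 / 10.0, rel=1e-9)

    def test_gradient_matches_finite_differences(self, two_state):
        cv = ContactMapDistance.from_contact_map(
            compute_contact_map(two_state.closed), name="D_closed")
        rng = np.random.default_rng(5)
        x = two_state.closed.xyz + 0.3 * rng.standard_normal(
            two_state.closed.xyz.shape)
        _, grad = cv.value_grad(x)
        h = 1e-6
        for a in (0, 7, 20):
            for d in range(3):
                xp = x.copy()
                xp[a, d] += h
                xm = x.copy()
                xm[a, d] -= h
                num = (cv.value(xp) - cv.value(xm)) / (2 * h)
                assert grad[a, d] == pytest.approx(num, abs=1e-6)


class TestLangevin:
    def test_zero_temperature_stays_at_minimum(self):
        K = 3.0

        def ff(x):
            return float(0.5 * K * (x ** 2).sum()), -K * x

        out = langevin_run(ff, np.zeros(3), 500, dt=0.05, friction=1.0,
                           temperature=0.0,
                           rng=np.random.default_rng(0))
        assert np.abs(out["x"]).max() == 0

    def test_harmonic_variance_matches_boltzmann(self):
        """⟨x²⟩ = k_B T / K within 2% on a long 1-D run."""
        K, T = 2.0, 300.0

        def ff(x):
            return float(0.5 * K * (x ** 2).sum()), -K * x

        out = langevin_run(ff, np.zeros(1), 400_000, dt=0.05, friction=1.0,
                           temperature=T,
                           rng=np.random.default_rng(0), sample_stride=5)
        xs = np.array(out["samples"])
        assert (xs ** 2).mean() == pytest.approx(KB * T / K, rel=0.02)

    def test_bitwise_deterministic(self):
        dw = make_double_well(5.0, 1.0)
        runs = [langevin_run(dw.force_fn(), np.array([1.0]), 2000, dt=0.01,
                             friction=1.0, temperature=300.0,
                             rng=np.random.default_rng(42),
                             sample_stride=10)
                for _ in range(2)]
        assert np.array_equal(np.array(runs[0]["samples"]),
                              np.array(runs[1]["samples"]))
        assert runs[0]["x"][0] == runs[1]["x"][0]

    def test_energy_conservation_deterministic_limit(self, two_state):
        """With zero friction and zero temperature BAOAB reduces to
        velocity Verlet; total energy drifts < 0.01 kcal/mol over 10⁴
        steps at the default timestep."""
        top = build_single_basin(two_state.closed, epsilon=0.8)
        rng = np.random.default_rng(1)
        v0 = 0.02 * rng.standard_normal(two_state.closed.xyz.shape)

        def ff(x):
            rep, f = energy_forces(top, x)
            return rep.total, f

        totals = []

        def hook(step, x, v):
            if step % 100 == 0:
                totals.append(ff(x)[0] + 0.5 * (v ** 2).sum())

        langevin_run(ff, two_state.closed.xyz, 10_000, dt=0.02,
                     friction=0.0, temperature=0.0,
                     rng=np.random.default_rng(2), v0=v0, hook=hook)
        assert max(totals) - min(totals) < 0.01

    def test_divergence_reported_with_step(self):
        def ff(x):
            return 0.0, 1e308 * np.ones_like(x)

        with pytest.raises(FloatingPointError, match="step"):
            with np.errstate(over="ignore", invalid="ignore"):
                langevin_run(ff, np.zeros(3), 50, dt=1.0, friction=0.0,
                             temperature=0.0,
                             rng=np.random.default_rng(0))

    def test_timestep_check(self, two_state):
        top = build_single_basin(two_state.closed)
        check_timestep(top, 0.02)
        with pytest.raises(ValueError, match="dt"):
            check_timestep(top, 0.2)


class TestMetadBias:
    def test_hill_center_value(self):
        bias = MetadBias(sigma=0.5, height=0.7, pace=10)
        bias.deposit([2.0], step=10)
        assert bias.energy([2.0]) == pytest.approx(0.7)

    def test_gaussian_tail(self):
        bias = MetadBias(sigma=0.5, height=0.7, pace=10)
        bias.deposit([2.0], step=10)
        far = bias.energy([2.0 + 5 * 0.5])
        assert far < 0.7 * np.exp(-12.5) * 1.001

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        bias = MetadBias(sigma=[0.4, 0.8], height=0.5, pace=10)
        for k in range(30):
            bias.deposit(rng.uniform(0, 4, 2), step=k)
        for point in rng.uniform(0, 4, (5, 2)):
            _, grad = bias.energy_grad(point)
            h = 1e-7
            for d in range(2):
                p = point.copy()
                p[d] += h
                m = point.copy()
                m[d] -= h
                num = (bias.energy(p) - bias.energy(m)) / (2 * h)
                assert grad[d] == pytest.approx(num, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            MetadBias(sigma=-0.1, height=0.5, pace=10)
        with pytest.raises(ValueError):
            MetadBias(sigma=0.1, height=0.0, pace=10)

    def test_well_tempered_heights_decay(self):
        bias = MetadBias(sigma=0.5, height=1.0, pace=10, wt_gamma=5.0,
                         temperature=300.0)
        for k in range(20):
            bias.deposit([0.0], step=k)
        assert bias.heights[-1] < bias.heights[0]
        assert all(h > 0 for h in bias.heights)

    def test_hills_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        bias = MetadBias(sigma=[0.4, 0.8], height=0.5, pace=10)
        for k in range(12):
            bias.deposit(rng.uniform(0, 4, 2), step=10 * k)
        path = tmp_path / "hills.txt"
        write_hills(bias, path, ["D_closed", "D_open"])
        centers, sigmas, heights = read_hills(path)
        np.testing.assert_array_equal(centers, np.array(bias.centers))
        np.testing.assert_array_equal(heights, np.array(bias.heights))
        np.testing.assert_array_equal(sigmas[0], bias.sigma)


class TestPtExchange:
    def test_identical_replicas_always_swap(self):
        rng = np.random.default_rng(0)
        assert pt_exchange(1.0, 1.0, 0.3, 0.3, 0.3, 0.3,
                           2.0, 2.0, rng)

    def test_harmonic_two_temperature_acceptance(self):
        """Measured swap acceptance for two harmonic replicas matches an
        independent Monte-Carlo estimate of E[min(1, e^Δ)] within 3 SE."""
        K, t1, t2 = 2.0, 300.0, 450.0
        b1, b2 = 1 / (KB * t1), 1 / (KB * t2)
        rng = np.random.default_rng(7)
        n = 40_000
        x1 = rng.normal(0, np.sqrt(KB * t1 / K), n)
        x2 = rng.normal(0, np.sqrt(KB * t2 / K), n)
        u1, u2 = 0.5 * K * x1 ** 2, 0.5 * K * x2 ** 2
        accepted = sum(
            pt_exchange(u1[k], u2[k], 0, 0, 0, 0, b1, b2, rng)
            for k in range(n)) / n
        # oracle: direct expectation on an independent sample
        rng2 = np.random.default_rng(1234)
        y1 = rng2.normal(0, np.sqrt(KB * t1 / K), n)
        y2 = rng2.normal(0, np.sqrt(KB * t2 / K), n)
        delta = (b1 - b2) * (0.5 * K * y2 ** 2 - 0.5 * K * y1 ** 2)
        oracle = np.minimum(1.0, np.exp(delta))
        se_diff = oracle.std() / np.sqrt(n) * np.sqrt(2)
        assert abs(accepted - oracle.mean()) < 3 * se_diff

    def test_temperature_flux_balance(self):
        """Over a long biased PT run, every accepted swap moves one walker
        up and one down the ladder — the net temperature flux through any
        ladder edge vanishes, and acceptance statistics are populated."""
        rng = np.random.default_rng(0)
        K = 2.0
        temps = np.array([300.0, 360.0, 432.0])
        betas = 1 / (KB * temps)
        x = rng.normal(0, np.sqrt(KB * temps / K))
        walker = np.arange(3)
        up = np.zeros(2)
        down = np.zeros(2)
        for sweep in range(20_000):
            # resample configurations from each replica's own ensemble
            x = rng.normal(0, np.sqrt(KB * temps / K))
            p = sweep % 2
            u = 0.5 * K * x ** 2
            if pt_exchange(u[p], u[p + 1], 0, 0, 0, 0,
                           betas[p], betas[p + 1], rng):
                walker[[p, p + 1]] = walker[[p + 1, p]]
                up[p] += 1
                down[p] += 1
        assert (up == down).all()
        assert up.min() > 1000


class TestRunPtmetad:
    def _quick_system(self, two_state):
        top = build_hybrid(two_state.closed, two_state.open,
                           two_state.switch_region, epsilon=0.8,
                           kd1=0.3, kd3=0.15)
        cv_c = ContactMapDistance.from_contact_map(
            compute_contact_map(two_state.closed), name="D_closed")
        cv_o = ContactMapDistance.from_contact_map(
            compute_contact_map(two_state.open), name="D_open")
        return top, [cv_c, cv_o]

    def test_zero_steps(self, two_state):
        top, cvs = self._quick_system(two_state)
        res = run_ptmetad(top, cvs, two_state.closed.xyz, n_steps=0,
                          seed=1, temperatures=(250.0, 340.0))
        assert res.biases[0].n_hills == 0
        assert res.cv_series.shape[1] == 0

    def test_same_seed_identical_hills(self, two_state):
        top, cvs = self._quick_system(two_state)
        runs = [run_ptmetad(top, cvs, two_state.closed.xyz, n_steps=3000,
                            seed=99, temperatures=(250.0, 340.0),
                            hill_pace=200, cv_stride=100)
                for _ in range(2)]
        np.testing.assert_array_equal(np.array(runs[0].biases[0].centers),
                                      np.array(runs[1].biases[0].centers))
        np.testing.assert_array_equal(runs[0].cv_series,
                                      runs[1].cv_series)

    def test_outputs_written(self, two_state, tmp_path):
        top, cvs = self._quick_system(two_state)
        run_ptmetad(top, cvs, two_state.closed.xyz, n_steps=2000, seed=5,
                    temperatures=(250.0, 340.0), hill_pace=200,
                    cv_stride=100, out_dir=tmp_path / "run")
        assert (tmp_path / "run" / "hills.replica0.txt").exists()
        assert (tmp_path / "run" / "cv.replica0.tsv").exists()
        assert (tmp_path / "run" / "run_metadata.json").exists()

    def test_bias_accelerates_double_well_crossing(self):
        """Unbiased low-temperature dynamics stays in its starting well;
        with metadynamics the walker crosses the barrier."""
        dw = make_double_well(h=5.0, a=1.0)
        T = 150.0
        ff = dw.force_fn()
        unbiased = langevin_run(ff, np.array([-1.0]), 50_000, dt=0.01,
                                friction=1.0, temperature=T,
                                rng=np.random.default_rng(0),
                                sample_stride=50)
        assert np.array(unbiased["samples"]).max() < 0.5

        bias = MetadBias(sigma=0.15, height=0.25, pace=200)
        state = {"x": None}

        def hook(step, x, v):
            if step % 200 == 0:
                bias.deposit([x[0]], step)

        def biased_ff(x):
            e, f = ff(x)
            vb, gb = bias.energy_grad(x)
            return e + vb, f - gb

        out = langevin_run(biased_ff, np.array([-1.0]), 50_000, dt=0.01,
                           friction=1.0, temperature=T,
                           rng=np.random.default_rng(0),
                           sample_stride=50, hook=hook)
        assert np.array(out["samples"]).max() > 0.5


def test_replica_ladder_validation():
    with pytest.raises(ValueError):
        ReplicaLadder(np.array([300.0, 300.0]))
    ladder = ReplicaLadder.geometric(250.0, 500.0, 4)
    assert len(ladder.temperatures) == 4
    assert np.all(np.diff(ladder.temperatures) > 0)
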
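import numpy as np
import pytest

from gshrad import metadyn

from oracles import brute_bias, brute_minimax_barrier


class TestBias:
    def test_no_hills_zero_everywhere(self):
        hills = metadyn.Hills(height=0.03, width=0.05)
        grid = np.linspace(2, 6, 11)
        assert np.all(hills.bias(grid[:, None], grid[None, :]) == 0.0)

    def test_single_hill_peak_equals_height(self):
        hills = metadyn.Hills(height=0.03, width=0.05)
        metadyn.deposit_bias(hills, metadyn.CollectiveVariables(3.0, 4.0),
                             metadyn.HillSchedule())
        assert hills.bias(3.0, 4.0) == pytest.approx(0.03)
        assert hills.bias(3.0 + 0.05, 4.0) == pytest.approx(
            0.03 * np.exp(-0.5), rel=1e-12)

    def test_fifty_hills_match_naive_sum(self):
        rng = np.random.default_rng(4)
        hills = metadyn.Hills(height=0.03, width=0.05)
        sched = metadyn.HillSchedule()
        for _ in range(50):
            metadyn.deposit_bias(
                hills, metadyn.CollectiveVariables(*rng.uniform(2, 5.8, 2)),
                sched)
        pts = rng.uniform(2, 6, size=(40, 2))
        expected = brute_bias(hills.centers, 0.03, 0.05, pts)
        got = hills.bias(pts[:, 0], pts[:, 1])
        assert np.allclose(got, expected, atol=1e-12)

    def test_linearity_in_hills(self):
        rng = np.random.default_rng(5)
        a = metadyn.Hills(height=0.03, width=0.05,
                          centers=[tuple(c) for c in rng.uniform(2, 5, (20, 2))],
                          steps=list(range(20)))
        b = metadyn.Hills(height=0.03, width=0.05,
                          centers=[tuple(c) for c in rng.uniform(2, 5, (30, 2))],
                          steps=list(range(30)))
        both = metadyn.Hills(height=0.03, width=0.05,
                             centers=a.centers + b.centers,
                             steps=a.steps + b.steps)
        x = np.linspace(2, 5.5, 15)
        assert np.allclose(both.bias(x, x), a.bias(x, x) + b.bias(x, x),
                           atol=1e-12)

    def test_deposit_outside_wall_rejected(self):
        hills = metadyn.Hills(height=0.03, width=0.05)
        with pytest.raises(ValueError):
            metadyn.deposit_bias(hills, metadyn.CollectiveVariables(6.5, 3.0),
                                 metadyn.HillSchedule())

    def test_cv_positivity(self):
        with pytest.raises(ValueError):
            metadyn.CollectiveVariables(-1.0, 2.0)


class TestSampler:
    def test_deterministic_per_seed(self):
        pot = metadyn.double_well_channel()
        sched = metadyn.HillSchedule(deposit_stride=100)
        r1 = metadyn.run_metadynamics(pot, sched, steps=20_000, seed=9)
        r2 = metadyn.run_metadynamics(pot, sched, steps=20_000, seed=9)
        assert r1.hills.centers == r2.hills.centers
        assert np.array_equal(r1.cv_trace, r2.cv_trace)
        r3 = metadyn.run_metadynamics(pot, sched, steps=20_000, seed=10)
        assert r1.hills.centers != r3.hills.centers

    def test_flat_potential_covers_domain(self):
        pot = metadyn.flat_potential()
        sched = metadyn.HillSchedule(height=0.0)
        res = metadyn.run_metadynamics(pot, sched, steps=300_000, seed=2)
        cv = res.cv_trace
        assert len(cv) > 1000
        inner = cv[(cv[:, 0] > 2.0) & (cv[:, 0] < 5.5)]
        # both halves of the walled region visited substantially
        left = np.mean(inner[:, 0] < 3.75)
        assert 0.2 < left < 0.8
        assert cv[:, 0].min() < 2.5 and cv[:, 0].max() > 5.0

    def test_unbiased_harmonic_matches_gaussian(self):
        """Height-zero sampling reproduces the analytic Boltzmann sd."""
        k = 2.0
        pot = metadyn.harmonic_well(center=(3.5, 3.5), k=k)
        sched = metadyn.HillSchedule(height=0.0)
        res = metadyn.run_metadynamics(pot, sched, steps=400_000, seed=3,
                                       x0=(3.5, 3.5))
        sd_expected = np.sqrt(metadyn.KB_KCAL * 310.0 / k)
        cv = res.cv_trace
        for axis in (0, 1):
            assert cv[:, axis].mean() == pytest.approx(3.5, abs=0.05)
            assert cv[:, axis].std() == pytest.approx(sd_expected, rel=0.12)

    def test_hill_dispersion_grows_as_well_fills(self):
        pot = metadyn.ModelPotential2D(depths=(2.5,), centers=((3.5, 3.5),),
                                       sigmas=(0.35,))
        sched = metadyn.HillSchedule(deposit_stride=25)
        res = metadyn.run_metadynamics(pot, sched, steps=400_000, seed=6,
                                       x0=(3.5, 3.5))
        c = res.hills.center_array()
        n = len(c)
        early = c[: n // 5]
        late = c[-n // 5:]
        assert late.std(axis=0).mean() > early.std(axis=0).mean()

    def test_step_validation(self):
        with pytest.raises(ValueError):
            metadyn.run_metadynamics(metadyn.flat_potential(),
                                     metadyn.HillSchedule(), steps=0)


class TestReconstruction:
    def test_single_hill_fes(self):
        hills = metadyn.Hills(height=0.03, width=0.05, centers=[(3.0, 3.0)],
                              steps=[1])
        axis = np.linspace(2, 4, 41)
        fes = metadyn.reconstruct_fes(hills, (axis, axis))
        assert fes.free_energy.min() == 0.0
        i = np.argmin(np.abs(axis - 3.0))
        assert fes.free_energy[i, i] == pytest.approx(0.0, abs=1e-12)
        assert fes.free_energy[0, 0] == pytest.approx(0.03, abs=1e-6)

    def test_empty_hills_error(self):
        with pytest.raises(ValueError):
            metadyn.reconstruct_fes(metadyn.Hills(0.03, 0.05),
                                    (np.arange(3.0), np.arange(3.0)))

    def test_symmetric_hills_symmetric_fes(self):
        hills = metadyn.Hills(height=0.03, width=0.3)
        sched = metadyn.HillSchedule(width=0.3)
        for c in [(3.0, 4.0), (4.0, 3.0), (3.5, 3.5)]:
            metadyn.deposit_bias(hills, metadyn.CollectiveVariables(*c), sched)
        axis = np.linspace(2.5, 4.5, 21)
        fes = metadyn.reconstruct_fes(hills, (axis, axis))
        assert np.allclose(fes.free_energy, fes.free_energy.T, atol=1e-12)

    def test_boltzmann_reference_reproduces_potential(self):
        pot = metadyn.double_well_channel()
        axis = np.arange(1.8, 6.0, 0.1)
        ref = metadyn.boltzmann_reference(pot, (axis, axis))
        v = pot.value(axis[:, None], axis[None, :])
        assert np.allclose(ref.free_energy, v - v.min(), atol=1e-9)


class TestMinima:
    def test_monotone_bowl_single_minimum(self):
        axis = np.linspace(-2, 2, 41)
        f = axis[:, None] ** 2 + axis[None, :] ** 2
        fes = metadyn.FESGrid(axis, axis, f - f.min())
        res = metadyn.locate_minima(fes)
        assert len(res.minima) == 1
        assert res.minima[0].cv1 == pytest.approx(0.0)

    def test_double_well_grid_recovery(self):
        pot = metadyn.double_well_channel()
        axis = np.arange(1.8, 6.0, 0.1)
        ref = metadyn.boltzmann_reference(pot, (axis, axis))
        res = metadyn.locate_minima(ref, min_prominence=0.1)
        assert len(res.minima) >= 2
        analytic = pot.minima()
        for (ax, ay), mn in zip(analytic, res.minima[:2]):
            assert abs(mn.cv1 - ax) <= 0.1 + 1e-9
            assert abs(mn.cv2 - ay) <= 0.1 + 1e-9

    def test_barrier_matches_exhaustive_minimax(self):
        """Union-find saddle equals brute-force threshold connectivity."""
        rng = np.random.default_rng(12)
        axis = np.linspace(0, 1, 12)
        f = rng.uniform(1.0, 2.0, (12, 12))
        f[2, 2] = 0.0
        f[9, 8] = 0.1
        fes = metadyn.FESGrid(axis, axis, f)
        res = metadyn.locate_minima(fes)
        vals = {(m.i, m.j): m for m in res.minima}
        assert (2, 2) in vals and (9, 8) in vals
        idx = {m: k for k, m in enumerate(res.minima)}
        shallow = vals[(9, 8)]
        bar = [b for b in res.barriers if b.minimum == idx[shallow]]
        assert bar, "shallow minimum must record its merge barrier"
        saddle = brute_minimax_barrier(f, (2, 2), (9, 8))
        assert bar[0].saddle_value == pytest.approx(saddle)
        assert bar[0].height == pytest.approx(saddle - 0.1)


def test_fes_accuracy_improves_with_length():
    """MAD vs the Boltzmann reference is non-increasing with run length."""
    mads = {}
    for steps in (150_000, 600_000):
        vals = []
        for seed in (1, 2):
            b = metadyn.run_double_well_benchmark(seed=seed, steps=steps)
            vals.append(b["mad"])
        mads[steps] = np.mean(vals)
    assert mads[600_000] <= mads[150_000] + 0.02
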
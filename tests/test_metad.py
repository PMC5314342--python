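"""Well-tempered metadynamics: bias sums, deposition rule, FES
reconstruction, unit conversion and reweighting plumbing."""

import numpy as np
import pytest

from pnadyn.constants import KB, KJ_PER_KCAL
from pnadyn.cvs import CoordinateCV
from pnadyn.metad import (FESGrid, Hill, MetadParams, bias_gradient,
                          bias_value, convert_units, deposit,
                          fes_from_hills, reweight, reweight_weights,
                          run_wtmetad)
from pnadyn.potentials import DoubleWell1D, ParticleSystem


def random_hills(rng, n, d=2):
    return [Hill(time=float(k), center=tuple(rng.normal(size=d)),
                 sigma=tuple(rng.uniform(0.5, 1.5, d)),
                 height=float(rng.uniform(0.5, 2.5))) for k in range(n)]


class TestBiasSum:
    def test_no_hills_is_zero(self):
        assert bias_value([], [0.3, 0.4]) == 0.0
        assert np.all(bias_gradient([], np.array([0.3, 0.4])) == 0.0)

    def test_single_hill_center_value(self):
        h = Hill(time=0.0, center=(1.0, 2.0), sigma=(0.1, 0.1), height=2.5)
        assert bias_value([h], [1.0, 2.0]) == pytest.approx(2.5)

    def test_matches_brute_force_sum(self, rng):
        hills = random_hills(rng, 50)
        for _ in range(10):
            s = rng.normal(size=2)
            expected = sum(
                h.height * np.exp(-sum((s[d] - h.center[d]) ** 2
                                       / (2 * h.sigma[d] ** 2)
                                       for d in range(2)))
                for h in hills)
            assert bias_value(hills, s) == pytest.approx(expected,
                                                         abs=1e-12)

    def test_gradient_matches_finite_difference(self, rng):
        hills = random_hills(rng, 20)
        s = rng.normal(size=2)
        g = bias_gradient(hills, s)
        h = 1e-6
        for d in range(2):
            sp, sm = s.copy(), s.copy()
            sp[d] += h
            sm[d] -= h
            num = (bias_value(hills, sp) - bias_value(hills, sm)) / (2 * h)
            assert g[d] == pytest.approx(num, abs=1e-6)

    def test_hill_validation(self):
        with pytest.raises(ValueError):
            Hill(time=0.0, center=(0.0,), sigma=(0.0,), height=1.0)
        with pytest.raises(ValueError):
            Hill(time=0.0, center=(0.0,), sigma=(0.1,), height=0.0)


class TestDeposit:
    params = MetadParams(w0=2.5, sigma=(0.1,), gamma=30.0, temperature=300.0)

    def test_first_hill_has_full_height(self):
        hills = []
        h = deposit(hills, [0.0], self.params)
        assert h.height == 2.5  # exactly W0 where no bias exists yet

    def test_height_decays_with_accumulated_bias(self):
        """At a point where V = kB DeltaT the next height is W0 / e."""
        kb_dT = KB * self.params.delta_T
        # stack identical hills at the origin until V is near kB*deltaT
        hills = [Hill(time=0.0, center=(0.0,), sigma=(0.1,), height=kb_dT)]
        h = deposit(hills, [0.0], self.params)
        assert h.height == pytest.approx(2.5 / np.e)

    def test_infinite_bias_factor_recovers_standard_metadynamics(self):
        params = MetadParams(w0=2.5, sigma=(0.1,), gamma=1e12,
                             temperature=300.0)
        hills = [Hill(time=0.0, center=(0.0,), sigma=(0.1,), height=2.5)]
        h = deposit(hills, [0.0], params)
        assert h.height == pytest.approx(2.5, rel=1e-9)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            MetadParams(gamma=1.0)


class TestFESFromHills:
    params = MetadParams(w0=2.5, sigma=(0.1,), gamma=30.0, temperature=300.0)
    edges = [np.linspace(-1.0, 1.0, 41)]

    def test_empty_hills_flat_zero(self):
        fes = fes_from_hills([], self.edges, self.params)
        assert np.all(fes.values == 0.0)

    def test_single_hill_scaled_inverted_gaussian(self):
        """Min-normalized: 0 at the hill center, (gamma/(gamma-1)) W in the
        far field."""
        h = Hill(time=0.0, center=(0.0,), sigma=(0.05,), height=2.0)
        edges = [np.arange(-1.025, 1.03, 0.05)]  # a cell centered at 0
        fes = fes_from_hills([h], edges, self.params)
        x = fes.centers()[0]
        center_idx = np.argmin(np.abs(x))
        assert abs(x[center_idx]) < 1e-12
        assert fes.values[center_idx] == pytest.approx(0.0, abs=1e-9)
        assert fes.values[0] == pytest.approx(30.0 / 29.0 * 2.0, abs=1e-6)

    def test_trailing_average_weights(self):
        """Averaging the running estimate over all depositions of two
        identical stacked hills gives 1.5x one hill's bias (mean of V
        after the first and after the second)."""
        h = Hill(time=0.0, center=(0.0,), sigma=(0.05,), height=2.0)
        h2 = Hill(time=1.0, center=(0.0,), sigma=(0.05,), height=2.0)
        edges = [np.arange(-1.025, 1.03, 0.05)]
        plain = fes_from_hills([h, h2], edges, self.params)
        avg = fes_from_hills([h, h2], edges, self.params,
                             average_fraction=1.0)
        # far-field (V=0) minus center depth: plain 2W, averaged 1.5W
        fac = 30.0 / 29.0
        assert plain.values[0] == pytest.approx(fac * 4.0, abs=1e-6)
        assert avg.values[0] == pytest.approx(fac * 3.0, abs=1e-6)

    def test_min_is_exactly_zero(self, rng):
        fes = fes_from_hills(random_hills(rng, 10, d=1), self.edges,
                             self.params)
        assert fes.values.min() == 0.0


class TestUnits:
    def test_kj_to_kcal(self):
        fes = FESGrid(edges=[np.array([0.0, 1.0])],
                      values=np.array([KJ_PER_KCAL]))
        out = convert_units(fes, "kcal/mol")
        assert out.values[0] == pytest.approx(1.0)
        assert out.units == "kcal/mol"

    def test_zero_is_zero(self):
        fes = FESGrid(edges=[np.array([0.0, 1.0])], values=np.array([0.0]))
        assert convert_units(fes, "kcal/mol").values[0] == 0.0

    def test_round_trip_identity(self, rng):
        fes = FESGrid(edges=[np.linspace(0, 1, 11)],
                      values=rng.uniform(0, 20, 10))
        back = convert_units(convert_units(fes, "kcal/mol"), "kJ/mol")
        assert np.allclose(back.values, fes.values, atol=1e-12)

    def test_unknown_unit_rejected(self):
        fes = FESGrid(edges=[np.array([0.0, 1.0])], values=np.array([0.0]))
        with pytest.raises(ValueError):
            convert_units(fes, "eV")


class TestRunWTMetad:
    def _system(self):
        return ParticleSystem(DoubleWell1D(h=5.0, a=0.05, c=0.0),
                              mass=10.0, dt=0.002, friction=10.0)

    def test_zero_height_matches_unbiased_run(self):
        from pnadyn.dynamics import simulate

        system = self._system()
        params = MetadParams(w0=0.0, sigma=(0.01,), gamma=30.0,
                             temperature=300.0)
        traj_b, hills, _ = run_wtmetad(system, [CoordinateCV(0, 0, "x")],
                                       params, steps=2000, seed=3)
        traj_u = simulate(system, steps=2000, temperature=300.0, seed=3,
                          stride=10)
        assert len(hills) == 0
        assert np.array_equal(traj_b.frames[-1].coordinates,
                              traj_u.frames[-1].coordinates)

    def test_bias_drives_barrier_crossings(self):
        """With hills the particle visits both wells; without bias at the
        same length it stays trapped (documented seed)."""
        system = ParticleSystem(DoubleWell1D(h=12.0, a=0.05, c=0.0),
                                mass=10.0, dt=0.002, friction=10.0)
        params = MetadParams(w0=2.5, sigma=(0.01,), stride_ps=0.2,
                             gamma=30.0, temperature=120.0)
        traj_b, hills, recs = run_wtmetad(system,
                                          [CoordinateCV(0, 0, "x")],
                                          params, steps=30000, seed=11)
        x_b = np.array([r.values["x"] for r in recs])
        from pnadyn.dynamics import simulate

        traj_u = simulate(system, steps=30000, temperature=120.0, seed=11,
                          stride=10)
        x_u = traj_u.coordinates()[:, 0, 0]
        assert x_b.max() > 0.02 and x_b.min() < -0.02  # both wells
        assert x_u.max() < 0.0  # trapped in the starting (left) well

    def test_heights_never_exceed_w0_and_shrink_at_revisits(self):
        system = self._system()
        params = MetadParams(w0=2.5, sigma=(0.01,), stride_ps=0.1,
                             gamma=30.0, temperature=300.0)
        _, hills, _ = run_wtmetad(system, [CoordinateCV(0, 0, "x")],
                                  params, steps=20000, seed=5)
        heights = np.array([h.height for h in hills])
        assert heights[0] == 2.5
        assert np.all(heights > 0)
        assert np.all(heights <= 2.5 + 1e-12)
        # at any fixed probe point the implied height is non-increasing
        kb_dT = KB * params.delta_T
        for probe in (-0.05, 0.0, 0.05):
            implied = []
            for k in range(len(hills)):
                v = bias_value(hills[:k], [probe])
                implied.append(2.5 * np.exp(-v / kb_dT))
            assert np.all(np.diff(implied) <= 1e-12)


class TestReweighting:
    def test_zero_bias_gives_uniform_weights(self):
        params = MetadParams(w0=0.0, sigma=(0.1,), gamma=30.0,
                             temperature=300.0)
        times = np.arange(10.0)
        w = reweight_weights(times, np.zeros(10), [],
                             [np.linspace(-1, 1, 11)], params)
        assert np.allclose(w, 0.1)

    def test_zero_bias_reweighted_fes_equals_plain_histogram(self, rng):
        params = MetadParams(w0=0.0, sigma=(0.1,), gamma=30.0,
                             temperature=300.0)
        kT = params.kT
        samples = rng.normal(0.0, 0.3, size=1000)
        edges = [np.linspace(-1, 1, 21)]
        fes = reweight(np.arange(1000.0), np.zeros(1000), [], edges,
                       params, samples, edges)
        hist, _ = np.histogram(samples, bins=edges[0])
        with np.errstate(divide="ignore"):
            expected = -kT * np.log(hist)
        expected -= expected[np.isfinite(expected)].min()
        finite = np.isfinite(expected)
        assert np.allclose(fes.values[finite], expected[finite], atol=1e-9)

    def test_degenerate_weights_warn(self):
        params = MetadParams(w0=2.5, sigma=(0.1,), gamma=30.0,
                             temperature=300.0)
        hills = [Hill(time=0.0, center=(0.0,), sigma=(0.1,), height=2.5)]
        # one frame dominates by an enormous logged bias
        bias = np.array([0.0] * 99 + [400.0])
        with pytest.warns(UserWarning, match="effective sample"):
            reweight(np.arange(100.0), bias, hills,
                     [np.linspace(-1, 1, 11)], params,
                     np.zeros(100), [np.linspace(-1, 1, 11)])


class TestFESGrid:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            FESGrid(edges=[np.linspace(0, 1, 11)], values=np.zeros(11))

    def test_normalized_requires_finite(self):
        grid = FESGrid(edges=[np.array([0.0, 1.0, 2.0])],
                       values=np.array([np.inf, np.inf]))
        with pytest.raises(ValueError):
            grid.normalized()
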
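import numpy as np
import pytest
from scipy.integrate import quad

from enspec import (
    BootstrapSpec,
    EnergyGrid,
    PhysicalConstants,
    TransitionSample,
    auto_delta,
    band_spectrum_discrete,
    full_spectrum_with_ci,
    gaussian_lineshape,
    read_spectrum_csv,
    write_spectrum_csv,
)
from enspec.discrete_nea import weighted_quantile
from enspec.errors import ConfigError, ValidationError


def _sample(state, delta_E, f):
    delta_E = np.asarray(delta_E, dtype=float)
    return TransitionSample(
        state=state,
        geom_ids=np.arange(len(delta_E)),
        delta_E=delta_E,
        f=np.asarray(f, dtype=float),
    )


class TestLineshape:
    def test_peak_value(self):
        # delta = 2 -> unit-sd normal at its mode
        assert gaussian_lineshape(0.0, 2.0) == pytest.approx(
            1.0 / np.sqrt(2.0 * np.pi), rel=1e-12
        )

    def test_symmetry(self):
        x = np.linspace(0.01, 3.0, 40)
        np.testing.assert_allclose(
            gaussian_lineshape(x, 0.7), gaussian_lineshape(-x, 0.7)
        )

    @pytest.mark.parametrize("delta", [0.01, 0.3, 2.5])
    def test_normalization_quadrature(self, delta):
        val, _ = quad(gaussian_lineshape, -10 * delta, 10 * delta, args=(delta,))
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_fwhm_convention(self):
        # at half the full width, the fwhm-convention curve is at half maximum
        delta = 0.8
        peak = gaussian_lineshape(0.0, delta, convention="fwhm")
        half = gaussian_lineshape(delta / 2.0, delta, convention="fwhm")
        assert half == pytest.approx(peak / 2.0, rel=1e-12)

    def test_bad_delta(self):
        with pytest.raises(ValidationError):
            gaussian_lineshape(0.0, 0.0)


class TestEnergyGrid:
    def test_requires_increasing(self):
        with pytest.raises(ValidationError):
            EnergyGrid(np.array([1.0, 1.0, 2.0]))

    def test_requires_positive(self):
        with pytest.raises(ValidationError):
            EnergyGrid(np.array([-1.0, 1.0]))

    def test_default_span(self):
        s = _sample(1, [4.0, 5.0], [0.1, 0.1])
        grid = EnergyGrid.default_for([s], max_delta=0.1, n=501)
        assert len(grid) == 501
        assert grid.energies[0] == pytest.approx(4.0 - 0.3)
        assert grid.energies[-1] == pytest.approx(5.0 + 0.3)


class TestBandSpectrumDiscrete:
    def test_all_dark_warns_and_zeroes(self):
        s = _sample(1, [4.0], [0.0])
        grid = EnergyGrid.linear(3.0, 5.0, 101)
        with pytest.warns(UserWarning, match="zero"):
            spec = band_spectrum_discrete(s, 0.1, grid)
        assert np.all(spec.sigma == 0)

    def test_single_geometry_peak_closed_form(self):
        e0, f0, delta = 4.5, 0.2, 0.1
        s = _sample(1, [e0], [f0])
        grid = EnergyGrid(np.array([4.0, e0, 5.0]))
        spec = band_spectrum_discrete(s, delta, grid)
        # at E = dE0 the prefactor 1/E cancels the dE weight exactly
        assert spec.sigma[1] == pytest.approx(
            f0 * gaussian_lineshape(0.0, delta), rel=1e-12
        )

    def test_small_delta_area_conservation(self, rng):
        de = rng.normal(5.0, 0.2, 200)
        f = rng.uniform(0.05, 0.3, 200)
        s = _sample(1, de, f)
        delta = 0.01 * de.min()
        grid = EnergyGrid.linear(de.min() - 10 * delta, de.max() + 10 * delta, 8001)
        spec = band_spectrum_discrete(s, delta, grid)
        area = np.trapezoid(spec.sigma, grid.energies)
        assert area == pytest.approx(f.mean(), rel=1e-3)

    def test_homogeneous_in_f(self, rng):
        de = rng.normal(5.0, 0.2, 50)
        f = rng.uniform(0.05, 0.3, 50)
        grid = EnergyGrid.linear(4.0, 6.0, 301)
        base = band_spectrum_discrete(_sample(1, de, f), 0.1, grid)
        scaled = band_spectrum_discrete(_sample(1, de, 3.0 * f), 0.1, grid)
        np.testing.assert_allclose(scaled.sigma, 3.0 * base.sigma, rtol=1e-12)

    def test_empty_sample(self):
        s = _sample(1, [], [])
        with pytest.raises(ValidationError):
            band_spectrum_discrete(s, 0.1, EnergyGrid.linear(1, 2, 11))

    def test_chunking_consistent(self, rng):
        de = rng.normal(5.0, 0.2, 100)
        f = rng.uniform(0.05, 0.3, 100)
        grid = EnergyGrid.linear(4.0, 6.0, 101)
        a = band_spectrum_discrete(_sample(1, de, f), 0.1, grid, _chunk=7)
        b = band_spectrum_discrete(_sample(1, de, f), 0.1, grid, _chunk=10000)
        np.testing.assert_allclose(a.sigma, b.sigma, rtol=1e-12)


class TestWeightedQuantile:
    def test_equal_weights_median(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w = np.ones(5)
        assert weighted_quantile(x, w, 0.5) == pytest.approx(3.0)

    def test_duplication_invariant(self, rng):
        x = rng.normal(size=31)
        w = rng.uniform(0.1, 1.0, size=31)
        q = [0.25, 0.5, 0.75]
        a = weighted_quantile(x, w, q)
        b = weighted_quantile(np.tile(x, 2), np.tile(w / 2, 2), q)
        np.testing.assert_allclose(a, b, rtol=1e-13)

    def test_point_mass(self):
        x = np.array([1.0, 2.0])
        w = np.array([0.0, 1.0])
        assert weighted_quantile(x, w, 0.5) == pytest.approx(2.0)


class TestAutoDelta:
    def _sample(self, rng, n=200):
        de = rng.normal(5.0, 0.2, n)
        f = rng.uniform(0.05, 0.3, n)
        return _sample(1, de, f)

    def test_delta_is_twice_h(self, rng):
        bw = auto_delta(self._sample(rng))
        assert bw.delta == 2.0 * bw.h  # bit-exact

    def test_duplication_scaling_identity(self, rng):
        s = self._sample(rng)
        doubled = TransitionSample(
            state=1,
            geom_ids=np.tile(s.geom_ids, 2),
            delta_E=np.tile(s.delta_E, 2),
            f=np.tile(s.f, 2),
        )
        a, b = auto_delta(s), auto_delta(doubled)
        assert b.n_eff == pytest.approx(2.0 * a.n_eff, rel=1e-12)
        assert b.h / a.h == pytest.approx(2.0 ** (-0.2), rel=1e-12)

    def test_equal_weight_formula_oracle(self):
        # equal dE*f weights -> direct evaluation of the rule of thumb
        de = np.array([4.8, 4.9, 5.0, 5.1, 5.2, 5.3, 5.4, 5.5])
        f = 0.2 / de  # makes dE * f constant
        bw = auto_delta(_sample(1, de, f))
        n = len(de)
        sd = np.sqrt(np.mean((de - de.mean()) ** 2))
        # Hazen nodes (i - 0.5)/n over the sorted values
        nodes = (np.arange(1, n + 1) - 0.5) / n
        q1, q3 = np.interp([0.25, 0.75], nodes, np.sort(de))
        expected = 0.9 * min(sd, (q3 - q1) / 1.34) * n ** (-0.2)
        assert bw.h == pytest.approx(expected, rel=1e-12)
        assert bw.n_eff == pytest.approx(n, rel=1e-12)

    def test_too_few_points(self, rng):
        s = self._sample(rng, n=5)
        with pytest.raises(ValidationError, match=">= 8"):
            auto_delta(s)

    def test_all_zero_weights(self):
        s = _sample(1, np.linspace(4, 5, 10), np.zeros(10))
        with pytest.raises(ValidationError, match="vanish"):
            auto_delta(s)


class TestBootstrapCI:
    def test_config_validation(self):
        with pytest.raises(ConfigError):
            BootstrapSpec(B=0)
        with pytest.raises(ConfigError):
            BootstrapSpec(alpha=1.5)

    def test_identical_geometries_zero_width(self, toy_table):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "geom_id": [f"g{i}" for i in range(10)],
                "state": 1,
                "delta_E": 5.0,
                "f": 0.2,
            }
        )
        from enspec import EnsembleTable

        table = EnsembleTable(frame)
        grid = EnergyGrid.linear(4.0, 6.0, 201)
        full = full_spectrum_with_ci(
            table, {1: 0.1}, grid, BootstrapSpec(B=99, seed=0)
        )
        comp = full.components[0]
        np.testing.assert_allclose(comp.ci_low, comp.sigma, rtol=1e-12)
        np.testing.assert_allclose(comp.ci_high, comp.sigma, rtol=1e-12)

    def test_two_geometry_enumeration(self):
        # N_g = 2: the bootstrap support has 3 distinct resamples with
        # probabilities 1/4, 1/2, 1/4; the 2.5/97.5% quantiles must equal the
        # pointwise extremes of that enumerated support.
        import pandas as pd

        from enspec import EnsembleTable

        frame = pd.DataFrame(
            {
                "geom_id": ["a", "b"],
                "state": [1, 1],
                "delta_E": [4.8, 5.2],
                "f": [0.1, 0.3],
            }
        )
        table = EnsembleTable(frame)
        grid = EnergyGrid.linear(4.0, 6.0, 101)
        delta = 0.2
        full = full_spectrum_with_ci(
            table, {1: delta}, grid, BootstrapSpec(B=999, seed=3)
        )
        comp = full.components[0]

        s_a = band_spectrum_discrete(
            _sample(1, [4.8, 4.8], [0.1, 0.1]), delta, grid
        ).sigma
        s_b = band_spectrum_discrete(
            _sample(1, [5.2, 5.2], [0.3, 0.3]), delta, grid
        ).sigma
        s_ab = band_spectrum_discrete(
            _sample(1, [4.8, 5.2], [0.1, 0.3]), delta, grid
        ).sigma
        enumerated = np.stack([s_a, s_ab, s_b])
        np.testing.assert_allclose(comp.ci_low, enumerated.min(axis=0), rtol=1e-9)
        np.testing.assert_allclose(comp.ci_high, enumerated.max(axis=0), rtol=1e-9)

    def test_seed_reproducibility(self, demo_table):
        deltas = {int(s): 0.1 for s in demo_table.states}
        grid = EnergyGrid.linear(3.0, 8.0, 201)
        a = full_spectrum_with_ci(demo_table, deltas, grid, BootstrapSpec(B=49, seed=7))
        b = full_spectrum_with_ci(demo_table, deltas, grid, BootstrapSpec(B=49, seed=7))
        for ca, cb in zip(a.components, b.components):
            np.testing.assert_array_equal(ca.ci_low, cb.ci_low)
            np.testing.assert_array_equal(ca.ci_high, cb.ci_high)

    def test_total_is_sum_of_components(self, demo_table):
        deltas = {int(s): 0.1 for s in demo_table.states}
        grid = EnergyGrid.linear(3.0, 8.0, 201)
        full = full_spectrum_with_ci(demo_table, deltas, grid, None)
        np.testing.assert_allclose(
            full.total,
            np.sum([c.sigma for c in full.components], axis=0),
            rtol=1e-12,
        )

    def test_ci_modes(self, demo_table):
        deltas = {int(s): 0.1 for s in demo_table.states}
        grid = EnergyGrid.linear(3.0, 8.0, 101)
        boot = BootstrapSpec(B=49, seed=7)
        sb = full_spectrum_with_ci(demo_table, deltas, grid, boot,
                                   ci_mode="sum_bounds")
        sr = full_spectrum_with_ci(demo_table, deltas, grid, boot,
                                   ci_mode="sum_replicas")
        # sum-of-bounds is always at least as wide as quantiles of sums
        assert np.all(sb.ci_low <= sr.ci_low + 1e-12)
        assert np.all(sb.ci_high >= sr.ci_high - 1e-12)
        assert np.all(sb.ci_low <= sb.ci_high)
        with pytest.raises(ConfigError):
            full_spectrum_with_ci(demo_table, deltas, grid, boot, ci_mode="bogus")


class TestSpectrumCSV:
    def test_round_trip(self, demo_table, tmp_path):
        deltas = {int(s): 0.1 for s in demo_table.states}
        grid = EnergyGrid.linear(3.0, 8.0, 101)
        full = full_spectrum_with_ci(
            demo_table, deltas, grid, BootstrapSpec(B=19, seed=0)
        )
        path = tmp_path / "spec.csv"
        write_spectrum_csv(full, path, header_lines=["seed=0"])
        back = read_spectrum_csv(path)
        np.testing.assert_allclose(back.total, full.total, rtol=1e-12)
        assert len(back.components) == len(full.components)
        np.testing.assert_allclose(
            back.components[1].ci_high, full.components[1].ci_high, rtol=1e-12
        )
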
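"""Posterior summaries versus brute-force recomputation on small fixtures."""

import numpy as np
import pytest
from scipy.special import expit

from faultmem.geometry import BoundaryType
from faultmem.lattice import TorusLattice
from faultmem.summaries import (boundary_mask, critical_trial_aggregate,
                                critical_trial_difference,
                                critical_trial_summary, difference_map, hdci,
                                marginal_sensitivity, mean_surface)


def brute_hdci(samples, mass):
    x = np.sort(samples)
    m = int(np.ceil(mass * len(x)))
    best = None
    for i in range(len(x) - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + m - 1])
    return best[1], best[2]


class TestHdci:
    def test_constant_samples(self):
        lo, hi = hdci(np.full(30, 4.2))
        assert (lo, hi) == (4.2, 4.2)

    def test_1_to_100(self):
        # narrowest 95-value window has width 94; ties -> lowest lower bound
        lo, hi = hdci(np.arange(1.0, 101.0), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    @pytest.mark.parametrize("mass", [0.5, 0.8, 0.95])
    def test_matches_exhaustive_window_search(self, mass):
        rng = np.random.default_rng(0)
        for dist in (rng.standard_normal(200),
                     rng.exponential(size=200),
                     rng.beta(2, 8, size=200)):
            assert hdci(dist, mass) == pytest.approx(brute_hdci(dist, mass))

    def test_normal_quantiles_large_sample(self):
        draws = np.random.default_rng(1).standard_normal(100_000)
        lo, hi = hdci(draws, 0.95)
        assert lo == pytest.approx(-1.960, abs=0.05)
        assert hi == pytest.approx(1.960, abs=0.05)

    def test_skewed_interval_beats_equal_tailed(self):
        draws = np.random.default_rng(2).exponential(size=50_000)
        lo, hi = hdci(draws, 0.95)
        eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < eq_hi - eq_lo
        assert lo == pytest.approx(0.0, abs=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hdci([])
        with pytest.raises(ValueError):
            hdci(np.arange(5))
        with pytest.raises(ValueError):
            hdci(np.arange(30), mass=1.0)


@pytest.fixture
def lattice():
    return TorusLattice(8)  # 45-degree grid


@pytest.fixture
def theta_fixture(lattice):
    """Random theta draws, shape (60, 8, 8)."""
    rng = np.random.default_rng(3)
    return expit(rng.standard_normal((60, lattice.L, lattice.L)))


class TestMeanSurface:
    def test_constant_draws(self, lattice):
        phi0 = 1.3
        draws = np.full((30, 8, 8), expit(phi0))
        surf = mean_surface(draws, mass=None)
        assert np.allclose(surf.mean, expit(phi0))

    def test_symmetric_logits_average_to_half(self):
        a = 2.7
        draws = expit(np.array([np.full((4, 4), a), np.full((4, 4), -a)] * 15))
        surf = mean_surface(draws, mass=None)
        assert np.allclose(surf.mean, 0.5)

    def test_matches_brute_force(self, theta_fixture):
        surf = mean_surface(theta_fixture, mass=0.9)
        assert np.allclose(surf.mean, theta_fixture.mean(axis=0))
        lo, hi = hdci(theta_fixture[:, 2, 5], 0.9)
        assert surf.lower[2, 5] == lo and surf.upper[2, 5] == hi
        assert (surf.lower <= surf.mean).all() and (surf.mean <= surf.upper).all()

    def test_chain_axis_flattened(self, theta_fixture):
        stacked = theta_fixture.reshape(3, 20, 8, 8)
        assert np.allclose(mean_surface(stacked, mass=None).mean,
                           mean_surface(theta_fixture, mass=None).mean)


class TestDifferenceMap:
    def test_self_difference_is_zero(self, theta_fixture):
        surf = difference_map(theta_fixture, theta_fixture)
        assert np.allclose(surf.mean, 0.0)
        assert np.allclose(surf.lower, 0.0) and np.allclose(surf.upper, 0.0)

    def test_constant_surfaces(self):
        a = np.full((40, 4, 4), 0.7)
        b = np.full((40, 4, 4), 0.2)
        surf = difference_map(a, b)
        assert np.allclose(surf.mean, 0.5)

    def test_matches_brute_force_pairing(self, theta_fixture):
        rng = np.random.default_rng(4)
        other = expit(rng.standard_normal((60, 8, 8)))
        surf = difference_map(theta_fixture, other)
        assert np.allclose(surf.mean, (theta_fixture - other).mean(axis=0))

    def test_mismatched_lattices_rejected(self, theta_fixture):
        with pytest.raises(ValueError):
            difference_map(theta_fixture, np.full((60, 4, 4), 0.5))


class TestCriticalTrials:
    def test_constant_surface(self, lattice):
        draws = np.full((40, 8, 8), 0.3)
        ct = critical_trial_summary(draws, lattice, BoundaryType.LEFT_RIGHT)
        assert ct.mean == pytest.approx(0.3)
        assert (ct.hdci_lower, ct.hdci_upper) == pytest.approx((0.3, 0.3))

    def test_crossing_set_isolated(self, lattice):
        mask = boundary_mask(lattice, BoundaryType.NORMAL_REVERSE)
        surface = np.where(mask, 0.9, 0.1)
        draws = np.broadcast_to(surface, (40, 8, 8))
        ct = critical_trial_summary(draws, lattice,
                                    BoundaryType.NORMAL_REVERSE)
        assert ct.mean == pytest.approx(0.9)

    def test_mask_excludes_diagonal_and_uses_geometry(self, lattice):
        mask = boundary_mask(lattice, BoundaryType.LEFT_RIGHT)
        assert not mask.diagonal().any()
        # 45 deg (left) vs 135 deg (right) crosses; 45 vs 90 does not (90 is
        # a pure reverse prototype with no lateral label)
        assert mask[1, 3]
        assert not mask[1, 2]

    def test_uniform_equals_trial_weighting_for_constant_counts(
            self, lattice, theta_fixture):
        w = np.full((8, 8), 7.0)
        a = critical_trial_aggregate(theta_fixture, lattice,
                                     BoundaryType.LEFT_RIGHT)
        b = critical_trial_aggregate(theta_fixture, lattice,
                                     BoundaryType.LEFT_RIGHT, weights=w)
        assert np.allclose(a, b)

    def test_difference_uses_paired_draws(self, lattice, theta_fixture):
        rng = np.random.default_rng(5)
        other = expit(rng.standard_normal((60, 8, 8)))
        mean, lo, hi = critical_trial_difference(
            theta_fixture, other, lattice, BoundaryType.LEFT_RIGHT)
        a = critical_trial_aggregate(theta_fixture, lattice,
                                     BoundaryType.LEFT_RIGHT)
        b = critical_trial_aggregate(other, lattice, BoundaryType.LEFT_RIGHT)
        assert mean == pytest.approx((a - b).mean())
        assert lo <= mean <= hi


class TestMarginalSensitivity:
    def test_flat_surface_gives_flat_curve(self, lattice):
        draws = np.full((40, 8, 8), 0.42)
        curve = marginal_sensitivity(draws, lattice, axis="memory")
        assert np.allclose(curve["mean"], 0.42)

    def test_cardinal_rows_peak(self, lattice):
        # elevate memory angles at the four cardinals -> memory curve peaks
        # exactly there (the oblique-effect signature)
        cardinal_rows = np.isin(lattice.angles, [0, 90, 180, 270])
        surface = np.where(cardinal_rows[:, None], 0.8, 0.2)
        draws = np.broadcast_to(surface, (40, 8, 8))
        curve = marginal_sensitivity(draws, lattice, axis="memory")
        peaks = set(curve.loc[curve["mean"] > 0.5, "angle"])
        assert peaks == {0.0, 90.0, 180.0, 270.0}
        probe_curve = marginal_sensitivity(draws, lattice, axis="probe")
        assert np.allclose(probe_curve["mean"], surface.mean(axis=0).mean())

    def test_symmetric_surface_same_curves(self, lattice, theta_fixture):
        sym = 0.5 * (theta_fixture + np.swapaxes(theta_fixture, 1, 2))
        mem = marginal_sensitivity(sym, lattice, axis="memory")
        prb = marginal_sensitivity(sym, lattice, axis="probe")
        assert np.allclose(mem["mean"], prb["mean"])

    def test_diagonal_exclusion(self, lattice):
        surface = np.full((8, 8), 0.5)
        np.fill_diagonal(surface, 0.1)
        draws = np.broadcast_to(surface, (40, 8, 8))
        with_d = marginal_sensitivity(draws, lattice, include_diagonal=True)
        without = marginal_sensitivity(draws, lattice, include_diagonal=False)
        assert np.allclose(without["mean"], 0.5)
        assert (with_d["mean"] < 0.5).all()
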
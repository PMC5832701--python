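"""Thresholding, range centres, shift vectors and the comparative statistics."""

import numpy as np
import pytest

from migrasim import (circular_anova, paired_t, range_centre, shift_vector,
                      slope_vs_unity, threshold_grid)
from migrasim.errors import InvalidInputError
from migrasim.grids import BinaryRange, SuitabilityGrid

from test_journeys import toy_grid


class TestThresholdGrid:
    def test_separable_reference_perfectly_classified(self):
        grid = toy_grid([[0.9, 0.8, 0.1, 0.2]])
        ref = np.array([[True, True, False, False]])
        rng_ = threshold_grid(grid, reference_presence=ref)
        np.testing.assert_array_equal(rng_.presence, ref)

    def test_maxsss_matches_exhaustive_scan(self):
        suit = [[0.05, 0.15, 0.35, 0.42, 0.55, 0.61, 0.70, 0.82, 0.90, 0.97]]
        ref = np.array([[False, False, False, True, False, True, True, True,
                         True, True]])
        grid = toy_grid(suit)
        rng_ = threshold_grid(grid, reference_presence=ref)
        # independent exhaustive scan over every candidate threshold
        s = np.asarray(suit)[0]
        r = ref[0]
        best_score, best_thr = -np.inf, None
        for thr in sorted(set(s)):
            sens = np.mean(s[r] >= thr)
            spec = np.mean(s[~r] < thr)
            if sens + spec > best_score:
                best_score, best_thr = sens + spec, thr
        assert rng_.threshold_used == pytest.approx(best_thr)
        np.testing.assert_array_equal(rng_.presence, s[None, :] >= best_thr)

    def test_presence_implies_above_threshold(self):
        grid = toy_grid([[0.3, 0.6, 0.9]])
        rng_ = threshold_grid(grid, threshold=0.5)
        assert np.all(grid.suitability[rng_.presence] >= rng_.threshold_used)

    def test_all_zero_suitability_warns_empty(self):
        grid = toy_grid([[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="empty range"):
            rng_ = threshold_grid(grid, threshold=0.5)
        assert rng_.is_empty

    def test_reference_without_positives_rejected(self):
        grid = toy_grid([[0.3, 0.6]])
        with pytest.raises(InvalidInputError):
            threshold_grid(grid, reference_presence=np.zeros((1, 2), bool))


class TestRangeCentre:
    def test_single_cell_exact(self):
        grid = toy_grid([[0.7]])
        rng_ = BinaryRange(grid.lon, grid.lat, np.ones((1, 1), bool), 0.5)
        assert range_centre(grid, rng_, seed=0) == (0.25, 40.25)

    def test_symmetric_pair_centred(self):
        # equal-weight cells at lon -0.75 and +0.75 on one parallel
        grid = SuitabilityGrid(lon=np.array([-0.75, -0.25, 0.25, 0.75]),
                               lat=np.array([0.25]),
                               suitability=np.array([[0.8, 0.0, 0.0, 0.8]]))
        rng_ = BinaryRange(grid.lon, grid.lat,
                           grid.suitability > 0.5, 0.5)
        lon_c, lat_c = range_centre(grid, rng_, n_samples=20_000, seed=1)
        assert lon_c == pytest.approx(0.0, abs=0.05)
        assert lat_c == pytest.approx(0.25, abs=0.05)

    def test_three_cell_weighted_vector_mean(self):
        """Monte Carlo centre converges to the closed-form weighted mean
        of the three cells' unit vectors."""
        lon = np.array([10.25, 10.75, 11.25])
        lat = np.array([45.25])
        w = np.array([0.9, 0.3, 0.6])
        grid = SuitabilityGrid(lon=lon, lat=lat, suitability=w[None, :])
        rng_ = BinaryRange(lon, lat, np.ones((1, 3), bool), 0.0)

        p = w / w.sum()
        lam, phi = np.radians(lon), np.radians(45.25)
        v = np.array([np.cos(phi) * np.cos(lam),
                      np.cos(phi) * np.sin(lam),
                      np.sin(phi) * np.ones_like(lam)]) @ p
        exp_lon = np.degrees(np.arctan2(v[1], v[0]))
        exp_lat = np.degrees(np.arcsin(v[2] / np.linalg.norm(v)))

        lon_c, lat_c = range_centre(grid, rng_, n_samples=50_000, seed=2)
        assert lon_c == pytest.approx(exp_lon, abs=0.02)
        assert lat_c == pytest.approx(exp_lat, abs=0.02)

    def test_longitude_rotation_equivariance(self):
        base = toy_grid([[0.9, 0.4, 0.7], [0.2, 0.8, 0.5]], lon0=10.25)
        rng_b = BinaryRange(base.lon, base.lat, np.ones((2, 3), bool), 0.0)
        lon_c, lat_c = range_centre(base, rng_b, n_samples=30_000, seed=3)
        delta = 25.0
        rot = SuitabilityGrid(lon=base.lon + delta, lat=base.lat,
                              suitability=base.suitability.copy())
        rng_r = BinaryRange(rot.lon, rot.lat, np.ones((2, 3), bool), 0.0)
        lon_r, lat_r = range_centre(rot, rng_r, n_samples=30_000, seed=3)
        assert lon_r - lon_c == pytest.approx(delta, abs=1e-9)
        assert lat_r == pytest.approx(lat_c, abs=1e-9)


class TestShiftVector:
    def test_identical_centres(self):
        sv = shift_vector((10.0, 50.0), (10.0, 50.0))
        assert sv.shift_km == 0.0

    def test_due_north(self):
        sv = shift_vector((10.0, 40.0), (10.0, 45.0))
        assert sv.bearing == pytest.approx(0.0, abs=1e-9)

    def test_equatorial_degree(self):
        sv = shift_vector((0.0, 0.0), (1.0, 0.0))
        assert sv.bearing == pytest.approx(90.0, abs=1e-9)
        assert sv.shift_km == pytest.approx(111.195, abs=0.001)


class TestShiftRecoveryPipeline:
    def test_group_mean_shift_recovery(self):
        """Imposed breeding (10 deg/400 km) and non-breeding (70 deg/300 km)
        shifts are recovered from the thresholded grids via range centres:
        group means within 5 degrees and 10%."""
        from migrasim.flight import FlightParams
        from migrasim.pipeline import run_species, traits_from_row
        from migrasim.synthetic import (ShiftSpec, SyntheticScenario,
                                        make_species)
        sc = SyntheticScenario(
            seed=21, n_species=6, prop_short=0.0,
            shifts_long={"breeding": ShiftSpec(10.0, 400.0),
                         "non_breeding": ShiftSpec(70.0, 300.0)})
        traits_df = make_species(6, seed=21, prop_short=0.0)
        params = FlightParams()
        bearings = {"breeding": [], "non_breeding": []}
        dists = {"breeding": [], "non_breeding": []}
        for _, row in traits_df.iterrows():
            run = run_species(sc, traits_from_row(row), params, n_reps=10)
            for season, sv in run.shift_vectors.items():
                bearings[season].append(sv.bearing)
                dists[season].append(sv.shift_km)
        for season, b_true, d_true in (("breeding", 10.0, 400.0),
                                       ("non_breeding", 70.0, 300.0)):
            mean_b = np.degrees(np.angle(np.mean(
                np.exp(1j * np.radians(bearings[season]))))) % 360
            assert abs((mean_b - b_true + 180) % 360 - 180) <= 5.0
            assert np.mean(dists[season]) == pytest.approx(d_true, rel=0.10)


def von_mises_deg(rng, mu_deg, kappa, n):
    return np.degrees(rng.vonmises(np.radians(mu_deg), kappa, n)) % 360.0


class TestCircularAnova:
    def test_identical_tight_groups_null(self):
        rng = np.random.default_rng(0)
        g = von_mises_deg(rng, 40.0, 50.0, 60)
        res = circular_anova([g, g.copy()])
        assert res.F_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99
        assert res.df_within == 120 - 2

    def test_separated_groups_rejected_and_agree_with_permutation(self):
        """Mean directions 12 vs 70 degrees (kappa=5, n=40): the F test
        rejects, and its decision matches a permutation test on the
        between-group resultant statistic."""
        rng = np.random.default_rng(1)
        g1 = von_mises_deg(rng, 12.0, 5.0, 40)
        g2 = von_mises_deg(rng, 70.0, 5.0, 40)
        res = circular_anova([g1, g2])
        assert res.p_value < 0.01

        angles = np.radians(np.concatenate([g1, g2]))
        n1 = len(g1)

        def stat(a):
            r1 = np.abs(np.exp(1j * a[:n1]).sum())
            r2 = np.abs(np.exp(1j * a[n1:]).sum())
            return r1 + r2  # large when groups are internally coherent

        obs = stat(angles)
        perm = np.empty(2000)
        for i in range(2000):
            perm[i] = stat(rng.permutation(angles))
        p_perm = (1 + np.sum(perm >= obs)) / (1 + len(perm))
        assert (res.p_value < 0.05) == (p_perm < 0.05)

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(2)
        g1 = von_mises_deg(rng, 0.0, 0.5, 30)
        g2 = von_mises_deg(rng, 90.0, 0.5, 30)
        with pytest.warns(UserWarning, match="kappa"):
            res = circular_anova([g1, g2])
        assert res.low_concentration

    def test_type_one_error_calibrated(self):
        """Null p-values roughly uniform: rejection rate near alpha."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            g1 = von_mises_deg(rng, 33.0, 5.0, 40)
            g2 = von_mises_deg(rng, 33.0, 5.0, 40)
            if circular_anova([g1, g2]).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_requires_two_groups_of_two(self):
        with pytest.raises(InvalidInputError):
            circular_anova([np.array([1.0, 2.0])])
        with pytest.raises(InvalidInputError):
            circular_anova([np.array([1.0, 2.0]), np.array([3.0])])


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert not res.degenerate

    def test_constant_shift_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate

    def test_hand_computed_five_pairs(self):
        now = np.array([10.0, 12.0, 9.0, 15.0, 11.0])
        fut = np.array([12.0, 13.0, 9.5, 18.0, 10.0])
        d = fut - now
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t(now, fut)
        assert res.t_statistic == pytest.approx(t_hand)
        assert res.df == 4


class TestSlopeVsUnity:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = slope_vs_unity(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.t_statistic == 0.0

    def test_recovers_known_slope(self):
        """y = 1.06 x + noise: the estimate falls within 2 SE of the true
        slope in at least 90% of replicates."""
        rng = np.random.default_rng(4)
        n, true_slope = 37, 1.06
        hits = 0
        for _ in range(200):
            x = rng.uniform(1000, 8000, n)
            y = true_slope * x + rng.normal(0, 0.05 * x.mean(), n)
            res = slope_vs_unity(x, y)
            if abs(res.slope - true_slope) <= 2 * res.se:
                hits += 1
        assert hits >= 180

    def test_row_exchange_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 12)
        y = 1.3 * x + rng.normal(0, 1, 12)
        res1 = slope_vs_unity(x, y)
        x2, y2 = x.copy(), y.copy()
        x2[[2, 9]], y2[[2, 9]] = x2[[9, 2]], y2[[9, 2]]
        res2 = slope_vs_unity(x2, y2)
        assert res1.slope == pytest.approx(res2.slope, rel=1e-12)

    def test_degenerate_x(self):
        assert slope_vs_unity([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]).degenerate
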
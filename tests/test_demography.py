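import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popvuln.demography import (
    classify_life_stage,
    estimate_age,
    mean_plant_distance,
    occupancy_area,
    size_structure_density,
    skewness,
    summarize_censuses,
    summarize_population,
)


class TestLifeStage:
    @pytest.mark.parametrize(
        "length,stage", [(30.0, "young"), (30.1, "adult"), (0.5, "young"), (100, "adult")]
    )
    def test_threshold_boundary(self, length, stage):
        assert classify_life_stage(length) == stage

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            classify_life_stage(0.0)

    def test_partitions_every_census(self):
        rng = np.random.default_rng(0)
        lengths = rng.gamma(2, 25, 500) + 0.1
        stages = classify_life_stage(lengths)
        assert set(np.unique(stages)) <= {"young", "adult"}
        assert (stages == "young").sum() + (stages == "adult").sum() == 500


class TestAgeEstimate:
    def test_thirty_cm_is_six_years(self):
        # 30 cm x 0.6 leaves/cm / 3 leaves/yr
        assert estimate_age(30.0) == pytest.approx(6.0)

    def test_linearity_and_zero_limit(self):
        assert estimate_age(50.0) == pytest.approx(2 * estimate_age(25.0))
        assert estimate_age(1e-9) < 1e-9

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            estimate_age(-1.0)
        with pytest.raises(ValueError):
            estimate_age(10.0, leaves_per_year=0)


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_right_tail_is_positive(self):
        assert skewness([1, 1, 1, 10]) > 0

    def test_matches_direct_moment_formula_and_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 10.0, 20)
        m = x.mean()
        oracle = np.mean((x - m) ** 3) / np.mean((x - m) ** 2) ** 1.5
        assert skewness(x) == pytest.approx(oracle, abs=1e-12)
        assert skewness(x) == pytest.approx(stats.skew(x, bias=True), abs=1e-12)
        assert skewness(x, kind="b1") == pytest.approx(stats.skew(x, bias=False), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            skewness([1, 2])
        with pytest.raises(ValueError):
            skewness([3, 3, 3])


class TestOccupancyArea:
    def test_unit_square_in_hectares(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        out = occupancy_area(pts)
        assert out.area_ha == pytest.approx(0.01)
        assert not out.degenerate

    def test_collinear_points_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.warns(UserWarning, match="collinear"):
            out = occupancy_area(pts)
        assert out.area_ha == 0.0 and out.degenerate

    def test_two_points_degenerate(self):
        with pytest.warns(UserWarning):
            out = occupancy_area(np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert out.degenerate

    def test_alpha_infinite_equals_convex_hull(self):
        """With alpha = inf every Delaunay triangle is kept, so the
        alpha-shape area must equal the hull area found by brute force
        over all point subsets (shoelace on the best subset)."""
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (12, 2))

        def shoelace(poly):
            x, y = poly[:, 0], poly[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

        best = 0.0
        for k in range(3, 13):
            for sub in itertools.combinations(range(12), k):
                poly = pts[list(sub)]
                c = poly.mean(axis=0)
                ang = np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0])
                area = shoelace(poly[np.argsort(ang)])
                best = max(best, area)
        out = occupancy_area(pts, alpha=np.inf)
        assert out.area_ha * 10_000 == pytest.approx(best, rel=1e-9)

    def test_small_alpha_carves_concavities(self):
        # two distant clusters: a small alpha keeps only local triangles
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, (10, 2))
        b = rng.uniform(0, 10, (10, 2)) + [200, 0]
        pts = np.vstack([a, b])
        assert occupancy_area(pts, alpha=20.0).area_ha < occupancy_area(pts).area_ha

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, (15, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + [1000, -500]
        assert occupancy_area(moved).area_ha == pytest.approx(
            occupancy_area(pts).area_ha, rel=1e-9
        )


class TestPlantDistances:
    def test_two_points(self):
        mean, sd = mean_plant_distance(np.array([[0.0, 0.0], [7.0, 0.0]]))
        assert mean == pytest.approx(7.0)
        assert np.isnan(sd)

    def test_equilateral_triangle(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        mean, sd = mean_plant_distance(pts)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, (10, 2))
        d = [
            np.hypot(*(pts[i] - pts[j]))
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        mean, sd = mean_plant_distance(pts)
        assert mean == pytest.approx(np.mean(d), abs=1e-12)
        assert sd == pytest.approx(np.std(d, ddof=1), abs=1e-12)

    def test_nearest_neighbour_mode(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        mean, _ = mean_plant_distance(pts, mode="nn")
        assert mean == pytest.approx((1 + 1 + 9) / 3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mean_plant_distance(np.array([[0.0, 0.0]]))


def census_frame(lengths, pts, statuses=None, population="pop"):
    n = len(lengths)
    return pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(n)],
            "population": population,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "stem_length_cm": lengths,
            "status": statuses if statuses is not None else ["non_reproductive"] * n,
        }
    )


class TestSummarizePopulation:
    def test_counts_partition_and_fields_match_independent_recomputation(self):
        rng = np.random.default_rng(6)
        lengths = rng.gamma(2.0, 25.0, 60) + 0.5
        pts = rng.uniform(0, 80, (60, 2))
        statuses = np.where(
            (lengths > 30) & (rng.uniform(size=60) < 0.4), "fruiting", "non_reproductive"
        )
        s = summarize_population(census_frame(lengths, pts, list(statuses)))
        assert s.n_young + s.n_adult == s.n_plants == 60
        assert s.n_young == int((lengths <= 30).sum())
        assert s.mean_stem_cm == pytest.approx(lengths.mean())
        assert s.sd_stem_cm == pytest.approx(np.std(lengths, ddof=1))
        assert s.n_fruiting == int((statuses == "fruiting").sum())
        assert s.skewness == pytest.approx(stats.skew(lengths, bias=True))
        assert s.density_per_ha == pytest.approx(60 / s.area_ha)
        assert s.young_density_per_ha == pytest.approx(s.n_young / s.area_ha)

    def test_single_plant_census(self):
        with pytest.warns(UserWarning):
            s = summarize_population(
                census_frame(np.array([42.0]), np.array([[1.0, 2.0]]))
            )
        assert s.mean_stem_cm == 42.0
        assert np.isnan(s.sd_stem_cm)
        assert np.isnan(s.density_per_ha)  # degenerate area -> NaN, not inf

    def test_multi_population_table(self):
        rng = np.random.default_rng(7)
        frames = []
        for k, n in enumerate([11, 20, 35]):
            lengths = rng.gamma(2.0, 20.0, n) + 0.5
            pts = rng.uniform(0, 50, (n, 2)) + 200 * k
            f = census_frame(lengths, pts, population=f"pop{k}")
            f["plant_id"] = [f"{k}-{i}" for i in range(n)]
            frames.append(f)
        table = summarize_censuses(pd.concat(frames, ignore_index=True))
        assert len(table) == 3
        assert table["n_plants"].tolist() == [11, 20, 35]
        assert (table["n_young"] + table["n_adult"]).equals(table["n_plants"])


class TestSizeStructure:
    def test_density_peaks_at_repeated_value(self):
        grid, dens = size_structure_density([40.0, 40.0], bandwidth=5.0)
        assert grid[np.argmax(dens)] == pytest.approx(40.0, abs=grid[1] - grid[0])
        assert dens.max() == pytest.approx(1.0)

    def test_kde_normalization_before_scaling(self):
        rng = np.random.default_rng(8)
        x = rng.gamma(3.0, 15.0, 200)
        kde = stats.gaussian_kde(x)
        grid = np.linspace(0, x.max() * 1.1, 512)
        raw = kde(grid)
        assert np.trapezoid(raw, grid) == pytest.approx(1.0, abs=0.05)
        _, dens = size_structure_density(x, grid=grid)
        np.testing.assert_allclose(dens, raw / raw.max())

    def test_bimodal_mixture_resolved(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(20, 3, 300), rng.normal(80, 3, 300)])
        bw = 4.0
        grid, dens = size_structure_density(x, bandwidth=bw, n_grid=512)
        peaks = [
            g for i, g in enumerate(grid[1:-1], 1)
            if dens[i] > dens[i - 1] and dens[i] > dens[i + 1] and dens[i] > 0.3
        ]
        assert len(peaks) == 2
        assert abs(peaks[0] - 20) < bw and abs(peaks[1] - 80) < bw
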
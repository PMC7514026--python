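import numpy as np
import pytest

from poicrime.geodata_io import PointSet, StudyArea
from poicrime.density_estimation import KernelSpec
from poicrime.sparse_model import ModelFit
from poicrime.synthetic_city import (ClassSpec, SyntheticCitySpec,
                                     generate_poi_layout, sample_crimes)
from poicrime.evaluation import (CityBundle, CvConfig, alpha_sweep,
                                 count_selected_classes, cross_validate_city,
                                 displacement_summary, improvement_stats,
                                 leave_one_city_out, r2_density, split_points)
from poicrime.reference import LIVERPOOL, uk_city_cv_reference


class TestSplitPoints:
    def test_even_and_near_even_sizes(self):
        rng = np.random.default_rng(0)
        sets = [PointSet("a", rng.uniform(0, 1, (10, 2))),
                PointSet("b", rng.uniform(0, 1, (11, 2)))]
        parts = split_points(sets, K=2, seed=1)
        assert sorted(len(p) for p in parts[0]) == [5, 5]
        assert sorted(len(p) for p in parts[1]) == [5, 6]

    def test_union_restores_input_and_parts_disjoint(self):
        rng = np.random.default_rng(3)
        ps = PointSet("a", rng.uniform(0, 1, (23, 2)))
        parts = split_points([ps], K=3, seed=9)[0]
        merged = np.vstack([p.points for p in parts])
        assert merged.shape == ps.points.shape
        assert {tuple(r) for r in merged} == {tuple(r) for r in ps.points}

    def test_deterministic_per_seed(self):
        ps = PointSet("a", np.arange(40.0).reshape(20, 2))
        a = split_points([ps], 2, seed=5)[0]
        b = split_points([ps], 2, seed=5)[0]
        assert all(np.array_equal(x.points, y.points) for x, y in zip(a, b))


class TestR2Density:
    def test_perfect_prediction(self):
        assert r2_density([1, 2, 3], [1, 2, 3]) == 1.0

    def test_constant_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_density(np.full(4, obs.mean()), obs) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert r2_density([1, 2, 3, 5], [1, 2, 3, 4]) == pytest.approx(0.8)

    def test_zero_variance_observed_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r2_density([1, 2], [3, 3])


def small_bundle(seed=0, n_crimes=1500, weights=None):
    weights = weights or {"Pubs, Bars and Inns": 1.0, "Cafes": 0.5}
    cluster = dict(layout="clustered", n_clusters=3, cluster_sd=200.0)
    classes = tuple(ClassSpec(name, 40, **cluster) for name in weights)
    spec = SyntheticCitySpec(
        area=StudyArea(0.0, 0.0, 3000.0, n_cells_per_side=40),
        classes=classes, true_weights=weights,
        kernel=KernelSpec("exponential", 75.0), n_crimes=n_crimes, seed=seed)
    layout = generate_poi_layout(spec)
    crimes = sample_crimes(spec, layout)
    return CityBundle(f"synth{seed}", layout, crimes, spec.area), spec


class TestCrossValidateCity:
    def test_high_signal_city_scores_high(self):
        # dense, strongly clustered city with ample data: the fitted model
        # should explain most of the held-out density variance
        cluster = dict(layout="clustered", n_clusters=3, cluster_sd=150.0)
        names = ["Pubs, Bars and Inns", "Fast Food and Takeaway Outlets",
                 "Bus Stops"]
        weights = {names[0]: 1.0, names[1]: 0.6, names[2]: 0.5}
        spec = SyntheticCitySpec(
            area=StudyArea(0.0, 0.0, 3000.0, n_cells_per_side=60),
            classes=tuple(ClassSpec(n, 200, **cluster) for n in names),
            true_weights=weights, kernel=KernelSpec("exponential", 75.0),
            n_crimes=20000, seed=3)
        layout = generate_poi_layout(spec)
        bundle = CityBundle("dense", layout, sample_crimes(spec, layout),
                            spec.area)
        cfg = CvConfig(K=2, n_repeats=2, seed=3, k_select=3)
        prop, base = cross_validate_city(bundle, cfg, spec.kernel)
        assert prop.mean_r2 > 0.9
        assert prop.mean_r2 >= base.mean_r2
        assert len(prop.per_run_r2) == cfg.K * cfg.n_repeats

    def test_first_repeat_reproducible_across_longer_runs(self):
        bundle, spec = small_bundle()
        k = CvConfig(K=2, n_repeats=1, seed=4, k_select=2)
        k2 = CvConfig(K=2, n_repeats=2, seed=4, k_select=2)
        one, _ = cross_validate_city(bundle, k, spec.kernel)
        two, _ = cross_validate_city(bundle, k2, spec.kernel)
        assert one.per_run_r2 == two.per_run_r2[:2]

    def test_bit_identical_reruns(self):
        bundle, spec = small_bundle()
        cfg = CvConfig(K=2, n_repeats=1, seed=8, k_select=2)
        a, ab = cross_validate_city(bundle, cfg, spec.kernel)
        b, bb = cross_validate_city(bundle, cfg, spec.kernel)
        assert a.per_run_r2 == b.per_run_r2
        assert ab.per_run_r2 == bb.per_run_r2


class TestLeaveOneCityOut:
    def test_identical_cities_transfer_well(self):
        cfg = CvConfig(K=2, n_repeats=1, seed=0, k_select=2)
        kernel = KernelSpec("exponential", 75.0)
        b0, _ = small_bundle(seed=10)
        b1, _ = small_bundle(seed=11)
        table, fits = leave_one_city_out([b0, b1], cfg, kernel)
        assert set(table["city"]) == {"synth10", "synth11"}
        assert (table["r2"] > 0.5).all()
        assert len(fits) == 2

    def test_weight_shift_degrades_transfer(self):
        cfg = CvConfig(K=2, n_repeats=1, seed=0, k_select=2)
        kernel = KernelSpec("exponential", 75.0)
        b0, _ = small_bundle(seed=10)
        b1, _ = small_bundle(seed=11)
        odd, _ = small_bundle(seed=12, weights={"Pubs, Bars and Inns": 0.05,
                                                "Cafes": 1.0})
        same = leave_one_city_out([b0, b1], cfg, kernel)[0]
        mixed = leave_one_city_out([b0, odd], cfg, kernel)[0]
        r2_same = same.set_index("city").loc["synth11", "r2"]
        r2_odd = mixed.set_index("city").loc["synth12", "r2"]
        assert r2_odd < r2_same

    def test_single_city_rejected(self):
        with pytest.raises(ValueError, match="two cities"):
            leave_one_city_out([small_bundle()[0]], CvConfig(),
                               KernelSpec("exponential", 75.0))


class TestAlphaSweep:
    def test_support_monotone_and_limits(self):
        bundle, spec = small_bundle()
        am_guess = [0.0, 1e-3, 1e-1, 1e4]
        cfg = CvConfig(K=2, n_repeats=1, seed=2, k_select=2)
        tab = alpha_sweep(bundle, am_guess, cfg, spec.kernel)
        tab = tab.sort_values("alpha").reset_index(drop=True)
        supports = tab["mean_support"].tolist()
        assert supports[0] == len(bundle.class_sets)
        assert supports[-1] == 0.0
        assert all(a >= b for a, b in zip(supports, supports[1:]))
        assert tab["mean_r2"].iloc[-1] <= 0.0  # intercept-only prediction


class TestCountSelectedClasses:
    def make(self, names):
        return ModelFit(list(names), {n: 1.0 for n in names}, 0.0)

    def test_hand_tally_sorted_desc_ties_alphabetical(self):
        fits = [self.make(["Pubs", "Cafes"]), self.make(["Pubs", "Banks"]),
                self.make(["Pubs", "Banks"])]
        tab = count_selected_classes(fits)
        assert tab["class"].tolist() == ["Pubs", "Banks", "Cafes"]
        assert tab["count"].tolist() == [3, 2, 1]

    def test_empty_input(self):
        assert count_selected_classes([]).empty


class TestImprovementStats:
    def test_single_city_published_pair(self):
        stats = improvement_stats([0.2968], [0.6091], ["Bristol"])
        assert stats.per_city["Bristol"] == 105

    def test_no_improvement_is_zero(self):
        stats = improvement_stats([0.5], [0.5], ["X"])
        assert stats.per_city["X"] == 0 and stats.mean == 0.0

    def test_ten_city_reference_table(self):
        ref = uk_city_cv_reference()
        stats = improvement_stats(ref["baseline_r2_mean"], ref["model_r2_mean"],
                                  ref["city"], exclude=(LIVERPOOL,))
        assert stats.per_city == dict(zip(ref["city"],
                                          ref["published_improvement_pct"]))
        assert stats.mean == 43.5
        assert stats.mean_excluding == 48.2

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            improvement_stats([0.0], [0.5], ["X"])


class TestDisplacementSummary:
    def test_all_zero(self):
        s = displacement_summary(np.zeros(7))
        assert (s.mean, s.median, s.p90) == (0.0, 0.0, 0.0)

    def test_hand_computed_deciles(self):
        s = displacement_summary(np.arange(10, 101, 10))
        assert s.mean == 55.0
        assert s.median == 55.0  # mid-average convention
        assert s.p90 == 90.0     # nearest-rank

    def test_constant_thirty(self):
        s = displacement_summary(np.full(25, 30.0))
        assert (s.mean, s.median, s.p90) == (30.0, 30.0, 30.0)

    def test_histogram_covers_all_mass(self):
        d = np.array([1.0, 7.0, 12.0, 33.0])
        s = displacement_summary(d, bin_width=5.0)
        assert s.bin_counts.sum() == 4
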
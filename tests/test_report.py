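"""Summary statistics: layer shares, class stats, potency, LOESS, densities."""

import math

import numpy as np
import pytest

from clonetrack.assembly import Clone
from clonetrack.barcode import parse_code
from clonetrack.report import (LocalPolynomialRegression,
                               cells_clones_correlation, clone_class_stats,
                               layer_percentages_from_counts,
                               mean_size_from_totals, potency_stats,
                               potency_stats_from_counts,
                               rgc_containing_fraction, size_count_fit,
                               size_density_by_potency)


def _clone(sizes_types, embryo="E1", layer_class=None, potency=None):
    code = parse_code("N:100000/C:000000")
    c = Clone(embryo, code, [f"c{i}" for i in range(len(sizes_types))],
              member_types=list(sizes_types))
    c.layer_class = layer_class
    c.potency_class = potency
    return c


class TestLayerPercentages:
    def test_rounding_to_two_decimals(self):
        out = layer_percentages_from_counts({"INL": 2, "ONL": 1, "GCL": 0})
        assert out == {"ONL": 33.33, "INL": 66.67, "GCL": 0.0}

    def test_single_layer_is_hundred(self):
        out = layer_percentages_from_counts({"ONL": 7})
        assert out["ONL"] == 100.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="no labeled cells"):
            layer_percentages_from_counts({})


class TestCloneClassStats:
    def test_mean_and_sem_from_small_sample(self):
        clones = [
            _clone(["RGC"] * 2, layer_class="GCL_only"),
            _clone(["RGC"] * 3, layer_class="GCL_only"),
            _clone(["RGC"] * 3, layer_class="GCL_only"),
        ]
        stats = clone_class_stats(clones).set_index("layer_class")
        row = stats.loc["GCL_only"]
        assert row["mean_size"] == 2.7  # mean of {2,3,3}
        assert row["sem_size"] == 0.3   # sd 0.577 / sqrt(3)
        assert row["n_cells"] == 8

    def test_single_clone_sem_is_zero(self):
        stats = clone_class_stats(
            [_clone(["RGC"] * 4, layer_class="GCL_only")])
        assert stats.set_index("layer_class").loc["GCL_only", "sem_size"] == 0.0

    def test_empty_class_reported_absent(self):
        stats = clone_class_stats(
            [_clone(["RGC"], layer_class="GCL_only")]).set_index("layer_class")
        assert stats.loc["trilaminar", "n_clones"] == 0
        assert math.isnan(stats.loc["trilaminar", "mean_size"])

    def test_proportions_sum_to_hundred(self, zero_noise_cells):
        from clonetrack.assembly import assemble_clones
        from clonetrack.calling import call_table
        from clonetrack.pipeline import classify_cells, classify_clones
        labeled = classify_cells(call_table(zero_noise_cells).labeled)
        clones = classify_clones(assemble_clones(labeled), labeled)
        stats = clone_class_stats(clones)
        assert abs(stats["proportion_pct"].sum() - 100.0) < 0.05
        assert stats["n_cells"].sum() == len(labeled)

    def test_mean_size_from_totals(self):
        assert mean_size_from_totals(779, 31) == 25.1
        with pytest.raises(ValueError):
            mean_size_from_totals(10, 0)


class TestPotencyStats:
    def test_reported_shares_from_counts(self):
        out = potency_stats_from_counts(28, 24, 20, 131)
        assert out["undetermined_pct"] == 64.53
        assert out["bi_multipotent_of_determined_pct"] == 72.22
        assert out["committed_pct"] == 9.85

    def test_all_committed(self):
        out = potency_stats_from_counts(0, 0, 10, 0)
        assert out["undetermined_pct"] == 0.0
        assert out["determined_pct"] == 100.0

    def test_from_clones(self):
        clones = [_clone(["RGC"], potency="committed"),
                  _clone(["undefined"], potency="undetermined"),
                  _clone(["RGC", "cone_photoreceptor"], potency="bipotent"),
                  _clone(["undefined"], potency="undetermined")]
        out = potency_stats(clones)
        assert out["undetermined_pct"] == 50.0
        assert out["bi_multipotent_of_determined_pct"] == 50.0

    def test_zero_clones_rejected(self):
        with pytest.raises(ValueError):
            potency_stats([])


class TestRgcFraction:
    def test_half_of_clones_contain_rgc(self):
        clones = [_clone(["RGC"]), _clone(["RGC", "undefined"]),
                  _clone(["cone_photoreceptor"]), _clone(["undefined"])]
        out = rgc_containing_fraction(clones)
        assert out["with_rgc_pct"] == 50.0
        assert out["without_rgc_pct"] == 50.0

    def test_no_rgc_anywhere(self):
        out = rgc_containing_fraction([_clone(["cone_photoreceptor"])])
        assert out["with_rgc_pct"] == 0.0


class TestCorrelation:
    def test_exact_line_is_one(self):
        assert cells_clones_correlation(
            [(100, 10), (200, 20), (400, 40)]) == pytest.approx(1.0)

    def test_anti_ordered_line_is_minus_one(self):
        assert cells_clones_correlation(
            [(100, 40), (200, 30), (300, 20)]) == pytest.approx(-1.0)

    def test_needs_three_embryos(self):
        with pytest.raises(ValueError):
            cells_clones_correlation([(1, 1), (2, 2)])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cells_clones_correlation([(1, 5), (2, 5), (3, 5)])

    def test_sampling_depth_induces_positive_correlation(self):
        # cohorts whose embryos differ in targeted-progenitor counts show
        # cells ~ clones correlation in nearly all replicates
        from clonetrack.calling import call_table
        from clonetrack.assembly import assemble_clones
        from clonetrack.simulate import (IntensityNoise, SimConfig,
                                         cohort_frame, simulate_cohort)
        positive = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=100 + seed, n_embryos=4,
                n_targeted_progenitors_per_embryo=(6, 14, 24, 40),
                intensity_noise=IntensityNoise(background_sd=0.0,
                                               signal_sd=0.0))
            embryos, _ = simulate_cohort(cfg)
            labeled = call_table(cohort_frame(embryos)).labeled
            clones = assemble_clones(labeled)
            pairs = [
                (int((labeled["embryo_id"] == e.embryo_id).sum()),
                 sum(1 for c in clones if c.embryo_id == e.embryo_id))
                for e in embryos]
            if cells_clones_correlation(pairs) > 0:
                positive += 1
        assert positive >= 0.95 * n_rep


class TestLocalPolynomialRegression:
    def test_matches_brute_force_weighted_least_squares(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(1, 30, 25))
        y = 50 * np.exp(-x / 8) + rng.normal(0, 2, 25)
        fit = LocalPolynomialRegression(x, y, span=0.75, degree=2).fit()

        def oracle(x0):
            d = np.abs(x - x0)
            q = min(max(int(math.ceil(0.75 * len(x))), 4), len(x))
            h = np.sort(d)[q - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            mask = w > 0
            coef = np.polyfit(x[mask] - x0, y[mask], 2, w=np.sqrt(w[mask]))
            return coef[-1]

        for g, f in zip(fit.grid, fit.fitted):
            assert f == pytest.approx(oracle(g), rel=1e-8)

    def test_constant_data_reproduced_exactly(self):
        x = np.arange(1.0, 11.0)
        fit = LocalPolynomialRegression(x, np.full(10, 5.0), span=0.5,
                                        degree=2).fit()
        assert np.allclose(fit.fitted, 5.0, atol=1e-10)
        assert np.allclose(fit.se, 0.0, atol=1e-10)

    def test_linear_data_reproduced_exactly(self):
        x = np.arange(1.0, 11.0)
        fit = LocalPolynomialRegression(x, 2 * x + 1, span=1.0,
                                        degree=1).fit()
        assert np.allclose(fit.fitted, 2 * fit.grid + 1, atol=1e-10)
        assert np.allclose(fit.se, 0.0, atol=1e-10)

    def test_band_is_1p96_se(self):
        rng = np.random.default_rng(3)
        x = np.arange(1.0, 16.0)
        y = rng.normal(10, 2, 15)
        fit = LocalPolynomialRegression(x, y).fit()
        assert np.allclose(fit.band_high - fit.fitted, 1.96 * fit.se)

    def test_mean_se_profile_covers_observed_sizes(self):
        sizes = [1] * 30 + [2] * 20 + [3] * 10 + [5] * 5 + [8] * 3 + [12] * 2
        fit = size_count_fit(sizes)
        assert set(fit.mean_se_up_to) == {1, 2, 3, 5, 8, 12}
        # the profile is a running mean of non-negative SEs
        assert all(v >= 0 for v in fit.mean_se_up_to.values())

    def test_rejects_bad_span_and_degree(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            LocalPolynomialRegression(x, x, span=0.0)
        with pytest.raises(ValueError):
            LocalPolynomialRegression(x, x, degree=-1)

    def test_requires_enough_distinct_points(self):
        with pytest.raises(ValueError, match="distinct"):
            LocalPolynomialRegression(np.array([1.0, 2.0, 2.0]),
                                      np.array([1.0, 2.0, 2.0]), degree=2)


class TestSizeDensities:
    def _clones(self, sizes, potency):
        return [_clone(["undefined"] * s, potency=potency) for s in sizes]

    def test_densities_integrate_to_one(self):
        clones = (self._clones([2, 3, 4, 6, 9, 12], "undetermined")
                  + self._clones([1, 1, 2, 3], "committed"))
        for grid, dens in size_density_by_potency(clones).values():
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_size_ranges_order_the_modes(self):
        clones = (self._clones([1, 2, 2, 3], "committed")
                  + self._clones([20, 25, 30, 35], "multipotent"))
        out = size_density_by_potency(clones)
        mode = {k: g[np.argmax(d)] for k, (g, d) in out.items()}
        assert mode["committed"] < mode["bi_multipotent"]

    def test_small_class_omitted_with_warning(self):
        clones = (self._clones([5], "committed")
                  + self._clones([2, 3, 4, 5], "undetermined"))
        with pytest.warns(UserWarning, match="too few"):
            out = size_density_by_potency(clones)
        assert "committed" not in out

    def test_bipotent_and_multipotent_pool_by_default(self):
        clones = (self._clones([2, 4], "bipotent")
                  + self._clones([3, 6], "multipotent"))
        out = size_density_by_potency(clones)
        assert set(out) == {"bi_multipotent"}


class TestPlots:
    def test_figures_written_to_disk(self, tmp_path, zero_noise_cells):
        from clonetrack.assembly import assemble_clones
        from clonetrack.calling import call_table
        from clonetrack.pipeline import classify_cells, classify_clones
        from clonetrack.plotting import (plot_clone_class_pie,
                                         plot_size_count_fit,
                                         plot_size_densities)
        labeled = classify_cells(call_table(zero_noise_cells).labeled)
        clones = classify_clones(assemble_clones(labeled), labeled)
        sizes = [c.size for c in clones]
        fit = size_count_fit(sizes)
        for path in (
            plot_size_count_fit(fit, sizes, tmp_path / "fit.svg"),
            plot_clone_class_pie(clones, tmp_path / "pie.png"),
            plot_size_densities(clones, tmp_path / "dens.svg"),
        ):
            assert path.exists() and path.stat().st_size > 0
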
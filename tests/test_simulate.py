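"""Synthetic-cohort generator: uptake, composition, placement, determinism."""

import numpy as np
import pandas as pd
import pytest

from clonetrack.barcode import code_complexity, parse_code
from clonetrack.calling import call_table
from clonetrack.classify import TYPE_TO_LAYER
from clonetrack.simulate import (CloneArchetype, ConfigError, IntensityNoise,
                                 LAYER_DEPTH_BANDS, SimConfig, cohort_frame,
                                 default_archetypes, place_clone,
                                 render_intensities, simulate_clone,
                                 simulate_cohort, simulate_uptake)


class TestUptake:
    def test_certain_uptake_gives_full_codes(self, rng):
        codes = simulate_uptake(50, 1.0, rng)
        assert all(code_complexity(c) == 12 for c in codes)

    def test_zero_uptake_gives_empty_codes(self, rng):
        codes = simulate_uptake(50, 0.0, rng)
        assert all(c.is_empty for c in codes)

    def test_mean_complexity_matches_binomial(self, rng):
        n = 10_000
        codes = simulate_uptake(n, 0.5, rng)
        mean = np.mean([code_complexity(c) for c in codes])
        se = np.sqrt(12 * 0.5 * 0.5 / n)
        assert abs(mean - 6.0) < 3 * se

    def test_per_construct_frequency_recovers_p(self, rng):
        n, p = 4_000, 0.3
        codes = simulate_uptake(n, p, rng)
        bits = np.array([c.bits for c in codes])
        freq = bits.mean(axis=0)
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(freq - p) < 3 * se).all()


class TestCloneComposition:
    def test_committed_rgc_clone_is_all_rgc(self, rng):
        arch = next(a for a in default_archetypes()
                    if a.name == "gcl_committed")
        types = simulate_clone(arch, rng, size=3)
        assert types == ["RGC", "RGC", "RGC"]

    def test_minimal_photoreceptor_clone(self, rng):
        arch = next(a for a in default_archetypes()
                    if a.name == "onl_committed")
        assert simulate_clone(arch, rng, size=1) == ["cone_photoreceptor"]

    def test_multipotent_clones_always_have_three_differentiated_types(self, rng):
        diff = {"cone_photoreceptor", "horizontal", "amacrine", "RGC"}
        for _ in range(500):
            types = simulate_clone("multipotent", rng)
            assert len(set(types) & diff) >= 3

    def test_size_below_structural_minimum_rejected(self, rng):
        arch = next(a for a in default_archetypes()
                    if a.name == "tri_multipotent")
        with pytest.raises(ValueError, match="below minimum"):
            simulate_clone(arch, rng, size=2)

    def test_unknown_potency_class_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown potency"):
            simulate_clone("totipotent", rng)

    def test_mean_size_matches_archetype(self, rng):
        arch = next(a for a in default_archetypes()
                    if a.name == "inl_undetermined")
        sizes = [len(simulate_clone(arch, rng)) for _ in range(3000)]
        se = np.std(sizes, ddof=1) / np.sqrt(len(sizes))
        assert abs(np.mean(sizes) - arch.mean_size) < 3 * se


class TestPlacement:
    def _cells(self, n=8):
        return [{"layer": "INL", "soma_relative_depth": 0.5}] * n

    def test_zero_sigma_collapses_to_one_column(self, rng):
        placed = place_clone(self._cells(), 50.0, 0.0, rng)
        assert len({c["tangential_um"] for c in placed}) == 1
        assert len({c["section_index"] for c in placed}) == 1

    def test_multi_section_fraction_matches_monte_carlo_oracle(self):
        # fraction of 6-cell clones spanning >= 2 sections, sigma 25 um
        sigma, thick, n_cells, n_clones = 25.0, 50.0, 6, 800
        rng = np.random.default_rng(7)
        spans = []
        for _ in range(n_clones):
            placed = place_clone(self._cells(n_cells), thick, sigma, rng,
                                 tangential_extent_um=2000.0)
            spans.append(len({c["section_index"] for c in placed}) >= 2)
        observed = np.mean(spans)
        # independent oracle: plain numpy draws of the same geometry
        orng = np.random.default_rng(99)
        anchors = orng.uniform(0, 2000.0, 4000)
        offs = anchors[:, None] + orng.normal(0, sigma, (4000, n_cells))
        offs = np.clip(offs, 0, 2000.0 - 1e-9)
        expected = np.mean(
            (np.floor(offs / thick).max(axis=1)
             != np.floor(offs / thick).min(axis=1)))
        se = np.sqrt(expected * (1 - expected) * (1 / n_clones + 1 / 4000))
        assert abs(observed - expected) < 4 * se

    def test_layer_depth_bands_are_disjoint(self):
        bands = sorted(LAYER_DEPTH_BANDS.values())
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            assert hi1 < lo2

    def test_depth_placed_within_layer_band(self, rng):
        cells = [{"layer": "ONL", "soma_relative_depth": 0.0},
                 {"layer": "ONL", "soma_relative_depth": 1.0}]
        placed = place_clone(cells, 50.0, 10.0, rng)
        lo, hi = LAYER_DEPTH_BANDS["ONL"]
        for c in placed:
            assert lo <= c["radial_depth_frac"] <= hi


class TestIntensities:
    def test_zero_noise_reads_background_plus_signal(self, rng):
        noise = IntensityNoise(background_mean=10, background_sd=0,
                               signal_mean=100, signal_sd=0)
        code = parse_code("N:100000/C:000006")
        out = render_intensities(code, noise, rng)
        assert out["YFP_nuc"] == 110 and out["YFP_cyt"] == 10
        assert out["EGFP_cyt"] == 110 and out["EGFP_nuc"] == 10
        assert out["mKO_nuc"] == out["mKO_cyt"] == 10

    def test_empty_code_is_pure_background(self, rng):
        noise = IntensityNoise(background_sd=0, signal_sd=0)
        out = render_intensities(parse_code("N:000000/C:000000"), noise, rng)
        values = [v for k, v in out.items() if not k.startswith("bg")]
        assert set(values) == {10.0}

    def test_calling_accuracy_monotone_in_snr(self, rng):
        # cytoplasm-only codes: accuracy limited purely by threshold errors
        from clonetrack.barcode import ColorCode, serialize_code
        accuracies = []
        for signal in (2.0, 6.0, 18.0, 54.0, 162.0):
            noise = IntensityNoise(background_mean=10, background_sd=2,
                                   signal_mean=signal, signal_sd=signal / 10)
            rows = []
            truths = []
            for i in range(300):
                bits = rng.random(6) < 0.4
                code = ColorCode((False,) * 6, tuple(bits))
                truths.append(serialize_code(code))
                row = {"cell_id": f"c{i}",
                       **render_intensities(code, noise, rng)}
                rows.append(row)
            called = call_table(pd.DataFrame(rows))
            acc = np.mean(np.array(called.cells["code"]) == np.array(truths))
            accuracies.append(acc)
        assert all(b >= a - 0.01 for a, b in zip(accuracies, accuracies[1:]))
        assert accuracies[-1] > accuracies[0]


class TestCohort:
    def test_same_seed_gives_byte_identical_tables(self):
        cfg = SimConfig(seed=3, n_embryos=2,
                        n_targeted_progenitors_per_embryo=10)
        a = cohort_frame(simulate_cohort(cfg)[0]).to_csv(index=False)
        b = cohort_frame(simulate_cohort(cfg)[0]).to_csv(index=False)
        assert a == b

    def test_cell_count_conserves_clone_sizes(self, zero_noise_cohort):
        embryos, truth = zero_noise_cohort
        n_cells = sum(e.n_cells for e in embryos)
        n_clone_cells = int(truth.progenitors["clone_size"].sum())
        n_excluded = int(truth.cells["excluded"].sum())
        assert n_cells == n_clone_cells + n_excluded

    def test_every_cell_maps_to_one_progenitor_sharing_its_code(
            self, zero_noise_cohort):
        _, truth = zero_noise_cohort
        prog = truth.progenitors.set_index("clone_id")
        assigned = truth.cells[~truth.cells["excluded"]]
        assert assigned["clone_id"].isin(prog.index).all()
        merged = assigned.merge(prog["code"], left_on="clone_id",
                                right_index=True, suffixes=("", "_prog"))
        assert (merged["code"] == merged["code_prog"]).all()

    def test_truth_types_match_truth_layers(self, zero_noise_cohort):
        _, truth = zero_noise_cohort
        assert (truth.cells["layer"]
                == truth.cells["cell_type"].map(TYPE_TO_LAYER)).all()

    def test_pooled_inl_share_within_reported_embryo_range(
            self, zero_noise_cohort):
        _, truth = zero_noise_cohort
        assigned = truth.cells[~truth.cells["excluded"]]
        inl = 100.0 * (assigned["layer"] == "INL").mean()
        assert 65.32 <= inl <= 92.95

    def test_single_progenitor_yields_at_most_one_clone(self):
        cfg = SimConfig(seed=0, n_embryos=1,
                        n_targeted_progenitors_per_embryo=1,
                        excluded_fraction=0.0)
        _, truth = simulate_cohort(cfg)
        assert truth.cells["clone_id"].nunique() <= 1

    def test_invalid_config_lists_all_offending_fields(self):
        cfg = SimConfig(p_uptake=2.0, section_thickness_um=-1.0)
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        assert {"p_uptake", "section_thickness_um"} <= set(err.value.fields)

    def test_archetype_below_feasible_mean_rejected(self):
        bad = CloneArchetype("bad", "GCL_only", "committed", ("RGC",) * 3,
                             {"RGC": 1.0}, weight=1, mean_size=1.0)
        with pytest.raises(ConfigError, match="mean_size"):
            SimConfig(archetypes=(bad,)).validate()

    def test_derived_mixtures_sum_to_one(self):
        cfg = SimConfig()
        for mixture in (cfg.potency_mixture(), cfg.layer_class_mixture(),
                        cfg.expected_layer_mixture()):
            assert abs(sum(mixture.values()) - 1.0) < 1e-9
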
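"""Synthetic study-region generator: structure, calibration, determinism."""

import numpy as np
import pytest

from srisoscape.samples import aggregate_site_ratios
from srisoscape.synthetic import (
    DEFAULT_LITHO_FREQ,
    SyntheticConfig,
    _median_sd_factor,
    aerosol_fields,
    generate_benchmark,
    generate_geology,
    sample_sites,
    true_bedrock,
)


class TestConfigValidation:
    def test_bad_frequencies_rejected(self):
        freq = dict(DEFAULT_LITHO_FREQ)
        freq["sc"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(litho_freq=freq)

    def test_endmember_bounds(self):
        with pytest.raises(ValueError):
            SyntheticConfig(salt_ratio=0.65)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(substrate_sd=-1e-4)


class TestGeology:
    def test_units_partition_grid(self):
        cfg = SyntheticConfig(nrows=40, ncols=40, n_units=8, seed=3)
        unit_grid, litho_grid, age_grid, units = generate_geology(cfg)
        vals = unit_grid.values
        assert set(np.unique(vals)) <= set(range(8))
        assert not np.isnan(vals).any()
        # lithology and age are piecewise constant by unit
        for _, row in units.units.iterrows():
            mask = vals == row["unit_id"]
            if mask.any():
                assert np.unique(age_grid.values[mask]).size == 1
                assert age_grid.values[mask][0] == pytest.approx(row["mean_age"])

    def test_voronoi_property_nearest_seed_wins(self):
        # any two cells of the same unit are closer to that unit's seed
        # than to any other -- verified indirectly: unit regions are the
        # nearest-neighbour partition, hence connected along straight lines
        cfg = SyntheticConfig(nrows=30, ncols=30, n_units=5, seed=1)
        unit_grid, *_ = generate_geology(cfg)
        # midpoint of two same-unit cells is (almost always) the same unit;
        # check the weaker, always-true property that each unit is nonempty
        # only if its seed's cell carries its id
        assert len(np.unique(unit_grid.values)) >= 2

    def test_age_within_lithology_range(self):
        cfg = SyntheticConfig(nrows=20, ncols=20, n_units=10, seed=5)
        *_, units = generate_geology(cfg)
        for _, row in units.units.iterrows():
            lo, hi = cfg.age_ranges[row["lithology"]]
            assert lo <= row["mean_age"] <= hi
            assert row["min_age"] == pytest.approx(0.9 * row["mean_age"])
            assert row["max_age"] == pytest.approx(1.1 * row["mean_age"])

    def test_lithology_frequencies_converge(self):
        # over many units, drawn lithology shares approach the configured
        # frequencies (law of large numbers, +/- 2 percentage points)
        cfg = SyntheticConfig(nrows=10, ncols=10, n_units=10, seed=0)
        counts = {c: 0 for c in cfg.litho_codes}
        rng_seeds = range(200)  # 200 x 10 units = 2000 draws... too slow;
        # instead draw one large geology
        big = SyntheticConfig(nrows=10, ncols=10, n_units=10_000, seed=11)
        *_, units = generate_geology(big)
        freq = units.units["lithology"].value_counts(normalize=True)
        for code, p in DEFAULT_LITHO_FREQ.items():
            assert freq.get(code, 0.0) == pytest.approx(p, abs=0.02)


class TestFields:
    def test_aerosol_shapes_and_gradients(self):
        cfg = SyntheticConfig(nrows=50, ncols=50)
        salt, dust = aerosol_fields(cfg)
        # salt decays west -> east; dust increases north -> south
        assert np.all(np.diff(salt.values, axis=1) < 0)
        assert np.all(np.diff(dust.values, axis=0) > 0)
        assert salt.values.max() <= 1.0 and dust.values.max() <= 1.0

    def test_salt_efold_hand_value(self):
        cfg = SyntheticConfig(nrows=2, ncols=120, salt_efold_m=50_000.0)
        salt, _ = aerosol_fields(cfg)
        # 50 km east of the origin the flux is down by exactly 1/e
        west = salt.values[0, 0]
        at_efold = salt.values[0, 50]  # 50 cells * 1 km
        assert at_efold / west == pytest.approx(np.exp(-1.0))

    def test_bioavailable_bounded_by_endmembers(self, small_benchmark):
        t = small_benchmark.truth
        lo = min(t.bedrock_grid.values.min(), small_benchmark.cfg.salt_ratio,
                 small_benchmark.cfg.dust_ratio)
        hi = max(t.bedrock_grid.values.max(), small_benchmark.cfg.salt_ratio,
                 small_benchmark.cfg.dust_ratio)
        assert t.bio_grid.values.min() >= lo - 1e-12
        assert t.bio_grid.values.max() <= hi + 1e-12

    def test_bedrock_truth_piecewise_constant(self):
        cfg = SyntheticConfig(nrows=25, ncols=25, n_units=6, seed=2)
        unit_grid, litho_grid, _, units = generate_geology(cfg)
        bed = true_bedrock(cfg, units, unit_grid)
        assert len(np.unique(bed.values)) <= 6
        assert np.all(bed.values > 0.69)


class TestSampling:
    def test_median_sd_factor_monte_carlo(self):
        # the analytic chi-mixture median matches a direct simulation
        probs = (0.5, 0.3, 0.2)
        factor = _median_sd_factor(probs)
        rng = np.random.default_rng(31)
        sds = []
        for _ in range(20_000):
            n = rng.choice([1, 2, 3], p=probs)
            if n < 2:
                continue
            sds.append(np.std(rng.standard_normal(n), ddof=1))
        assert np.median(sds) == pytest.approx(factor, rel=0.02)

    def test_observable_median_sd_matches_config(self):
        # end to end: the generator's median within-site SD statistic
        # recovers the configured substrate SD
        from srisoscape.diagnostics import within_population_uncertainty
        cfg = SyntheticConfig(nrows=80, ncols=80, n_units=10, n_sites=4000,
                              seed=13)
        bm = generate_benchmark(cfg)
        med, _ = within_population_uncertainty(bm.truth.samples)
        assert med == pytest.approx(cfg.substrate_sd, rel=0.15)

    def test_sites_distinct_and_inside_grid(self):
        cfg = SyntheticConfig(nrows=30, ncols=30, n_units=5, n_sites=200,
                              seed=4)
        bm = generate_benchmark(cfg)
        df = bm.truth.samples.records
        sites = df.drop_duplicates("site_id")
        assert len(sites) == 200
        spec = cfg.spec
        x, y = spec.crs.from_lonlat(sites["longitude"].to_numpy(),
                                    sites["latitude"].to_numpy())
        assert np.all(spec.contains(*spec.index_of(x, y)))

    def test_records_per_site_distribution(self):
        cfg = SyntheticConfig(nrows=60, ncols=60, n_units=5, n_sites=3000,
                              seed=6)
        bm = generate_benchmark(cfg)
        counts = bm.truth.samples.records.groupby("site_id").size()
        share = counts.value_counts(normalize=True)
        for n, p in zip((1, 2, 3), cfg.records_per_site_probs):
            assert share[n] == pytest.approx(p, abs=0.03)

    def test_noise_free_config_reproduces_truth_exactly(self):
        cfg = SyntheticConfig(nrows=20, ncols=20, n_units=4, n_sites=50,
                              substrate_sd=0.0, measurement_sd=0.0, seed=8)
        bm = generate_benchmark(cfg)
        df = bm.truth.samples.records
        spec = cfg.spec
        for sid, g in df.groupby("site_id"):
            x, y = spec.crs.from_lonlat(g["longitude"].iloc[0],
                                        g["latitude"].iloc[0])
            r, c = spec.index_of(np.atleast_1d(x), np.atleast_1d(y))
            truth = bm.truth.bio_grid.values[r[0], c[0]]
            assert aggregate_site_ratios(g) == pytest.approx(truth, abs=1e-12)

    def test_site_bias_requires_litho_grid(self):
        cfg = SyntheticConfig(nrows=10, ncols=10, n_units=3, n_sites=20)
        bm = generate_benchmark(cfg)
        with pytest.raises(ValueError, match="lithology grid"):
            sample_sites(cfg, bm.truth.bio_grid, site_bias={"sc": 5.0})

    def test_more_sites_than_cells_rejected(self):
        cfg = SyntheticConfig(nrows=5, ncols=5, n_units=2, n_sites=26)
        with pytest.raises(ValueError, match="more sites"):
            generate_benchmark(cfg)


class TestBenchmark:
    def test_stack_layer_names(self, small_benchmark):
        names = [g.name for g in small_benchmark.stack.layers]
        assert names == ["r.litho", "r.meanage", "r.m1", "r.srsrq1",
                         "r.srsrq3", "r.salt", "r.dust"]

    def test_bit_reproducible_across_calls(self):
        cfg = SyntheticConfig(nrows=25, ncols=25, n_units=5, n_sites=60, seed=19)
        a = generate_benchmark(cfg)
        b = generate_benchmark(cfg)
        np.testing.assert_array_equal(a.truth.bio_grid.values,
                                      b.truth.bio_grid.values)
        assert a.truth.samples.records.equals(b.truth.samples.records)

    def test_different_seeds_differ(self):
        cfg = SyntheticConfig(nrows=25, ncols=25, n_units=5, n_sites=60)
        a = generate_benchmark(cfg, seed=1)
        b = generate_benchmark(cfg, seed=2)
        assert not np.array_equal(a.truth.bio_grid.values,
                                  b.truth.bio_grid.values)

    def test_bedrock_model_is_informative_but_not_truth(self, small_benchmark):
        # the model's median layer correlates with the true bedrock but is
        # not identical to it (independent Monte-Carlo draws)
        t = small_benchmark.truth
        model = small_benchmark.bedrock_model.median.values
        r = np.corrcoef(model.ravel(), t.bedrock_grid.values.ravel())[0, 1]
        assert 0.3 < r < 0.999999
        assert not np.allclose(model, t.bedrock_grid.values)

    def test_matrix_has_all_covariates_and_sites(self, small_benchmark,
                                                 small_matrix):
        assert len(small_matrix.data) == small_benchmark.cfg.n_sites
        assert small_matrix.covariate_names == \
            [g.name for g in small_benchmark.stack.layers]
        assert small_matrix.categorical == ["r.litho"]
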
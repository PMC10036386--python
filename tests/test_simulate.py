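import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from del22q import canonical_deletions
from del22q.simulate import (
    CohortParams,
    DeletionScenario,
    SampleTruth,
    SimParams,
    carrier_fraction,
    expected_depth_ratio,
    generate_cohort,
    simulate_sample,
)


def scenario(origin, model=None, deletion="A-D"):
    if origin == "none":
        return DeletionScenario(origin="none")
    return DeletionScenario(origin=origin, interval=canonical_deletions(model)[deletion])


class TestDepthModel:
    @pytest.mark.parametrize(
        "origin,ff,expected",
        [
            ("fetal_de_novo", 0.10, 0.95),
            ("paternal_fetal", 0.10, 0.95),
            ("maternal_not_transmitted", 0.10, 0.55),
            ("maternal_transmitted", 0.10, 0.50),
            ("maternal_transmitted", 0.37, 0.50),  # independent of ff
            ("none", 0.10, 1.00),
        ],
    )
    def test_expected_ratio(self, model, origin, ff, expected):
        assert expected_depth_ratio(scenario(origin, model), ff) == pytest.approx(expected)

    @pytest.mark.parametrize("ff", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_ff_rejected(self, model, ff):
        with pytest.raises(ValueError):
            expected_depth_ratio(scenario("fetal_de_novo", model), ff)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_ratio_decreases_with_carrier_fraction(self, ff1, ff2):
        # across scenarios at fixed ff, larger carrier fraction -> lower ratio
        order = ["none", "fetal_de_novo", "maternal_not_transmitted", "maternal_transmitted"]
        if ff1 < 0.5:
            cs = [carrier_fraction(o, ff1) for o in order]
            assert cs == sorted(cs)
        # maternal_not_transmitted ratio increases with ff
        lo, hi = sorted((ff1, ff2))
        if lo < hi:
            r_lo = 1 - carrier_fraction("maternal_not_transmitted", lo) / 2
            r_hi = 1 - carrier_fraction("maternal_not_transmitted", hi) / 2
            assert r_lo <= r_hi

    def test_scenario_requires_interval_iff_event(self, model):
        with pytest.raises(ValueError):
            DeletionScenario(origin="fetal_de_novo")
        with pytest.raises(ValueError):
            DeletionScenario(origin="none", interval=canonical_deletions(model)["A-D"])


class TestSimulateSample:
    def test_deterministic_under_seed(self, model, sim_params):
        truth = SampleTruth("s", 0.1, scenario("maternal_transmitted", model), seed=77)
        a = simulate_sample(truth, sim_params, model.grid)
        b = simulate_sample(truth, sim_params, model.grid)
        assert np.array_equal(a.counts, b.counts)

    def test_null_sample_mean_depth(self, model, sim_params):
        truth = SampleTruth("s", 0.1, DeletionScenario("none"), seed=5)
        prof = simulate_sample(truth, sim_params, model.grid)
        se = np.sqrt(sim_params.mean_depth / model.n_bins)
        assert abs(prof.counts.mean() - sim_params.mean_depth) < 3 * se
        # conservation: total reads within 4 SE of depth * n_bins
        total_se = np.sqrt(sim_params.mean_depth * model.n_bins)
        assert abs(prof.counts.sum() - sim_params.mean_depth * model.n_bins) < 4 * total_se

    def test_deleted_bins_depressed_to_expectation(self, model, sim_params):
        iv = canonical_deletions(model)["A-D"]
        truth = SampleTruth(
            "s", 0.10, DeletionScenario("maternal_not_transmitted", iv), seed=6
        )
        prof = simulate_sample(truth, sim_params, model.grid)
        inside = model.grid.overlap_fractions(iv) == 1.0
        n_in = int(inside.sum())
        se = np.sqrt(550.0 / n_in)
        assert abs(prof.counts[inside].mean() - 550.0) < 3 * se

    def test_boundary_bin_proportional(self, model, sim_params):
        # deletion ending mid-bin: that bin's mean sits midway between levels
        iv_full = canonical_deletions(model)["A-D"]
        iv = type(iv_full)(iv_full.chrom, iv_full.start, iv_full.end + 25_000)
        frac = model.grid.overlap_fractions(iv)
        half_bin = int(np.where((frac > 0) & (frac < 1))[0][0])
        assert frac[half_bin] == 0.5
        means = []
        for seed in range(300):
            truth = SampleTruth(
                "s", 0.10, DeletionScenario("maternal_transmitted", iv), seed=seed
            )
            means.append(simulate_sample(truth, sim_params, model.grid).counts[half_bin])
        expected = 1000 * (1 - 0.5 * 0.5)  # half of the bin at ratio 0.5
        se = np.sqrt(expected / 300)
        assert abs(np.mean(means) - expected) < 3 * se

    def test_overdispersion_inflates_variance(self, model):
        params = SimParams(mean_depth=1000.0, dispersion=0.05)
        truth = SampleTruth("s", 0.1, DeletionScenario("none"), seed=3)
        prof = simulate_sample(truth, params, model.grid)
        # NB variance = m + d m^2 = 51x Poisson here
        assert prof.counts.var() > 5 * 1000.0

    def test_interval_outside_grid_rejected(self, model, sim_params):
        iv = type(model.region)("chr22", 1_000_000, 2_000_000)
        truth = SampleTruth("s", 0.1, DeletionScenario("fetal_de_novo", iv), seed=1)
        with pytest.raises(ValueError, match="outside"):
            simulate_sample(truth, sim_params, model.grid)


class TestGenerateCohort:
    def test_latent_shares_match_parameters(self, model, sim_params):
        cp = CohortParams(n_cases=4000)
        _, table = generate_cohort(cp, model, SimParams(mean_depth=50.0), seed=42)
        maternal = table["origin"].str.startswith("maternal")
        se = np.sqrt(0.577 * 0.423 / len(table))
        assert abs(maternal.mean() - 0.577) < 3 * se
        transmitted = table.loc[maternal, "origin"] == "maternal_transmitted"
        se_t = np.sqrt(0.25 / maternal.sum())
        assert abs(transmitted.mean() - 0.5) < 3 * se_t

    def test_ff_distribution_median_and_bounds(self, model):
        cp = CohortParams(n_cases=4000)
        _, table = generate_cohort(cp, model, SimParams(mean_depth=50.0), seed=43)
        assert abs(table["ff"].median() - 0.1048) < 0.006
        assert table["ff"].between(*cp.ff_bounds).all()

    def test_reproducible_truth_table(self, model):
        cp = CohortParams(n_cases=50)
        params = SimParams(mean_depth=100.0)
        _, t1 = generate_cohort(cp, model, params, seed=9)
        _, t2 = generate_cohort(cp, model, params, seed=9)
        assert t1.to_csv(sep="\t", index=False) == t2.to_csv(sep="\t", index=False)

    def test_invalid_n_cases(self, model, sim_params):
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(n_cases=0), model, sim_params, seed=1)

    def test_size_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortParams(size_mix={"A-D": 0.5, "C-D": 0.2})
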
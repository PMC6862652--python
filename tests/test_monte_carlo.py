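"""Monte Carlo engine: determinism, convergence, monotone-transform identity."""

import warnings

import numpy as np
import pytest

from fluorisk import (
    ConcentrationSummary,
    DataAnomalyWarning,
    MonteCarloSettings,
    RiskConfig,
    cumulative_curve,
    run_simulation,
    summarize_to_table,
)
from fluorisk.monte_carlo import round_sig

from conftest import GROUPS, TABLE3


def point_study(study_id, conc):
    return ConcentrationSummary(
        study_id, mean_conc=conc, min_conc=conc, max_conc=conc, eval_conc=conc
    )


def tri_cdf(x, a, c, b):
    """Closed-form triangular CDF (independent oracle)."""
    if x <= a:
        return 0.0
    if x <= c:
        return (x - a) ** 2 / ((b - a) * (c - a))
    if x < b:
        return 1 - (b - x) ** 2 / ((b - a) * (b - c))
    return 1.0


class TestRunSimulation:
    def test_point_mass_reproduces_deterministic_cells(self, populations, config):
        # a degenerate distribution makes the simulation exactly the
        # deterministic model: every percentile equals the point value
        res = run_simulation(
            [point_study("26", 2.63)], populations[:1],
            MonteCarloSettings(n_iterations=500, master_seed=1), config,
        )[0]
        assert round_sig(res.point_cdi) == 6.74e-2
        assert round_sig(res.point_hq) == 1.12
        for p, q in res.cdi_percentiles.items():
            assert round_sig(q) == 6.74e-2
            assert round_sig(res.hq_percentiles[p]) == 1.12
        assert res.prob_hq_exceeds == 1.0  # HQ 1.12 > 1 with zero variance

    def test_point_mass_below_threshold_never_exceeds(self, populations, config):
        res = run_simulation(
            [point_study("23", 0.36)], populations[:1],
            MonteCarloSettings(n_iterations=500, master_seed=1), config,
        )[0]
        assert res.prob_hq_exceeds == 0.0

    def test_triangular_exceedance_matches_analytic(self, populations, config):
        # HQ > 1 inverts to C > threshold*RfD*BW/IR = 2.34 mg/L for men
        summary = ConcentrationSummary(
            "26", mean_conc=2.02, min_conc=0.7, max_conc=3.27, eval_conc=2.63
        )
        men = populations[0]
        cut = config.hazard_threshold * config.rfd * men.bw / men.ir
        assert cut == pytest.approx(2.34)
        analytic = 1 - tri_cdf(cut, 0.7, 2.02, 3.27)
        res = run_simulation(
            [summary], [men],
            MonteCarloSettings(n_iterations=10**5, master_seed=2), config,
            family="triangular",
        )[0]
        assert res.prob_hq_exceeds == pytest.approx(analytic, abs=0.01)

    def test_monotone_transform_identity_exact(self, studies, populations, config):
        results = run_simulation(
            studies, populations,
            MonteCarloSettings(n_iterations=2000, master_seed=3), config,
        )
        for r in results:
            for p, q in r.cdi_percentiles.items():
                assert r.hq_percentiles[p] == q / config.rfd

    def test_percentiles_nondecreasing(self, studies, populations, config):
        results = run_simulation(
            studies, populations,
            MonteCarloSettings(n_iterations=2000, master_seed=3), config,
        )
        for r in results:
            qs = [r.cdi_percentiles[p] for p in sorted(r.cdi_percentiles)]
            assert qs == sorted(qs)
            assert 0 <= r.prob_hq_exceeds <= 1

    def test_seed_determinism(self, studies, populations, config):
        settings = MonteCarloSettings(n_iterations=1000, master_seed=9)
        a = run_simulation(studies, populations, settings, config)
        b = run_simulation(studies, populations, settings, config)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.conc_samples, rb.conc_samples)
            assert ra.cdi_percentiles == rb.cdi_percentiles
            assert ra.prob_hq_exceeds == rb.prob_hq_exceeds

    def test_empirical_p95_converges_to_analytic(self, populations, config):
        summary = ConcentrationSummary("27", mean_conc=1.28, min_conc=1.11, max_conc=1.44)
        men = populations[0]
        res = run_simulation(
            [summary], [men],
            MonteCarloSettings(n_iterations=10**5, master_seed=4, percentiles=(0.95,)),
            config,
        )[0]
        # closed-form triangular quantile, upper branch
        b, a, c = 1.44, 1.11, 1.28
        q95 = b - np.sqrt((1 - 0.95) * (b - a) * (b - c))
        expected = q95 * men.ir / men.bw
        assert res.cdi_percentiles[0.95] == pytest.approx(expected, rel=0.01)

    def test_point_value_falls_back_to_simulated_p95(self, populations, config):
        summary = ConcentrationSummary("x", mean_conc=1.28, min_conc=1.11, max_conc=1.44)
        men = populations[0]
        res = run_simulation(
            [summary], [men],
            MonteCarloSettings(n_iterations=5000, master_seed=5), config,
        )[0]
        assert res.eval_conc == pytest.approx(
            np.quantile(res.conc_samples, 0.95, method="inverted_cdf")
        )
        assert res.point_cdi == pytest.approx(res.eval_conc * men.ir / men.bw)

    def test_unfittable_study_without_eval_is_skipped(self, populations, config):
        bad = ConcentrationSummary("bad", mean_conc=1.0, min_conc=0.5, max_conc=1.5)
        good = point_study("ok", 1.0)
        with pytest.warns(DataAnomalyWarning, match="skipped"):
            results = run_simulation(
                [bad, good], populations[:1],
                MonteCarloSettings(n_iterations=100, master_seed=6), config,
                family="truncated_normal",
            )
        assert [r.study_id for r in results] == ["ok"]

    def test_empty_inputs_rejected(self, populations, config):
        with pytest.raises(ValueError, match="at least one"):
            run_simulation([], populations, MonteCarloSettings(), config)

    def test_settings_validation(self):
        with pytest.raises(ValueError, match="n_iterations"):
            MonteCarloSettings(n_iterations=0)
        with pytest.raises(ValueError, match="percentile"):
            MonteCarloSettings(percentiles=(1.5,))
        with pytest.raises(ValueError, match="assurance_grid"):
            MonteCarloSettings(assurance_grid=(0.5, 0.4))


class TestCumulativeCurve:
    def test_uniform_ranks(self):
        curve = cumulative_curve([3, 1, 4, 2])
        assert list(curve["value"]) == [1, 2, 3, 4]
        assert list(curve["cumulative_probability"]) == [0.25, 0.5, 0.75, 1.0]

    def test_single_sample(self):
        curve = cumulative_curve([1.8])
        assert curve.shape == (1, 2)
        assert curve["cumulative_probability"].iloc[0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            cumulative_curve([])

    def test_uniform_draws_match_straight_line_cdf(self):
        rng = np.random.default_rng(8)
        draws = 0.13 + 0.31 * rng.random(10**5)
        curve = cumulative_curve(draws)
        theo = (curve["value"] - 0.13) / 0.31
        assert np.max(np.abs(curve["cumulative_probability"] - theo)) < 0.01


@pytest.fixture(scope="module")
def as_published_results(studies, populations, config):
    return run_simulation(
        studies, populations,
        MonteCarloSettings(n_iterations=1000, master_seed=7), config,
        mode="as_published",
    )


class TestSummarizeToTable:
    def test_published_rows(self, as_published_results, config):
        table = summarize_to_table(as_published_results, config, formatted=False)
        row28 = table.set_index("study_id").loc["28"]
        assert round_sig(row28["cdi_men"]) == 5.36e-2
        assert round_sig(row28["thq_men"]) == 0.893
        row17 = table.set_index("study_id").loc["17"]
        assert round_sig(row17["thq_children"]) == 1.63e-3

    def test_point_columns_only_by_default(self, as_published_results, config):
        table = summarize_to_table(as_published_results, config)
        assert not any("p95" in c for c in table.columns)
        assert list(table.columns[:2]) == ["study_id", "eval_conc_mgL"]

    def test_percentile_columns_on_request(self, as_published_results, config):
        table = summarize_to_table(as_published_results, config, percentiles=(0.95,))
        assert "cdi_p95_men" in table.columns and "thq_p95_children" in table.columns

    def test_formatted_cells_are_3_sigfig_strings(self, as_published_results, config):
        table = summarize_to_table(as_published_results, config)
        assert table.loc[table["study_id"] == "26", "thq_men"].item() == "1.12"
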
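"""Study design, truncated-normal calibration and fixture determinism."""

import numpy as np
import pytest
from scipy.stats import norm

from no2risk.exposure_data import Season
from no2risk.pipeline import run_assessment
from no2risk.synthetic_data import (
    CalibrationError,
    CampaignConfig,
    build_risk_fixture,
    calibrate_scenario_row,
    calibrate_truncated_normal,
    default_study_design,
    fixture_cells,
    generate_campaign,
    load_risk_fixture,
    scenario_rows_from_file,
)


def _numeric_truncated_moments(mu, sigma, lower, upper, n_grid=200_001):
    """Independent oracle: trapezoidal integration of the parent density.

    Works in log-space so far-tail truncations (where the raw pdf
    underflows) still integrate to a proper density.
    """
    x = np.linspace(lower, upper, n_grid)
    logw = norm.logpdf(x, loc=mu, scale=sigma)
    w = np.exp(logw - logw.max())
    z = np.trapezoid(w, x)
    mean = np.trapezoid(x * w, x) / z
    var = np.trapezoid((x - mean) ** 2 * w, x) / z
    return mean, np.sqrt(var)


class TestDefaultStudyDesign:
    def test_total_and_per_cell_counts(self):
        config = default_study_design()
        assert sum(r.n for r in config.scenario_rows) == 76
        by_hospital = {}
        for r in config.scenario_rows:
            by_hospital[r.hospital_id] = by_hospital.get(r.hospital_id, 0) + r.n
        assert by_hospital == {"HTH": 22, "MTH": 18, "OSH": 14, "LTH": 22}

    def test_printed_summaries(self):
        rows = {(r.hospital_id, r.season): r for r in default_study_design().scenario_rows}
        hth_hot = rows[("HTH", Season.HOT)]
        assert (hth_hot.n, hth_hot.mean, hth_hot.sd) == (11, 827.27, 39.27)
        assert (hth_hot.min, hth_hot.max) == (770.0, 930.0)
        assert rows[("OSH", Season.HOT)].n == rows[("OSH", Season.COLD)].n == 7
        assert rows[("LTH", Season.COLD)].mean == 240.00

    def test_duplicate_cells_rejected(self):
        rows = default_study_design().scenario_rows
        with pytest.raises(ValueError):
            CampaignConfig(scenario_rows=rows + (rows[0],))

    def test_scenario_rows_from_yaml(self, tmp_path):
        path = tmp_path / "design.yaml"
        path.write_text(
            "- {hospital_id: HTH, season: hot, n: 11, mean: 827.27, sd: 39.27, "
            "min: 770, max: 930}\n"
        )
        (row,) = scenario_rows_from_file(path)
        assert row.hospital_id == "HTH" and row.traffic.value == "HT"
        assert row.mean == 827.27


class TestCalibration:
    def test_unbounded_interval_is_identity(self):
        assert calibrate_truncated_normal(5.0, 2.0) == (5.0, 2.0)

    def test_symmetric_bounds_give_mu_at_target(self):
        mu, sigma = calibrate_truncated_normal(100.0, 8.0, 80.0, 120.0)
        assert mu == pytest.approx(100.0, abs=1e-4)
        assert sigma > 8.0  # truncation sheds variance, parent must be wider

    def test_hth_hot_row_against_numeric_oracle(self):
        mu, sigma = calibrate_truncated_normal(827.27, 39.27, 770.0, 930.0)
        assert mu < 827.27  # lower truncation cuts more mass
        mean, sd = _numeric_truncated_moments(mu, sigma, 770.0, 930.0)
        assert mean == pytest.approx(827.27, rel=1e-5)
        assert sd == pytest.approx(39.27, rel=1e-5)

    def test_infeasible_sd_raises(self):
        # a distribution confined to [360, 370] cannot carry SD 5
        with pytest.raises(CalibrationError):
            calibrate_truncated_normal(363.33, 5.0, 360.0, 370.0)

    @pytest.mark.parametrize("bad_kwargs", [
        dict(target_mean=50.0, target_sd=1.0, lower=60.0, upper=70.0),
        dict(target_mean=65.0, target_sd=-1.0, lower=60.0, upper=70.0),
        dict(target_mean=65.0, target_sd=1.0, lower=70.0, upper=60.0),
    ])
    def test_invalid_targets_rejected(self, bad_kwargs):
        with pytest.raises(ValueError):
            calibrate_truncated_normal(**bad_kwargs)

    def test_generator_fallback_matches_mean_exactly(self):
        # the printed SD of this cell is unattainable on its interval:
        # the fallback must still match the mean and come as close in SD
        # as the family allows
        mu, sigma = calibrate_scenario_row(363.33, 5.0, 360.0, 370.0)
        mean, sd = _numeric_truncated_moments(mu, sigma, 360.0, 370.0)
        assert mean == pytest.approx(363.33, rel=1e-5)
        assert 2.0 < sd < 5.0  # near the interval's supremum, below target


class TestGenerateCampaign:
    def test_default_design_yields_76_records(self, default_campaign):
        assert len(default_campaign) == 76

    def test_every_draw_inside_printed_bounds(self, default_campaign):
        rows = {(r.hospital_id, r.season): r for r in default_study_design().scenario_rows}
        for m in default_campaign:
            row = rows[(m.hospital_id, m.season)]
            assert row.min <= m.concentration <= row.max

    def test_same_seed_reproduces_bit_exactly(self, default_campaign):
        again = generate_campaign(default_study_design(seed=1))
        assert again == default_campaign

    def test_different_seeds_differ(self, default_campaign):
        other = generate_campaign(default_study_design(seed=2))
        assert other != default_campaign

    def test_row_order_does_not_affect_draws(self, default_campaign):
        config = default_study_design(seed=1)
        reordered = CampaignConfig(
            scenario_rows=tuple(reversed(config.scenario_rows)), seed=1
        )
        by_key = {}
        for m in generate_campaign(reordered):
            by_key.setdefault((m.hospital_id, m.season), []).append(m.concentration)
        for m in default_campaign:
            key = (m.hospital_id, m.season)
            assert m.concentration == by_key[key].pop(0)

    def test_mean_recovery_hth_hot(self):
        # replicate-averaged sample mean converges on the design mean
        # (200 replicates here; the acceptance run uses 1,000)
        means = []
        for seed in range(1, 201):
            campaign = generate_campaign(default_study_design(seed=seed))
            values = [
                m.concentration
                for m in campaign
                if m.hospital_id == "HTH" and m.season == Season.HOT
            ]
            assert len(values) == 11
            means.append(np.mean(values))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 827.27) < 3 * se

    def test_sd_recovery_hth_hot(self):
        # the one cell whose printed (mean, SD) pair is jointly attainable
        sds = []
        for seed in range(1, 201):
            campaign = generate_campaign(default_study_design(seed=seed))
            values = [
                m.concentration
                for m in campaign
                if m.hospital_id == "HTH" and m.season == Season.HOT
            ]
            sds.append(np.std(values, ddof=1))
        sds = np.asarray(sds)
        se = sds.std(ddof=1) / np.sqrt(len(sds))
        # expected sample SD sits slightly below the population value
        # (n=11 small-sample bias), so allow that bias plus sampling error
        assert sds.mean() == pytest.approx(39.27, abs=3 * se + 1.5)


class TestRiskFixtures:
    def test_fixture_is_pure_and_deterministic(self):
        for cell in fixture_cells():
            assert build_risk_fixture(*cell) == build_risk_fixture(*cell)

    def test_packaged_csvs_match_builder(self):
        for cell in fixture_cells():
            assert load_risk_fixture(*cell) == build_risk_fixture(*cell)

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError):
            build_risk_fixture("XYZ", Season.HOT)

    @pytest.mark.parametrize(
        "hospital, season, rf_subset",
        [
            ("HTH", "hot", {4, 6}),
            ("HTH", "cold", {4, 6}),
            ("MTH", "hot", {2, 3}),
            ("OSH", "hot", {2, 3}),
            ("LTH", "cold", {2, 3}),
        ],
    )
    def test_fixture_rf_ranges(self, hospital, season, rf_subset):
        fixture = build_risk_fixture(hospital, season)
        (table,) = run_assessment(fixture)
        assert set(table.risk_factors) == rf_subset

    def test_osh_hot_moderate_count(self):
        (table,) = run_assessment(build_risk_fixture("OSH", "hot"))
        moderate = [r for r in table.rows if r.score.category == "moderate"]
        assert len(moderate) == 4 and len(table.rows) == 7

    def test_occupancy_reconstruction_counts(self):
        # continuous-care labels carry occupancy > 0.75, support labels 0.5
        expected_high_occupancy = {
            ("HTH", Season.HOT): 8,
            ("HTH", Season.COLD): 7,
            ("MTH", Season.HOT): 7,
            ("MTH", Season.COLD): 7,
            ("OSH", Season.HOT): 4,
            ("OSH", Season.COLD): 4,
            ("LTH", Season.HOT): 6,
            ("LTH", Season.COLD): 6,
        }
        for cell, count in expected_high_occupancy.items():
            fixture = build_risk_fixture(*cell)
            high = [m for m in fixture if m.occupancy_fraction > 0.75]
            rest = [m for m in fixture if 0.25 <= m.occupancy_fraction <= 0.75]
            assert len(high) == count
            assert len(high) + len(rest) == len(fixture)
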
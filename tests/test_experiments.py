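"""Strategy grids, the age-range regression, the sensitivity sweep, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import bcscreen as bc
from bcscreen.cli import main as cli_main
from bcscreen.experiments import (GridSpec, relative_benefit_regression,
                                  relative_effect_pct, run_grid,
                                  sensitivity_sweep)
from bcscreen.natural_history import ModelError


class TestRunGrid:
    def test_combinatorial_row_count(self, japan_small_grid):
        # 2 intervals x 2 starts x 3 stops
        assert len(japan_small_grid.rows) == 12

    def test_zero_participation_gives_zero_benefit(self, japan_params, japan_perf):
        spec = GridSpec(params=japan_params, performance=japan_perf,
                        start_ages=(40,), stop_ages=(69,), intervals=(2,),
                        participation=0.0)
        r = run_grid(spec).rows[0]
        assert r.deaths_averted == pytest.approx(0.0, abs=1e-6)
        assert r.screenings == 0 and r.false_positives == 0

    def test_wide_range_dominates_narrow(self, japan_small_grid):
        wide = japan_small_grid.row(2, 40, 74)
        narrow = japan_small_grid.row(2, 50, 74)
        assert wide.deaths_averted > narrow.deaths_averted
        assert wide.false_positives > narrow.false_positives

    def test_rows_independent_of_list_order(self, japan_params, japan_perf):
        a = run_grid(GridSpec(params=japan_params, performance=japan_perf,
                              start_ages=(40, 50), stop_ages=(69,), intervals=(2,)))
        b = run_grid(GridSpec(params=japan_params, performance=japan_perf,
                              start_ages=(50, 40), stop_ages=(69,), intervals=(2,)))
        assert a.row(2, 40, 69) == b.row(2, 40, 69)
        assert a.row(2, 50, 69) == b.row(2, 50, 69)

    def test_biennial_rows_carry_maintained_percentage(self, japan_small_grid):
        for r in japan_small_grid.rows:
            if r.interval == 2:
                assert r.maintained_pct is not None
                assert 50 < r.maintained_pct < 100
            else:
                assert r.maintained_pct is None

    def test_reference_quantities(self, japan_small_grid):
        g = japan_small_grid
        assert g.baseline_deaths > 0
        assert g.no_bc_life_expectancy > g.baseline_life_expectancy
        assert g.theoretical_max_days > 0


class TestRegression:
    def test_exact_linear_response_recovered(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in (40, 45, 50, 55):
            for e in (69, 74, 79, 84):
                rows.append({"scmin": s, "scmax": e, "interval": 2,
                             "resp": 10 - 0.5 * s + 0.3 * e})
        df = pd.DataFrame(rows)
        res = relative_benefit_regression(df, response="resp")
        assert res.coef["initiating_age"] == pytest.approx(-0.5, abs=1e-10)
        assert res.coef["terminating_age"] == pytest.approx(0.3, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_normal_equations(self):
        # 6-point dataset solved by hand via the normal equations
        df = pd.DataFrame({
            "scmin": [40, 40, 50, 50, 60, 60],
            "scmax": [69, 79, 69, 79, 69, 79],
            "interval": 2,
            "resp": [31.0, 38.0, 27.0, 34.0, 22.0, 30.0],
        })
        X = np.column_stack([np.ones(6), df["scmin"], df["scmax"]])
        y = df["resp"].to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = relative_benefit_regression(df, response="resp")
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.coef["initiating_age"] == pytest.approx(beta[1], abs=1e-10)
        assert res.coef["terminating_age"] == pytest.approx(beta[2], abs=1e-10)

    def test_sign_pattern_on_fixture_grid(self, japan_small_grid):
        """Earlier initiation and later termination both add benefit."""
        for interval in (1, 2):
            res = relative_benefit_regression(japan_small_grid,
                                              response="death_reduction_pct",
                                              interval=interval)
            assert res.coef["initiating_age"] < 0
            assert res.coef["terminating_age"] > 0

    def test_standardized_beta_definition(self, japan_small_grid):
        res = relative_benefit_regression(japan_small_grid, interval=2)
        df = japan_small_grid.to_frame()
        df = df[df["interval"] == 2]
        sy = df["death_reduction_pct"].std(ddof=1)
        assert res.beta["initiating_age"] == pytest.approx(
            res.coef["initiating_age"] * df["scmin"].std(ddof=1) / sy)

    def test_collinear_design_rejected(self):
        df = pd.DataFrame({"scmin": [40, 40, 40, 40], "scmax": [69, 74, 79, 84],
                           "interval": 2, "resp": [1, 2, 3, 4]})
        with pytest.raises(ModelError):
            relative_benefit_regression(df, response="resp")

    def test_ale_extension_pct_response(self, japan_small_grid):
        res = relative_benefit_regression(japan_small_grid,
                                          response="ale_extension_pct", interval=2)
        assert res.coef["initiating_age"] < 0


class TestSensitivity:
    def test_relative_effect_formula(self):
        # published example: (63 - 50) / 50 days -> 26%
        assert relative_effect_pct(63, 50) == pytest.approx(26.0)

    def test_identical_extensions_give_zero(self):
        assert relative_effect_pct(50, 50) == 0.0

    def test_zero_narrow_extension_flagged(self):
        with pytest.raises(ModelError):
            relative_effect_pct(10, 0)

    def test_sweep_monotone_in_multiplier(self, japan_params, japan_perf):
        res = sensitivity_sweep(japan_params, japan_perf, (1.0, 1.5, 2.0, 3.0))
        assert res.ext_wide == tuple(sorted(res.ext_wide))
        assert res.ext_narrow == tuple(sorted(res.ext_narrow))

    def test_sweep_at_default_multiplier_matches_direct_run(self, japan_params,
                                                            japan_perf,
                                                            japan_baseline):
        """m = 1.5 in the sweep reuses the same code path bit-exactly."""
        res = sensitivity_sweep(japan_params, japan_perf, (1.5,))
        traj = bc.simulate(japan_params, japan_perf,
                           bc.ScreeningStrategy.make(40, 74, 2, 1.0))
        direct = bc.extension_days(
            bc.average_life_expectancy(traj, 40),
            bc.average_life_expectancy(japan_baseline, 40))
        assert res.ext_wide[0] == direct

    def test_m_outside_range_rejected(self, japan_params, japan_perf):
        with pytest.raises(ModelError):
            sensitivity_sweep(japan_params, japan_perf, (0.5,))


class TestCLI:
    def test_grid_writes_table(self, tmp_path):
        out = tmp_path / "grid.tsv"
        r = CliRunner().invoke(cli_main, [
            "grid", "--preset", "japan-fixture", "--intervals", "2",
            "--starts", "40,50", "--stops", "69", "--out", str(out)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out, sep="\t")
        assert len(df) == 2

    def test_sensitivity_row_count(self, tmp_path):
        out = tmp_path / "sens.tsv"
        r = CliRunner().invoke(cli_main, [
            "sensitivity", "--preset", "japan-fixture",
            "--m", "1.0:3.0:0.25", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert len(pd.read_csv(out, sep="\t")) == 9

    def test_run_smoke(self):
        r = CliRunner().invoke(cli_main, [
            "run", "--preset", "japan-fixture",
            "--strategy", "start=40,end=69,interval=2,participation=1.0"])
        assert r.exit_code == 0, r.output
        assert "total BC deaths" in r.output

    def test_missing_rate_file_nonzero_exit(self, tmp_path):
        r = CliRunner().invoke(cli_main, [
            "regress", "--grid", str(tmp_path / "absent.tsv")])
        assert r.exit_code != 0

    def test_fixtures_written(self, tmp_path):
        r = CliRunner().invoke(cli_main, [
            "fixtures", "--country", "japan", "--out-dir", str(tmp_path)])
        assert r.exit_code == 0, r.output
        s = bc.read_rate_table(tmp_path / "japan_incidence.csv", "h1")
        assert s.values.max() == pytest.approx(0.00146)
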
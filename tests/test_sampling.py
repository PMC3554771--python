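"""Concentration grid, rate sampling, screen aggregation, and analyses."""

import numpy as np
import pandas as pd
import pytest

from mapkscreen.config import RunConfig, SamplingConfig
from mapkscreen.network import ConcentrationVector, KineticRates, RATE_NAMES, build_network
from mapkscreen.sampling import (DegenerateScanError, InsufficientDataError,
                                 MissingCellsError, ScreenDesign,
                                 UnknownSelectorError, concentration_grid,
                                 group_by_gradient, mapkk_scan,
                                 ratio_grouping, robust_rate_vectors,
                                 run_screen, sample_rates)

from conftest import SCREEN_SOLVER


class TestConcentrationGrid:
    def test_exactly_36_vectors(self):
        assert len(concentration_grid()) == 36

    def test_corner_ids_match_design_order(self):
        grid = concentration_grid()
        first, last = grid[0], grid[-1]
        assert (first.mapkk, first.mapk, first.m2kp, first.mkp) \
            == (0.2, 0.2, 0.02, 0.02)
        assert (last.mapkk, last.mapk, last.m2kp, last.mkp) == (5, 5, 5, 5)
        # id 5 (1-based): MAPKK 0.2, MAPK 1.0, phosphatases at the 0.1 level
        v5 = grid[4]
        assert (v5.mapkk, v5.mapk, v5.m2kp, v5.mkp) == (0.2, 1.0, 0.02, 0.1)

    def test_phosphatase_factors_track_substrates(self):
        for cv in concentration_grid():
            assert round(cv.m2kp / cv.mapkk, 9) in (0.1, 1.0)
            assert round(cv.mkp / cv.mapk, 9) in (0.1, 1.0)


class TestSampleRates:
    def test_seeded_determinism(self):
        a = sample_rates(5, seed=1)
        b = sample_rates(5, seed=1)
        assert all(x.values == y.values for x, y in zip(a, b))

    def test_no_feedback_pins_kf_to_zero(self):
        assert all(r.kf == 0.0 for r in sample_rates(8, 3, "none"))
        assert all(r.kf > 0.0 for r in sample_rates(8, 3, "negative"))

    def test_prefix_property_of_seeded_draws(self):
        """The first n vectors of a larger draw equal the n-vector draw,
        so subset screens share rate vectors with their parent screen."""
        big = sample_rates(40, seed=9)
        small = sample_rates(15, seed=9)
        assert all(x.values == y.values for x, y in zip(big[:15], small))

    def test_log_ratio_marginal_symmetric(self):
        """log10(kb5/kd5) over many draws: symmetric about 0, within [-2, 2]."""
        draws = sample_rates(10_000, seed=4)
        logs = np.log10([r["kb5"] / r["kd5"] for r in draws])
        assert np.all(np.abs(logs) <= 2.0)
        assert abs(np.mean(logs)) < 0.05
        assert abs(np.mean(logs < 0) - 0.5) < 0.02

    def test_range_is_configurable(self):
        cfg = SamplingConfig(low=0.5, high=2.0)
        draws = sample_rates(200, seed=0, sampling=cfg)
        arr = np.concatenate([r.as_array() for r in draws])
        arr = arr[arr > 0]
        assert arr.min() >= 0.5 and arr.max() <= 2.0


class TestRunScreen:
    def test_small_screen_counts_and_ratios(self, screen_config):
        design = ScreenDesign(cvs=concentration_grid()[:4],
                              krvs=sample_rates(2, seed=7),
                              topologies=("none",))
        summ = run_screen(design, screen_config, full=True)
        assert len(summ.records) == 4 * 2
        cell = summ.cell_summary
        assert (cell["N_ultrasensitive"] <= cell["N_responsive"]).all()
        assert (cell["N_bistable"] <= cell["N_responsive"]).all()
        assert (cell["N_responsive"] <= cell["N_total"]).all()

    def test_unresponsive_cell_reports_null_ratios(self, screen_config):
        """0/0 ratios are null, never 0."""
        dead = KineticRates({n: (0.0 if n in ("ka_in", "kf") else 1.0)
                             for n in RATE_NAMES})
        design = ScreenDesign(cvs=concentration_grid()[:2], krvs=[dead],
                              topologies=("none",))
        summ = run_screen(design, screen_config, full=True)
        cell = summ.cell_summary
        assert (cell["r_EA"] == 0.0).all()
        assert cell["r_SU"].isna().all()
        assert cell["r_BI"].isna().all()

    def test_screen_resumable_from_records(self, screen_config, tmp_path):
        design = ScreenDesign(cvs=concentration_grid()[:3],
                              krvs=sample_rates(1, seed=5),
                              topologies=("none",))
        path = tmp_path / "records.csv"
        first = run_screen(design, screen_config, full=False,
                           records_path=path)
        # resume with a superset design: only new cells are evaluated
        design2 = ScreenDesign(cvs=concentration_grid()[:5],
                               krvs=design.krvs, topologies=("none",))
        second = run_screen(design2, screen_config, full=False,
                            records_path=path)
        assert len(second.records) == 5
        merged = second.records.set_index("cv_id")
        for cv_id in (1, 2, 3):
            assert merged.loc[cv_id, "o_max"] == pytest.approx(
                first.records.set_index("cv_id").loc[cv_id, "o_max"])


class TestRobustRateVectors:
    @staticmethod
    def _table(pattern: dict[int, int]) -> pd.DataFrame:
        rows = []
        for krv_id, n_resp in pattern.items():
            for cv_id in range(1, 37):
                rows.append({"krv_id": krv_id, "cv_id": cv_id,
                             "topology": "none",
                             "responsive": cv_id <= n_resp})
        return pd.DataFrame(rows)

    def test_strict_threshold_and_brute_force_agreement(self):
        pattern = {0: 36, 1: 31, 2: 30, 3: 29, 4: 0}
        tbl = self._table(pattern)
        got = robust_rate_vectors(tbl, min_cases=30)
        brute = [k for k, n in pattern.items() if n > 30]
        assert got == sorted(brute) == [0, 1]

    def test_incomplete_coverage_raises(self):
        tbl = self._table({0: 36}).iloc[:-3]
        with pytest.raises(MissingCellsError):
            robust_rate_vectors(tbl, min_cases=30)


class TestRatioGrouping:
    def test_empty_input_gives_zero_histogram(self):
        counts = ratio_grouping([], "kb5/kd5")
        assert (counts == 0).all()

    def test_manual_tally(self):
        vecs = []
        ratios = [0.05, 0.3, 0.3, 1.0, 3.0, 3.0, 3.0, 30.0, 99.0, 0.011]
        for rho in ratios:
            vals = {n: 1.0 for n in RATE_NAMES}
            vals["kb5"] = rho
            vals["kd5"] = 1.0
            vecs.append(KineticRates(vals))
        counts = ratio_grouping(vecs, "kb5/kd5")
        assert counts.sum() == len(ratios)
        # half-decade bins, indexed by left edge on the log10 scale
        assert counts.loc[-2.0] == 1   # 0.011 (log10 ~ -1.96)
        assert counts.loc[-1.5] == 1   # 0.05  (log10 ~ -1.30)
        assert counts.loc[-1.0] == 2   # 0.3 twice (log10 ~ -0.52)
        assert counts.loc[0.0] == 4    # 1.0 and 3.0 x3 (log10 0 and ~0.48)
        assert counts.loc[1.0] == 1    # 30.0 (log10 ~ 1.48)
        assert counts.loc[1.5] == 1    # 99.0 (log10 ~ 2.0)

    def test_single_rate_selector(self):
        vals = {n: 1.0 for n in RATE_NAMES}
        vals["k3"] = 0.2
        counts = ratio_grouping([KineticRates(vals)], "k3")
        assert counts.sum() == 1
        assert counts.loc[-1.0] == 1  # log10(0.2) ~ -0.7

    def test_unknown_selector_rejected(self):
        with pytest.raises(UnknownSelectorError):
            ratio_grouping([], "kb9/kd9")
        with pytest.raises(UnknownSelectorError):
            ratio_grouping([], "nope")


class TestGroupByGradient:
    def test_boundary_conventions(self):
        class R:
            def __init__(self, g):
                self.gradient = g
        reports = [R(0.5), R(1.0), R(5.0), R(10.0), R(100.0), R(101.0)]
        groups = group_by_gradient(reports)
        assert [r.gradient for r in groups["low"]] == [5.0, 10.0]
        assert [r.gradient for r in groups["medium"]] == [100.0]
        assert [r.gradient for r in groups["high"]] == [101.0]


class TestMapkkScan:
    def test_pearson_matches_textbook_formula(self, rng):
        from mapkscreen.sampling import _pearson
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        n = len(x)
        manual = ((n * np.sum(x * y) - np.sum(x) * np.sum(y))
                  / np.sqrt((n * np.sum(x * x) - np.sum(x) ** 2)
                            * (n * np.sum(y * y) - np.sum(y) ** 2)))
        assert _pearson(x, y) == pytest.approx(manual, rel=1e-12)

    def test_gradient_rises_with_mapkk_total(self, fixture_catalog,
                                             screen_config):
        """More MAPKK -> steeper response (positive correlation)."""
        fix = fixture_catalog["ultrasensitive"]
        net = build_network(fix.topology)
        res = mapkk_scan(net, fix.rates, fix.cv, [0.2, 0.5, 1.0, 2.0, 5.0],
                         screen_config, SCREEN_SOLVER)
        assert res.corr_gradient > 0.5
        assert np.all(np.diff(res.gradients) > 0)

    def test_rejects_too_few_values(self, fixture_catalog):
        fix = fixture_catalog["ultrasensitive"]
        net = build_network(fix.topology)
        with pytest.raises(ValueError):
            mapkk_scan(net, fix.rates, fix.cv, [0.5, 1.0, 2.0])

    def test_unresponsive_scan_reports_insufficient_data(self,
                                                         fixture_catalog,
                                                         screen_config):
        fix = fixture_catalog["quiescent"]
        net = build_network(fix.topology)
        with pytest.raises(InsufficientDataError), pytest.warns(UserWarning):
            mapkk_scan(net, fix.rates, fix.cv, [0.2, 0.5, 1.0, 2.0, 5.0],
                       screen_config, SCREEN_SOLVER)
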
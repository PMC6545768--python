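"""Grid search, increase rate, rank statistics, and full-condition runs."""

import numpy as np
import pytest

from fdbci import (
    FilterConfig,
    WindowSpec,
    compare_techniques,
    grid_search,
    improvement_test,
    increase_rate,
    run_condition,
)
from fdbci.classification import InsufficientTrialsError
from fdbci.evaluation import plot_band_curves, select_best_config
from fdbci.synthetic import SyntheticConfig, generate_study

SMALL_WINDOW = WindowSpec(1.0, 0.5)
TINY_GRID = dict(widths=(10, 20), f_low_stride=8)


class TestIncreaseRate:
    def test_direct_arithmetic(self):
        assert increase_rate(0.50, 0.60) == pytest.approx(20.0)
        assert increase_rate(0.61, 0.61) == 0.0
        # published-table-style rounded cells give ~4.6 percent
        assert increase_rate(0.65, 0.68) == pytest.approx(4.62, abs=0.01)

    def test_sign_and_zero_behaviour(self):
        assert increase_rate(0.5, 0.4) < 0
        with pytest.raises(ValueError, match="positive"):
            increase_rate(0.0, 0.5)


class TestSelectionRule:
    def test_maximum_wins(self):
        entries = [(FilterConfig(8, 10), 0.7), (FilterConfig(4, 20), 0.8),
                   (FilterConfig(1, 10), 0.6)]
        assert select_best_config(entries) == FilterConfig(4, 20)

    def test_ties_break_to_smaller_width_then_lower_cutoff(self):
        entries = [(FilterConfig(4, 20), 0.8), (FilterConfig(8, 10), 0.8),
                   (FilterConfig(2, 10), 0.8)]
        assert select_best_config(entries) == FilterConfig(2, 10)


class TestCompareTechniques:
    def test_identical_groups_are_degenerate_without_flags(self):
        g = np.full(30, 0.6)
        out = compare_techniques({"higuchi": g, "katz": g, "ar": g})
        assert out.degenerate and not out.significant
        assert not any(out.flagged.values())

    def test_type_one_error_calibrated_on_independent_groups(self):
        rng = np.random.default_rng(81)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {t: rng.normal(0.6, 0.05, size=30) for t in ("a", "b", "c")}
            rejections += compare_techniques(groups).significant
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_shifted_group_detected_and_others_flagged(self):
        rng = np.random.default_rng(82)
        groups = {
            "higuchi": rng.normal(0.8, 0.03, size=30),
            "katz": rng.normal(0.5, 0.03, size=30),
            "ar": rng.normal(0.5, 0.03, size=30),
        }
        out = compare_techniques(groups)
        assert out.pvalue < 1e-3 and out.best == "higuchi"
        assert out.flagged["katz"] and out.flagged["ar"] and not out.flagged["higuchi"]

    def test_unequal_group_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            compare_techniques({"a": np.zeros(30), "b": np.zeros(29), "c": np.zeros(30)})


class TestImprovementTest:
    def test_identical_groups_not_significant(self):
        g = np.full(30, 0.6)
        p, significant = improvement_test(g, g)
        assert p == 1.0 and not significant

    def test_null_rejection_rate_within_alpha(self):
        rng = np.random.default_rng(83)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            _, sig = improvement_test(rng.normal(0.6, 0.05, 30), rng.normal(0.6, 0.05, 30))
            rejections += sig
        assert rejections / n_sim <= 0.02

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(84)
        p, significant = improvement_test(rng.normal(0.55, 0.04, 30),
                                          rng.normal(0.70, 0.04, 30))
        assert significant and p < 1e-3


class TestGridSearch:
    def test_selected_band_beats_or_ties_classical(self, small_study):
        day1, day2 = small_study
        gs = grid_search(day1, day2, "higuchi", SMALL_WINDOW, seed=3, **TINY_GRID)
        assert gs.reduced
        assert gs.selected_mean >= gs.classical_result.mean
        assert len(gs.entries) == len(set(map(tuple, gs.entries[["f_low", "width"]].values)))

    def test_planted_band_recovered(self, small_study):
        day1, day2 = small_study
        gs = grid_search(day1, day2, "higuchi", SMALL_WINDOW, seed=4,
                         widths=(10, 20), f_low_stride=4)
        assert gs.selected.f_low <= 12 and gs.selected.f_high >= 8

    def test_underdetermined_configurations_reported(self):
        cfg = SyntheticConfig(n_channels=8, trials_per_class_per_session=5,
                              trial_seconds=2.0, erd_channels=(1,), seed=85)
        day1, day2 = generate_study(cfg)
        # AR features have d = 16 > 2 * floor(0.7 * 5): nothing is evaluable
        with pytest.raises(InsufficientTrialsError):
            grid_search(day1, day2, "ar", SMALL_WINDOW, seed=1, **TINY_GRID)

    def test_plot_export(self, small_study):
        import matplotlib

        matplotlib.use("Agg")
        day1, day2 = small_study
        gs = grid_search(day1, day2, "higuchi", SMALL_WINDOW, seed=6,
                         widths=(10,), f_low_stride=16)
        ax = plot_band_curves(gs)
        assert ax.get_xlabel().startswith("low cutoff")


class TestRunCondition:
    @staticmethod
    def _study():
        cfg = SyntheticConfig(n_channels=8, trials_per_class_per_session=24,
                              trial_seconds=2.0, erd_channels=(1, 3, 5), seed=90)
        return generate_study(cfg)

    def test_condition_roles(self):
        day1, day2 = self._study()
        kw = dict(techniques=("higuchi",), window=SMALL_WINDOW, seed=1, **TINY_GRID)
        a = run_condition(day1, day2, "A", **kw)
        b = run_condition(day1, day2, "B", **kw)
        assert a.train_session == "day1" and a.test_session == "day2"
        assert b.train_session == "day2" and b.test_session == "day1"
        with pytest.raises(ValueError, match="condition"):
            run_condition(day1, day2, "C", **kw)

    def test_outputs_reproducible_byte_for_byte(self, tmp_path):
        day1, day2 = self._study()
        kw = dict(techniques=("higuchi", "katz"), window=SMALL_WINDOW, seed=2, **TINY_GRID)
        run_condition(day1, day2, "A", out_dir=tmp_path / "run1", **kw)
        run_condition(day1, day2, "A", out_dir=tmp_path / "run2", **kw)
        names = [p.name for p in sorted((tmp_path / "run1").iterdir())]
        assert "accuracy_classical.csv" in names and "stats.csv" in names
        for name in names:
            assert (tmp_path / "run1" / name).read_bytes() == \
                   (tmp_path / "run2" / name).read_bytes()

    def test_strong_effect_gives_gain_and_significance(self):
        day1, day2 = self._study()
        report = run_condition(day1, day2, "A", techniques=("higuchi", "katz", "ar"),
                               window=SMALL_WINDOW, seed=3, **TINY_GRID)
        hig = report.outcomes["higuchi"]
        assert hig.optimal.mean > hig.classical.mean
        assert hig.increase_rate > 0
        assert hig.improvement_significant
        # katz has little leverage on this waveform family: the comparison
        # must separate it from the winning technique
        assert report.stats.kw_optimal.significant
        assert report.stats.kw_optimal.best in ("higuchi", "ar")
        assert report.stats.kw_optimal.flagged["katz"]

    def test_tables_validate(self):
        day1, day2 = self._study()
        report = run_condition(day1, day2, "A", techniques=("higuchi",),
                               window=SMALL_WINDOW, seed=4, **TINY_GRID)
        report.classical_table().validate()
        report.optimal_table().validate()
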
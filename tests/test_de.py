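"""Normalisation, per-ZT tests, fold-change tiers, ANOVA and amplitude ratios."""

import numpy as np
import pandas as pd
import pytest

from zeitgeber.cosinor import TimePointSeries
from zeitgeber.de import (
    amplitude_ratio,
    fold_change_screen,
    normalize_to_reference,
    phase_cluster_summary,
    platform_correlation,
    ratio_from_p2t,
    rescale_relative,
    timepoint_tests,
    twoway_anova_tukey,
)
from zeitgeber.jtk import RhythmCall, classify_ccg
from zeitgeber.simulate import ExperimentDesign, RhythmParams, simulate_timecourse


def _long(analytes, treatments=("control", "alcohol"), zts=(0.0, 12.0), reps=3):
    rows = []
    for a, vals in analytes.items():
        for t in treatments:
            for z in zts:
                for r in range(1, reps + 1):
                    rows.append({"analyte": a, "treatment": t, "zt": z, "replicate": r,
                                 "value": vals[t] * (1 + 0.01 * r + 0.02 * (z > 0))})
    return pd.DataFrame(rows)


class TestNormalize:
    def test_unit_reference_is_identity(self):
        df = _long({"g": {"control": 2.0, "alcohol": 3.0}, "18S": {"control": 1.0, "alcohol": 1.0}})
        # make the reference exactly 1 for every sample
        df.loc[df.analyte == "18S", "value"] = 1.0
        out = normalize_to_reference(df)
        assert "18S" not in set(out.analyte)
        ref = df[df.analyte == "g"].reset_index(drop=True)
        np.testing.assert_allclose(out["value"], ref["value"])

    def test_common_scaling_cancels(self):
        df = _long({"g": {"control": 2.0, "alcohol": 3.0}, "18S": {"control": 0.5, "alcohol": 0.8}})
        out1 = normalize_to_reference(df)
        df2 = df.copy()
        df2["value"] *= 2.0
        out2 = normalize_to_reference(df2)
        np.testing.assert_allclose(out1["value"], out2["value"])

    def test_hand_computed_toy(self):
        df = pd.DataFrame({
            "analyte": ["g", "g", "18S", "18S"],
            "treatment": ["control"] * 4,
            "zt": [0.0, 0.0, 0.0, 0.0],
            "replicate": [1, 2, 1, 2],
            "value": [6.0, 9.0, 2.0, 3.0],
        })
        out = normalize_to_reference(df)
        np.testing.assert_allclose(sorted(out["value"]), [3.0, 3.0])

    def test_missing_reference_sample_named(self):
        df = _long({"g": {"control": 2.0, "alcohol": 3.0}, "18S": {"control": 1.0, "alcohol": 1.0}})
        df = df[~((df.analyte == "18S") & (df.treatment == "alcohol") & (df.replicate == 2))]
        with pytest.raises(KeyError, match="alcohol"):
            normalize_to_reference(df)


class TestRescale:
    def test_minimum_per_zt_mean_becomes_one(self):
        rng = np.random.default_rng(3)
        zt = np.repeat([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 4)
        c = TimePointSeries("g", "control", zt, rng.lognormal(1.0, 0.3, zt.size))
        a = TimePointSeries("g", "alcohol", zt, rng.lognormal(1.4, 0.3, zt.size))
        rc, ra = rescale_relative(c, a)
        mins = [s.values[s.zt == z].mean() for s in (rc, ra) for z in np.unique(s.zt)]
        assert min(mins) == pytest.approx(1.0, abs=1e-12)

    def test_known_scale_divides_through(self):
        zt = np.repeat([0.0, 12.0], 2)
        c = TimePointSeries("g", "control", zt, np.array([4.0, 4.0, 8.0, 8.0]))
        a = TimePointSeries("g", "alcohol", zt, np.array([6.0, 6.0, 12.0, 12.0]))
        rc, _ = rescale_relative(c, a)
        np.testing.assert_allclose(rc.values, [1.0, 1.0, 2.0, 2.0])


class TestTimepointTests:
    def test_identical_groups_give_p_one(self):
        zt = np.repeat([0.0, 12.0], 3)
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        p = timepoint_tests(TimePointSeries("g", "c", zt, vals), TimePointSeries("g", "a", zt, vals.copy()))
        assert p[0.0] == pytest.approx(1.0)
        assert p[12.0] == pytest.approx(1.0)

    def test_hand_three_vs_three_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        zt = np.repeat([0.0, 12.0], 3)
        p = timepoint_tests(TimePointSeries("g", "c", zt, x), TimePointSeries("g", "a", zt, y))[0.0]
        x0, y0 = x[:3], y[:3]
        sp2 = ((x0.size - 1) * x0.var(ddof=1) + (y0.size - 1) * y0.var(ddof=1)) / (x0.size + y0.size - 2)
        t_stat = (y0.mean() - x0.mean()) / np.sqrt(sp2 * (1 / x0.size + 1 / y0.size))
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_stat), 4), rel=1e-12)

    def test_one_tailed_direction_halves_p_when_concordant(self):
        rng = np.random.default_rng(0)
        zt = np.repeat([0.0, 12.0], 5)
        x = np.concatenate([rng.normal(1.0, 0.1, 5), rng.normal(1.0, 0.1, 5)])
        y = np.concatenate([rng.normal(1.5, 0.1, 5), rng.normal(1.0, 0.1, 5)])
        c, a = TimePointSeries("g", "c", zt, x), TimePointSeries("g", "a", zt, y)
        p_two = timepoint_tests(c, a)[0.0]
        p_one = timepoint_tests(c, a, one_tailed_zts={0.0: "greater"})[0.0]
        assert p_one == pytest.approx(p_two / 2, rel=1e-9)

    def test_power_at_planted_mesor_shift(self):
        hits = 0
        runs = 100
        for i in range(runs):
            d = ExperimentDesign(n_per_cell=5, seed=30_000 + i)
            tab = simulate_timecourse(d, {
                ("g", "control"): RhythmParams(1.0, noise_cv=0.1),
                ("g", "alcohol"): RhythmParams(2.2, noise_cv=0.1),
            })
            c = TimePointSeries.from_timecourse(tab, "g", "control")
            a = TimePointSeries.from_timecourse(tab, "g", "alcohol")
            p = timepoint_tests(c, a)
            hits += all(v < 0.05 for v in p.values())
        assert hits / runs >= 0.90


class TestFoldChangeScreen:
    def test_boundary_tiers(self):
        assert fold_change_screen(
            _long({"g": {"control": 1.0, "alcohol": 2.0}}), p_values={"g": 0.01}
        )[0][0].tier == "strong"
        rec = fold_change_screen(
            _long({"g": {"control": 1.0, "alcohol": 0.6}}), p_values={"g": 0.01}
        )[0][0]
        assert rec.direction == "down"
        assert rec.tier == "moderate"
        assert rec.magnitude == pytest.approx(1 / 0.6)

    def test_planted_tiers_recovered_exactly_without_noise(self):
        rng = np.random.default_rng(1)
        design = ExperimentDesign(zts=(2.5,), n_per_cell=4, seed=5)
        params = {}
        planted = {"strong": 10, "moderate": 15}
        idx = 0
        for _ in range(planted["strong"]):
            params[(f"g{idx:03d}", "control")] = RhythmParams(1.0)
            params[(f"g{idx:03d}", "alcohol")] = RhythmParams(2.5)
            idx += 1
        for _ in range(planted["moderate"]):
            params[(f"g{idx:03d}", "control")] = RhythmParams(1.0)
            params[(f"g{idx:03d}", "alcohol")] = RhythmParams(1.7)
            idx += 1
        for _ in range(75):
            level = float(rng.uniform(0.5, 2.0))
            params[(f"g{idx:03d}", "control")] = RhythmParams(level)
            params[(f"g{idx:03d}", "alcohol")] = RhythmParams(level)
            idx += 1
        table = simulate_timecourse(design, params)
        _, counts = fold_change_screen(table)
        assert counts.loc["strong", "up"] == planted["strong"]
        assert counts.loc["moderate", "up"] == planted["moderate"]
        assert counts.loc["strong", "down"] == 0
        assert counts.loc["moderate", "down"] == 0

    def test_tiers_are_disjoint_and_counts_add_up(self):
        rng = np.random.default_rng(8)
        design = ExperimentDesign(zts=(2.5,), n_per_cell=5, seed=9)
        params = {}
        for i in range(40):
            fc = float(rng.uniform(0.3, 3.0))
            params[(f"g{i:02d}", "control")] = RhythmParams(1.0, noise_cv=0.1)
            params[(f"g{i:02d}", "alcohol")] = RhythmParams(fc, noise_cv=0.1)
        records, counts = fold_change_screen(simulate_timecourse(design, params))
        tiered = [r for r in records if r.tier is not None]
        assert counts.to_numpy().sum() == len(tiered)
        for rec in tiered:
            assert rec.p_value < 0.05
            assert rec.magnitude >= 1.5


class TestAnova:
    def test_toy_sums_of_squares_match_brute_force(self):
        df = pd.DataFrame({
            "zt": [0, 0, 0, 0, 12, 12, 12, 12],
            "treatment": ["c", "c", "a", "a"] * 2,
            "value": [1.0, 2.0, 3.0, 5.0, 2.0, 4.0, 7.0, 9.0],
        })
        res = twoway_anova_tukey(df, transform="none")
        # brute-force cell/marginal means oracle
        v = df["value"]
        grand = v.mean()
        ss_time = sum(4 * (df[df.zt == z].value.mean() - grand) ** 2 for z in (0, 12))
        ss_treat = sum(4 * (df[df.treatment == t].value.mean() - grand) ** 2 for t in ("c", "a"))
        ss_cells = sum(
            2 * (df[(df.zt == z) & (df.treatment == t)].value.mean() - grand) ** 2
            for z in (0, 12) for t in ("c", "a")
        )
        ss_int = ss_cells - ss_time - ss_treat
        assert res.table.loc["Time", "sum_sq"] == pytest.approx(ss_time)
        assert res.table.loc["Treatment", "sum_sq"] == pytest.approx(ss_treat)
        assert res.table.loc["Interaction", "sum_sq"] == pytest.approx(ss_int)
        ms_resid = res.table.loc["Residual", "sum_sq"] / res.table.loc["Residual", "df"]
        assert res.table.loc["Treatment", "F"] == pytest.approx(ss_treat / ms_resid)
        assert set(res.tukey_pairs) == {0.0, 12.0}

    def test_planted_interaction_detected(self):
        hits = 0
        runs = 100
        for i in range(runs):
            d = ExperimentDesign(n_per_cell=5, seed=70_000 + i)
            tab = simulate_timecourse(d, {
                ("g", "control"): RhythmParams(1.0, noise_cv=0.15),
                # effect confined to mid/late day (ZT8, ZT12): a phase-locked bump
                ("g", "alcohol"): RhythmParams(1.4, ((1, 0.6, 10.0),), noise_cv=0.15),
            })
            res = twoway_anova_tukey(tab, compute_tukey=False)
            hits += res.p("Interaction") < 0.05
        assert hits / runs >= 0.90

    def test_lognormal_values_trigger_log_transform(self):
        d = ExperimentDesign(n_per_cell=6, seed=3)
        tab = simulate_timecourse(d, {
            ("g", "control"): RhythmParams(1.0, noise_cv=0.8),
            ("g", "alcohol"): RhythmParams(1.0, noise_cv=0.8),
        })
        res = twoway_anova_tukey(tab)
        assert res.transform_applied in {"log", "sqrt", "none"}
        # heavy multiplicative noise is very non-normal on the raw scale
        assert res.transform_applied != "none"

    def test_missing_cell_raises(self):
        df = pd.DataFrame({
            "zt": [0, 0, 12, 12], "treatment": ["c", "c", "c", "c"], "value": [1.0, 2.0, 3.0, 4.0]
        })
        with pytest.raises(ValueError, match="cell"):
            twoway_anova_tukey(df)


class TestAmplitudeRatio:
    def test_identical_series_ratio_one(self):
        zt = np.repeat([0.0, 8.0, 16.0], 2)
        vals = np.array([1.0, 1.2, 3.0, 3.2, 2.0, 2.2])
        c = TimePointSeries("g", "control", zt, vals)
        a = TimePointSeries("g", "alcohol", zt, vals.copy())
        assert amplitude_ratio(c, a).ratio == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        zt = np.repeat([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 3)
        c = TimePointSeries("g", "control", zt, rng.lognormal(0, 0.4, zt.size))
        a = TimePointSeries("g", "alcohol", zt, rng.lognormal(0.5, 0.4, zt.size))
        base = amplitude_ratio(c, a)
        c2 = TimePointSeries("g", "control", zt, 7.3 * c.values)
        a2 = TimePointSeries("g", "alcohol", zt, 7.3 * a.values)
        scaled = amplitude_ratio(c2, a2)
        assert scaled.ratio == base.ratio
        assert scaled.control_p2t == pytest.approx(base.control_p2t)

    def test_rounding_is_half_up(self):
        assert ratio_from_p2t(38.5, 8.0) == 0.2
        assert ratio_from_p2t(5.9, 6.2) == 1.1  # per1 row: 6.2/5.9 = 1.0508
        assert ratio_from_p2t(2.0, 0.5) == 0.3  # 0.25 rounds up, not to even


class TestPhaseClusterSummary:
    def _call(self, analyte, q, period, phase):
        return classify_ccg(RhythmCall(analyte, 0.9, 0.001, 0.01, period, phase, q_value=q))

    def test_non_ccgs_yield_empty_summary(self):
        recs, _ = fold_change_screen(_long({"g": {"control": 1.0, "alcohol": 3.0}}), p_values={"g": 0.01})
        cont, hist = phase_cluster_summary(recs, [self._call("g", 0.5, 24.0, 9.0)])
        assert cont.to_numpy().sum() == 0
        assert hist.to_numpy().sum() == 0

    def test_single_day_peaking_up_ccg(self):
        recs, _ = fold_change_screen(_long({"g": {"control": 1.0, "alcohol": 3.0}}), p_values={"g": 0.01})
        cont, hist = phase_cluster_summary(recs, [self._call("g", 0.05, 24.0, 9.0)])
        assert cont.loc["up", "day"] == 1
        assert cont.to_numpy().sum() == 1
        assert hist.loc["up", "ZT8-12"] == 1

    def test_planted_phase_windows_dominate_histogram(self):
        analytes = {}
        calls = []
        rng = np.random.default_rng(4)
        for i in range(30):
            name = f"u{i}"
            analytes[name] = {"control": 1.0, "alcohol": 3.0}
            calls.append(self._call(name, 0.01, 24.0, float(rng.uniform(8, 16))))
        for i in range(30):
            name = f"d{i}"
            analytes[name] = {"control": 3.0, "alcohol": 1.0}
            calls.append(self._call(name, 0.01, 24.0, float(rng.uniform(20, 28) % 24)))
        recs, _ = fold_change_screen(_long(analytes), p_values={a: 0.01 for a in analytes})
        _, hist = phase_cluster_summary(recs, calls)
        up = hist.loc["up"]
        down = hist.loc["down"]
        assert up[["ZT8-12", "ZT12-16"]].sum() == 30
        assert down[["ZT20-24", "ZT0-4"]].sum() == 30


def test_platform_correlation_on_matched_vectors():
    x = np.array([1.2, 2.0, 0.5, 3.1, 0.8])
    r, p = platform_correlation(x, 2.0 * x + 0.1)
    assert r == pytest.approx(1.0)
    assert p < 0.01
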
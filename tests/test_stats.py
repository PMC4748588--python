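"""γH2AX normalization, growth fitting, split-plot and one-way ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hcscreen.gating import MissingControlError
from hcscreen.layout import make_row_layout
from hcscreen.stats import (DesignError, fit_growth, holm_adjust,
                            one_way_anova_and_sem, plate_column_adjust,
                            row_normalize_gamma, split_plot_interaction)

TIMES = [0.0, 1.0, 2.0, 6.0, 24.0, 48.0]


def _gamma_cells(layout, values_by_well):
    rows = []
    for well, vals in values_by_well.items():
        for i, v in enumerate(vals):
            rows.append({"plate": "P1", "well": well, "cell_id": i,
                         "total_gH2AX": v})
    return pd.DataFrame(rows)


class TestRowNormalize:
    def test_subtracts_control_mean(self):
        layout = make_row_layout(n_replicates=1)
        cells = _gamma_cells(layout, {"A1": [25.0, 30.0],
                                      "A2": [10.0, 10.0]})  # A2 is control
        out = row_normalize_gamma(cells, layout)
        exp = out[out["well"] == "A1"]["gamma_row_norm"]
        assert list(exp) == [15.0, 20.0]

    def test_null_case_centred_on_zero(self):
        rng = np.random.default_rng(0)
        layout = make_row_layout(n_replicates=3)
        vals = {w: rng.normal(50, 5, 400)
                for w in layout.wells["well"]}
        out = row_normalize_gamma(_gamma_cells(layout, vals), layout)
        exp = out[~out["is_control"]]["gamma_row_norm"]
        # SE of the normalized mean includes the control-mean uncertainty
        n_ctrl = (out["is_control"]).sum()
        se = np.sqrt(exp.var() / len(exp) + exp.var() / n_ctrl)
        assert abs(exp.mean()) < 2 * se

    def test_invariant_to_whole_row_offset(self):
        rng = np.random.default_rng(1)
        layout = make_row_layout(n_replicates=2)
        base = {w: rng.normal(50, 5, 300) for w in layout.wells["well"]}
        out0 = row_normalize_gamma(_gamma_cells(layout, base), layout)
        shifted = {w: v + 50.0 for w, v in base.items()}
        out1 = row_normalize_gamma(_gamma_cells(layout, shifted), layout)
        assert np.allclose(out0["gamma_row_norm"], out1["gamma_row_norm"])

    def test_missing_control_rejected(self):
        layout = make_row_layout(n_replicates=2)
        cells = _gamma_cells(layout, {"A1": [1.0] * 3, "A2": [2.0] * 3})
        layout.wells.loc[layout.wells["well"] == "A3", "is_control"] = False
        with pytest.raises(MissingControlError):
            row_normalize_gamma(cells, layout)


def _plate_frame(rng, plate_effects=None, col_effects=None, n_cells=60):
    plate_effects = plate_effects or {"P1": 0.0, "P2": 0.0}
    col_effects = col_effects or {}
    rows = []
    for plate, eff in plate_effects.items():
        for col in range(1, 6):
            for t in (0.0, 24.0):
                for i in range(n_cells):
                    rows.append({
                        "plate": plate, "well": f"A{col}", "column": col,
                        "time_h": t,
                        "gamma_row_norm": rng.normal(0, 1) + eff
                        + col_effects.get(col, 0.0),
                    })
    return pd.DataFrame(rows)


class TestPlateColumnAdjust:
    def test_removes_injected_plate_effect(self):
        rng = np.random.default_rng(2)
        df = _plate_frame(rng, plate_effects={"P1": 0.0, "P2": 5.0})
        adj = plate_column_adjust(df)
        t0 = adj[adj["time_h"] == 0.0]
        means = t0.groupby("plate")["gamma_adjusted"].mean()
        assert abs(means["P1"] - means["P2"]) < 0.5

    def test_recovers_injected_column_gradient(self):
        rng = np.random.default_rng(3)
        grad = {c: v for c, v in zip(range(1, 6), (-3.0, -1.5, 0.0, 1.5, 3.0))}
        df = _plate_frame(rng, col_effects=grad)
        adj = plate_column_adjust(df)
        est = (adj["gamma_row_norm"] - adj["gamma_adjusted"]) \
            .groupby(adj["column"]).mean()
        injected = pd.Series(grad)
        assert np.corrcoef(est[injected.index], injected)[0, 1] > 0.95

    def test_near_identity_without_effects(self):
        rng = np.random.default_rng(4)
        df = _plate_frame(rng)
        adj = plate_column_adjust(df)
        t0 = df[df["time_h"] == 0.0]["gamma_row_norm"]
        se = t0.std() / np.sqrt(len(t0))
        shift = (adj["gamma_adjusted"] - adj["gamma_row_norm"]).abs()
        assert (shift < 2 * max(se, 0.05) * 10).all()
        assert shift.max() < 0.5  # small on this design

    def test_preserves_within_well_ordering(self):
        rng = np.random.default_rng(5)
        df = _plate_frame(rng, plate_effects={"P1": 0.0, "P2": 3.0})
        adj = plate_column_adjust(df)
        for (_, _), grp in adj.groupby(["plate", "well"]):
            order_before = np.argsort(grp["gamma_row_norm"].to_numpy())
            order_after = np.argsort(grp["gamma_adjusted"].to_numpy())
            assert np.array_equal(order_before, order_after)

    def test_plate_without_time_zero_named(self):
        rng = np.random.default_rng(6)
        df = _plate_frame(rng)
        df = df[~((df["plate"] == "P2") & (df["time_h"] == 0.0))]
        with pytest.raises(DesignError, match="P2"):
            plate_column_adjust(df)


class TestFitGrowth:
    def test_noiseless_exponential_recovered_exactly(self):
        counts = [100 * 2 ** (t / 24.0) for t in TIMES]
        fit = fit_growth(counts, TIMES)
        assert fit.a == pytest.approx(np.log2(100), rel=1e-12)
        assert fit.b == pytest.approx(1 / 24.0, rel=1e-12)
        assert fit.doubling_time_h == pytest.approx(24.0, rel=1e-12)
        assert fit.doubling_time_legacy_convention == \
            pytest.approx(2 ** (1 / 24.0))
        assert np.allclose(fit.predict_count(np.array(TIMES)), counts)

    def test_constant_counts_no_doubling_time(self):
        fit = fit_growth([500.0] * 6, TIMES)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(fit.doubling_time_h)

    def test_noisy_doubling_time_within_2h(self):
        rng = np.random.default_rng(7)
        times, counts = [], []
        for t in TIMES:
            for _ in range(5):  # replicate wells
                times.append(t)
                counts.append(200 * 2 ** (t / 20.0)
                              * rng.lognormal(0.0, 0.05))
        fit = fit_growth(counts, times)
        assert 18.0 <= fit.doubling_time_h <= 22.0

    def test_zero_counts_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_growth([100, 0, 200, 400], [0, 1, 24, 48])
        assert fit.n_points == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(DesignError):
            fit_growth([10, 20], [0, 24])


def _splitplot_data(rng, slopes, noise=2.0, n_wells=5):
    rows = []
    for plate, slope in slopes.items():
        for t in TIMES:
            for _ in range(n_wells):
                rows.append({"plate": plate, "time_h": t,
                             "proportion": 30 + slope * t
                             + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestSplitPlot:
    def test_power_at_3x_slope_standard_error(self):
        rng = np.random.default_rng(8)
        noise, n_wells = 2.0, 5
        t = np.repeat(TIMES, n_wells).astype(float)
        sxx = ((t - t.mean()) ** 2).sum()
        se_diff = noise * np.sqrt(2.0 / sxx)
        delta = 3.0 * se_diff
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            data = _splitplot_data(rng, {"P0": 0.1, "P5": 0.1 + delta},
                                   noise=noise, n_wells=n_wells)
            hits += split_plot_interaction(data).p_value < 0.05
        assert hits / n_sim > 0.8

    def test_single_treatment_rejected(self):
        rng = np.random.default_rng(9)
        data = _splitplot_data(rng, {"P0": 0.1})
        with pytest.raises(DesignError):
            split_plot_interaction(data)

    def test_stratified_by_phenotype(self):
        rng = np.random.default_rng(10)
        frames = []
        for ph in ("DN", "DP"):
            d = _splitplot_data(rng, {"P0": 0.1, "P5": 0.1})
            d["phenotype"] = ph
            frames.append(d)
        results = split_plot_interaction(pd.concat(frames),
                                         phenotype_column="phenotype")
        assert sorted(r.phenotype for r in results) == ["DN", "DP"]
        for r in results:
            assert 0.0 <= r.p_value <= 1.0


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        f, p, _ = one_way_anova_and_sem({"a": [1.0, 2.0, 3.0],
                                         "b": [1.0, 2.0, 3.0]})
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_anova_table(self):
        # groups {1,2,3} vs {11,12,13}: SSB=150 (df 1), SSW=4 (df 4) -> F=150
        f, p, summary = one_way_anova_and_sem({"a": [1, 2, 3],
                                               "b": [11, 12, 13]})
        assert f == pytest.approx(150.0, rel=1e-12)
        assert p == pytest.approx(sps.f.sf(150.0, 1, 4), rel=1e-9)
        assert p == pytest.approx(0.00026, abs=5e-5)
        sem_a = summary.loc[summary["group"] == "a", "sem"].iloc[0]
        assert sem_a == pytest.approx(1.0 / np.sqrt(3))

    def test_sem_example(self):
        _, _, summary = one_way_anova_and_sem(
            {"g": [20, 22, 24, 26, 28], "h": [1.0, 2.0]})
        sem = summary.loc[summary["group"] == "g", "sem"].iloc[0]
        assert sem == pytest.approx(1.4142, abs=1e-3)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(DesignError):
            one_way_anova_and_sem({"a": [1.0]})
        with pytest.raises(DesignError):
            one_way_anova_and_sem({"a": [1.0, 2.0], "b": [3.0]})


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=st.floats(2.0, 12.0), b=st.floats(-0.05, 0.08))
def test_growth_fit_inverts_noiseless_exponential(a, b):
    """Any noiseless exponential is recovered to near machine precision."""
    times = np.array([0.0, 1.0, 2.0, 6.0, 24.0, 48.0])
    counts = 2.0 ** (a + b * times)
    fit = fit_growth(counts, times)
    assert fit.a == pytest.approx(a, rel=1e-9, abs=1e-9)
    assert fit.b == pytest.approx(b, rel=1e-9, abs=1e-9)
    assert np.allclose(fit.predict_count(times), counts, rtol=1e-9)


def test_holm_adjustment_monotone_and_bounded():
    p = [0.001, 0.02, 0.04, 0.5]
    adj = holm_adjust(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.004)
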
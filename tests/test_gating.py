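"""Mixture fitting, control-anchored thresholds, classification, tables."""

import math

import numpy as np
import pandas as pd
import pytest

from hcscreen.gating import (DegenerateFitError, InsufficientDataError,
                             MarkerGate, MissingControlError, MixtureFit,
                             classify_cells, derive_threshold,
                             fit_log_intensity_mixture, fit_normal_mixture,
                             frequency_table, overlap_table, quadrant_label,
                             safe_log, two_normal_crossing)
from hcscreen.layout import make_row_layout


def analytic_crossing(w1, m1, s1, w2, m2, s2):
    """Independent quadratic-root oracle for the two-normal intersection."""
    A = 1.0 / s1**2 - 1.0 / s2**2
    B = 2.0 * (m2 / s2**2 - m1 / s1**2)
    C = m1**2 / s1**2 - m2**2 / s2**2 + 2.0 * math.log((w2 * s1) / (w1 * s2))
    if abs(A) < 1e-15:
        return -C / B
    roots = np.roots([A, B, C])
    roots = roots[np.isreal(roots)].real
    lo, hi = min(m1, m2), max(m1, m2)
    inside = roots[(roots > lo) & (roots < hi)]
    return float(inside.min())


def _gate_from_params(weights, means, sds):
    fit = MixtureFit(np.asarray(weights, float), np.asarray(means, float),
                     np.asarray(sds, float), loglik=0.0, n=1000)
    return MarkerGate(marker="K14", replicate_row="r", fit=fit)


class TestMixtureFit:
    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(2, 0.3, 5000),
                            rng.normal(5, 0.4, 5000)])
        fit = fit_normal_mixture(x, k=2)
        assert abs(fit.means[0] - 2.0) < 0.05
        assert abs(fit.means[1] - 5.0) < 0.05
        assert abs(fit.weights[0] - 0.5) < 0.03

    def test_recovers_minor_component_weight(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(2, 0.3, 9000),
                            rng.normal(5, 0.4, 1000)])
        fit = fit_normal_mixture(x, k=2)
        assert abs(fit.weights[1] - 0.1) < 0.03

    def test_single_population_collapses_gracefully(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3, 0.5, 5000)
        fit = fit_normal_mixture(x, k=2)
        collapsed = (abs(fit.means[1] - fit.means[0]) < x.std()) \
            or min(fit.weights) < 0.05
        assert collapsed

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(2, 0.3, 500), rng.normal(5, 0.4, 500)])
        f1 = fit_normal_mixture(x, 2)
        f2 = fit_normal_mixture(x, 2)
        assert np.array_equal(f1.means, f2.means)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_normal_mixture(np.arange(10.0), 2)
        with pytest.raises(DegenerateFitError):
            fit_normal_mixture(np.full(100, 3.3), 2)

    def test_agrees_with_independent_em_implementation(self):
        # cross-check against scikit-learn's GaussianMixture on the same data
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(2, 0.3, 4000),
                            rng.normal(5, 0.4, 2000)])
        ours = fit_normal_mixture(x, 2)
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             random_state=0, n_init=3).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert np.allclose(ours.means, gm.means_.ravel()[order], atol=0.02)
        assert np.allclose(ours.sds,
                           np.sqrt(gm.covariances_.ravel()[order]),
                           atol=0.02)
        assert np.allclose(ours.weights, gm.weights_[order], atol=0.01)


class TestThreshold:
    def test_matches_analytic_two_normal_intersection(self):
        rng = np.random.default_rng(4)
        gate = _gate_from_params([0.5, 0.5], [2.0, 5.0], [0.3, 0.4])
        ctrl = rng.normal(2.0, 0.3, 2000)
        tau = derive_threshold(gate, ctrl)
        oracle = analytic_crossing(0.5, 2.0, 0.3, 0.5, 5.0, 0.4)
        assert tau == pytest.approx(oracle, abs=1e-6)
        assert gate.null_component_ids == [0]
        # library crossing helper agrees with the in-test oracle
        assert two_normal_crossing(0.5, 2.0, 0.3, 0.5, 5.0, 0.4) == \
            pytest.approx(oracle, abs=1e-9)

    def test_fallback_when_positive_mode_absent(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(3.0, 0.4, 4000)
        gate = fit_log_intensity_mixture(ctrl, k=2)
        tau = derive_threshold(gate, ctrl)
        assert gate.used_fallback
        assert tau == pytest.approx(np.quantile(ctrl, 0.999))
        assert (ctrl > tau).mean() <= 0.0015  # essentially all negative

    def test_multiplicative_shift_moves_tau_by_log_c(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.lognormal(3.0, 0.35, 3000),
                               rng.lognormal(4.6, 0.40, 2000)])
        ctrl = rng.lognormal(3.0, 0.35, 1500)
        c = 2.5

        def tau_for(scale):
            gate = fit_log_intensity_mixture(np.log(vals * scale), k=2)
            return derive_threshold(gate, np.log(ctrl * scale))

        assert tau_for(c) - tau_for(1.0) == pytest.approx(math.log(c),
                                                          abs=1e-6)

    def test_control_required(self):
        gate = _gate_from_params([0.5, 0.5], [2.0, 5.0], [0.3, 0.4])
        with pytest.raises(MissingControlError):
            derive_threshold(gate, np.array([1.0, 2.0]))

    def test_recovery_over_randomized_separations(self):
        # fitted-threshold vs analytic-intersection agreement, >= 2.5 SD apart
        rng = np.random.default_rng(7)
        hits = 0
        n_rows = 100
        for _ in range(n_rows):
            s_neg = rng.uniform(0.30, 0.40)
            s_pos = rng.uniform(0.30, 0.45)
            sep = rng.uniform(2.5, 6.0)
            m_neg = rng.uniform(2.5, 3.5)
            m_pos = m_neg + sep * 0.5 * (s_neg + s_pos)
            w_neg = rng.uniform(0.4, 0.8)
            n = 4000
            n_neg = int(round(w_neg * n))
            x = np.concatenate([rng.normal(m_neg, s_neg, n_neg),
                                rng.normal(m_pos, s_pos, n - n_neg)])
            ctrl = rng.normal(m_neg, s_neg, 1200)
            gate = fit_log_intensity_mixture(np.concatenate([x, ctrl]), k=2)
            tau = derive_threshold(gate, ctrl)
            pooled_w_neg = (n_neg + 1200) / (n + 1200)
            oracle = analytic_crossing(pooled_w_neg, m_neg, s_neg,
                                       1 - pooled_w_neg, m_pos, s_pos)
            hits += abs(tau - oracle) < 0.1
        assert hits >= 95


class TestClassification:
    def test_quadrant_rule(self):
        assert quadrant_label(True, False) == "K14+"
        assert quadrant_label(False, True) == "K19+"
        assert quadrant_label(True, True) == "DP"
        assert quadrant_label(False, False) == "DN"

    def test_classify_against_manual_thresholds(self):
        cells = pd.DataFrame({
            "plate": "P1", "well": "A1", "cell_id": [1, 2, 3, 4],
            "replicate_row": "r1",
            "mean_Cy3": np.exp([5.0, 5.0, 2.0, 2.0]),   # K14
            "mean_Cy5": np.exp([5.0, 2.0, 5.0, 2.0]),   # K19
        })
        gates = {}
        for m in ("K14", "K19"):
            g = _gate_from_params([0.5, 0.5], [2.0, 5.0], [0.3, 0.4])
            g.threshold = 3.5
            gates[("r1", m)] = g
        calls = classify_cells(cells, gates)
        assert list(calls["phenotype"]) == ["DP", "K14+", "K19+", "DN"]

    def test_safe_log_handles_nonpositive(self):
        logs = safe_log(np.array([0.0, -2.0, 4.0, 16.0]))
        assert np.all(np.isfinite(logs))
        assert logs[0] == logs[1] == pytest.approx(math.log(2.0))

    def test_table_level_accuracy_on_separated_classes(self):
        from hcscreen.simulate import (SimulationConfig, draw_well_cells,
                                       well_rng)
        cfg = SimulationConfig(cells_per_well=5000, apply_growth=False)
        meta = dict(plate="P1", well="A1", dose_gy=0.0, time_h=0.0,
                    is_control=False)
        truth = draw_well_cells(cfg, meta, well_rng(8, "P1", "A1"))
        ctrl = draw_well_cells(cfg, dict(meta, well="A2", is_control=True),
                               well_rng(8, "P1", "A2"))
        gates = {}
        for m in ("K14", "K19"):
            pooled = np.log(np.concatenate([truth[f"value_{m}"],
                                            ctrl[f"value_{m}"]]))
            gate = fit_log_intensity_mixture(pooled, k=2, marker=m,
                                             replicate_row="r1")
            derive_threshold(gate, np.log(ctrl[f"value_{m}"].to_numpy()))
            gates[("r1", m)] = gate
        cells = pd.DataFrame({
            "plate": "P1", "well": "A1",
            "cell_id": truth["cell_index"], "replicate_row": "r1",
            "mean_Cy3": truth["value_K14"], "mean_Cy5": truth["value_K19"],
        })
        calls = classify_cells(cells, gates)
        accuracy = (calls["phenotype"].to_numpy()
                    == truth["true_class"].to_numpy()).mean()
        assert accuracy >= 0.98


class TestFrequencyTable:
    def _layout(self, n_wells):
        return make_row_layout(n_replicates=n_wells)

    def _calls(self, dp_pcts, cells_per_well=50):
        rows = []
        for i, pct in enumerate(dp_pcts):
            well = f"A{i + 1}"
            n_dp = int(round(cells_per_well * pct / 100))
            labels = ["DP"] * n_dp + ["DN"] * (cells_per_well - n_dp)
            for j, lab in enumerate(labels):
                rows.append({"plate": "P1", "well": well, "cell_id": j,
                             "phenotype": lab})
        return pd.DataFrame(rows)

    def test_mean_and_sem_arithmetic(self):
        calls = self._calls([20, 22, 24, 26, 28])
        table = frequency_table(calls, self._layout(5), grouping=["donor"])
        row = table.iloc[0]
        assert row["DP_mean_pct"] == pytest.approx(24.0)
        assert row["DP_sem"] == pytest.approx(np.std([20, 22, 24, 26, 28],
                                                     ddof=1) / np.sqrt(5))
        assert row["DP_sem"] == pytest.approx(1.4142, abs=1e-3)

    def test_single_well_all_dp(self):
        calls = self._calls([100], cells_per_well=40)
        table = frequency_table(calls, self._layout(1), grouping=["donor"])
        row = table.iloc[0]
        assert row["DP_mean_pct"] == pytest.approx(100.0)
        assert np.isnan(row["DP_sem"])  # n = 1

    def test_percentages_sum_to_100_per_group(self):
        calls = self._calls([35, 45, 55])
        table = frequency_table(calls, self._layout(3), grouping=["donor"])
        total = sum(table.iloc[0][c] for c in table.columns
                    if c.endswith("_mean_pct"))
        assert total == pytest.approx(100.0, abs=0.01)


class TestOverlapTable:
    def _calls(self, flags):
        df = pd.DataFrame(flags)
        df["cell_id"] = np.arange(len(df))
        return df

    def test_matches_brute_force_set_algebra(self):
        rng = np.random.default_rng(9)
        flags = {f"{m}_pos": rng.random(500) < p
                 for m, p in [("K14", 0.4), ("K5", 0.7), ("K19", 0.5)]}
        table = overlap_table(self._calls(flags), ("K14", "K5", "K19"))
        regions = table[~table["region"].str.contains("marginal|total")]
        assert regions["count"].sum() == 500
        for _, row in regions.iterrows():
            mask = np.ones(500, dtype=bool)
            for part in row["region"].split("/"):
                m, sign = part[:-1], part[-1]
                mask &= flags[f"{m}_pos"] == (sign == "+")
            assert row["count"] == mask.sum()

    def test_exclusive_single_positives_have_empty_overlaps(self):
        n = 90
        flags = {"A_pos": np.zeros(n, bool), "B_pos": np.zeros(n, bool),
                 "C_pos": np.zeros(n, bool)}
        for i, m in enumerate(("A", "B", "C")):
            flags[f"{m}_pos"][i * 30:(i + 1) * 30] = True
        table = overlap_table(self._calls(flags), ("A", "B", "C"))
        double = table[table["region"].str.count(r"\+") >= 2]
        double = double[~double["region"].str.contains("marginal")]
        assert (double["count"] == 0).all()

    def test_identical_markers_have_no_exclusive_regions(self):
        rng = np.random.default_rng(10)
        a = rng.random(200) < 0.5
        table = overlap_table(self._calls({"A_pos": a, "B_pos": a.copy()}),
                              ("A", "B"))
        lookup = dict(zip(table["region"], table["count"]))
        assert lookup["A+/B-"] == 0
        assert lookup["A-/B+"] == 0
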
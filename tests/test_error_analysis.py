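import itertools

import numpy as np
import pandas as pd
import pytest

from rfharmonize.error_analysis import (attribute_features, compute_errors,
                                        fit_error_model,
                                        friedman_by_parameter,
                                        nemenyi_posthoc,
                                        wilcoxon_by_parameter,
                                        wilcoxon_rank_sum)
from rfharmonize.exceptions import ConfigurationError
from rfharmonize.synthetic_data import StudyConfig, generate_study

from conftest import small_config


def pred_frame(rows):
    return pd.DataFrame(rows, columns=[
        "dataset_id", "compound_id", "approach", "sample_matrix",
        "spike_level", "predicted_concentration", "true_concentration"])


class TestComputeErrors:
    @pytest.mark.parametrize("pred,true,fold,log_err", [
        (1e-8, 1e-8, 1.0, 0.0),
        (1e-7, 1e-8, 10.0, 1.0),
        (1e-9, 1e-8, 10.0, -1.0),
    ])
    def test_fold_and_log_error(self, pred, true, fold, log_err):
        df = compute_errors(pred_frame(
            [("L1", "c1", "parent_TP", "hplc_water", "high", pred, true)]))
        assert df["fold_error"].iloc[0] == pytest.approx(fold, rel=1e-12)
        assert df["log_error"].iloc[0] == pytest.approx(log_err, abs=1e-12)
        assert df["log_fold_error"].iloc[0] == pytest.approx(abs(log_err))

    def test_fold_error_invariant_under_swap(self):
        rng = np.random.default_rng(0)
        pred, true = rng.uniform(1e-9, 1e-6, 20), rng.uniform(1e-9, 1e-6, 20)
        a = compute_errors(pred_frame(
            [("L1", f"c{i}", "MLR_IE", "hplc_water", "high", p, t)
             for i, (p, t) in enumerate(zip(pred, true))]))
        b = compute_errors(pred_frame(
            [("L1", f"c{i}", "MLR_IE", "hplc_water", "high", t, p)
             for i, (p, t) in enumerate(zip(pred, true))]))
        np.testing.assert_allclose(a["fold_error"], b["fold_error"], rtol=1e-12)

    def test_nonpositive_records_skipped(self):
        df = compute_errors(pred_frame(
            [("L1", "c1", "MLR_IE", "hplc_water", "high", 0.0, 1e-8),
             ("L1", "c2", "MLR_IE", "hplc_water", "high", 1e-8, 1e-8)]))
        assert len(df) == 1


def exact_rank_sum_p(x, y):
    """Full enumeration of all group assignments (no ties assumed)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    count_le = count_ge = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = sum(ranks[pooled[i]] for i in combo) - n1 * (n1 + 1) / 2
        count_le += u <= u_obs
        count_ge += u >= u_obs
        total += 1
    return min(1.0, 2 * min(count_le, count_ge) / total)


class TestWilcoxon:
    def test_extreme_separation_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(2 / 70, rel=1e-10)

    def test_identical_groups(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_value"] == pytest.approx(1.0)
        assert res["effect_size_r"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, int(rng.integers(3, 9)))
        y = rng.normal(0.5, 1, int(rng.integers(3, 9)))
        res = wilcoxon_rank_sum(x, y)
        assert res["p_value"] == pytest.approx(exact_rank_sum_p(x, y),
                                               rel=1e-10)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, 12)
        y = rng.lognormal(0.3, 1, 15)
        p1 = wilcoxon_rank_sum(x, y)["p_value"]
        p2 = wilcoxon_rank_sum(np.log(x), np.log(y))["p_value"]
        p3 = wilcoxon_rank_sum(x**3, y**3)["p_value"]
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert p1 == pytest.approx(p3, rel=1e-12)

    def test_bonferroni_family_is_strata_count(self):
        rng = np.random.default_rng(6)
        rows = []
        for ds, additive in [("L1", "acid"), ("L2", "buffer"),
                             ("L3", "acid"), ("L4", "buffer")]:
            for app in ("parent_TP", "MLR_IE"):
                for lvl in ("low", "high"):
                    for i in range(5):
                        t = 1e-8
                        rows.append((ds, f"c{i}", app, "hplc_water", lvl,
                                     t * 10 ** rng.normal(0, 0.3), t))
        errors = compute_errors(pred_frame(rows))
        meta = pd.DataFrame({"dataset_id": ["L1", "L2", "L3", "L4"],
                             "additive_type": ["acid", "buffer"] * 2})
        out = wilcoxon_by_parameter(errors, meta, "additive_type")
        assert len(out) == 4  # 2 approaches x 2 levels
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, out["p_value"] * 4), rtol=1e-12)

    def test_requires_two_levels(self):
        errors = compute_errors(pred_frame(
            [("L1", "c1", "MLR_IE", "hplc_water", "high", 1e-8, 1e-8)]))
        meta = pd.DataFrame({"dataset_id": ["L1"], "analyzer": ["Orbitrap"]})
        with pytest.raises(ConfigurationError):
            wilcoxon_by_parameter(errors, meta, "analyzer")


def friedman_oracle(table):
    """Direct rank-formula chi-square (continuous data, no ties)."""
    n, k = table.shape
    ranks = np.zeros_like(table, dtype=float)
    for i in range(n):
        order = np.argsort(table[i])
        for r, j in enumerate(order):
            ranks[i, j] = r + 1
    rank_sums = ranks.sum(axis=0)
    return (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3 * n * (k + 1)


class TestFriedman:
    def make_inputs(self, cell_values):
        """cell_values: dict (compound, band) -> value, one dataset per band."""
        rows, meta_rows = [], []
        bands = sorted({b for _, b in cell_values})
        for b_idx, band in enumerate(bands):
            ds = f"L{b_idx}"
            meta_rows.append({"dataset_id": ds, "spray_voltage_band": band})
            for (comp, b2), v in cell_values.items():
                if b2 == band:
                    rows.append((ds, comp, "MLR_IE", "hplc_water", "high",
                                 v * 1e-8, 1e-8))
        return compute_errors(pred_frame(rows)), pd.DataFrame(meta_rows)

    def test_identical_cells_give_zero_statistic(self):
        cells = {(f"c{i}", b): 2.0 for i in range(4)
                 for b in ("<3.0 kV", "3.0–3.5 kV", ">3.5 kV")}
        errors, meta = self.make_inputs(cells)
        res = friedman_by_parameter(errors, meta, "spray_voltage_band")
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_statistic_matches_rank_formula(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(1.5, 8.0, (5, 3))
        bands = ("<3.0 kV", "3.0–3.5 kV", ">3.5 kV")
        cells = {(f"c{i}", b): vals[i, j] for i in range(5)
                 for j, b in enumerate(bands)}
        errors, meta = self.make_inputs(cells)
        res = friedman_by_parameter(errors, meta, "spray_voltage_band")
        assert res["statistic"] == pytest.approx(friedman_oracle(vals),
                                                 rel=1e-10)

    def test_dominant_treatment_triggers_nemenyi(self):
        rng = np.random.default_rng(8)
        bands = ("<3.0 kV", "3.0–3.5 kV", ">3.5 kV")
        cells = {}
        for i in range(12):
            base = rng.uniform(1.5, 3.0)
            cells[(f"c{i}", bands[0])] = base + 5.0  # dominant fold error
            cells[(f"c{i}", bands[1])] = base + rng.uniform(0, 0.1)
            cells[(f"c{i}", bands[2])] = base + rng.uniform(0, 0.1)
        errors, meta = self.make_inputs(cells)
        res = friedman_by_parameter(errors, meta, "spray_voltage_band")
        assert res["p_value"] < 0.05
        assert res["posthoc"] is not None
        assert res["posthoc"].loc[bands[0], bands[1]] < 0.05

    def test_nemenyi_zero_rank_difference_is_one(self):
        blocked = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                                "c": [4.0, 5.0, 6.0]})
        p = nemenyi_posthoc(blocked)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_under_three_blocks_skipped(self):
        bands = ("<3.0 kV", "3.0–3.5 kV", ">3.5 kV")
        cells = {("c0", b): 2.0 for b in bands}
        errors, meta = self.make_inputs(cells)
        res = friedman_by_parameter(errors, meta, "spray_voltage_band")
        assert not res["tested"]


@pytest.fixture(scope="module")
def planted_study():
    # balanced additive design so the planted -0.5 buffer shift is not
    # confounded with laboratories; error noise scaled so the shift carries
    # a substantial share of the variance
    cfg = small_config(n_datasets=14, prediction_shift_buffer=-0.5,
                       additive_balance=0.5, prediction_error_scale=0.6)
    peaks, meta, pred, truth = generate_study(cfg, seed=21)
    errors = compute_errors(pred)
    return errors, meta, truth


class TestErrorModel:
    def test_same_seed_identical_predictions(self, planted_study):
        errors, meta, _ = planted_study
        em1 = fit_error_model(errors, meta, seed=42)
        em2 = fit_error_model(errors, meta, seed=42)
        np.testing.assert_array_equal(em1.model.predict(em1.X_test),
                                      em2.model.predict(em2.X_test))
        assert em1.test_datasets == em2.test_datasets

    def test_grouped_split_keeps_datasets_whole(self, planted_study):
        errors, meta, _ = planted_study
        em = fit_error_model(errors, meta, seed=1)
        assert not set(em.train_datasets) & set(em.test_datasets)
        assert len(em.test_datasets) >= 1

    def test_constant_target_scores_zero(self, planted_study):
        errors, meta, _ = planted_study
        flat = errors.copy()
        flat["log_error"] = 0.0
        em = fit_error_model(flat, meta, seed=1)
        assert em.r2_test == 0.0

    def test_planted_buffer_effect_is_learnable(self, planted_study):
        errors, meta, _ = planted_study
        em = fit_error_model(errors, meta, seed=42)
        assert em.r2_test > 0.2

    def test_refuses_fewer_than_three_datasets(self):
        rows = [("L1", "c1", "MLR_IE", "hplc_water", "high", 1e-8, 1e-8),
                ("L2", "c1", "MLR_IE", "hplc_water", "high", 2e-8, 1e-8)]
        errors = compute_errors(pred_frame(rows))
        meta = pd.DataFrame({"dataset_id": ["L1", "L2"]})
        with pytest.raises(ConfigurationError):
            fit_error_model(errors, meta)


class TestAttribution:
    def test_additivity_to_prediction_minus_baseline(self, planted_study):
        errors, meta, _ = planted_study
        em = fit_error_model(errors, meta, seed=42)
        attr = attribute_features(em)
        contrib, baseline = attr["attributions"], attr["baseline"]
        preds = em.model.predict(em.X_all)
        np.testing.assert_allclose(baseline + contrib.sum(axis=1), preds,
                                   atol=1e-6)

    def test_unused_feature_gets_zero(self, planted_study):
        errors, meta, _ = planted_study
        flat_meta = meta.copy()
        flat_meta["analyzer"] = "Orbitrap"  # constant -> never split on
        em = fit_error_model(errors, flat_meta, seed=1)
        attr = attribute_features(em)
        idx = em.features.index("analyzer")
        assert np.abs(attr["attributions"][:, idx]).max() == 0.0

    def test_buffer_ranks_first_with_negative_direction(self, planted_study):
        errors, meta, _ = planted_study
        em = fit_error_model(errors, meta, seed=42)
        attr = attribute_features(em)
        assert attr["summary"]["feature"].iloc[0] == "additive_type"
        direction = attr["directions"]
        buf = direction[(direction["feature"] == "additive_type")
                        & (direction["level"] == "buffer")]
        assert buf["mean_attribution"].iloc[0] < 0

    def test_permutation_fallback_runs(self, planted_study):
        errors, meta, _ = planted_study
        em = fit_error_model(errors, meta, seed=1)
        attr = attribute_features(em, method="permutation")
        assert set(attr["summary"]["feature"]) == set(em.features)
        assert np.isfinite(attr["summary"]["mean_abs_attribution"]).all()
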
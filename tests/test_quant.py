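"""One-site binding fits, PQN, QC CV filtering and volcano selection."""

import numpy as np
import pandas as pd
import pytest

from rbpkit.quant import (
    fit_fp,
    fp_one_site,
    pca_scores,
    pqn_normalize,
    qc_cv_filter,
    volcano_select,
)
from rbpkit.simulate import sim_fp, sim_metabolites

GRID = (0, 5, 10, 25, 50, 100, 250, 500, 1000)


class TestOneSiteLaw:
    def test_zero_concentration_gives_baseline(self):
        assert fp_one_site(0, kd=47, fp0=60, fpmax=160) == 60

    def test_half_saturation_at_kd(self):
        assert fp_one_site(47, kd=47, fp0=60, fpmax=160) == pytest.approx(110)

    def test_saturation_limit(self):
        val = fp_one_site(47e6, kd=47, fp0=60, fpmax=160)
        assert val == pytest.approx(160, rel=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fp_one_site(10, kd=0, fp0=0, fpmax=1)
        with pytest.raises(ValueError):
            fp_one_site(-1, kd=47, fp0=0, fpmax=1)


class TestFitFP:
    def test_noiseless_titration_recovered_exactly(self):
        table, truth = sim_fp(kd=47, fp0=60, fpmax=160, conc_grid=GRID, noise_sd=0)
        fit = fit_fp(table["conc_nM"], table["fp"], n_boot=0)
        assert fit.kd == pytest.approx(47, rel=1e-6)
        assert fit.fp0 == pytest.approx(60, rel=1e-6)
        assert fit.fpmax == pytest.approx(160, rel=1e-6)
        assert fit.residual_sse < 1e-12

    def test_bootstrap_ci_brackets_truth_at_low_noise(self):
        table, _ = sim_fp(kd=47, noise_sd=1.0, n_replicates=3, seed=1)
        fit = fit_fp(table["conc_nM"], table["fp"], n_boot=200, seed=2)
        assert fit.kd_ci is not None
        lo, hi = fit.kd_ci
        assert lo < 47 < hi

    def test_flat_titration_rejected(self):
        with pytest.raises(ValueError):
            fit_fp(GRID, [100.0] * len(GRID), n_boot=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_fp([0, 10, 50, 100], [60, 80, 120, 140], n_boot=0)

    def test_median_recovery_within_two_percent_at_one_percent_noise(self):
        errors = []
        for seed in range(100):
            table, _ = sim_fp(kd=47, fp0=60, fpmax=160, noise_sd=1.0, n_replicates=3, seed=seed)
            fit = fit_fp(table["conc_nM"], table["fp"], n_boot=0)
            errors.append(abs(fit.kd - 47) / 47)
        assert np.median(errors) < 0.02


class TestPQN:
    def test_pure_dilution_removed(self):
        base = pd.Series([10.0, 20, 30, 40, 50])
        table = pd.DataFrame({"QC1": base, "QC2": base, "s1": base, "s2": 2 * base})
        roles = {"QC1": "QC", "QC2": "QC", "s1": "control", "s2": "knockdown"}
        norm, q = pqn_normalize(table, roles)
        assert q["s1"] == pytest.approx(1.0) and q["s2"] == pytest.approx(2.0)
        assert np.allclose(norm["s1"], norm["s2"])

    def test_identical_samples_unchanged(self):
        base = pd.Series([5.0, 7, 9])
        table = pd.DataFrame({c: base for c in ("QC1", "QC2", "s1")})
        roles = {"QC1": "QC", "QC2": "QC", "s1": "control"}
        norm, q = pqn_normalize(table, roles)
        assert np.allclose(q, 1.0)
        assert np.allclose(norm, table)

    def test_planted_dilution_factors_recovered_exactly(self):
        factors = [1.0] * 5 + [0.5, 1, 2, 4, 1] + [1.0] * 5
        table, roles, truth = sim_metabolites(
            n_features=100,
            dilution_factors=factors,
            high_cv_fraction=0.0,
            base_cv=0.0,
            group_noise_sd=0.0,
            log2_fold_change=0.0,
            seed=5,
        )
        _, q = pqn_normalize(table, roles)
        for col, d in truth.truth["dilution_factors"].items():
            assert q[col] == pytest.approx(d, abs=1e-12)

    def test_idempotent(self):
        table, roles, _ = sim_metabolites(seed=6)
        norm, _ = pqn_normalize(table, roles)
        _, q2 = pqn_normalize(norm, roles)
        assert np.allclose(q2, 1.0, atol=1e-12)

    def test_median_of_all_reference(self):
        base = pd.Series([10.0, 20, 30])
        table = pd.DataFrame({"s1": base, "s2": base * 3})
        norm, q = pqn_normalize(table, {"s1": "control", "s2": "control"}, reference="median_of_all")
        assert q["s2"] / q["s1"] == pytest.approx(3.0)

    def test_qc_required_for_default_reference(self):
        table = pd.DataFrame({"s1": [1.0]})
        with pytest.raises(ValueError):
            pqn_normalize(table, {"s1": "control"})


class TestQCCVFilter:
    def _table(self, qc_rows):
        return pd.DataFrame(qc_rows, columns=["QC1", "QC2", "QC3"]), {
            "QC1": "QC",
            "QC2": "QC",
            "QC3": "QC",
        }

    def test_constant_feature_kept(self):
        table, roles = self._table([[100.0, 100, 100]])
        kept, dropped = qc_cv_filter(table, roles)
        assert len(kept) == 1 and dropped == []

    def test_high_cv_feature_dropped(self):
        table = pd.DataFrame({"QC1": [100.0], "QC2": [200.0]})
        roles = {"QC1": "QC", "QC2": "QC"}
        kept, dropped = qc_cv_filter(table, roles)
        # sd/mean = (100/sqrt(2))/150 ~ 0.471
        assert len(kept) == 0 and dropped == [0]

    def test_boundary_cv_is_dropped(self):
        # values 100, 125, 75: mean 100, sd(ddof=1) = 25 -> CV exactly 0.25,
        # excluded under the strict "lower than 25%" rule
        table, roles = self._table([[100.0, 125.0, 75.0]])
        kept, dropped = qc_cv_filter(table, roles)
        assert len(kept) == 0 and dropped == [0]

    def test_zero_mean_dropped_with_warning(self):
        table, roles = self._table([[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning):
            kept, dropped = qc_cv_filter(table, roles)
        assert len(kept) == 0

    def test_planted_cv_truth_recovered(self):
        table, roles, truth = sim_metabolites(
            n_features=100, high_cv_fraction=0.2, high_cv=0.30, base_cv=0.05, seed=7
        )
        kept, dropped = qc_cv_filter(table, roles)
        assert set(dropped) == set(truth.truth["high_cv_features"])

    def test_single_qc_sample_rejected(self):
        table = pd.DataFrame({"QC1": [1.0], "s1": [1.0]})
        with pytest.raises(ValueError):
            qc_cv_filter(table, {"QC1": "QC", "s1": "control"})


class TestVolcano:
    def _roles(self, n=5):
        roles = {f"ctrl{i}": "control" for i in range(n)}
        roles.update({f"kd{i}": "knockdown" for i in range(n)})
        return roles

    def test_identical_groups_never_selected(self):
        roles = self._roles()
        table = pd.DataFrame({c: [100.0, 50.0] for c in roles})
        res = volcano_select(table, roles)
        assert not res["selected"].any()
        assert np.allclose(res["log2fc"], 0.0)

    def test_fold_change_gate_blocks_significant_small_effects(self):
        roles = self._roles()
        rngs = np.random.default_rng(0)
        ctrl = 100 * (1 + 0.001 * rngs.standard_normal((1, 5)))
        kd = ctrl.mean() * 2**0.39 * (1 + 0.001 * rngs.standard_normal((1, 5)))
        table = pd.DataFrame(
            np.hstack([ctrl, kd]), columns=[f"ctrl{i}" for i in range(5)] + [f"kd{i}" for i in range(5)]
        )
        res = volcano_select(table, roles)
        assert res["t_p"].iloc[0] < 1e-6
        assert abs(res["log2fc"].iloc[0]) < 0.4
        assert not res["selected"].iloc[0]

    def test_planted_twofold_change_selected(self):
        table, roles, truth = sim_metabolites(
            n_features=100, n_effect_features=10, log2_fold_change=1.0, high_cv_fraction=0.0, seed=8
        )
        res = volcano_select(table, roles)
        effect = truth.truth["effect_features"]
        assert res.loc[effect, "selected"].all()

    def test_linear_scale_flag(self):
        roles = self._roles()
        ctrl = np.full((1, 5), 100.0)
        kd = np.full((1, 5), 150.0) + np.arange(5) * 0.1
        table = pd.DataFrame(
            np.hstack([ctrl + np.arange(5) * 0.1, kd]),
            columns=[f"ctrl{i}" for i in range(5)] + [f"kd{i}" for i in range(5)],
        )
        res = volcano_select(table, roles, fc_scale="linear")
        assert res["selected"].iloc[0]  # 1.5-fold exceeds the 1.4-fold bound

    def test_small_group_rejected(self):
        table = pd.DataFrame({"ctrl0": [1.0], "kd0": [1.0]})
        with pytest.raises(ValueError):
            volcano_select(table, {"ctrl0": "control", "kd0": "knockdown"})


def test_pca_scores_shape_and_centering():
    table, roles, _ = sim_metabolites(seed=9)
    scores = pca_scores(table, n_components=3)
    assert scores.shape == (table.shape[1], 3)
    assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)
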
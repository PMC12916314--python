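import subprocess

import numpy as np
import pytest

import cortexbench as cb
from cortexbench.combat import (
    HarmonizationConfig,
    LeakageError,
    UnseenSiteError,
    apply_combat,
    fit_combat,
    harmonize_leave_site_out,
)
from cortexbench.scenarios import recovery_scenario
from cortexbench.synthetic import simulate_cohort


def _identical_batches(p=40, n=30, seed=0):
    rng = np.random.default_rng(seed)
    block = rng.standard_normal((n, p))
    y = np.vstack([block, block])
    batch = np.array(["A"] * n + ["B"] * n)
    return y, batch


class TestFitCombat:
    def test_identical_batches_give_null_parameters(self):
        # delta* carries the canonical n/(n-1) factor from the unbiased
        # within-batch variance, so the no-batch-effect limit needs n large
        y, batch = _identical_batches(p=20, n=1200)
        params = fit_combat(y, batch, None)
        assert np.abs(params.gamma_star).max() < 1e-6
        assert np.abs(params.delta_star - 1).max() < 1e-3

    def test_uniform_shift_identified_before_shrinkage(self):
        y, batch = _identical_batches()
        c = 1.7
        y = y.copy()
        y[batch == "B"] += c
        params = fit_combat(y, batch, None)
        raw_gap = (params.gamma_hat[1] - params.gamma_hat[0]) * np.sqrt(params.var_pooled)
        assert np.allclose(raw_gap, c, atol=1e-8)

    def test_single_batch_rejected(self):
        y, _ = _identical_batches()
        with pytest.raises(ValueError, match="at least 2 batches"):
            fit_combat(y, np.array(["A"] * len(y)), None)

    def test_collinear_covariate_rejected(self):
        y, batch = _identical_batches()
        cov = (batch == "A").astype(float)[:, None]  # collinear with batch
        with pytest.raises(ValueError, match="rank"):
            fit_combat(y, batch, cov)

    def test_tiny_batch_rejected(self):
        y, batch = _identical_batches()
        batch = batch.copy()
        batch[:-1] = "A"
        with pytest.raises(ValueError, match=">= 2 subjects"):
            fit_combat(y, batch, None)

    def test_shrinkage_never_overshoots_prior_mean(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((60, 50))
        y[30:] += rng.standard_normal(50) * 0.5
        batch = np.array(["A"] * 30 + ["B"] * 30)
        params = fit_combat(y, batch, None)
        for i, b in enumerate(params.batches):
            gbar = params.hyper[b]["gamma_bar"]
            assert np.all(np.abs(params.gamma_star[i] - gbar)
                          <= np.abs(params.gamma_hat[i] - gbar) + 1e-12)


class TestParameterRecovery:
    @pytest.fixture(scope="class")
    def fitted(self, mesh3):
        sites, spec = recovery_scenario(n_per_site=100)
        cohort, feats = simulate_cohort(sites, spec, mesh3, seed=31)
        fs = feats[("thickness", "lh")]
        y = fs.values[:, :200]
        cov = cohort[["age", "sex"]].to_numpy(float)
        params = fit_combat(y, cohort["site"].to_numpy(), cov, HarmonizationConfig())
        harmonized = apply_combat(params, y, cohort["site"].to_numpy(), cov)
        return cohort, fs, y, cov, params, harmonized

    def test_gamma_recovered(self, fitted):
        _, fs, _, _, params, _ = fitted
        gt = fs.ground_truth
        n = np.array([100, 100])
        gamma_dev = gt["gamma"][:, :200] - (n / n.sum()) @ gt["gamma"][:, :200]
        for i in range(2):
            est = params.gamma_star[i] * np.sqrt(params.var_pooled)
            assert np.corrcoef(est, gamma_dev[i])[0, 1] > 0.95

    def test_delta_recovered(self, fitted):
        _, fs, _, _, params, _ = fitted
        true_delta = fs.ground_truth["delta"]
        est = np.sqrt(params.delta_star * params.var_pooled[None, :])  # noise_sd = 1
        rel = (est - true_delta[:, None]) / true_delta[:, None]
        assert np.sqrt((rel ** 2).mean()) < 0.15

    def test_age_slopes_preserved(self, fitted):
        cohort, fs, y, cov, _, harmonized = fitted
        design = np.column_stack([np.ones(len(cohort)), cov])
        pre = np.linalg.lstsq(design, y, rcond=None)[0][1]
        post = np.linalg.lstsq(design, harmonized, rcond=None)[0][1]
        true_slope = fs.ground_truth["beta_age"][:200]
        big = np.abs(true_slope) > 0.2  # above the slope map's RMS amplitude
        assert big.sum() > 40
        assert np.abs((post[big] - pre[big]) / pre[big]).max() < 0.10

    def test_between_site_means_equalized(self, fitted):
        cohort, _, y, cov, _, harmonized = fitted
        site = cohort["site"].to_numpy()
        design = np.column_stack([np.ones(len(cohort)), cov])

        def adjusted_gap(data):
            resid = data - design @ np.linalg.lstsq(design, data, rcond=None)[0]
            return resid[site == "siteA"].mean(axis=0) - resid[site == "siteB"].mean(axis=0)

        before = adjusted_gap(y)
        after = adjusted_gap(harmonized)
        assert (after ** 2).mean() < 0.1 * (before ** 2).mean()

    def test_refit_on_harmonized_is_near_null(self, fitted):
        cohort, _, _, cov, _, harmonized = fitted
        params2 = fit_combat(harmonized, cohort["site"].to_numpy(), cov)
        assert np.abs(params2.gamma_star).max() < 0.05
        assert np.abs(params2.delta_star - 1).max() < 0.05


class TestApplyCombat:
    def test_identity_limit_on_no_batch_effect(self):
        # the canonical estimator rescales by sqrt((n-1)/n) even with zero
        # batch effect, so the identity limit holds to O(1/n), not exactly
        y, batch = _identical_batches(p=20, n=1200)
        params = fit_combat(y, batch, None)
        out = apply_combat(params, y, batch, None)
        assert np.allclose(out, y, rtol=2e-3, atol=2e-3)
        assert np.abs(out - y).max() < np.abs(y).max() / 1200

    def test_unseen_batch_raises(self):
        y, batch = _identical_batches()
        params = fit_combat(y, batch, None)
        with pytest.raises(UnseenSiteError, match="reference"):
            apply_combat(params, y[:3], np.array(["C"] * 3), None)

    def test_constant_features_pass_through(self):
        y, batch = _identical_batches()
        y = y.copy()
        y[:, 0] = 4.0
        y[batch == "B", 1:] += 1.0
        params = fit_combat(y, batch, None)
        out = apply_combat(params, y, batch, None)
        assert np.array_equal(out[:, 0], y[:, 0])
        assert not np.allclose(out[:, 1], y[:, 1])


class TestLeaveSiteOut:
    def _train_test(self, shift=0.0, seed=11, p=80, n=200):
        rng = np.random.default_rng(seed)
        gamma = {b: rng.standard_normal(p) * 0.6 for b in "AB"}
        train_y = np.vstack([rng.standard_normal((n, p)) + gamma[b] for b in "AB"])
        train_b = np.array(["A"] * n + ["B"] * n)
        # harmonized training data are centered on the grand mean (gamma_A+gamma_B)/2;
        # a "matched" test site must share that center (plus any injected shift)
        grand = (gamma["A"] + gamma["B"]) / 2.0
        test_y = rng.standard_normal((n, p)) + grand + shift
        test_b = np.array(["C"] * n)
        return train_y, train_b, test_y, test_b

    def test_training_data_bitwise_unchanged(self):
        train_y, train_b, test_y, test_b = self._train_test(shift=2.0)
        train_h, _, params = harmonize_leave_site_out(
            train_y, train_b, None, test_y, test_b, None)
        expected = apply_combat(params["stage1"], train_y, train_b, None)
        assert np.array_equal(train_h, expected)

    def test_matched_test_site_barely_changes(self):
        # test site drawn from the harmonized training distribution (unit noise)
        train_y, train_b, test_y, test_b = self._train_test(shift=0.0)
        _, test_h, _ = harmonize_leave_site_out(train_y, train_b, None, test_y, test_b, None)
        assert np.abs(test_h - test_y).mean() < 0.25  # noise_sd / 4

    def test_known_shift_mostly_removed(self):
        c = 2.0
        train_y, train_b, test_y, test_b = self._train_test(shift=c)
        train_h, test_h, _ = harmonize_leave_site_out(train_y, train_b, None, test_y, test_b, None)
        gap_before = np.abs(test_y.mean(axis=0) - train_h.mean(axis=0)).mean()
        gap_after = np.abs(test_h.mean(axis=0) - train_h.mean(axis=0)).mean()
        assert gap_after < 0.2 * gap_before

    def test_overlapping_sites_rejected(self):
        train_y, train_b, test_y, _ = self._train_test()
        with pytest.raises(LeakageError):
            harmonize_leave_site_out(train_y, train_b, None, test_y,
                                     np.array(["A"] * len(test_y)), None)

    def test_test_rows_cannot_influence_training_fit(self):
        train_y, train_b, test_y, test_b = self._train_test(shift=1.0)
        _, _, p1 = harmonize_leave_site_out(train_y, train_b, None, test_y, test_b, None)
        _, _, p2 = harmonize_leave_site_out(train_y, train_b, None, test_y + 100.0,
                                            test_b, None)
        assert np.array_equal(p1["stage1"].gamma_star, p2["stage1"].gamma_star)
        assert np.array_equal(p1["stage1"].delta_star, p2["stage1"].delta_star)


class TestAgainstSvaOracle:
    """Independent cross-check: Bioconductor sva::ComBat on the same fixture."""

    @pytest.fixture(scope="class")
    def fixture_data(self):
        rng = np.random.default_rng(7)
        n1, n2, p = 25, 18, 30
        batch = np.array(["A"] * n1 + ["B"] * n2)
        cov = np.column_stack([rng.uniform(20, 60, n1 + n2),
                               rng.integers(0, 2, n1 + n2).astype(float)])
        y = rng.standard_normal((n1 + n2, p)) * 1.2
        y += cov[:, :1] * rng.standard_normal(p) * 0.05
        y += cov[:, 1:] * rng.standard_normal(p) * 0.4
        y[batch == "B"] += rng.standard_normal(p) * 0.8
        y[batch == "B"] += rng.standard_normal((n2, p)) * 0.5
        return y, batch, cov

    @pytest.fixture(scope="class")
    def sva_outputs(self, fixture_data, tmp_path_factory):
        y, batch, cov = fixture_data
        d = tmp_path_factory.mktemp("sva")
        np.savetxt(d / "y.csv", y, delimiter=",")
        np.savetxt(d / "cov.csv", cov, delimiter=",")
        (d / "batch.txt").write_text("\n".join(batch))
        script = f"""
suppressMessages(library(sva))
y <- t(as.matrix(read.csv("{d}/y.csv", header=FALSE)))
batch <- readLines("{d}/batch.txt")
cov <- as.matrix(read.csv("{d}/cov.csv", header=FALSE))
write.table(t(ComBat(dat=y, batch=batch, mod=cov, par.prior=TRUE)),
            "{d}/std.csv", sep=",", row.names=FALSE, col.names=FALSE)
write.table(t(ComBat(dat=y, batch=batch, mod=cov, par.prior=TRUE, ref.batch="A")),
            "{d}/ref.csv", sep=",", row.names=FALSE, col.names=FALSE)
"""
        (d / "script.R").write_text(script)
        res = subprocess.run(["Rscript", str(d / "script.R")],
                             capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        return (np.loadtxt(d / "std.csv", delimiter=","),
                np.loadtxt(d / "ref.csv", delimiter=","))

    def test_standard_mode_matches_sva(self, fixture_data, sva_outputs):
        y, batch, cov = fixture_data
        params = fit_combat(y, batch, cov, HarmonizationConfig())
        mine = apply_combat(params, y, batch, cov)
        assert np.allclose(mine, sva_outputs[0], rtol=1e-5, atol=1e-8)

    def test_reference_batch_mode_matches_sva(self, fixture_data, sva_outputs):
        y, batch, cov = fixture_data
        cfg = HarmonizationConfig(mode="reference_batch", reference_batch="A")
        params = fit_combat(y, batch, cov, cfg)
        mine = apply_combat(params, y, batch, cov)
        assert np.allclose(mine, sva_outputs[1], rtol=1e-5, atol=1e-8)
        assert np.array_equal(mine[batch == "A"], y[batch == "A"])


def test_parameters_save_load_round_trip(tmp_path):
    y, batch = _identical_batches()
    y = y.copy()
    y[batch == "B"] += 0.7
    cov = np.linspace(20, 60, len(y))[:, None]
    cfg = HarmonizationConfig(covariates=("age",))
    params = fit_combat(y, batch, cov, cfg)
    params.save(tmp_path / "combat.h5")
    from cortexbench.combat import CombatParameters
    back = CombatParameters.load(tmp_path / "combat.h5")
    assert back.batches == params.batches
    assert np.array_equal(back.gamma_star, params.gamma_star)
    assert np.array_equal(back.delta_star, params.delta_star)
    out_a = apply_combat(params, y, batch, cov)
    out_b = apply_combat(back, y, batch, cov)
    assert np.array_equal(out_a, out_b)
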
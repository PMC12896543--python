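"""Platform noise pipeline, concordance metrics, stress tests, ablation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triaxis import (
    PlatformProfile,
    SignatureDefinition,
    ablate_signature,
    concordance,
    default_hot_signature,
    run_signature_panel,
    score_signature,
    simulate_platform,
    stress_test,
)
from triaxis.platform_sim import _cohen_kappa, _lin_ccc


class TestSimulatePlatform:
    def test_identity_profile_bit_identical(self, panel_expression):
        out = simulate_platform(panel_expression, PlatformProfile.identity(),
                                seed=0)
        assert (out.to_numpy() == panel_expression.to_numpy()).all()

    def test_full_dropout_floors_everything(self, panel_expression):
        prof = PlatformProfile("d", dropout_rate=1.0)
        out = simulate_platform(panel_expression, prof, seed=0)
        assert (out.to_numpy() == panel_expression.to_numpy().min()).all()

    def test_deterministic_under_seed(self, panel_expression):
        prof = PlatformProfile.rtqpcr_like()
        a = simulate_platform(panel_expression, prof, seed=9)
        b = simulate_platform(panel_expression, prof, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_realized_batch_variance_fraction(self, rng):
        # pure batch profile; realized between-batch variance ~ 10% of signal
        expr = pd.DataFrame(rng.normal(5, 1, size=(60, 200)))
        prof = PlatformProfile("b", batch_count=2, batch_variance_fraction=0.1)
        batch = np.arange(200) % 2
        ratios = []
        for seed in range(30):
            out = simulate_platform(expr, prof, seed=seed).to_numpy()
            delta = out - expr.to_numpy()
            b0 = delta[:, batch == 0].mean(axis=1)
            b1 = delta[:, batch == 1].mean(axis=1)
            # per-gene batch offsets have variance f * Var(x)
            ratios.append(np.mean((b0**2 + b1**2) / 2)
                          / expr.to_numpy().var(axis=1).mean())
        assert np.mean(ratios) == pytest.approx(0.1, rel=0.2)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            PlatformProfile("bad", dropout_rate=1.5)

    def test_score_variance_scales_inversely_with_signature_size(self, rng):
        # pure independent noise: variance of a k-gene mean-z score ~ 1/k
        n = 2000
        expr = pd.DataFrame(rng.normal(0, 1, size=(27, n)),
                            index=[f"g{i}" for i in range(27)])
        variances = {}
        for k in (1, 9, 27):
            sig = SignatureDefinition(f"k{k}",
                                      tuple(f"g{i}" for i in range(k)))
            variances[k] = score_signature(expr, sig).scores.var()
        assert variances[1] / variances[27] == pytest.approx(27, rel=0.25)
        assert variances[1] / variances[9] == pytest.approx(9, rel=0.25)


class TestConcordance:
    def test_perfect_agreement(self, rng):
        x = rng.normal(size=30)
        rep = concordance(x, x.copy(), n_boot=50, seed=0)
        assert rep.spearman == 1.0
        assert rep.kappa == 1.0
        assert rep.ccc == pytest.approx(1.0)
        assert rep.bias == 0.0

    def test_kappa_hand_table(self):
        # calls A=[1,1,0,0] vs B=[1,0,0,0]: po=0.75, pe=0.5, kappa=0.5
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 0, 0])
        assert _cohen_kappa(a, b) == pytest.approx(0.5)
        rep = concordance([1.0, 1.0, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0],
                          dichot_threshold=0.5, n_boot=0)
        assert rep.kappa == pytest.approx(0.5)

    def test_ccc_formula_arithmetic(self):
        assert _lin_ccc(np.array([1.0, -1.0]),
                        np.array([-1.0, 1.0])) == pytest.approx(-1.0)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        rep = concordance(x, -x, n_boot=0)
        assert rep.ccc == pytest.approx(-1.0)

    def test_matches_brute_force_on_short_vectors(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(0, 0.5, 10)
        rep = concordance(x, y, n_boot=0)
        # Spearman: Pearson on midranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho_bf = np.corrcoef(rx, ry)[0, 1]
        assert rep.spearman == pytest.approx(rho_bf, abs=1e-12)
        ccc_bf = 2 * np.cov(x, y, ddof=0)[0, 1] / (
            x.var() + y.var() + (x.mean() - y.mean()) ** 2)
        assert rep.ccc == pytest.approx(ccc_bf, abs=1e-12)
        diffs = y - x
        assert rep.bias == pytest.approx(diffs.mean())
        assert rep.loa[1] - rep.loa[0] == pytest.approx(
            2 * 1.96 * diffs.std(ddof=1))

    def test_bootstrap_ci_brackets_estimate(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.3, 50)
        rep = concordance(x, y, n_boot=300, seed=1)
        lo, hi = rep.spearman_ci
        assert lo <= rep.spearman <= hi

    def test_zero_variance_reported_missing(self):
        rep = concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_boot=0)
        assert np.isnan(rep.spearman)
        assert "zero variance" in rep.note

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            concordance([1.0, 2.0], [1.0, 2.0])


class TestStressTest:
    def test_single_value_grid_matches_direct_run(self, panel_expression):
        prof = PlatformProfile.rtqpcr_like()
        sig = default_hot_signature()
        sweep = stress_test(panel_expression, prof, "multiplicative_cv",
                            [0.1], sig, n_rep=1, seed=4)
        sim = simulate_platform(panel_expression,
                                prof.replace(multiplicative_cv=0.1), seed=4)
        ref_s = score_signature(panel_expression, sig).scores.to_numpy()
        sim_s = score_signature(sim, sig).scores.to_numpy()
        direct = concordance(ref_s, sim_s, n_boot=0)
        got = sweep[sweep.metric == "spearman"]["estimate"].iloc[0]
        assert got == pytest.approx(direct.spearman)

    def test_batch_sweep_monotone_non_increasing(self, panel_expression):
        sweep = stress_test(
            panel_expression, PlatformProfile.rtqpcr_like(),
            "batch_variance_fraction", [0.0, 0.05, 0.1, 0.2],
            default_hot_signature(), n_rep=10, seed=5,
        )
        means = (sweep[sweep.metric == "spearman"]
                 .groupby("value")["estimate"].mean())
        assert means.is_monotonic_decreasing

    def test_efficiency_distortion_milder_than_batch(self, panel_expression):
        # systematic batch shifts hurt score concordance more than
        # matched-width per-gene slope distortion
        sig = default_hot_signature()
        prof = PlatformProfile("p", batch_count=2)
        batch = stress_test(panel_expression, prof, "batch_variance_fraction",
                            [0.2], sig, n_rep=10, seed=6)
        eff = stress_test(panel_expression, prof, "efficiency_deviation",
                          [0.2], sig, n_rep=10, seed=6)
        rho_batch = batch[batch.metric == "spearman"]["estimate"].mean()
        rho_eff = eff[eff.metric == "spearman"]["estimate"].mean()
        assert rho_eff > rho_batch

    def test_unknown_parameter_rejected(self, panel_expression):
        with pytest.raises(ValueError, match="unknown profile parameter"):
            stress_test(panel_expression, PlatformProfile.identity(),
                        "warp_speed", [1], default_hot_signature())


class TestAblateSignature:
    def test_half_ablation_of_27_keeps_14(self):
        out = ablate_signature(default_hot_signature(), fraction=0.5, seed=0)
        assert len(out.genes) == 14
        assert set(out.genes) <= set(default_hot_signature().genes)

    def test_zero_fraction_is_identity(self):
        sig = default_hot_signature()
        assert ablate_signature(sig, fraction=0.0) is sig

    def test_correlated_program_survives_ablation_better_than_random(
        self, bulk_cohort, panel_expression
    ):
        from triaxis import make_negative_controls

        expr = bulk_cohort.expression
        hot = default_hot_signature()
        rand = make_negative_controls(expr.index, size=27, n_controls=1,
                                      seed=8)[0]
        diffs = []
        for seed in range(5):
            hot_half = ablate_signature(hot, 0.5, seed=seed)
            rand_half = ablate_signature(rand, 0.5, seed=seed)
            r_hot = stats.spearmanr(
                score_signature(expr, hot).scores,
                score_signature(expr, hot_half).scores).statistic
            r_rand = stats.spearmanr(
                score_signature(expr, rand).scores,
                score_signature(expr, rand_half).scores).statistic
            diffs.append(r_hot - r_rand)
        assert np.mean(diffs) > 0


class TestSignaturePanel:
    def test_identity_profile_all_perfect(self, panel_expression):
        sigs = [default_hot_signature(),
                SignatureDefinition("B", ("BCL2A1",)),
                SignatureDefinition("C", ("CD274",))]
        tab = run_signature_panel(panel_expression, sigs,
                                  [PlatformProfile.identity()], seed=0)
        np.testing.assert_allclose(tab["spearman"], 1.0)
        np.testing.assert_allclose(tab["kappa"], 1.0)

    def test_panel_deterministic(self, panel_expression):
        sigs = [default_hot_signature()]
        profs = [PlatformProfile.htg_like(), PlatformProfile.nanostring_like()]
        a = run_signature_panel(panel_expression, sigs, profs, seed=2)
        b = run_signature_panel(panel_expression, sigs, profs, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_multi_gene_score_more_robust_than_worst_member(
        self, panel_expression
    ):
        sigs = [default_hot_signature()] + [
            SignatureDefinition(f"g_{g}", (g,))
            for g in default_hot_signature().genes[:5]
        ]
        prof = PlatformProfile("drop", dropout_rate=0.3,
                               multiplicative_cv=0.2)
        rhos = []
        for seed in range(5):
            tab = run_signature_panel(panel_expression, sigs, [prof],
                                      seed=seed)
            hot_rho = tab[tab.signature == "HOT"]["spearman"].iloc[0]
            worst = tab[tab.signature != "HOT"]["spearman"].min()
            rhos.append(hot_rho - worst)
        assert np.mean(rhos) > 0

    def test_empty_registry_rejected(self, panel_expression):
        with pytest.raises(ValueError):
            run_signature_panel(panel_expression, [],
                                [PlatformProfile.identity()])
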
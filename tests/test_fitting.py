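"""MAP fitting, Laplace evidence, hierarchical fits, PXP."""

import numpy as np
import pytest

from explorebandit import fitting as ft
from explorebandit import task as tk
from explorebandit.likelihood import compile_session
from explorebandit.models import get_model
from tests.conftest import simulate_group


def _compiled_group(sessions):
    return [compile_session(s.trials, s.participant_id) for s in sessions]


class TestLaplaceEvidence:
    def test_exact_on_conjugate_gaussian(self):
        """For a Gaussian likelihood and Gaussian prior the Laplace
        approximation equals the closed-form marginal likelihood."""
        y, sigma2, mu0, v0 = 1.3, 0.5, 0.0, 2.0
        post_var = 1.0 / (1 / sigma2 + 1 / v0)
        mode = post_var * (y / sigma2 + mu0 / v0)

        def nlp(theta):
            return (
                0.5 * ((y - theta) ** 2 / sigma2 + np.log(2 * np.pi * sigma2))
                + 0.5 * ((theta - mu0) ** 2 / v0 + np.log(2 * np.pi * v0))
            )

        hessian = np.array([[1 / sigma2 + 1 / v0]])
        log_z = ft.laplace_evidence(nlp(mode), hessian, 1)
        closed = -0.5 * (
            (y - mu0) ** 2 / (sigma2 + v0) + np.log(2 * np.pi * (sigma2 + v0))
        )
        assert log_z == pytest.approx(closed, abs=1e-8)

    def test_zero_dimensional_evidence_is_negative_nll(self):
        assert ft.laplace_evidence(12.5, np.zeros((0, 0)), 0) == -12.5

    def test_regularizes_non_pd_hessian(self):
        log_z, jitter = ft.laplace_evidence(
            1.0, np.array([[-1.0, 0.0], [0.0, 2.0]]), 2, return_jitter=True
        )
        assert np.isfinite(log_z) and jitter > 0

    def test_evidence_separates_models_with_more_data(self):
        """On a Gaussian toy, the evidence margin between the true-mean
        model and a wrong-mean model grows with the amount of data."""
        rng = np.random.default_rng(0)

        def margin(n):
            y = rng.normal(0.0, 1.0, n)
            # models: fixed mean 0 vs fixed mean 1, unit variance, no free
            # parameters -> evidence = -NLL
            nll_true = 0.5 * np.sum(y**2) + 0.5 * n * np.log(2 * np.pi)
            nll_wrong = 0.5 * np.sum((y - 1.0) ** 2) + 0.5 * n * np.log(2 * np.pi)
            return ft.laplace_evidence(nll_true, np.zeros((0, 0)), 0) - ft.laplace_evidence(
                nll_wrong, np.zeros((0, 0)), 0
            )

        margins_small = [margin(20) for _ in range(40)]
        margins_large = [margin(200) for _ in range(40)]
        assert np.mean(margins_large) > np.mean(margins_small) > 0


class TestFitMap:
    def test_parameter_recovery_on_simulated_sessions(self):
        """Median learning-rate error across simulated subjects stays
        within the broad single-session identifiability band."""
        model = get_model("baseline")
        errors = []
        for i in range(20):
            structure = tk.generate_task(tk.TaskConfig(), 600 + i)
            session = tk.simulate_agent(
                structure, model, {"beta_sm": 6.0, "eta": 0.7}, seed=700 + i
            )
            fit = ft.fit_map(
                compile_session(session.trials, "p"), model, n_restarts=3, seed=i
            )
            errors.append(abs(fit.params["eta"] - 0.7))
        assert np.median(errors) < 0.2

    def test_uninformative_data_pulled_to_prior_mean(self):
        structure = tk.generate_task(tk.TaskConfig(), 8)
        session = tk.simulate_agent(
            structure, get_model("baseline"), {"beta_sm": 0.001, "eta": 0.5}, seed=9
        )
        fit = ft.fit_map(
            compile_session(session.trials, "p"),
            get_model("novelty_bias"),
            n_restarts=3,
            seed=0,
        )
        # random choices carry no information about the novelty bias, whose
        # mode stays near the prior mean; the inverse-temperature mode is
        # pulled toward the prior mean relative to its unbounded ML limit
        # (beta -> 0, i.e. unconstrained -> -inf)
        assert abs(fit.x[2]) < 0.5
        assert np.isfinite(fit.x[0]) and fit.x[0] > -4.0

    def test_deterministic_given_seed(self, famgate_compiled):
        model = get_model("familiarity_gate")
        a = ft.fit_map(famgate_compiled, model, n_restarts=4, seed=5)
        b = ft.fit_map(famgate_compiled, model, n_restarts=4, seed=5)
        assert np.array_equal(a.x, b.x)
        assert a.log_evidence == b.log_evidence

    def test_occam_penalty_favors_simpler_model_on_its_own_data(self):
        """Laplace evidence penalizes the unused novelty parameter when the
        data come from the baseline model."""
        base, rich = get_model("baseline"), get_model("novelty_bias")
        margins = []
        for i in range(10):
            structure = tk.generate_task(tk.TaskConfig(), 900 + i)
            session = tk.simulate_agent(
                structure, base, {"beta_sm": 8.0, "eta": 0.7}, seed=950 + i
            )
            compiled = compile_session(session.trials, "p")
            fb = ft.fit_map(compiled, base, n_restarts=3, seed=i)
            fr = ft.fit_map(compiled, rich, n_restarts=3, seed=i)
            margins.append(fb.log_evidence - fr.log_evidence)
        assert np.mean(margins) > 0


class TestProtectedExceedance:
    def test_normalization_and_shift_invariance(self):
        rng = np.random.default_rng(3)
        evidence = rng.normal(size=(25, 4))
        xp, pxp, bor, _ = ft.protected_exceedance(evidence, seed=0, n_samples=50_000)
        assert pxp.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all((pxp >= 0) & (pxp <= 1))
        shifted = evidence + rng.normal(size=(25, 1))  # per-subject constant
        xp2, pxp2, bor2, _ = ft.protected_exceedance(shifted, seed=0, n_samples=50_000)
        assert np.allclose(xp, xp2, atol=1e-12)
        assert bor == pytest.approx(bor2, abs=1e-9)

    def test_null_limit_identical_evidences(self):
        evidence = np.tile(np.linspace(-3, -1, 30)[:, None], (1, 4))
        xp, pxp, bor, _ = ft.protected_exceedance(evidence, seed=1)
        assert bor > 0.9
        assert np.allclose(pxp, 0.25, atol=0.03)

    def test_decisive_evidence_gives_pxp_one(self):
        evidence = np.zeros((20, 3))
        evidence[:, 0] = 5.0  # every subject favors model 0 by 5 nats
        xp, pxp, bor, _ = ft.protected_exceedance(evidence, seed=2)
        assert pxp[0] > 0.95 and bor < 0.05

    def test_symmetric_two_model_case(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 0.01, size=20)
        evidence = np.column_stack([noise, -noise])
        xp, pxp, bor, _ = ft.protected_exceedance(evidence, seed=3, n_samples=100_000)
        assert abs(xp[0] - 0.5) < 0.02

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ft.protected_exceedance(np.array([[np.nan, 0.0]]))
        with pytest.raises(ValueError):
            ft.protected_exceedance(np.zeros((5,)))


class TestHBIFit:
    @pytest.fixture(scope="class")
    def novelty_vs_baseline(self, novelty_cohort_sessions):
        compiled = _compiled_group(novelty_cohort_sessions[:15])
        return ft.hbi_fit(
            compiled,
            ["baseline", "novelty_bias", "familiarity_gate"],
            ft.HBIConfig(seed=0, n_restarts=2, is_samples=200),
        )

    def test_generating_model_dominates(self, novelty_vs_baseline):
        result = novelty_vs_baseline
        j = result.model_index("novelty_bias")
        assert result.frequencies[j] > 0.7
        assert int(np.argmax(result.pxp)) == j

    def test_responsibilities_row_normalize(self, novelty_vs_baseline):
        rows = novelty_vs_baseline.responsibilities.sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-9)
        assert novelty_vs_baseline.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_frequencies_consistent_with_responsibilities(self, novelty_vs_baseline):
        result = novelty_vs_baseline
        expected = (1.0 + result.responsibilities.sum(axis=0)) / (
            len(result.participant_ids) + len(result.models)
        )
        assert np.allclose(result.frequencies, expected, atol=1e-9)

    def test_group_prior_approaches_generating_mean(self, novelty_cohort_sessions):
        compiled = _compiled_group(novelty_cohort_sessions)
        result = ft.hbi_fit(
            compiled,
            ["novelty_bias"],
            ft.HBIConfig(seed=0, n_restarts=3, is_samples=500),
        )
        assert result.group_means["novelty_bias"][2] == pytest.approx(1.49, abs=0.5)

    def test_needs_two_subjects(self, famgate_compiled):
        with pytest.raises(ValueError):
            ft.hbi_fit([famgate_compiled], ["baseline"], ft.HBIConfig())


class TestGroupParameterTest:
    def _result(self, values, resp=None):
        n = len(values)
        modes = np.column_stack([np.zeros(n), np.zeros(n), values])
        return ft.HBIResult(
            models=("novelty_bias",),
            participant_ids=tuple(f"p{i}" for i in range(n)),
            responsibilities=np.ones((n, 1)) if resp is None else resp,
            frequencies=np.ones(1),
            dirichlet_alpha=np.ones(1),
            evidence=np.zeros((n, 1)),
            group_means={"novelty_bias": modes.mean(axis=0)},
            group_variances={"novelty_bias": modes.var(axis=0) + 1e-3},
            subject_modes={"novelty_bias": modes},
            xp=np.ones(1),
            pxp=np.ones(1),
            bor=0.0,
            n_iter=1,
            converged=True,
        )

    def test_full_membership_dof(self):
        t, dof, p = ft.group_parameter_test(
            self._result(np.linspace(1, 2, 30)), "novelty_bias", "novelty_bias"
        )
        assert dof == pytest.approx(29.0)
        assert t > 0 and p < 1e-6

    def test_zero_mean_gives_zero_t(self):
        t, dof, p = ft.group_parameter_test(
            self._result(np.array([-1.0, 1.0, -2.0, 2.0])), "novelty_bias", "novelty_bias"
        )
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            ft.group_parameter_test(
                self._result(np.ones(5)), "novelty_bias", "w_unc"
            )

    def test_positive_bias_detected_in_replicate_cohorts(self):
        """Power check: child-like cohorts generated with a positive
        novelty bias yield a significant positive group test in nearly all
        replicates."""
        hits = 0
        n_reps = 8
        for rep in range(n_reps):
            sessions = simulate_group(
                "novelty_bias",
                lambda rng: {
                    "beta_sm": 6.0,
                    "eta": 0.7,
                    "novelty_bias": float(rng.normal(1.49, 0.5)),
                },
                n=12,
                seed0=50 + rep,
                age=10.0,
            )
            result = ft.hbi_fit(
                _compiled_group(sessions),
                ["novelty_bias"],
                ft.HBIConfig(seed=rep, n_restarts=2, is_samples=200),
            )
            t, dof, p = ft.group_parameter_test(result, "novelty_bias", "novelty_bias")
            if t > 0 and p < 0.05:
                hits += 1
        assert hits >= n_reps - 1
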
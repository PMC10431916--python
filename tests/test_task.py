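"""Task generation, agent simulation, cohorts, memory test."""

import numpy as np
import pandas as pd
import pytest

from explorebandit import task as tk
from explorebandit.models import get_model


class TestGenerateTask:
    def test_default_geometry(self, default_task):
        assert len(default_task.blocks) == 10
        difficulties = [b.difficulty for b in default_task.blocks]
        assert difficulties.count("easy") == 5 and difficulties.count("hard") == 5
        for block in default_task.blocks:
            assert len(block.trials) == 15
            assert len(set(block.stimuli)) == 3
            triple = (0.8, 0.5, 0.2) if block.difficulty == "easy" else (0.7, 0.5, 0.3)
            assert sorted(block.probs) == sorted(triple)
            for left, right in block.trials:
                assert left in block.stimuli and right in block.stimuli
                assert left != right

    def test_one_debut_per_block(self, default_task):
        seen = set()
        for i, block in enumerate(default_task.blocks):
            new = set(block.stimuli) - seen
            assert len(new) == (3 if i == 0 else 1)
            seen |= set(block.stimuli)

    def test_balanced_pair_schedule_option(self):
        structure = tk.generate_task(tk.TaskConfig(pair_scheduling="balanced"), seed=13)
        for block in structure.blocks:
            pairs = [frozenset(t) for t in block.trials]
            counts = pd.Series(pairs).value_counts()
            assert len(counts) == 3 and (counts == 5).all()

    def test_random_pair_schedule_is_uniform_with_spread(self):
        per_block_counts = []
        for seed in range(40):
            structure = tk.generate_task(tk.TaskConfig(), 9_000 + seed)
            for block in structure.blocks:
                counts = pd.Series([frozenset(t) for t in block.trials]).value_counts()
                per_block_counts.extend(counts.tolist())
        per_block_counts = np.array(per_block_counts, dtype=float)
        # uniform sampling: each pair averages 5 shows per block but varies
        assert abs(per_block_counts.mean() - 5.0) < 0.3
        assert per_block_counts.std() > 0.8

    def test_single_block_degenerate(self):
        structure = tk.generate_task(tk.TaskConfig(n_blocks=1, n_easy=1), seed=0)
        assert len(structure.blocks) == 1
        assert len(set(structure.blocks[0].stimuli)) == 3

    def test_deterministic_given_seed(self):
        a = tk.generate_task(tk.TaskConfig(), 5)
        b = tk.generate_task(tk.TaskConfig(), 5)
        assert a == b

    def test_pool_exhaustion_rejected(self):
        with pytest.raises(ValueError):
            tk.TaskConfig(n_blocks=20, stimulus_pool_size=14).validate()

    def test_side_placement_balanced_across_seeds(self):
        left_first = 0
        total = 0
        for seed in range(60):
            structure = tk.generate_task(tk.TaskConfig(), 700 + seed)
            for block in structure.blocks:
                for left, right in block.trials:
                    total += 1
                    if left < right:
                        left_first += 1
        rate = left_first / total
        assert abs(rate - 0.5) < 4 * np.sqrt(0.25 / total)

    def test_reused_stimulus_encounter_range(self):
        """Across many seeds, prior-encounter counts of reused stimuli span
        a wide range (single digits up to dozens)."""
        lo, hi = np.inf, -np.inf
        for seed in range(100):
            structure = tk.generate_task(tk.TaskConfig(), 3000 + seed)
            counts: dict = {}
            seen: set = set()
            for block in structure.blocks:
                for s in block.stimuli:
                    if s in seen:
                        prior = counts.get(s, 0)
                        lo, hi = min(lo, prior), max(hi, prior)
                seen |= set(block.stimuli)
                for left, right in block.trials:
                    counts[left] = counts.get(left, 0) + 1
                    counts[right] = counts.get(right, 0) + 1
        assert lo < 10
        assert hi > 40


class TestSimulateAgent:
    def test_greedy_limit_converges_to_winning_option(self):
        config = tk.TaskConfig(easy_probs=(1.0, 0.0, 0.0), n_easy=10)
        structure = tk.generate_task(config, 2)
        session = tk.simulate_agent(
            structure,
            get_model("baseline"),
            {"beta_sm": 19.9, "eta": 0.99},
            seed=3,
        )
        late = session.trials[session.trials["trial"] > 7]
        chose_prob = np.where(
            late["choice"] == "left", late["prob_left"], late["prob_right"]
        )
        best_shown = np.maximum(late["prob_left"], late["prob_right"])
        assert np.mean(chose_prob == best_shown) > 0.95

    def test_indifference_limit_is_unbiased(self):
        structure = tk.generate_task(tk.TaskConfig(), 4)
        rates = []
        for seed in range(20):
            session = tk.simulate_agent(
                structure, get_model("baseline"), {"beta_sm": 0.001, "eta": 0.5}, seed=seed
            )
            rates.append((session.trials["choice"] == "left").mean())
        assert abs(np.mean(rates) - 0.5) < 4 * np.sqrt(0.25 / (20 * 150))

    def test_long_run_reward_frequencies_match_design(self):
        """Outcome frequencies at each design probability (80/70/50/30/20%)
        match within a binomial band at n ~ 10,000 per level."""
        outcomes: dict = {}
        model = get_model("baseline")
        for i in range(400):
            structure = tk.generate_task(tk.TaskConfig(), 40_000 + i)
            session = tk.simulate_agent(
                structure, model, {"beta_sm": 0.001, "eta": 0.5}, seed=50_000 + i
            )
            made = session.trials["choice"].isin(["left", "right"])
            t = session.trials[made]
            p = np.where(t["choice"] == "left", t["prob_left"], t["prob_right"])
            win = (t["outcome"] == "win").to_numpy()
            for prob, w in zip(p, win):
                outcomes.setdefault(round(prob, 1), []).append(w)
        assert set(outcomes) == {0.8, 0.7, 0.5, 0.3, 0.2}
        for prob, wins in outcomes.items():
            n = len(wins)
            assert n > 8000
            assert abs(np.mean(wins) - prob) < 4 * np.sqrt(prob * (1 - prob) / n)

    def test_outcome_present_iff_choice_made(self, famgate_session):
        t = famgate_session.trials
        assert ((t["choice"] == "missed") == (t["outcome"] == "none")).all()
        made = t[t["choice"] != "missed"]
        assert made["rt_sec"].between(0, 4.0, inclusive="right").all()

    def test_missing_parameter_rejected(self, default_task):
        with pytest.raises(ValueError):
            tk.simulate_agent(
                default_task, get_model("novelty_bias"), {"beta_sm": 5, "eta": 0.5}, 0
            )


class TestGenerateCohort:
    def test_default_cohort_mirrors_study(self):
        sessions, truth = tk.generate_cohort(tk.default_cohort_config(), seed=9)
        assert len(sessions) == 122
        assert truth.groupby("group").size().to_dict() == {
            "children": 30,
            "adolescents": 30,
            "adults": 62,
        }
        assert truth["age_years"].between(8, 28).all()
        # children generated from the novelty-bias model, others fam-gate
        assert (truth.loc[truth["group"] == "children", "model"] == "novelty_bias").all()
        assert (truth.loc[truth["group"] != "children", "model"] == "familiarity_gate").all()
        assert all(s.memory is not None and len(s.memory) == 10 for s in sessions)

    def test_zero_sd_gives_identical_parameters(self):
        group = tk.GroupSpec(
            name="adults",
            age_range=(18, 28),
            n_subjects=4,
            model="baseline",
            param_means={"beta_sm": 6.0, "eta": 0.7},
            param_sds={},
        )
        _, truth = tk.generate_cohort(tk.CohortConfig(groups=(group,)), seed=1)
        assert truth["true_beta_sm"].nunique() == 1
        assert truth["true_eta"].nunique() == 1

    def test_ground_truth_round_trips_through_csv(self, tmp_path):
        group = tk.GroupSpec(
            name="adults",
            age_range=(18, 28),
            n_subjects=3,
            model="familiarity_gate",
            param_means={"beta_sm": 6.0, "eta": 0.7, "w_unc": -0.15},
            param_sds={"w_unc": 0.1},
        )
        _, truth = tk.generate_cohort(tk.CohortConfig(groups=(group,)), seed=2)
        path = tmp_path / "truth.csv"
        truth.to_csv(path, index=False)
        reloaded = pd.read_csv(path)
        pd.testing.assert_frame_equal(truth, reloaded)

    def test_injected_bad_trial_rate(self):
        cfg = tk.default_cohort_config()
        sessions, _ = tk.generate_cohort(cfg, seed=3)
        trials = pd.concat([s.trials for s in sessions])
        bad = (trials["choice"] == "missed") | (trials["rt_sec"] < 0.2)
        rate = bad.mean()
        target = cfg.miss_rate + (1 - cfg.miss_rate) * cfg.fast_rate
        assert abs(rate - target) < 4 * np.sqrt(target * (1 - target) / len(trials))


class TestMemoryTest:
    def test_array_structure(self, default_task):
        memory = tk.generate_memory_test(default_task, seed=1, accuracy=0.5)
        assert len(memory) == 10
        for rec in memory.itertuples(index=False):
            options = [getattr(rec, f"option_{i}") for i in range(1, 6)]
            assert len(set(options)) == 5
            block = default_task.blocks[rec.block - 1]
            assert rec.correct_id == block.best_stimulus
            assert set(block.stimuli) <= set(options)
            extras = set(options) - set(block.stimuli)
            shown = set(default_task.shown_stimuli)
            assert sum(1 for e in extras if e in shown) == 1  # old, other block
            assert sum(1 for e in extras if e not in shown) == 1  # never shown

    def test_chance_and_perfect_responders(self, default_task):
        correct = []
        for seed in range(150):
            memory = tk.generate_memory_test(default_task, seed=seed, accuracy=0.2)
            correct.extend((memory["response_id"] == memory["correct_id"]).tolist())
        acc = np.mean(correct)
        assert abs(acc - 0.2) < 4 * np.sqrt(0.2 * 0.8 / len(correct))
        perfect = tk.generate_memory_test(default_task, seed=0, accuracy=1.0)
        assert (perfect["response_id"] == perfect["correct_id"]).all()

    def test_single_block_task_rejected(self):
        structure = tk.generate_task(tk.TaskConfig(n_blocks=1, n_easy=0), seed=0)
        with pytest.raises(ValueError):
            tk.generate_memory_test(structure, seed=0)
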
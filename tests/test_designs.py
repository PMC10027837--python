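import collections

import numpy as np
import pandas as pd
import pytest

import rok
from rok.assignment import RANDOM
from rok.designs import (
    COHERENCE_LEVELS,
    CONGRUENCY_LEVELS,
    DISTRACTOR_BLOCKS,
    N_DISTRACTOR_OBJECTS,
    TRIALS_PER_BLOCK,
)


@pytest.fixture(scope="module")
def exp1():
    return rok.build_experiment("exp1", rng=np.random.default_rng(100))


class TestExperimentStructure:
    def test_ten_blocks_of_72_with_16_training(self, exp1):
        assert len(exp1.blocks) == 10
        assert all(len(b.trials) == TRIALS_PER_BLOCK for b in exp1.blocks)
        assert exp1.training_trials == 16
        assert all(t.context == "training" for t in exp1.training)

    def test_blocks_one_and_six_are_distractor_blocks(self, exp1):
        for i, block in enumerate(exp1.blocks):
            expected = "distractor" if i in DISTRACTOR_BLOCKS else "factorial"
            assert block.block_type == expected

    def test_task_switches_between_halves(self, exp1):
        first_half = {b.task for b in exp1.blocks[:5]}
        second_half = {b.task for b in exp1.blocks[5:]}
        assert first_half == {rok.MainTask.movement}
        assert second_half == {rok.MainTask.orientation}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_factorial_cell_balance(self, seed):
        design = rok.build_experiment("exp1", rng=np.random.default_rng(seed))
        for i, block in enumerate(design.blocks):
            if block.block_type != "factorial":
                continue
            cells = collections.Counter(
                (t.meta["coherence"], t.meta["congruency"]) for t in block.trials
            )
            assert len(cells) == 12
            assert set(cells.values()) == {6}
            assert set(c for c, _ in cells) == set(COHERENCE_LEVELS)
            assert set(c for _, c in cells) == set(CONGRUENCY_LEVELS)

    def test_seeds_shuffle_orders_but_not_contents(self):
        a = rok.build_experiment("exp1", rng=np.random.default_rng(1))
        b = rok.build_experiment("exp1", rng=np.random.default_rng(2))
        cells_a = [(t.meta["coherence"], t.meta["congruency"]) for t in a.blocks[1].trials]
        cells_b = [(t.meta["coherence"], t.meta["congruency"]) for t in b.blocks[1].trials]
        assert sorted(cells_a) == sorted(cells_b)
        assert cells_a != cells_b

    def test_task_order_counterbalancing_preserves_trial_multiset(self):
        a = rok.build_experiment("exp1", "motion_first", rng=np.random.default_rng(3))
        b = rok.build_experiment("exp1", "orientation_first", rng=np.random.default_rng(3))

        def multiset(design):
            return sorted(
                (t.meta["block_type"], t.meta["task"], t.meta["coherence"], t.meta["congruency"])
                for block in design.blocks
                for t in block.trials
            )

        assert multiset(a) == multiset(b)

    def test_key_mapping_reverses_correct_keys(self):
        a = rok.build_experiment("exp1", key_mapping="up_F", rng=np.random.default_rng(4))
        b = rok.build_experiment("exp1", key_mapping="up_J", rng=np.random.default_rng(4))
        for design, up_key in ((a, "F"), (b, "J")):
            for t in design.blocks[1].trials:
                expected = up_key if t.meta["direction"] == 90.0 else ("J" if up_key == "F" else "F")
                assert t.correct_choice == [expected]

    def test_two_direction_displays_and_distractor_settings(self, exp1):
        t = exp1.blocks[1].trials[0]
        layer = t.scene.apertures[0][1]
        assert layer.coherence_movement + layer.coherence_movement_opposite == pytest.approx(1.0)
        d = exp1.blocks[0].trials[0]
        assert d.meta["coherence"] == 0.65 and d.meta["congruency"] == 0.50

    def test_exp2_uses_sprites_and_background(self):
        design = rok.build_experiment("exp2", rng=np.random.default_rng(5))
        t = design.blocks[1].trials[0]
        assert t.scene.background_image == "builtin:nature"
        assert t.scene.apertures[0][1].stimulus_type is rok.StimulusType.image

    def test_design_json_round_trip(self, exp1):
        dumped = exp1.model_dump_json()
        back = rok.DesignSpec.model_validate_json(dumped)
        assert back == exp1


class TestDistractorLayer:
    def test_seventy_objects_at_target_geometry(self, rng):
        aperture, layer = rok.build_distractor_layer(rng)
        assert layer.number_of_oobs == N_DISTRACTOR_OBJECTS
        assert layer.oob_size == 1.0 and layer.movement_speed == 3.0

    def test_orientation_classes_all_random(self, rng):
        for _ in range(20):
            _, layer = rok.build_distractor_layer(rng)
            a = rok.build_layer_assignment(layer, layer.number_of_oobs, rng)
            assert np.all(a.orientation_class == RANDOM)
            assert np.all(a.movement_class == RANDOM)

    def test_colors_split_evenly(self):
        rng = np.random.default_rng(8)
        counts = np.zeros(2)
        draws = 0
        for _ in range(100):
            aperture, layer = rok.build_distractor_layer(rng)
            state = rok.realize_layer(aperture, layer, rng)
            turquoise = (state.colors == np.array([64, 224, 208], np.uint8)).all(axis=1)
            counts[0] += turquoise.sum()
            counts[1] += (~turquoise).sum()
            draws += state.n
        p = counts[0] / draws
        se = np.sqrt(0.25 / draws)
        assert abs(p - 0.5) < 3 * se

    def test_distractor_trial_fraction_near_ten_percent(self):
        present = total = 0
        for seed in range(30):
            design = rok.build_experiment("exp1", rng=np.random.default_rng(seed))
            for b in DISTRACTOR_BLOCKS:
                flags = [t.meta["distractor"] for t in design.blocks[b].trials]
                present += sum(flags)
                total += len(flags)
        p = present / total
        se = np.sqrt(0.1 * 0.9 / total)
        assert abs(p - 0.10) < 3 * se

    def test_quota_mode_is_exact(self):
        design = rok.build_experiment(
            "exp1", rng=np.random.default_rng(9), distractor_quota=True
        )
        for b in DISTRACTOR_BLOCKS:
            assert sum(t.meta["distractor"] for t in design.blocks[b].trials) == 7


class TestSyntheticObserver:
    def _trial(self, coherence, congruency):
        design_trial = rok.build_experiment("exp1", rng=np.random.default_rng(0)).blocks[1].trials[0]
        meta = dict(design_trial.meta, coherence=coherence, congruency=congruency)
        return design_trial.model_copy(update={"meta": meta})

    def test_accuracy_matches_logistic_model(self):
        rng = np.random.default_rng(17)
        params = rok.SyntheticObserverParams()
        trial = self._trial(0.75, 0.25)
        logit = (
            params.accuracy_intercept
            + params.accuracy_coherence_slope * 0.75
            + params.accuracy_congruency_slope * 0.25
        )
        p = (1 - params.lapse) / (1 + np.exp(-logit)) + params.lapse / 2
        hits = sum(
            rok.synthetic_observer(trial, params, rng).key == trial.correct_choice[0]
            for _ in range(10_000)
        )
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(hits / 10_000 - p) < 3 * se

    def test_full_lapse_is_chance(self):
        rng = np.random.default_rng(18)
        params = rok.SyntheticObserverParams(lapse=1.0)
        trial = self._trial(0.9, 1.0)
        hits = sum(
            rok.synthetic_observer(trial, params, rng).key == trial.correct_choice[0]
            for _ in range(4000)
        )
        se = np.sqrt(0.25 / 4000)
        assert abs(hits / 4000 - 0.5) < 4 * se

    def test_steep_coherence_slope_saturates_accuracy(self):
        rng = np.random.default_rng(19)
        params = rok.SyntheticObserverParams(accuracy_coherence_slope=100.0, lapse=0.0)
        trial = self._trial(0.9, 1.0)
        assert all(
            rok.synthetic_observer(trial, params, rng).key == trial.correct_choice[0]
            for _ in range(200)
        )

    def test_rt_decreases_with_coherence(self):
        rng = np.random.default_rng(20)
        params = rok.SyntheticObserverParams()
        slow = np.mean([rok.synthetic_observer(self._trial(0.6, 0.5), params, rng).time
                        for _ in range(2000)])
        fast = np.mean([rok.synthetic_observer(self._trial(0.9, 0.5), params, rng).time
                        for _ in range(2000)])
        assert fast < slow


class TestFilterTrials:
    def _table(self):
        return pd.DataFrame(
            {
                "participant": ["p0"] * 6,
                "context": ["experimental"] * 6,
                "rt": [150.0, 800.0, np.nan, 900.0, 700.0, 650.0],
                "correct": [True, False, False, True, True, True],
                "timeout": [False, False, True, False, False, False],
            }
        )

    def test_flags(self):
        df = rok.filter_trials(self._table())
        assert df["fast"].tolist() == [True, False, False, False, False, False]
        assert df["error"].tolist() == [False, True, False, False, False, False]
        # trial after the error (and after the timeout, which is not an error)
        assert df["post_error"].tolist() == [False, False, True, False, False, False]

    def test_participant_exclusion_threshold(self):
        df = self._table()
        df["correct"] = [False, False, False, True, True, False]
        out = rok.filter_trials(df)
        assert out["excluded_participant"].all()  # 2/5 responded correct <= 60%
        good = rok.filter_trials(self._table())
        assert not good["excluded_participant"].any()  # 4/5 responded correct

    def test_all_correct_run_has_no_error_flags(self):
        rng = np.random.default_rng(21)
        design = rok.build_experiment("exp1", rng=rng)
        params = rok.SyntheticObserverParams(accuracy_coherence_slope=100.0, lapse=0.0)
        sub = design.model_copy(update={"blocks": design.blocks[1:2], "training": []})
        df = rok.filter_trials(rok.simulate_experiment(sub, params, rng))
        assert not df["error"].any() and not df["post_error"].any()


class TestParameterRecovery:
    def test_logistic_fit_recovers_coefficient_signs(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        frames = []
        for p in range(2):
            design = rok.build_experiment("exp1", rng=rng)
            df = rok.simulate_experiment(
                design, rok.SyntheticObserverParams(), rng,
                participant=f"p{p}", include_training=False,
            )
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        df = rok.filter_trials(df)
        fac = df[(df["block_type"] == "factorial") & ~df["timeout"] & ~df["fast"]]

        X = sm.add_constant(fac[["coherence", "congruency"]].astype(float))
        fit = sm.Logit(fac["error"].astype(int), X).fit(disp=0)
        assert fit.params["coherence"] < 0  # fewer errors at high coherence
        assert fit.params["congruency"] < 0  # fewer errors when congruent

        rt = fac[fac["correct"] & ~fac["post_error"]]
        ols = sm.OLS(rt["rt"].astype(float), sm.add_constant(rt[["coherence", "congruency"]].astype(float))).fit()
        assert ols.params["coherence"] < 0  # faster at high coherence
        assert ols.params["congruency"] < 0
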
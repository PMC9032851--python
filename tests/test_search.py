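import numpy as np
import pytest

import oracles
from cpgsieve import (
    BetaMatrix,
    ClassifierSpec,
    LabelVector,
    SearchConfig,
    SearchState,
    SynthSpec,
    ValidationError,
    elimination_step,
    evaluate_subset,
    generate,
    make_split_plan,
    run_search,
)


class FixedChoiceRng:
    """Stands in for a Generator: returns preset values from integers()."""

    def __init__(self, choices):
        self.choices = list(choices)

    def integers(self, high):
        value = self.choices.pop(0)
        assert value < high
        return value


@pytest.fixture(scope="module")
def instance():
    bm, labels, truth = generate(SynthSpec(n_cpgs=30, n_informative=6, seed=19))
    plan = make_split_plan(bm.n_samples, labels, n_repeats=5, seed=23)
    return bm, labels, plan, truth


@pytest.fixture
def sep_plus_noise(separable_bm):
    bm, labels = separable_bm
    plan = make_split_plan(bm.n_samples, labels, n_repeats=5, seed=13)
    return bm, labels, plan


class TestEvaluateSubset:
    def test_separating_cpg_alone_reaches_one(self, sep_plus_noise, stub_spec):
        bm, labels, plan = sep_plus_noise
        assert evaluate_subset(bm, labels, ["cg_sep"], plan, stub_spec) == 1.0

    def test_all_noise_matches_majority_oracle(self):
        rng = np.random.default_rng(3)
        labels = LabelVector(np.array([0] * 5 + [1] * 7))
        bm = BetaMatrix(rng.random((12, 3)), ["a", "b", "c"],
                        [f"s{i}" for i in range(12)])
        plan = make_split_plan(12, labels, n_repeats=8, seed=4)
        got = evaluate_subset(bm, labels, ["a", "b", "c"], plan,
                              ClassifierSpec(backend="majority_stub"))
        expected = oracles.majority_mf(labels.labels.tolist(), plan.partitions)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_centroid_oracle(self, stub_spec):
        rng = np.random.default_rng(9)
        labels = LabelVector(np.arange(14) % 2)
        bm = BetaMatrix(rng.random((14, 4)), ["a", "b", "c", "d"],
                        [f"s{i}" for i in range(14)])
        plan = make_split_plan(14, labels, n_repeats=6, seed=7)
        got = evaluate_subset(bm, labels, ["b", "d"], plan, stub_spec)
        expected = oracles.threshold_subset_mf(
            bm.values.tolist(), labels.labels.tolist(), [1, 3], plan.partitions
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_is_an_error(self, sep_plus_noise, stub_spec):
        bm, labels, plan = sep_plus_noise
        with pytest.raises(ValidationError):
            evaluate_subset(bm, labels, [], plan, stub_spec)


class TestEliminationStep:
    def test_removing_the_noise_cpg_is_accepted(self, sep_plus_noise, stub_spec):
        bm, labels, plan = sep_plus_noise
        mf0 = evaluate_subset(bm, labels, ["cg_sep", "cg_noise"], plan, stub_spec)
        assert mf0 < 1.0  # the noise CpG hurts the centroid rule here
        state = SearchState(current_cpgs=["cg_sep", "cg_noise"], mf_current=mf0)
        elimination_step(state, bm, labels, plan, stub_spec, FixedChoiceRng([1]))
        assert state.current_cpgs == ["cg_sep"]
        assert state.mf_current == 1.0
        assert state.history[-1].accepted

    def test_removing_the_separating_cpg_is_rejected(self, sep_plus_noise, stub_spec):
        bm, labels, plan = sep_plus_noise
        mf0 = evaluate_subset(bm, labels, ["cg_sep", "cg_noise"], plan, stub_spec)
        state = SearchState(current_cpgs=["cg_sep", "cg_noise"], mf_current=mf0)
        elimination_step(state, bm, labels, plan, stub_spec, FixedChoiceRng([0]))
        assert state.current_cpgs == ["cg_sep", "cg_noise"]
        assert state.mf_current == mf0
        assert not state.history[-1].accepted

    def test_exact_tie_is_rejected(self, stub_spec):
        # two identical separating columns: removing either leaves MF unchanged
        col = np.array([0.1, 0.1, 0.1, 0.9, 0.9, 0.9])
        bm = BetaMatrix(np.column_stack([col, col]), ["cg_a", "cg_b"],
                        [f"s{i}" for i in range(6)])
        labels = LabelVector(np.array([0, 0, 0, 1, 1, 1]))
        plan = make_split_plan(6, labels, n_repeats=3, train_fraction=0.5, seed=1)
        mf0 = evaluate_subset(bm, labels, ["cg_a", "cg_b"], plan, stub_spec)
        state = SearchState(current_cpgs=["cg_a", "cg_b"], mf_current=mf0)
        elimination_step(state, bm, labels, plan, stub_spec, FixedChoiceRng([0]))
        assert not state.history[-1].accepted
        assert state.current_cpgs == ["cg_a", "cg_b"]

    def test_cannot_shrink_below_min_subset_size(self, sep_plus_noise, stub_spec):
        bm, labels, plan = sep_plus_noise
        state = SearchState(current_cpgs=["cg_sep"], mf_current=1.0)
        with pytest.raises(ValidationError, match="minimum size"):
            elimination_step(state, bm, labels, plan, stub_spec, FixedChoiceRng([0]))


class TestRunSearch:
    def test_monotone_improvement_and_nested_subsets(self, instance, stub_spec):
        bm, labels, plan, _ = instance
        cfg = SearchConfig(itermax=100, mf_target=1.0, seed=31)
        state = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, cfg)
        accepted = state.accepted_mfs
        assert all(b > a for a, b in zip(accepted, accepted[1:]))
        assert len(state.current_cpgs) == len(bm.cpg_ids) - len(accepted)
        assert set(state.current_cpgs) <= set(bm.cpg_ids)
        assert state.mf_current >= evaluate_subset(bm, labels, bm.cpg_ids, plan, stub_spec)

    def test_identical_seed_gives_identical_history(self, instance, stub_spec):
        bm, labels, plan, _ = instance
        cfg = SearchConfig(itermax=60, mf_target=1.0, seed=7)
        a = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, cfg)
        b = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, cfg)
        assert a.history_frame().to_csv() == b.history_frame().to_csv()
        assert a.current_cpgs == b.current_cpgs

    def test_zero_target_stops_before_any_iteration(self, instance, stub_spec):
        bm, labels, plan, _ = instance
        cfg = SearchConfig(itermax=50, mf_target=0.0, seed=1)
        state = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, cfg)
        assert state.iteration == 0
        assert state.history == []
        assert state.current_cpgs == bm.cpg_ids

    def test_itermax_bounds_the_iteration_count(self, stub_spec):
        # noise-only instance: the accuracy target stays out of reach, so
        # the iteration cap is what terminates the search
        bm, labels, _ = generate(SynthSpec(n_cpgs=20, n_informative=0, seed=3))
        plan = make_split_plan(bm.n_samples, labels, n_repeats=4, seed=4)
        cfg = SearchConfig(itermax=5, mf_target=1.0, seed=2)
        state = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, cfg)
        assert state.iteration == len(state.history) == 5

    def test_min_subset_size_is_a_floor(self, sep_plus_noise, stub_spec):
        bm, labels, plan = sep_plus_noise
        cfg = SearchConfig(itermax=50, mf_target=1.0, min_subset_size=1, seed=3)
        state = run_search(bm, labels, ["cg_sep", "cg_noise"], plan, stub_spec, cfg)
        assert len(state.current_cpgs) >= 1

    def test_incumbent_reevaluation_is_a_noop_for_deterministic_backends(
        self, instance, stub_spec
    ):
        bm, labels, plan, _ = instance
        base = SearchConfig(itermax=40, mf_target=1.0, seed=5)
        redo = SearchConfig(itermax=40, mf_target=1.0, seed=5,
                            reevaluate_incumbent=True)
        a = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, base)
        b = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, redo)
        assert a.current_cpgs == b.current_cpgs
        assert a.history_frame().equals(b.history_frame())

    def test_replaying_history_through_exhaustive_evaluator(self, stub_spec):
        """Each accept/reject must match a from-scratch subset re-evaluation."""
        bm, labels, truth = generate(SynthSpec(n_cpgs=4, n_informative=2, seed=5))
        plan = make_split_plan(bm.n_samples, labels, n_repeats=4, seed=6)
        cfg = SearchConfig(itermax=25, mf_target=1.0, seed=8)
        state = run_search(bm, labels, bm.cpg_ids, plan, stub_spec, cfg)

        current = list(bm.cpg_ids)
        incumbent = oracles.threshold_subset_mf(
            bm.values.tolist(), labels.labels.tolist(),
            [bm.cpg_ids.index(c) for c in current], plan.partitions,
        )
        for record in state.history:
            candidate = [c for c in current if c != record.removed_cpg]
            candidate_mf = oracles.threshold_subset_mf(
                bm.values.tolist(), labels.labels.tolist(),
                [bm.cpg_ids.index(c) for c in candidate], plan.partitions,
            )
            assert candidate_mf == pytest.approx(record.candidate_mf, abs=1e-12)
            assert record.accepted == (candidate_mf > incumbent)
            if record.accepted:
                current, incumbent = candidate, candidate_mf
        assert current == state.current_cpgs
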
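"""Iterative score-gated selection: schedule, disposition, conservation."""

import warnings

import numpy as np
import pytest

from sift2d.errors import ConsistencyError, ValidationError
from sift2d.io import ClassRecord, ScoreTable
from sift2d.synthetic import mock_backend, round_robin_rule, scripted_scorer
from sift2d.workflow import (
    ClassificationResult,
    IterationPlan,
    SelectionState,
    disposition_classes,
    final_batches,
    plan_iterations,
    run_workflow,
)


def make_result(spec):
    """spec: list of (class_index, member_ids)."""
    total = sum(len(m) for _, m in spec)
    classes = [
        (None, list(members),
         ClassRecord(idx, 1.0, 10.0, len(members) / total))
        for idx, members in spec
    ]
    return ClassificationResult(classes)


def make_scores(pairs):
    return ScoreTable(
        class_indices=[i for i, _ in pairs],
        image_refs=[("m", i) for i, _ in pairs],
        scores=[s for _, s in pairs],
    )


class TestPlanIterations:
    @pytest.mark.parametrize(
        "box,expected",
        [(150, 5), (199, 5), (200, 3), (250, 3), (300, 3), (301, 2), (350, 2)],
    )
    def test_schedule(self, box, expected):
        assert plan_iterations(box) == expected

    def test_invalid_box(self):
        with pytest.raises(ValidationError):
            plan_iterations(0)


class TestDisposition:
    def _run(self, spec, scores, plan=None, seed=1):
        plan = plan or IterationPlan(box_px=150, seed=seed)
        result = make_result(spec)
        all_ids = [pid for _, m in spec for pid in m]
        state = SelectionState.fresh(all_ids)
        delta = disposition_classes(
            result, make_scores(scores), plan, np.random.default_rng(seed), state
        )
        return state, delta

    def test_bookkeeping_example(self):
        """1000@2.0 + 500@3.0 + 200@4.8 -> 700 pooled, 800 in flight, 200 rejected."""
        state, _ = self._run(
            [(0, range(1000)), (1, range(1000, 1500)), (2, range(1500, 1700))],
            [(0, 2.0), (1, 3.0), (2, 4.8)],
        )
        assert len(state.pooled) == 700
        assert len(state.in_flight) == 800
        assert len(state.rejected) == 200

    def test_exactly_at_accept_cutoff_rejected(self):
        state, _ = self._run([(0, range(100))], [(0, 4.5)])
        assert len(state.rejected) == 100 and not state.pooled

    def test_exactly_at_good_cutoff_split(self):
        state, _ = self._run([(0, range(100))], [(0, 2.5)])
        assert len(state.pooled) == 70 and len(state.in_flight) == 30

    def test_round_half_up_on_setaside(self):
        # 70% of 5 = 3.5 -> 4 pooled
        state, _ = self._run([(0, range(5))], [(0, 1.0)])
        assert len(state.pooled) == 4

    def test_middle_band_stays_in_flight(self):
        state, _ = self._run([(0, range(50))], [(0, 3.7)])
        assert len(state.in_flight) == 50 and not state.pooled and not state.rejected

    def test_setaside_can_be_dropped_by_config(self):
        plan = IterationPlan(box_px=150, seed=1, pool_setaside=False)
        state, _ = self._run([(0, range(100))], [(0, 2.0)], plan=plan)
        assert len(state.rejected) == 70 and not state.pooled

    def test_duplicate_particle_across_classes_rejected(self):
        classes = [
            (None, [0, 1], ClassRecord(0, 1.0, 10.0, 0.5)),
            (None, [1, 2], ClassRecord(1, 1.0, 10.0, 0.5)),
        ]
        with pytest.raises(ConsistencyError):
            ClassificationResult(classes).validate_partition({0, 1, 2})

    def test_conservation_on_randomized_scenarios(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_classes = int(rng.integers(1, 6))
            sizes = rng.integers(1, 50, size=n_classes)
            ids, spec = 0, []
            for k, size in enumerate(sizes):
                spec.append((k, range(ids, ids + size)))
                ids += size
            scores = [(k, float(rng.uniform(0.5, 6.0))) for k in range(n_classes)]
            state, _ = self._run(spec, scores, seed=int(rng.integers(1 << 30)))
            assert len(state.pooled) + len(state.in_flight) + len(state.rejected) == ids


class TestFinalBatches:
    def test_nested_threshold_counting(self):
        scores = make_scores([(0, 2.0), (1, 3.0), (2, 4.0)])
        membership = {0: range(10), 1: range(10, 20), 2: range(20, 30)}
        batches = final_batches(scores, membership, (2.5, 3.5, 4.5))
        assert [len(b) for b in batches] == [10, 20, 30]
        assert batches[0] <= batches[1] <= batches[2]

    def test_all_bad_classes_give_empty_batches(self):
        scores = make_scores([(0, 5.0), (1, 5.0)])
        batches = final_batches(scores, {0: range(5), 1: range(5, 9)})
        assert all(len(b) == 0 for b in batches)

    def test_boundary_inclusive(self):
        scores = make_scores([(0, 3.5)])
        batches = final_batches(scores, {0: range(7)}, (2.5, 3.5, 4.5))
        assert [len(b) for b in batches] == [0, 7, 7]


class TestRunWorkflow:
    def test_absorbing_rejection(self):
        backend = mock_backend(round_robin_rule(1))
        state = run_workflow(
            range(500), backend, scripted_scorer([5.0]), IterationPlan(box_px=150, seed=0)
        )
        assert len(state.rejected) == 500 and not state.pooled
        assert all(len(b) == 0 for b in state.final_batches)

    def test_geometric_pooling_two_rounds(self):
        """Always-good class, N=2: 700 then 210 pooled, 90 flushed -> all pooled."""
        backend = mock_backend(round_robin_rule(1))
        state = run_workflow(
            range(1000), backend, scripted_scorer([1.0]),
            IterationPlan(box_px=350, seed=0),
        )
        assert len(state.pooled) == 1000 and not state.rejected
        # audit carries the 700/300 then 210/90 rounds
        split_rows = [r for r in state.audit_log if str(r[3]).startswith("split")]
        assert split_rows[0][4] == 1000 and split_rows[1][4] == 300

    def test_identical_seeds_identical_audit(self):
        backend = mock_backend(round_robin_rule(3))
        plan = IterationPlan(box_px=250, seed=42)
        scorer = lambda result: make_scores(
            [(rec.class_index, 2.0 + rec.class_index) for _, _, rec in result.classes]
        )
        a = run_workflow(range(300), backend, scorer, plan)
        b = run_workflow(range(300), backend, scorer, plan)
        assert a.to_json() == b.to_json()

    def test_resume_equals_uninterrupted(self):
        backend = mock_backend(round_robin_rule(2))
        plan = IterationPlan(box_px=150, seed=7)
        scorer = lambda result: make_scores(
            [(rec.class_index, [2.0, 3.0][rec.class_index % 2]) for _, _, rec in result.classes]
        )
        full = run_workflow(range(200), backend, scorer, plan)
        # stop after 2 rounds, snapshot, resume
        partial = SelectionState.fresh(range(200))
        for _ in range(2):
            ids = sorted(partial.in_flight)
            result = backend(ids, partial.iteration, plan.seed)
            disposition_classes(
                result, scorer(result), plan,
                np.random.default_rng([plan.seed, partial.iteration]), partial,
            )
            partial.iteration += 1
        snapshot = SelectionState.from_json(partial.to_json())
        resumed = run_workflow([], backend, scorer, plan, state=snapshot)
        assert resumed.to_json() == full.to_json()

    def test_lowering_accept_cutoff_never_grows_pool(self):
        backend = mock_backend(round_robin_rule(4))
        scorer = lambda result: make_scores(
            [(rec.class_index, 1.5 + 1.1 * rec.class_index) for _, _, rec in result.classes]
        )
        pooled_sizes = []
        for cutoff in (4.5, 3.6, 2.6):
            plan = IterationPlan(box_px=250, seed=3, accept_cutoff=cutoff, good_cutoff=2.0)
            state = run_workflow(range(400), backend, scorer, plan)
            pooled_sizes.append(len(state.pooled))
        assert pooled_sizes == sorted(pooled_sizes, reverse=True)

    def test_early_termination_warns_not_errors(self):
        backend = mock_backend(round_robin_rule(1))
        plan = IterationPlan(box_px=150, seed=0)  # 5 rounds planned
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            state = run_workflow(range(50), backend, scripted_scorer([5.0]), plan)
        assert any("early" in str(w.message) for w in caught)
        assert len(state.rejected) == 50

    def test_backend_contract_violation_detected(self):
        def rogue_backend(ids, iteration, seed):
            return make_result([(0, list(ids) + [999_999])])

        with pytest.raises(ConsistencyError):
            run_workflow(
                range(10), rogue_backend, scripted_scorer([2.0]),
                IterationPlan(box_px=150, seed=0),
            )

    def test_two_different_backends_same_contract(self):
        """The workflow only relies on the partition contract."""

        def halves_rule(ids, iteration, seed):
            ids = sorted(ids)
            mid = len(ids) // 2
            return {0: ids[:mid], 1: ids[mid:]} if mid else {0: ids}

        for backend in (mock_backend(round_robin_rule(2)), mock_backend(halves_rule)):
            state = run_workflow(
                range(100), backend, scripted_scorer([2.0]),
                IterationPlan(box_px=350, seed=1),
            )
            state.check_invariants()
            assert state.final_batches[0] <= state.final_batches[2]
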
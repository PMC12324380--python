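"""Iterative, score-gated particle selection against a pluggable backend.

The curation loop alternates 2D classification, class-quality scoring and
per-class disposition of the member particles:

* classes scoring **at or better than** the good cutoff (default 2.5 —
  lower scores are better): a seeded random 70% of their particles is set
  aside into the accepted pool, the remaining 30% stays in flight for the
  next classification round (mitigating the attractor effect while keeping
  rare views);
* classes scoring **at or worse than** the accept cutoff (default 4.5):
  their particles are discarded;
* everything in between stays in flight.

The number of rounds follows the extraction box side (a proxy for particle
size): 5 rounds below 200 px, 3 for 200-300 px, 2 above 300 px. After the
final round the surviving in-flight particles join the pool, the pool is
classified once more, and the final classes are split into three *nested*
batches at score thresholds 2.5 / 3.5 / 4.5.

The backend is any callable ``backend(particle_ids, iteration, seed) ->
ClassificationResult`` that partitions its input into classes; the scorer is
any callable ``scorer(result) -> ScoreTable``. Nothing else is assumed, so
mocks, scripted scenarios and real classification engines are
interchangeable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConsistencyError, ValidationError
from .io import ClassRecord, ScoreTable

__all__ = [
    "IterationPlan",
    "SelectionState",
    "ClassificationResult",
    "plan_iterations",
    "disposition_classes",
    "run_workflow",
    "final_batches",
]

ParticleId = int


def plan_iterations(box_px: int) -> int:
    """Number of classification rounds for a given extraction box side.

    Small particles (box < 200 px) get 5 rounds, medium boxes (200-300 px
    inclusive) 3, large boxes (> 300 px) 2.
    """
    if box_px <= 0:
        raise ValidationError(f"extraction box must be positive, got {box_px}")
    if box_px < 200:
        return 5
    if box_px <= 300:
        return 3
    return 2


@dataclass(frozen=True)
class IterationPlan:
    """Cutoffs, set-aside fraction and round count for one curation run."""

    box_px: int = 128
    n_iterations: Optional[int] = None  # None = derive from box_px
    accept_cutoff: float = 4.5
    good_cutoff: float = 2.5
    setaside_fraction: float = 0.70
    final_thresholds: tuple[float, ...] = (2.5, 3.5, 4.5)
    seed: int = 0
    pool_setaside: bool = True  # set-aside particles go to the pool (not dropped)

    def __post_init__(self):
        if not self.good_cutoff < self.accept_cutoff:
            raise ValidationError("good_cutoff must be below accept_cutoff")
        if not 0.0 <= self.setaside_fraction <= 1.0:
            raise ValidationError("setaside_fraction must lie in [0, 1]")
        if list(self.final_thresholds) != sorted(set(self.final_thresholds)):
            raise ValidationError("final_thresholds must be strictly increasing")

    @property
    def rounds(self) -> int:
        return self.n_iterations if self.n_iterations is not None else plan_iterations(self.box_px)


@dataclass
class ClassificationResult:
    """Output of one 2D classification job: a partition of the particles.

    ``classes`` holds (class average image or None, member particle ids,
    ClassRecord) triples; every input particle must appear in exactly one
    class.
    """

    classes: list[tuple[Optional[np.ndarray], list[ParticleId], ClassRecord]]

    def validate_partition(self, expected: set[ParticleId]) -> None:
        seen: set[ParticleId] = set()
        for _, members, record in self.classes:
            m = set(members)
            if len(m) != len(members):
                raise ConsistencyError(
                    f"class {record.class_index} lists duplicate particles"
                )
            overlap = seen & m
            if overlap:
                raise ConsistencyError(
                    f"particles in two classes (e.g. {sorted(overlap)[:3]})"
                )
            seen |= m
        if seen != expected:
            extra, missing = seen - expected, expected - seen
            raise ConsistencyError(
                f"classification does not partition its input "
                f"({len(extra)} unexpected, {len(missing)} missing particles)"
            )


@dataclass
class SelectionState:
    """Bookkeeping across the workflow: every particle is always in exactly
    one of pooled / in_flight / rejected (disjointness and conservation are
    asserted after every disposition)."""

    pooled: set[ParticleId] = field(default_factory=set)
    in_flight: set[ParticleId] = field(default_factory=set)
    rejected: set[ParticleId] = field(default_factory=set)
    iteration: int = 0
    audit_log: list[tuple] = field(default_factory=list)
    initial_count: int = 0
    final_batches: Optional[list[set[ParticleId]]] = None
    final_scores: Optional[list[tuple[int, float]]] = None

    @classmethod
    def fresh(cls, particles: Sequence[ParticleId]) -> "SelectionState":
        ids = set(particles)
        return cls(in_flight=ids, initial_count=len(ids))

    def check_invariants(self) -> None:
        if self.pooled & self.in_flight or self.pooled & self.rejected or (
            self.in_flight & self.rejected
        ):
            raise ConsistencyError("pooled/in_flight/rejected sets overlap")
        total = len(self.pooled) + len(self.in_flight) + len(self.rejected)
        if total != self.initial_count:
            raise ConsistencyError(
                f"particle conservation violated: {total} != {self.initial_count}"
            )

    # -- snapshot / resume -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "pooled": sorted(self.pooled),
                "in_flight": sorted(self.in_flight),
                "rejected": sorted(self.rejected),
                "iteration": self.iteration,
                "audit_log": [list(row) for row in self.audit_log],
                "initial_count": self.initial_count,
                "final_batches": (
                    [sorted(b) for b in self.final_batches]
                    if self.final_batches is not None
                    else None
                ),
                "final_scores": self.final_scores,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionState":
        d = json.loads(text)
        return cls(
            pooled=set(d["pooled"]),
            in_flight=set(d["in_flight"]),
            rejected=set(d["rejected"]),
            iteration=d["iteration"],
            audit_log=[tuple(row) for row in d["audit_log"]],
            initial_count=d["initial_count"],
            final_batches=(
                [set(b) for b in d["final_batches"]]
                if d.get("final_batches") is not None
                else None
            ),
            final_scores=(
                [tuple(r) for r in d["final_scores"]]
                if d.get("final_scores") is not None
                else None
            ),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SelectionState":
        return cls.from_json(Path(path).read_text())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def disposition_classes(
    result: ClassificationResult,
    scores: ScoreTable,
    plan: IterationPlan,
    rng: np.random.Generator,
    state: SelectionState,
) -> dict:
    """Apply the per-class cutoff rules to one round's classes.

    Boundary semantics: a class scoring exactly ``good_cutoff`` gets the
    70/30 split ("better than or equal to"); a class scoring exactly
    ``accept_cutoff`` is discarded ("worse or equal to"). The set-aside count
    per class is round-half-up of fraction * members. Mutates ``state`` and
    returns the delta ``{"pooled": ..., "rejected": ..., "kept": ...}``.
    """
    score_by_class = dict(zip(scores.class_indices, scores.scores))
    delta = {"pooled": set(), "rejected": set(), "kept": set()}
    for _, members, record in sorted(result.classes, key=lambda c: c[2].class_index):
        idx = record.class_index
        if idx not in score_by_class:
            raise ValidationError(f"no score for class {idx}")
        s = float(score_by_class[idx])
        members = sorted(members)
        if s >= plan.accept_cutoff:
            disposition = "rejected"
            delta["rejected"].update(members)
        elif s <= plan.good_cutoff:
            n_aside = _round_half_up(plan.setaside_fraction * len(members))
            order = rng.permutation(len(members))
            aside = {members[i] for i in order[:n_aside]}
            keep = set(members) - aside
            if plan.pool_setaside:
                delta["pooled"].update(aside)
                disposition = f"split:{len(aside)}pooled/{len(keep)}kept"
            else:
                delta["rejected"].update(aside)
                disposition = f"split:{len(aside)}dropped/{len(keep)}kept"
            delta["kept"].update(keep)
        else:
            disposition = "kept"
            delta["kept"].update(members)
        state.audit_log.append(
            (state.iteration, idx, round(s, 6), disposition, len(members))
        )
    state.in_flight -= delta["pooled"] | delta["rejected"]
    state.pooled |= delta["pooled"]
    state.rejected |= delta["rejected"]
    state.check_invariants()
    return delta


def final_batches(
    pooled_scores: ScoreTable,
    membership: dict[int, Sequence[ParticleId]],
    thresholds: Sequence[float] = (2.5, 3.5, 4.5),
) -> list[set[ParticleId]]:
    """Split the final classification into nested score-thresholded batches.

    ``batch_k`` contains the particles of every class whose final score is
    <= ``thresholds[k]``; since the thresholds increase, the batches are
    nested by construction (asserted).
    """
    thresholds = list(thresholds)
    if thresholds != sorted(set(thresholds)):
        raise ValidationError("thresholds must be strictly increasing")
    score_by_class = dict(zip(pooled_scores.class_indices, pooled_scores.scores))
    batches: list[set[ParticleId]] = []
    for t in thresholds:
        batch = set()
        for idx, members in membership.items():
            if score_by_class[idx] <= t:
                batch.update(members)
        batches.append(batch)
    for a, b in zip(batches, batches[1:]):
        assert a <= b, "final batches must be nested"
    return batches


def run_workflow(
    particles: Sequence[ParticleId],
    backend: Callable[[list[ParticleId], int, int], ClassificationResult],
    scorer: Callable[[ClassificationResult], ScoreTable],
    plan: IterationPlan,
    state: Optional[SelectionState] = None,
) -> SelectionState:
    """Run (or resume) the full iterative selection workflow.

    Each round classifies the in-flight set, scores the classes and applies
    :func:`disposition_classes`; the round's random generator is derived
    from ``(plan.seed, round)`` so an interrupted run resumed from a
    snapshot finishes identically to an uninterrupted one. After the last
    round the surviving in-flight particles (all of which scored below the
    accept cutoff in their last class) join the pool; the pool is classified
    and scored once more and split into the nested final batches.
    """
    if state is None:
        state = SelectionState.fresh(particles)
        state.check_invariants()

    while state.iteration < plan.rounds:
        if not state.in_flight:
            warnings.warn(
                f"in-flight set empty after {state.iteration} of {plan.rounds} "
                "rounds; terminating early",
                stacklevel=2,
            )
            break
        ids = sorted(state.in_flight)
        result = backend(ids, state.iteration, plan.seed)
        result.validate_partition(set(ids))
        scores = scorer(result)
        rng = np.random.default_rng([plan.seed, state.iteration])
        disposition_classes(result, scores, plan, rng, state)
        state.iteration += 1

    # flush survivors: everything still in flight passed the accept cutoff
    # in its last classification
    if state.in_flight:
        state.audit_log.append(
            (state.iteration, -1, 0.0, "flushed_to_pool", len(state.in_flight))
        )
        state.pooled |= state.in_flight
        state.in_flight = set()
        state.check_invariants()

    if state.pooled and state.final_batches is None:
        ids = sorted(state.pooled)
        result = backend(ids, plan.rounds, plan.seed)
        result.validate_partition(set(ids))
        scores = scorer(result)
        membership = {
            rec.class_index: members for _, members, rec in result.classes
        }
        state.final_scores = [
            (int(i), float(s)) for i, s in zip(scores.class_indices, scores.scores)
        ]
        state.final_batches = final_batches(
            scores, membership, plan.final_thresholds
        )
        for i, batch in enumerate(state.final_batches):
            state.audit_log.append(
                (plan.rounds, -1, plan.final_thresholds[i], "final_batch", len(batch))
            )
    elif state.final_batches is None:
        state.final_batches = [set() for _ in plan.final_thresholds]
    return state
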
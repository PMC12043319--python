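"""Walker-batch orchestration.

The supervision loop: seed a batch of walkers from one state, propagate each
for the stage's time window, score the supervised metrics, extend the
productive walker from its exact final coordinates and velocities (never
reassigning velocities), and repeat until the stage's termination rule
fires. Multi-stage protocols chain stages with exact state continuity.
Single-walker supervised MD with tabu-like restarts (revert coordinates,
redraw thermal velocities on an unfavorable slope) is provided for
benchmarking against the multiple-walker scheme.

Everything is driven by a master seed through a stable per-walker hash, so a
protocol is replayable bit-for-bit with the toy propagator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import PropagationError
from .metrics import DECREASE, MetricSeries, MetricSpec, evaluate_frame, evaluate_series
from .scoring import AcceptanceSpec, select_walker, slope as ols_slope, walker_scores
from .structures import Trajectory, WalkerState, maxwell_boltzmann_velocities

__all__ = [
    "TerminationRule",
    "SupervisionStage",
    "BatchRecord",
    "StageOutcome",
    "ProtocolLog",
    "walker_seed",
    "run_batch",
    "advance_stage",
    "run_protocol",
    "sumd_advance",
]


@dataclass
class TerminationRule:
    """When a stage stops.

    kinds: ``metric_threshold`` (a metric slot crosses a threshold with the
    given comparator), ``max_productive_time`` (ps accumulated along winning
    windows), ``max_batches`` (batch count).
    Comparators: "<=", ">=", "<", ">".
    """

    kind: str
    metric_slot: int = 1
    comparator: str = ">="
    threshold: float = 0.0
    limit: float = 0.0

    _OPS = {
        "<=": lambda v, t: v <= t,
        ">=": lambda v, t: v >= t,
        "<": lambda v, t: v < t,
        ">": lambda v, t: v > t,
    }

    def __post_init__(self) -> None:
        if self.kind not in ("metric_threshold", "max_productive_time", "max_batches"):
            raise ValueError(f"unknown termination kind {self.kind!r}")
        if self.kind == "metric_threshold" and self.comparator not in self._OPS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.kind == "metric_threshold" and self.metric_slot not in (1, 2):
            raise ValueError("metric_slot must be 1 or 2")

    def metric_satisfied(self, value: float) -> bool:
        if self.kind != "metric_threshold":
            return False
        return self._OPS[self.comparator](value, self.threshold)


@dataclass
class SupervisionStage:
    """One phase of a protocol.

    ``acceptance=None`` makes the stage unsupervised (plain MD relaxation):
    one walker, always accepted. ``max_batches`` is a safety cap; exhausting
    it is an outcome, not an error.
    """

    label: str
    metrics: list[MetricSpec]
    acceptance: AcceptanceSpec | None
    window_ps: float
    n_walkers: int
    termination: TerminationRule
    max_batches: int = 1000
    sample_interval: float | None = None

    def __post_init__(self) -> None:
        if self.window_ps <= 0:
            raise ValueError("window_ps must be > 0")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if self.acceptance is not None:
            if len(self.metrics) != self.acceptance.n_metrics:
                raise ValueError(
                    f"acceptance {self.acceptance.method} requires "
                    f"{self.acceptance.n_metrics} metric(s), got {len(self.metrics)}"
                )
        elif self.n_walkers != 1:
            raise ValueError("unsupervised stages must use exactly 1 walker")

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(m.direction for m in self.metrics)


@dataclass
class BatchRecord:
    """Audit record of one batch: seeds, scores, winner."""

    stage_label: str
    batch_index: int
    seeds: list[int]
    scores: list[float | None]
    last_values: list[list[float]]  # per walker, per metric slot
    chosen: int
    productive_time: float  # ps accumulated after this batch
    failed: list[bool] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage_label,
                "batch": self.batch_index,
                "seeds": self.seeds,
                "scores": self.scores,
                "last_values": self.last_values,
                "chosen": self.chosen,
                "productive_time_ps": self.productive_time,
                "failed": self.failed,
            },
            sort_keys=True,
        )


@dataclass
class StageOutcome:
    stage_label: str
    terminated_by: str  # threshold | max_productive_time | max_batches |
    #                     budget_exhausted | pre_satisfied | failure_cap
    batches_used: int
    productive_time: float
    total_propagated_time: float
    restarts: int = 0  # single-walker tabu restarts only


@dataclass
class ProtocolLog:
    """Replayable audit trail of a protocol run."""

    master_seed: int
    stage_labels: list[str] = field(default_factory=list)
    batches: list[BatchRecord] = field(default_factory=list)
    outcomes: list[StageOutcome] = field(default_factory=list)

    @property
    def total_propagated_time(self) -> float:
        return sum(o.total_propagated_time for o in self.outcomes)

    @property
    def productive_time(self) -> float:
        return sum(o.productive_time for o in self.outcomes)

    def to_json_lines(self) -> str:
        lines = [json.dumps({"master_seed": self.master_seed, "stages": self.stage_labels}, sort_keys=True)]
        lines += [b.to_json() for b in self.batches]
        for o in self.outcomes:
            lines.append(
                json.dumps(
                    {
                        "stage_outcome": o.stage_label,
                        "terminated_by": o.terminated_by,
                        "batches_used": o.batches_used,
                        "productive_time_ps": o.productive_time,
                        "total_propagated_time_ps": o.total_propagated_time,
                        "restarts": o.restarts,
                    },
                    sort_keys=True,
                )
            )
        return "\n".join(lines) + "\n"


def walker_seed(master_seed: int, stage_label: str, batch_index: int, walker: int) -> int:
    """Stable 64-bit seed for one walker window.

    Hash-derived from (master seed, stage label, batch, walker) so inserting
    or reordering stages does not shift the random streams of other stages.
    """
    key = f"{master_seed}|{stage_label}|{batch_index}|{walker}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**63)


@dataclass
class WalkerResult:
    trajectory: Trajectory | None
    final_state: WalkerState | None
    series: list[MetricSeries] | None
    seed: int
    failed: bool = False


def run_batch(
    state: WalkerState,
    propagator,
    stage: SupervisionStage,
    batch_index: int,
    master_seed: int,
) -> list[WalkerResult]:
    """Propagate one batch of walkers from a common state.

    Every walker starts from the identical coordinates AND velocities of
    ``state``; only the stochastic-force seed differs. A failed walker is
    recorded as such; the batch fails only if all walkers fail.
    """
    results: list[WalkerResult] = []
    for k in range(stage.n_walkers):
        seed = walker_seed(master_seed, stage.label, batch_index, k)
        try:
            traj, final = propagator.run(state.copy(), stage.window_ps, seed)
            series = [
                evaluate_series(traj, spec, stage.sample_interval)
                for spec in stage.metrics
            ]
            results.append(WalkerResult(traj, final, series, seed))
        except PropagationError:
            results.append(WalkerResult(None, None, None, seed, failed=True))
    if all(r.failed for r in results):
        raise PropagationError(
            f"all {stage.n_walkers} walkers failed in batch {batch_index} "
            f"of stage {stage.label!r}"
        )
    return results


def _select_among(
    results: list[WalkerResult], stage: SupervisionStage
) -> tuple[int, list[float | None]]:
    """Winner index among non-failed walkers, plus loggable scores."""
    ok = [i for i, r in enumerate(results) if not r.failed]
    if stage.acceptance is None:
        return ok[0], [None for _ in results]
    batch = [results[i].series for i in ok]
    raw = walker_scores(batch, stage.acceptance, stage.directions)
    winner_local = select_walker(batch, stage.acceptance, stage.directions)
    scores: list[float | None] = [None] * len(results)
    for local, i in enumerate(ok):
        scores[i] = float(raw[local])
    return ok[winner_local], scores


def _entry_satisfied(state: WalkerState, stage: SupervisionStage) -> bool:
    rule = stage.termination
    if rule.kind != "metric_threshold" or not stage.metrics:
        return False
    spec = stage.metrics[rule.metric_slot - 1]
    return rule.metric_satisfied(evaluate_frame(state.coordinates, spec))


def advance_stage(
    state: WalkerState,
    propagator,
    stage: SupervisionStage,
    log: ProtocolLog,
) -> tuple[WalkerState, Trajectory]:
    """Run one supervision stage to termination.

    Continuity contract: each batch starts from the previous winner's final
    coordinates and velocities, bit-identical — velocities are never
    reassigned. The merged trajectory concatenates winning windows only;
    discarded walkers survive only in the log.
    """
    merged = Trajectory([state.copy()])
    productive = 0.0
    total = 0.0
    current = state
    if _entry_satisfied(state, stage):
        log.outcomes.append(
            StageOutcome(stage.label, "pre_satisfied", 0, 0.0, 0.0)
        )
        return current, merged

    terminated_by = "budget_exhausted"
    batches = 0
    for batch_index in range(stage.max_batches):
        results = run_batch(current, propagator, stage, batch_index, log.master_seed)
        winner, scores = _select_among(results, stage)
        win = results[winner]
        current = win.final_state
        merged.extend(win.trajectory, skip_first=True)
        productive += stage.window_ps
        total += stage.window_ps * sum(1 for r in results if not r.failed)
        batches = batch_index + 1
        log.batches.append(
            BatchRecord(
                stage_label=stage.label,
                batch_index=batch_index,
                seeds=[r.seed for r in results],
                scores=scores,
                last_values=[
                    [s.last_value for s in r.series] if not r.failed else []
                    for r in results
                ],
                chosen=winner,
                productive_time=productive,
                failed=[r.failed for r in results],
            )
        )
        rule = stage.termination
        if rule.kind == "metric_threshold":
            value = win.series[rule.metric_slot - 1].last_value
            if rule.metric_satisfied(value):
                terminated_by = "threshold"
                break
        elif rule.kind == "max_productive_time" and productive >= rule.limit:
            terminated_by = "max_productive_time"
            break
        elif rule.kind == "max_batches" and batches >= rule.limit:
            terminated_by = "max_batches"
            break
    log.outcomes.append(
        StageOutcome(stage.label, terminated_by, batches, productive, total)
    )
    return current, merged


def run_protocol(
    initial: WalkerState,
    stages: list[SupervisionStage],
    propagator,
    master_seed: int,
) -> tuple[ProtocolLog, Trajectory, WalkerState]:
    """Execute stages in order with exact state continuity between them.

    A budget-exhausted stage stops the protocol; partial results are
    returned with the outcome flagged in the log.
    """
    if not stages:
        raise ValueError("protocol needs at least one stage")
    log = ProtocolLog(master_seed=master_seed, stage_labels=[s.label for s in stages])
    state = initial.copy()
    merged = Trajectory([initial.copy()])
    for stage in stages:
        state, stage_traj = advance_stage(state, propagator, stage, log)
        merged.extend(stage_traj, skip_first=True)
        if log.outcomes[-1].terminated_by == "budget_exhausted":
            break
    return log, merged, state


def sumd_advance(
    state: WalkerState,
    propagator,
    stage: SupervisionStage,
    log: ProtocolLog,
    max_consecutive_failures: int = 50,
) -> tuple[WalkerState, Trajectory]:
    """Single-walker supervised MD with tabu-like restarts.

    One window at a time; the slope of the supervised metric decides. A
    favorable slope (strictly negative for a decreasing metric, strictly
    positive for an increasing one) continues from the window's final
    coordinates and velocities; otherwise the window is discarded, the
    coordinates revert to its start, and fresh Maxwell–Boltzmann velocities
    are drawn with a new seed. Exceeding ``max_consecutive_failures``
    consecutive rejections is a budget-exhausted outcome.
    """
    if stage.acceptance is None or stage.acceptance.method != "slope":
        raise ValueError("single-walker supervision uses the slope acceptance rule")
    spec = stage.metrics[0]
    merged = Trajectory([state.copy()])
    current = state.copy()
    productive = 0.0
    total = 0.0
    consecutive = 0
    restarts = 0
    terminated_by = "budget_exhausted"
    batches = 0
    if _entry_satisfied(state, stage):
        log.outcomes.append(StageOutcome(stage.label, "pre_satisfied", 0, 0.0, 0.0))
        return current, merged

    for batch_index in range(stage.max_batches):
        seed = walker_seed(log.master_seed, stage.label, batch_index, 0)
        traj, final = propagator.run(current.copy(), stage.window_ps, seed)
        series = evaluate_series(traj, spec, stage.sample_interval)
        s = ols_slope(series)
        total += stage.window_ps
        favorable = s < 0 if spec.direction == DECREASE else s > 0
        batches = batch_index + 1
        if favorable:
            current = final
            merged.extend(traj, skip_first=True)
            productive += stage.window_ps
            consecutive = 0
        else:
            # tabu move: revert coordinates, redraw thermal velocities
            restart_seed = walker_seed(log.master_seed, stage.label, batch_index, 1)
            current = WalkerState(
                current.coordinates.copy(),
                maxwell_boltzmann_velocities(
                    propagator.topology, propagator.params.temperature, restart_seed
                ),
                current.box,
                current.time,
            )
            if propagator.potential.frozen:
                current.velocities[propagator.potential.frozen] = 0.0
            consecutive += 1
            restarts += 1
        log.batches.append(
            BatchRecord(
                stage_label=stage.label,
                batch_index=batch_index,
                seeds=[seed],
                scores=[float(s)],
                last_values=[[series.last_value]],
                chosen=0 if favorable else -1,
                productive_time=productive,
                failed=[False],
            )
        )
        rule = stage.termination
        if favorable and rule.kind == "metric_threshold" and rule.metric_satisfied(
            series.last_value
        ):
            terminated_by = "threshold"
            break
        if rule.kind == "max_productive_time" and productive >= rule.limit:
            terminated_by = "max_productive_time"
            break
        if rule.kind == "max_batches" and batches >= rule.limit:
            terminated_by = "max_batches"
            break
        if consecutive > max_consecutive_failures:
            terminated_by = "failure_cap"
            break
    log.outcomes.append(
        StageOutcome(stage.label, terminated_by, batches, productive, total, restarts)
    )
    return current, merged
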
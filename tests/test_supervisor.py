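import numpy as np
import pytest

from mwsumd.metrics import MetricSpec
from mwsumd.potentials import ZeroPotential
from mwsumd.propagators import LangevinParams, LangevinPropagator
from mwsumd.scoring import AcceptanceSpec
from mwsumd.structures import AtomSelection, Topology, WalkerState
from mwsumd.supervisor import (
    ProtocolLog,
    SupervisionStage,
    TerminationRule,
    advance_stage,
    run_batch,
    run_protocol,
    sumd_advance,
    walker_seed,
)
from mwsumd.toys import make_double_well, make_binding_funnel


@pytest.fixture
def dw():
    return make_double_well()


def dw_stage(system, n_walkers=3, window=1.0, max_batches=60, acceptance="SMscore",
             threshold=2.0):
    return SupervisionStage(
        label="cross",
        metrics=[system.metric],
        acceptance=AcceptanceSpec(acceptance) if acceptance else None,
        window_ps=window,
        n_walkers=n_walkers,
        termination=TerminationRule(
            kind="metric_threshold", metric_slot=1, comparator="<=", threshold=threshold
        ),
        max_batches=max_batches,
    )


class TestWalkerSeeds:
    def test_deterministic_and_distinct(self):
        seeds = [walker_seed(1, "s", 0, k) for k in range(100)]
        assert len(set(seeds)) == 100
        assert seeds == [walker_seed(1, "s", 0, k) for k in range(100)]

    def test_insensitive_to_other_stages(self):
        # the stream of one stage does not depend on what other stages exist
        assert walker_seed(7, "stageB", 3, 2) == walker_seed(7, "stageB", 3, 2)
        assert walker_seed(7, "stageA", 3, 2) != walker_seed(7, "stageB", 3, 2)


class TestRunBatch:
    def test_single_walker_degenerates_to_window(self, dw):
        stage = dw_stage(dw, n_walkers=1)
        results = run_batch(dw.initial_state, dw.propagator(), stage, 0, 1)
        assert len(results) == 1
        assert not results[0].failed

    def test_identical_reruns_bitwise(self, dw):
        stage = dw_stage(dw)
        r1 = run_batch(dw.initial_state, dw.propagator(), stage, 0, 5)
        r2 = run_batch(dw.initial_state, dw.propagator(), stage, 0, 5)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.final_state.coordinates, b.final_state.coordinates)
            np.testing.assert_array_equal(a.final_state.velocities, b.final_state.velocities)

    def test_walkers_diverge_pairwise(self, dw):
        stage = dw_stage(dw, n_walkers=5)
        results = run_batch(dw.initial_state, dw.propagator(), stage, 0, 5)
        finals = [r.final_state.coordinates for r in results]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(finals[i], finals[j])

    def test_walkers_share_exact_start(self, dw):
        stage = dw_stage(dw)
        results = run_batch(dw.initial_state, dw.propagator(), stage, 0, 9)
        for r in results:
            np.testing.assert_array_equal(
                r.trajectory.frames[0].coordinates, dw.initial_state.coordinates
            )
            np.testing.assert_array_equal(
                r.trajectory.frames[0].velocities, dw.initial_state.velocities
            )


class TestAdvanceStage:
    def test_threshold_at_entry_zero_batches(self, dw):
        stage = dw_stage(dw, threshold=20.0)  # initial distance is 10
        log = ProtocolLog(master_seed=3)
        state, merged = advance_stage(dw.initial_state.copy(), dw.propagator(), stage, log)
        assert log.outcomes[-1].terminated_by == "pre_satisfied"
        assert log.outcomes[-1].batches_used == 0
        assert merged.n_frames == 1

    def test_metric_satisfies_threshold_at_stage_end(self, dw):
        stage = dw_stage(dw, n_walkers=8, window=2.0)
        log = ProtocolLog(master_seed=11)
        state, merged = advance_stage(dw.initial_state.copy(), dw.propagator(), stage, log)
        assert log.outcomes[-1].terminated_by == "threshold"
        from mwsumd.metrics import evaluate_frame

        assert evaluate_frame(state.coordinates, dw.metric) <= 2.0

    def test_continuity_between_batches(self, dw):
        """The winner's final state is bit-identical to the next batch's
        common initial state; velocities are never reassigned."""
        stage = dw_stage(dw, n_walkers=3, window=1.0, max_batches=4, threshold=0.0)
        propagator = dw.propagator()
        log = ProtocolLog(master_seed=17)
        advance_stage(dw.initial_state.copy(), propagator, stage, log)
        assert len(log.batches) == 4
        # replay: reconstruct each batch from the log and verify the chaining
        current = dw.initial_state.copy()
        for record in log.batches:
            results = run_batch(current, propagator, stage, record.batch_index, 17)
            winner = results[record.chosen]
            nxt = winner.final_state
            if record.batch_index + 1 < len(log.batches):
                nxt_results = run_batch(nxt, propagator, stage, record.batch_index + 1, 17)
                for r in nxt_results:
                    np.testing.assert_array_equal(
                        r.trajectory.frames[0].coordinates, nxt.coordinates
                    )
                    np.testing.assert_array_equal(
                        r.trajectory.frames[0].velocities, nxt.velocities
                    )
            current = nxt

    def test_budget_exhausted_is_outcome_not_error(self, dw):
        stage = dw_stage(dw, max_batches=2, threshold=0.0)  # unreachable
        log = ProtocolLog(master_seed=1)
        advance_stage(dw.initial_state.copy(), dw.propagator(), stage, log)
        assert log.outcomes[-1].terminated_by == "budget_exhausted"
        assert log.outcomes[-1].batches_used == 2

    def test_wall_time_accounting(self, dw):
        stage = dw_stage(dw, n_walkers=4, window=1.5, max_batches=3, threshold=0.0)
        log = ProtocolLog(master_seed=2)
        advance_stage(dw.initial_state.copy(), dw.propagator(), stage, log)
        outcome = log.outcomes[-1]
        assert outcome.productive_time == pytest.approx(3 * 1.5)
        assert outcome.total_propagated_time == pytest.approx(4 * 3 * 1.5)


class TestRunProtocol:
    def test_single_stage_equals_advance_stage(self, dw):
        stage = dw_stage(dw, n_walkers=3, window=1.0, max_batches=5, threshold=0.0)
        log1 = ProtocolLog(master_seed=4)
        state1, _ = advance_stage(dw.initial_state.copy(), dw.propagator(), stage, log1)
        log2, _, state2 = run_protocol(dw.initial_state.copy(), [stage], dw.propagator(), 4)
        np.testing.assert_array_equal(state1.coordinates, state2.coordinates)
        np.testing.assert_array_equal(state1.velocities, state2.velocities)

    def test_two_stage_continuity(self, dw):
        def fixed_batches(label, n_walkers):
            return SupervisionStage(
                label=label, metrics=[dw.metric], acceptance=AcceptanceSpec("SMscore"),
                window_ps=1.0, n_walkers=n_walkers,
                termination=TerminationRule(kind="max_batches", limit=2),
                max_batches=10,
            )

        s1 = fixed_batches("cross", 3)
        s2 = fixed_batches("second", 2)
        log, merged, final = run_protocol(
            dw.initial_state.copy(), [s1, s2], dw.propagator(), 8
        )
        assert [o.stage_label for o in log.outcomes] == ["cross", "second"]
        # stage 2's first batch must start from stage 1's exit state
        stage1_records = [b for b in log.batches if b.stage_label == "cross"]
        state = dw.initial_state.copy()
        propagator = dw.propagator()
        for record in stage1_records:
            results = run_batch(state, propagator, s1, record.batch_index, 8)
            state = results[record.chosen].final_state
        stage2_first = run_batch(state, propagator, s2, 0, 8)
        rec2 = [b for b in log.batches if b.stage_label == "second"][0]
        assert rec2.seeds == [r.seed for r in stage2_first]

    def test_replay_determinism_byte_identical_logs(self, dw):
        stage = dw_stage(dw, n_walkers=4, window=1.0, max_batches=6)
        out = []
        for _ in range(2):
            log, merged, _ = run_protocol(dw.initial_state.copy(), [stage], dw.propagator(), 123)
            out.append((log.to_json_lines(), merged.coordinates.tobytes()))
        assert out[0][0] == out[1][0]
        assert out[0][1] == out[1][1]

    def test_empty_protocol_rejected(self, dw):
        with pytest.raises(ValueError):
            run_protocol(dw.initial_state, [], dw.propagator(), 1)


class TestSuMD:
    def _slope_stage(self, system, threshold=2.0, max_batches=100, window=1.0):
        return SupervisionStage(
            label="sumd",
            metrics=[system.metric],
            acceptance=AcceptanceSpec("slope"),
            window_ps=window,
            n_walkers=1,
            termination=TerminationRule(
                kind="metric_threshold", metric_slot=1, comparator="<=", threshold=threshold
            ),
            max_batches=max_batches,
        )

    def test_frozen_dynamics_never_favorable(self):
        """Identity dynamics give slope exactly 0, which is unfavorable
        (strict inequality), so the walker restarts until the failure cap."""
        top = Topology(
            atom_names=["L", "T"], elements=["C", "C"], residue_names=["L", "T"],
            residue_ids=np.array([1, 2]), chain_ids=["A", "A"],
            masses=np.array([10.0, 10.0]),
        )
        frozen_pot = ZeroPotential(frozen=[0, 1])
        params = LangevinParams(0.1, 1.0, 300.0, top.masses)
        propagator = LangevinPropagator(top, params, frozen_pot, frame_interval=0.1)
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        state = WalkerState(coords, np.zeros_like(coords))
        spec = MetricSpec(
            kind="centroid_distance", direction="decrease",
            selection_a=AtomSelection(np.array([0])),
            selection_b=AtomSelection(np.array([1])),
        )
        stage = SupervisionStage(
            label="frozen", metrics=[spec], acceptance=AcceptanceSpec("slope"),
            window_ps=1.0, n_walkers=1,
            termination=TerminationRule(
                kind="metric_threshold", comparator="<=", threshold=1.0
            ),
            max_batches=50,
        )
        log = ProtocolLog(master_seed=0)
        sumd_advance(state, propagator, stage, log, max_consecutive_failures=10)
        assert log.outcomes[-1].terminated_by == "failure_cap"
        assert log.outcomes[-1].restarts == 11
        assert log.outcomes[-1].productive_time == 0.0

    def test_restart_reverts_coordinates_and_redraws_velocities(self):
        dw = make_double_well()
        stage = self._slope_stage(dw, threshold=0.0, max_batches=30)
        log = ProtocolLog(master_seed=42)
        sumd_advance(dw.initial_state.copy(), dw.propagator(), stage, log,
                     max_consecutive_failures=1000)
        rejected = [b for b in log.batches if b.chosen == -1]
        accepted = [b for b in log.batches if b.chosen == 0]
        assert rejected, "expected at least one tabu restart in 30 windows"
        assert accepted, "expected at least one accepted window"
        # replay the first rejected window: productive time must not advance
        first_rej = rejected[0]
        prior = [b for b in log.batches if b.batch_index < first_rej.batch_index]
        expected_prod = prior[-1].productive_time if prior else 0.0
        assert first_rej.productive_time == expected_prod

    def test_reaches_target_on_double_well(self):
        dw = make_double_well()
        stage = self._slope_stage(dw, threshold=2.0, max_batches=400, window=2.0)
        log = ProtocolLog(master_seed=5)
        final, merged = sumd_advance(
            dw.initial_state.copy(), dw.propagator(), stage, log,
            max_consecutive_failures=400,
        )
        assert log.outcomes[-1].terminated_by == "threshold"
        assert abs(final.coordinates[0, 0] - 5.0) < 2.0


class TestUnsupervisedStage:
    def test_always_accepts_single_walker(self, dw):
        stage = SupervisionStage(
            label="relax", metrics=[dw.metric], acceptance=None,
            window_ps=1.0, n_walkers=1,
            termination=TerminationRule(kind="max_productive_time", limit=3.0),
        )
        log = ProtocolLog(master_seed=6)
        advance_stage(dw.initial_state.copy(), dw.propagator(), stage, log)
        assert log.outcomes[-1].terminated_by == "max_productive_time"
        assert log.outcomes[-1].productive_time == pytest.approx(3.0)
        assert all(b.chosen == 0 for b in log.batches)
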
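"""Self-contained toy systems and the first-passage benchmark harness.

Each toy system bundles a topology, an analytic potential, an initial
walker state, named selections, a suggested supervision metric with its
termination rule, and integrator parameters — everything a protocol needs,
generated programmatically with no external input.

Barrier heights are stated in k_BT so the systems are thermostat-
independent; they are converted to kcal/mol at the construction temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL
from .errors import ConfigError
from .metrics import DECREASE, INCREASE, MetricSpec
from .potentials import AnalyticPotential, BindingFunnel, DoubleWell1D, MuellerBrown
from .propagators import LangevinParams, LangevinPropagator
from .scoring import AcceptanceSpec
from .structures import AtomSelection, Topology, WalkerState
from .supervisor import (
    ProtocolLog,
    SupervisionStage,
    TerminationRule,
    advance_stage,
    sumd_advance,
    walker_seed,
)

__all__ = [
    "ToySystem",
    "make_double_well",
    "make_mueller_brown",
    "make_binding_funnel",
    "unbinding_variant",
    "BenchmarkProtocol",
    "BenchmarkResult",
    "first_passage_benchmark",
]


@dataclass
class ToySystem:
    """A ready-to-supervise synthetic system."""

    name: str
    topology: Topology
    potential: AnalyticPotential
    initial_state: WalkerState
    params: LangevinParams
    selections: dict[str, AtomSelection]
    metric: MetricSpec
    termination: TerminationRule
    window_ps: float  # a sensible supervision window for this system
    frame_interval: float  # ps between emitted frames

    def propagator(self) -> LangevinPropagator:
        return LangevinPropagator(
            self.topology, self.params, self.potential, self.frame_interval
        )


def _bead_topology(names: list[str], masses: list[float]) -> Topology:
    n = len(names)
    return Topology(
        atom_names=names,
        elements=["C"] * n,
        residue_names=[name[:3] for name in names],
        residue_ids=np.arange(1, n + 1),
        chain_ids=["A"] * n,
        masses=np.array(masses),
    )


def make_double_well(
    barrier_kt: float = 6.0,
    separation: float = 10.0,
    temperature: float = 300.0,
    mass: float = 100.0,
    friction: float = 5.0,
    timestep: float = 0.02,
) -> ToySystem:
    """One coarse bead in a symmetric 1-D quartic double well.

    The bead (mass 100 amu, a small-molecule-scale particle) starts in the
    left minimum; a frozen marker sits at the right (target) minimum so the
    supervised metric is an ordinary centroid distance, set to decrease.
    The barrier is ``barrier_kt``·k_BT at the given temperature.
    """
    if barrier_kt <= 0:
        raise ValueError("barrier must be positive")
    a = separation / 2.0
    barrier_kcal = barrier_kt * KB_KCAL * temperature
    topology = _bead_topology(["LIG", "TGT"], [mass, mass])
    potential = DoubleWell1D(barrier=barrier_kcal, a=a, frozen=[1])
    coords = np.array([[-a, 0.0, 0.0], [a, 0.0, 0.0]])
    state = WalkerState(coords, np.zeros_like(coords))
    params = LangevinParams(timestep, friction, temperature, topology.masses)
    sel_lig = AtomSelection(np.array([0]), "ligand")
    sel_tgt = AtomSelection(np.array([1]), "target")
    metric = MetricSpec(
        kind="centroid_distance",
        direction=DECREASE,
        selection_a=sel_lig,
        selection_b=sel_tgt,
        label="distance_to_target",
    )
    termination = TerminationRule(
        kind="metric_threshold", metric_slot=1, comparator="<=", threshold=2.0
    )
    return ToySystem(
        name="double_well",
        topology=topology,
        potential=potential,
        initial_state=state,
        params=params,
        selections={"ligand": sel_lig, "target": sel_tgt},
        metric=metric,
        termination=termination,
        window_ps=2.0,
        frame_interval=0.2,
    )


def make_mueller_brown(temperature: float = 300.0) -> ToySystem:
    """One bead on the canonical Müller–Brown surface.

    The raw surface spans ~150 energy units between the deepest minimum and
    the highest saddle; it is scaled so that the surface corrugation is a
    few k_BT at the construction temperature, making transitions rare but
    reachable. A frozen marker at the deepest minimum (−0.558, 1.442)
    provides the distance metric.
    """
    scale = 0.10 * KB_KCAL * temperature  # surface units -> kcal/mol
    topology = _bead_topology(["LIG", "TGT"], [10.0, 10.0])
    potential = MuellerBrown(scale=scale, frozen=[1])
    target = np.array([-0.558, 1.442, 0.0])
    start = np.array([0.623, 0.028, 0.0])  # shallowest-basin minimum
    coords = np.stack([start, target])
    state = WalkerState(coords, np.zeros_like(coords))
    params = LangevinParams(2e-4, 100.0, temperature, topology.masses)
    sel_lig = AtomSelection(np.array([0]), "ligand")
    sel_tgt = AtomSelection(np.array([1]), "target")
    metric = MetricSpec(
        kind="centroid_distance",
        direction=DECREASE,
        selection_a=sel_lig,
        selection_b=sel_tgt,
        label="distance_to_deepest_minimum",
    )
    termination = TerminationRule(
        kind="metric_threshold", metric_slot=1, comparator="<=", threshold=0.2
    )
    return ToySystem(
        name="mueller_brown",
        topology=topology,
        potential=potential,
        initial_state=state,
        params=params,
        selections={"ligand": sel_lig, "target": sel_tgt},
        metric=metric,
        termination=termination,
        window_ps=0.02,
        frame_interval=2e-3,
    )


def make_binding_funnel(
    n_receptor_beads: int = 8,
    seed: int = 0,
    temperature: float = 300.0,
    well_depth_kt: float = 8.0,
    start_distance: float = 32.0,
) -> ToySystem:
    """A mobile ligand bead and a harmonically restrained receptor pocket.

    Receptor beads form a ring around the binding site at the origin; the
    ligand starts ``start_distance`` Å away along the approach axis. The
    ligand feels a short-range attraction at the site, a weak long-range
    funnel bias, and repulsive bead cores. The suggested metric is the
    ligand–site centroid distance, set to decrease (binding); for unbinding
    runs flip the direction and terminate at 40 Å, mirroring the standard
    peptide-unbinding stop rule.
    """
    if n_receptor_beads < 4:
        raise ValueError("need at least 4 receptor beads")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n_receptor_beads) / n_receptor_beads
    ring = np.stack(
        [
            np.zeros(n_receptor_beads),
            4.0 * np.cos(angles),
            4.0 * np.sin(angles),
        ],
        axis=1,
    )
    ring += 0.05 * rng.standard_normal(ring.shape)  # break exact symmetry
    names = ["LIG"] + [f"R{i}" for i in range(n_receptor_beads)]
    masses = [50.0] + [100.0] * n_receptor_beads
    topology = _bead_topology(names, masses)
    coords = np.vstack([[start_distance, 0.0, 0.0], ring])
    home = coords.copy()
    depth_kcal = well_depth_kt * KB_KCAL * temperature
    potential = BindingFunnel(
        home=home, site_center=np.zeros(3), well_depth=depth_kcal
    )
    state = WalkerState(coords, np.zeros_like(coords))
    params = LangevinParams(0.02, 5.0, temperature, topology.masses)
    sel_lig = AtomSelection(np.array([0]), "ligand")
    sel_site = AtomSelection(np.arange(1, n_receptor_beads + 1), "site")
    metric = MetricSpec(
        kind="centroid_distance",
        direction=DECREASE,
        selection_a=sel_lig,
        selection_b=sel_site,
        label="ligand_site_distance",
    )
    termination = TerminationRule(
        kind="metric_threshold", metric_slot=1, comparator="<=", threshold=2.0
    )
    return ToySystem(
        name="binding_funnel",
        topology=topology,
        potential=potential,
        initial_state=state,
        params=params,
        selections={"ligand": sel_lig, "site": sel_site},
        metric=metric,
        termination=termination,
        window_ps=2.0,
        frame_interval=0.2,
    )


def unbinding_variant(system: ToySystem, threshold: float = 40.0) -> ToySystem:
    """Flip a binding system into an unbinding one: start bound, metric set
    to increase, stop when the distance reaches ``threshold`` Å."""
    bound = system.initial_state.copy()
    bound.coordinates[0] = np.array([0.0, 0.0, 0.0])
    metric = MetricSpec(
        kind="centroid_distance",
        direction=INCREASE,
        selection_a=system.metric.selection_a,
        selection_b=system.metric.selection_b,
        label=system.metric.label,
    )
    return ToySystem(
        name=system.name + "_unbinding",
        topology=system.topology,
        potential=system.potential,
        initial_state=bound,
        params=system.params,
        selections=system.selections,
        metric=metric,
        termination=TerminationRule(
            kind="metric_threshold", metric_slot=1, comparator=">=", threshold=threshold
        ),
        window_ps=system.window_ps,
        frame_interval=system.frame_interval,
    )


# --------------------------------------------------------------------------
# benchmark harness
# --------------------------------------------------------------------------

@dataclass
class BenchmarkProtocol:
    """One contender in a first-passage comparison.

    mode: ``mwsumd`` (multi-walker selection), ``sumd`` (single walker,
    slope acceptance, tabu restarts), or ``unsupervised`` (single walker,
    always accepted — plain MD cut into windows).
    """

    id: str
    mode: str
    n_walkers: int = 1
    window_ps: float = 2.0
    acceptance: str = "SMscore"

    def __post_init__(self) -> None:
        if self.mode not in ("mwsumd", "sumd", "unsupervised"):
            raise ConfigError(f"unknown benchmark mode {self.mode!r}", f"protocols.{self.id}")
        if self.mode != "mwsumd" and self.n_walkers != 1:
            raise ConfigError("single-walker modes use n_walkers=1", f"protocols.{self.id}")


@dataclass
class BenchmarkResult:
    protocol_id: str
    n_replicates: int
    successes: int
    productive_times: list[float]  # ps to target, successes only
    total_times: list[float]  # total propagated ps, every replicate

    @property
    def success_rate(self) -> float:
        return self.successes / self.n_replicates


def _protocol_stage(
    protocol: BenchmarkProtocol, system: ToySystem, budget_ps: float
) -> SupervisionStage:
    per_batch = protocol.n_walkers * protocol.window_ps
    max_batches = int(budget_ps // per_batch)
    if max_batches < 1:
        raise ConfigError("budget smaller than one window", "budget_ps")
    if protocol.mode == "mwsumd":
        acceptance = AcceptanceSpec(protocol.acceptance)
    elif protocol.mode == "sumd":
        acceptance = AcceptanceSpec("slope")
    else:
        acceptance = None
    return SupervisionStage(
        label=protocol.id,
        metrics=[system.metric],
        acceptance=acceptance,
        window_ps=protocol.window_ps,
        n_walkers=protocol.n_walkers,
        termination=system.termination,
        max_batches=max_batches,
    )


def run_benchmark_replicate(
    system: ToySystem,
    protocol: BenchmarkProtocol,
    budget_ps: float,
    replicate_seed: int,
) -> tuple[bool, float, float]:
    """One replicate: (success, productive time to target, total propagated)."""
    stage = _protocol_stage(protocol, system, budget_ps)
    propagator = system.propagator()
    log = ProtocolLog(master_seed=replicate_seed, stage_labels=[stage.label])
    if protocol.mode == "sumd":
        sumd_advance(system.initial_state.copy(), propagator, stage, log,
                     max_consecutive_failures=stage.max_batches)
    else:
        advance_stage(system.initial_state.copy(), propagator, stage, log)
    outcome = log.outcomes[-1]
    success = outcome.terminated_by in ("threshold", "pre_satisfied")
    return success, outcome.productive_time, outcome.total_propagated_time


def first_passage_benchmark(
    system: ToySystem,
    protocols: list[BenchmarkProtocol],
    budget_ps: float,
    n_replicates: int,
    master_seed: int,
) -> list[BenchmarkResult]:
    """Compare protocols at MATCHED total propagated time.

    Each protocol runs ``n_replicates`` times from the system's initial
    state with replicate seeds derived from the master seed. Success means
    the termination rule fired before the total-propagated-time budget
    (walkers × window × batches) was exhausted. Fairness is matched total
    propagated cost, not matched productive time.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1", "n_replicates")
    results = []
    for protocol in protocols:
        successes = 0
        prod_times: list[float] = []
        totals: list[float] = []
        for r in range(n_replicates):
            seed = walker_seed(master_seed, f"benchmark|{protocol.id}", r, 0)
            ok, prod, total = run_benchmark_replicate(system, protocol, budget_ps, seed)
            if ok:
                successes += 1
                prod_times.append(prod)
            totals.append(total)
        results.append(
            BenchmarkResult(
                protocol_id=protocol.id,
                n_replicates=n_replicates,
                successes=successes,
                productive_times=prod_times,
                total_times=totals,
            )
        )
    return results
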
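"""Langevin propagation of walker states over analytic potentials.

The integrator is BAOAB (kick–drift–thermostat–drift–kick), which has
excellent configurational accuracy at moderate timesteps and reduces to
velocity Verlet in the zero-friction limit, where energy is conserved.
Propagation is bitwise deterministic for a fixed seed, the property the
supervisor's replay guarantee rests on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_AKMA, KCAL_TO_AKMA
from .errors import CongruenceError, PropagationError
from .potentials import AnalyticPotential
from .structures import Topology, Trajectory, WalkerState

__all__ = [
    "LangevinParams",
    "propagate",
    "kinetic_temperature",
    "equilibrium_temperature_check",
    "LangevinPropagator",
]


@dataclass
class LangevinParams:
    """Integrator parameters.

    friction is the thermostat damping γ in 1/ps (0 gives microcanonical
    velocity-Verlet dynamics); temperature the thermostat target in K.
    """

    timestep: float  # ps
    friction: float  # 1/ps
    temperature: float  # K
    masses: np.ndarray  # (N,) amu

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")


def _forces_akma(potential: AnalyticPotential, coords: np.ndarray, step: int) -> np.ndarray:
    g = potential.gradient(coords)
    if not np.all(np.isfinite(g)):
        raise PropagationError(f"non-finite force at step {step}")
    f = -g * KCAL_TO_AKMA  # kcal/mol/Å -> amu·Å/ps²
    if potential.frozen:
        f[potential.frozen] = 0.0
    return f


def propagate(
    state: WalkerState,
    duration: float,
    seed: int,
    params: LangevinParams,
    potential: AnalyticPotential,
    frame_interval: float | None = None,
) -> tuple[Trajectory, WalkerState]:
    """Propagate a walker for ``duration`` ps with the BAOAB scheme.

    ``duration`` must be an integer multiple of the timestep. Frames are
    emitted at ``frame_interval`` (every step when None), always including
    the initial and final step; frame times continue the walker clock.
    Velocities of ``potential.frozen`` atoms are pinned to zero.
    """
    n = state.n_atoms
    if params.masses.shape != (n,):
        raise CongruenceError("params.masses incongruent with state atom count")
    dt = params.timestep
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be an integer multiple of the timestep")
    x = state.coordinates.copy()
    if state.velocities is None:
        v = np.zeros_like(x)
    else:
        v = state.velocities.copy()
    if potential.frozen:
        v[potential.frozen] = 0.0

    if n_steps == 0:
        final = WalkerState(x.copy(), v.copy(), state.box, state.time)
        return Trajectory([final], frame_interval=0.0), final.copy()

    stride = 1 if frame_interval is None else max(1, int(round(frame_interval / dt)))
    m = params.masses[:, None]
    inv_m = 1.0 / m
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma = np.sqrt(KB_AKMA * params.temperature * inv_m)
    rng = np.random.default_rng(seed)
    frozen = potential.frozen

    frames = [WalkerState(x.copy(), v.copy(), state.box, state.time)]
    f = _forces_akma(potential, x, 0)
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f * inv_m
        x += 0.5 * dt * v
        if params.friction > 0:
            v = c1 * v + c2 * sigma * rng.standard_normal(x.shape)
            if frozen:
                v[frozen] = 0.0
        x += 0.5 * dt * v
        f = _forces_akma(potential, x, step)
        v += 0.5 * dt * f * inv_m
        if frozen:
            v[frozen] = 0.0
        if step % stride == 0 or step == n_steps:
            frames.append(
                WalkerState(x.copy(), v.copy(), state.box, state.time + step * dt)
            )
    traj = Trajectory(frames, frame_interval=stride * dt)
    final = frames[-1].copy()
    return traj, final


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature (2·KE)/(3N·k_B) in K."""
    velocities = np.asarray(velocities, float)
    masses = np.asarray(masses, float)
    ke = 0.5 * (masses[:, None] * velocities**2).sum()
    n_dof = 3 * len(masses)
    return float(2.0 * ke / (n_dof * KB_AKMA))


def equilibrium_temperature_check(
    trajectory: Trajectory, masses: np.ndarray, mobile: np.ndarray | None = None
) -> float:
    """Time-averaged kinetic temperature over a trajectory, K.

    ``mobile`` restricts the average to non-frozen atoms; frames must carry
    velocities.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    masses = np.asarray(masses, float)
    idx = np.arange(len(masses)) if mobile is None else np.asarray(mobile, int)
    temps = []
    for frame in trajectory.frames:
        if frame.velocities is None:
            raise ValueError("trajectory frames lack velocities")
        temps.append(kinetic_temperature(frame.velocities[idx], masses[idx]))
    return float(np.mean(temps))


@dataclass
class LangevinPropagator:
    """Bundles topology, integrator parameters and a potential.

    This is the propagation contract the supervisor consumes: anything with
    a ``topology`` and a ``run(state, duration, seed)`` returning
    ``(Trajectory, final WalkerState)`` can drive a protocol — the external
    engine adapter satisfies the same contract.
    """

    topology: Topology
    params: LangevinParams
    potential: AnalyticPotential
    frame_interval: float | None = None

    def run(self, state: WalkerState, duration: float, seed: int):
        return propagate(
            state, duration, seed, self.params, self.potential, self.frame_interval
        )

    @property
    def mobile_atoms(self) -> np.ndarray:
        mask = np.ones(self.topology.n_atoms, dtype=bool)
        if self.potential.frozen:
            mask[self.potential.frozen] = False
        return np.nonzero(mask)[0]
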
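"""External-engine adapter contract and a mock file-based engine.

A production protocol would hand each window to a GPU MD engine (ACEMD,
NAMD, GROMACS, OpenMM...). The adapter contract keeps the supervisor
engine-agnostic: the adapter writes the walker state and run parameters to
files, "invokes" the engine, and reads the resulting trajectory and final
state back. The mock engine implements the full file round trip — PDB
coordinates, plain-text velocity table, plain-text run parameters in;
multi-frame XYZ plus final-state files out — driving the built-in Langevin
integrator behind the file boundary, which proves the contract without
bundling any real engine.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import AdapterError
from .potentials import AnalyticPotential
from .propagators import LangevinParams, propagate
from .structures import (
    Topology,
    Trajectory,
    WalkerState,
    read_pdb,
    read_xyz_traj,
    write_pdb,
    write_xyz_traj,
)

__all__ = ["MockEngineAdapter"]


def _write_velocities(path, velocities: np.ndarray) -> None:
    with open(path, "w") as fh:
        for vx, vy, vz in velocities:
            fh.write(f"{vx:.17g} {vy:.17g} {vz:.17g}\n")


def _read_velocities(path) -> np.ndarray:
    if not os.path.exists(path):
        raise AdapterError(f"missing velocity file {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 3:
                raise AdapterError(f"{path}: malformed velocity row {line!r}")
            rows.append([float(p) for p in parts])
    if not rows:
        raise AdapterError(f"{path}: empty velocity table")
    return np.array(rows, dtype=float)


@dataclass
class MockEngineAdapter:
    """File-contract adapter around the toy Langevin integrator.

    Satisfies the same propagation contract as ``LangevinPropagator``
    (attributes ``topology``; method ``run``), but every walker window goes
    through explicit input/output files in ``workdir``, one subdirectory per
    invocation, mimicking how a subprocess-driven engine would be wired.
    """

    topology: Topology
    params: LangevinParams
    potential: AnalyticPotential
    workdir: str
    frame_interval: float | None = None
    _counter: int = 0

    # --- input side -------------------------------------------------------
    def write_input(self, state: WalkerState, rundir: str, duration: float, seed: int):
        os.makedirs(rundir, exist_ok=True)
        write_pdb(self.topology, state.coordinates, os.path.join(rundir, "input.pdb"))
        vel = state.velocities
        if vel is None:
            vel = np.zeros_like(state.coordinates)
        _write_velocities(os.path.join(rundir, "input.vel"), vel)
        with open(os.path.join(rundir, "run.conf"), "w") as fh:
            fh.write(f"duration {duration:.17g}\n")
            fh.write(f"seed {seed}\n")
            fh.write(f"time0 {state.time:.17g}\n")

    # --- the "engine" -----------------------------------------------------
    def execute(self, rundir: str) -> None:
        """Stand-in for the subprocess call: reads only the input files."""
        topology, coords = read_pdb(os.path.join(rundir, "input.pdb"))
        vel = _read_velocities(os.path.join(rundir, "input.vel"))
        conf = {}
        with open(os.path.join(rundir, "run.conf")) as fh:
            for line in fh:
                key, value = line.split()
                conf[key] = value
        state = WalkerState(coords, vel, time=float(conf["time0"]))
        traj, final = propagate(
            state,
            float(conf["duration"]),
            int(conf["seed"]),
            self.params,
            self.potential,
            self.frame_interval,
        )
        write_xyz_traj(traj, os.path.join(rundir, "output.xyz"), topology.atom_names)
        write_pdb(self.topology, final.coordinates, os.path.join(rundir, "final.pdb"))
        _write_velocities(os.path.join(rundir, "final.vel"), final.velocities)
        with open(os.path.join(rundir, "final.time"), "w") as fh:
            fh.write(f"{final.time:.17g}\n")

    # --- output side ------------------------------------------------------
    def read_output(self, rundir: str) -> tuple[Trajectory, WalkerState]:
        traj_path = os.path.join(rundir, "output.xyz")
        if not os.path.exists(traj_path):
            raise AdapterError(f"engine produced no trajectory in {rundir}")
        traj = read_xyz_traj(traj_path)
        for f in ("final.pdb", "final.vel", "final.time"):
            if not os.path.exists(os.path.join(rundir, f)):
                raise AdapterError(f"engine output missing {f} in {rundir}")
        _, coords = read_pdb(os.path.join(rundir, "final.pdb"))
        vel = _read_velocities(os.path.join(rundir, "final.vel"))
        if coords.shape != vel.shape or coords.shape[0] != self.topology.n_atoms:
            raise AdapterError("final state files incongruent with topology")
        with open(os.path.join(rundir, "final.time")) as fh:
            t = float(fh.read().strip())
        return traj, WalkerState(coords, vel, time=t)

    # --- contract entry point --------------------------------------------
    def run(self, state: WalkerState, duration: float, seed: int):
        rundir = os.path.join(self.workdir, f"window_{self._counter:05d}")
        self._counter += 1
        self.write_input(state, rundir, duration, seed)
        self.execute(rundir)
        return self.read_output(rundir)
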
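"""Protocol/benchmark configuration schema (YAML or JSON, same layout).

A protocol config names a system (a built-in toy or a PDB file), a master
seed, and a list of stages mirroring the supervision vocabulary: time-window
duration, number of walkers, supervised metric(s), acceptance method and a
termination rule. Unknown keys are rejected; errors carry a dotted field
path.

Example::

    system: {toy: double_well}
    master_seed: 1
    stages:
      - label: approach
        metrics: [suggested]
        acceptance: SMscore
        window_ps: 2.0
        walkers: 10
        terminate: {kind: metric_threshold, slot: 1, comparator: "<=", threshold: 2.0}
        max_batches: 200
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigError
from .metrics import MetricSpec
from .scoring import AcceptanceSpec, METHODS
from .structures import maxwell_boltzmann_velocities, read_pdb, select, WalkerState
from .supervisor import SupervisionStage, TerminationRule
from .toys import ToySystem, make_binding_funnel, make_double_well, make_mueller_brown, unbinding_variant

__all__ = ["ProtocolConfig", "load_config", "config_hash"]

_TOY_FACTORIES = {
    "double_well": make_double_well,
    "mueller_brown": make_mueller_brown,
    "binding_funnel": make_binding_funnel,
}


def _check_keys(doc: dict, allowed: set[str], path: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)}", path)


def _require(doc: dict, key: str, path: str):
    if key not in doc:
        raise ConfigError(f"missing required key {key!r}", path)
    return doc[key]


@dataclass
class ProtocolConfig:
    """A validated, fully resolved protocol ready to run."""

    system: ToySystem
    stages: list[SupervisionStage]
    master_seed: int
    raw: dict
    sumd_mode: bool = False

    def initial_state(self) -> WalkerState:
        state = self.system.initial_state.copy()
        if state.velocities is None or not np.any(state.velocities):
            vel = maxwell_boltzmann_velocities(
                self.system.topology, self.system.params.temperature, self.master_seed
            )
            if self.system.potential.frozen:
                vel[self.system.potential.frozen] = 0.0
            state.velocities = vel
        return state


def _build_system(doc: dict, path: str) -> ToySystem:
    if not isinstance(doc, dict):
        raise ConfigError("system must be a mapping", path)
    _check_keys(doc, {"toy", "params", "unbinding"}, path)
    toy = _require(doc, "toy", path)
    if toy not in _TOY_FACTORIES:
        raise ConfigError(
            f"unknown toy {toy!r}; available: {sorted(_TOY_FACTORIES)}", f"{path}.toy"
        )
    params = doc.get("params", {})
    if not isinstance(params, dict):
        raise ConfigError("params must be a mapping", f"{path}.params")
    try:
        system = _TOY_FACTORIES[toy](**params)
    except TypeError as exc:
        raise ConfigError(f"bad toy parameters: {exc}", f"{path}.params") from exc
    if doc.get("unbinding", False):
        system = unbinding_variant(system)
    return system


def _build_metric(doc, system: ToySystem, path: str) -> MetricSpec:
    if doc == "suggested":
        return system.metric
    if not isinstance(doc, dict):
        raise ConfigError("metric must be 'suggested' or a mapping", path)
    allowed = {
        "kind", "direction", "selection_a", "selection_b", "cutoff",
        "reference_pdb", "fit_selection", "measure_selection", "mass_weighted", "label",
    }
    _check_keys(doc, allowed, path)
    kind = _require(doc, "kind", path)
    direction = _require(doc, "direction", path)

    def _sel(expr_key):
        expr = _require(doc, expr_key, path)
        if isinstance(expr, str) and expr.startswith("@"):
            name = expr[1:]
            if name not in system.selections:
                raise ConfigError(
                    f"unknown named selection {name!r}", f"{path}.{expr_key}"
                )
            return system.selections[name]
        return select(system.topology, expr)

    kwargs = dict(kind=kind, direction=direction, label=doc.get("label", ""))
    if kind in ("centroid_distance", "contact_count"):
        kwargs["selection_a"] = _sel("selection_a")
        kwargs["selection_b"] = _sel("selection_b")
        if kind == "contact_count":
            kwargs["cutoff"] = float(_require(doc, "cutoff", path))
        if doc.get("mass_weighted", False):
            kwargs["mass_weighted"] = True
            kwargs["masses"] = system.topology.masses
    elif kind == "rmsd_to_reference":
        ref_path = _require(doc, "reference_pdb", path)
        _, ref_coords = read_pdb(ref_path)
        kwargs["reference_coordinates"] = ref_coords
        kwargs["fit_selection"] = _sel("fit_selection")
        kwargs["measure_selection"] = _sel("measure_selection")
    else:
        raise ConfigError(f"unknown metric kind {kind!r}", f"{path}.kind")
    try:
        return MetricSpec(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc), path) from exc


def _build_termination(doc: dict, path: str) -> TerminationRule:
    if not isinstance(doc, dict):
        raise ConfigError("terminate must be a mapping", path)
    _check_keys(doc, {"kind", "slot", "comparator", "threshold", "limit"}, path)
    kind = _require(doc, "kind", path)
    try:
        return TerminationRule(
            kind=kind,
            metric_slot=int(doc.get("slot", 1)),
            comparator=doc.get("comparator", ">="),
            threshold=float(doc.get("threshold", 0.0)),
            limit=float(doc.get("limit", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc), path) from exc


def _build_stage(doc: dict, system: ToySystem, index: int) -> SupervisionStage:
    path = f"stages[{index}]"
    if not isinstance(doc, dict):
        raise ConfigError("stage must be a mapping", path)
    allowed = {
        "label", "metrics", "acceptance", "window_ps", "walkers",
        "terminate", "max_batches", "sample_interval",
    }
    _check_keys(doc, allowed, path)
    acceptance_name = doc.get("acceptance", "SMscore")
    if acceptance_name in (None, "none", "unsupervised"):
        acceptance = None
    elif acceptance_name in METHODS:
        acceptance = AcceptanceSpec(acceptance_name)
    else:
        raise ConfigError(
            f"acceptance must be one of {METHODS} or 'none'", f"{path}.acceptance"
        )
    metrics_doc = doc.get("metrics", ["suggested"])
    if not isinstance(metrics_doc, list):
        raise ConfigError("metrics must be a list", f"{path}.metrics")
    metrics = [
        _build_metric(m, system, f"{path}.metrics[{i}]") for i, m in enumerate(metrics_doc)
    ]
    if acceptance is not None and len(metrics) != acceptance.n_metrics:
        raise ConfigError(
            f"acceptance arity: {acceptance.method} supervises "
            f"{acceptance.n_metrics} metric(s), config lists {len(metrics)}",
            f"{path}.metrics",
        )
    try:
        return SupervisionStage(
            label=str(doc.get("label", f"stage{index}")),
            metrics=metrics,
            acceptance=acceptance,
            window_ps=float(_require(doc, "window_ps", path)),
            n_walkers=int(doc.get("walkers", 1)),
            termination=_build_termination(_require(doc, "terminate", path), f"{path}.terminate"),
            max_batches=int(doc.get("max_batches", 1000)),
            sample_interval=doc.get("sample_interval"),
        )
    except ValueError as exc:
        raise ConfigError(str(exc), path) from exc


def load_config(source) -> ProtocolConfig:
    """Parse and validate a protocol config from a path or a dict."""
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping", "")
    _check_keys(doc, {"system", "master_seed", "stages", "mode"}, "")
    system = _build_system(_require(doc, "system", ""), "system")
    master_seed = int(doc.get("master_seed", 0))
    stages_doc = _require(doc, "stages", "")
    if not isinstance(stages_doc, list) or not stages_doc:
        raise ConfigError("stages must be a non-empty list", "stages")
    stages = [_build_stage(s, system, i) for i, s in enumerate(stages_doc)]
    mode = doc.get("mode", "mwsumd")
    if mode not in ("mwsumd", "sumd"):
        raise ConfigError("mode must be 'mwsumd' or 'sumd'", "mode")
    if mode == "sumd":
        for i, stage in enumerate(stages):
            if stage.acceptance is None or stage.acceptance.method != "slope":
                raise ConfigError(
                    "sumd mode requires slope acceptance", f"stages[{i}].acceptance"
                )
            if stage.n_walkers != 1:
                raise ConfigError("sumd mode uses 1 walker", f"stages[{i}].walkers")
    return ProtocolConfig(
        system=system,
        stages=stages,
        master_seed=master_seed,
        raw=doc,
        sumd_mode=(mode == "sumd"),
    )


def config_hash(doc: dict) -> str:
    """Stable short hash of a config document, embedded in every artifact."""
    payload = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.blake2b(payload, digest_size=8).hexdigest()
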
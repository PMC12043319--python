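"""Post-hoc trajectory analysis: contacts, hydrogen bonds, interaction
persistency over merged replicas, RMSD timelines and summaries.

Hydrogen bonds use the geometric criterion of a donor–acceptor distance of
at most 3.3 Å together with a donor–hydrogen–acceptor angle of at least
120°, both boundaries inclusive. Contacts are heavy-atom pairs within a
cutoff (4.0 Å by default), aggregated to residue pairs. Persistency is the
percentage of frames carrying the interaction, counted over all frames of
all merged replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .metrics import MetricSeries, MetricSpec, evaluate_series
from .structures import AtomSelection, Topology, Trajectory

__all__ = [
    "InteractionRecord",
    "PersistencyTable",
    "detect_hbonds",
    "detect_contacts",
    "persistency",
    "rmsd_timeline",
    "summary_second_half",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "DEFAULT_CONTACT_CUTOFF",
]

HBOND_DISTANCE_CUTOFF = 3.3  # Å, donor-acceptor
HBOND_ANGLE_CUTOFF = 120.0  # degrees, D-H...A measured at H
DEFAULT_CONTACT_CUTOFF = 4.0  # Å, heavy-atom contacts


@dataclass
class InteractionRecord:
    """One detected interaction in one frame."""

    frame_index: int
    residue_a: tuple[str, int]  # (chain, resid)
    residue_b: tuple[str, int]
    kind: str  # "contact" | "hbond"
    distance: float  # Å
    angle: float | None = None  # degrees, hbonds only

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return tuple(sorted((self.residue_a, self.residue_b)))


@dataclass
class PersistencyTable:
    """Percentage of merged frames in which each residue pair interacts."""

    percentages: dict[tuple, float]
    total_frames: int
    kind: str = "contact"
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "residue_a": f"{a[0]}:{a[1]}",
                "residue_b": f"{b[0]}:{b[1]}",
                "kind": self.kind,
                "persistency_pct": pct,
            }
            for (a, b), pct in sorted(self.percentages.items())
        ]
        return pd.DataFrame(rows, columns=["residue_a", "residue_b", "kind", "persistency_pct"])


def _residue_key(topology: Topology, atom: int) -> tuple[str, int]:
    return (topology.chain_ids[atom], int(topology.residue_ids[atom]))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    coordinates: np.ndarray,
    topology: Topology,
    donor_triples: list[tuple[int, int]],
    acceptors: list[int],
    dist_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """Geometric hydrogen-bond detection.

    ``donor_triples`` are (donor, bonded hydrogen) atom index pairs — the
    hydrogen is supplied explicitly, no bond perception is attempted. A bond
    is recorded iff distance(D, A) <= ``dist_cutoff`` AND the D–H···A angle
    at the hydrogen >= ``angle_cutoff``; boundary values count.
    """
    coordinates = np.asarray(coordinates, float)
    n = coordinates.shape[0]
    records = []
    for donor, hydrogen in donor_triples:
        if not (0 <= hydrogen < n) or not (0 <= donor < n):
            raise IndexError(f"donor/hydrogen index out of range: ({donor}, {hydrogen})")
        for acc in acceptors:
            if acc in (donor, hydrogen):
                continue
            d_da = float(np.linalg.norm(coordinates[donor] - coordinates[acc]))
            if d_da > dist_cutoff:
                continue
            ang = _angle_deg(coordinates[donor], coordinates[hydrogen], coordinates[acc])
            if ang < angle_cutoff:
                continue
            records.append(
                InteractionRecord(
                    frame_index=frame_index,
                    residue_a=_residue_key(topology, donor),
                    residue_b=_residue_key(topology, acc),
                    kind="hbond",
                    distance=d_da,
                    angle=ang,
                )
            )
    return records


def detect_contacts(
    coordinates: np.ndarray,
    topology: Topology,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    heavy_only: bool = True,
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """Residue-pair contacts: a residue pair is in contact in a frame iff at
    least one (heavy) atom pair across the selections is within cutoff.

    The record carries the minimum atom-pair distance of the pair.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    coordinates = np.asarray(coordinates, float)

    def _filter(sel: AtomSelection) -> np.ndarray:
        idx = sel.indices
        if heavy_only:
            idx = np.array([i for i in idx if topology.elements[i] != "H"], dtype=int)
        if idx.size == 0:
            raise SelectionError("selection contains no (heavy) atoms")
        return idx

    ia, ib = _filter(sel_a), _filter(sel_b)
    d = cdist(coordinates[ia], coordinates[ib])
    best: dict[tuple, float] = {}
    for (pi, pj) in zip(*np.nonzero(d <= cutoff)):
        i, j = ia[pi], ib[pj]
        if i == j:
            continue
        key = tuple(sorted((_residue_key(topology, i), _residue_key(topology, j))))
        dist = float(d[pi, pj])
        if key not in best or dist < best[key]:
            best[key] = dist
    return [
        InteractionRecord(
            frame_index=frame_index,
            residue_a=key[0],
            residue_b=key[1],
            kind="contact",
            distance=dist,
        )
        for key, dist in sorted(best.items())
    ]


def persistency(
    trajectories: list[Trajectory],
    detector,
    detector_kwargs: dict,
    kind: str = "contact",
) -> PersistencyTable:
    """Interaction persistency over the merged frames of all replicas.

    For each residue pair: 100 × (frames with ≥1 record) / (total frames,
    all trajectories pooled). Invariant to the order of the replicas.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    total = sum(t.n_frames for t in trajectories)
    if total == 0:
        raise ValueError("zero total frames")
    counts: dict[tuple, int] = {}
    frame_no = 0
    for traj in trajectories:
        for frame in traj.frames:
            records = detector(frame.coordinates, frame_index=frame_no, **detector_kwargs)
            for key in {r.pair for r in records}:
                counts[key] = counts.get(key, 0) + 1
            frame_no += 1
    percentages = {key: 100.0 * c / total for key, c in counts.items()}
    return PersistencyTable(
        percentages=percentages,
        total_frames=total,
        kind=kind,
        metadata={"n_replicas": len(trajectories)},
    )


def rmsd_timeline(trajectory: Trajectory, spec: MetricSpec) -> MetricSeries:
    """Per-frame RMSD to the reference (every frame sampled)."""
    if spec.kind != "rmsd_to_reference":
        raise ValueError("rmsd_timeline needs an rmsd_to_reference spec")
    return evaluate_series(trajectory, spec, sample_interval=None)


def summary_second_half(series: MetricSeries) -> tuple[float, float]:
    """Mean and population SD over the second half of a series.

    The boundary is ⌈n/2⌉: frames with index >= ⌈n/2⌉ are kept, so the later
    frame survives when n is odd. This is the convention behind summaries
    quoted as "mean ± SD" over the stabilized part of a merged trajectory.
    """
    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 samples for a second-half summary")
    start = -(-n // 2)  # ceil(n/2)
    tail = series.values[start:]
    return float(tail.mean()), float(tail.std(ddof=0))
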
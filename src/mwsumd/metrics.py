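"""Supervised collective variables.

The supervision metrics the selector acts on: centroid distance between two
selections, RMSD to a reference after Kabsch superposition with independent
fit/measure selections, and atomic contact counts. ``evaluate_series`` turns
a trajectory window into the sampled series the acceptance rules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    CongruenceError,
    DegenerateFitError,
    InsufficientSamplesError,
    SelectionError,
)
from .structures import AtomSelection, Trajectory

__all__ = [
    "MetricSpec",
    "MetricSeries",
    "centroid",
    "centroid_distance",
    "kabsch_superpose",
    "rmsd_to_reference",
    "contact_count",
    "evaluate_series",
]

DECREASE = "decrease"
INCREASE = "increase"


@dataclass
class MetricSpec:
    """What is supervised and in which direction progress lies.

    kind:
      * ``centroid_distance`` — distance between centroids of ``selection_a``
        and ``selection_b`` (geometric by default, mass-weighted on request).
      * ``rmsd_to_reference`` — superpose on ``fit_selection``, then report
        RMSD over ``measure_selection`` against ``reference_coordinates``
        (full-system reference array indexed by the same atom indices).
      * ``contact_count`` — number of atom pairs across the two selections
        within ``cutoff`` Å.

    ``direction`` states whether the protocol wants the metric to decrease
    (binding, dimerization) or increase (unbinding, domain opening).
    """

    kind: str
    direction: str
    selection_a: AtomSelection | None = None
    selection_b: AtomSelection | None = None
    reference_coordinates: np.ndarray | None = None
    fit_selection: AtomSelection | None = None
    measure_selection: AtomSelection | None = None
    cutoff: float | None = None
    mass_weighted: bool = False
    masses: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (DECREASE, INCREASE):
            raise ValueError(f"direction must be decrease/increase, got {self.direction!r}")
        if self.kind in ("centroid_distance", "contact_count"):
            if self.selection_a is None or self.selection_b is None:
                raise ValueError(f"{self.kind} requires selection_a and selection_b")
            if self.kind == "contact_count":
                if self.cutoff is None or self.cutoff <= 0:
                    raise ValueError("contact_count requires cutoff > 0")
        elif self.kind == "rmsd_to_reference":
            if (
                self.reference_coordinates is None
                or self.fit_selection is None
                or self.measure_selection is None
            ):
                raise ValueError(
                    "rmsd_to_reference requires reference_coordinates, "
                    "fit_selection and measure_selection"
                )
            self.reference_coordinates = np.asarray(self.reference_coordinates, float)
            nref = self.reference_coordinates.shape[0]
            for sel in (self.fit_selection, self.measure_selection):
                if sel.indices.max() >= nref:
                    raise CongruenceError(
                        "selection index exceeds reference coordinate count"
                    )
        else:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.mass_weighted and self.masses is None:
            raise ValueError("mass_weighted metrics need masses")
        if not self.label:
            self.label = self.kind


@dataclass
class MetricSeries:
    """Sampled metric values over one time window.

    ``last_value`` is the value at the final sample (X_lastframe in the
    acceptance scores); ``window_mean`` the arithmetic mean over the window,
    final sample included (X̄).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise CongruenceError("times and values must be matching 1-D arrays")
        if self.times.size == 0:
            raise InsufficientSamplesError("metric series needs at least one sample")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("series times must be strictly increasing")

    @property
    def last_value(self) -> float:
        return float(self.values[-1])

    @property
    def window_mean(self) -> float:
        return float(self.values.mean())

    def __len__(self) -> int:
        return len(self.values)


# --------------------------------------------------------------------------

def centroid(
    coordinates: np.ndarray,
    selection: AtomSelection,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Geometric (or mass-weighted) center of the selected atoms, Å."""
    pts = np.asarray(coordinates, float)[selection.indices]
    if not mass_weighted:
        return pts.mean(axis=0)
    if masses is None:
        raise ValueError("mass-weighted centroid needs masses")
    w = np.asarray(masses, float)[selection.indices]
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def centroid_distance(
    coordinates: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> float:
    """Euclidean distance between the centroids of two selections (Å)."""
    ca = centroid(coordinates, sel_a, mass_weighted, masses)
    cb = centroid(coordinates, sel_b, mass_weighted, masses)
    return float(np.linalg.norm(ca - cb))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fit_rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD to
    ``reference``. The rotation is proper (det +1): a reflection in the SVD
    solution is corrected by flipping the smallest singular direction.

    Requires M >= 3 non-collinear points for a unique rotation.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise CongruenceError("mobile and reference must be matching (M, 3) arrays")
    m = mobile.shape[0]
    if m < 3:
        raise DegenerateFitError("need at least 3 points for a unique superposition")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    mob_c = mobile - (mobile * w[:, None]).sum(axis=0)
    ref_c = reference - (reference * w[:, None]).sum(axis=0)
    h = (w[:, None] * mob_c).T @ ref_c  # 3x3 covariance
    u, s, vt = np.linalg.svd(h)
    # collinear point sets leave a free rotation about the line
    scale = max(float(np.sqrt((w * (mob_c**2).sum(axis=1)).sum())), 1e-300)
    if s[1] <= 1e-8 * max(s[0], scale**2):
        raise DegenerateFitError("fit atoms are collinear; rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    ref_center = (reference * w[:, None]).sum(axis=0)
    mob_center = (mobile * w[:, None]).sum(axis=0)
    translation = ref_center - rotation @ mob_center
    moved = mobile @ rotation.T + translation
    fit_rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return rotation, translation, fit_rmsd


def rmsd_to_reference(coordinates: np.ndarray, spec: MetricSpec) -> float:
    """RMSD over the measure selection after superposing on the fit selection.

    The Kabsch transform is computed from ``fit_selection`` atoms only, then
    applied to ``measure_selection`` atoms; fit and measure may differ (e.g.
    fit on the receptor core, measure on the ligand).
    """
    if spec.kind != "rmsd_to_reference":
        raise ValueError("spec.kind must be rmsd_to_reference")
    coordinates = np.asarray(coordinates, float)
    fit_idx = spec.fit_selection.indices
    meas_idx = spec.measure_selection.indices
    if coordinates.shape[0] <= max(fit_idx.max(), meas_idx.max()):
        raise CongruenceError("coordinates do not cover the fit/measure selections")
    rot, trans, _ = kabsch_superpose(
        coordinates[fit_idx], spec.reference_coordinates[fit_idx]
    )
    moved = coordinates[meas_idx] @ rot.T + trans
    dev = moved - spec.reference_coordinates[meas_idx]
    return float(np.sqrt((dev**2).sum(axis=1).mean()))


def contact_count(
    coordinates: np.ndarray,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float,
) -> int:
    """Number of unordered atom pairs across two selections within cutoff.

    Pairs at exactly the cutoff distance are counted (``<=`` convention);
    self-pairs are excluded and any pair is counted once even when the
    selections overlap.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    coordinates = np.asarray(coordinates, float)
    ia, ib = sel_a.indices, sel_b.indices
    d = cdist(coordinates[ia], coordinates[ib])
    within = d <= cutoff
    pairs = set()
    ai, bj = np.nonzero(within)
    for i, j in zip(ia[ai], ib[bj]):
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    return len(pairs)


def _evaluate_single(coordinates: np.ndarray, spec: MetricSpec) -> float:
    if spec.kind == "centroid_distance":
        return centroid_distance(
            coordinates, spec.selection_a, spec.selection_b,
            spec.mass_weighted, spec.masses,
        )
    if spec.kind == "rmsd_to_reference":
        return rmsd_to_reference(coordinates, spec)
    if spec.kind == "contact_count":
        return float(contact_count(coordinates, spec.selection_a, spec.selection_b, spec.cutoff))
    raise ValueError(f"unknown metric kind {spec.kind!r}")


def evaluate_frame(coordinates: np.ndarray, spec: MetricSpec) -> float:
    """Evaluate a metric on a single coordinate frame."""
    return _evaluate_single(coordinates, spec)


def evaluate_series(
    trajectory: Trajectory,
    spec: MetricSpec,
    sample_interval: float | None = None,
) -> MetricSeries:
    """Sample a metric over a trajectory window at a regular interval.

    By default every frame is sampled. With ``sample_interval`` an integer
    multiple of the frame interval, frames are strided accordingly; the final
    frame is always included, as the scores depend on it.
    """
    n = trajectory.n_frames
    if n < 2:
        raise InsufficientSamplesError("need at least 2 frames to build a series")
    if sample_interval is None or trajectory.frame_interval <= 0:
        idx = list(range(n))
    else:
        stride = max(1, int(round(sample_interval / trajectory.frame_interval)))
        idx = list(range(0, n, stride))
        if idx[-1] != n - 1:
            idx.append(n - 1)
    if len(idx) < 2:
        raise InsufficientSamplesError("sampling interval leaves fewer than 2 samples")
    times = trajectory.times[idx]
    values = np.array(
        [_evaluate_single(trajectory.frames[i].coordinates, spec) for i in idx]
    )
    return MetricSeries(times=times, values=values)
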
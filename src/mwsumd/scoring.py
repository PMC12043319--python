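"""Acceptance rules and productive-walker selection.

Three rules decide which walker of a batch is extended:

* slope    — least-squares slope of metric vs time; the favorable sign is
             negative for a decreasing metric, positive for an increasing one.
* SMscore  — sqrt(X_lastframe * X̄_window) for a single metric; lowest wins
             when the metric should decrease, highest when it should increase.
* DMscore  — 100 * [(X'_last / X̄'_batch − 1) + (X''_last / X̄''_batch − 1)]
             for two metrics, each addend multiplied by −1 when its metric is
             set to decrease so that positive is always better; highest wins.

Exactly one walker per batch is always productive; ties break to the lowest
walker index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError
from .metrics import DECREASE, INCREASE, MetricSeries

__all__ = [
    "AcceptanceSpec",
    "BatchStatistics",
    "slope",
    "sm_score",
    "dm_score",
    "batch_statistics",
    "select_walker",
]

METHODS = ("slope", "SMscore", "DMscore")


@dataclass
class AcceptanceSpec:
    """Which rule picks the productive walker.

    slope and SMscore supervise exactly one metric; DMscore exactly two.
    """

    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")

    @property
    def n_metrics(self) -> int:
        return 2 if self.method == "DMscore" else 1


@dataclass
class BatchStatistics:
    """Per-batch metric averages over all walkers (X̄_batch walkers)."""

    batch_mean_metric_1: float
    batch_mean_metric_2: float | None = None
    n_walkers: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.batch_mean_metric_1):
            raise ValueError("batch mean must be finite")
        if self.batch_mean_metric_2 is not None and not np.isfinite(self.batch_mean_metric_2):
            raise ValueError("batch mean must be finite")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")


def slope(series: MetricSeries) -> float:
    """Ordinary-least-squares slope of metric value vs time (units/ps)."""
    t = series.times
    if len(t) < 2:
        raise DegenerateFitError("slope needs at least 2 samples")
    if np.ptp(t) == 0:
        raise DegenerateFitError("all sample times identical; slope undefined")
    tc = t - t.mean()
    return float((tc @ (series.values - series.values.mean())) / (tc @ tc))


def sm_score(series: MetricSeries) -> float:
    """Single-metric score: sqrt(last value × window mean).

    Valid for non-negative metrics (distances, RMSDs, counts); a negative
    product signals a metric unsuitable for this score.
    """
    product = series.last_value * series.window_mean
    if product < 0:
        raise ValueError(
            "SMscore undefined: last value and window mean have opposite signs"
        )
    return float(np.sqrt(product))


def dm_score(
    last_1: float,
    last_2: float,
    stats: BatchStatistics,
    directions: tuple[str, str],
) -> float:
    """Double-metric score.

    Each addend is (last / batch mean − 1); an addend whose metric is set to
    decrease is multiplied by −1 so that a positive score always means
    progress. When a last value equals its batch mean that addend is null and
    the score depends only on the remaining metric. The sum is scaled by 100.
    """
    if stats.batch_mean_metric_2 is None:
        raise ValueError("DMscore requires batch means for both metrics")
    eps = 1e-12
    if abs(stats.batch_mean_metric_1) < eps or abs(stats.batch_mean_metric_2) < eps:
        raise ZeroDivisionError("DMscore batch mean is (numerically) zero")
    score = 0.0
    for last, mean, direction in (
        (last_1, stats.batch_mean_metric_1, directions[0]),
        (last_2, stats.batch_mean_metric_2, directions[1]),
    ):
        addend = last / mean - 1.0
        if direction == DECREASE:
            addend = -addend
        elif direction != INCREASE:
            raise ValueError(f"invalid direction {direction!r}")
        score += addend
    return float(score * 100.0)


def batch_statistics(batch: list[list[MetricSeries]]) -> BatchStatistics:
    """Pooled per-metric averages over all walkers of a batch.

    All sampled values of each metric across every walker are pooled; with
    equal samples per walker this equals the mean of per-walker window means.
    """
    if not batch:
        raise ValueError("empty batch")
    n_metrics = len(batch[0])
    means = []
    for slot in range(n_metrics):
        pooled = np.concatenate([np.asarray(w[slot].values) for w in batch])
        means.append(float(pooled.mean()))
    return BatchStatistics(
        batch_mean_metric_1=means[0],
        batch_mean_metric_2=means[1] if n_metrics > 1 else None,
        n_walkers=len(batch),
    )


def walker_scores(
    batch: list[list[MetricSeries]],
    acceptance: AcceptanceSpec,
    directions: tuple[str, ...],
) -> list[float]:
    """Raw per-walker scores under the given acceptance rule."""
    if acceptance.method == "slope":
        return [slope(w[0]) for w in batch]
    if acceptance.method == "SMscore":
        return [sm_score(w[0]) for w in batch]
    stats = batch_statistics(batch)
    return [
        dm_score(w[0].last_value, w[1].last_value, stats, (directions[0], directions[1]))
        for w in batch
    ]


def select_walker(
    batch: list[list[MetricSeries]],
    acceptance: AcceptanceSpec,
    directions: tuple[str, ...],
) -> int:
    """Index of the productive walker of a batch.

    slope/SMscore: lowest score wins for a decreasing metric, highest for an
    increasing one (for slope, "lowest" is the most negative slope). DMscore:
    highest score wins, the sign normalization having made positive mean
    progress. Ties break to the lowest walker index. With a single walker it
    is returned regardless of score: one replica per batch is always
    productive.
    """
    if not batch:
        raise ValueError("cannot select from an empty batch")
    n_metrics = acceptance.n_metrics
    for w in batch:
        if len(w) != n_metrics:
            raise ValueError(
                f"{acceptance.method} needs {n_metrics} metric series per walker"
            )
    if len(directions) < n_metrics:
        raise ValueError("one direction per supervised metric required")
    scores = np.array(walker_scores(batch, acceptance, directions))
    if acceptance.method == "DMscore":
        return int(np.argmax(scores))
    if directions[0] == DECREASE:
        return int(np.argmin(scores))
    return int(np.argmax(scores))
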
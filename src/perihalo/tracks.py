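"""Per-track migration statistics and group comparisons.

A track is an ordered sequence of (time, x, y) samples for one cell.  All
lengths are in micrometres, times in minutes and angles in degrees.  The
directional metrics are defined relative to a :class:`GradientFrame`, whose
``direction`` points straight up the attractant gradient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


def welch_p(treated: np.ndarray, reference: np.ndarray) -> float:
    """Two-sided Welch t-test p-value; identical zero-variance groups give 1."""
    with warnings.catch_warnings():
        # nearly identical samples trigger a harmless precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(treated, reference, equal_var=False).pvalue)
    if math.isnan(p) and np.mean(treated) == np.mean(reference):
        return 1.0
    return p

__all__ = [
    "CellTrack",
    "GradientFrame",
    "TrackMetrics",
    "GroupComparison",
    "track_metrics",
    "filter_by_displacement",
    "angle_histogram",
    "group_compare",
]


@dataclass(frozen=True)
class CellTrack:
    """Trajectory of a single cell.

    Parameters
    ----------
    track_id
        Identifier, unique within one table.
    times
        Sample times in minutes, strictly increasing.
    positions
        ``(n, 2)`` array of x/y coordinates in micrometres.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or positions.ndim != 2 or positions.shape[1] != 2:
            raise ValueError(f"track {self.track_id!r}: times must be 1-D and positions (n, 2)")
        if len(times) != len(positions):
            raise ValueError(f"track {self.track_id!r}: {len(times)} times vs {len(positions)} positions")
        if len(times) < 2:
            raise ValueError(f"track {self.track_id!r}: needs at least 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise ValueError(f"track {self.track_id!r}: non-finite values")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"track {self.track_id!r}: times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def steps(self) -> np.ndarray:
        """Displacement vectors between consecutive samples, shape (n-1, 2)."""
        return np.diff(self.positions, axis=0)


@dataclass(frozen=True)
class GradientFrame:
    """Unit vector pointing straight up the gradient (plus optional origin)."""

    direction: np.ndarray
    origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        direction = np.asarray(self.direction, dtype=float)
        if direction.shape != (2,):
            raise ValueError("gradient direction must be a 2-vector")
        norm = float(np.linalg.norm(direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"gradient direction must be a unit vector (|v| = {norm:.3g})")
        object.__setattr__(self, "direction", direction)
        if self.origin is not None:
            object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


@dataclass(frozen=True)
class TrackMetrics:
    """Summary statistics of a single track (NaN marks an undefined value)."""

    track_id: str
    track_length: float
    displacement: float
    upgradient_displacement: float
    chemotactic_displacement: float
    speed: float
    chemotactic_index: float
    mean_angle_change: float
    #: |heading change| per consecutive step pair, degrees in [0, 180]
    angle_changes: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict[str, float]:
        return {
            "track_id": self.track_id,
            "track_length": self.track_length,
            "displacement": self.displacement,
            "upgradient_displacement": self.upgradient_displacement,
            "chemotactic_displacement": self.chemotactic_displacement,
            "speed": self.speed,
            "chemotactic_index": self.chemotactic_index,
            "mean_angle_change": self.mean_angle_change,
        }


def _wrap_degrees(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)
    return wrapped


def track_metrics(track: CellTrack, gradient: GradientFrame) -> TrackMetrics:
    """Compute all per-track migration metrics.

    ``track_length`` is the summed step length, ``displacement`` the
    start-to-end distance, and ``upgradient_displacement`` the signed
    component of the net displacement along the gradient direction.
    ``chemotactic_displacement`` divides the upgradient displacement by the
    track length; ``chemotactic_index`` is the cosine of the angle between
    the gradient and the start-to-end vector; ``speed`` is track length per
    elapsed time and ``mean_angle_change`` the mean absolute heading change
    between consecutive steps, wrapped to [0, 180] degrees.

    Degenerate quantities are reported as NaN, never coerced to zero: a
    zero-length track has undefined ratio metrics, and a zero net
    displacement leaves the chemotactic index undefined.
    """
    steps = track.steps
    step_lengths = np.linalg.norm(steps, axis=1)
    track_length = float(step_lengths.sum())
    net = track.positions[-1] - track.positions[0]
    displacement = float(np.linalg.norm(net))
    upgradient = float(net @ gradient.direction)
    elapsed = float(track.times[-1] - track.times[0])
    speed = track_length / elapsed

    if track_length > 0.0:
        chemotactic_displacement = upgradient / track_length
    else:
        chemotactic_displacement = math.nan
    if displacement > 0.0:
        chemotactic_index = upgradient / displacement
    else:
        chemotactic_index = math.nan

    moving = step_lengths > 0.0
    headings = np.degrees(np.arctan2(steps[moving, 1], steps[moving, 0]))
    if len(headings) >= 2:
        deltas = np.abs(_wrap_degrees(np.diff(headings)))
        mean_angle_change = float(deltas.mean())
    else:
        deltas = np.empty(0)
        mean_angle_change = math.nan

    return TrackMetrics(
        track_id=track.track_id,
        track_length=track_length,
        displacement=displacement,
        upgradient_displacement=upgradient,
        chemotactic_displacement=chemotactic_displacement,
        speed=speed,
        chemotactic_index=chemotactic_index,
        mean_angle_change=mean_angle_change,
        angle_changes=deltas,
    )


def filter_by_displacement(tracks: Iterable[CellTrack], min_displacement: float) -> list[CellTrack]:
    """Keep tracks whose start-to-end displacement is >= ``min_displacement``.

    The default collagen-assay threshold used in the pipeline is 24.1 um;
    the comparison is inclusive.
    """
    if min_displacement < 0:
        raise ValueError("min_displacement must be >= 0")
    kept = []
    for track in tracks:
        net = track.positions[-1] - track.positions[0]
        if float(np.linalg.norm(net)) >= min_displacement:
            kept.append(track)
    return kept


def angle_histogram(
    tracks: Sequence[CellTrack],
    gradient: GradientFrame,
    n_bins: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin per-track endpoint angles (relative to upgradient) into sectors.

    Sectors are equal 360/n_bins-degree wedges centred so that 0 degrees
    (straight upgradient) is a sector centre.  Returns ``(bin_centers,
    fractions)`` with fractions summing to 1.  Tracks with zero net
    displacement are excluded (their angle is undefined).
    """
    if n_bins < 2 or 360 % n_bins != 0:
        raise ValueError("n_bins must be >= 2 and divide 360")
    if len(tracks) == 0:
        raise ValueError("angle_histogram needs at least one track")
    gdir = gradient.direction
    gangle = math.degrees(math.atan2(gdir[1], gdir[0]))
    angles = []
    for track in tracks:
        net = track.positions[-1] - track.positions[0]
        if np.linalg.norm(net) == 0:
            continue
        a = math.degrees(math.atan2(net[1], net[0])) - gangle
        angles.append(float(_wrap_degrees(a)))
    if not angles:
        raise ValueError("no track has nonzero displacement")
    width = 360.0 / n_bins
    # shift by half a sector so 0 deg sits at a bin centre
    idx = np.floor((np.asarray(angles) + width / 2.0) / width).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    centers = _wrap_degrees(np.arange(n_bins) * width)
    return np.asarray(centers, dtype=float), counts / counts.sum()


@dataclass(frozen=True)
class GroupComparison:
    """Per-metric group summary: means, SEMs, fold change and Welch p."""

    metric: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    fold_change: float
    p_value: float
    reference: str
    treated: str


def _clean(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[np.isfinite(arr)]


def group_compare(
    metrics_by_group: Mapping[str, Sequence[Mapping[str, float] | TrackMetrics]],
    reference: str | None = None,
    metrics: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """Compare per-track metrics between groups with Welch's t-test.

    ``metrics_by_group`` maps a group label to a sequence of per-observation
    metric mappings (``TrackMetrics`` instances are accepted).  The fold
    change is mean(treated)/mean(reference); with more than two groups each
    non-reference group is compared against the reference and one
    :class:`GroupComparison` is emitted per (metric, treated) pair.  NaN
    observations are dropped before testing.
    """
    if len(metrics_by_group) < 2:
        raise ValueError("group_compare needs at least two groups")
    tables: dict[str, list[dict]] = {}
    for group, rows in metrics_by_group.items():
        tables[group] = [r.as_dict() if isinstance(r, TrackMetrics) else dict(r) for r in rows]
    group_names = list(tables)
    if reference is None:
        reference = group_names[0]
    if reference not in tables:
        raise ValueError(f"reference group {reference!r} not present")
    if metrics is None:
        metrics = [k for k in tables[group_names[0]][0] if k != "track_id"]

    results: list[GroupComparison] = []
    for metric in metrics:
        values = {g: _clean(row[metric] for row in rows) for g, rows in tables.items()}
        for g, v in values.items():
            if len(v) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 finite observations for {metric!r}")
        means = {g: float(v.mean()) for g, v in values.items()}
        sems = {g: float(stats.sem(v)) for g, v in values.items()}
        ns = {g: int(len(v)) for g, v in values.items()}
        for treated in group_names:
            if treated == reference:
                continue
            ref_vals, tr_vals = values[reference], values[treated]
            p = welch_p(tr_vals, ref_vals)
            fold = means[treated] / means[reference] if means[reference] != 0 else math.nan
            results.append(
                GroupComparison(
                    metric=metric,
                    group_means=means,
                    group_sems=sems,
                    group_ns=ns,
                    fold_change=fold,
                    p_value=p,
                    reference=reference,
                    treated=treated,
                )
            )
    return results
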
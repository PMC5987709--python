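"""Bespoke assay quantitations.

Covers point-to-vessel minimum distances with a spatial-randomness
normalization, the microfluidic adhesion rule, transwell standard-curve
calibration and kinetic summaries, replicate particle-size histogram
averaging, and transwell membrane pore coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import MultiLineString

__all__ = [
    "VesselMap",
    "SizeHistogram",
    "StandardCurve",
    "min_distance_to_vessels",
    "normalized_mean_distance",
    "adherent_tracks",
    "calibrate_transwell",
    "nta_average",
    "pore_coverage",
]

UM2_PER_CM2 = 1e8


@dataclass(frozen=True)
class VesselMap:
    """Vessel centre-line polylines within a rectangular field.

    ``bounds`` is (xmin, ymin, xmax, ymax) in micrometres and defines the
    field used for density normalization; it defaults to the bounding box of
    all polylines.
    """

    polylines: tuple[np.ndarray, ...]
    bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.polylines:
            raise ValueError("vessel map needs at least one polyline")
        lines = []
        for i, line in enumerate(self.polylines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
                raise ValueError(f"polyline {i}: needs shape (>=2, 2)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"polyline {i}: non-finite vertices")
            lines.append(arr)
        object.__setattr__(self, "polylines", tuple(lines))
        if self.bounds is None:
            stacked = np.vstack(lines)
            object.__setattr__(
                self,
                "bounds",
                (
                    float(stacked[:, 0].min()),
                    float(stacked[:, 1].min()),
                    float(stacked[:, 0].max()),
                    float(stacked[:, 1].max()),
                ),
            )
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("field bounds must enclose a nonzero area")

    @property
    def field_area(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    @property
    def total_length(self) -> float:
        return sum(
            float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum()) for line in self.polylines
        )

    @property
    def length_density(self) -> float:
        """Vessel length per field area, 1/um."""
        return self.total_length / self.field_area

    def as_shapely(self) -> MultiLineString:
        return MultiLineString([line.tolist() for line in self.polylines])


def min_distance_to_vessels(points: np.ndarray, vessels: VesselMap) -> np.ndarray:
    """Euclidean distance from each point to the nearest vessel polyline."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a nonempty (n, 2) array")
    geom = vessels.as_shapely()
    return shapely.distance(shapely.points(pts), geom).astype(float)


def normalized_mean_distance(
    points: np.ndarray,
    vessels: VesselMap,
    seed: int = 0,
    n_monte_carlo: int = 10_000,
) -> dict[str, float]:
    """Mean minimum distance normalized by the uniform-random expectation.

    The observed mean point-to-vessel distance is divided by the expected
    minimum distance of points placed uniformly at random over the field
    (seeded Monte-Carlo).  Under complete spatial randomness the statistic
    is 1; attraction toward vessels pushes it below 1.  The raw mean
    distance and the vessel length density are reported alongside.
    """
    distances = min_distance_to_vessels(points, vessels)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = vessels.bounds
    random_pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_monte_carlo), rng.uniform(ymin, ymax, n_monte_carlo)]
    )
    null_distances = min_distance_to_vessels(random_pts, vessels)
    expected = float(null_distances.mean())
    observed = float(distances.mean())
    return {
        "mean_distance_um": observed,
        "expected_csr_distance_um": expected,
        "normalized_distance": observed / expected,
        "vessel_length_density_per_um": vessels.length_density,
        "n_points": float(len(distances)),
    }


def adherent_tracks(
    events: Mapping[str, Sequence[bool]] | Sequence[Sequence[bool]],
    min_duration_s: float = 3.0,
    frame_interval_s: float = 1.0,
) -> int:
    """Count tracks with an uninterrupted adhesion run of >= min_duration_s.

    Each track is a boolean presence series sampled at ``frame_interval_s``.
    A run of k consecutive detections spans k * frame_interval_s seconds;
    the comparison is inclusive.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    series = events.values() if isinstance(events, Mapping) else events
    count = 0
    for presence in series:
        arr = np.asarray(list(presence), dtype=bool)
        run = longest = 0
        for present in arr:
            run = run + 1 if present else 0
            longest = max(longest, run)
        if longest * frame_interval_s >= min_duration_s:
            count += 1
    return count


@dataclass(frozen=True)
class StandardCurve:
    """Fluorescence-to-cell-count calibration points."""

    fluorescence: np.ndarray
    cell_count: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        c = np.asarray(self.cell_count, dtype=float)
        if f.ndim != 1 or f.shape != c.shape or len(f) < 2:
            raise ValueError("standard curve needs >= 2 (fluorescence, cell_count) points")
        if np.any(c < 0):
            raise ValueError("cell counts must be >= 0")
        if np.ptp(f) == 0:
            raise ValueError("degenerate standard curve: all fluorescence values equal")
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "cell_count", c)

    def fit(self) -> tuple[float, float]:
        """OLS slope and intercept of cell_count vs fluorescence."""
        slope, intercept, *_ = stats.linregress(self.fluorescence, self.cell_count)
        return float(slope), float(intercept)


def calibrate_transwell(
    curve: StandardCurve,
    readings: np.ndarray,
    times_min: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Convert fluorescence readings to transmigrated-cell counts.

    ``readings`` is (n_times,) or (n_times, n_replicates).  Counts are the
    OLS-mapped readings clipped at zero.  With replicates, per-time mean and
    SEM kinetic curves are included.
    """
    slope, intercept = curve.fit()
    arr = np.asarray(readings, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    counts = np.clip(slope * arr + intercept, 0.0, None)
    out: dict[str, np.ndarray] = {"counts": counts[:, 0] if squeeze else counts}
    if times_min is not None:
        out["times_min"] = np.asarray(times_min, dtype=float)
    out["mean"] = counts.mean(axis=1)
    out["sem"] = (
        counts.std(axis=1, ddof=1) / math.sqrt(counts.shape[1])
        if counts.shape[1] > 1
        else np.zeros(counts.shape[0])
    )
    return out


@dataclass(frozen=True)
class SizeHistogram:
    """Particle concentration per diameter bin (nanometres, particles/ml)."""

    bin_edges: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        conc = np.asarray(self.concentration, dtype=float)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if conc.shape != (len(edges) - 1,):
            raise ValueError("need one concentration per bin")
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "concentration", conc)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.concentration.sum())


def nta_average(replicates: Sequence[SizeHistogram]) -> tuple[SizeHistogram, dict[str, float]]:
    """Bin-wise mean of replicate histograms plus summary statistics.

    Summary: concentration-weighted mean diameter, modal bin centre and
    total concentration of the averaged histogram.
    """
    if not replicates:
        raise ValueError("no replicate histograms")
    edges = replicates[0].bin_edges
    for i, rep in enumerate(replicates[1:], start=2):
        if rep.bin_edges.shape != edges.shape or not np.allclose(rep.bin_edges, edges):
            raise ValueError(f"replicate {i}: bin edges differ from replicate 1")
    mean_conc = np.mean([rep.concentration for rep in replicates], axis=0)
    averaged = SizeHistogram(bin_edges=edges.copy(), concentration=mean_conc)
    centers = averaged.bin_centers
    total = averaged.total
    if total > 0:
        mean_diameter = float((centers * mean_conc).sum() / total)
        mode_diameter = float(centers[int(np.argmax(mean_conc))])
    else:
        mean_diameter = math.nan
        mode_diameter = math.nan
    summary = {
        "mean_diameter_nm": mean_diameter,
        "mode_diameter_nm": mode_diameter,
        "total_concentration_per_ml": total,
    }
    return averaged, summary


def pore_coverage(pore_diameter_um: float, pore_density_per_cm2: float) -> float:
    """Percent of membrane area occupied by circular pores."""
    if pore_diameter_um <= 0:
        raise ValueError("pore diameter must be > 0")
    if pore_density_per_cm2 <= 0:
        raise ValueError("pore density must be > 0")
    pore_area_um2 = math.pi * (pore_diameter_um / 2.0) ** 2
    return 100.0 * pore_area_um2 * pore_density_per_cm2 / UM2_PER_CM2
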
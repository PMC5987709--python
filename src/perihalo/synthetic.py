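"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (tracks, morphometry, halo,
proteomics, assays) can be exercised on output of this module without any
external data.  All generators take one explicit integer seed and are
deterministic: equal seeds give byte-identical outputs.  No global random
state is touched.

Walk model
----------
Cell tracks follow a biased persistent random walk.  At each step the new
heading is drawn from a wrapped-normal distribution centred on the direction
of ``persistence * e(previous heading) + bias * (1 + protrusion) * g`` (g =
unit upgradient vector) with angular spread ``heading_noise_sd * sqrt(1 +
protrusion)``; the realized step speed is ``base_speed / (1 + protrusion)``.
The single ``protrusion`` knob therefore simultaneously lowers speed, raises
angular exploration and raises effective gradient coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assays import SizeHistogram, StandardCurve, VesselMap
from .halo import LineProfile
from .morphometry import CellContour
from .proteomics import CHANNELS, SampleMeta
from .tracks import CellTrack, GradientFrame

__all__ = [
    "WalkParams",
    "SpikeDesign",
    "HaloDesign",
    "simulate_tracks",
    "simulate_peptide_table",
    "simulate_profile",
    "simulate_vessel_field",
    "simulate_cell_points",
    "simulate_size_histograms",
    "simulate_contours",
    "simulate_transwell_kinetics",
]


# ---------------------------------------------------------------------------
# cell tracks


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the biased persistent random walk."""

    n_cells: int = 100
    n_steps: int = 60
    dt: float = 1.0  # minutes
    base_speed: float = 4.0  # um/min
    persistence: float = 0.5  # in [0, 1)
    bias: float = 0.0  # >= 0, gradient coupling
    protrusion: float = 0.0  # >= 0
    heading_noise_sd: float = 40.0  # degrees, before protrusion scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_steps < 1:
            raise ValueError("n_cells and n_steps must be >= 1")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.base_speed < 0:
            raise ValueError("base_speed must be >= 0")
        if self.bias < 0 or self.protrusion < 0:
            raise ValueError("bias and protrusion must be >= 0")
        if self.heading_noise_sd < 0:
            raise ValueError("heading_noise_sd must be >= 0")


def simulate_tracks(params: WalkParams, gradient: GradientFrame) -> list[CellTrack]:
    """Simulate ``n_cells`` tracks of ``n_steps + 1`` points each."""
    rng = np.random.default_rng(params.seed)
    g = gradient.direction
    speed = params.base_speed / (1.0 + params.protrusion)
    # angular exploration grows sub-linearly while gradient gain grows
    # linearly, so protrusion raises turning AND net directionality
    noise_sd = math.radians(params.heading_noise_sd) * math.sqrt(1.0 + params.protrusion)
    bias_weight = params.bias * (1.0 + params.protrusion)
    tracks = []
    times = np.arange(params.n_steps + 1) * params.dt
    for i in range(params.n_cells):
        theta = rng.uniform(-math.pi, math.pi)
        pos = np.zeros((params.n_steps + 1, 2))
        for step in range(params.n_steps):
            v = params.persistence * np.array([math.cos(theta), math.sin(theta)]) + bias_weight * g
            center = math.atan2(v[1], v[0]) if np.linalg.norm(v) > 1e-12 else theta
            theta = math.remainder(center + rng.normal(0.0, noise_sd), 2.0 * math.pi)
            pos[step + 1] = pos[step] + speed * params.dt * np.array(
                [math.cos(theta), math.sin(theta)]
            )
        tracks.append(CellTrack(track_id=f"sim_{i:05d}", times=times.copy(), positions=pos))
    return tracks


# ---------------------------------------------------------------------------
# peptide tables


@dataclass(frozen=True)
class SpikeDesign:
    """Spike-in design for a 3 vs 3 six-channel reporter experiment.

    ``log2_fold_changes`` holds the per-protein treated/reference ground
    truth; scalars are broadcast.  ``n_peptides_per_protein`` is either a
    fixed count or an inclusive (lo, hi) range sampled uniformly.
    """

    n_proteins: int = 100
    n_peptides_per_protein: int | tuple[int, int] = 5
    groups: dict[str, str] = field(
        default_factory=lambda: {
            "c1": "ss", "c2": "ss", "c3": "ss", "c4": "TNFa", "c5": "TNFa", "c6": "TNFa",
        }
    )
    log2_fold_changes: float | Sequence[float] = 0.0
    peptide_cv: float = 0.0
    protein_concentrations: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHANNELS}
    )
    base_abundance_log10_mean: float = 6.0
    base_abundance_log10_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        counts = self.n_peptides_per_protein
        if isinstance(counts, tuple):
            if counts[0] < 1 or counts[1] < counts[0]:
                raise ValueError("peptide count range must be 1 <= lo <= hi")
        elif counts < 1:
            raise ValueError("every protein needs at least 1 peptide")
        if self.peptide_cv < 0:
            raise ValueError("peptide_cv must be >= 0")
        SampleMeta(groups=dict(self.groups), concentrations=dict(self.protein_concentrations))
        fc = self.log2_fold_changes
        if not np.isscalar(fc) and len(np.asarray(fc)) != self.n_proteins:
            raise ValueError("log2_fold_changes must be scalar or length n_proteins")

    @property
    def meta(self) -> SampleMeta:
        return SampleMeta(groups=dict(self.groups), concentrations=dict(self.protein_concentrations))


def simulate_peptide_table(design: SpikeDesign) -> tuple[pd.DataFrame, SampleMeta, pd.Series]:
    """Generate a peptide-level reporter table with retrievable ground truth.

    Per peptide and channel the intensity is ``base abundance x group fold
    change x peptide efficiency x log-normal noise``, divided by the
    channel's concentration scaling (emulating equal-amount pooling of the
    labelled samples, which the normalization stage undoes).  Returns the
    table, the sample metadata and the true per-protein log2 fold change
    (treated over reference) as a Series indexed by protein id.
    """
    rng = np.random.default_rng(design.seed)
    meta = design.meta
    ref_label, tr_label = meta.group_labels
    fc = np.asarray(design.log2_fold_changes, dtype=float)
    if fc.ndim == 0:
        fc = np.full(design.n_proteins, float(fc))
    protein_ids = [f"P{i:05d}" for i in range(design.n_proteins)]
    truth = pd.Series(fc, index=pd.Index(protein_ids, name="protein_id"), name="log2_fold_change")

    counts = design.n_peptides_per_protein
    if isinstance(counts, tuple):
        n_peptides = rng.integers(counts[0], counts[1] + 1, size=design.n_proteins)
    else:
        n_peptides = np.full(design.n_proteins, int(counts))

    min_conc = min(meta.concentrations.values())
    pooling = {c: meta.concentrations[c] / min_conc for c in CHANNELS}
    # log-normal noise parameterized so that sd/mean == peptide_cv
    noise_sigma = math.sqrt(math.log1p(design.peptide_cv**2))

    rows = []
    for p, pid in enumerate(protein_ids):
        base = 10.0 ** rng.normal(design.base_abundance_log10_mean, design.base_abundance_log10_sd)
        linear_fc = 2.0 ** fc[p]
        for j in range(n_peptides[p]):
            efficiency = 10.0 ** rng.normal(0.0, 0.3)
            row: dict[str, object] = {"protein_id": pid, "peptide_id": f"{pid}_pep{j:03d}"}
            for c in CHANNELS:
                group_fc = linear_fc if meta.groups[c] == tr_label else 1.0
                noise = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0
                row[c] = base * group_fc * efficiency * noise / pooling[c]
            rows.append(row)
    table = pd.DataFrame.from_records(rows, columns=["protein_id", "peptide_id", *CHANNELS])
    return table, meta, truth


# ---------------------------------------------------------------------------
# line profiles


@dataclass(frozen=True)
class HaloDesign:
    """Two-sided Gaussian band profile design, one entry per channel.

    For a channel with half-width ``h`` the bands sit at ``vessel_center +/-
    h`` with Gaussian spread ``h / 2``, so every width-like readout of the
    profile scales linearly with ``h`` and channel half-width ratios are
    recoverable downstream.
    """

    vessel_center: float = 0.0
    channel_band_halfwidths: dict[str, float] = field(
        default_factory=lambda: {"CD9": 8.0, "podoplanin": 4.0}
    )
    band_amplitudes: dict[str, float] | None = None
    background: float = 10.0
    noise_sd: float = 0.0
    sampling_step: float = 0.1  # um
    extent: float | None = None  # half-length of the profile, um
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channel_band_halfwidths:
            raise ValueError("need at least one channel")
        for ch, h in self.channel_band_halfwidths.items():
            if h <= 0:
                raise ValueError(f"channel {ch}: halfwidth must be > 0")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_profile(design: HaloDesign) -> tuple[LineProfile, dict[str, float]]:
    """Generate a cross-sectional profile; returns (profile, ground truth).

    Ground truth maps each channel to its designed band half-width.
    """
    rng = np.random.default_rng(design.seed)
    extent = design.extent
    if extent is None:
        extent = 4.0 * max(design.channel_band_halfwidths.values()) + 5.0
    n = int(round(2 * extent / design.sampling_step)) + 1
    x = design.vessel_center + np.linspace(-extent, extent, n)
    amplitudes = design.band_amplitudes or {
        ch: 100.0 for ch in design.channel_band_halfwidths
    }
    channels = {}
    for ch, h in design.channel_band_halfwidths.items():
        amp = amplitudes.get(ch, 100.0)
        sd = h / 2.0
        d = x - design.vessel_center
        signal = design.background + amp * (
            np.exp(-0.5 * ((d - h) / sd) ** 2) + np.exp(-0.5 * ((d + h) / sd) ** 2)
        )
        if design.noise_sd > 0:
            signal = signal + rng.normal(0.0, design.noise_sd, size=n)
        channels[ch] = signal
    profile = LineProfile(distances=x, channels=channels)
    return profile, dict(design.channel_band_halfwidths)


# ---------------------------------------------------------------------------
# vessel fields and cell points


def simulate_vessel_field(
    n_vessels: int = 4,
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0),
    n_vertices: int = 20,
    wiggle: float = 30.0,
    seed: int = 0,
) -> VesselMap:
    """Random meandering vessel polylines crossing a rectangular field."""
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = bounds
    lines = []
    for _ in range(n_vessels):
        horizontal = rng.random() < 0.5
        if horizontal:
            xs = np.linspace(xmin, xmax, n_vertices)
            y0 = rng.uniform(ymin, ymax)
            ys = np.clip(y0 + np.cumsum(rng.normal(0, wiggle, n_vertices)) / 3.0, ymin, ymax)
        else:
            ys = np.linspace(ymin, ymax, n_vertices)
            x0 = rng.uniform(xmin, xmax)
            xs = np.clip(x0 + np.cumsum(rng.normal(0, wiggle, n_vertices)) / 3.0, xmin, xmax)
        lines.append(np.column_stack([xs, ys]))
    return VesselMap(polylines=tuple(lines), bounds=bounds)


def simulate_cell_points(
    vessels: VesselMap,
    n_points: int = 200,
    mode: str = "csr",
    attraction_scale: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Cell point pattern relative to vessels.

    ``csr`` draws uniformly over the field (Poisson-like null); ``near``
    places points at Gaussian offsets from random positions along vessels;
    ``far`` thins uniform draws in favour of vessel-distant locations.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = vessels.bounds
    if mode == "csr":
        return np.column_stack(
            [rng.uniform(xmin, xmax, n_points), rng.uniform(ymin, ymax, n_points)]
        )
    if mode == "near":
        geom = vessels.as_shapely()
        fractions = rng.random(n_points)
        pts = []
        for f in fractions:
            anchor = geom.interpolate(f, normalized=True)
            offset = rng.normal(0.0, attraction_scale, 2)
            pts.append([anchor.x + offset[0], anchor.y + offset[1]])
        arr = np.asarray(pts)
        arr[:, 0] = np.clip(arr[:, 0], xmin, xmax)
        arr[:, 1] = np.clip(arr[:, 1], ymin, ymax)
        return arr
    if mode == "far":
        from .assays import min_distance_to_vessels

        accepted: list[np.ndarray] = []
        dmax = max(xmax - xmin, ymax - ymin)
        while len(accepted) < n_points:
            cand = np.column_stack(
                [rng.uniform(xmin, xmax, 4 * n_points), rng.uniform(ymin, ymax, 4 * n_points)]
            )
            d = min_distance_to_vessels(cand, vessels)
            keep = rng.random(len(cand)) < np.minimum(1.0, d / (0.25 * dmax))
            accepted.extend(cand[keep])
        return np.asarray(accepted[:n_points])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# particle-size histograms


def simulate_size_histograms(
    mode_nm: float = 83.0,
    sigma_log: float = 0.35,
    total_concentration: float = 1e9,
    n_particles: int = 20_000,
    bin_edges: np.ndarray | None = None,
    n_replicates: int = 5,
    seed: int = 0,
) -> tuple[list[SizeHistogram], dict[str, float]]:
    """Replicate log-normal particle diameter histograms.

    Diameters follow a log-normal whose mode is ``mode_nm``; each replicate
    resamples particles.  Returns (replicates, ground truth).
    """
    rng = np.random.default_rng(seed)
    if bin_edges is None:
        bin_edges = np.arange(0.0, 605.0, 10.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    # lognormal mode = exp(mu - sigma^2)
    mu = math.log(mode_nm) + sigma_log**2
    replicates = []
    for _ in range(n_replicates):
        diameters = rng.lognormal(mu, sigma_log, n_particles)
        counts, _ = np.histogram(diameters, bins=bin_edges)
        conc = counts / counts.sum() * total_concentration
        replicates.append(SizeHistogram(bin_edges=bin_edges.copy(), concentration=conc))
    truth = {
        "mode_nm": mode_nm,
        "mean_nm": math.exp(mu + sigma_log**2 / 2.0),
        "total_concentration_per_ml": total_concentration,
    }
    return replicates, truth


# ---------------------------------------------------------------------------
# cell contours


def simulate_contours(
    n_contours: int = 10,
    protrusion_amplitude: float = 0.0,
    n_protrusions: int = 7,
    radius_um: float = 10.0,
    n_vertices: int = 256,
    jitter: float = 0.0,
    seed: int = 0,
) -> list[CellContour]:
    """Star-shaped polygons: r(phi) = R * (1 + a * cos(k * phi)).

    ``protrusion_amplitude`` in [0, 1) controls spikiness; amplitude 0 gives
    a regular polygon approximating a circle (circularity near 1).
    """
    if not (0.0 <= protrusion_amplitude < 1.0):
        raise ValueError("protrusion_amplitude must be in [0, 1)")
    rng = np.random.default_rng(seed)
    contours = []
    phi = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    for i in range(n_contours):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        r = radius_um * (1.0 + protrusion_amplitude * np.cos(n_protrusions * phi + phase))
        if jitter > 0:
            r = np.maximum(r * (1.0 + rng.normal(0.0, jitter, n_vertices)), 0.05 * radius_um)
        verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        contours.append(CellContour(contour_id=f"cell_{i:04d}", vertices=verts))
    return contours


# ---------------------------------------------------------------------------
# transwell kinetics


def simulate_transwell_kinetics(
    n_times: int = 9,
    dt_min: float = 15.0,
    plateau_cells: float = 2000.0,
    t_half_min: float = 45.0,
    rise_min: float = 15.0,
    fluorescence_per_cell: float = 0.1,
    fluorescence_offset: float = 50.0,
    n_replicates: int = 3,
    noise_sd_cells: float = 0.0,
    seed: int = 0,
) -> tuple[StandardCurve, np.ndarray, np.ndarray, np.ndarray]:
    """Logistic cell-arrival curve mapped to fluorescence readings.

    Returns ``(standard_curve, times_min, readings, true_counts)`` where
    ``readings`` is (n_times, n_replicates) fluorescence and ``true_counts``
    the underlying noise-free transmigrated-cell counts.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_times) * dt_min
    true_counts = plateau_cells / (1.0 + np.exp(-(times - t_half_min) / rise_min))
    counts = np.repeat(true_counts[:, None], n_replicates, axis=1)
    if noise_sd_cells > 0:
        counts = counts + rng.normal(0.0, noise_sd_cells, (n_times, n_replicates))
    counts = np.clip(counts, 0.0, None)
    readings = counts * fluorescence_per_cell + fluorescence_offset
    curve_counts = np.linspace(0.0, 1.2 * plateau_cells, 6)
    curve = StandardCurve(
        fluorescence=curve_counts * fluorescence_per_cell + fluorescence_offset,
        cell_count=curve_counts,
    )
    return curve, times, readings, true_counts
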
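"""Plain-text readers and writers for every pipeline input format.

All formats are delimited UTF-8 text with mandatory headers (CSV/TSV), GMT
for protein clusters, and JSON/YAML for metadata.  Validation failures raise
:class:`FormatError` naming the file, line and offending record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .assays import SizeHistogram, StandardCurve, VesselMap
from .halo import LineProfile
from .morphometry import CellContour
from .proteomics import CHANNELS, SampleMeta, validate_peptide_table
from .tracks import CellTrack

__all__ = [
    "FormatError",
    "read_tracks", "write_tracks",
    "read_contours", "write_contours",
    "read_profile", "write_profile",
    "read_peptides", "write_peptides",
    "read_abundance_matrix",
    "read_sample_meta", "write_sample_meta",
    "read_gmt", "write_gmt",
    "read_vessels", "write_vessels",
    "read_points", "write_points",
    "read_size_histograms", "write_size_histograms",
    "read_standard_curve", "write_standard_curve",
]


class FormatError(ValueError):
    """A malformed input file; message names the file and record."""


def _read_table(path: str | Path, required: Sequence[str], sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unparseable ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


# -- tracks -----------------------------------------------------------------

TRACK_COLUMNS = ["track_id", "t_min", "x_um", "y_um"]


def read_tracks(path: str | Path) -> list[CellTrack]:
    """Read a track CSV: ``track_id,t_min,x_um,y_um``, one row per sample."""
    df = _read_table(path, TRACK_COLUMNS)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("t_min", kind="stable")
        times = sub["t_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            first_bad = int(sub.index[np.argmin(np.diff(times) > 0) + 1]) + 2
            raise FormatError(f"{path}: track {tid!r}: non-increasing time at line {first_bad}")
        try:
            tracks.append(
                CellTrack(
                    track_id=str(tid),
                    times=times,
                    positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not tracks:
        raise FormatError(f"{path}: no tracks")
    return tracks


def write_tracks(path: str | Path, tracks: Sequence[CellTrack]) -> None:
    rows = []
    for track in tracks:
        for t, (x, y) in zip(track.times, track.positions):
            rows.append({"track_id": track.track_id, "t_min": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


# -- contours ---------------------------------------------------------------

CONTOUR_COLUMNS = ["contour_id", "frame", "vertex_index", "x_um", "y_um"]


def read_contours(path: str | Path) -> dict[tuple[str, int], CellContour]:
    """Read contour CSV keyed by (contour_id, frame)."""
    df = _read_table(path, CONTOUR_COLUMNS)
    contours = {}
    for (cid, frame), sub in df.groupby(["contour_id", "frame"], sort=False):
        sub = sub.sort_values("vertex_index", kind="stable")
        try:
            contours[(str(cid), int(frame))] = CellContour(
                contour_id=f"{cid}@{frame}", vertices=sub[["x_um", "y_um"]].to_numpy(dtype=float)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not contours:
        raise FormatError(f"{path}: no contours")
    return contours


def write_contours(path: str | Path, contours: dict[tuple[str, int], CellContour]) -> None:
    rows = []
    for (cid, frame), contour in contours.items():
        for i, (x, y) in enumerate(contour.vertices):
            rows.append(
                {"contour_id": cid, "frame": frame, "vertex_index": i, "x_um": x, "y_um": y}
            )
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


# -- line profiles ----------------------------------------------------------


def read_profile(path: str | Path) -> LineProfile:
    """Read a profile CSV: ``distance_um,<channel>,...``."""
    df = _read_table(path, ["distance_um"])
    channels = [c for c in df.columns if c != "distance_um"]
    if not channels:
        raise FormatError(f"{path}: no intensity channels")
    try:
        return LineProfile(
            distances=df["distance_um"].to_numpy(dtype=float),
            channels={c: df[c].to_numpy(dtype=float) for c in channels},
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_profile(path: str | Path, profile: LineProfile) -> None:
    df = pd.DataFrame({"distance_um": profile.distances, **profile.channels})
    df.to_csv(path, index=False)


# -- peptide tables ---------------------------------------------------------

PEPTIDE_COLUMNS = ["protein_id", "peptide_id", *CHANNELS]


def read_peptides(path: str | Path) -> pd.DataFrame:
    """Read a peptide TSV with exactly six reporter channels c1..c6."""
    df = _read_table(path, ["protein_id", "peptide_id"], sep="\t")
    extra = [c for c in df.columns if c.startswith("c") and c not in CHANNELS]
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing or extra:
        raise FormatError(
            f"{path}: expected exactly channels {CHANNELS}; missing {missing}, unexpected {extra}"
        )
    try:
        return validate_peptide_table(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_peptides(path: str | Path, table: pd.DataFrame) -> None:
    validate_peptide_table(table)
    table[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a per-protein abundance TSV: ``protein_id[,gene_name],c1..c6``.

    Used for externally quantified protein tables; returns a DataFrame
    indexed by protein id with the six channel columns (and ``gene_name``
    if present).
    """
    df = _read_table(path, ["protein_id", *CHANNELS], sep="\t")
    df = df.set_index("protein_id")
    keep = [c for c in ["gene_name", *CHANNELS] if c in df.columns]
    values = df[CHANNELS].to_numpy(dtype=float)
    if not np.all(np.isfinite(values) | np.isnan(values)):
        raise FormatError(f"{path}: abundance matrix contains infinities")
    return df[keep]


# -- sample metadata --------------------------------------------------------


def read_sample_meta(path: str | Path) -> SampleMeta:
    """Read channel metadata from JSON or YAML: ``channel: {group, concentration}``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping of channel -> {{group, concentration}}")
    try:
        groups = {ch: str(entry["group"]) for ch, entry in data.items()}
        concentrations = {ch: float(entry["concentration"]) for ch, entry in data.items()}
        return SampleMeta(groups=groups, concentrations=concentrations)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid sample metadata ({exc})") from exc


def write_sample_meta(path: str | Path, meta: SampleMeta) -> None:
    path = Path(path)
    data = {
        ch: {"group": meta.groups[ch], "concentration": meta.concentrations[ch]}
        for ch in CHANNELS
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# -- GMT clusters -----------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read cluster definitions in GMT format (name, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    clusters: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise FormatError(f"{path}: line {lineno}: GMT record with empty member set")
        name = parts[0]
        if name in clusters:
            raise FormatError(f"{path}: line {lineno}: duplicate cluster {name!r}")
        clusters[name] = {p.strip() for p in parts[2:] if p.strip()}
    if not clusters:
        raise FormatError(f"{path}: no clusters")
    return clusters


def write_gmt(path: str | Path, clusters: dict[str, Sequence[str]], descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, members in clusters.items():
        desc = (descriptions or {}).get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- vessels and points -----------------------------------------------------

VESSEL_COLUMNS = ["polyline_id", "vertex_index", "x_um", "y_um"]


def read_vessels(
    path: str | Path, bounds: tuple[float, float, float, float] | None = None
) -> VesselMap:
    df = _read_table(path, VESSEL_COLUMNS)
    lines = []
    for _, sub in df.groupby("polyline_id", sort=False):
        sub = sub.sort_values("vertex_index", kind="stable")
        lines.append(sub[["x_um", "y_um"]].to_numpy(dtype=float))
    try:
        return VesselMap(polylines=tuple(lines), bounds=bounds)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_vessels(path: str | Path, vessels: VesselMap) -> None:
    rows = []
    for pid, line in enumerate(vessels.polylines):
        for i, (x, y) in enumerate(line):
            rows.append({"polyline_id": pid, "vertex_index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=VESSEL_COLUMNS).to_csv(path, index=False)


def read_points(path: str | Path) -> np.ndarray:
    df = _read_table(path, ["x_um", "y_um"])
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(pts) == 0:
        raise FormatError(f"{path}: no points")
    return pts


def write_points(path: str | Path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x_um", "y_um"]).to_csv(
        path, index=False
    )


# -- size histograms --------------------------------------------------------

HISTOGRAM_COLUMNS = ["replicate", "bin_lo_nm", "bin_hi_nm", "conc_per_ml"]


def read_size_histograms(path: str | Path) -> list[SizeHistogram]:
    """Read replicate histograms: ``replicate,bin_lo_nm,bin_hi_nm,conc_per_ml``."""
    df = _read_table(path, HISTOGRAM_COLUMNS)
    histograms = []
    for _, sub in df.groupby("replicate", sort=True):
        sub = sub.sort_values("bin_lo_nm", kind="stable")
        lo = sub["bin_lo_nm"].to_numpy(dtype=float)
        hi = sub["bin_hi_nm"].to_numpy(dtype=float)
        if not np.allclose(lo[1:], hi[:-1]):
            raise FormatError(f"{path}: non-contiguous bins in a replicate")
        try:
            histograms.append(
                SizeHistogram(
                    bin_edges=np.append(lo, hi[-1]),
                    concentration=sub["conc_per_ml"].to_numpy(dtype=float),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not histograms:
        raise FormatError(f"{path}: no histograms")
    return histograms


def write_size_histograms(path: str | Path, histograms: Sequence[SizeHistogram]) -> None:
    rows = []
    for r, hist in enumerate(histograms):
        for lo, hi, conc in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.concentration):
            rows.append({"replicate": r, "bin_lo_nm": lo, "bin_hi_nm": hi, "conc_per_ml": conc})
    pd.DataFrame(rows, columns=HISTOGRAM_COLUMNS).to_csv(path, index=False)


# -- standard curves --------------------------------------------------------

CURVE_COLUMNS = ["fluorescence", "cell_count"]


def read_standard_curve(path: str | Path) -> StandardCurve:
    df = _read_table(path, CURVE_COLUMNS)
    try:
        return StandardCurve(
            fluorescence=df["fluorescence"].to_numpy(dtype=float),
            cell_count=df["cell_count"].to_numpy(dtype=float),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_standard_curve(path: str | Path, curve: StandardCurve) -> None:
    pd.DataFrame(
        {"fluorescence": curve.fluorescence, "cell_count": curve.cell_count}
    ).to_csv(path, index=False)
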
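"""Isobaric-reporter (6-plex) protein quantitation.

Stages: per-channel median normalization with input-concentration scaling,
Top3 interprotein abundance, TNFa/ss ratio and dual significance testing,
ratio-density summaries, heat-map matrices and protein-cluster enrichment.

The peptide table is a pandas DataFrame with columns ``protein_id``,
``peptide_id`` and the six reporter channels ``c1 .. c6``.  Sample metadata
maps each channel to a group label and a measured input protein
concentration.  Zero reporter intensities are treated as non-detections and
excluded from medians and Top3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import welch_p

__all__ = [
    "CHANNELS",
    "SampleMeta",
    "ProteinQuant",
    "ClusterEnrichment",
    "validate_peptide_table",
    "normalize_channels",
    "top3",
    "ratios_and_significance",
    "quant_from_abundance_matrix",
    "ratio_density",
    "heatmap_matrix",
    "cluster_enrichment",
    "benjamini_hochberg",
]

CHANNELS = ["c1", "c2", "c3", "c4", "c5", "c6"]


@dataclass(frozen=True)
class SampleMeta:
    """Channel -> group label plus measured input protein concentration (mg/ml)."""

    groups: dict[str, str]
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.groups) != set(CHANNELS) or set(self.concentrations) != set(CHANNELS):
            raise ValueError(f"metadata must cover exactly channels {CHANNELS}")
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise ValueError("exactly two group labels required")
        for label in labels:
            n = sum(1 for g in self.groups.values() if g == label)
            if n != 3:
                raise ValueError(f"group {label!r} has {n} channels, expected 3")
        for ch, conc in self.concentrations.items():
            if not (conc > 0):
                raise ValueError(f"channel {ch}: concentration must be > 0")

    def channels_of(self, group: str) -> list[str]:
        return [c for c in CHANNELS if self.groups[c] == group]

    @property
    def group_labels(self) -> tuple[str, str]:
        """(reference, treated): 'ss' is the reference when present."""
        labels = sorted(set(self.groups.values()))
        if "ss" in labels:
            other = next(l for l in labels if l != "ss")
            return "ss", other
        return labels[0], labels[1]


def validate_peptide_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ["protein_id", "peptide_id", *CHANNELS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    values = table[CHANNELS].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("peptide table contains non-finite intensities")
    if np.any(values < 0):
        raise ValueError("peptide table contains negative intensities")
    return table


def normalize_channels(table: pd.DataFrame, meta: SampleMeta) -> pd.DataFrame:
    """Equalize channel medians, then scale by input concentration.

    Each channel is scaled so its median nonzero intensity equals the median
    of the per-channel medians, then multiplied by that sample's measured
    protein concentration divided by the minimum concentration of the six
    samples, making intensities proportional to input protein amounts.  The
    result is a new DataFrame; the input is not modified.
    """
    validate_peptide_table(table)
    out = table.copy()
    medians = {}
    for ch in CHANNELS:
        v = out[ch].to_numpy(dtype=float)
        nz = v[v > 0]
        if len(nz) == 0:
            raise ValueError(f"channel {ch}: all intensities are zero")
        medians[ch] = float(np.median(nz))
    target = float(np.median(list(medians.values())))
    min_conc = min(meta.concentrations.values())
    for ch in CHANNELS:
        scale = (target / medians[ch]) * (meta.concentrations[ch] / min_conc)
        out[ch] = out[ch].to_numpy(dtype=float) * scale
    return out


def top3(table: pd.DataFrame) -> pd.DataFrame:
    """Interprotein abundance: mean of the three largest peptide intensities.

    Computed per protein and channel on nonzero intensities; with fewer than
    three detected peptides the mean of those available is used.  Proteins
    with no detection in a channel get NaN.
    """
    validate_peptide_table(table)

    def _top3_channel(values: np.ndarray) -> float:
        nz = values[values > 0]
        if len(nz) == 0:
            return math.nan
        return float(np.sort(nz)[-3:].mean())

    grouped = table.groupby("protein_id", sort=True)
    rows = {
        pid: [_top3_channel(sub[ch].to_numpy(dtype=float)) for ch in CHANNELS]
        for pid, sub in grouped
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=CHANNELS).rename_axis("protein_id")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up FDR adjustment; NaNs are passed through."""
    p = np.asarray(p_values, dtype=float)
    adjusted = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        adjusted[mask] = stats.false_discovery_control(p[mask], method="bh")
    return adjusted


@dataclass(frozen=True)
class ProteinQuant:
    """Full per-protein quantitation result."""

    abundances: pd.DataFrame  # index protein_id, columns CHANNELS
    stats: pd.DataFrame  # ratio, log10_ratio, p_sample, p_ratio, p_ratio_fdr, significant
    meta: SampleMeta
    alpha: float = 0.05


def _peptide_log_ratios(
    table: pd.DataFrame, treated_channels: Sequence[str], ref_channels: Sequence[str]
) -> pd.Series:
    """Per-peptide log10(mean treated / mean reference), zeros as missing."""
    def _nonzero_mean(block: np.ndarray) -> np.ndarray:
        detected = block > 0
        counts = detected.sum(axis=1)
        sums = np.where(detected, block, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    tr_mean = _nonzero_mean(table[list(treated_channels)].to_numpy(dtype=float))
    rf_mean = _nonzero_mean(table[list(ref_channels)].to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((tr_mean > 0) & (rf_mean > 0), tr_mean / rf_mean, np.nan)
        return pd.Series(np.log10(ratio), index=table.index)


def ratios_and_significance(
    table: pd.DataFrame,
    meta: SampleMeta,
    alpha: float = 0.05,
    normalized: bool = False,
) -> ProteinQuant:
    """Per-protein ratio and dual significance decision.

    ratio      mean Top3 abundance over treated channels / over reference
    p_sample   two-sided Welch t-test on log10 abundances, 3 vs 3 channels
    p_ratio    one-sample t-test of peptide-level log10 ratios against 0,
               BH-adjusted across proteins (``p_ratio_fdr``)
    A protein is significant iff p_sample < alpha and p_ratio_fdr < alpha.

    This replaces the original isobar noise model with plainly documented
    tests; the decision rule (both p-values below alpha) is kept as stated.
    """
    if not normalized:
        table = normalize_channels(table, meta)
    abundances = top3(table)
    ref_label, tr_label = meta.group_labels
    ref_ch = meta.channels_of(ref_label)
    tr_ch = meta.channels_of(tr_label)

    pep_log_ratios = _peptide_log_ratios(table, tr_ch, ref_ch)
    ratios_by_protein = {
        pid: series.dropna().to_numpy()
        for pid, series in pep_log_ratios.groupby(table["protein_id"])
    }

    records = []
    for pid, row in abundances.iterrows():
        ref_ab = row[ref_ch].to_numpy(dtype=float)
        tr_ab = row[tr_ch].to_numpy(dtype=float)
        ref_ab = ref_ab[np.isfinite(ref_ab) & (ref_ab > 0)]
        tr_ab = tr_ab[np.isfinite(tr_ab) & (tr_ab > 0)]
        if len(ref_ab) == 0 or len(tr_ab) == 0:
            ratio = math.nan
            p_sample = math.nan
        else:
            ratio = float(tr_ab.mean() / ref_ab.mean())
            if len(ref_ab) >= 2 and len(tr_ab) >= 2:
                log_tr, log_ref = np.log10(tr_ab), np.log10(ref_ab)
                if np.ptp(log_tr) == 0 and np.ptp(log_ref) == 0:
                    # degenerate noise-free groups: equal means are maximally
                    # unsurprising, unequal means maximally surprising
                    p_sample = 1.0 if log_tr[0] == log_ref[0] else 0.0
                else:
                    p_sample = welch_p(log_tr, log_ref)
            else:
                p_sample = math.nan
        lr = ratios_by_protein.get(pid, np.empty(0))
        if len(lr) >= 2 and np.ptp(lr) > 0:
            p_ratio = float(stats.ttest_1samp(lr, 0.0).pvalue)
        elif len(lr) >= 2:
            p_ratio = 1.0 if lr[0] == 0.0 else 0.0  # noise-free peptide ratios
        else:
            p_ratio = math.nan
        records.append(
            {
                "protein_id": pid,
                "ratio": ratio,
                "log10_ratio": math.log10(ratio) if ratio > 0 else math.nan,
                "p_sample": p_sample,
                "p_ratio": p_ratio,
            }
        )
    result = pd.DataFrame.from_records(records).set_index("protein_id")
    result["p_ratio_fdr"] = benjamini_hochberg(result["p_ratio"].to_numpy())
    result["significant"] = (result["p_sample"] < alpha) & (result["p_ratio_fdr"] < alpha)
    return ProteinQuant(abundances=abundances, stats=result, meta=meta, alpha=alpha)


def quant_from_abundance_matrix(
    abundances: pd.DataFrame, meta: SampleMeta, alpha: float = 0.05
) -> ProteinQuant:
    """Build a :class:`ProteinQuant` from per-protein channel abundances.

    For externally quantified tables (no peptide level available): ratios
    and the sample p-value are computed as usual, the peptide-level ratio
    p-value is reported as NaN and the dual significance flag therefore
    stays False.  Zero or missing abundances are treated as non-detections.
    """
    ab = abundances[CHANNELS].astype(float)
    ref_label, tr_label = meta.group_labels
    ref_ch, tr_ch = meta.channels_of(ref_label), meta.channels_of(tr_label)
    records = []
    for pid, row in ab.iterrows():
        ref_ab = row[ref_ch].to_numpy()
        tr_ab = row[tr_ch].to_numpy()
        ref_ab = ref_ab[np.isfinite(ref_ab) & (ref_ab > 0)]
        tr_ab = tr_ab[np.isfinite(tr_ab) & (tr_ab > 0)]
        if len(ref_ab) == 0 or len(tr_ab) == 0:
            ratio, p_sample = math.nan, math.nan
        else:
            ratio = float(tr_ab.mean() / ref_ab.mean())
            p_sample = (
                welch_p(np.log10(tr_ab), np.log10(ref_ab))
                if len(ref_ab) >= 2 and len(tr_ab) >= 2
                else math.nan
            )
        records.append(
            {
                "protein_id": pid,
                "ratio": ratio,
                "log10_ratio": math.log10(ratio) if ratio > 0 else math.nan,
                "p_sample": p_sample,
                "p_ratio": math.nan,
            }
        )
    result = pd.DataFrame.from_records(records).set_index("protein_id")
    result["p_ratio_fdr"] = benjamini_hochberg(result["p_ratio"].to_numpy())
    result["significant"] = (result["p_sample"] < alpha) & (result["p_ratio_fdr"] < alpha)
    return ProteinQuant(abundances=ab, stats=result, meta=meta, alpha=alpha)


def ratio_density(
    quant: ProteinQuant, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of per-protein log10 ratios plus the overall fold change.

    Returns ``(bin_edges, fractions, overall_fold_change)`` where the
    overall fold change is the summed treated-group abundance divided by the
    summed reference-group abundance over all quantified proteins.
    """
    ref_label, tr_label = quant.meta.group_labels
    ref_ch = quant.meta.channels_of(ref_label)
    tr_ch = quant.meta.channels_of(tr_label)
    log_ratios = quant.stats["log10_ratio"].dropna().to_numpy()
    if len(log_ratios) == 0:
        raise ValueError("no finite ratios to histogram")
    edges = np.histogram_bin_edges(log_ratios, bins=n_bins)
    counts, edges = np.histogram(log_ratios, bins=edges)
    fractions = counts / counts.sum()
    ref_total = float(np.nansum(quant.abundances[ref_ch].mean(axis=1)))
    tr_total = float(np.nansum(quant.abundances[tr_ch].mean(axis=1)))
    overall = tr_total / ref_total if ref_total > 0 else math.nan
    return edges, fractions, overall


def heatmap_matrix(quant: ProteinQuant) -> pd.DataFrame:
    """log10 of each sample's abundance over the protein's reference-group mean."""
    ref_label, _ = quant.meta.group_labels
    ref_ch = quant.meta.channels_of(ref_label)
    ab = quant.abundances
    ref_mean = ab[ref_ch].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.log10(ab.to_numpy(dtype=float) / ref_mean.to_numpy(dtype=float)[:, None])
    mat[~np.isfinite(mat)] = np.nan
    return pd.DataFrame(mat, index=ab.index, columns=ab.columns)


@dataclass(frozen=True)
class ClusterEnrichment:
    cluster: str
    n_members: int
    unmatched: tuple[str, ...]
    enrichment: dict[str, float]  # group label -> fold enrichment
    p_value: dict[str, float]  # group label -> Welch p, cluster vs all


def cluster_enrichment(
    quant: ProteinQuant, clusters: Mapping[str, set[str] | Sequence[str]]
) -> list[ClusterEnrichment]:
    """Mean cluster abundance over mean abundance of all quantified proteins.

    Computed separately per group; the comparison statistic is a Welch
    t-test of cluster-member abundances against all quantified proteins.
    A cluster with no quantified member raises, naming the cluster.
    """
    ref_label, tr_label = quant.meta.group_labels
    per_group = {
        label: quant.abundances[quant.meta.channels_of(label)].mean(axis=1)
        for label in (ref_label, tr_label)
    }
    results = []
    for name, members in clusters.items():
        members = set(members)
        if not members:
            raise ValueError(f"cluster {name!r} is empty")
        matched = members & set(quant.abundances.index)
        if not matched:
            raise ValueError(f"cluster {name!r} has no quantified member proteins")
        unmatched = tuple(sorted(members - matched))
        enrichment = {}
        p_value = {}
        for label, ab in per_group.items():
            all_vals = ab.dropna()
            member_vals = ab.loc[sorted(matched)].dropna()
            enrichment[label] = float(member_vals.mean() / all_vals.mean())
            if len(member_vals) >= 2 and len(all_vals) >= 2:
                p = welch_p(member_vals.to_numpy(), all_vals.to_numpy())
            else:
                p = math.nan
            p_value[label] = p
        results.append(
            ClusterEnrichment(
                cluster=name,
                n_members=len(matched),
                unmatched=unmatched,
                enrichment=enrichment,
                p_value=p_value,
            )
        )
    return results
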
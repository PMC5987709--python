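"""Reporter quantitation: normalization, Top3, significance, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from perihalo.proteomics import (
    CHANNELS,
    ProteinQuant,
    SampleMeta,
    benjamini_hochberg,
    cluster_enrichment,
    heatmap_matrix,
    normalize_channels,
    ratio_density,
    ratios_and_significance,
    top3,
)
from perihalo.synthetic import SpikeDesign, simulate_peptide_table


def unit_meta(concentrations=None):
    return SampleMeta(
        groups={"c1": "ss", "c2": "ss", "c3": "ss", "c4": "TNFa", "c5": "TNFa", "c6": "TNFa"},
        concentrations=concentrations or {c: 1.0 for c in CHANNELS},
    )


def table_from_rows(rows):
    return pd.DataFrame(rows, columns=["protein_id", "peptide_id", *CHANNELS])


def peptide_row(pid, pep, values):
    return {"protein_id": pid, "peptide_id": pep, **dict(zip(CHANNELS, values))}


# ---------------------------------------------------------------------------
# normalization


def test_normalize_equalizes_medians():
    rng = np.random.default_rng(5)
    rows = []
    scales = [10, 20, 40, 5, 80, 1]
    for i in range(101):
        base = rng.lognormal(3, 1)
        rows.append(peptide_row(f"P{i}", f"p{i}", [base * s for s in scales]))
    out = normalize_channels(table_from_rows(rows), unit_meta())
    medians = [np.median(out[c][out[c] > 0]) for c in CHANNELS]
    assert np.allclose(medians, medians[0])


def test_concentration_scaling_applied_after_median_step():
    rows = [peptide_row(f"P{i}", f"p{i}", [float(i + 1)] * 6) for i in range(7)]
    conc = {"c1": 1.0, "c2": 1.0, "c3": 1.0, "c4": 2.0, "c5": 1.0, "c6": 1.0}
    out = normalize_channels(table_from_rows(rows), unit_meta(conc))
    # equal medians already, so the median step is identity; channel c4 is
    # multiplied by conc/min_conc = 2 exactly
    assert np.allclose(out["c4"], 2.0 * np.asarray([float(i + 1) for i in range(7)]))
    assert np.allclose(out["c1"], [float(i + 1) for i in range(7)])


def test_normalize_idempotent_with_equal_concentrations():
    rng = np.random.default_rng(6)
    rows = [
        peptide_row(f"P{i}", f"p{i}", rng.lognormal(3, 1, 6) * [1, 2, 3, 4, 5, 6])
        for i in range(51)
    ]
    meta = unit_meta()
    once = normalize_channels(table_from_rows(rows), meta)
    twice = normalize_channels(once, meta)
    assert np.allclose(once[CHANNELS].to_numpy(), twice[CHANNELS].to_numpy(), atol=1e-12)


def test_normalize_idempotent_up_to_global_scale_with_unequal_concentrations():
    # with concentration scaling the repeat application differs only by one
    # global scalar, so all downstream ratios are unchanged
    rng = np.random.default_rng(7)
    rows = [peptide_row(f"P{i}", f"p{i}", rng.lognormal(3, 1, 6)) for i in range(51)]
    meta = unit_meta({"c1": 1.0, "c2": 1.5, "c3": 2.0, "c4": 1.0, "c5": 3.0, "c6": 1.0})
    once = normalize_channels(table_from_rows(rows), meta)
    twice = normalize_channels(once, meta)
    ratio = twice[CHANNELS].to_numpy() / once[CHANNELS].to_numpy()
    assert np.allclose(ratio, ratio.flat[0])


def test_all_zero_channel_rejected():
    rows = [peptide_row("P1", "p1", [1, 2, 3, 0, 5, 6])]
    with pytest.raises(ValueError, match="c4"):
        normalize_channels(table_from_rows(rows), unit_meta())


# ---------------------------------------------------------------------------
# Top3


def test_top3_five_peptides():
    rows = [peptide_row("P1", f"p{i}", [v] * 6) for i, v in enumerate([1, 2, 3, 4, 5])]
    ab = top3(table_from_rows(rows))
    assert np.allclose(ab.loc["P1"], 4.0)


def test_top3_three_peptides():
    rows = [peptide_row("P1", f"p{i}", [v] * 6) for i, v in enumerate([10, 20, 30])]
    assert np.allclose(top3(table_from_rows(rows)).loc["P1"], 20.0)


def test_top3_single_peptide():
    rows = [peptide_row("P1", "p0", [7] * 6)]
    assert np.allclose(top3(table_from_rows(rows)).loc["P1"], 7.0)


def test_top3_zeros_are_missing():
    rows = [peptide_row("P1", f"p{i}", [v] * 6) for i, v in enumerate([0, 0, 5])]
    assert np.allclose(top3(table_from_rows(rows)).loc["P1"], 5.0)


def test_top3_permutation_invariant_and_monotone(rng):
    values = rng.lognormal(2, 1, (6, 6))
    rows = [peptide_row("P1", f"p{i}", values[i]) for i in range(6)]
    base = top3(table_from_rows(rows)).loc["P1"].to_numpy()
    perm = rng.permutation(6)
    shuffled = [peptide_row("P1", f"p{i}", values[j]) for i, j in enumerate(perm)]
    assert np.allclose(top3(table_from_rows(shuffled)).loc["P1"].to_numpy(), base)
    bumped_values = values.copy()
    bumped_values[3, 0] *= 10
    bumped = [peptide_row("P1", f"p{i}", bumped_values[i]) for i in range(6)]
    assert top3(table_from_rows(bumped)).loc["P1", "c1"] >= base[0]


# ---------------------------------------------------------------------------
# significance machinery


def test_benjamini_hochberg_hand_example():
    adjusted = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adjusted, 0.04)


def test_noise_free_null_zero_significant():
    table, meta, _ = simulate_peptide_table(
        SpikeDesign(n_proteins=40, n_peptides_per_protein=4, peptide_cv=0.0, seed=1)
    )
    quant = ratios_and_significance(table, meta)
    assert int(quant.stats["significant"].sum()) == 0
    assert np.allclose(quant.stats["ratio"], 1.0)


def test_spiked_protein_flagged_significant():
    fc = np.zeros(30)
    fc[0] = 2.0  # 4-fold
    table, meta, _ = simulate_peptide_table(
        SpikeDesign(
            n_proteins=30, n_peptides_per_protein=6, log2_fold_changes=fc,
            peptide_cv=0.1, seed=11,
        )
    )
    quant = ratios_and_significance(table, meta)
    assert bool(quant.stats.loc["P00000", "significant"])
    assert quant.stats.loc["P00000", "ratio"] == pytest.approx(4.0, rel=0.25)


def test_protein_missing_in_one_group_gives_missing_ratio():
    rows = [peptide_row("P1", "p0", [1, 1, 1, 2, 2, 2]),
            peptide_row("P2", "p0", [0, 0, 0, 2, 2, 2])]
    quant = ratios_and_significance(table_from_rows(rows), unit_meta(), normalized=True)
    assert math.isnan(quant.stats.loc["P2", "ratio"])
    assert not bool(quant.stats.loc["P2", "significant"])


# ---------------------------------------------------------------------------
# ratio density / heat map


def quant_from_abundances(values: dict[str, list[float]]) -> ProteinQuant:
    ab = pd.DataFrame.from_dict(values, orient="index", columns=CHANNELS).rename_axis(
        "protein_id"
    )
    meta = unit_meta()
    ref, tr = meta.group_labels
    rows = []
    for pid, row in ab.iterrows():
        ref_mean = row[meta.channels_of(ref)].mean()
        ratio = row[meta.channels_of(tr)].mean() / ref_mean if ref_mean > 0 else math.nan
        rows.append({"protein_id": pid, "ratio": ratio,
                     "log10_ratio": math.log10(ratio) if ratio > 0 else math.nan,
                     "p_sample": math.nan,
                     "p_ratio": math.nan, "p_ratio_fdr": math.nan, "significant": False})
    stats = pd.DataFrame(rows).set_index("protein_id")
    return ProteinQuant(abundances=ab, stats=stats, meta=meta)


def test_ratio_density_all_ratios_two():
    quant = quant_from_abundances(
        {f"P{i}": [1, 1, 1, 2, 2, 2] for i in range(10)}
    )
    edges, fractions, overall = ratio_density(quant, n_bins=5)
    assert overall == pytest.approx(2.0)
    peak_bin = np.argmax(fractions)
    assert fractions[peak_bin] == pytest.approx(1.0)
    assert edges[peak_bin] <= math.log10(2.0) <= edges[peak_bin + 1]


def test_ratio_density_self_comparison_unity():
    quant = quant_from_abundances({f"P{i}": [float(i + 1)] * 6 for i in range(8)})
    _, _, overall = ratio_density(quant)
    assert overall == pytest.approx(1.0)


def test_ratio_density_symmetric_spikes_near_unity():
    quant = quant_from_abundances(
        {"up": [10, 10, 10, 20, 20, 20], "down": [20, 20, 20, 10, 10, 10]}
    )
    _, _, overall = ratio_density(quant)
    assert overall == pytest.approx(1.0)


def test_heatmap_reference_columns():
    quant = quant_from_abundances({"P1": [5, 5, 5, 50, 50, 50]})
    heat = heatmap_matrix(quant)
    assert np.allclose(heat.loc["P1", ["c1", "c2", "c3"]], 0.0)
    assert np.allclose(heat.loc["P1", ["c4", "c5", "c6"]], 1.0)


def test_heatmap_zero_reference_mean_missing():
    quant = quant_from_abundances({"P1": [0, 0, 0, 1, 1, 1]})
    heat = heatmap_matrix(quant)
    assert heat.loc["P1"].isna().all()


# ---------------------------------------------------------------------------
# cluster enrichment


def test_cluster_of_all_proteins_enrichment_one():
    quant = quant_from_abundances({f"P{i}": [float(i + 1)] * 6 for i in range(6)})
    (res,) = cluster_enrichment(quant, {"all": {f"P{i}" for i in range(6)}})
    assert res.enrichment["ss"] == pytest.approx(1.0)
    assert res.enrichment["TNFa"] == pytest.approx(1.0)


def test_cluster_hand_example():
    quant = quant_from_abundances({"A": [1] * 6, "B": [3] * 6, "C": [8] * 6})
    (res,) = cluster_enrichment(quant, {"c": {"C"}})
    assert res.enrichment["ss"] == pytest.approx(8.0 / 4.0)


def test_cluster_enrichment_scale_invariant():
    base = {"A": [1] * 6, "B": [3] * 6, "C": [8] * 6}
    scaled = {k: [100.0 * v for v in row] for k, row in base.items()}
    (r1,) = cluster_enrichment(quant_from_abundances(base), {"c": {"C"}})
    (r2,) = cluster_enrichment(quant_from_abundances(scaled), {"c": {"C"}})
    assert r1.enrichment["ss"] == pytest.approx(r2.enrichment["ss"], abs=1e-12)


def test_cluster_without_members_errors():
    quant = quant_from_abundances({"A": [1] * 6})
    with pytest.raises(ValueError, match="ghost"):
        cluster_enrichment(quant, {"ghost": {"ZZZ"}})
    with pytest.raises(ValueError, match="empty"):
        cluster_enrichment(quant, {"empty": set()})


def test_unmatched_ids_reported():
    quant = quant_from_abundances({"A": [1] * 6, "B": [2] * 6})
    (res,) = cluster_enrichment(quant, {"c": {"A", "MISSING"}})
    assert res.unmatched == ("MISSING",)
    assert res.n_members == 1


# ---------------------------------------------------------------------------
# end-to-end recovery


def test_pipeline_recovers_spiked_fold_changes():
    rng = np.random.default_rng(42)
    fc = np.zeros(1000)
    spiked = rng.choice(1000, 160, replace=False)
    fc[spiked[:80]] = rng.uniform(0.6, 2.5, 80)
    fc[spiked[80:]] = -rng.uniform(0.6, 2.5, 80)
    table, meta, truth = simulate_peptide_table(
        SpikeDesign(
            n_proteins=1000, n_peptides_per_protein=(3, 8),
            log2_fold_changes=fc, peptide_cv=0.2, seed=99,
        )
    )
    quant = ratios_and_significance(table, meta)
    est_log2 = np.log2(quant.stats["ratio"].reindex(truth.index))
    err = est_log2.to_numpy() - truth.to_numpy()
    assert np.abs(np.mean(err)) < 0.05
    assert np.mean(np.abs(err)) < 0.15


def test_type_one_error_calibrated():
    table, meta, _ = simulate_peptide_table(
        SpikeDesign(
            n_proteins=1000, n_peptides_per_protein=5, log2_fold_changes=0.0,
            peptide_cv=0.2, seed=7,
        )
    )
    quant = ratios_and_significance(table, meta)
    raw_rate = float((quant.stats["p_ratio"] < 0.05).mean())
    assert raw_rate == pytest.approx(0.05, abs=0.025)
    assert int(quant.stats["significant"].sum()) <= 5


def test_noise_free_exact_fixed_point():
    # single 2-fold spike on the largest protein: channel medians stay put,
    # so the whole pipeline returns the design fold changes exactly
    fc = np.zeros(9)
    fc[8] = 1.0
    table, meta, truth = simulate_peptide_table(
        SpikeDesign(n_proteins=9, n_peptides_per_protein=5,
                    log2_fold_changes=fc, peptide_cv=0.0, seed=3)
    )
    quant = ratios_and_significance(table, meta)
    expected = 2.0 ** truth.to_numpy()
    assert np.allclose(quant.stats["ratio"].reindex(truth.index).to_numpy(), expected,
                       rtol=1e-12)


# ---------------------------------------------------------------------------
# metadata validation


def test_meta_requires_three_per_group():
    with pytest.raises(ValueError, match="expected 3"):
        SampleMeta(
            groups={"c1": "ss", "c2": "ss", "c3": "ss", "c4": "ss", "c5": "TNFa", "c6": "TNFa"},
            concentrations={c: 1.0 for c in CHANNELS},
        )


def test_meta_requires_positive_concentrations():
    with pytest.raises(ValueError, match="concentration"):
        unit_meta({**{c: 1.0 for c in CHANNELS}, "c2": 0.0})
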
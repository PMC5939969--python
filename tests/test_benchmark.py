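"""Benchmark layer: metric oracles, outlier rule, grid runs, fraction summaries."""

import math

import numpy as np
import pytest

from ampholyte import (
    DatasetRecord,
    MethodSpec,
    ModifiedSequence,
    PeptideSimConfig,
    ValidationError,
    default_grid,
    flag_outliers,
    pearson_r,
    pearson_r2,
    per_fraction_summary,
    predict_dataset,
    reports_table,
    rmsd,
    run_grid,
    simulate_peptides,
    sort_reports,
)


# ------------------------------------------------------------------ metrics


def test_perfect_and_shifted_correlation():
    e = [4.0, 6.0, 8.0, 5.0]
    assert pearson_r2(e, e) == pytest.approx(1.0, abs=1e-12)
    shifted = [x + 1 for x in e]
    assert pearson_r2(e, shifted) == pytest.approx(1.0, abs=1e-12)
    assert rmsd(e, shifted) == pytest.approx(1.0, abs=1e-12)


def test_pearson_hand_computed_value():
    e = np.array([4.0, 6.0, 8.0])
    p = np.array([4.0, 6.0, 7.0])
    # independent hand computation of the product-moment correlation
    ce, cp = e - e.mean(), p - p.mean()
    expected_r = float(np.sum(ce * cp) / np.sqrt(np.sum(ce**2) * np.sum(cp**2)))
    assert pearson_r(e, p) == pytest.approx(expected_r, abs=1e-12)
    assert pearson_r2(e, p) == pytest.approx(expected_r**2, abs=1e-12)


def test_pearson_rejects_constant_vectors():
    with pytest.raises(ValidationError):
        pearson_r2([4.0, 4.0, 4.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValidationError):
        pearson_r2([1.0, 2.0], [1.0, 2.0])  # too short


def test_rmsd_hand_cases():
    assert rmsd([4.0, 6.0], [4.0, 6.0]) == 0.0
    assert rmsd([4.0, 5.0, 6.0], [5.0, 6.0, 7.0]) == pytest.approx(1.0, abs=1e-12)
    assert rmsd([4.0, 6.0], [4.0, 8.0]) == pytest.approx(math.sqrt(2.0), abs=1e-12)
    with pytest.raises(ValidationError):
        rmsd([1.0, 2.0], [1.0])


def test_outlier_rule_hand_case():
    # predicted (4,6,8): sample SD = 2; residuals (1,1,3) -> only the last flags
    experimental = [5.0, 7.0, 11.0]
    predicted = [4.0, 6.0, 8.0]
    assert list(flag_outliers(experimental, predicted)) == [False, False, True]


def test_outlier_rule_zero_residuals_and_sd_zero():
    assert not flag_outliers([4.0, 6.0, 8.0], [4.0, 6.0, 8.0]).any()
    # constant predictions: SD=0, only strictly positive residuals flag
    flags = flag_outliers([5.0, 5.0, 6.0], [5.0, 5.0, 5.0])
    assert list(flags) == [False, False, True]
    with pytest.raises(ValidationError):
        flag_outliers([5.0], [5.0])


# ---------------------------------------------------------------- grid runs


def test_default_grid_has_sixteen_combinations():
    grid = default_grid(include_svm=True)
    assert len(grid) == 16
    labels = {g.label for g in grid}
    assert {
        "SVM", "ITERATIVE_GRIMSLEY", "BJELL_DEFAULT", "ITERATIVE_RODWELL",
        "BJELL_CALIBRATED", "BJELL_EXPASY", "ITERATIVE_THURLKILL", "COFACTOR",
        "ITERATIVE_SILLERO", "ITERATIVE_TOSELAND", "ITERATIVE_EMBOSS",
        "BRANCA", "BJELL_SKOOG", "ITERATIVE_SOLOMON", "ITERATIVE_LEHNINGER",
        "ITERATIVE_PATRICKIOS",
    } == labels


@pytest.fixture(scope="module")
def noise_free_dataset():
    cfg = PeptideSimConfig(n=120, noise_sd=0.0, seed=9)
    return simulate_peptides(cfg)


def test_self_benchmark_is_perfect(noise_free_dataset):
    reports = run_grid(noise_free_dataset, [MethodSpec("bjellqvist", "expasy")])
    rep = reports[0]
    assert rep.n == len(noise_free_dataset) and rep.n_failed == 0
    assert rep.r2 == pytest.approx(1.0, abs=1e-12)
    assert rep.rmsd == pytest.approx(0.0, abs=1e-12)
    assert not rep.residuals["outlier"].any()


def test_metric_cross_check_from_residuals(noise_free_dataset):
    cfg = PeptideSimConfig(n=120, noise_sd=0.3, seed=10)
    ds = simulate_peptides(cfg)
    for rep in run_grid(ds, [MethodSpec("iterative", "emboss")]):
        ok = rep.residuals.dropna(subset=["predicted"])
        assert rep.rmsd == pytest.approx(
            float(np.sqrt(np.mean(ok["residual"] ** 2))), abs=1e-12
        )
        assert rep.r2 == pytest.approx(
            pearson_r2(ok["experimental"], ok["predicted"]), abs=1e-12
        )


def test_branca_failures_counted_not_crashed(emboss):
    records = [
        DatasetRecord(f"g{i}", ModifiedSequence("MDEGGHG"), 5.0 + 0.1 * i)
        for i in range(5)
    ]
    reports = run_grid(records, [MethodSpec("branca", "bjellqvist")])
    rep = reports[0]
    assert rep.n == 0 and rep.n_failed == 5
    assert math.isnan(rep.rmsd)
    assert set(rep.residuals["failure"]) == {"not_applicable"}


def test_run_grid_deterministic(noise_free_dataset):
    grid = [MethodSpec("iterative", "emboss"), MethodSpec("bjellqvist", "default")]
    t1 = reports_table(run_grid(noise_free_dataset, grid))
    t2 = reports_table(run_grid(noise_free_dataset, grid))
    assert t1.equals(t2)


def test_run_grid_empty_dataset_rejected():
    with pytest.raises(ValidationError):
        run_grid([], [MethodSpec("iterative", "emboss")])


def test_sort_reports_orders_leaderboard(noise_free_dataset):
    reports = run_grid(
        noise_free_dataset,
        [MethodSpec("iterative", "patrickios"), MethodSpec("bjellqvist", "expasy")],
    )
    ordered = sort_reports(reports)
    assert ordered[0].label == "BJELL_EXPASY"
    assert ordered[0].rmsd <= ordered[1].rmsd


# ----------------------------------------------------------- per fraction


def test_per_fraction_partition_and_ordering(noise_free_dataset):
    spec = MethodSpec("bjellqvist", "expasy")
    preds = predict_dataset(noise_free_dataset, spec)
    table = per_fraction_summary(noise_free_dataset, preds)
    assert table["n"].sum() == len(noise_free_dataset)
    mids = table["experimental_midpoint"].to_numpy()
    assert np.all(np.diff(mids) > 0)


def test_per_fraction_single_record_annotated():
    records = [
        DatasetRecord("a", ModifiedSequence("KDEK"), 4.2, fraction="F01"),
        DatasetRecord("b", ModifiedSequence("KHEK"), 6.8, fraction="F02"),
        DatasetRecord("c", ModifiedSequence("KHGK"), 7.1, fraction="F02"),
    ]
    preds = predict_dataset(records, MethodSpec("iterative", "emboss"))
    table = per_fraction_summary(records, preds).set_index("fraction")
    assert table.loc["F01", "n"] == 1
    assert table.loc["F01", "sd_predicted"] == 0.0
    assert "single record" in table.loc["F01", "note"]
    assert table.loc["F02", "sd_predicted"] > 0
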
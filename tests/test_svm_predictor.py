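"""SVR pI pipeline: featurization, training contracts, recovery, portability."""

import numpy as np
import pytest
from scipy import stats

from ampholyte import (
    DataSizeError,
    FeatureSpec,
    MethodSpec,
    ModifiedSequence,
    PeptideSimConfig,
    ValidationError,
    diprotic_midpoint,
    featurize,
    get_set,
    load_model,
    load_property_scales,
    predict,
    save_model,
    simulate_peptides,
    solve_pi,
    train,
)


@pytest.fixture(scope="module")
def scales():
    return load_property_scales()


@pytest.fixture(scope="module")
def train_600():
    recs = simulate_peptides(PeptideSimConfig(n=600, noise_sd=0.2, seed=101))
    return [(r.sequence, r.experimental_pi) for r in recs]


@pytest.fixture(scope="module")
def model_600(train_600):
    return train(train_600, seed=5)


def test_feature_vector_length_matches_spec(scales):
    spec = FeatureSpec()
    vec = featurize("ACDEFGHIK", spec, scales)
    assert vec.shape == (spec.length,)
    assert spec.length == 20 + 1 + 1 + 2 + 2
    assert len(spec.feature_names()) == spec.length


def test_composition_of_homopolymer(scales):
    spec = FeatureSpec()
    vec = featurize("AAAA", spec, scales)
    names = spec.feature_names()
    comp = {n: v for n, v in zip(names, vec) if n.startswith("comp_")}
    assert comp["comp_A"] == 1.0
    assert sum(v for n, v in comp.items() if n != "comp_A") == 0.0


def test_degenerate_codes_renormalize_composition(scales):
    spec = FeatureSpec()
    vec = featurize("AAXX", spec, scales)
    comp = dict(zip(spec.feature_names(), vec))
    assert comp["comp_A"] == 1.0  # X contributes zero; denominator shrinks


def test_seed_pi_feature_equals_solver(scales):
    spec = FeatureSpec(seed_pka_set="emboss")
    vec = featurize("GGGG", spec, scales)
    idx = spec.feature_names().index("seed_pi_emboss")
    s = get_set("emboss")
    assert vec[idx] == pytest.approx(diprotic_midpoint(s.c_term, s.n_term), abs=1e-3)
    assert vec[idx] == solve_pi("GGGG", s)


def test_mean_property_aggregation(scales):
    spec = FeatureSpec()
    vec = featurize("AK", spec, scales)
    idx = spec.feature_names().index("mean_kd_hydropathy")
    kd = scales["kd_hydropathy"]
    assert vec[idx] == pytest.approx((kd["A"] + kd["K"]) / 2)


def test_ptm_count_features(scales):
    spec = FeatureSpec()
    mseq = ModifiedSequence("GSGTK", frozenset({2, 4}), n_term_acetylated=True)
    vec = dict(zip(spec.feature_names(), featurize(mseq, spec, scales)))
    assert vec["n_phospho"] == 2.0
    assert vec["n_term_acetyl"] == 1.0


def test_empty_sequence_rejected(scales):
    with pytest.raises(Exception):
        featurize("", FeatureSpec(), scales)


def test_training_size_contract(train_600):
    with pytest.raises(DataSizeError):
        train(train_600[:10])


def test_training_rejects_bad_targets(train_600):
    bad = [(s, float("nan")) for s, _ in train_600[:60]]
    with pytest.raises(ValidationError):
        train(bad)


def test_training_is_deterministic(train_600, model_600):
    again = train(train_600, seed=5)
    seqs = [s for s, _ in train_600[:40]]
    assert np.array_equal(model_600.predict_values(seqs), again.predict_values(seqs))


def test_predictions_interpolate_training_data(model_600, train_600):
    """On low-noise synthetic data the fit tracks its labels closely."""
    seqs = [s for s, _ in train_600]
    y = np.array([t for _, t in train_600])
    pred = model_600.predict_values(seqs)
    rmsd = float(np.sqrt(np.mean((pred - y) ** 2)))
    assert rmsd <= 0.35  # labels carry noise SD 0.2
    assert np.all((pred > 0) & (pred < 14))


def test_metadata_records_the_split(model_600):
    meta = model_600.training_metadata
    assert meta["n_sequences"] == 600
    assert meta["n_validation"] == 120
    assert meta["holdout_rmsd"] > 0


def test_seed_only_model_tracks_seed_method(train_600):
    """With only the seed-pI feature, predictions rank like the seed method."""
    spec = FeatureSpec(
        use_composition=False, use_length=False, use_seed_pi=True,
        seed_pka_set="emboss", property_tables=(), include_ptm_counts=False,
    )
    model = train(train_600, spec, seed=2)
    seqs = [s for s, _ in train_600[:150]]
    emboss = get_set("emboss")
    seed_pis = [solve_pi(s, emboss) for s in seqs]
    pred = model.predict_values(seqs)
    rho = stats.spearmanr(seed_pis, pred).statistic
    assert rho >= 0.95


def test_serialization_roundtrip_bit_exact(tmp_path, model_600, train_600):
    path = tmp_path / "model.joblib"
    save_model(model_600, path)
    again = load_model(path)
    seqs = [s for s, _ in train_600[:60]]
    assert np.array_equal(model_600.predict_values(seqs), again.predict_values(seqs))


def test_version_mismatch_refused(tmp_path, model_600):
    import joblib

    path = tmp_path / "model.joblib"
    save_model(model_600, path)
    raw = joblib.load(path)
    raw["format_version"] = 999
    joblib.dump(raw, path)
    from ampholyte import FeatureSpecError

    with pytest.raises(FeatureSpecError):
        load_model(path)


def test_predict_empty_and_order(model_600, train_600):
    assert predict(model_600, []) == []
    pairs = [(f"s{i}", s) for i, (s, _) in enumerate(train_600[:5])]
    out = predict(model_600, pairs)
    assert [r.id for r in out] == [p[0] for p in pairs]
    assert all(r.method == "svm" and r.ok for r in out)


def test_retrainability_adapts_to_generator():
    """Models trained on different generating methods each fit their own best."""
    cfg_a = PeptideSimConfig(
        n=300, noise_sd=0.05, seed=31,
        generating_method=MethodSpec("iterative", "emboss"),
    )
    cfg_b = PeptideSimConfig(
        n=300, noise_sd=0.05, seed=32,
        generating_method=MethodSpec("iterative", "patrickios"),
    )
    data_a = [(r.sequence, r.experimental_pi) for r in simulate_peptides(cfg_a)]
    data_b = [(r.sequence, r.experimental_pi) for r in simulate_peptides(cfg_b)]
    model_a = train(data_a, seed=1)
    model_b = train(data_b, seed=1)

    def rmsd_on(model, data):
        p = model.predict_values([s for s, _ in data])
        y = np.array([t for _, t in data])
        return float(np.sqrt(np.mean((p - y) ** 2)))

    test_a = data_a[200:]
    test_b = data_b[200:]
    assert rmsd_on(model_a, test_a) < rmsd_on(model_b, test_a)
    assert rmsd_on(model_b, test_b) < rmsd_on(model_a, test_b)
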
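"""Retrainable support-vector-regression pI predictor.

Learning-based pI prediction trades the fixed physics of a pKa basis for the
ability to absorb the quirks of a particular analytical setting — at the
price of needing a large, good training set.  This module is the retrainable
*pipeline*: sequence-derived features (residue composition, length, a
physics-based seed pI, mean per-residue property scales, modification
counts) feeding an epsilon-insensitive kernel regression
(scikit-learn ``SVR``), with a seeded 80/20 train/validation split and a
small grid search for hyperparameters.  Models serialize with their feature
specification and training metadata and refuse to load across feature-format
versions.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import yaml
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import DataSizeError, FeatureSpecError, ValidationError
from .modifications import STANDARD_RESIDUES, ModifiedSequence, coerce_sequence
from .records import PredictionRecord
from .registry import get_set
from .solvers import DEFAULT_CONFIG, solve_pi

#: bump when the feature layout changes; serialized models carry this
FEATURE_FORMAT_VERSION = 1

_COMPOSITION_ORDER = tuple(sorted(STANDARD_RESIDUES))  # fixed, versioned order
_PI_CLIP = (0.01, 13.99)


def load_property_scales() -> dict[str, dict[str, float]]:
    """Bundled per-residue property scales (AAindex-style), name → residue → value."""
    text = (resources.files("ampholyte.data") / "property_scales.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, entry in raw.items():
        values = {str(k).upper(): float(v) for k, v in entry["values"].items()}
        missing = STANDARD_RESIDUES - set(values)
        if missing:
            raise ValidationError(
                f"property scale {name!r} missing residues {sorted(missing)}"
            )
        out[name] = values
    return out


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to compute, in a fixed, versioned order.

    Order: composition (20, alphabetical), length, seed pI, one mean per
    property table (in listed order), then modification counts
    (n phosphosites, acetylation flag).
    """

    use_composition: bool = True
    use_length: bool = True
    use_seed_pi: bool = True
    seed_pka_set: str = "bjellqvist"
    property_tables: tuple[str, ...] = ("kd_hydropathy", "residue_mass")
    include_ptm_counts: bool = True
    version: int = FEATURE_FORMAT_VERSION

    @property
    def length(self) -> int:
        return (
            20 * self.use_composition
            + int(self.use_length)
            + int(self.use_seed_pi)
            + len(self.property_tables)
            + 2 * self.include_ptm_counts
        )

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.use_composition:
            names += [f"comp_{aa}" for aa in _COMPOSITION_ORDER]
        if self.use_length:
            names.append("length")
        if self.use_seed_pi:
            names.append(f"seed_pi_{self.seed_pka_set}")
        names += [f"mean_{t}" for t in self.property_tables]
        if self.include_ptm_counts:
            names += ["n_phospho", "n_term_acetyl"]
        return names

    def to_mapping(self) -> dict:
        d = asdict(self)
        d["property_tables"] = list(self.property_tables)
        return d

    @staticmethod
    def from_mapping(d: Mapping) -> "FeatureSpec":
        return FeatureSpec(
            use_composition=bool(d["use_composition"]),
            use_length=bool(d["use_length"]),
            use_seed_pi=bool(d["use_seed_pi"]),
            seed_pka_set=str(d["seed_pka_set"]),
            property_tables=tuple(d["property_tables"]),
            include_ptm_counts=bool(d["include_ptm_counts"]),
            version=int(d["version"]),
        )


def featurize(
    seq: "str | ModifiedSequence",
    spec: FeatureSpec = FeatureSpec(),
    scales: Mapping[str, Mapping[str, float]] | None = None,
) -> np.ndarray:
    """Deterministic feature vector for one sequence.

    Composition is normalized over standard residues only (degenerate codes
    contribute zero and the denominator shrinks accordingly).  A sequence for
    which the seed method has no pI falls back to neutral 7.0 for that
    feature (rare: requires single-polarity group lists).
    """
    mseq = coerce_sequence(seq)
    res = mseq.residues
    if not res:
        raise ValidationError("cannot featurize an empty sequence")
    if scales is None:
        scales = load_property_scales()
    feats: list[float] = []
    standard = [aa for aa in res if aa in STANDARD_RESIDUES]
    n_std = max(len(standard), 1)
    if spec.use_composition:
        counts = {aa: 0 for aa in _COMPOSITION_ORDER}
        for aa in standard:
            counts[aa] += 1
        feats += [counts[aa] / n_std for aa in _COMPOSITION_ORDER]
    if spec.use_length:
        feats.append(float(len(res)))
    if spec.use_seed_pi:
        try:
            feats.append(solve_pi(mseq, get_set(spec.seed_pka_set), DEFAULT_CONFIG))
        except Exception:
            feats.append(7.0)
    for table in spec.property_tables:
        if table not in scales:
            raise FeatureSpecError(f"property table {table!r} not available")
        tab = scales[table]
        vals = [tab[aa] for aa in standard]
        feats.append(float(np.mean(vals)) if vals else 0.0)
    if spec.include_ptm_counts:
        feats.append(float(len(mseq.phospho_sites)))
        feats.append(float(mseq.n_term_acetylated))
    vec = np.asarray(feats, dtype=float)
    assert vec.shape == (spec.length,)
    return vec


@dataclass
class TrainedModel:
    """A fitted SVR pipeline plus everything needed to reuse it honestly."""

    feature_spec: FeatureSpec
    kernel: str
    hyperparameters: dict
    pipeline: Pipeline
    training_metadata: dict = field(default_factory=dict)

    def predict_values(self, seqs: Sequence["str | ModifiedSequence"]) -> np.ndarray:
        if len(seqs) == 0:
            return np.empty(0, dtype=float)
        scales = load_property_scales()
        X = np.vstack([featurize(s, self.feature_spec, scales) for s in seqs])
        return np.clip(self.pipeline.predict(X), *_PI_CLIP)


# The pI response is close to linear in the standardized features (the seed
# pI dominates), so the grid reaches down to very small RBF bandwidths.
_DEFAULT_GRID = tuple(
    {"C": c, "epsilon": eps, "gamma": gamma}
    for gamma in (0.002, 0.01, "scale")
    for c in (1.0, 10.0, 100.0)
    for eps in (0.01, 0.1)
)


def train(
    dataset: Sequence[tuple["str | ModifiedSequence", float]],
    spec: FeatureSpec = FeatureSpec(),
    hyperparameter_grid: Iterable[Mapping] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit an RBF SVR on (sequence, experimental pI) pairs.

    Requires at least 50 records — learning-based pI predictors are only as
    good as their training data, and tiny sets produce misleading models.
    Deterministic given (dataset order, seed): the 80/20 train/validation
    split is drawn from ``seed`` and the grid is scanned in a fixed order.
    The held-out RMSD stored in the metadata is computed on the 20% split.
    """
    records = list(dataset)
    if len(records) < 50:
        raise DataSizeError(
            f"training needs >= 50 records, got {len(records)}; learning-based "
            "pI prediction is unreliable on small datasets"
        )
    y = np.array([float(t) for _, t in records])
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite training targets")
    if np.any((y <= 0) | (y >= 14)):
        raise ValidationError("training targets must lie in (0, 14)")
    scales = load_property_scales()
    X = np.vstack([featurize(s, spec, scales) for s, _ in records])

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_val = max(1, len(records) // 5)
    val_idx, tr_idx = order[:n_val], order[n_val:]

    grid = tuple(hyperparameter_grid) if hyperparameter_grid is not None else _DEFAULT_GRID
    best: tuple[float, dict, Pipeline] | None = None
    for params in grid:
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **params))]
        )
        pipe.fit(X[tr_idx], y[tr_idx])
        rmsd = float(np.sqrt(np.mean((pipe.predict(X[val_idx]) - y[val_idx]) ** 2)))
        if best is None or rmsd < best[0]:
            best = (rmsd, dict(params), pipe)
    holdout_rmsd, params, pipe = best
    meta = {
        "n_sequences": len(records),
        "n_train": int(len(tr_idx)),
        "n_validation": int(len(val_idx)),
        "seed": int(seed),
        "date": _dt.date.today().isoformat(),
        "holdout_rmsd": holdout_rmsd,
        "grid_size": len(grid),
    }
    return TrainedModel(
        feature_spec=spec,
        kernel="rbf",
        hyperparameters=params,
        pipeline=pipe,
        training_metadata=meta,
    )


def predict(
    model: TrainedModel,
    seqs: Sequence[tuple[str, "str | ModifiedSequence"]],
) -> list[PredictionRecord]:
    """Order-preserving batch prediction as PredictionRecords."""
    values = model.predict_values([s for _, s in seqs])
    return [
        PredictionRecord(seq_id, "svm", model.feature_spec.seed_pka_set, predicted_pi=float(v))
        for (seq_id, _), v in zip(seqs, values)
    ]


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format_version": FEATURE_FORMAT_VERSION,
            "feature_spec": model.feature_spec.to_mapping(),
            "kernel": model.kernel,
            "hyperparameters": model.hyperparameters,
            "pipeline": model.pipeline,
            "training_metadata": model.training_metadata,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    raw = joblib.load(path)
    if raw.get("format_version") != FEATURE_FORMAT_VERSION:
        raise FeatureSpecError(
            f"model feature-format version {raw.get('format_version')} does not "
            f"match this library's version {FEATURE_FORMAT_VERSION}"
        )
    return TrainedModel(
        feature_spec=FeatureSpec.from_mapping(raw["feature_spec"]),
        kernel=raw["kernel"],
        hyperparameters=raw["hyperparameters"],
        pipeline=raw["pipeline"],
        training_metadata=raw["training_metadata"],
    )
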
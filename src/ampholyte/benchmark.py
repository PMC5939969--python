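"""Benchmarking layer: correlation, RMSD, outlier flags, method×set grids.

Predicted pIs are compared to experimental values with the squared Pearson
correlation (reported alongside the signed r, since a squared value hides
anti-correlation) and the root-mean-square deviation.  An *outlier* is a
record whose absolute residual meets or exceeds the sample standard
deviation of the predicted values — a simple QC rule for electrophoretic
experiments: a well-behaved separation has few residuals larger than the
spread of the theory itself.

``run_grid`` evaluates a whole method × parameterization grid over one
dataset and emits one report per combination, with per-sequence failures
(no isoelectric point, method not applicable) counted rather than raised, so
methods with applicability limits can sit in the same leaderboard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bjellqvist import solve_pi_bjellqvist
from .corrections import solve_pi_branca, solve_pi_cofactor
from .errors import (
    PredictionFailure,
    SequenceError,
    UnknownNameError,
    ValidationError,
)
from .modifications import ModifiedSequence
from .records import DatasetRecord, PredictionRecord
from .registry import (
    get_correction_table,
    get_set,
    get_variant,
)
from .solvers import DEFAULT_CONFIG, SolverConfig, solve_pi
from .svm import TrainedModel

# ---------------------------------------------------------------- metrics


def _paired(experimental, predicted, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(experimental, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if e.shape != p.shape or e.ndim != 1:
        raise ValidationError("experimental and predicted must be equal-length 1-D vectors")
    if len(e) < min_len:
        raise ValidationError(f"need at least {min_len} pairs, got {len(e)}")
    return e, p


def pearson_r(experimental, predicted) -> float:
    """Signed Pearson product-moment correlation."""
    e, p = _paired(experimental, predicted, 3)
    if np.ptp(e) == 0 or np.ptp(p) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(e, p).statistic)


def pearson_r2(experimental, predicted) -> float:
    """Squared Pearson correlation (the usual leaderboard 'R²')."""
    return pearson_r(experimental, predicted) ** 2


def rmsd(experimental, predicted) -> float:
    """Root-mean-square deviation in pH units."""
    e, p = _paired(experimental, predicted, 1)
    return float(np.sqrt(np.mean((e - p) ** 2)))


def flag_outliers(experimental, predicted) -> np.ndarray:
    """|residual| ≥ sample SD of the *predicted* vector.

    The threshold is the n−1 standard deviation of the theoretical values.
    When that SD is zero (constant predictions) only strictly positive
    residuals flag, so a perfect constant fit is not all-outliers.
    """
    e, p = _paired(experimental, predicted, 2)
    sd = float(np.std(p, ddof=1))
    resid = np.abs(e - p)
    if sd == 0.0:
        return resid > 0.0
    return resid >= sd


# ------------------------------------------------------- grid definitions


@dataclass(frozen=True)
class MethodSpec:
    """One cell of the method × parameterization grid."""

    method: str           # iterative | bjellqvist | cofactor | branca | svm
    parameter: str        # pKa-set name, variant name, or seed-set label

    @property
    def label(self) -> str:
        if self.method == "iterative":
            return f"ITERATIVE_{self.parameter.upper()}"
        if self.method == "bjellqvist":
            return f"BJELL_{self.parameter.upper()}"
        return self.method.upper()


#: Base set used where a method's leaderboard row carries no pKa-set label.
_CONTEXT_BASE_SET = "bjellqvist"

_ITERATIVE_SETS = (
    "grimsley", "rodwell", "thurlkill", "sillero", "toseland",
    "emboss", "solomon", "lehninger", "patrickios",
)
_BJELL_VARIANTS = ("default", "calibrated", "expasy", "skoog")


def default_grid(include_svm: bool = True) -> list[MethodSpec]:
    """The full 16-combination leaderboard grid.

    One SVM row, nine iterative rows (one per bundled basis set), four
    Bjellqvist variants, cofactor and branca.
    """
    grid: list[MethodSpec] = []
    if include_svm:
        grid.append(MethodSpec("svm", "default"))
    grid += [MethodSpec("iterative", s) for s in _ITERATIVE_SETS]
    grid += [MethodSpec("bjellqvist", v) for v in _BJELL_VARIANTS]
    grid.append(MethodSpec("cofactor", _CONTEXT_BASE_SET))
    grid.append(MethodSpec("branca", _CONTEXT_BASE_SET))
    return grid


def predictor_for(
    spec: MethodSpec,
    config: SolverConfig = DEFAULT_CONFIG,
    svm_model: TrainedModel | None = None,
) -> Callable[[ModifiedSequence], float]:
    """Resolve a grid cell to a callable sequence → pI.

    Raises :class:`UnknownNameError` for unresolvable names, and
    :class:`ValidationError` if an SVM cell is requested without a model.
    """
    if spec.method == "iterative":
        pka = get_set(spec.parameter)
        return lambda s: solve_pi(s, pka, config)
    if spec.method == "bjellqvist":
        var = get_variant(spec.parameter)
        return lambda s: solve_pi_bjellqvist(s, var, config)
    if spec.method == "cofactor":
        base = get_set(spec.parameter)
        table = get_correction_table("cofactor")
        return lambda s: solve_pi_cofactor(s, base, table, config)
    if spec.method == "branca":
        base = get_set(spec.parameter)
        table = get_correction_table("branca")
        return lambda s: solve_pi_branca(s, base, table, config)
    if spec.method == "svm":
        if svm_model is None:
            raise ValidationError("an SVM grid cell requires a trained model")
        model = svm_model
        return lambda s: float(model.predict_values([s])[0])
    raise UnknownNameError(
        f"unknown method {spec.method!r}; known: iterative, bjellqvist, "
        "cofactor, branca, svm"
    )


# ---------------------------------------------------------------- reports


@dataclass
class BenchmarkReport:
    """Per-combination evaluation: metrics plus the per-record residual table."""

    method: str
    pka_set: str
    n: int
    n_failed: int
    r: float            # signed Pearson correlation (NaN when undefined)
    r2: float           # squared Pearson correlation (NaN when undefined)
    rmsd: float         # NaN when no pairs survive
    residuals: pd.DataFrame = field(repr=False, default=None)
    per_fraction: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def label(self) -> str:
        return MethodSpec(self.method, self.pka_set).label


def _evaluate(
    records: Sequence[DatasetRecord],
    predictions: Sequence[PredictionRecord],
) -> BenchmarkReport:
    rows = []
    for rec, pred in zip(records, predictions):
        rows.append(
            {
                "id": rec.id,
                "fraction": rec.fraction,
                "experimental": rec.experimental_pi,
                "predicted": pred.predicted_pi,
                "failure": pred.failure_reason,
            }
        )
    df = pd.DataFrame(rows)
    df["predicted"] = pd.to_numeric(df["predicted"])
    df["experimental"] = pd.to_numeric(df["experimental"])
    ok = df["failure"].isna() if len(df) else pd.Series(dtype=bool)
    n_ok = int(ok.sum())
    n_failed = len(df) - n_ok
    sub = df.loc[ok] if n_ok else df.iloc[0:0]
    r_val = r2_val = rms_val = float("nan")
    if n_ok >= 1:
        rms_val = rmsd(sub["experimental"], sub["predicted"])
    if n_ok >= 3 and sub["experimental"].nunique() > 1 and sub["predicted"].nunique() > 1:
        r_val = pearson_r(sub["experimental"], sub["predicted"])
        r2_val = r_val**2
    df["residual"] = df["experimental"] - df["predicted"]
    df["outlier"] = False
    if n_ok >= 2:
        df.loc[ok, "outlier"] = flag_outliers(sub["experimental"], sub["predicted"])
    method, pka = predictions[0].method, predictions[0].pka_set_or_variant
    per_frac = None
    if any(r.fraction is not None for r in records):
        per_frac = per_fraction_summary(records, predictions)
    return BenchmarkReport(
        method=method,
        pka_set=pka,
        n=n_ok,
        n_failed=n_failed,
        r=r_val,
        r2=r2_val,
        rmsd=rms_val,
        residuals=df,
        per_fraction=per_frac,
    )


def predict_dataset(
    records: Sequence[DatasetRecord],
    spec: MethodSpec,
    config: SolverConfig = DEFAULT_CONFIG,
    svm_model: TrainedModel | None = None,
) -> list[PredictionRecord]:
    """Order-preserving predictions with annotated per-record failures."""
    fn = predictor_for(spec, config, svm_model)
    out: list[PredictionRecord] = []
    for rec in records:
        try:
            out.append(
                PredictionRecord(
                    rec.id, spec.method, spec.parameter,
                    predicted_pi=float(fn(rec.sequence)),
                )
            )
        except SequenceError:
            out.append(
                PredictionRecord(
                    rec.id, spec.method, spec.parameter,
                    failure_reason="invalid_sequence",
                )
            )
        except PredictionFailure as exc:
            out.append(
                PredictionRecord(
                    rec.id, spec.method, spec.parameter, failure_reason=exc.reason
                )
            )
    return out


def run_grid(
    dataset: Sequence[DatasetRecord],
    grid: Iterable[MethodSpec] | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
    svm_model: TrainedModel | None = None,
) -> list[BenchmarkReport]:
    """One report per grid combination over one dataset.

    Failed predictions are excluded pairwise (per combination) and counted in
    ``n_failed``; a combination where every record fails still yields a
    report (with NaN metrics), never a crash.
    """
    records = list(dataset)
    if not records:
        raise ValidationError("empty dataset after null filtering")
    if grid is None:
        grid = default_grid(include_svm=svm_model is not None)
    reports = []
    for spec in grid:
        preds = predict_dataset(records, spec, config, svm_model)
        reports.append(_evaluate(records, preds))
    return reports


def sort_reports(reports: Iterable[BenchmarkReport]) -> list[BenchmarkReport]:
    """Leaderboard order: RMSD ascending, then R² descending (NaNs last)."""
    def key(rep: BenchmarkReport):
        rms = rep.rmsd if np.isfinite(rep.rmsd) else np.inf
        r2 = rep.r2 if np.isfinite(rep.r2) else -np.inf
        return (rms, -r2)

    return sorted(reports, key=key)


def reports_table(reports: Iterable[BenchmarkReport]) -> pd.DataFrame:
    """The leaderboard as a DataFrame (one row per combination)."""
    return pd.DataFrame(
        [
            {
                "label": rep.label,
                "method": rep.method,
                "pka_set": rep.pka_set,
                "n": rep.n,
                "n_failed": rep.n_failed,
                "r": rep.r,
                "r2": rep.r2,
                "rmsd": rep.rmsd,
            }
            for rep in sort_reports(reports)
        ]
    )


def per_fraction_summary(
    records: Sequence[DatasetRecord],
    predictions: Sequence[PredictionRecord],
) -> pd.DataFrame:
    """Per IEF fraction: n, mean/SD of predicted pI, RMSD vs experimental.

    Fractions are ordered by the midpoint (mean) of their experimental pIs.
    Single-record fractions report SD 0 with a note, since a one-point spread
    is undefined rather than truly zero.
    """
    rows = []
    for rec, pred in zip(records, predictions):
        if rec.fraction is None or pred.predicted_pi is None:
            continue
        rows.append(
            {
                "fraction": rec.fraction,
                "experimental": rec.experimental_pi,
                "predicted": pred.predicted_pi,
            }
        )
    df = pd.DataFrame(rows, columns=["fraction", "experimental", "predicted"])
    out = []
    for frac, g in df.groupby("fraction"):
        n = len(g)
        out.append(
            {
                "fraction": frac,
                "n": n,
                "experimental_midpoint": float(g["experimental"].mean()),
                "mean_predicted": float(g["predicted"].mean()),
                "sd_predicted": float(g["predicted"].std(ddof=1)) if n > 1 else 0.0,
                "rmsd": float(np.sqrt(np.mean((g["experimental"] - g["predicted"]) ** 2))),
                "note": "" if n > 1 else "single record; SD reported as 0",
            }
        )
    res = pd.DataFrame(
        out,
        columns=[
            "fraction", "n", "experimental_midpoint", "mean_predicted",
            "sd_predicted", "rmsd", "note",
        ],
    )
    return res.sort_values("experimental_midpoint", kind="stable").reset_index(drop=True)
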
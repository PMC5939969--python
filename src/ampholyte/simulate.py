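"""Seeded synthetic datasets with the structure of real pI benchmarks.

Two generators:

* :func:`simulate_peptides` emulates an OFF-GEL IEF experiment on a tryptic
  digest: random peptides ending in K/R, a ground-truth pI from a chosen
  generating method, optional phospho/acetyl sub-populations, Gaussian
  measurement noise, and assignment to one of 15 fractions spanning
  pH 3–10.  Defaults: n=2000 peptides of length 7–25, noise SD 0.2 pH
  (a realistic per-fraction IEF uncertainty), phospho/acetyl rates 0.
* :func:`simulate_proteins` emulates a literature-collated protein table in
  which many proteins carry several discordant experimental pIs: a
  rate-controlled share of proteins receives 2–5 measurements drawn around
  truth with a between-laboratory SD (default 1.0 pH), and a small subset
  shows a wide focalization zone (max−min ≥ 3.5 pH).

Everything is deterministic per seed.  What these datasets deliberately do
not model: MS/MS identification error, composition bias of real proteomes
(uniform residue usage by default), chemical derivatization, and diffusion
between adjacent fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmark import MethodSpec, predictor_for
from .errors import PredictionFailure, ValidationError
from .modifications import PHOSPHO_RESIDUES, ModifiedSequence
from .records import DatasetRecord
from .solvers import DEFAULT_CONFIG, SolverConfig

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class PeptideSimConfig:
    """Conditions of the emulated OFF-GEL peptide experiment."""

    n: int = 2000
    length_range: tuple[int, int] = (7, 25)
    tryptic: bool = True
    generating_method: MethodSpec = field(
        default_factory=lambda: MethodSpec("bjellqvist", "expasy")
    )
    noise_sd: float = 0.2
    n_fractions: int = 15
    ph_range: tuple[float, float] = (3.0, 10.0)
    phospho_rate: float = 0.0
    acetyl_rate: float = 0.0
    quantize_to_fraction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.phospho_rate, self.acetyl_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("modification rates must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_fractions < 1:
            raise ValidationError("n_fractions must be >= 1")
        if not self.length_range[0] <= self.length_range[1]:
            raise ValidationError("length_range must be (min, max) with min <= max")


@dataclass(frozen=True)
class ProteinSimConfig:
    """Conditions of the emulated multi-measurement protein table."""

    n: int = 1000
    length_range: tuple[int, int] = (50, 400)
    multi_measurement_rate: float = 0.5
    between_lab_sd: float = 1.0
    wide_zone_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.multi_measurement_rate, self.wide_zone_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.between_lab_sd < 0:
            raise ValidationError("between_lab_sd must be >= 0")


def random_sequence(
    rng: np.random.Generator,
    length_range: tuple[int, int],
    tryptic: bool = False,
) -> str:
    """A uniform-random residue string, optionally with a K/R C-terminus."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    body = rng.choice(_RESIDUES, size=length)
    if tryptic:
        body[-1] = "K" if rng.random() < 0.5 else "R"
    return "".join(body)


def _clip_pi(x: float) -> float:
    return float(min(max(x, 0.01), 13.99))


def _fraction_id(pi: float, ph_range: tuple[float, float], n_fractions: int) -> str:
    lo, hi = ph_range
    idx = int(np.floor((pi - lo) / (hi - lo) * n_fractions))
    idx = min(max(idx, 0), n_fractions - 1)  # out-of-range pIs land in end bins
    return f"F{idx + 1:02d}"


def _fraction_midpoint(frac: str, ph_range: tuple[float, float], n_fractions: int) -> float:
    idx = int(frac[1:]) - 1
    lo, hi = ph_range
    width = (hi - lo) / n_fractions
    return lo + (idx + 0.5) * width


def simulate_peptides(
    config: PeptideSimConfig = PeptideSimConfig(),
    solver_config: SolverConfig = DEFAULT_CONFIG,
) -> list[DatasetRecord]:
    """An OFF-GEL-style peptide dataset with known ground truth.

    The experimental pI of each record is the generating method's pI (with
    any modifications applied) plus Gaussian noise; the fraction id bins the
    experimental value over ``ph_range``.  The rare peptide for which the
    generating method fails is redrawn.
    """
    rng = np.random.default_rng(config.seed)
    predict = predictor_for(config.generating_method, solver_config)
    records: list[DatasetRecord] = []
    i = 0
    while len(records) < config.n:
        i += 1
        seq_str = random_sequence(rng, config.length_range, config.tryptic)
        phospho: frozenset[int] = frozenset()
        if config.phospho_rate and rng.random() < config.phospho_rate:
            candidates = [
                k + 1 for k, aa in enumerate(seq_str) if aa in PHOSPHO_RESIDUES
            ]
            if candidates:
                n_sites = int(rng.integers(1, min(2, len(candidates)) + 1))
                chosen = rng.choice(candidates, size=n_sites, replace=False)
                phospho = frozenset(int(c) for c in chosen)
        acetyl = bool(config.acetyl_rate and rng.random() < config.acetyl_rate)
        mseq = ModifiedSequence(seq_str, phospho, acetyl)
        try:
            truth = predict(mseq)
        except PredictionFailure:
            continue  # redraw: e.g. acetylated all-acid draw
        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
        observed = _clip_pi(truth + noise)
        frac = _fraction_id(observed, config.ph_range, config.n_fractions)
        if config.quantize_to_fraction:
            observed = _fraction_midpoint(frac, config.ph_range, config.n_fractions)
        records.append(
            DatasetRecord(
                id=f"pep{len(records) + 1:05d}",
                sequence=mseq,
                experimental_pi=observed,
                fraction=frac,
                source=config.generating_method.label,
            )
        )
    return records


def simulate_proteins(
    config: ProteinSimConfig = ProteinSimConfig(),
    solver_config: SolverConfig = DEFAULT_CONFIG,
) -> list[DatasetRecord]:
    """A literature-style protein table with repeated, discordant measurements.

    Ground truth comes from the iterative method (emboss basis).  Each
    protein yields one record per simulated measurement, all sharing the
    protein id; a ``wide_zone_rate`` subset gets measurements spread over at
    least 3.5 pH units, emulating proteins reported in both acid and basic
    regions.
    """
    rng = np.random.default_rng(config.seed)
    predict = predictor_for(MethodSpec("iterative", "emboss"), solver_config)
    records: list[DatasetRecord] = []
    made = 0
    while made < config.n:
        seq_str = random_sequence(rng, config.length_range, tryptic=False)
        mseq = ModifiedSequence(seq_str)
        try:
            truth = predict(mseq)
        except PredictionFailure:
            continue
        made += 1
        pid = f"prot{made:05d}"
        wide = rng.random() < config.wide_zone_rate
        multi = wide or rng.random() < config.multi_measurement_rate
        k = int(rng.integers(2, 6)) if multi else 1
        values = truth + rng.normal(0.0, config.between_lab_sd, size=k)
        if wide:
            # force a focalization zone of >= 3.5 pH units; keep the zone
            # centred as close to truth as the (0, 14) domain allows
            span = 3.5 + rng.uniform(0.0, 1.5)
            centre = min(max(truth, 0.02 + span / 2), 13.98 - span / 2)
            values[0] = centre - span / 2
            values[1] = centre + span / 2
        for j, v in enumerate(values, start=1):
            records.append(
                DatasetRecord(
                    id=pid,
                    sequence=mseq,
                    experimental_pi=_clip_pi(float(v)),
                    fraction=None,
                    source=f"lab{j}" if k > 1 else "single",
                )
            )
    return records
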
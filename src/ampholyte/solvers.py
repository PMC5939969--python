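"""pI root-finding: the iterative Henderson–Hasselbalch method family.

The pI is the unique root of the strictly decreasing net-charge function
Z(pH).  We bracket it on [ph_lo, ph_hi] and bisect: guaranteed convergence
on a monotone function, bit-for-bit reproducible, and fast enough that
robustness is worth far more than Newton-style speed at this scale.

Sequences whose groups all share one polarity (e.g. an acetylated peptide
with only acidic groups) have no root in the domain; that is reported as
:class:`NoIsoelectricPointError`, never silently clamped to 0 or 14, because
a clamped value would poison downstream benchmark statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .charge import IonizableGroup, enumerate_groups, net_charge
from .errors import NoIsoelectricPointError, PredictionFailure, SequenceError, ValidationError
from .modifications import ModifiedSequence, coerce_sequence
from .records import PredictionRecord
from .registry import PkaSet


@dataclass(frozen=True)
class SolverConfig:
    """Bisection parameters; the defaults suit all shipped basis sets."""

    tolerance: float = 1e-4      # final bracket width, pH units
    max_iterations: int = 200
    ph_lo: float = 0.0
    ph_hi: float = 14.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if not self.ph_lo < self.ph_hi:
            raise ValidationError("ph_lo must be below ph_hi")


DEFAULT_CONFIG = SolverConfig()


def bisect_root(
    f: Callable[[float], float], config: SolverConfig = DEFAULT_CONFIG
) -> float:
    """Root of a strictly decreasing ``f`` on [ph_lo, ph_hi] by bisection.

    Raises :class:`NoIsoelectricPointError` when f has the same sign at both
    bounds (the message names the sign).
    """
    lo, hi = config.ph_lo, config.ph_hi
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo < 0.0 or f_hi > 0.0:
        sign = "negative" if f_lo < 0.0 else "positive"
        raise NoIsoelectricPointError(
            f"net charge is {sign} over the whole pH domain "
            f"[{lo:g}, {hi:g}]; no isoelectric point exists"
        )
    for _ in range(config.max_iterations):
        mid = 0.5 * (lo + hi)
        if hi - lo < config.tolerance:
            return mid
        f_mid = f(mid)
        if f_mid == 0.0:
            return mid
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_pi_groups(
    groups: Sequence[IonizableGroup], config: SolverConfig = DEFAULT_CONFIG
) -> float:
    """pI of an explicit group list."""
    if len(groups) == 0:
        raise NoIsoelectricPointError("no ionizable groups: charge is identically zero")
    return bisect_root(lambda ph: net_charge(groups, ph), config)


def solve_pi(
    seq: "str | ModifiedSequence",
    pka_set: PkaSet,
    config: SolverConfig = DEFAULT_CONFIG,
) -> float:
    """pI of a (possibly modified) sequence under one pKa basis set."""
    return solve_pi_groups(enumerate_groups(seq, pka_set), config)


def solve_pi_batch(
    seqs: Iterable[tuple[str, "str | ModifiedSequence"]],
    pka_set: PkaSet,
    config: SolverConfig = DEFAULT_CONFIG,
) -> list[PredictionRecord]:
    """Order-preserving batch solve; per-element failures become annotated rows.

    ``seqs`` is an iterable of (id, sequence) pairs.  A failing element is
    recorded with its failure reason rather than aborting the batch, so
    downstream null-value handling sees every input.
    """
    out: list[PredictionRecord] = []
    for seq_id, seq in seqs:
        try:
            pi = solve_pi(coerce_sequence(seq), pka_set, config)
            out.append(
                PredictionRecord(seq_id, "iterative", pka_set.name, predicted_pi=pi)
            )
        except SequenceError:
            out.append(
                PredictionRecord(
                    seq_id, "iterative", pka_set.name, failure_reason="invalid_sequence"
                )
            )
        except PredictionFailure as exc:
            out.append(
                PredictionRecord(
                    seq_id, "iterative", pka_set.name, failure_reason=exc.reason
                )
            )
    return out


def diprotic_midpoint(acid_pka: float, base_pka: float) -> float:
    """Closed-form pI of a two-group (one acid, one base) ampholyte.

    At pH = (pKa_acid + pKb_base)/2 the protonated-base and
    deprotonated-acid fractions are equal, so the net charge is zero: the
    analytic oracle for every diprotic case.
    """
    return 0.5 * (float(acid_pka) + float(base_pka))


def _is_finite_pi(x: float) -> bool:
    return math.isfinite(x) and 0.0 < x < 14.0
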
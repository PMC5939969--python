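"""Sequence-context pKa corrections: the Cofactor and Branca methods.

Both methods start from a plain pKa basis and shift individual pKas
according to the local sequence neighborhood:

* **Cofactor** applies fixed ΔpKa terms from residues up to ±3 positions
  away to the acidic carboxyl groups only — D/E sidechains and the
  C-terminus.  Corrections are applied once, before root solving.
* **Branca** considers ionizable neighbors up to six residues away, but
  weights each correction by the *charged fraction* of the neighboring group
  at the current pH estimate, which makes the corrected pKas depend on the
  pI being solved for.  We resolve this self-consistently with a damped
  fixed-point iteration seeded at the uncorrected iterative pI.  A global
  statistical term keyed by the count of Asp and Glu sidechains is added to
  the D/E pKas.  The method is defined only for peptides with a basic (K/R)
  C-terminus — tryptic peptides — and refuses anything else.

Correction constants are data (:class:`~ampholyte.registry.CorrectionTable`);
with an all-zero table both methods reduce exactly to the iterative method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .charge import IonizableGroup, enumerate_groups
from .errors import ConvergenceError, NotApplicableError, ValidationError
from .modifications import ModifiedSequence, coerce_sequence
from .registry import CorrectionTable, PkaSet
from .solvers import DEFAULT_CONFIG, SolverConfig, solve_pi_groups

_PKA_MARGIN = 1e-3  # corrected pKas are kept inside the open (0, 14) domain


def _clamped(pka: float) -> float:
    return min(max(pka, _PKA_MARGIN), 14.0 - _PKA_MARGIN)


def _with_pka(g: IonizableGroup, pka: float) -> IonizableGroup:
    return IonizableGroup(g.kind, g.residue, g.position, g.polarity, _clamped(pka))


def _neighbor_sum(
    seq_res: str, position: int, table: CorrectionTable
) -> float:
    """Σ table[(residue at position+offset, offset)] over in-bounds offsets ≠ 0."""
    total = 0.0
    n = len(seq_res)
    for off in range(-table.window, table.window + 1):
        if off == 0:
            continue
        q = position + off
        if 1 <= q <= n:
            total += table.delta(seq_res[q - 1], off)
    return total


def cofactor_pkas(
    seq: "str | ModifiedSequence", base_set: PkaSet, table: CorrectionTable
) -> list[IonizableGroup]:
    """Groups with context-corrected pKas on D/E sidechains and the C-terminus.

    All other groups (K/R/H/C/Y, N-terminus, modifications) pass through
    unchanged.  Offsets are signed, so a table may distinguish N-side from
    C-side neighbors (or collapse them symmetrically).
    """
    if table.method != "cofactor":
        raise ValidationError(f"expected a cofactor table, got method {table.method!r}")
    if table.window != 3:
        raise ValidationError(f"cofactor window must be 3, got {table.window}")
    mseq = coerce_sequence(seq)
    out = []
    for g in enumerate_groups(mseq, base_set):
        corrects = (g.kind == "sidechain" and g.residue in ("D", "E")) or g.kind == "c_term"
        if corrects:
            g = _with_pka(g, g.pka + _neighbor_sum(mseq.residues, g.position, table))
        out.append(g)
    return out


def solve_pi_cofactor(
    seq: "str | ModifiedSequence",
    base_set: PkaSet,
    table: CorrectionTable,
    config: SolverConfig = DEFAULT_CONFIG,
) -> float:
    """pI with Cofactor context corrections applied before root solving."""
    return solve_pi_groups(cofactor_pkas(seq, base_set, table), config)


@dataclass
class BrancaState:
    """Diagnostic trace of the Branca fixed-point iteration."""

    ph_estimate: float
    effective_pkas: dict[int, float] = field(default_factory=dict)
    charged_fractions: dict[int, float] = field(default_factory=dict)
    iteration: int = 0


def _branca_effective_groups(
    mseq: ModifiedSequence,
    base_groups: list[IonizableGroup],
    table: CorrectionTable,
    ph: float,
    carboxyl_term: float,
) -> tuple[list[IonizableGroup], dict[int, float], dict[int, float]]:
    """One correction pass at a fixed pH estimate.

    Correction *sources* are sidechain and modification groups (the terminal
    groups share a residue letter with a sidechain and are not re-keyed);
    every group is a potential *receiver*.  Each source's table entry is
    scaled by its charged fraction at ``ph``, computed from the base pKas.
    """
    fractions = {i: g.charged_fraction(ph) for i, g in enumerate(base_groups)}
    sources = [
        (i, g) for i, g in enumerate(base_groups) if g.kind in ("sidechain", "modification")
    ]
    corrected: list[IonizableGroup] = []
    eff: dict[int, float] = {}
    for i, g in enumerate(base_groups):
        delta = 0.0
        for j, s in sources:
            if j == i:
                continue
            off = s.position - g.position
            if off == 0 or abs(off) > table.window:
                continue
            delta += table.delta(s.residue, off) * fractions[j]
        if g.kind == "sidechain" and g.residue in ("D", "E"):
            delta += carboxyl_term
        pka = _clamped(g.pka + delta)
        eff[i] = pka
        corrected.append(_with_pka(g, pka))
    return corrected, eff, fractions


def solve_pi_branca(
    seq: "str | ModifiedSequence",
    base_set: PkaSet,
    table: CorrectionTable,
    config: SolverConfig = DEFAULT_CONFIG,
    return_state: bool = False,
):
    """pI by the self-consistent Branca scheme.

    Fixed point: (1) seed the pH estimate with the uncorrected iterative pI;
    (2) compute each group's charged fraction at the estimate; (3) build
    effective pKas = base + Σ neighbor-entry × charged fraction (+ the
    carboxyl count term on D/E); (4) re-solve for the pI.  Repeat 2–4 until
    the estimate moves less than the solver tolerance.  Updates are damped by
    0.5 when the step direction alternates (oscillation guard).
    """
    if table.method != "branca":
        raise ValidationError(f"expected a branca table, got method {table.method!r}")
    if table.window != 6:
        raise ValidationError(f"branca window must be 6, got {table.window}")
    mseq = coerce_sequence(seq)
    if mseq.residues[-1] not in ("K", "R"):
        raise NotApplicableError(
            "the Branca method is defined only for peptides with a K/R "
            f"C-terminus; got {mseq.residues[-1]!r}"
        )
    base_groups = enumerate_groups(mseq, base_set)
    n_d = mseq.residues.count("D")
    n_e = mseq.residues.count("E")
    carboxyl_term = table.carboxyl_delta(n_d, n_e)

    ph = solve_pi_groups(base_groups, config)  # uncorrected seed
    prev_step = 0.0
    state = BrancaState(ph_estimate=ph)
    for iteration in range(1, config.max_iterations + 1):
        corrected, eff, fractions = _branca_effective_groups(
            mseq, base_groups, table, ph, carboxyl_term
        )
        new_ph = solve_pi_groups(corrected, config)
        step = new_ph - ph
        if prev_step * step < 0:  # sign-alternating updates: damp
            new_ph = ph + 0.5 * step
            step = new_ph - ph
        state = BrancaState(new_ph, eff, fractions, iteration)
        if abs(step) < config.tolerance:
            return (new_ph, state) if return_state else new_ph
        ph, prev_step = new_ph, step
    raise ConvergenceError(
        f"Branca fixed point did not converge in {config.max_iterations} "
        f"iterations; last estimates {ph:.6f} -> {ph + prev_step:.6f}"
    )
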
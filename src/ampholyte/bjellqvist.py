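"""The Bjellqvist method: position-dependent pKas.

Historically the first pI algorithm to let a pKa depend on where the residue
sits in the chain: the alpha-amino pKa varies with the identity of the first
residue, and sidechains may take different values in N-terminal, C-terminal
or internal context.  All position dependence lives in
:class:`~ampholyte.registry.TerminalVariant` data tables (default, expasy,
calibrated, skoog); the algorithm itself is a single code path, so swapping
variants is a data change, not a code change.
"""

from __future__ import annotations

from .charge import IonizableGroup, sidechain_polarity
from .modifications import ModifiedSequence, apply_acetylation, coerce_sequence, phospho_groups
from .registry import TerminalVariant
from .solvers import DEFAULT_CONFIG, SolverConfig, solve_pi_groups


def _context(position: int, length: int) -> str:
    # A length-1 chain is treated as n-terminal context (documented tie-break).
    if position == 1:
        return "n-terminal"
    if position == length:
        return "c-terminal"
    return "internal"


def bjellqvist_groups(
    seq: "str | ModifiedSequence", variant: TerminalVariant
) -> list[IonizableGroup]:
    """Group enumeration with positional pKa lookup.

    Terminal pKas are chosen by the identity of the first/last residue (with
    the variant's base values as fallback); sidechain pKas consult the
    positional table with internal fallback.  A variant with empty tables
    therefore reduces exactly to the plain enumeration over its base set.
    Modifications are honoured as in the iterative method.
    """
    mseq = coerce_sequence(seq)
    res = mseq.residues
    n = len(res)
    groups: list[IonizableGroup] = [
        IonizableGroup("n_term", res[0], 1, "base", variant.n_term_pka(res[0]))
    ]
    for i, aa in enumerate(res, start=1):
        pka = variant.sidechain_pka(aa, _context(i, n))
        if pka is not None:
            groups.append(IonizableGroup("sidechain", aa, i, sidechain_polarity(aa), pka))
    groups.append(IonizableGroup("c_term", res[-1], n, "acid", variant.c_term_pka(res[-1])))
    if mseq.n_term_acetylated:
        groups = apply_acetylation(groups)
    for site in sorted(mseq.phospho_sites):
        groups.extend(phospho_groups(mseq, site))
    return groups


def solve_pi_bjellqvist(
    seq: "str | ModifiedSequence",
    variant: TerminalVariant,
    config: SolverConfig = DEFAULT_CONFIG,
) -> float:
    """pI under a Bjellqvist terminal variant."""
    return solve_pi_groups(bjellqvist_groups(seq, variant), config)
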
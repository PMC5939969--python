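"""Cofactor and Branca context corrections: reductions, locality, fixed point."""

import numpy as np
import pytest

from ampholyte import (
    CorrectionTable,
    NotApplicableError,
    ValidationError,
    cofactor_pkas,
    enumerate_groups,
    solve_pi,
    solve_pi_branca,
    solve_pi_cofactor,
    zero_table,
)
from ampholyte.corrections import _branca_effective_groups  # fixed-point internals

from conftest import grid_scan_pi, random_peptide


def _pka_map(groups):
    return {(g.kind, g.position, g.residue): g.pka for g in groups}


# ----------------------------------------------------------------- cofactor


def test_cofactor_zero_table_is_identity(emboss, random_peptides):
    zt = zero_table("cofactor")
    for mseq in random_peptides:
        assert _pka_map(cofactor_pkas(mseq, emboss, zt)) == _pka_map(
            enumerate_groups(mseq, emboss)
        )
        assert solve_pi_cofactor(mseq, emboss, zt) == solve_pi(mseq, emboss)


def test_cofactor_bounds_clipping(emboss):
    # D at position 2 of a length-3 peptide: only offsets -1 and +1 are in range
    table = CorrectionTable(
        "cofactor", 3,
        entries={("K", -1): -0.2, ("K", 1): -0.1, ("K", -3): -0.5, ("K", 3): -0.5},
    )
    groups = cofactor_pkas("KDK", emboss, table)
    d = next(g for g in groups if g.kind == "sidechain" and g.residue == "D")
    assert d.pka == pytest.approx(emboss.sidechain["D"] - 0.2 - 0.1)


def test_cofactor_targets_only_carboxyl_groups(emboss):
    # a large negative correction keyed on every neighbor residue
    entries = {(aa, off): -0.3 for aa in "ACDEFGHIKLMNPQRSTVWY"
               for off in (-3, -2, -1, 1, 2, 3)}
    table = CorrectionTable("cofactor", 3, entries=entries)
    base = _pka_map(enumerate_groups("KDEKHYC", emboss))
    corrected = _pka_map(cofactor_pkas("KDEKHYC", emboss, table))
    for key in base:
        kind, pos, res = key
        if (kind == "sidechain" and res in "DE") or kind == "c_term":
            assert corrected[key] < base[key]
        else:
            assert corrected[key] == base[key]  # K, H, Y, C, n_term untouched


def test_cofactor_negative_delta_on_d_lowers_pi(emboss):
    seq = "KDGGK"
    table = CorrectionTable("cofactor", 3, entries={("K", -1): -0.5})
    # the pI sits far above the D pKa, so the shift is tiny: solve tightly
    from ampholyte import SolverConfig

    cfg = SolverConfig(tolerance=1e-11)
    before = solve_pi(seq, emboss, cfg)
    after = solve_pi_cofactor(seq, emboss, table, cfg)
    assert after < before
    # the shift agrees with an independent grid scan over the corrected groups
    assert after == pytest.approx(
        grid_scan_pi(cofactor_pkas(seq, emboss, table)), abs=1e-4
    )


def test_cofactor_window_mismatch_rejected(emboss):
    bad = CorrectionTable("cofactor", window=2, entries={})
    with pytest.raises(ValidationError, match="window"):
        solve_pi_cofactor("KDE", emboss, bad)
    with pytest.raises(ValidationError, match="cofactor"):
        solve_pi_cofactor("KDE", emboss, zero_table("branca"))


def test_cofactor_locality(emboss):
    """Editing a residue > window away from every D/E/terminus leaves output unchanged."""
    table = CorrectionTable(
        "cofactor", 3,
        entries={(aa, off): -0.1 for aa in "KR" for off in (-3, -1, 1, 3)},
    )
    a = "DEGGGGGAGGGGGGGGKDE"
    # edit position 8: more than 3 residues from D/E at 1, 2, 18, 19 and both termini
    b = a[:7] + "W" + a[8:]
    assert solve_pi_cofactor(a, emboss, table) == solve_pi_cofactor(b, emboss, table)


# ------------------------------------------------------------------- branca


def test_branca_zero_table_reduces_to_iterative(emboss, rng):
    zt = zero_table("branca")
    for _ in range(25):
        seq = random_peptide(rng, tryptic=True)
        assert solve_pi_branca(seq, emboss, zt) == solve_pi(seq, emboss)


def test_branca_requires_basic_c_terminus(emboss):
    with pytest.raises(NotApplicableError, match="K/R"):
        solve_pi_branca("MDEGGHG", emboss, zero_table("branca"))


def test_branca_charged_fraction_weights_corrections(emboss):
    """A charged neighbor applies its full correction; a neutral one almost none."""
    table = CorrectionTable("branca", 6, entries={("R", -1): -0.4})
    seq = "GRDGGK"  # R at 2 feeds the D at 3 via offset -1
    groups = enumerate_groups(seq, emboss)
    d_idx = next(
        i for i, g in enumerate(groups) if g.kind == "sidechain" and g.residue == "D"
    )
    base_d = groups[d_idx].pka
    # at pH 4, Arg (pKa 12.5) is essentially fully protonated: full correction
    corrected, eff, frac = _branca_effective_groups(None, groups, table, 4.0, 0.0)
    assert eff[d_idx] == pytest.approx(base_d - 0.4, abs=1e-3)
    # at pH 14-, Arg is essentially neutral: almost no correction
    corrected, eff, frac = _branca_effective_groups(None, groups, table, 13.9, 0.0)
    assert eff[d_idx] == pytest.approx(base_d, abs=0.4 * 0.05)


def test_branca_carboxyl_count_term_applies_to_d_and_e(emboss):
    table = CorrectionTable(
        "branca", 6, carboxyl_correction={(1, 1): 0.3}
    )
    seq = "GDEGGK"  # one D, one E -> the (1,1) entry fires
    pi_plain = solve_pi(seq, emboss)
    pi_corr = solve_pi_branca(seq, emboss, table)
    assert pi_corr > pi_plain  # raising acid pKas raises the pI
    seq2 = "GDDEGK"  # (2,1) has no entry -> reduces to iterative
    assert solve_pi_branca(seq2, emboss, table) == solve_pi(seq2, emboss)


def test_branca_fixed_point_stability(emboss, rng):
    """Re-running the correction pass from a converged pI moves it < tolerance."""
    from ampholyte import get_correction_table
    from ampholyte.solvers import DEFAULT_CONFIG, solve_pi_groups
    from ampholyte.modifications import ModifiedSequence

    table = get_correction_table("branca")
    for _ in range(10):
        seq = random_peptide(rng, tryptic=True)
        mseq = ModifiedSequence(seq)
        pi, state = solve_pi_branca(mseq, emboss, table, return_state=True)
        groups = enumerate_groups(mseq, emboss)
        n_d, n_e = seq.count("D"), seq.count("E")
        corrected, _, _ = _branca_effective_groups(
            mseq, groups, table, pi, table.carboxyl_delta(n_d, n_e)
        )
        repeat = solve_pi_groups(corrected, DEFAULT_CONFIG)
        assert abs(repeat - pi) < 2 * DEFAULT_CONFIG.tolerance, seq


def test_branca_oracle_agreement_with_synthetic_table(emboss, rng):
    """The converged pI is the root of the charge sum over the final pKas."""
    table = CorrectionTable(
        "branca", 6,
        entries={("K", -1): -0.2, ("K", 1): -0.2, ("D", 1): 0.15, ("E", -2): 0.1},
    )
    for _ in range(10):
        seq = random_peptide(rng, tryptic=True)
        from ampholyte.modifications import ModifiedSequence

        mseq = ModifiedSequence(seq)
        pi, state = solve_pi_branca(mseq, emboss, table, return_state=True)
        groups = enumerate_groups(mseq, emboss)
        corrected, _, _ = _branca_effective_groups(
            mseq, groups, table, pi,
            table.carboxyl_delta(seq.count("D"), seq.count("E")),
        )
        assert pi == pytest.approx(grid_scan_pi(corrected), abs=5e-4), seq


def test_branca_converged_fractions_in_unit_interval(emboss):
    from ampholyte import get_correction_table

    pi, state = solve_pi_branca(
        "KDEDEGHYRK", emboss, get_correction_table("branca"), return_state=True
    )
    assert state.charged_fractions
    assert all(0.0 <= f <= 1.0 for f in state.charged_fractions.values())
    assert state.iteration >= 1
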
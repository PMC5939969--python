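"""Henderson–Hasselbalch net-charge model.

The net charge of a denatured polypeptide at a given pH is the sum over its
ionizable groups of the fractional charge each group carries:

    Z(pH) = Σ_base 1 / (1 + 10^(pH − pKa)) − Σ_acid 1 / (1 + 10^(pKa − pH))

Basic groups (K, R, H sidechains; the free alpha-amino terminus) contribute
+1 scaled by their protonated fraction; acidic groups (D, E, C, Y sidechains;
the alpha-carboxyl terminus; phosphosite groups) contribute −1 scaled by
their deprotonated fraction.  Z is continuous and strictly decreasing in pH
whenever at least one group exists, which is what makes the pI — the root of
Z — unique.

Conventions: residues are indexed 1-based; the N-terminal group is attached
to position 1 and the C-terminal group to position len(seq).  No disulfide or
structural effects are modelled (chains are assumed denatured), and pKas
carry no temperature or ionic-strength dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .modifications import ModifiedSequence, apply_acetylation, coerce_sequence, phospho_groups
from .registry import ACID_SIDECHAINS, BASE_SIDECHAINS, PkaSet

_POLARITIES = ("acid", "base")
_KINDS = ("sidechain", "n_term", "c_term", "modification")


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site: the unit of the net-charge sum."""

    kind: str
    residue: str
    position: int
    polarity: str
    pka: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown group kind {self.kind!r}")
        if self.polarity not in _POLARITIES:
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if not 0.0 < self.pka < 14.0:
            raise ValidationError(
                f"group {self.residue}@{self.position}: pKa {self.pka} outside (0, 14)"
            )

    def fractional_charge(self, ph):
        """Signed fractional charge at ``ph`` (scalar or ndarray)."""
        if self.polarity == "base":
            return 1.0 / (1.0 + np.power(10.0, np.asarray(ph, dtype=float) - self.pka))
        return -1.0 / (1.0 + np.power(10.0, self.pka - np.asarray(ph, dtype=float)))

    def charged_fraction(self, ph) -> float:
        """|fractional charge|: the Branca correction weight, in [0, 1]."""
        return float(np.abs(self.fractional_charge(ph)))


@dataclass(frozen=True)
class ChargeProfile:
    """Net charge tabulated on a strictly increasing pH grid."""

    ph_grid: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.ph_grid, dtype=float)
        ch = np.asarray(self.charges, dtype=float)
        if grid.ndim != 1 or grid.shape != ch.shape:
            raise ValidationError("ph_grid and charges must be matching 1-D arrays")
        if not np.all(np.diff(grid) > 0):
            raise ValidationError("ph_grid must be strictly increasing")
        object.__setattr__(self, "ph_grid", grid)
        object.__setattr__(self, "charges", ch)


def sidechain_polarity(residue: str) -> str:
    if residue in BASE_SIDECHAINS:
        return "base"
    if residue in ACID_SIDECHAINS:
        return "acid"
    raise ValidationError(f"{residue!r} has no defined sidechain polarity")


def enumerate_groups(
    seq: "str | ModifiedSequence", pka_set: PkaSet
) -> list[IonizableGroup]:
    """All ionizable groups of a (possibly modified) sequence under one basis.

    Order is deterministic: n_term (unless acetylated), sidechains by
    position, c_term, then modification groups by position.  Residues without
    an entry in ``pka_set.sidechain`` are treated as non-ionizable.
    """
    mseq = coerce_sequence(seq)
    res = mseq.residues
    groups: list[IonizableGroup] = [
        IonizableGroup("n_term", res[0], 1, "base", pka_set.n_term)
    ]
    for i, aa in enumerate(res, start=1):
        pka = pka_set.sidechain.get(aa)
        if pka is not None:
            groups.append(IonizableGroup("sidechain", aa, i, sidechain_polarity(aa), pka))
    groups.append(IonizableGroup("c_term", res[-1], len(res), "acid", pka_set.c_term))
    if mseq.n_term_acetylated:
        groups = apply_acetylation(groups)
    for site in sorted(mseq.phospho_sites):
        groups.extend(phospho_groups(mseq, site))
    return groups


def net_charge(groups: Iterable[IonizableGroup], ph) -> "float | np.ndarray":
    """Net charge (elementary-charge units) at ``ph`` (scalar or array)."""
    ph_arr = np.asarray(ph, dtype=float)
    total = np.zeros_like(ph_arr)
    for g in groups:
        total = total + g.fractional_charge(ph_arr)
    if np.ndim(ph) == 0:
        return float(total)
    return total


def group_pka_arrays(groups: Sequence[IonizableGroup]) -> tuple[np.ndarray, np.ndarray]:
    """(signs, pkas) arrays for vectorized charge evaluation: sign +1 base, −1 acid."""
    signs = np.array([1.0 if g.polarity == "base" else -1.0 for g in groups])
    pkas = np.array([g.pka for g in groups])
    return signs, pkas


def charge_profile(
    seq: "str | ModifiedSequence",
    pka_set: PkaSet,
    ph_min: float = 0.0,
    ph_max: float = 14.0,
    step: float = 0.01,
) -> ChargeProfile:
    """Tabulate the titration curve on a regular grid."""
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    if not ph_min < ph_max:
        raise ValidationError(f"ph_min ({ph_min}) must be below ph_max ({ph_max})")
    grid = np.arange(ph_min, ph_max + step / 2, step)
    groups = enumerate_groups(seq, pka_set)
    return ChargeProfile(ph_grid=grid, charges=np.asarray(net_charge(groups, grid)))
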
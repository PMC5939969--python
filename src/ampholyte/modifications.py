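"""Modified sequences and the charge effects of common PTMs.

Two modifications are modelled, following their standard treatment in
IEF-aware proteomics:

* **Phosphorylation** of Ser/Thr/Tyr adds a phosphate monoester, a diprotic
  acid.  Each site contributes two acidic ionizable groups with default pKas
  1.2 and 6.5 (overridable via the bundled modification-pKa data file), so at
  high pH a phosphosite carries −2.
* **N-terminal acetylation** caps the alpha-amino group: the N-terminal
  ionizable group is simply omitted from the enumeration, removing a positive
  charge.

Both effects can only lower a peptide's pI, which is what IEF experiments on
modified sub-populations observe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

from .errors import SequenceError, ValidationError

#: The 20 standard one-letter residue codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Degenerate / rare codes accepted in input but carrying no ionizable group.
DEGENERATE_RESIDUES = frozenset("BZXUO")
ALLOWED_RESIDUES = STANDARD_RESIDUES | DEGENERATE_RESIDUES

PHOSPHO_RESIDUES = frozenset("STY")

_ANNOTATION_RE = re.compile(r"^(?P<kind>[a-z]+)@(?P<where>nterm|\d+)$")


def normalize_residues(raw: str) -> str:
    """Uppercase a residue string and validate its alphabet.

    B/Z/X/U/O are accepted (they are treated as non-ionizable downstream);
    anything else raises :class:`SequenceError`.
    """
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    bad = sorted(set(seq) - ALLOWED_RESIDUES)
    if bad:
        raise SequenceError(f"illegal residue code(s) {bad!r} in sequence {raw!r}")
    return seq


@dataclass(frozen=True)
class ModifiedSequence:
    """A residue string plus modification annotations.

    ``phospho_sites`` are 1-based positions whose residue must be S, T or Y.
    This is the universal sequence input type: every predictor accepts either
    a plain ``str`` (no modifications) or a ``ModifiedSequence``.
    """

    residues: str
    phospho_sites: frozenset[int] = field(default_factory=frozenset)
    n_term_acetylated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))
        object.__setattr__(self, "phospho_sites", frozenset(self.phospho_sites))
        for pos in self.phospho_sites:
            if not 1 <= pos <= len(self.residues):
                raise SequenceError(
                    f"phospho site {pos} outside sequence of length {len(self.residues)}"
                )
            if self.residues[pos - 1] not in PHOSPHO_RESIDUES:
                raise SequenceError(
                    f"phospho site {pos} is {self.residues[pos - 1]!r}, "
                    "expected S, T or Y"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_modified(self) -> bool:
        return bool(self.phospho_sites) or self.n_term_acetylated

    def unmodified(self) -> "ModifiedSequence":
        """The same residue string with all modifications stripped."""
        return ModifiedSequence(self.residues)

    def annotation_string(self) -> str:
        """Serialize modifications in the ``phospho@3;acetyl@nterm`` dialect."""
        parts = [f"phospho@{p}" for p in sorted(self.phospho_sites)]
        if self.n_term_acetylated:
            parts.append("acetyl@nterm")
        return ";".join(parts)


def coerce_sequence(seq: "str | ModifiedSequence") -> ModifiedSequence:
    if isinstance(seq, ModifiedSequence):
        return seq
    return ModifiedSequence(seq)


def parse_annotations(residues: str, annotation: str | None) -> ModifiedSequence:
    """Parse a ``phospho@3;acetyl@nterm`` annotation string (strict dialect).

    An empty/None annotation yields an unmodified sequence.  Unknown
    modification kinds, malformed tokens, or a position on a non-S/T/Y residue
    raise :class:`SequenceError`.
    """
    if annotation is None or not str(annotation).strip():
        return ModifiedSequence(residues)
    phospho: set[int] = set()
    acetyl = False
    for token in str(annotation).split(";"):
        token = token.strip()
        if not token:
            continue
        m = _ANNOTATION_RE.match(token.lower())
        if m is None:
            raise SequenceError(f"malformed modification token {token!r}")
        kind, where = m.group("kind"), m.group("where")
        if kind == "phospho":
            if where == "nterm":
                raise SequenceError("phospho@nterm is not a valid site")
            phospho.add(int(where))
        elif kind == "acetyl":
            if where != "nterm":
                raise SequenceError("acetylation is modelled at the N-terminus only")
            acetyl = True
        else:
            raise SequenceError(f"unknown modification kind {kind!r}")
    return ModifiedSequence(residues, frozenset(phospho), acetyl)


# --- modification pKa table -------------------------------------------------

_DEFAULT_MOD_PKAS: dict[str, tuple[float, ...]] | None = None


def load_modification_pkas() -> dict[str, tuple[float, ...]]:
    """Site-type → acidic pKas, read from the bundled data file.

    Default: ``phospho`` → (1.2, 6.5), applied identically to S, T and Y
    sites (values are stated for S/T; Y reuses them, an explicit design
    choice documented in the data file).
    """
    global _DEFAULT_MOD_PKAS
    if _DEFAULT_MOD_PKAS is None:
        text = (resources.files("ampholyte.data") / "modifications.yaml").read_text()
        raw = yaml.safe_load(text)
        table: dict[str, tuple[float, ...]] = {}
        for name, entry in raw.items():
            pkas = tuple(float(x) for x in entry["pkas"])
            for v in pkas:
                if not 0.0 < v < 14.0:
                    raise ValidationError(
                        f"modification {name!r}: pKa {v} outside (0, 14)"
                    )
            if entry.get("polarity", "acid") != "acid":
                raise ValidationError(
                    f"modification {name!r}: only acidic modification groups "
                    "are supported"
                )
            table[name] = pkas
        _DEFAULT_MOD_PKAS = table
    return dict(_DEFAULT_MOD_PKAS)


def phospho_site_pkas() -> tuple[float, ...]:
    return load_modification_pkas()["phospho"]


def phospho_groups(seq: ModifiedSequence, site: int, pkas: Iterable[float] | None = None):
    """The two acidic ionizable groups contributed by one phosphosite.

    Raises :class:`ValidationError` if ``site`` is not annotated on ``seq``.
    Returns a list of :class:`~ampholyte.charge.IonizableGroup`.
    """
    from .charge import IonizableGroup  # local import: charge depends on this module

    if site not in seq.phospho_sites:
        raise ValidationError(f"position {site} is not an annotated phospho site")
    use = tuple(pkas) if pkas is not None else phospho_site_pkas()
    return [
        IonizableGroup(
            kind="modification",
            residue=f"phospho-{seq.residues[site - 1]}",
            position=site,
            polarity="acid",
            pka=float(p),
        )
        for p in use
    ]


def apply_acetylation(groups):
    """Drop the N-terminal group from a group enumeration; all else unchanged."""
    return [g for g in groups if g.kind != "n_term"]
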
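"""pKa basis sets, terminal variants and correction tables, served as data.

Every solver in the toolkit is parameterized by a named basis of
acid-dissociation constants rather than hard-coded values: the central
empirical finding this toolkit exists to probe is that pI accuracy is highly
sensitive to the choice of basis set, so swapping sets must be trivial.

Bundled sets live in ``ampholyte/data/*.yaml`` — one human-readable file per
set, each carrying its literature citation — and are validated on load.
Custom sets can be registered at runtime or loaded from user files with the
same format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import yaml

from .errors import DataFileError, RegistryConflictError, UnknownNameError, ValidationError

#: Residues that may carry an ionizable sidechain in any basis set.
IONIZABLE_SIDECHAINS = frozenset("CDEHKRY")
ACID_SIDECHAINS = frozenset("CDEY")
BASE_SIDECHAINS = frozenset("HKR")

_POSITIONAL_CONTEXTS = ("n-terminal", "c-terminal", "internal")


def _check_pka(value: float, what: str) -> float:
    value = float(value)
    if not 0.0 < value < 14.0:
        raise ValidationError(f"{what}: pKa {value} outside the open interval (0, 14)")
    return value


@dataclass(frozen=True)
class PkaSet:
    """A named basis of acid-dissociation constants.

    ``sidechain`` maps a subset of {C, D, E, H, K, R, Y} to pKa values; a
    missing key means that residue is treated as non-ionizable under this
    set (the Patrickios set, for instance, omits C, H and Y entirely).
    """

    name: str
    sidechain: Mapping[str, float]
    n_term: float
    c_term: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("PkaSet.name must be non-empty")
        bad = sorted(set(self.sidechain) - IONIZABLE_SIDECHAINS)
        if bad:
            raise ValidationError(
                f"set {self.name!r}: sidechain keys {bad!r} are not ionizable residues"
            )
        clean = {
            res: _check_pka(v, f"set {self.name!r}, sidechain {res}")
            for res, v in self.sidechain.items()
        }
        object.__setattr__(self, "sidechain", MappingProxyType(clean))
        object.__setattr__(self, "n_term", _check_pka(self.n_term, f"set {self.name!r}, n_term"))
        object.__setattr__(self, "c_term", _check_pka(self.c_term, f"set {self.name!r}, c_term"))

    def shifted(self, delta: float, name: str | None = None) -> "PkaSet":
        """A copy with every pKa shifted by ``delta`` (for perturbation tests)."""
        return PkaSet(
            name=name or f"{self.name}+{delta:g}",
            sidechain={r: v + delta for r, v in self.sidechain.items()},
            n_term=self.n_term + delta,
            c_term=self.c_term + delta,
            source=self.source,
        )

    def to_mapping(self) -> dict:
        return {
            "name": self.name,
            "source": self.source,
            "n_term": self.n_term,
            "c_term": self.c_term,
            "sidechain": dict(self.sidechain),
        }


@dataclass(frozen=True)
class TerminalVariant:
    """Position-dependent pKa tables for the Bjellqvist method.

    The alpha-amino/alpha-carboxyl pKa may depend on the identity of the
    first/last residue, and a sidechain pKa may depend on its positional
    context (n-terminal, c-terminal, internal). Any lookup without a
    positional entry falls back to the embedded base :class:`PkaSet`.
    """

    name: str
    base: PkaSet
    n_term_by_residue: Mapping[str, float] = field(default_factory=dict)
    c_term_by_residue: Mapping[str, float] = field(default_factory=dict)
    sidechain_positional: Mapping[tuple[str, str], float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        nt = {
            r: _check_pka(v, f"variant {self.name!r}, n_term[{r}]")
            for r, v in self.n_term_by_residue.items()
        }
        ct = {
            r: _check_pka(v, f"variant {self.name!r}, c_term[{r}]")
            for r, v in self.c_term_by_residue.items()
        }
        pos: dict[tuple[str, str], float] = {}
        for (res, ctx), v in dict(self.sidechain_positional).items():
            if ctx not in _POSITIONAL_CONTEXTS:
                raise ValidationError(
                    f"variant {self.name!r}: unknown positional context {ctx!r}"
                )
            pos[(res, ctx)] = _check_pka(v, f"variant {self.name!r}, {res}@{ctx}")
        object.__setattr__(self, "n_term_by_residue", MappingProxyType(nt))
        object.__setattr__(self, "c_term_by_residue", MappingProxyType(ct))
        object.__setattr__(self, "sidechain_positional", MappingProxyType(pos))

    def n_term_pka(self, first_residue: str) -> float:
        return self.n_term_by_residue.get(first_residue, self.base.n_term)

    def c_term_pka(self, last_residue: str) -> float:
        return self.c_term_by_residue.get(last_residue, self.base.c_term)

    def sidechain_pka(self, residue: str, context: str) -> float | None:
        """Positional lookup with internal fallback; None if non-ionizable."""
        if (residue, context) in self.sidechain_positional:
            return self.sidechain_positional[(residue, context)]
        if (residue, "internal") in self.sidechain_positional:
            return self.sidechain_positional[(residue, "internal")]
        return self.base.sidechain.get(residue)


@dataclass(frozen=True)
class CorrectionTable:
    """Sequence-context ΔpKa corrections for the Cofactor/Branca methods.

    ``entries`` maps (neighbor residue code, signed offset) to a ΔpKa; the
    offset is the neighbor's position minus the corrected group's position,
    bounded by ``window`` (3 for cofactor, 6 for branca). ``carboxyl_correction``
    (branca only) maps a (count of D, count of E) pattern to an additive term.
    Entries with zero ΔpKa are equivalent to absent entries.
    """

    method: str
    window: int
    entries: Mapping[tuple[str, int], float] = field(default_factory=dict)
    carboxyl_correction: Mapping[tuple[int, int], float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("cofactor", "branca"):
            raise ValidationError(f"unknown correction method {self.method!r}")
        clean = {}
        for (res, off), delta in dict(self.entries).items():
            off = int(off)
            if off == 0 or abs(off) > self.window:
                raise ValidationError(
                    f"{self.method} table: offset {off} outside ±{self.window} window"
                )
            if float(delta) != 0.0:  # zero entries are equivalent to absent ones
                clean[(res, off)] = float(delta)
        object.__setattr__(self, "entries", MappingProxyType(clean))
        cc = {
            (int(nd), int(ne)): float(d)
            for (nd, ne), d in dict(self.carboxyl_correction).items()
            if float(d) != 0.0
        }
        object.__setattr__(self, "carboxyl_correction", MappingProxyType(cc))

    def delta(self, residue: str, offset: int) -> float:
        return self.entries.get((residue, offset), 0.0)

    def carboxyl_delta(self, n_d: int, n_e: int) -> float:
        return self.carboxyl_correction.get((n_d, n_e), 0.0)


def zero_table(method: str, window: int | None = None) -> CorrectionTable:
    """An all-zero correction table (the reduction-to-iterative case)."""
    if window is None:
        window = 3 if method == "cofactor" else 6
    return CorrectionTable(method=method, window=window, source="all-zero table")


# --- serialization ----------------------------------------------------------

def serialize_set(pka_set: PkaSet) -> str:
    return yaml.safe_dump(pka_set.to_mapping(), sort_keys=True)


def parse_set(text: str, origin: str = "<string>") -> PkaSet:
    try:
        raw = yaml.safe_load(io.StringIO(text))
        return PkaSet(
            name=str(raw["name"]),
            sidechain={str(k).upper(): float(v) for k, v in (raw.get("sidechain") or {}).items()},
            n_term=float(raw["n_term"]),
            c_term=float(raw["c_term"]),
            source=str(raw.get("source", "")),
        )
    except ValidationError:
        raise
    except Exception as exc:  # malformed YAML / missing keys
        raise DataFileError(f"malformed pKa set file {origin}: {exc}") from exc


def _parse_variant(raw: dict, sets: Mapping[str, PkaSet], origin: str) -> TerminalVariant:
    try:
        base = sets[str(raw["base_set"]).lower()]
        pos = {
            (str(e["residue"]).upper(), str(e["context"])): float(e["pka"])
            for e in (raw.get("sidechain_positional") or [])
        }
        return TerminalVariant(
            name=str(raw["name"]),
            base=base,
            n_term_by_residue={str(k).upper(): float(v) for k, v in (raw.get("n_term_by_residue") or {}).items()},
            c_term_by_residue={str(k).upper(): float(v) for k, v in (raw.get("c_term_by_residue") or {}).items()},
            sidechain_positional=pos,
            source=str(raw.get("source", "")),
        )
    except ValidationError:
        raise
    except Exception as exc:
        raise DataFileError(f"malformed terminal-variant file {origin}: {exc}") from exc


def _parse_correction(raw: dict, origin: str) -> CorrectionTable:
    try:
        entries = {
            (str(e["residue"]).upper(), int(e["offset"])): float(e["delta"])
            for e in (raw.get("entries") or [])
        }
        cc = {
            (int(e["n_d"]), int(e["n_e"])): float(e["delta"])
            for e in (raw.get("carboxyl_correction") or [])
        }
        return CorrectionTable(
            method=str(raw["method"]),
            window=int(raw["window"]),
            entries=entries,
            carboxyl_correction=cc,
            source=str(raw.get("source", "")),
        )
    except ValidationError:
        raise
    except Exception as exc:
        raise DataFileError(f"malformed correction-table file {origin}: {exc}") from exc


# --- registry ---------------------------------------------------------------

_SET_FILES = (
    "solomon.yaml", "rodwell.yaml", "lehninger.yaml", "grimsley.yaml",
    "patrickios.yaml", "thurlkill.yaml", "toseland.yaml", "sillero.yaml",
    "emboss.yaml", "bjellqvist.yaml", "skoog_base.yaml",
)
_VARIANT_FILES = (
    "variant_default.yaml", "variant_expasy.yaml",
    "variant_calibrated.yaml", "variant_skoog.yaml",
)
_CORRECTION_FILES = {
    "cofactor": "cofactor_synthetic.yaml",
    "branca": "branca_synthetic.yaml",
}

_sets: dict[str, PkaSet] = {}
_variants: dict[str, TerminalVariant] = {}
_corrections: dict[str, CorrectionTable] = {}
_loaded = False


def _data_text(fname: str) -> str:
    return (resources.files("ampholyte.data") / fname).read_text()


def _ensure_loaded() -> None:
    global _loaded
    if _loaded:
        return
    for fname in _SET_FILES:
        s = parse_set(_data_text(fname), origin=fname)
        _sets[s.name.lower()] = s
    for fname in _VARIANT_FILES:
        raw = yaml.safe_load(_data_text(fname))
        v = _parse_variant(raw, _sets, origin=fname)
        _variants[v.name.lower()] = v
    for method, fname in _CORRECTION_FILES.items():
        t = _parse_correction(yaml.safe_load(_data_text(fname)), origin=fname)
        if t.method != method:
            raise DataFileError(f"{fname}: declares method {t.method!r}, expected {method!r}")
        _corrections[method] = t
    _loaded = True


def load_builtin_sets() -> dict[str, PkaSet]:
    """All bundled pKa sets, keyed by lowercase name."""
    _ensure_loaded()
    return dict(_sets)


def load_builtin_variants() -> dict[str, TerminalVariant]:
    _ensure_loaded()
    return dict(_variants)


def get_set(name: str) -> PkaSet:
    """Look up a registered pKa set by (case-insensitive) name."""
    _ensure_loaded()
    key = name.strip().lower()
    if key not in _sets:
        raise UnknownNameError(
            f"unknown pKa set {name!r}; registered: {', '.join(sorted(_sets))}"
        )
    return _sets[key]


def get_variant(name: str) -> TerminalVariant:
    _ensure_loaded()
    key = name.strip().lower()
    if key not in _variants:
        raise UnknownNameError(
            f"unknown terminal variant {name!r}; registered: {', '.join(sorted(_variants))}"
        )
    return _variants[key]


def get_correction_table(method: str) -> CorrectionTable:
    _ensure_loaded()
    key = method.strip().lower()
    if key not in _corrections:
        raise UnknownNameError(
            f"unknown correction table {method!r}; registered: {', '.join(sorted(_corrections))}"
        )
    return _corrections[key]


def register_set(pka_set: PkaSet, overwrite: bool = False) -> None:
    """Make a (validated) custom set retrievable by name.

    Construction of :class:`PkaSet` already enforces the invariants, so any
    instance passed here is valid.
    """
    _ensure_loaded()
    key = pka_set.name.strip().lower()
    if key in _sets and not overwrite:
        raise RegistryConflictError(
            f"pKa set {pka_set.name!r} already registered; pass overwrite=True to replace"
        )
    _sets[key] = pka_set


def register_set_from_file(path: str | Path, overwrite: bool = False) -> PkaSet:
    path = Path(path)
    s = parse_set(path.read_text(), origin=str(path))
    register_set(s, overwrite=overwrite)
    return s


def available_set_names() -> list[str]:
    _ensure_loaded()
    return sorted(_sets)


def available_variant_names() -> list[str]:
    _ensure_loaded()
    return sorted(_variants)
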
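"""Lipid shorthand nomenclature: parsing, canonical formatting and class → internal
standard resolution.

Lipid species are annotated at the summed-composition level, ``Class_(C:D)``, where
``C`` is the total number of fatty-acyl carbons and ``D`` the total number of
carbon–carbon double bonds.  Acyl-carnitines prefix the carbon count with ``C``
(``Carn_(C03:0)``) and count only the acyl chain, excluding the carnitine backbone.
Hydroxylated (``-OH``) and dicarboxylic (``-2COOH``) modifications are suffixed
inside the parentheses, and a single ether/plasmalogen dialect
(``PC_C18(plas)-18:1``) is supported.

Chain parity (odd/even total carbon count) is the working proxy for "contains an
odd-chain fatty acid": a summed composition with an odd total must contain at least
one odd-chain acyl group.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "LipidSpecies",
    "ClassISMap",
    "LipidNameError",
    "UnknownClassError",
    "KNOWN_CLASSES",
    "parse_lipid_name",
    "format_lipid_name",
    "chain_parity",
    "internal_standard_for",
]

#: Class abbreviations recognised by the parser.
KNOWN_CLASSES = frozenset({
    "Carn", "Cer", "CL", "DG", "FA", "GM1", "Hex-Cer", "LPC", "LPE", "LPI",
    "LPS", "Lyso_CL", "MG", "PA", "PC", "PE", "PG", "PI", "PS", "S", "SM", "TG",
})

#: Modifier tokens as they appear in names, mapped to canonical modifier labels.
_MODIFIERS = {"OH": "OH", "2COOH": "2COOH"}


class LipidNameError(ValueError):
    """A lipid name does not match any supported shorthand dialect."""


class UnknownClassError(LipidNameError):
    """A structurally valid name uses a class code that is not recognised."""


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed summed-composition lipid identity.

    ``carbon_width`` / ``db_width`` record the zero-padding used in the source
    name (e.g. ``CL_(66:02)``) so that formatting round-trips bit-identically.
    ``plasmalogen_head`` holds the sn-1 ether chain length for the plasmalogen
    dialect.
    """

    class_code: str
    total_carbons: int
    double_bonds: int
    modifiers: frozenset[str] = frozenset()
    raw_name: str = ""
    carbon_width: int = field(default=0, compare=False)
    db_width: int = field(default=0, compare=False)
    plasmalogen_head: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.total_carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbon and double-bond counts must be non-negative")


# class alternation sorted longest-first so Hex-Cer wins over Cer, Lyso_CL over CL
_CLASS_ALT = "|".join(re.escape(c) for c in sorted(KNOWN_CLASSES, key=len, reverse=True))
_NAME_RE = re.compile(
    rf"(?P<cls>{_CLASS_ALT}|[A-Za-z][\w-]*?)_\("
    r"(?P<cpfx>C)?(?P<c>\d+):(?P<d>\d+)(?:-(?P<mod>[A-Za-z0-9]+))?\)"
)
_PLAS_RE = re.compile(
    rf"(?P<cls>{_CLASS_ALT}|[A-Za-z][\w-]*?)_C(?P<head>\d+)\(plas\)-(?P<c>\d+):(?P<d>\d+)"
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Raises :class:`LipidNameError` for malformed names (naming the offending
    token) and :class:`UnknownClassError` for unrecognised class codes.
    """
    raw = name
    name = name.strip()
    m = _PLAS_RE.fullmatch(name)
    if m:
        cls = m.group("cls")
        if cls not in KNOWN_CLASSES:
            raise UnknownClassError(f"unknown lipid class {cls!r} in {raw!r}")
        head, tail = int(m.group("head")), int(m.group("c"))
        return LipidSpecies(
            class_code=cls,
            total_carbons=head + tail,
            double_bonds=int(m.group("d")),
            modifiers=frozenset({"plasmalogen"}),
            raw_name=raw,
            carbon_width=len(m.group("c")),
            db_width=len(m.group("d")),
            plasmalogen_head=head,
        )
    m = _NAME_RE.fullmatch(name)
    if m is None:
        raise LipidNameError(f"malformed lipid name: {raw!r}")
    cls = m.group("cls")
    if cls not in KNOWN_CLASSES:
        raise UnknownClassError(f"unknown lipid class {cls!r} in {raw!r}")
    if (m.group("cpfx") is not None) != (cls == "Carn"):
        token = f"{m.group('cpfx') or ''}{m.group('c')}"
        raise LipidNameError(
            f"carbon token {token!r} in {raw!r}: the 'C' prefix is used by "
            "acyl-carnitine names only"
        )
    modifiers: frozenset[str] = frozenset()
    if m.group("mod") is not None:
        mod = _MODIFIERS.get(m.group("mod"))
        if mod is None:
            raise LipidNameError(f"unknown modifier token {m.group('mod')!r} in {raw!r}")
        modifiers = frozenset({mod})
    return LipidSpecies(
        class_code=cls,
        total_carbons=int(m.group("c")),
        double_bonds=int(m.group("d")),
        modifiers=modifiers,
        raw_name=raw,
        carbon_width=len(m.group("c")),
        db_width=len(m.group("d")),
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; the inverse of :func:`parse_lipid_name`."""
    if "plasmalogen" in species.modifiers:
        tail = species.total_carbons - species.plasmalogen_head
        return (f"{species.class_code}_C{species.plasmalogen_head}(plas)-"
                f"{tail}:{species.double_bonds}")
    c_width = species.carbon_width or (2 if species.class_code == "Carn" else 1)
    carbons = f"{species.total_carbons:0{c_width}d}"
    if species.class_code == "Carn":
        carbons = "C" + carbons
    dbs = f"{species.double_bonds:0{species.db_width or 1}d}"
    mod = ""
    for token, label in _MODIFIERS.items():
        if label in species.modifiers:
            mod = f"-{token}"
    return f"{species.class_code}_({carbons}:{dbs}{mod})"


def chain_parity(species: LipidSpecies) -> str:
    """``"odd"`` or ``"even"`` by the summed fatty-acyl carbon count."""
    return "odd" if species.total_carbons % 2 else "even"


@dataclass(frozen=True)
class ClassISMap:
    """Mapping of lipid class code to its quantitation internal standard(s).

    Acyl-carnitines carry two standards (short- and long-chain); all other
    classes carry exactly one.  ``carnitine_cutoff`` is the largest acyl chain
    length quantified against the short-chain carnitine standard.
    """

    standards: Mapping[str, tuple[str, ...]]
    adducts: Mapping[str, tuple[str, ...]]
    carnitine_cutoff: int = 8

    @classmethod
    def from_csv(cls, path=None, carnitine_cutoff: int = 8) -> "ClassISMap":
        """Load the class map from a CSV (default: the packaged transcription)."""
        if path is None:
            ref = resources.files("lipiddose.data").joinpath("class_is_map.csv")
            with ref.open(newline="") as fh:
                rows = list(csv.DictReader(fh))
        else:
            with open(path, newline="") as fh:
                rows = list(csv.DictReader(fh))
        standards = {}
        adducts = {}
        for row in rows:
            code = row["class_code"]
            standards[code] = tuple(s.strip() for s in row["internal_standard"].split(";"))
            adducts[code] = tuple(a.strip() for a in row["adducts"].split(";"))
        return cls(standards=standards, adducts=adducts, carnitine_cutoff=carnitine_cutoff)


def internal_standard_for(species: LipidSpecies, mapping: ClassISMap) -> str:
    """Resolve the single internal standard used to quantify ``species``.

    Acyl-carnitines resolve by chain length: acyl carbons ≤ the map's cutoff go
    to the short-chain standard, longer chains to the long-chain standard.
    """
    try:
        candidates = mapping.standards[species.class_code]
    except KeyError:
        raise KeyError(
            f"no internal standard configured for lipid class {species.class_code!r}"
        ) from None
    if len(candidates) == 1:
        return candidates[0]
    if species.class_code == "Carn":
        short, long = candidates
        return short if species.total_carbons <= mapping.carnitine_cutoff else long
    raise ValueError(
        f"ambiguous internal standard for class {species.class_code!r}: {candidates}"
    )
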
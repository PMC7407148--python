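"""Monoisotopic mass, adduct and deuterium-isotopologue m/z computation.

Internal standards are stable-isotope (deuterium) labelled lipids.  Each
standard's extracted-ion-chromatogram target set combines several singly charged
adducts ([M+H]+, [M+H−H2O]+, [M+NH4]+, [M+Na]+, [M+K]+, [M−H]−) and, for heavily
labelled standards, deuterium-loss isotopologues spaced by m(D) − m(H) ≈
1.006277 Da (synthesis leaves a distribution of label counts, and some positions
are exchange-labile).  Analyte (endogenous lipid) targets are supplied directly
as m/z lists; only standards are computed from elemental formulas.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ATOMIC_MASSES",
    "DEUTERIUM_SHIFT",
    "PROTON_MASS",
    "ADDUCTS",
    "ElementalFormula",
    "AdductSpec",
    "InternalStandard",
    "MzTarget",
    "monoisotopic_mass",
    "adduct_mz",
    "isotopologue_series",
    "load_standards",
    "load_analytes",
    "build_target_list",
]

# Monoisotopic atomic masses (Da), pinned for bit-stable arithmetic.
ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "D": 2.0141017780,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
}

#: Mass shift of one H → D substitution (Da).
DEUTERIUM_SHIFT = ATOMIC_MASSES["D"] - ATOMIC_MASSES["H"]

#: Proton mass (Da); the electron-corrected charge-carrier convention.
PROTON_MASS = 1.007276

_WATER = 18.010565  # monoisotopic H2O


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ionisation product: label, polarity and mass delta."""

    label: str
    polarity: str  # "+ve" | "-ve"
    mass_delta: float

    def __post_init__(self) -> None:
        sign = self.label.rstrip()[-1]
        if (sign == "+") != (self.polarity == "+ve"):
            raise ValueError(f"polarity {self.polarity!r} inconsistent with {self.label!r}")


ADDUCTS: Mapping[str, AdductSpec] = {
    a.label: a
    for a in (
        AdductSpec("[M+H]+", "+ve", PROTON_MASS),
        AdductSpec("[M+H-H2O]+", "+ve", PROTON_MASS - _WATER),
        AdductSpec("[M+NH4]+", "+ve", 18.033823),
        AdductSpec("[M+Na]+", "+ve", 22.989218),
        AdductSpec("[M+K]+", "+ve", 38.963158),
        AdductSpec("[M-H]-", "-ve", -PROTON_MASS),
    )
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts plus a count of H positions carrying deuterium."""

    counts: Mapping[str, int]
    n_deuterium: int = 0

    def __post_init__(self) -> None:
        unsupported = sorted(set(self.counts) - set(ATOMIC_MASSES))
        if unsupported:
            raise ValueError(f"unsupported element(s): {', '.join(unsupported)}")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("element counts must be non-negative")
        if self.n_deuterium < 0:
            raise ValueError("n_deuterium must be non-negative")
        if self.n_deuterium > self.counts.get("H", 0):
            raise ValueError(
                f"n_deuterium ({self.n_deuterium}) exceeds hydrogen count "
                f"({self.counts.get('H', 0)})"
            )

    @classmethod
    def parse(cls, formula: str, n_deuterium: int = 0) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C11H21NO4"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        return cls(counts=counts, n_deuterium=n_deuterium)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass (Da), including the deuterium substitutions."""
    mass = sum(ATOMIC_MASSES[el] * n for el, n in formula.counts.items())
    return mass + formula.n_deuterium * DEUTERIUM_SHIFT


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of a singly charged adduct of a neutral molecule."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    return neutral_mass + adduct.mass_delta


def isotopologue_series(base_mz: float, n_down: int) -> list[float]:
    """m/z series obtained by swapping 0..n_down deuteriums back to hydrogen."""
    if n_down < 0:
        raise ValueError("n_down must be >= 0")
    return [base_mz - k * DEUTERIUM_SHIFT for k in range(n_down + 1)]


@dataclass(frozen=True)
class InternalStandard:
    """A labelled standard with its configured EIC product assignments.

    ``products`` is a sequence of (adduct label, deuterium count) pairs, one per
    EIC target ion; ``printed_mz`` carries the corresponding reference values
    from the packaged transcription (used by verification tests, not by the
    pipeline).  ``primary`` designates the reference product used for mass
    verification.
    """

    id: str
    formula: ElementalFormula
    polarity: str
    expected_rt: float
    products: tuple[tuple[str, int], ...]
    printed_mz: tuple[float, ...] = ()
    primary: tuple[str, int, float] | None = None  # (adduct, n_D, printed m/z)

    def product_mz(self, adduct: str, n_deuterium: int) -> float:
        """m/z of one product, computed from the elemental formula."""
        base = monoisotopic_mass(
            ElementalFormula(self.formula.counts, n_deuterium=n_deuterium)
        )
        return adduct_mz(base, adduct)

    def product_mzs(self) -> list[tuple[float, str]]:
        """All configured EIC products as (m/z, polarity) pairs."""
        return [
            (self.product_mz(adduct, n_d), ADDUCTS[adduct].polarity)
            for adduct, n_d in self.products
        ]


@dataclass(frozen=True)
class MzTarget:
    """One analyte's EIC target: ion products plus an expected retention time."""

    analyte_id: str
    products: tuple[tuple[float, str], ...]  # (m/z, polarity)
    expected_rt: float
    rt_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError(f"empty product list for {self.analyte_id!r}")
        for mz, _pol in self.products:
            if not 100.0 <= mz <= 1800.0:
                raise ValueError(
                    f"product m/z {mz:.4f} of {self.analyte_id!r} outside the "
                    "instrument scan range [100, 1800]"
                )


def _parse_products(spec: str) -> tuple[tuple[str, int], ...]:
    out = []
    for token in spec.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            adduct, n_d = token.rsplit("@", 1)
        except ValueError:
            raise ValueError(f"bad product token {token!r}; expected 'adduct@nD'")
        if adduct not in ADDUCTS:
            raise ValueError(f"unknown adduct {adduct!r} in product token {token!r}")
        out.append((adduct, int(n_d)))
    return tuple(out)


def load_standards(path=None) -> dict[str, InternalStandard]:
    """Load internal standards (default: the packaged configuration)."""
    if path is None:
        ref = resources.files("lipiddose.data").joinpath("internal_standards.csv")
        with ref.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    standards = {}
    for row in rows:
        formula = ElementalFormula.parse(row["formula"], n_deuterium=int(row["n_deuterium"]))
        printed = tuple(
            float(x) for x in row.get("printed_mz", "").split(";") if x.strip()
        )
        primary = None
        if row.get("primary_adduct"):
            primary = (
                row["primary_adduct"],
                int(row["primary_n_deuterium"]),
                float(row["primary_printed_mz"]),
            )
        standards[row["id"]] = InternalStandard(
            id=row["id"],
            formula=formula,
            polarity=row["polarity"],
            expected_rt=float(row["expected_rt"]),
            products=_parse_products(row["products"]),
            printed_mz=printed,
            primary=primary,
        )
    return standards


def load_analytes(path) -> list[dict]:
    """Read an analyte target CSV: name, mz_list (';'-separated), polarity, expected_rt."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    required = {"name", "mz_list", "polarity", "expected_rt"}
    for row in rows:
        missing = required - set(row)
        if missing:
            raise ValueError(f"analyte CSV missing column(s): {sorted(missing)}")
    return rows


def build_target_list(
    standards_csv=None,
    analytes_csv=None,
    rt_tolerance: float = 0.1,
) -> dict[str, MzTarget]:
    """Combine standards (computed from formulas) and analytes (explicit m/z lists)
    into one EIC target set."""
    targets: dict[str, MzTarget] = {}
    for std in load_standards(standards_csv).values():
        targets[std.id] = MzTarget(
            analyte_id=std.id,
            products=tuple(std.product_mzs()),
            expected_rt=std.expected_rt,
            rt_tolerance=rt_tolerance,
        )
    if analytes_csv is not None:
        for row in load_analytes(analytes_csv):
            polarity = row["polarity"]
            products = tuple(
                (float(x), polarity) for x in row["mz_list"].split(";") if x.strip()
            )
            targets[row["name"]] = MzTarget(
                analyte_id=row["name"],
                products=products,
                expected_rt=float(row["expected_rt"]),
                rt_tolerance=rt_tolerance,
            )
    return targets
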
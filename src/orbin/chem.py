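"""Exact-mass bookkeeping for derivatized amino-acid fragment ions.

The method measures the 15N/14N ratio of an electron-impact fragment of an
N-trifluoroacetyl amino-acid methyl ester directly from the resolved
isotopologue peaks (unsubstituted, single-15N, single-13C).  Everything here
is therefore single-substitution arithmetic: monoisotopic mass of the base
composition, plus one 15N-14N or 13C-12C mass difference, divided by charge.

Atomic constants are pinned in one table so printed-mass comparisons are
reproducible.  Values are CODATA/AME monoisotopic masses in Da.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterator, Mapping

import yaml

#: Principal-isotope monoisotopic masses (Da).
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.0,
        "H": 1.00782503,
        "N": 14.00307401,
        "O": 15.99491462,
        "F": 18.99840316,
        "S": 31.97207117,
    }
)

ELECTRON_MASS = 0.00054858  # Da

#: Single-substitution mass differences (Da).
DELTA_15N = 0.99703489  # 15N - 14N
DELTA_13C = 1.00335484  # 13C - 12C

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """An element symbol without a pinned monoisotopic mass."""


class CompositionError(ValueError):
    """An elemental composition violating its invariants."""


@dataclass(frozen=True)
class ElementalComposition:
    """Non-negative element counts of the *unsubstituted* fragment.

    Isotopic substitutions are never folded into the composition; they are
    applied afterwards through :func:`substituted_mass`.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for symbol, count in self.counts.items():
            if symbol not in MONOISOTOPIC_MASS:
                raise UnknownElementError(
                    f"no monoisotopic mass pinned for element {symbol!r}"
                )
            if count < 0 or int(count) != count:
                raise CompositionError(
                    f"count for {symbol} must be a non-negative integer, got {count!r}"
                )
            if count > 0:
                clean[symbol] = int(count)
        if not clean:
            raise CompositionError("composition must contain at least one atom")
        object.__setattr__(self, "counts", MappingProxyType(clean))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-notation formula string such as ``"C3H3F3NO"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise CompositionError(
                    f"cannot parse formula {formula!r} at position {pos}"
                )
            pos = match.end()
            symbol, digits = match.groups()
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        if pos != len(formula) or not counts:
            raise CompositionError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def formula(self) -> str:
        """Hill notation: C, H, then alphabetical."""
        order = sorted(
            self.counts, key=lambda s: (s != "C", s != "H", s)
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in order
        )

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for symbol, count in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return ElementalComposition(merged)


def monoisotopic_mass(composition: ElementalComposition, charge: int) -> float:
    """Monoisotopic m/z of the unsubstituted ion.

    For cations the electron mass is subtracted per removed electron.  A
    charge of 0 returns the neutral monoisotopic mass.
    """
    if charge < 0:
        raise ValueError("charge must be >= 0 (anions are not modelled)")
    mass = sum(
        count * MONOISOTOPIC_MASS[symbol]
        for symbol, count in composition.counts.items()
    )
    mass -= charge * ELECTRON_MASS
    return mass / max(charge, 1)


def substituted_mass(
    composition: ElementalComposition, charge: int, substitution: str
) -> float:
    """m/z of the single-substitution isotopologue (``"15N"`` or ``"13C"``)."""
    if substitution == "15N":
        element, delta = "N", DELTA_15N
    elif substitution == "13C":
        element, delta = "C", DELTA_13C
    else:
        raise ValueError(f"unknown substitution {substitution!r}; use '15N' or '13C'")
    if composition[element] < 1:
        raise CompositionError(
            f"composition {composition.formula()} has no {element} atom to substitute"
        )
    return monoisotopic_mass(composition, charge) + delta / max(charge, 1)


@dataclass(frozen=True)
class FragmentDef:
    """A targeted fragment ion and its scan window.

    ``printed_masses`` optionally carries published (base, 15N, 13C) m/z
    values for cross-checks; the authoritative masses are always computed
    from the composition and the pinned constants.
    """

    name: str
    composition: ElementalComposition
    charge: int
    scan_range: tuple[float, float]
    printed_masses: tuple[float, float, float] | None = None
    base_mass: float = field(init=False)
    mass_15N: float = field(init=False)
    mass_13C: float = field(init=False)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("fragment charge must be a positive integer")
        low, high = self.scan_range
        if not low < high:
            raise ValueError(f"scan_range low must be < high, got {self.scan_range}")
        object.__setattr__(
            self, "base_mass", monoisotopic_mass(self.composition, self.charge)
        )
        object.__setattr__(
            self, "mass_15N", substituted_mass(self.composition, self.charge, "15N")
        )
        object.__setattr__(
            self, "mass_13C", substituted_mass(self.composition, self.charge, "13C")
        )
        for mass in (self.base_mass, self.mass_15N, self.mass_13C):
            if not low <= mass <= high:
                raise ValueError(
                    f"{self.name}: isotopologue m/z {mass:.5f} outside scan range "
                    f"{self.scan_range}"
                )


def required_resolution(fragment: FragmentDef) -> float:
    """m/Δm needed to separate the 15N peak from the heavier 13C peak."""
    return fragment.mass_15N / (fragment.mass_13C - fragment.mass_15N)


def is_resolvable(fragment: FragmentDef, resolution_setting: float = 60_000.0) -> bool:
    """Whether the 15N/13C doublet is resolved at the configured setting.

    The resolution setting is defined at m/z 200 and falls off as 1/sqrt(m/z)
    on Orbitrap analyzers; the comparison uses the setting scaled to the
    fragment's own m/z.
    """
    at_mass = resolution_setting * (200.0 / fragment.mass_15N) ** 0.5
    return required_resolution(fragment) < at_mass


# Published Table of targeted fragments: N-TFA amino-acid methyl esters after
# loss of the methoxycarbonyl radical (·COOCH3) under 70 eV electron impact.
# Printed masses are retained as annotation; small (<2e-4 Da) discrepancies
# against computed values reflect unstated constants in the source table.
_BUILTIN = [
    ("Glycine", "C3H3F3NO", (121.0, 131.0), (126.01612, 127.01334, 127.01943)),
    ("beta-alanine", "C4H4F3NO", (134.0, 144.0), (139.02400, 140.02130, 140.02744)),
    ("DL-alanine", "C4H5F3NO", (135.0, 145.0), (140.03178, 141.02901, 141.03513)),
    ("DL-valine", "C6H9F3NO", (163.0, 173.0), (168.06299, 169.06018, 169.06630)),
    ("alpha-AIB", "C5H7F3NO", (149.0, 159.0), (154.04742, 155.04457, 155.05069)),
]


def builtin_fragments() -> list[FragmentDef]:
    """The five built-in derivatized amino-acid fragment definitions."""
    return [
        FragmentDef(
            name=name,
            composition=ElementalComposition.from_formula(formula),
            charge=1,
            scan_range=scan_range,
            printed_masses=printed,
        )
        for name, formula, scan_range, printed in _BUILTIN
    ]


def _normalize_name(name: str) -> str:
    # unify unicode dashes, case, and separator style
    for dash in "‐‑‒–—−":
        name = name.replace(dash, "-")
    return name.lower().replace("_", "-").replace(" ", "-").replace("α", "alpha").replace(
        "β", "beta"
    )


def get_fragment(name: str) -> FragmentDef:
    """Look up a built-in fragment by (dash/case-insensitive) name."""
    wanted = _normalize_name(name)
    for fragment in builtin_fragments():
        if _normalize_name(fragment.name) == wanted:
            return fragment
    known = ", ".join(entry[0] for entry in _BUILTIN)
    raise KeyError(f"unknown fragment {name!r}; built-ins: {known}")


def fragments_from_config(path: str | Path) -> list[FragmentDef]:
    """Load fragment definitions from a YAML/JSON config file.

    Each entry needs ``name``, ``formula`` (Hill notation), ``charge`` and
    ``scan_range`` ([low, high] in Da).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    fragments = []
    for entry in data:
        fragments.append(
            FragmentDef(
                name=entry["name"],
                composition=ElementalComposition.from_formula(entry["formula"]),
                charge=int(entry["charge"]),
                scan_range=(float(entry["scan_range"][0]), float(entry["scan_range"][1])),
            )
        )
    return fragments
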
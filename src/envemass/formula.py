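"""Chemical formulas over C, H, N, O, S and their closed-form mass moments.

A protein is treated as a point in the 5-dimensional space of atom counts.
Integer points are real molecules; fractional points arise from averagine
arithmetic and support the same closed-form moments (which are linear in
the counts), but cannot be expanded into an isotopic distribution until
rounded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

from .constants import DEFAULT_ISOTOPES, ELEMENTS, IsotopeTable

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """Atom counts per element, restricted to C, H, N, O, S.

    Counts may be fractional (averagine arithmetic) but never negative.
    """

    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        clean: Dict[str, float] = {}
        for element, count in self.counts.items():
            if element not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if count < 0:
                raise ValueError(f"negative count for {element}: {count}")
            if count != 0:
                clean[element] = count
        object.__setattr__(self, "counts", clean)

    # -- construction -------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ChemicalFormula":
        """Parse a Hill-like element+count string such as ``C254H377N65O75S6``.

        An omitted count means one atom.  Repeated element symbols accumulate.
        """
        if not text or not text.strip():
            raise ValueError("empty formula string")
        pos = 0
        counts: Dict[str, float] = {}
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"malformed formula near {text[pos:]!r}")
            element, digits = match.groups()
            if element not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {element!r}")
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"malformed formula near {text[pos:]!r}")
        return cls(counts)

    # -- presentation --------------------------------------------------

    def __str__(self) -> str:
        parts = []
        for element in ELEMENTS:
            n = self.counts.get(element, 0)
            if n:
                if n != int(n):
                    parts.append(f"{element}{n:g}")
                else:
                    parts.append(element + (str(int(n)) if n != 1 else ""))
        return "".join(parts)

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    def __iter__(self) -> Iterator[str]:
        return iter(e for e in ELEMENTS if e in self.counts)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    @property
    def is_integral(self) -> bool:
        return all(float(n).is_integer() for n in self.counts.values())

    def total_atoms(self) -> float:
        return sum(self.counts.values())

    # -- arithmetic in molecule space ---------------------------------

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            counts[element] = counts.get(element, 0) + n
        return ChemicalFormula(counts)

    def scaled(self, factor: float) -> "ChemicalFormula":
        return ChemicalFormula({e: n * factor for e, n in self.counts.items()})

    def rounded(self) -> "ChemicalFormula":
        return ChemicalFormula({e: round(n) for e, n in self.counts.items()})

    def replace(self, element: str, count: float) -> "ChemicalFormula":
        counts = dict(self.counts)
        counts[element] = count
        return ChemicalFormula(counts)

    # -- closed-form mass moments -------------------------------------

    def monoisotopic_mass(self, table: IsotopeTable = DEFAULT_ISOTOPES) -> float:
        """Mass of the all-lightest-isotopes variant (requires integer counts)."""
        self._require_nonempty()
        return sum(n * table.lightest_mass(e) for e, n in self.counts.items())

    def average_mass(self, table: IsotopeTable = DEFAULT_ISOTOPES) -> float:
        """Abundance-weighted mean mass; linear in the counts."""
        self._require_nonempty()
        return sum(n * table.mean_mass(e) for e, n in self.counts.items())

    def spectrum_variance(self, table: IsotopeTable = DEFAULT_ISOTOPES) -> float:
        """Variance of the isotopologue mass distribution.

        Atoms draw their isotopes independently, so the variance is the sum
        of per-atom isotope-mass variances.
        """
        self._require_nonempty()
        return sum(n * table.mass_variance(e) for e, n in self.counts.items())

    def _require_nonempty(self):
        if self.is_empty:
            raise ValueError("empty chemical formula")


def parse_formula(text: str) -> ChemicalFormula:
    """Module-level convenience alias for :meth:`ChemicalFormula.parse`."""
    return ChemicalFormula.parse(text)
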
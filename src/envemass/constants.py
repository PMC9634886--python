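"""Physical constants: the pinned isotope table for C, H, N, O, S.

The whole package computes against a single embedded isotope table so that
every printed mass is reproducible.  The values are the NIST standard
isotope masses and natural abundances (the same table `pyteomics` ships);
a different table can be supplied through :func:`load_isotope_table` for
users who need to match another convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

#: Element order used for every 5-vector over molecule space.
ELEMENTS: Tuple[str, ...] = ("C", "H", "N", "O", "S")

#: Mass of a proton in Da (CODATA); used to reduce m/z to neutral mass in
#: positive-ion mode.
PROTON_MASS: float = 1.007276466812

# (isotope mass in Da, natural abundance), sorted by mass, NIST.
_NIST_TABLE: Dict[str, List[Tuple[float, float]]] = {
    "C": [(12.0000000000, 0.9893), (13.0033548378, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177780, 0.000115)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317000, 0.00038), (17.9991610000, 0.00205)],
    "S": [(31.9720710000, 0.9499), (32.9714587600, 0.0075), (33.9678669000, 0.0425),
          (35.9670808800, 0.0001)],
}


class IsotopeTable:
    """Per-element isotope masses and abundances, plus derived per-atom moments.

    Abundances of each element must sum to one (within 1e-9) and masses must
    be strictly increasing.
    """

    def __init__(self, table: Dict[str, List[Tuple[float, float]]]):
        for element, pairs in table.items():
            masses = [m for m, _ in pairs]
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {element} sum to {total!r}, expected 1"
                )
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {element} not increasing")
        self._table = {e: list(pairs) for e, pairs in table.items()}

    def __contains__(self, element: str) -> bool:
        return element in self._table

    def isotopes(self, element: str) -> List[Tuple[float, float]]:
        return list(self._table[element])

    def lightest_mass(self, element: str) -> float:
        return self._table[element][0][0]

    def mean_mass(self, element: str) -> float:
        return sum(m * a for m, a in self._table[element])

    def mass_variance(self, element: str) -> float:
        """Variance of the isotope-mass distribution of a single atom."""
        mu = self.mean_mass(element)
        return sum(a * (m - mu) ** 2 for m, a in self._table[element])

    def mean_extra_mass(self, element: str) -> float:
        """Expected mass above the lightest isotope for a single atom."""
        return self.mean_mass(element) - self.lightest_mass(element)

    def nucleon_offsets(self, element: str) -> List[int]:
        """Neutron count of each isotope relative to the lightest one."""
        base = round(self._table[element][0][0])
        return [round(m) - base for m, _ in self._table[element]]


#: The default table every computation uses unless told otherwise.
DEFAULT_ISOTOPES = IsotopeTable(_NIST_TABLE)


def load_isotope_table(path: str | Path) -> IsotopeTable:
    """Read an isotope table override from a whitespace-delimited text file.

    Each non-comment line is ``element isotope_mass abundance``.  Lines for
    the same element accumulate; validation matches the embedded table.
    """
    raw: Dict[str, List[Tuple[float, float]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(f"malformed isotope-table line: {line!r}")
        element, mass, abundance = fields[0], float(fields[1]), float(fields[2])
        raw.setdefault(element, []).append((mass, abundance))
    for element in raw:
        raw[element].sort()
    table = IsotopeTable(raw)
    for element in ELEMENTS:
        if element not in table:
            raise ValueError(f"isotope table misses element {element}")
    return table


def neutron_spacing(table: IsotopeTable = DEFAULT_ISOTOPES) -> float:
    """Rough inter-cluster spacing: the 13C-12C mass difference."""
    c = table.isotopes("C")
    return c[1][0] - c[0][0]
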
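"""Aggregated isotopic distributions of molecules.

Isotopologues that share a total nucleon count are aggregated into a single
cluster; clusters are ~1 Da apart and each is represented by one centroid
peak carrying the summed probability and the probability-weighted mean mass
of its fine structure.  The computation is a per-element polynomial
convolution over the extra-neutron count, carried out by binary
exponentiation with tail pruning, which keeps even 400 kDa proteins cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .constants import DEFAULT_ISOTOPES, IsotopeTable
from .formula import ChemicalFormula

#: States below this relative probability are dropped during convolution.
PRUNE_THRESHOLD = 1e-12


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Centroided aggregated isotope pattern: (mass Da, probability) peaks.

    Masses are strictly increasing; probabilities are positive and sum to at
    most one.  ``coverage`` records the summed probability retained when the
    spectrum was trimmed.
    """

    masses: np.ndarray
    probs: np.ndarray
    coverage: float = 1.0

    def __post_init__(self):
        masses = np.asarray(self.masses, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if masses.ndim != 1 or masses.shape != probs.shape:
            raise ValueError("masses and probs must be matching 1-D arrays")
        if masses.size and np.any(np.diff(masses) <= 0):
            raise ValueError("peak masses must be strictly increasing")
        if np.any(probs <= 0):
            raise ValueError("peak probabilities must be positive")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.masses.size

    # Normalized view: probabilities as a proper distribution.
    @property
    def normalized_probs(self) -> np.ndarray:
        return self.probs / self.probs.sum()

    def moments(self) -> Tuple[float, float]:
        """Probability-weighted mean and central variance of the peaks."""
        if not len(self):
            raise ValueError("empty spectrum")
        p = self.normalized_probs
        mean = float(np.dot(p, self.masses))
        var = float(np.dot(p, (self.masses - mean) ** 2))
        return mean, var

    def most_abundant_peak(self) -> Tuple[float, float]:
        """The maximal-probability peak; ties resolve to the lower mass."""
        if not len(self):
            raise ValueError("empty spectrum")
        i = int(np.argmax(self.probs))  # argmax returns the first maximum
        return float(self.masses[i]), float(self.probs[i])

    def shifted(self, offset: float) -> "TheoreticalSpectrum":
        return TheoreticalSpectrum(self.masses + offset, self.probs, self.coverage)

    def trimmed(self, coverage: float, boundary: str = "fractional") -> "TheoreticalSpectrum":
        """Keep the most probable peaks until ``coverage`` probability is retained.

        ``boundary='fractional'`` (default) keeps the crossing peak with only
        the probability needed to make the retained total exactly equal to
        ``coverage``, emulating truncation at the fine-structure level where
        the outermost cluster is only partially retained.  ``'whole'`` keeps
        the crossing peak in full.
        """
        if not 0 < coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        total = self.probs.sum()
        if coverage >= total:
            return self
        target = coverage
        order = np.argsort(self.probs, kind="stable")[::-1]
        csum = np.cumsum(self.probs[order])
        k = int(np.searchsorted(csum, target))
        weights = np.zeros_like(self.probs)
        weights[order[:k]] = self.probs[order[:k]]
        if k < order.size:
            shortfall = target - (csum[k - 1] if k else 0.0)
            if boundary == "whole":
                weights[order[k]] = self.probs[order[k]]
            elif boundary == "fractional":
                weights[order[k]] = shortfall
            else:
                raise ValueError(f"unknown boundary mode: {boundary!r}")
        keep = weights > 0
        return TheoreticalSpectrum(
            self.masses[keep], weights[keep], float(weights.sum())
        )


def _prune(probs: np.ndarray, mass_moment: np.ndarray, offset: int):
    keep = probs > probs.max() * PRUNE_THRESHOLD
    lo = int(np.argmax(keep))
    hi = int(len(keep) - np.argmax(keep[::-1]))
    return probs[lo:hi], mass_moment[lo:hi], offset + lo


def _convolve(a, b):
    """Convolve two aggregated distributions.

    Each operand is (probs, mass_moment, offset): probability per
    extra-neutron index and the corresponding probability-weighted mean-mass
    moment (prob * conditional mean).  The mass moment of a sum of
    independent contributions convolves as p_a*m_b + m_a*p_b.
    """
    pa, ma, oa = a
    pb, mb, ob = b
    p = np.convolve(pa, pb)
    m = np.convolve(ma, pb) + np.convolve(pa, mb)
    return _prune(p, m, oa + ob)


def _element_distribution(element: str, n: int, table: IsotopeTable):
    """Aggregated distribution of ``n`` atoms of one element (multinomial)."""
    offsets = table.nucleon_offsets(element)
    size = max(offsets) + 1
    p1 = np.zeros(size)
    m1 = np.zeros(size)
    for (mass, abundance), idx in zip(table.isotopes(element), offsets):
        p1[idx] += abundance
        m1[idx] += abundance * mass
    result = (np.array([1.0]), np.array([0.0]), 0)
    base = (p1, m1, 0)
    k = n
    while k:
        if k & 1:
            result = _convolve(result, base)
        k >>= 1
        if k:
            base = _convolve(base, base)
    return result


def aggregated_spectrum(
    formula: ChemicalFormula,
    coverage: float = 0.99,
    table: IsotopeTable = DEFAULT_ISOTOPES,
    boundary: str = "fractional",
) -> TheoreticalSpectrum:
    """Aggregated isotope pattern of an integer formula.

    Peaks are grouped by total nucleon count; each centroid is the
    probability-weighted mean mass of its cluster.  The most probable peaks
    are retained until their summed probability reaches ``coverage`` (see
    :meth:`TheoreticalSpectrum.trimmed`), and returned sorted by mass.
    """
    if formula.is_empty:
        raise ValueError("empty chemical formula")
    if not formula.is_integral:
        raise ValueError(
            "aggregated spectra need integer atom counts; round averagine "
            "formulas before expanding them"
        )
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    acc = (np.array([1.0]), np.array([0.0]), 0)
    for element in formula:
        acc = _convolve(acc, _element_distribution(element, int(formula[element]), table))
    probs, mass_moment, _ = acc
    centroids = mass_moment / probs
    # pruning loses ~1e-12 of the mass; renormalize to a proper distribution
    spectrum = TheoreticalSpectrum(centroids, probs / probs.sum())
    if coverage < 1.0:
        spectrum = spectrum.trimmed(coverage, boundary=boundary)
    return spectrum
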
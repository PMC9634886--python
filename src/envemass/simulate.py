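"""Synthetic proteome and spectrum generation.

Stands in for sampling real protein records: formulas are built by scaling
the averagine unit to a target average mass, dispersing each element count
with an independent multiplicative log-normal factor (the knob controlling
how strongly composition varies at fixed mass), rounding, and rebalancing
hydrogen.  Noisy "experimental" spectra add multiplicative intensity noise
and per-peak ppm mass jitter to the theoretical pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .averagine import AveragineModel
from .constants import DEFAULT_ISOTOPES, ELEMENTS, PROTON_MASS
from .formula import ChemicalFormula
from .isotopes import TheoreticalSpectrum, aggregated_spectrum
from .spectrum import AXIS_DALTON, AXIS_MZ, ExperimentalSpectrum

DEFAULT_MASS_RANGE = (8_000.0, 400_000.0)
DEFAULT_DISPERSION = 0.03


@dataclass(frozen=True)
class SyntheticProtein:
    """A synthetic protein: formula, true monoisotopic mass, spectrum moments.

    ``m_avg`` and ``m_var`` are the moments of the coverage-trimmed
    aggregated spectrum — the quantities the predictor actually sees —
    not the closed-form formula moments.
    """

    formula: ChemicalFormula
    m_mono: float
    m_avg: float
    m_var: float
    coverage: float

    def spectrum(self, boundary: str = "fractional") -> TheoreticalSpectrum:
        """Regenerate the aggregated spectrum this protein was scored with."""
        return aggregated_spectrum(self.formula, self.coverage, boundary=boundary)


def generate_protein(
    target_avg: float,
    dispersion: float = DEFAULT_DISPERSION,
    rng: Optional[np.random.Generator] = None,
    averagine: Optional[AveragineModel] = None,
    coverage: float = 0.99,
    max_retries: int = 10,
) -> SyntheticProtein:
    """One protein-like formula near a target average mass.

    Element counts are the averagine scaling multiplied by independent
    log-normal factors with log-sd ``dispersion``, rounded to integers;
    hydrogen is then rebalanced so the average mass returns to within half
    a hydrogen of the target.
    """
    if rng is None:
        rng = np.random.default_rng()
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    averagine = averagine or AveragineModel.default()
    table = averagine.table
    n_units = target_avg / averagine.unit_avg_mass
    if n_units < 1:
        raise ValueError("target mass below one averagine unit")
    for _ in range(max_retries):
        factors = rng.lognormal(mean=0.0, sigma=dispersion, size=len(ELEMENTS))
        counts = {
            e: averagine.unit[e] * n_units * f for e, f in zip(ELEMENTS, factors)
        }
        formula = ChemicalFormula(counts).rounded()
        h_shift = round(
            (target_avg - formula.average_mass(table)) / table.mean_mass("H")
        )
        new_h = formula["H"] + h_shift
        if new_h < 0 or formula.is_empty:
            continue
        formula = formula.replace("H", new_h)
        spectrum = aggregated_spectrum(formula, coverage, table)
        m_avg, m_var = spectrum.moments()
        return SyntheticProtein(
            formula=formula,
            m_mono=formula.monoisotopic_mass(table),
            m_avg=m_avg,
            m_var=m_var,
            coverage=coverage,
        )
    raise RuntimeError("could not generate a feasible formula")


def sample_proteome(
    n: int,
    seed: int | np.random.Generator = 0,
    mass_range: Tuple[float, float] = DEFAULT_MASS_RANGE,
    dispersion: float = DEFAULT_DISPERSION,
    averagine: Optional[AveragineModel] = None,
    coverage: float = 0.99,
) -> List[SyntheticProtein]:
    """Proteins with average masses log-uniform over ``mass_range``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = np.log(mass_range[0]), np.log(mass_range[1])
    return [
        generate_protein(
            float(np.exp(rng.uniform(lo, hi))), dispersion, rng, averagine, coverage
        )
        for _ in range(n)
    ]


def noisy_spectrum(
    spectrum: TheoreticalSpectrum,
    rng: Optional[np.random.Generator] = None,
    intensity_cv: float = 0.05,
    mass_jitter_ppm: float = 2.0,
    axis: str = AXIS_DALTON,
    charge: Optional[int] = None,
    scale: float = 1e6,
) -> ExperimentalSpectrum:
    """Degrade a theoretical pattern into a synthetic experimental spectrum.

    Intensities are multiplied by independent log-normal factors with the
    requested coefficient of variation; each peak position receives
    independent Gaussian jitter with the requested ppm standard deviation.
    With ``axis='mz'`` the peaks are re-expressed at the given charge state
    (positive-ion protonation).
    """
    if rng is None:
        rng = np.random.default_rng()
    masses = spectrum.masses.copy()
    if mass_jitter_ppm > 0:
        masses = masses * (1 + rng.normal(0.0, mass_jitter_ppm * 1e-6, masses.size))
    intensities = spectrum.normalized_probs * scale
    if intensity_cv > 0:
        sigma = np.sqrt(np.log1p(intensity_cv**2))
        intensities = intensities * rng.lognormal(0.0, sigma, intensities.size)
    order = np.argsort(masses)
    masses, intensities = masses[order], intensities[order]
    if axis == AXIS_MZ:
        if not charge or charge < 1:
            raise ValueError("charge required for an m/z spectrum")
        positions = masses / charge + PROTON_MASS
    else:
        positions = masses
    return ExperimentalSpectrum(positions, intensities, axis, charge)


def comb_spectrum(
    n_peaks: int = 12,
    zeta: float = 1.0023,
    delta: float = 0.3,
    start_index: int = 10_000,
    jitter: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    weights: Optional[Sequence[float]] = None,
) -> TheoreticalSpectrum:
    """Exactly periodic comb {delta + k*zeta}, optionally jittered.

    ``jitter`` is a multiplicative position perturbation (uniform within
    +/- jitter), useful for testing period recovery under imperfection.
    """
    k = np.arange(start_index, start_index + n_peaks)
    masses = delta + k * zeta
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        masses = masses * (1 + rng.uniform(-jitter, jitter, masses.size))
        masses = np.sort(masses)
    if weights is None:
        # smooth envelope roughly like an isotope pattern
        center = (n_peaks - 1) / 2
        w = np.exp(-0.5 * ((np.arange(n_peaks) - center) / (n_peaks / 4)) ** 2)
    else:
        w = np.asarray(weights, dtype=float)
    return TheoreticalSpectrum(masses, w / w.sum())
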
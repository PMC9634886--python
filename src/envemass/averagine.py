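"""Averagine scaling and Wasserstein matching of candidate spectra.

The averagine unit is a hypothetical mean amino-acid residue with fractional
CHNOS composition.  Scaling it to a target average mass gives a surrogate
formula for an unknown protein; displacing the fractional formula along the
variance-adjustment direction (the spectral-variance gradient projected
orthogonally to the average-mass gradient) reshapes the envelope width
without moving its average mass.  Candidates built this way, shifted over
the experimental envelope in whole grid steps, are scored by Wasserstein
distance and the best-scoring one stands in for the unknown molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_ISOTOPES, ELEMENTS, IsotopeTable
from .formula import ChemicalFormula
from .isotopes import TheoreticalSpectrum, aggregated_spectrum
from .spectrum import NormalizedSpectrum, wasserstein

#: Senko's classic averagine composition per 111.1254 Da residue.
SENKO_RATIOS = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}

#: Average mass of one averagine residue in Da.
UNIT_AVG_MASS = 110.4728


def derive_variance_direction(table: IsotopeTable = DEFAULT_ISOTOPES) -> np.ndarray:
    """Unit 5-vector that changes spectral variance fastest at fixed average mass.

    The gradient of the molecule's spectral variance with respect to atom
    counts is the vector of per-atom isotope-mass variances; projecting it
    orthogonally to the gradient of the average mass (the per-atom mean
    masses) and normalizing yields the steepest mass-preserving direction.
    """
    v = np.array([table.mass_variance(e) for e in ELEMENTS])
    mbar = np.array([table.mean_mass(e) for e in ELEMENTS])
    projected = v - (v @ mbar) / (mbar @ mbar) * mbar
    norm = np.linalg.norm(projected)
    if norm < 1e-12:
        raise ValueError("variance gradient is parallel to the mass gradient")
    return projected / norm


def derive_phase_direction(
    table: IsotopeTable = DEFAULT_ISOTOPES,
    support: Tuple[str, ...] = ("C", "N", "O"),
) -> np.ndarray:
    """Unit 5-vector that shifts the isotope comb under the envelope.

    Moving a formula along this direction changes the expected
    mean-minus-monoisotopic offset (where the cluster comb sits relative to
    the envelope) while leaving both the average mass and the spectral
    variance exactly unchanged: it spans the nullspace of the average-mass
    and variance gradients restricted to ``support``.  Sulfur is excluded
    by default because its huge per-atom variance makes integer rounding
    along any S-bearing direction noisy, and hydrogen is reserved for mass
    rebalancing; the result is a C/N vs O exchange.
    """
    idx = [ELEMENTS.index(e) for e in support]
    mbar = np.array([table.mean_mass(e) for e in ELEMENTS])
    vvar = np.array([table.mass_variance(e) for e in ELEMENTS])
    constraints = np.stack([mbar[idx], vvar[idx]])
    _, singular, vt = np.linalg.svd(constraints, full_matrices=True)
    null = vt[len(singular):]
    if null.shape[0] != 1:
        raise ValueError("phase direction requires a 1-D nullspace; widen support")
    direction = np.zeros(len(ELEMENTS))
    direction[idx] = null[0]
    a = np.array([table.mean_extra_mass(e) for e in ELEMENTS])
    slope = a @ direction
    if abs(slope) < 1e-12:
        raise ValueError("offset gradient lies in the mass/variance span")
    if slope < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


@dataclass(frozen=True)
class AveragineModel:
    """Fractional averagine unit plus the spectrum-shaping directions."""

    unit: ChemicalFormula
    unit_avg_mass: float
    variance_direction: np.ndarray
    table: IsotopeTable = DEFAULT_ISOTOPES
    phase_direction: np.ndarray | None = None

    def __post_init__(self):
        if abs(self.unit.average_mass(self.table) - self.unit_avg_mass) > 1e-4:
            raise ValueError("unit composition and unit_avg_mass disagree")
        direction = np.asarray(self.variance_direction, dtype=float)
        if direction.shape != (len(ELEMENTS),):
            raise ValueError("variance_direction must be a 5-vector over CHNOS")
        object.__setattr__(self, "variance_direction", direction)
        phase = self.phase_direction
        if phase is None:
            phase = derive_phase_direction(self.table)
        phase = np.asarray(phase, dtype=float)
        if phase.shape != (len(ELEMENTS),):
            raise ValueError("phase_direction must be a 5-vector over CHNOS")
        object.__setattr__(self, "phase_direction", phase)

    @classmethod
    def default(cls, table: IsotopeTable = DEFAULT_ISOTOPES) -> "AveragineModel":
        """Senko's ratios rescaled uniformly to a 110.4728 Da average unit."""
        raw = ChemicalFormula(SENKO_RATIOS)
        unit = raw.scaled(UNIT_AVG_MASS / raw.average_mass(table))
        return cls(unit, UNIT_AVG_MASS, derive_variance_direction(table), table)

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], table: IsotopeTable = DEFAULT_ISOTOPES
    ) -> "AveragineModel":
        """Re-derive the unit as the mean residue composition of a sequence set."""
        from pyteomics import mass as _pmass

        totals: Dict[str, float] = {e: 0.0 for e in ELEMENTS}
        n_residues = 0
        for seq in sequences:
            for residue in seq.strip().upper():
                comp = _pmass.std_aa_comp.get(residue)
                if comp is None:
                    continue  # skip gaps/ambiguity codes
                for element, count in comp.items():
                    if element in totals:
                        totals[element] += count
                n_residues += 1
        if n_residues == 0:
            raise ValueError("no standard residues found")
        unit = ChemicalFormula({e: c / n_residues for e, c in totals.items() if c})
        return cls(unit, unit.average_mass(table), derive_variance_direction(table), table)

    @classmethod
    def from_fasta(cls, path, table: IsotopeTable = DEFAULT_ISOTOPES) -> "AveragineModel":
        from pyteomics import fasta

        with fasta.read(str(path)) as reader:
            return cls.from_sequences((entry.sequence for entry in reader), table)


def scale_averagine(
    target_avg: float,
    model: AveragineModel,
    rho: float = 0.0,
    tau: float = 0.0,
    max_clip: float = 1.0,
) -> ChemicalFormula:
    """Integer surrogate formula with a given average mass and envelope width.

    The fractional unit is multiplied up to the target average mass, the
    variance-adjustment direction scaled by ``rho`` (and optionally the
    phase-adjustment direction scaled by ``tau``) is added before rounding,
    entries are clipped at zero, counts are rounded, and the hydrogen count
    is rebalanced so the average mass lands within half a hydrogen of the
    target.
    """
    table = model.table
    if target_avg < model.unit_avg_mass:
        raise ValueError("target average mass below one averagine unit")
    n_units = target_avg / model.unit_avg_mass
    counts = {}
    for element, v_comp, p_comp in zip(
        ELEMENTS, model.variance_direction, model.phase_direction
    ):
        value = model.unit[element] * n_units + rho * v_comp + tau * p_comp
        if value < -max_clip:
            raise ValueError(
                f"(rho={rho}, tau={tau}) drives {element} to {value:.2f}; "
                "clipping budget exceeded"
            )
        counts[element] = max(value, 0.0)
    formula = ChemicalFormula(counts).rounded()
    h_mean = table.mean_mass("H")
    h_shift = round((target_avg - formula.average_mass(table)) / h_mean)
    new_h = formula["H"] + h_shift
    if new_h < 0:
        raise ValueError("hydrogen rebalancing made the count negative")
    return formula.replace("H", new_h)


def _shaped_formula(
    target_avg: float,
    model: AveragineModel,
    rho: float,
    tau: float,
    max_clip: float = 1.0,
) -> ChemicalFormula:
    """Integer candidate formula with rounding-compensated comb alignment.

    Like :func:`scale_averagine`, but after rounding, the error that
    rounding introduced in the mean-minus-monoisotopic offset (dominated by
    the half-atom of sulfur the rho direction can gain or lose) is repaired
    by a small extra step along the phase direction, which only touches
    C/N/O and therefore rounds quietly.  Keeps the Wasserstein objective
    smooth enough to optimize.
    """
    table = model.table
    if target_avg < model.unit_avg_mass:
        raise ValueError("target average mass below one averagine unit")
    n_units = target_avg / model.unit_avg_mass
    a = np.array([table.mean_extra_mass(e) for e in ELEMENTS])
    slope = float(a @ model.phase_direction)
    frac = np.array(
        [
            model.unit[e] * n_units + rho * v + tau * p
            for e, v, p in zip(ELEMENTS, model.variance_direction, model.phase_direction)
        ]
    )
    if np.any(frac < -max_clip):
        raise ValueError(f"(rho={rho}, tau={tau}) exceeds the clipping budget")
    frac = np.clip(frac, 0.0, None)
    counts = np.round(frac)
    for _ in range(2):  # alignment repair; converges immediately in practice
        offset_err = float(a @ (counts - frac))
        counts = np.round(frac - (offset_err / slope) * model.phase_direction)
    if np.any(counts < 0):
        raise ValueError("alignment repair drove an element count negative")
    formula = ChemicalFormula(dict(zip(ELEMENTS, counts)))
    h_shift = round((target_avg - formula.average_mass(table)) / table.mean_mass("H"))
    new_h = formula["H"] + h_shift
    if new_h < 0:
        raise ValueError("hydrogen rebalancing made the count negative")
    return formula.replace("H", new_h)


@dataclass(frozen=True)
class CandidateSpectrum:
    """A positioned, shape-adjusted averagine spectrum and its score."""

    k: int
    rho: float
    formula: ChemicalFormula
    spectrum: TheoreticalSpectrum
    w_dist: float
    shift: float
    tau: float = 0.0


def position_candidate(
    exp: NormalizedSpectrum,
    formula: ChemicalFormula,
    k: int,
    zeta: float,
    coverage: float = 0.99,
    table: IsotopeTable = DEFAULT_ISOTOPES,
    rho: float = 0.0,
    tau: float = 0.0,
    spectrum: Optional[TheoreticalSpectrum] = None,
) -> CandidateSpectrum:
    """Rigidly place a candidate spectrum over the experimental envelope.

    The anchor is the candidate's first aggregated peak at or below its own
    average mass; for k = 0 the anchor lands exactly on the experimental
    most abundant peak, and each k step slides the whole spectrum by
    k * zeta Da.
    """
    if spectrum is None:
        spectrum = aggregated_spectrum(formula, coverage, table)
    if not len(spectrum):
        raise ValueError("candidate spectrum is empty")
    mean, _ = spectrum.moments()
    below = np.nonzero(spectrum.masses <= mean)[0]
    anchor = spectrum.masses[below[-1]] if below.size else spectrum.masses[0]
    exp_mab, _ = exp.most_abundant_peak()
    shift = exp_mab + k * zeta - anchor
    placed = spectrum.shifted(shift)
    w = wasserstein(exp, placed)
    return CandidateSpectrum(k, rho, formula, placed, w, shift, tau)


def fit_candidate(
    exp: NormalizedSpectrum,
    model: AveragineModel,
    zeta: float,
    k_range: Sequence[int] = tuple(range(-3, 9)),
    rho_bound: Optional[float] = None,
    tau_bound: Optional[float] = None,
    coverage: float = 0.99,
    rho_tol: float = 1e-3,
    n_coarse: int = 33,
    n_descent: int = 2,
) -> CandidateSpectrum:
    """Wasserstein-optimal candidate over shifts k and shape parameters.

    For each integer shift k the candidate shape is optimized by coordinate
    descent over the two mass-preserving directions: rho (envelope width)
    and tau (position of the isotope comb under the envelope).  Each 1-D
    pass is a coarse scan over the bounded interval followed by bounded
    scalar minimization around the best coarse point — rounding to integer
    formulas makes the objective piecewise constant, so the scan guards the
    local refinement.  The winning candidate over all k is returned.
    Deterministic given inputs.
    """
    if not len(k_range):
        raise ValueError("empty k range")
    target_avg, _ = exp.moments()
    n_units = target_avg / model.unit_avg_mass
    if rho_bound is None:
        rho_bound = 0.05 * n_units
    if tau_bound is None:
        tau_bound = 0.3 * n_units
    spectra_cache: Dict[Tuple, TheoreticalSpectrum] = {}

    # The descent runs in decoupled coordinates (u, t): all spectral
    # functionals are exactly linear in atom counts, so compensating each
    # unit of rho with `coupling` units of tau makes the u axis change the
    # variance at a fixed comb-under-envelope alignment, while the t axis
    # changes only the alignment.  Plain (rho, tau) axes both move the
    # alignment, which traps coordinate descent in a diagonal valley.
    a = np.array([model.table.mean_extra_mass(e) for e in ELEMENTS])
    coupling = float((a @ model.variance_direction) / (a @ model.phase_direction))

    def candidate_for(k: int, u: float, t: float) -> Optional[CandidateSpectrum]:
        rho = u
        tau = t - coupling * u
        try:
            formula = _shaped_formula(target_avg, model, rho, tau)
        except ValueError:
            return None
        key = tuple(sorted(formula.counts.items()))
        spectrum = spectra_cache.get(key)
        if spectrum is None:
            spectrum = aggregated_spectrum(formula, coverage, model.table)
            spectra_cache[key] = spectrum
        return position_candidate(
            exp, formula, k, zeta, coverage, model.table,
            rho=rho, tau=tau, spectrum=spectrum,
        )

    from scipy.optimize import minimize_scalar

    def line_search(k, u, t, axis):
        """Best (w_dist, u, t) along one decoupled axis: scan then refine."""
        bound = rho_bound if axis == "u" else tau_bound

        def at(x):
            return candidate_for(k, x, t) if axis == "u" else candidate_for(k, u, x)

        grid = np.linspace(-bound, bound, n_coarse)
        coarse = [(c.w_dist, x) for x in grid if (c := at(x)) is not None]
        if not coarse:
            return None
        _, center = min(coarse)
        step = grid[1] - grid[0] if n_coarse > 1 else bound
        result = minimize_scalar(
            lambda x: (c.w_dist if (c := at(x)) else 1e6),  # finite infeasible penalty
            bounds=(center - step, center + step),
            method="bounded",
            options={"xatol": rho_tol},
        )
        candidates = [(w, x) for w, x in coarse] + [
            (c.w_dist, float(result.x))
            for c in (at(float(result.x)),)
            if c is not None
        ]
        w_best, x_best = min(candidates)
        return (w_best, x_best, t) if axis == "u" else (w_best, u, x_best)

    best: Optional[CandidateSpectrum] = None
    for k in sorted(k_range):
        u, t = 0.0, 0.0
        current = candidate_for(k, u, t)
        for _ in range(n_descent):
            for axis in ("t", "u"):  # align the comb first, then fit the width
                probe = line_search(k, u, t, axis)
                if probe is None:
                    continue
                w_probe, u_probe, t_probe = probe
                if current is None or w_probe < current.w_dist:
                    u, t = u_probe, t_probe
                    current = candidate_for(k, u, t)
        if current is not None and (best is None or current.w_dist < best.w_dist):
            best = current
    if best is None:
        raise RuntimeError("no candidate spectrum could be simulated")
    return best
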
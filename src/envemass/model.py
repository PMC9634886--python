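"""Monoisotopic mass determination, packaged as a model / results pair.

:class:`MonoisotopicModel` wraps one single-analyte spectrum — either a
noise-free theoretical isotope pattern or an experimental peak list — and
``fit()`` runs the two-stage prediction:

1. an initial linear estimate from the spectrum's average mass and variance,
2. rounding of that estimate to the grid of candidate monoisotopic
   positions (step from the universal linear law, phase from the circular
   mean of the spectrum), with a small relative recentering.

Experimental spectra get a preparatory stage: a variance-adjusted, shifted
averagine spectrum is matched to the envelope by Wasserstein distance, and
the prediction runs on that simulated spectrum, whose moments are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .averagine import AveragineModel, CandidateSpectrum, fit_candidate
from .config import PredictorCoefficients, RunConfig
from .constants import DEFAULT_ISOTOPES
from .formula import ChemicalFormula
from .grid import GridModel, estimate_delta, round_to_grid, universal_zeta
from .isotopes import TheoreticalSpectrum, aggregated_spectrum
from .spectrum import ExperimentalSpectrum, NormalizedSpectrum, read_peaklist


def initial_estimate(m_avg: float, m_var: float, coef: PredictorCoefficients) -> float:
    """Linear first guess: beta0 + beta_avg * M_avg + beta_var * M_var."""
    if m_avg < 0 or m_var < 0:
        raise ValueError("moments must be non-negative")
    return coef.beta0 + coef.beta_avg * m_avg + coef.beta_var * m_var


@dataclass(frozen=True)
class MonoisotopicResults:
    """Outcome of a fit: the mass estimate with its construction trail."""

    m_mono: float
    m_initial: float
    m_avg: float
    m_var: float
    grid: GridModel
    candidate: Optional[CandidateSpectrum] = None
    n_peaks: int = 0

    @property
    def rounding_shift(self) -> float:
        return self.m_mono - self.m_initial

    def to_dict(self) -> dict:
        record = {
            "m_mono": self.m_mono,
            "m_initial": self.m_initial,
            "m_avg": self.m_avg,
            "m_var": self.m_var,
            "zeta": self.grid.zeta,
            "delta": self.grid.delta,
            "lambda": self.grid.lambda_corr,
            "n_peaks": self.n_peaks,
        }
        if self.candidate is not None:
            record.update(
                k_best=self.candidate.k,
                rho_best=self.candidate.rho,
                w_best=self.candidate.w_dist,
                candidate_formula=str(self.candidate.formula),
            )
        return record

    def plot(self, spectrum=None, ax=None):
        """Stick plot of the envelope, the matched candidate (if any) and
        the predicted monoisotopic position.

        ``spectrum`` is the input spectrum to draw under the candidate;
        pass the model's spectrum for a diagnostic overlay akin to a
        matched-spectra figure.  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        if spectrum is not None:
            probs = getattr(spectrum, "normalized_probs", None)
            positions = getattr(spectrum, "masses", None)
            if positions is None:
                positions = spectrum.positions
                probs = spectrum.intensities / spectrum.intensities.max()
            ax.vlines(positions, 0, probs / probs.max(), color="C0", label="spectrum")
        if self.candidate is not None:
            cand = self.candidate.spectrum
            p = cand.normalized_probs
            ax.vlines(
                cand.masses, 0, -p / p.max(), color="C1", label="matched candidate"
            )
        ax.axvline(self.m_mono, color="C3", linestyle="--", label="predicted $M_{mono}$")
        ax.set_xlabel("mass [Da]")
        ax.set_ylabel("relative intensity")
        ax.legend(loc="best", fontsize="small")
        return ax

    def summary(self) -> str:
        rows = [
            ("monoisotopic mass [Da]", f"{self.m_mono:.4f}"),
            ("initial estimate [Da]", f"{self.m_initial:.4f}"),
            ("average mass M_avg [Da]", f"{self.m_avg:.4f}"),
            ("spectrum variance M_var [Da^2]", f"{self.m_var:.4f}"),
            ("grid step zeta [Da]", f"{self.grid.zeta:.7f}"),
            ("grid shift delta [Da]", f"{self.grid.delta:+.6f}"),
            ("lambda correction", f"{self.grid.lambda_corr:.4e}"),
            ("peaks used", str(self.n_peaks)),
        ]
        if self.candidate is not None:
            rows += [
                ("candidate shift k", str(self.candidate.k)),
                ("candidate rho", f"{self.candidate.rho:.3f}"),
                ("candidate formula", str(self.candidate.formula)),
                ("Wasserstein distance [Da]", f"{self.candidate.w_dist:.5f}"),
            ]
        width = max(len(name) for name, _ in rows)
        lines = ["Monoisotopic mass determination", "=" * 34]
        lines += [f"{name.ljust(width)}  {value}" for name, value in rows]
        return "\n".join(lines)


class MonoisotopicModel:
    """Predicts the monoisotopic mass of the analyte behind one spectrum.

    Parameters
    ----------
    spectrum:
        A :class:`TheoreticalSpectrum` (noise-free pattern, used directly)
        or an :class:`ExperimentalSpectrum` (matched by an averagine
        candidate first).
    config:
        Coefficients and search settings; defaults to the shipped profile.
    averagine:
        Averagine model for the experimental route.
    """

    def __init__(
        self,
        spectrum: Union[TheoreticalSpectrum, ExperimentalSpectrum],
        config: RunConfig = RunConfig(),
        averagine: Optional[AveragineModel] = None,
    ):
        self.spectrum = spectrum
        self.config = config
        self.averagine = averagine or AveragineModel.default()
        self.is_experimental = isinstance(spectrum, ExperimentalSpectrum)
        n = len(spectrum)
        if self.is_experimental and n < 3:
            raise ValueError("experimental spectra need at least three peaks")
        if not self.is_experimental and n < 2:
            raise ValueError("theoretical spectra need at least two peaks")

    # -- constructors --------------------------------------------------

    @classmethod
    def from_formula(
        cls,
        formula: Union[str, ChemicalFormula],
        config: RunConfig = RunConfig(),
        table=DEFAULT_ISOTOPES,
    ) -> "MonoisotopicModel":
        """Model for the theoretical spectrum of a known chemical formula."""
        if isinstance(formula, str):
            formula = ChemicalFormula.parse(formula)
        spectrum = aggregated_spectrum(
            formula, config.coverage, table, boundary=config.boundary
        )
        return cls(spectrum, config)

    @classmethod
    def from_peaklist(
        cls,
        source,
        axis: str = "dalton",
        charge: Optional[int] = None,
        config: RunConfig = RunConfig(),
        averagine: Optional[AveragineModel] = None,
    ) -> "MonoisotopicModel":
        spectrum = read_peaklist(source, axis=axis, charge=charge)
        return cls(spectrum, config, averagine)

    # -- fitting -------------------------------------------------------

    def fit(self) -> MonoisotopicResults:
        if self.is_experimental:
            return self._fit_experimental()
        return self._fit_theoretical(self.spectrum, candidate=None)

    def _fit_theoretical(
        self, spectrum, candidate: Optional[CandidateSpectrum]
    ) -> MonoisotopicResults:
        coef = self.config.coefficients
        m_avg, m_var = spectrum.moments()
        zeta = universal_zeta(m_avg, coef.gamma0, coef.gamma_avg)
        delta = estimate_delta(spectrum, zeta)
        grid = GridModel(zeta, delta, coef.lambda_corr, self.config.lambda_mode)
        m_init = initial_estimate(m_avg, m_var, coef)
        m_final = round_to_grid(m_init, grid)
        return MonoisotopicResults(
            m_mono=m_final,
            m_initial=m_init,
            m_avg=m_avg,
            m_var=m_var,
            grid=grid,
            candidate=candidate,
            n_peaks=len(spectrum),
        )

    def _fit_experimental(self) -> MonoisotopicResults:
        coef = self.config.coefficients
        exp = self.spectrum.to_dalton()
        if self.config.min_rel_intensity > 0:
            exp = exp.filtered(self.config.min_rel_intensity)
        norm = exp.normalize()
        exp_avg, _ = norm.moments()
        # gamma_avg is tiny, so the noisy experimental average mass is good
        # enough to fix the grid step used for candidate placement
        zeta = universal_zeta(exp_avg, coef.gamma0, coef.gamma_avg)
        candidate = fit_candidate(
            norm,
            self.averagine,
            zeta,
            k_range=self.config.k_range,
            rho_bound=self.config.rho_bound_scale * exp_avg / self.averagine.unit_avg_mass,
            coverage=self.config.coverage,
            rho_tol=self.config.rho_tol,
        )
        return self._fit_theoretical(candidate.spectrum, candidate)


def predict_theoretical(
    spectrum: TheoreticalSpectrum, config: RunConfig = RunConfig()
) -> MonoisotopicResults:
    """Functional shorthand for the theoretical-spectrum route."""
    return MonoisotopicModel(spectrum, config).fit()


def predict_experimental(
    spectrum: ExperimentalSpectrum,
    config: RunConfig = RunConfig(),
    averagine: Optional[AveragineModel] = None,
) -> MonoisotopicResults:
    """Functional shorthand for the experimental-spectrum route."""
    return MonoisotopicModel(spectrum, config, averagine).fit()
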
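import numpy as np
import pytest

from envemass import (
    AveragineModel,
    DEFAULT_ISOTOPES,
    ELEMENTS,
    aggregated_spectrum,
    derive_variance_direction,
    fit_candidate,
    position_candidate,
    scale_averagine,
)
from envemass.averagine import UNIT_AVG_MASS
from envemass.formula import ChemicalFormula


class TestVarianceDirection:
    def test_orthogonal_to_mean_mass_vector(self):
        direction = derive_variance_direction()
        mbar = np.array([DEFAULT_ISOTOPES.mean_mass(e) for e in ELEMENTS])
        assert abs(direction @ mbar) < 1e-9

    def test_unit_norm(self):
        assert np.linalg.norm(derive_variance_direction()) == pytest.approx(1.0)

    def test_sulfur_dominates(self):
        """Sulfur has by far the largest per-atom isotopic variance, so it
        must carry the largest positive component."""
        direction = dict(zip(ELEMENTS, derive_variance_direction()))
        assert direction["S"] > 0
        assert direction["S"] == max(direction.values())

    def test_first_order_effect_on_fractional_formula(self):
        """Moving along the direction changes the variance at the advertised
        rate and leaves the average mass untouched (both are linear)."""
        base = ChemicalFormula({"C": 500.0, "H": 800.0, "N": 130.0, "O": 150.0, "S": 5.0})
        direction = derive_variance_direction()
        eps = 0.37
        moved = ChemicalFormula(
            {e: base[e] + eps * d for e, d in zip(ELEMENTS, direction)}
        )
        assert moved.average_mass() == pytest.approx(base.average_mass(), abs=1e-8)
        v = np.array([DEFAULT_ISOTOPES.mass_variance(e) for e in ELEMENTS])
        assert moved.spectrum_variance() - base.spectrum_variance() == pytest.approx(
            eps * float(v @ direction), rel=1e-9
        )


class TestAveragineModel:
    def test_default_unit_average_mass(self, averagine):
        assert averagine.unit.average_mass() == pytest.approx(UNIT_AVG_MASS, abs=1e-6)

    def test_inconsistent_unit_mass_rejected(self):
        unit = ChemicalFormula({"C": 5.0, "H": 8.0, "N": 1.4, "O": 1.5})
        with pytest.raises(ValueError, match="disagree"):
            AveragineModel(unit, 200.0, derive_variance_direction())

    def test_from_sequences_single_glycine(self):
        # a glycine residue is C2H3NO
        model = AveragineModel.from_sequences(["G"])
        assert model.unit.counts == {"C": 2, "H": 3, "N": 1, "O": 1}

    def test_from_sequences_tracks_composition(self):
        model = AveragineModel.from_sequences(["ACDEFGHIKLMNPQRSTVWY"])
        assert 100 < model.unit_avg_mass < 130
        assert model.unit["S"] > 0  # C and M contribute sulfur


class TestScaleAveragine:
    def test_single_unit_lands_within_hydrogen_granularity(self, averagine):
        formula = scale_averagine(UNIT_AVG_MASS, averagine)
        assert formula.is_integral
        assert abs(formula.average_mass() - UNIT_AVG_MASS) <= 0.55

    def test_hundred_units_before_rounding(self, averagine):
        target = 100 * UNIT_AVG_MASS
        scaled = averagine.unit.scaled(target / averagine.unit_avg_mass)
        for element in ELEMENTS:
            assert scaled[element] == pytest.approx(100 * averagine.unit[element])
        formula = scale_averagine(target, averagine)
        assert abs(formula.average_mass() - target) <= 0.55

    def test_rho_raises_variance_at_fixed_mass(self, averagine):
        target = 20_000.0
        flat = scale_averagine(target, averagine, rho=0.0)
        wide = scale_averagine(target, averagine, rho=5.0)
        assert wide.spectrum_variance() > flat.spectrum_variance()
        assert abs(wide.average_mass() - flat.average_mass()) <= 1.1

    def test_variance_monotone_in_rho(self, averagine):
        target = 30_000.0
        variances = [
            scale_averagine(target, averagine, rho=r).spectrum_variance()
            for r in (-6.0, -2.0, 0.0, 2.0, 6.0)
        ]
        assert variances == sorted(variances)

    def test_target_below_one_unit_rejected(self, averagine):
        with pytest.raises(ValueError, match="below one averagine unit"):
            scale_averagine(50.0, averagine)

    def test_excessive_negative_rho_rejected(self, averagine):
        with pytest.raises(ValueError, match="clipping budget"):
            scale_averagine(500.0, averagine, rho=-50.0)


@pytest.fixture(scope="module")
def exp():
    formula = scale_averagine(12_000.0, AveragineModel.default())
    spectrum = aggregated_spectrum(formula, 0.99)
    from envemass import NormalizedSpectrum

    return NormalizedSpectrum(spectrum.masses, spectrum.normalized_probs)


class TestCandidatePositioning:

    def test_anchor_matches_most_abundant_peak(self, exp, averagine):
        formula = scale_averagine(12_000.0, averagine)
        candidate = position_candidate(exp, formula, k=0, zeta=1.0023)
        mean, _ = candidate.spectrum.moments()
        below = candidate.spectrum.masses[candidate.spectrum.masses <= mean]
        assert below[-1] == pytest.approx(exp.most_abundant_peak()[0], abs=1e-9)

    def test_k_shift_is_rigid(self, exp, averagine):
        formula = scale_averagine(12_000.0, averagine)
        zeta = 1.0023
        c0 = position_candidate(exp, formula, k=0, zeta=zeta)
        c1 = position_candidate(exp, formula, k=1, zeta=zeta)
        np.testing.assert_allclose(
            c1.spectrum.masses, c0.spectrum.masses + zeta, atol=1e-12
        )

    def test_self_match_prefers_k_zero(self, exp, averagine):
        formula = scale_averagine(12_000.0, averagine)
        distances = {
            k: position_candidate(exp, formula, k, zeta=1.0023).w_dist
            for k in (-1, 0, 1)
        }
        assert distances[0] < distances[-1]
        assert distances[0] < distances[1]


class TestFitCandidate:
    def test_self_consistency_on_averagine_multiple(self, averagine):
        """Fitting an exact averagine-multiple spectrum recovers rho near 0
        and an essentially zero Wasserstein distance."""
        formula = scale_averagine(15_000.0, averagine)
        spectrum = aggregated_spectrum(formula, 0.99)
        from envemass import NormalizedSpectrum

        exp = NormalizedSpectrum(spectrum.masses, spectrum.normalized_probs)
        best = fit_candidate(exp, averagine, zeta=1.0023)
        assert abs(best.rho) < 2.0  # rounding granularity of one formula step
        assert best.w_dist < 5e-3

    def test_best_beats_probed_alternatives(self, averagine):
        from envemass import NormalizedSpectrum
        from envemass.averagine import _shaped_formula

        formula = scale_averagine(10_000.0, averagine, rho=3.0)
        spectrum = aggregated_spectrum(formula, 0.99)
        exp = NormalizedSpectrum(spectrum.masses, spectrum.normalized_probs)
        best = fit_candidate(exp, averagine, zeta=1.0023, k_range=range(-2, 3))
        # the winner's own formula at every other shift
        for k in range(-2, 3):
            probe = position_candidate(exp, best.formula, k, 1.0023)
            assert best.w_dist <= probe.w_dist + 1e-12
        # nearby shape perturbations at the winning shift; integer rounding
        # makes the objective rough at the ~5e-3 level, so the winner only
        # has to be competitive within that roughness
        for d_rho, d_tau in ((1.0, 0.0), (-1.0, 0.0), (0.0, 5.0), (0.0, -5.0)):
            shaped = _shaped_formula(
                10_000.0, averagine, best.rho + d_rho, best.tau + d_tau
            )
            probe = position_candidate(exp, shaped, best.k, 1.0023)
            assert best.w_dist <= probe.w_dist + 0.01

    def test_empty_k_range_rejected(self, averagine):
        from envemass import NormalizedSpectrum

        exp = NormalizedSpectrum(
            np.array([100.0, 101.0, 102.0]), np.array([0.2, 0.5, 0.3])
        )
        with pytest.raises(ValueError, match="empty k range"):
            fit_candidate(exp, averagine, zeta=1.0023, k_range=())
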
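import numpy as np
import pytest

from envemass import (
    MonoisotopicModel,
    RunConfig,
    TheoreticalSpectrum,
    aggregated_spectrum,
    generate_protein,
    initial_estimate,
    noisy_spectrum,
    predict_experimental,
    predict_theoretical,
    sample_proteome,
)


class TestInitialEstimate:
    def test_intercept(self, published):
        assert initial_estimate(0.0, 0.0, published) == pytest.approx(-0.14557)

    def test_linearity(self, published):
        assert initial_estimate(1000.0, 0.0, published) == pytest.approx(
            -0.14557 + 999.78
        )

    def test_insulin_with_published_coefficients(self, insulin, published):
        """The printed coefficients applied to insulin's spectrum moments
        land within half a dalton of the true monoisotopic mass."""
        m_avg, m_var = aggregated_spectrum(insulin, 0.99).moments()
        estimate = initial_estimate(m_avg, m_var, published)
        assert estimate == pytest.approx(5729.60, abs=0.5)

    def test_negative_moments_rejected(self, published):
        with pytest.raises(ValueError):
            initial_estimate(-1.0, 0.0, published)


class TestTheoreticalRoute:
    def test_insulin_end_to_end(self, insulin):
        results = MonoisotopicModel.from_formula("C254H377N65O75S6").fit()
        assert results.m_mono == pytest.approx(insulin.monoisotopic_mass(), abs=0.5)

    def test_myoglobin_end_to_end(self, myoglobin):
        results = MonoisotopicModel.from_formula("C769H1212N210O218S2").fit()
        assert results.m_mono == pytest.approx(myoglobin.monoisotopic_mass(), abs=0.5)

    def test_invariant_to_probability_rescaling(self, insulin):
        spectrum = aggregated_spectrum(insulin, 0.99)
        rescaled = TheoreticalSpectrum(spectrum.masses, spectrum.probs * 0.37)
        a = predict_theoretical(spectrum)
        b = predict_theoretical(rescaled)
        assert a.m_mono == b.m_mono

    def test_deterministic(self, myoglobin):
        runs = {
            predict_theoretical(aggregated_spectrum(myoglobin, 0.99)).m_mono
            for _ in range(3)
        }
        assert len(runs) == 1

    def test_rounding_shift_bounded(self, small_proteome):
        """Grid rounding never moves the estimate further than half a grid
        step plus the lambda correction."""
        for protein in small_proteome[:60]:
            r = predict_theoretical(protein.spectrum())
            bound = r.grid.zeta / 2 + abs(r.grid.lambda_corr) * r.m_initial + 1e-9
            assert abs(r.m_mono - r.m_initial) <= bound

    def test_failures_are_off_by_whole_clusters(self):
        """When the prediction misses, it misses by ~ an integer number of
        grid steps (the off-by-one phenomenology)."""
        proteins = sample_proteome(60, seed=99, mass_range=(150e3, 400e3))
        misses = 0
        for p in proteins:
            r = predict_theoretical(p.spectrum())
            err = r.m_mono - p.m_mono
            if abs(err) > 0.5:
                misses += 1
                nearest = round(err / r.grid.zeta) * r.grid.zeta
                assert abs(err - nearest) < 0.1
        assert misses > 0  # heavy band: some off-by-one errors must occur

    def test_single_peak_spectrum_rejected(self):
        spectrum = TheoreticalSpectrum([100.0], [1.0])
        with pytest.raises(ValueError):
            MonoisotopicModel(spectrum)

    def test_summary_mentions_key_quantities(self, insulin):
        text = MonoisotopicModel.from_formula(insulin).fit().summary()
        for needle in ("monoisotopic mass", "zeta", "delta", "initial estimate"):
            assert needle in text


class TestExperimentalRoute:
    def test_noiseless_synthetic_spectrum(self, rng):
        protein = generate_protein(14_000.0, dispersion=0.03, rng=rng)
        exp = noisy_spectrum(protein.spectrum(), rng, intensity_cv=0, mass_jitter_ppm=0)
        results = predict_experimental(exp)
        assert results.m_mono == pytest.approx(protein.m_mono, abs=0.5)
        assert results.candidate is not None
        assert results.candidate.w_dist < 0.05

    def test_noisy_synthetic_spectrum(self, rng):
        protein = generate_protein(20_000.0, dispersion=0.03, rng=rng)
        exp = noisy_spectrum(
            protein.spectrum(), rng, intensity_cv=0.05, mass_jitter_ppm=2.0
        )
        results = predict_experimental(exp)
        assert results.m_mono == pytest.approx(protein.m_mono, abs=0.5)

    def test_candidate_moments_match_truth(self, rng):
        """The matched candidate reproduces the analyte's average mass and
        variance — the surrogate features the linear model consumes."""
        protein = generate_protein(16_000.0, dispersion=0.03, rng=rng)
        exp = noisy_spectrum(
            protein.spectrum(), rng, intensity_cv=0.05, mass_jitter_ppm=2.0
        )
        results = predict_experimental(exp)
        assert results.m_avg == pytest.approx(protein.m_avg, abs=0.6)
        assert results.m_var == pytest.approx(protein.m_var, rel=0.05)

    def test_charge_states_agree(self, rng):
        protein = generate_protein(12_000.0, dispersion=0.0, rng=rng)
        clean = protein.spectrum()
        outcomes = []
        for z in (2, 3):
            exp = noisy_spectrum(
                clean, rng, intensity_cv=0, mass_jitter_ppm=0, axis="mz", charge=z
            )
            outcomes.append(predict_experimental(exp).m_mono)
        assert outcomes[0] == pytest.approx(outcomes[1], abs=1e-6)

    def test_peak_order_independent(self, tmp_path, rng):
        protein = generate_protein(11_000.0, dispersion=0.0, rng=rng)
        spectrum = protein.spectrum()
        lines = [
            f"{m:.6f} {p:.8e}" for m, p in zip(spectrum.masses, spectrum.normalized_probs)
        ]
        forward = tmp_path / "fwd.txt"
        backward = tmp_path / "bwd.txt"
        forward.write_text("\n".join(lines))
        backward.write_text("\n".join(reversed(lines)))
        a = MonoisotopicModel.from_peaklist(forward).fit()
        b = MonoisotopicModel.from_peaklist(backward).fit()
        assert a.m_mono == b.m_mono

    def test_too_few_peaks_rejected(self):
        from envemass import ExperimentalSpectrum

        spectrum = ExperimentalSpectrum([100.0, 101.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="three peaks"):
            MonoisotopicModel(spectrum)


class TestConfigProfiles:
    def test_profile_switch_changes_coefficients(self):
        config = RunConfig().with_profile("published")
        assert config.coefficients.beta0 == pytest.approx(-0.14557)

    def test_unknown_profile_rejected(self):
        with pytest.raises(KeyError):
            RunConfig().with_profile("nonexistent")

    def test_config_roundtrip(self, tmp_path):
        config = RunConfig().with_profile("published")
        path = tmp_path / "coef.cfg"
        config.to_file(path)
        loaded = RunConfig.from_file(path)
        assert loaded == config

    def test_config_missing_coefficients_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("beta0 = 1.0\n")
        with pytest.raises(ValueError, match="misses coefficients"):
            RunConfig.from_file(path)


class TestPlot:
    def test_plot_returns_axes(self, insulin):
        import matplotlib

        matplotlib.use("Agg")
        model = MonoisotopicModel.from_formula(insulin)
        results = model.fit()
        ax = results.plot(spectrum=model.spectrum)
        assert ax.get_xlabel() == "mass [Da]"
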
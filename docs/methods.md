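# Methods

This note documents the models inside `envemass`, the choices that were
genuinely open, and what the synthetic benchmarks do and do not show.

## Isotope model

All computations use a single embedded isotope table for C, H, N, O, S —
the NIST standard masses and natural abundances, identical to the table
`pyteomics` ships — overridable via `envemass.constants.load_isotope_table`.
Printed atomic masses are reproducible only relative to a pinned table:
with this table, bovine insulin (C254H377N65O75S6) has monoisotopic mass
5729.6009 Da and average mass 5733.5004 Da.  (Literature sources sometimes
print average masses ~13 ppm higher, consistent with older or
higher-¹³C-abundance tables; monoisotopic masses are table-robust.)

A molecule's **aggregated spectrum** groups isotopologues by total nucleon
count; each cluster is represented by the probability-weighted centroid of
its fine structure.  The distribution is computed by per-element polynomial
convolution over the extra-neutron count (binary exponentiation with
pruning of states below 1e-12 relative probability), carrying a first-moment
array alongside the probabilities so centroids are exact.  A 400 kDa
protein costs a few milliseconds.

Two exact consequences worth knowing:

* the spectrum's mean equals the closed-form average mass
  (probability-weighted per-element means) to ~1e-9 Da;
* the spectrum's variance is *smaller* than the closed-form per-atom
  variance sum by the mean within-cluster variance that centroiding
  discards — about 5e-6 relative for proteins (e.g. 9e-5 Da² at 22 kDa).
  Tests assert this signed deficit rather than pretending the identity is
  exact.

**Coverage trimming** keeps the most probable clusters until the retained
probability reaches the coverage (default 0.99, matching the convention of
stopping a simulation once 99 % of intensity is accounted for).  The
boundary cluster is kept *fractionally* — with exactly the probability
needed to hit the coverage — emulating truncation at the fine-structure
level, where the outermost cluster is partially retained.  Whole-peak
trimming is available (`boundary="whole"`) but makes truncated moments a
sawtooth function of mass: the boundary peak popping in or out jumps the
variance by ~0.5 % (≈1.3 Da² at 400 kDa), enough to cause spurious
off-by-one errors at high mass.

## The predictor

*Initial estimate*: `M̂ = β0 + βavg·M_avg + βvar·M_var`, with moments taken
from the (renormalised) coverage-trimmed spectrum — the same convention the
training harness uses, so train and predict see identical quantities.

*Grid*: step `ζ̂ = γ0 + γavg·M_avg`; phase `Δ̂` from the argument of the
probability-weighted complex mean of the peaks wound onto a circle of
circumference ζ̂.  For concentrated envelopes this equals the brute-force
minimiser of the weighted squared circular distance (verified to 1e-6 Da).
The per-protein optimal step (circular-variance minimisation: 2001-point
scan over [0.998, 1.008] Da plus bounded refinement to 1e-7) is provided as
a validation utility, not in the main path — the universal linear law is
used instead, because the per-protein optimum adds cost and, on this
package's aggregated spectra, correlates with mass only weakly
(Pearson ≈ −0.05 ± 0.06 on 300 proteins; slope indistinguishable from 0).

*Rounding*: nearest grid node, ties toward the lower mass (the
monoisotopic variant is the lightest), then the λ correction.  λ is applied
as a *relative* shift, `final = node·(1+λ)`: its magnitude (~1e-7) is a
ppm-scale drift of effective cluster spacing across the envelope, which
accumulates in proportion to how far the monoisotopic position extrapolates
from the envelope centre — i.e. proportionally to mass.  An
`absolute_per_node` mode is provided as an alternative reading.

## Coefficients: why the package retrains them

The published coefficient set (β0 = −0.14557, βavg = 0.99978,
βvar = −0.59817; γ0 = 1.002355, γavg = 6.9584e-10; λ = −1.1982e-7) was
fitted against a specific isotope table, a fine-structure simulator, and
real proteome compositions.  Against this package's NIST table and
averagine-based synthetic proteome those values carry a mass-proportional
bias of roughly ±1.3e-5·M under either moment convention — several daltons
at 400 kDa, i.e. guaranteed off-by-one errors above ~50 kDa.  The βvar
value itself encodes the real proteome's composition variance structure: at
fixed mass, real proteins differ mostly in sulfur, whose per-atom
mean-shift/variance ratio (~0.55) matches the printed βvar; a synthetic
proteome with uniform per-element dispersion is dominated by carbon-count
variation (ratio ~1.007) and must refit to βvar ≈ −1.05.

The package therefore follows the train-then-predict workflow end to end:
the shipped `8-400kDa-default` profile is produced by
`scripts/train_default_profile.py` (20 000 proteins, training seed
20220712, distinct from any evaluation seed) and frozen in
`envemass.config`.  The refit reproduces βavg to within 2.8e-4 of the
published value and λ with the published sign and order of magnitude
(−1.44e-7 vs −1.198e-7).  The `published` profile remains available for
comparison.

## Experimental spectra and the candidate fit

m/z peak lists are reduced to neutral mass with the proton mass
1.007276466812 Da (positive-ion protonation assumed); peaks are treated as
already-centroided sticks, and intensities are normalised over whatever
segment the user supplies.  An optional minimum-relative-intensity filter
(default off) is available for denoising.

The candidate construction scales the averagine unit (Senko's classic
ratios rescaled uniformly so one residue averages 110.4728 Da; a utility
re-derives the unit from any FASTA set via standard residue compositions)
to the envelope's average mass, then searches:

* integer shifts k (default −3…+8) of the whole spectrum by k·ζ̂, anchored
  so that the candidate's first aggregated peak at or below its own average
  mass sits on the experimental most abundant peak;
* the width direction ρ — the per-atom-variance gradient projected
  orthogonally to the average-mass gradient, i.e. the fastest
  mass-preserving variance change (sulfur-dominated);
* the alignment direction τ — a C/N vs O exchange in the nullspace of the
  average-mass *and* variance gradients, which slides the isotope comb
  under the envelope at fixed mass and width.  Sulfur is excluded from this
  direction because half-atom rounding of sulfur perturbs the comb position
  by ~0.05 Da and makes the objective too rough to optimise; hydrogen is
  reserved for mass rebalancing.

The τ direction is this package's extension of the one-parameter (ρ-only)
construction.  It is necessary above ~30 kDa: with ρ alone, envelope
alignment and variance are rigidly coupled (0.048 Da of comb slide and
0.093 Da² of variance per unit ρ), so any composition deviation
perpendicular to the averagine line forces a variance error of up to
±0.97 Da² — an off-by-one at 30–60 kDa.  With the two directions the
Wasserstein fit recovers both moments: on noiseless synthetic spectra at
8–60 kDa the true mass is recovered within 0.5 Da in 97/100 cases (93/100
with 5 % intensity noise and 2 ppm jitter), and the candidate's variance
matches the analyte's within 5 %.

The optimizer is deterministic coordinate descent in decoupled coordinates
(alignment first, then width; two cycles), each pass a 33-point coarse scan
over the bounded interval followed by bounded scalar minimisation
(tolerance 1e-3) around the best coarse point; candidate formulas are
rounded to integers with a post-rounding alignment repair along τ, and
bounds default to ρ ∈ ±0.05·n_units, τ ∈ ±0.3·n_units.  Candidate spectra
are computed at 0.99 coverage, like everything else.  The fitted
candidate — not the noisy envelope — supplies M_avg, M_var and Δ̂ for the
final prediction, which is the point of the construction: the simulated
spectrum provides precisely measured features that the experimental one
cannot.

## The synthetic proteome

`generate_protein` scales the averagine unit to a target average mass,
multiplies each element count by an independent log-normal factor
(log-sd = dispersion, default 0.03), rounds, and rebalances hydrogen onto
the target mass.  Evaluation sets draw target masses log-uniformly over
8–400 kDa.  The defaults are the package's study conditions; 0.03 gives
element-count coefficients of variation of ~3 %, a plausible stand-in for
real composition variability at fixed mass.

What the generator does *not* emulate: the real proteome's covariance
structure (sulfur-dominated variation between proteins of equal mass),
fine isotopic structure, chemical noise, baseline, charge-state overlap,
and detector effects.  Consequently the synthetic benchmarks measure the
pipeline's internal consistency, not instrument performance:

* off-by-one-free fraction, 2 000 proteins, shipped coefficients:
  **92–94 %** across seeds.  The uniform-dispersion generator leaves a
  residual of ~1.8 ppm·M around the best two-predictor linear fit
  (oxygen- and carbon-count dispersion dominate), so the low-90s is the
  structural ceiling under these conditions — a proteome whose composition
  variance is sulfur-dominated, as the real one is, would do better at
  high mass.
* overall MAE ≈ 0.23–0.31 ppm; conditional MAE (off-by-one-free cases)
  ≈ 0.011 ppm.  The conditional error is *smaller* than on fine-structure
  spectra because aggregated centroids plus a λ calibrated to this exact
  grid leave only ~1 mDa of phase error.
* 10-fold CV of the Eq-1 refit (20 000 proteins): ≈ 93 % below 0.5 Da.

## Numerical conventions

Convolution pruning at 1e-12 relative probability; ζ search interval
[0.998, 1.008] Da; Δ̂ canonicalised into [−ζ/2, ζ/2); rounding ties toward
lower mass; minimum 2 peaks for theoretical spectra and 3 for experimental
(below that, moments and phase are meaningless and the tool refuses);
single-peak ζ estimation and circularly-uniform Δ̂ are signalled as errors,
not silently defaulted.  Every stochastic component takes an explicit seed
or `numpy.random.Generator`; identical inputs and configuration give
bit-identical results.

## Known limitations

Single-analyte spectra only; elements restricted to CHNOS (no adducts,
PTMs with other elements, or metal binding); no profile-mode peak picking;
the universal grid step is extrapolated from synthetic training and the
published experimental validation covers only the low tens of kDa; the
averagine unit average mass is taken as the printed 110.4728 Da while the
exact published unit composition is not available, so Senko ratios rescaled
to that mass stand in (configurable).
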
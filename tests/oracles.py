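"""Independent brute-force references used to pin expected values.

These deliberately avoid the package's convolution path: isotopologues are
enumerated exhaustively, so they are only usable for tiny formulas, which
is exactly what makes them trustworthy.
"""

import itertools
from collections import defaultdict

import numpy as np

from envemass import DEFAULT_ISOTOPES, ELEMENTS


def enumerate_aggregated(formula, table=DEFAULT_ISOTOPES):
    """Aggregated spectrum by exhaustive enumeration over all isotopologues.

    Returns (masses, probs) sorted by mass, full coverage.  Exponential in
    the atom count — keep formulas to a handful of atoms.
    """
    atoms = []
    for element in ELEMENTS:
        n = int(formula[element]) if element in formula.counts else 0
        isotopes = table.isotopes(element)
        offsets = table.nucleon_offsets(element)
        atoms.extend([list(zip(offsets, isotopes))] * n)
    clusters = defaultdict(lambda: [0.0, 0.0])  # key -> [prob, prob*mass]
    for combo in itertools.product(*atoms):
        key = sum(offset for offset, _ in combo)
        prob = 1.0
        mass = 0.0
        for _, (iso_mass, abundance) in combo:
            prob *= abundance
            mass += iso_mass
        clusters[key][0] += prob
        clusters[key][1] += prob * mass
    keys = sorted(clusters)
    probs = np.array([clusters[k][0] for k in keys])
    masses = np.array([clusters[k][1] / clusters[k][0] for k in keys])
    return masses, probs


def brute_force_delta(masses, probs, zeta, n_scan=20001):
    """Grid shift minimizing the weighted squared circular distance to peaks.

    Dense scan over [-zeta/2, zeta/2) followed by parabolic refinement.
    """

    def objective(delta):
        wrapped = (masses - delta + zeta / 2) % zeta - zeta / 2
        return float(np.dot(probs, wrapped**2))

    candidates = np.linspace(-zeta / 2, zeta / 2, n_scan, endpoint=False)
    values = [objective(d) for d in candidates]
    best = int(np.argmin(values))
    lo = candidates[best] - 2 * zeta / n_scan
    hi = candidates[best] + 2 * zeta / n_scan
    from scipy.optimize import minimize_scalar

    result = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    return float(result.x)


def cdf_wasserstein(masses_a, probs_a, masses_b, probs_b):
    """W1 by direct numerical integration of |CDF_a - CDF_b|."""
    support = np.unique(np.concatenate([masses_a, masses_b]))
    cdf_a = np.array([probs_a[masses_a <= x].sum() for x in support])
    cdf_b = np.array([probs_b[masses_b <= x].sum() for x in support])
    gaps = np.diff(support)
    return float(np.sum(np.abs(cdf_a[:-1] - cdf_b[:-1]) * gaps))
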
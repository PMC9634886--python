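"""Coefficient profiles and run configuration.

Two coefficient profiles ship with the package:

``8-400kDa-default``
    Coefficients retrained by the package's own synthetic-proteome harness
    (``scripts/train_default_profile.py``; 20 000 averagine-like proteins,
    log-uniform 8-400 kDa, per-element dispersion 0.03, coverage 0.99,
    training seed 20220712).  This profile is self-consistent with the
    embedded NIST isotope table and the aggregated-spectrum engine, and is
    the default for every prediction.

``published``
    The coefficients printed for the original algorithm.  They were fitted
    against a different isotope table and a fine-structure simulator, and
    carry a mass-proportional bias of roughly 1e-5 * M against this
    package's engine; they are provided for comparison, not for use as the
    default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Tuple


@dataclass(frozen=True)
class PredictorCoefficients:
    """The (beta, gamma, lambda) bundle driving a prediction.

    beta0 [Da], beta_avg [-], beta_var [1/Da] form the initial linear
    estimate; gamma0 [Da], gamma_avg [-] give the universal grid step;
    lambda_corr [-] is the relative recentering applied after rounding.
    """

    beta0: float
    beta_avg: float
    beta_var: float
    gamma0: float
    gamma_avg: float
    lambda_corr: float

    def __post_init__(self):
        if not 0.99 < self.beta_avg < 1.01:
            raise ValueError("beta_avg outside the physical window (0.99, 1.01)")
        if not 0.99 < self.gamma0 < 1.02:
            raise ValueError("gamma0 outside the physical window (0.99, 1.02)")


#: Coefficients printed for the original algorithm (see module docstring).
PUBLISHED = PredictorCoefficients(
    beta0=-0.14557,
    beta_avg=0.99978,
    beta_var=-0.59817,
    gamma0=1.002355,
    gamma_avg=6.9584e-10,
    lambda_corr=-1.1982e-7,
)

#: Retrained on this package's synthetic proteome (see module docstring).
SYNTHETIC_DEFAULT = PredictorCoefficients(
    beta0=-0.0155118,
    beta_avg=1.0000608,
    beta_var=-1.0521589,
    gamma0=1.0023125,
    gamma_avg=-1.209e-11,
    lambda_corr=-1.4369e-07,
)

PROFILES: Dict[str, PredictorCoefficients] = {
    "8-400kDa-default": SYNTHETIC_DEFAULT,
    "published": PUBLISHED,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a prediction run needs besides the spectrum itself."""

    coefficients: PredictorCoefficients = SYNTHETIC_DEFAULT
    coverage: float = 0.99
    boundary: str = "fractional"
    lambda_mode: str = "relative"
    k_min: int = -3
    k_max: int = 8
    rho_bound_scale: float = 0.05
    rho_tol: float = 1e-3
    zeta_search_lo: float = 0.998
    zeta_search_hi: float = 1.008
    min_rel_intensity: float = 0.0
    circular_mean_weighted: bool = True

    @property
    def k_range(self) -> Tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1))

    def with_profile(self, name: str) -> "RunConfig":
        try:
            return replace(self, coefficients=PROFILES[name])
        except KeyError:
            raise KeyError(
                f"unknown profile {name!r}; available: {sorted(PROFILES)}"
            ) from None

    # -- flat key=value round trip ------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in fields(PredictorCoefficients):
            lines.append(f"{f.name} = {getattr(self.coefficients, f.name)!r}")
        for f in fields(RunConfig):
            if f.name == "coefficients":
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: Dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        coef_names = {f.name for f in fields(PredictorCoefficients)}
        coef_kwargs = {}
        run_kwargs = {}
        for key, value in raw.items():
            target = coef_kwargs if key in coef_names else run_kwargs
            target[key] = _parse_scalar(value)
        missing = coef_names - set(coef_kwargs)
        if missing:
            raise ValueError(f"config misses coefficients: {sorted(missing)}")
        valid = {f.name for f in fields(RunConfig)} - {"coefficients"}
        unknown = set(run_kwargs) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(coefficients=PredictorCoefficients(**coef_kwargs), **run_kwargs)


def _parse_scalar(text: str):
    if text in ("True", "False"):
        return text == "True"
    if text.startswith("'") or text.startswith('"'):
        return text.strip("'\"")
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text
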
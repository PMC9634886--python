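"""Experimental spectra: reading, charge reduction, normalization, Wasserstein.

Spectra are centroided stick lists.  Positions can be on the neutral dalton
axis or on m/z; m/z spectra carry a known charge and are reduced to neutral
mass assuming positive-ion mode (protonation).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
from scipy.stats import wasserstein_distance

from .constants import PROTON_MASS

AXIS_DALTON = "dalton"
AXIS_MZ = "mz"


@dataclass(frozen=True)
class ExperimentalSpectrum:
    """Centroided peak list with an axis tag and (for m/z) a charge state."""

    positions: np.ndarray
    intensities: np.ndarray
    axis: str = AXIS_DALTON
    charge: int | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.shape != inten.shape or pos.size == 0:
            raise ValueError("positions and intensities must be matching 1-D arrays")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        if not np.any(inten > 0):
            raise ValueError("spectrum has no positive intensity")
        if self.axis not in (AXIS_DALTON, AXIS_MZ):
            raise ValueError(f"unknown axis: {self.axis!r}")
        order = np.argsort(pos, kind="stable")
        pos, inten = pos[order], inten[order]
        keep = inten > 0
        pos, inten = pos[keep], inten[keep]
        if np.any(np.diff(pos) <= 0):
            raise ValueError("duplicate peak positions")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.positions.size

    def to_dalton(self) -> "ExperimentalSpectrum":
        """Reduce m/z positions to neutral mass: (m/z - m_proton) * z."""
        if self.axis == AXIS_DALTON:
            return self
        if not self.charge or self.charge < 1:
            raise ValueError("charge state required to convert m/z to daltons")
        neutral = (self.positions - PROTON_MASS) * self.charge
        return ExperimentalSpectrum(neutral, self.intensities, AXIS_DALTON, self.charge)

    def filtered(self, min_relative_intensity: float) -> "ExperimentalSpectrum":
        """Drop peaks below a fraction of the base peak (optional denoising)."""
        if min_relative_intensity <= 0:
            return self
        keep = self.intensities >= min_relative_intensity * self.intensities.max()
        return ExperimentalSpectrum(
            self.positions[keep], self.intensities[keep], self.axis, self.charge
        )

    def normalize(self) -> "NormalizedSpectrum":
        if self.axis != AXIS_DALTON:
            raise ValueError("convert to the dalton axis before normalizing")
        return NormalizedSpectrum(self.positions, self.intensities / self.intensities.sum())


@dataclass(frozen=True)
class NormalizedSpectrum:
    """Discrete probability distribution over masses in Da."""

    masses: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        masses = np.asarray(self.masses, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if masses.ndim != 1 or masses.shape != probs.shape or masses.size == 0:
            raise ValueError("masses and probs must be matching 1-D arrays")
        if np.any(np.diff(masses) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be positive and sum to one")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.masses.size

    @property
    def normalized_probs(self) -> np.ndarray:  # shared interface with theory spectra
        return self.probs

    def moments(self) -> Tuple[float, float]:
        mean = float(np.dot(self.probs, self.masses))
        var = float(np.dot(self.probs, (self.masses - mean) ** 2))
        return mean, var

    def most_abundant_peak(self) -> Tuple[float, float]:
        i = int(np.argmax(self.probs))
        return float(self.masses[i]), float(self.probs[i])


def read_peaklist(
    source: Union[str, Path, io.TextIOBase],
    axis: str = AXIS_DALTON,
    charge: int | None = None,
) -> ExperimentalSpectrum:
    """Parse a two-column (position, intensity) text peak list.

    Columns may be separated by whitespace or commas; blank lines and
    ``#`` comments are ignored.  Zero-intensity rows are dropped and peaks
    are sorted by position.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    positions, intensities = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            positions.append(float(fields[0]))
            intensities.append(float(fields[1]))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    if not positions:
        raise ValueError("no peaks found in input")
    return ExperimentalSpectrum(np.array(positions), np.array(intensities), axis, charge)


def read_mzml(
    source: Union[str, Path],
    index: int = 0,
    axis: str = AXIS_MZ,
    charge: int | None = None,
) -> ExperimentalSpectrum:
    """Adapter: pull one centroided spectrum out of an mzML container.

    Minimal reader for the common encodings (32/64-bit floats, optional
    zlib compression); selects the spectrum by positional index.
    """
    import base64
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = etree.parse(str(source))
    spectra = tree.findall(f".//{ns}spectrum")
    if index >= len(spectra):
        raise ValueError(f"spectrum index {index} not found in {source}")
    arrays = {}
    for array_el in spectra[index].findall(f".//{ns}binaryDataArray"):
        accessions = {
            cv.get("accession") for cv in array_el.findall(f"{ns}cvParam")
        }
        binary_el = array_el.find(f"{ns}binary")
        raw = base64.b64decode(binary_el.text or "")
        if "MS:1000574" in accessions:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = "<f4" if "MS:1000521" in accessions else "<f8"
        values = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in accessions:
            arrays["mz"] = values
        elif "MS:1000515" in accessions:
            arrays["intensity"] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError("spectrum lacks m/z or intensity arrays")
    return ExperimentalSpectrum(arrays["mz"], arrays["intensity"], axis, charge)


def wasserstein(a, b) -> float:
    """First-order Wasserstein distance between two normalized spectra (Da).

    Accepts any objects exposing ``masses`` and normalized probabilities;
    computed as the integral of the absolute CDF difference.
    """
    pa = getattr(a, "normalized_probs", None)
    pb = getattr(b, "normalized_probs", None)
    if pa is None or pb is None:
        raise TypeError("wasserstein expects spectrum-like operands")
    for p in (pa, pb):
        if abs(float(np.sum(p)) - 1.0) > 1e-6:
            raise ValueError("wasserstein requires normalized spectra")
    return float(wasserstein_distance(a.masses, b.masses, pa, pb))
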
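"""Gravity center of fluorescence emission spectra and spectral shifts.

Tryptophan emission of the enzyme is recorded over 305-450 nm; solvent effects
show up as small displacements of the intensity-weighted mean emission
wavelength (the spectrum's gravity center, GC). A negative GC difference
between a treated and a reference spectrum is a hypsochromic (blue) shift,
indicating a less polar tryptophan microenvironment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmissionSpectrum", "gravity_center", "spectral_shift"]


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum on a wavelength grid.

    lam: wavelengths in nm, strictly increasing; intensity: nonnegative
    emission intensities, a.u., with at least one positive value.
    """

    lam: np.ndarray
    intensity: np.ndarray
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.lam.ndim != 1 or self.lam.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity grids must match and be 1-D")
        if not np.all(np.diff(self.lam) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.lam)


def gravity_center(spec: EmissionSpectrum) -> float:
    """Intensity-weighted mean emission wavelength, GC = sum(I*lam)/sum(I), nm.

    Discrete sum over the stored grid (no interpolation). Raises on an
    all-zero spectrum.
    """
    total = float(np.sum(spec.intensity))
    if total <= 0:
        raise ZeroDivisionError("all-zero spectrum: gravity center undefined")
    return float(np.sum(spec.intensity * spec.lam) / total)


def spectral_shift(spec_a: EmissionSpectrum, spec_b: EmissionSpectrum) -> float:
    """GC(spec_b) - GC(spec_a) in nm; negative = hypsochromic (blue) shift."""
    return gravity_center(spec_b) - gravity_center(spec_a)
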
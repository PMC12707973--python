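"""Wavelength grid, hemoglobin extinction table, and the blood-absorption
forward model.

Conventions
-----------
Extinction coefficients are decadic (base-10) molar extinctions in
cm^-1 M^-1; the absorption coefficient mu_a (cm^-1, natural-log scale)
therefore carries an ln(10) factor, and absorbance spectra are base-10
throughout. Each acquisition band is treated as a delta function at its
center wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

LN10 = float(np.log(10.0))

#: Default total hemoglobin concentration of whole blood, mol/L
#: (150 g/L at 64,500 g/mol tetramer-equivalent molar mass).
DEFAULT_HEMOGLOBIN_MOLARITY = 150.0 / 64500.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Band-center wavelengths in nm, strictly ascending.

    The default grid is the 23-band acquisition grid: 500, 510, ..., 720 nm.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.arange(500.0, 721.0, 10.0)
    )

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("wavelength grid needs at least two band centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "centers", centers)

    def __len__(self) -> int:
        return self.centers.size

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        return cls(np.arange(float(start), float(stop) + step / 2.0, float(step)))


class ExtinctionTable:
    """Tabulated oxy-/deoxyhemoglobin decadic molar extinction spectra.

    Lookup at non-tabulated wavelengths is linear interpolation; queries
    outside the tabulated support raise, naming the offending wavelength.

    The vendored default table is a synthetic compilation (see
    ``data/hemoglobin_extinction_synthetic.csv``): shape-faithful to the
    standard published spectra but not metrologically traceable.
    """

    def __init__(self, wavelength: np.ndarray, eps_oxy: np.ndarray,
                 eps_deoxy: np.ndarray, version: str = "custom"):
        wavelength = np.asarray(wavelength, dtype=float)
        eps_oxy = np.asarray(eps_oxy, dtype=float)
        eps_deoxy = np.asarray(eps_deoxy, dtype=float)
        if not (wavelength.shape == eps_oxy.shape == eps_deoxy.shape):
            raise ValueError("table columns must have equal length")
        if not np.all(np.diff(wavelength) > 0):
            raise ValueError("table wavelengths must be strictly increasing")
        if np.any(eps_oxy <= 0) or np.any(eps_deoxy <= 0):
            raise ValueError("extinction values must be strictly positive")
        self.wavelength = wavelength
        self.eps_oxy = eps_oxy
        self.eps_deoxy = eps_deoxy
        self.version = version

    @classmethod
    def vendored(cls) -> "ExtinctionTable":
        """Load the packaged synthetic hemoglobin compilation."""
        ref = resources.files("tdhsi.data") / "hemoglobin_extinction_synthetic.csv"
        with ref.open("r") as fh:
            rows = [ln for ln in fh if not ln.startswith("#")]
        data = np.loadtxt(rows, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], data[:, 2], version="synthetic-v1")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        data = np.loadtxt(path, delimiter=",", skiprows=1, comments="#")
        return cls(data[:, 0], data[:, 1], data[:, 2], version=str(path))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("wavelength_nm,eps_oxy,eps_deoxy\n")
            for w, eo, ed in zip(self.wavelength, self.eps_oxy, self.eps_deoxy):
                fh.write(f"{w:g},{eo:g},{ed:g}\n")

    def _check_support(self, lam: np.ndarray) -> None:
        lo, hi = self.wavelength[0], self.wavelength[-1]
        bad = lam[(lam < lo) | (lam > hi)]
        if bad.size:
            raise ValueError(
                f"wavelength {bad[0]:g} nm outside table support "
                f"[{lo:g}, {hi:g}] nm"
            )

    def oxy(self, lam) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        self._check_support(lam)
        return np.interp(lam, self.wavelength, self.eps_oxy)

    def deoxy(self, lam) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        self._check_support(lam)
        return np.interp(lam, self.wavelength, self.eps_deoxy)


@dataclass(frozen=True)
class BloodSpec:
    """Hemoglobin content and preset oxygen saturation of a blood volume.

    Parameters
    ----------
    hemoglobin_molarity : total hemoglobin concentration B, mol/L.
    so2 : preset oxygen saturation, fraction in [0, 1]. The arterial and
        venous presets used throughout the simulation study are 0.98 and
        0.75.
    """

    hemoglobin_molarity: float = DEFAULT_HEMOGLOBIN_MOLARITY
    so2: float = 0.98

    def __post_init__(self):
        if self.hemoglobin_molarity <= 0:
            raise ValueError("hemoglobin concentration must be positive")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 preset must lie in [0, 1]")


def blood_mu_a(blood: BloodSpec, grid: WavelengthGrid,
               table: ExtinctionTable) -> np.ndarray:
    """Whole-blood absorption coefficient per band, cm^-1.

    mu_a(lambda) = ln(10) * B * [eps_oxy * SO2 + eps_deoxy * (1 - SO2)],
    the decadic extinctions converted to a natural-log attenuation
    coefficient. Linear (affine) in SO2 and homogeneous of degree 1 in B.
    """
    lam = grid.centers
    eps = table.oxy(lam) * blood.so2 + table.deoxy(lam) * (1.0 - blood.so2)
    return LN10 * blood.hemoglobin_molarity * eps


def theoretical_absorbance(blood: BloodSpec, path_length: float,
                           offset: float, grid: WavelengthGrid,
                           table: ExtinctionTable) -> np.ndarray:
    """Noise-free modified Beer-Lambert vessel absorbance (base 10).

    A(lambda) = B * [eps_oxy * SO2 + eps_deoxy * (1 - SO2)] * L + xi,
    with L the optical path length in cm and xi a wavelength-flat offset
    absorbing non-hemoglobin losses. Serves as the forward model for
    round-trip tests; equals path_length * blood_mu_a / ln(10) + offset.
    """
    if path_length < 0:
        raise ValueError("path length must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    lam = grid.centers
    eps = table.oxy(lam) * blood.so2 + table.deoxy(lam) * (1.0 - blood.so2)
    return blood.hemoglobin_molarity * eps * path_length + offset
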
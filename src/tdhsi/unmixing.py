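"""Modified Beer-Lambert spectral unmixing of vessel absorbance into
oxygen saturation, with Pearson-gated acceptance.

The measured base-10 vessel absorbance A(lambda) over the band grid is fit
as A ~ X c with design matrix X = [1, eps_oxy(lambda), eps_deoxy(lambda)]
and c = (xi, B*SO2*L, B*(1-SO2)*L) >= 0 solved by non-negative least
squares; SO2 = c2 / (c2 + c3). A fit is accepted when the Pearson
correlation between measured and fitted spectra is >= 0.9 and a hemoglobin
signature is present (c2 + c3 > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .spectra import ExtinctionTable, WavelengthGrid

#: Pearson goodness-of-fit acceptance gate
R_THRESHOLD = 0.9
#: Minimum usable bands for a pixel/spectrum to be fit at all
MIN_BANDS = 10

#: Reason codes for rejected fits
REASON_OK = ""
REASON_LOW_R = "low_r"
REASON_NO_HEMOGLOBIN = "no_hemoglobin"
REASON_BAD_BANDS = "bad_bands"


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Per-band base-10 vessel absorbance; NaN marks non-detectable bands."""

    wavelengths: np.ndarray
    a_vessel: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.a_vessel, dtype=float)
        if w.shape != a.shape:
            raise ValueError("wavelengths and absorbance must align")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "a_vessel", a)


@dataclass(frozen=True)
class UnmixResult:
    """NNLS fit of one spectrum.

    c = (xi, B*SO2*L, B*(1-SO2)*L), all non-negative; so2 is NaN when the
    fit is rejected, with ``reason`` one of low_r / no_hemoglobin /
    bad_bands.
    """

    c: np.ndarray
    so2: float
    pearson_r: float
    accepted: bool
    reason: str = REASON_OK
    n_bands_used: int = 0


def vessel_absorbance(sample_fraction, background_fraction,
                      grid: WavelengthGrid) -> AbsorbanceSpectrum:
    """Base-10 vessel absorbance from paired detected fractions.

    a(lambda) = log10(background / sample); bands where either fraction is
    non-positive (vessel optically opaque at that band, or Monte Carlo
    starvation) are flagged NaN rather than dropped, so downstream fits can
    account for them.
    """
    s = np.asarray(sample_fraction, dtype=float)
    b = np.asarray(background_fraction, dtype=float)
    if s.shape != b.shape or s.shape != grid.centers.shape:
        raise ValueError("fractions must match the wavelength grid")
    a = np.full_like(s, np.nan)
    ok = (s > 0) & (b > 0)
    a[ok] = np.log10(b[ok] / s[ok])
    return AbsorbanceSpectrum(grid.centers.copy(), a)


def build_design_matrix(grid: WavelengthGrid,
                        table: ExtinctionTable) -> np.ndarray:
    """(n_bands x 3) matrix with columns [1, eps_oxy, eps_deoxy]."""
    lam = grid.centers
    return np.column_stack([np.ones(lam.size), table.oxy(lam),
                            table.deoxy(lam)])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def solve(a: AbsorbanceSpectrum | np.ndarray, x: np.ndarray,
          r_threshold: float = R_THRESHOLD,
          min_bands: int = MIN_BANDS) -> UnmixResult:
    """Non-negative least-squares unmixing of one absorbance spectrum.

    NaN (non-detectable) bands are excluded from both the fit and the
    Pearson correlation; fewer than ``min_bands`` usable bands rejects the
    spectrum outright.
    """
    avec = a.a_vessel if isinstance(a, AbsorbanceSpectrum) else np.asarray(a, float)
    if avec.shape[0] != x.shape[0]:
        raise ValueError("spectrum and design matrix lengths disagree")
    ok = np.isfinite(avec)
    n_used = int(ok.sum())
    if n_used < min_bands:
        return UnmixResult(np.zeros(3), np.nan, np.nan, False,
                           REASON_BAD_BANDS, n_used)
    c, _ = nnls(x[ok], avec[ok])
    fitted = x[ok] @ c
    r = _pearson(avec[ok], fitted)
    hb = c[1] + c[2]
    if hb <= 0.0:
        return UnmixResult(c, np.nan, r, False, REASON_NO_HEMOGLOBIN, n_used)
    so2 = float(np.clip(c[1] / hb, 0.0, 1.0))
    if not np.isfinite(r) or r < r_threshold:
        return UnmixResult(c, np.nan, r if np.isfinite(r) else np.nan,
                           False, REASON_LOW_R, n_used)
    return UnmixResult(c, so2, r, True, REASON_OK, n_used)


class SO2Unmixer(BaseEstimator):
    """Scikit-learn style estimator mapping absorbance spectra to SO2.

    Parameters
    ----------
    wavelengths : band centers in nm; None uses the default 23-band grid.
    table : ExtinctionTable; None loads the vendored compilation.
    r_threshold : Pearson acceptance gate (default 0.9).
    min_bands : minimum usable bands per spectrum (default 10).

    After :meth:`fit`, ``design_matrix_`` holds the (n_bands x 3) modified
    Beer-Lambert design matrix. :meth:`predict` maps an (n_spectra x
    n_bands) array to SO2 fractions (NaN when rejected); :meth:`unmix`
    returns the full per-spectrum :class:`UnmixResult` list.
    """

    def __init__(self, wavelengths=None, table=None,
                 r_threshold=R_THRESHOLD, min_bands=MIN_BANDS):
        self.wavelengths = wavelengths
        self.table = table
        self.r_threshold = r_threshold
        self.min_bands = min_bands

    def fit(self, X=None, y=None):
        grid = (WavelengthGrid() if self.wavelengths is None
                else WavelengthGrid(np.asarray(self.wavelengths, float)))
        table = self.table if self.table is not None else ExtinctionTable.vendored()
        self.grid_ = grid
        self.table_ = table
        self.design_matrix_ = build_design_matrix(grid, table)
        return self

    def _check_fitted(self):
        if not hasattr(self, "design_matrix_"):
            self.fit()

    def unmix(self, A) -> list[UnmixResult]:
        self._check_fitted()
        A = np.atleast_2d(np.asarray(A, dtype=float))
        return [solve(row, self.design_matrix_, self.r_threshold,
                      self.min_bands) for row in A]

    def predict(self, A) -> np.ndarray:
        """SO2 per spectrum; NaN for rejected fits."""
        return np.array([r.so2 for r in self.unmix(A)])
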
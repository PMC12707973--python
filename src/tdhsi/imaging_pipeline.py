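"""Per-pixel SO2 mapping from hyperspectral stacks, oxygenation dynamics,
and concentric-annulus quantification around a tumor center.

A stack is corrected against reference (flat-field) and dark frames, ratioed
against an avascular background spectrum, converted to base-10 vessel
absorbance per pixel, and unmixed pixel-independently. Dynamics reduce a
vessel ROI to one SO2 value per time point; hypoxia challenges are
summarized by peak response and recovery time. Spatial tumor analysis
averages accepted SO2 over 0.5 mm concentric annuli out to 4.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import unmixing
from .spectra import ExtinctionTable, WavelengthGrid
from .unmixing import (MIN_BANDS, R_THRESHOLD, REASON_BAD_BANDS, SO2Unmixer,
                       build_design_matrix, solve)


class CalibrationError(ValueError):
    """Reference/dark frames inconsistent with the acquisition."""


@dataclass
class SpectralStack:
    """(rows x cols x bands) intensity cube with calibration frames.

    ``reference`` and ``dark`` may be per-band scalars (shape (bands,)) or
    full frames (rows x cols x bands); they broadcast against the data.
    ``mode`` records the detection geometry (reflective | transmissive) and
    ``pixel_size`` is mm per pixel.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    reference: np.ndarray
    dark: np.ndarray
    pixel_size: float
    mode: str = "transmissive"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (rows, cols, bands)")
        nb = self.data.shape[2]
        if self.wavelengths.shape != (nb,):
            raise ValueError("one wavelength per band required")
        for name, arr in (("reference", self.reference), ("dark", self.dark)):
            if arr.shape not in ((nb,), self.data.shape):
                raise ValueError(
                    f"{name} must be (bands,) or match the data shape")
        if self.mode not in ("reflective", "transmissive"):
            raise ValueError("mode must be reflective or transmissive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self):
        return self.data.shape

    def _bands(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(1, 1, -1) if arr.ndim == 1 else arr


@dataclass
class SO2Map:
    """Per-pixel unmixing output.

    ``so2`` is NaN where rejected; ``reject_reason`` holds '' for accepted
    pixels else one of the unmixing reason codes.
    """

    so2: np.ndarray
    accepted_mask: np.ndarray
    pearson_map: np.ndarray
    reject_reason: np.ndarray


@dataclass(frozen=True)
class OxygenTimeSeries:
    """SO2 of one vessel over time (minutes), with a pre-stimulus baseline
    window (t_start, t_end) whose mean defines the reference level."""

    times: np.ndarray
    so2_values: np.ndarray
    baseline_window: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.so2_values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must align")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "so2_values", v)

    @property
    def baseline(self) -> float:
        lo, hi = self.baseline_window
        sel = (self.times >= lo) & (self.times <= hi)
        if not sel.any():
            raise ValueError("baseline window contains no samples")
        return float(self.so2_values[sel].mean())


@dataclass
class AnnulusProfile:
    """Mean accepted SO2 in concentric 0.5 mm rings about the tumor center.

    Rings span 0-4.5 mm; the tumor region is rings with outer edge <= 3 mm
    and the adjacent region spans 3-4.5 mm. Empty rings carry NaN means.
    """

    ring_edges: np.ndarray
    mean_so2: np.ndarray
    pixel_counts: np.ndarray
    tumor_mean: float
    adjacent_mean: float

    @property
    def tumor_rings(self):
        return np.where(self.ring_edges[1:] <= 3.0)[0]

    @property
    def adjacent_rings(self):
        return np.where(self.ring_edges[1:] > 3.0)[0]


# ---------------------------------------------------------------------------
# Eq-8-style correction and mapping


def background_spectrum(stack: SpectralStack, roi_mask: np.ndarray) -> np.ndarray:
    """Per-band median raw intensity over an avascular ROI (robust to stray
    vessels)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.data.shape[:2]:
        raise ValueError("ROI mask must match the image shape")
    if not roi_mask.any():
        raise ValueError("background ROI is empty")
    return np.median(stack.data[roi_mask, :], axis=0)


def corrected_ratio(stack: SpectralStack,
                    background: np.ndarray) -> np.ndarray:
    """Reference/dark-corrected per-pixel, per-band transmission/reflection
    ratio against the avascular background spectrum.

    ratio = [(I - I_dark) / (I_ref - I_dark)] /
            [(I_bg - I_dark) / (I_ref - I_dark)]
    with ``background`` given as raw per-band intensities from the same
    acquisition (see :func:`background_spectrum`).
    """
    ref = stack._bands(stack.reference)
    dark = stack._bands(stack.dark)
    denom = ref - dark
    bad = np.nonzero(np.min(denom.reshape(-1, denom.shape[-1]), axis=0) <= 0)[0]
    if bad.size:
        raise CalibrationError(
            f"reference does not exceed dark at band "
            f"{stack.wavelengths[bad[0]]:g} nm"
        )
    num = (stack.data - dark) / denom
    # background is a raw per-band spectrum: correct it with the per-band
    # mean calibration frames
    ref_b = ref.mean(axis=(0, 1)) if ref.ndim == 3 else ref.ravel()
    dark_b = dark.mean(axis=(0, 1)) if dark.ndim == 3 else dark.ravel()
    bg_corr = (np.asarray(background, float) - dark_b) / (ref_b - dark_b)
    if np.any(bg_corr <= 0):
        raise CalibrationError("background spectrum non-positive after "
                               "dark correction")
    return num / bg_corr.reshape(1, 1, -1)


def map_so2(stack: SpectralStack,
            background_roi: np.ndarray | None = None,
            background: np.ndarray | None = None,
            table: ExtinctionTable | None = None,
            r_threshold: float = R_THRESHOLD,
            min_bands: int = MIN_BANDS) -> SO2Map:
    """Per-pixel SO2 map: corrected ratio -> vessel absorbance -> NNLS.

    Either an avascular ``background_roi`` mask or an explicit raw
    ``background`` spectrum must be given. Pixel failures become reject
    reasons; the map never aborts as a whole. Processing is
    pixel-independent, hence order-invariant.
    """
    if background is None:
        if background_roi is None:
            raise ValueError("either background_roi or background required")
        background = background_spectrum(stack, background_roi)
    ratio = corrected_ratio(stack, background)
    with np.errstate(divide="ignore", invalid="ignore"):
        absorbance = np.where(ratio > 0, -np.log10(np.maximum(ratio, 1e-300)),
                              np.nan)
    rows, cols, nb = absorbance.shape
    unmixer = SO2Unmixer(wavelengths=stack.wavelengths, table=table,
                         r_threshold=r_threshold, min_bands=min_bands).fit()
    results = unmixer.unmix(absorbance.reshape(-1, nb))
    so2 = np.array([r.so2 for r in results]).reshape(rows, cols)
    accepted = np.array([r.accepted for r in results]).reshape(rows, cols)
    pearson = np.array([r.pearson_r for r in results]).reshape(rows, cols)
    reason = np.array([r.reason for r in results], dtype=object
                      ).reshape(rows, cols)
    return SO2Map(so2, accepted, pearson, reason)


# ---------------------------------------------------------------------------
# Dynamics


def delta_so2(series: OxygenTimeSeries) -> np.ndarray:
    """Relative SO2 change (S_i - S_BL) / S_BL against the baseline mean.

    Invariant to rescaling the whole series by any k > 0.
    """
    bl = series.baseline
    if bl == 0:
        raise ValueError("baseline SO2 is zero; relative change undefined")
    return (series.so2_values - bl) / bl


def hypoxia_metrics(series: OxygenTimeSeries, stimulus_onset: float):
    """Peak response and recovery time of a hypoxia challenge.

    peak_response is the maximal relative SO2 decrease at/after stimulus
    onset (a positive fraction; 0 for a flat series). recovery_time is the
    time from onset until SO2 first returns to at least baseline after the
    trough, linearly interpolated between samples and requiring two
    consecutive at-or-above-baseline samples to guard against noise;
    None when the series never recovers.
    """
    d = delta_so2(series)
    t = series.times
    post = t >= stimulus_onset
    if not post.any():
        raise ValueError("series does not span the stimulus onset")
    dpost = d[post]
    tpost = t[post]
    peak = float(max(0.0, -dpost.min()))
    if peak == 0.0:
        return 0.0, 0.0
    trough = int(np.argmin(dpost))
    rec_time = None
    for i in range(trough + 1, dpost.size):
        if dpost[i] >= 0.0 and (i + 1 >= dpost.size or dpost[i + 1] >= 0.0):
            t0, t1 = tpost[i - 1], tpost[i]
            d0, d1 = dpost[i - 1], dpost[i]
            if d0 < 0.0 and d1 != d0:
                t_cross = t0 + (0.0 - d0) * (t1 - t0) / (d1 - d0)
            else:
                t_cross = t1
            rec_time = float(t_cross - stimulus_onset)
            break
    return peak, rec_time


# ---------------------------------------------------------------------------
# Concentric-annulus tumor quantification

RING_STEP_MM = 0.5
MAX_RADIUS_MM = 4.5
TUMOR_RADIUS_MM = 3.0


def annulus_profile(so2_map: SO2Map, center: tuple, pixel_size: float
                    ) -> AnnulusProfile:
    """Mean accepted SO2 in 0.5 mm rings within 4.5 mm of the tumor center.

    ``center`` is (row, col) in floating pixels; ring membership is by
    pixel-center distance. The tumor region aggregates accepted pixels
    within 3 mm, the adjacent region 3-4.5 mm.
    """
    rows, cols = so2_map.so2.shape
    cr, cc = center
    max_px = MAX_RADIUS_MM / pixel_size
    if (cr - max_px < -0.5 or cc - max_px < -0.5
            or cr + max_px > rows - 0.5 or cc + max_px > cols - 0.5):
        raise ValueError("4.5 mm radius does not fit inside the image")
    rr, cc_idx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dist_mm = np.hypot(rr - cr, cc_idx - cc) * pixel_size
    edges = np.arange(0.0, MAX_RADIUS_MM + RING_STEP_MM / 2, RING_STEP_MM)
    n_rings = edges.size - 1
    means = np.full(n_rings, np.nan)
    counts = np.zeros(n_rings, dtype=int)
    ok = so2_map.accepted_mask & np.isfinite(so2_map.so2)
    for i in range(n_rings):
        ring = (dist_mm >= edges[i]) & (dist_mm < edges[i + 1]) & ok
        counts[i] = int(ring.sum())
        if counts[i]:
            means[i] = float(so2_map.so2[ring].mean())
    tumor = (dist_mm < TUMOR_RADIUS_MM) & ok
    adjacent = (dist_mm >= TUMOR_RADIUS_MM) & (dist_mm < MAX_RADIUS_MM) & ok
    tumor_mean = float(so2_map.so2[tumor].mean()) if tumor.any() else np.nan
    adj_mean = float(so2_map.so2[adjacent].mean()) if adjacent.any() else np.nan
    return AnnulusProfile(edges, means, counts, tumor_mean, adj_mean)


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O


def write_stack(stack: SpectralStack, prefix) -> None:
    """Write data/reference/dark as multi-page TIFF (pages in ascending
    wavelength order) plus a YAML sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(f"{prefix}.tif",
                     np.moveaxis(stack.data, 2, 0).astype(np.float32))
    ref = stack.reference if stack.reference.ndim == 3 else \
        np.broadcast_to(stack.reference, stack.data.shape)
    dark = stack.dark if stack.dark.ndim == 3 else \
        np.broadcast_to(stack.dark, stack.data.shape)
    tifffile.imwrite(f"{prefix}_reference.tif",
                     np.moveaxis(np.asarray(ref), 2, 0).astype(np.float32))
    tifffile.imwrite(f"{prefix}_dark.tif",
                     np.moveaxis(np.asarray(dark), 2, 0).astype(np.float32))
    meta = {
        "wavelengths_nm": [float(w) for w in stack.wavelengths],
        "pixel_size_mm": float(stack.pixel_size),
        "mode": stack.mode,
    }
    with open(f"{prefix}.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stack(prefix) -> SpectralStack:
    prefix = Path(prefix)
    with open(f"{prefix}.yaml") as fh:
        meta = yaml.safe_load(fh)
    data = np.moveaxis(tifffile.imread(f"{prefix}.tif"), 0, 2)
    ref = np.moveaxis(tifffile.imread(f"{prefix}_reference.tif"), 0, 2)
    dark = np.moveaxis(tifffile.imread(f"{prefix}_dark.tif"), 0, 2)
    return SpectralStack(data, np.asarray(meta["wavelengths_nm"]), ref, dark,
                         meta["pixel_size_mm"], meta["mode"])
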
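"""Monte Carlo photon transport through layered tissue with reflective and
transmissive detection.

The geometry is a laterally infinite slab stack illuminated from above by a
flat (top-hat) beam at normal incidence; z increases downward from the
illuminated surface. One layer may be designated vascular: its absorption
follows whole-blood hemoglobin content and saturation per band, while every
other optical parameter is wavelength-independent. Detection integrates all
weight exiting the top (reflective) or bottom (transmissive) surface within
a co-axial aperture; a radial exit profile is kept as a diagnostic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from ._rng import derive_seed
from .spectra import BloodSpec, ExtinctionTable, WavelengthGrid, blood_mu_a

#: Russian-roulette weight threshold and survival probability (MCML custom)
ROULETTE_THRESHOLD = 1e-4
ROULETTE_CHANCE = 0.1

#: Radial diagnostic binning: 100 bins of 0.05 cm
N_RADIAL_BINS = 100
RADIAL_BIN_WIDTH = 0.05


class ConfigurationError(ValueError):
    """Invalid tissue/beam/detection configuration."""


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous slab layer.

    thickness in cm (np.inf allowed for a semi-infinite bottom layer),
    mu_a and mu_s in cm^-1, Henyey-Greenstein anisotropy g in (-1, 1),
    refractive index n >= 1.
    """

    thickness: float
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class TissueModel:
    """Ordered optical layers, top to bottom, with an optional vascular layer.

    When ``vascular_layer_index`` is set, that layer's mu_a is replaced per
    band by the whole-blood absorption of ``vascular_blood`` during spectral
    sweeps. ``vessel_depth`` is the distance from the illuminated surface to
    the top of the vascular layer.
    """

    layers: tuple
    vascular_layer_index: int | None = None
    vascular_blood: BloodSpec | None = None
    vascular_blood_fraction: float = 1.0
    ambient_n: float = 1.0

    def __post_init__(self):
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("at least one layer required")
        if self.vascular_layer_index is not None:
            if not 0 <= self.vascular_layer_index < len(layers):
                raise ValueError("vascular layer index out of range")
            if self.vascular_blood is None:
                raise ValueError("vascular layer requires a BloodSpec")
        if not 0.0 < self.vascular_blood_fraction <= 1.0:
            raise ValueError("blood volume fraction must be in (0, 1]")
        object.__setattr__(self, "layers", layers)

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    @property
    def vessel_depth(self) -> float | None:
        if self.vascular_layer_index is None:
            return None
        return float(sum(l.thickness
                         for l in self.layers[: self.vascular_layer_index]))

    def background(self) -> "TissueModel":
        """Identical stack with the vascular layer's blood absorption
        replaced by the absorption of its host (nearest non-vascular
        neighbour) layer."""
        if self.vascular_layer_index is None:
            return self
        i = self.vascular_layer_index
        host = self.layers[i + 1] if i + 1 < len(self.layers) else self.layers[i - 1]
        newlayers = list(self.layers)
        newlayers[i] = replace(newlayers[i], mu_a=host.mu_a)
        return TissueModel(tuple(newlayers), vascular_layer_index=None,
                           vascular_blood=None, ambient_n=self.ambient_n)

    def same_geometry(self, other: "TissueModel") -> bool:
        if len(self.layers) != len(other.layers) or self.ambient_n != other.ambient_n:
            return False
        return all(
            a.thickness == b.thickness and a.mu_s == b.mu_s
            and a.g == b.g and a.n == b.n
            for a, b in zip(self.layers, other.layers)
        )


@dataclass(frozen=True)
class BeamSpec:
    """Flat circular beam at normal incidence.

    diameter in cm (default 4), energy in J (default 0.1; fractions are
    energy-normalized so this only scales absolute intensities),
    detection_radius in cm — None means the co-axial aperture defaults to
    the beam radius; np.inf tallies every exit.
    """

    diameter: float = 4.0
    energy: float = 0.1
    profile: str = "flat"
    detection_radius: float | None = None

    def __post_init__(self):
        if self.diameter <= 0 or self.energy <= 0:
            raise ValueError("beam diameter and energy must be positive")
        if self.profile != "flat":
            raise ValueError("only the flat beam profile is supported")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def aperture(self) -> float:
        return self.radius if self.detection_radius is None else self.detection_radius


@dataclass
class DetectionRecord:
    """Integrated detection fractions for one run at one wavelength.

    All fractions are per unit launched weight. ``escaped_fraction`` is
    weight exiting outside the detection aperture; the five fractions sum
    to 1 within float rounding (exactly 1 minus nothing: weight-exact
    roulette bookkeeping).
    """

    wavelength: float
    reflected_fraction: float
    transmitted_fraction: float
    absorbed_fraction: float
    specular_fraction: float
    escaped_fraction: float
    photon_count: int
    seed: int
    radial_edges: np.ndarray = field(repr=False, default=None)
    reflected_profile: np.ndarray = field(repr=False, default=None)
    transmitted_profile: np.ndarray = field(repr=False, default=None)

    @property
    def conservation_residual(self) -> float:
        return abs(self.reflected_fraction + self.transmitted_fraction
                   + self.absorbed_fraction + self.specular_fraction
                   + self.escaped_fraction - 1.0)


def optical_signature(model: TissueModel) -> tuple:
    """Canonical optical form of a stack: adjacent layers with identical
    (mu_a, mu_s, g, n) merged. Two models with equal signatures are
    physically indistinguishable (transport depends on the optical
    profile, not on where bookkeeping splits it into layers); useful for
    sharing background sweeps across vessel depths."""
    merged: list[list[float]] = []
    for l in model.layers:
        props = (l.mu_a, l.mu_s, l.g, l.n)
        if merged and tuple(merged[-1][1:]) == props:
            merged[-1][0] += l.thickness
        else:
            merged.append([l.thickness, *props])
    # round thickness sums so equivalent splits hash identically
    return (model.ambient_n,
            tuple((round(m[0], 9), *m[1:]) for m in merged))


def _layer_arrays(model: TissueModel, mu_a_vascular: float | None):
    th = np.array([l.thickness for l in model.layers])
    mua = np.array([l.mu_a for l in model.layers])
    mus = np.array([l.mu_s for l in model.layers])
    g = np.array([l.g for l in model.layers])
    n = np.array([l.n for l in model.layers])
    if mu_a_vascular is not None and model.vascular_layer_index is not None:
        mua[model.vascular_layer_index] = mu_a_vascular
    return th, mua, mus, g, n


def simulate(model: TissueModel, beam: BeamSpec, wavelength: float,
             photon_count: int, seed: int,
             mu_a_vascular: float | None = None) -> DetectionRecord:
    """Transport ``photon_count`` packets through ``model`` at one band.

    Deterministic given (seed, photon_count). ``mu_a_vascular`` overrides
    the vascular layer's absorption for this band (used by spectral
    sweeps); by default layer mu_a values are used as-is.
    """
    if photon_count < 1:
        raise ValueError("photon_count must be >= 1")
    th, mua, mus, g, n = _layer_arrays(model, mu_a_vascular)
    det = beam.aperture
    det_arg = -1.0 if np.isinf(det) else float(det)
    refl, trans, absd, spec, esc, rprof, tprof = _kernel.transport(
        int(photon_count), int(seed) & 0x7FFFFFFF, th, mua, mus, g, n,
        float(model.ambient_n), beam.radius, det_arg,
        ROULETTE_THRESHOLD, N_RADIAL_BINS, RADIAL_BIN_WIDTH,
    )
    edges = np.arange(N_RADIAL_BINS + 1) * RADIAL_BIN_WIDTH
    return DetectionRecord(
        wavelength=float(wavelength),
        reflected_fraction=float(refl),
        transmitted_fraction=float(trans),
        absorbed_fraction=float(absd),
        specular_fraction=float(spec),
        escaped_fraction=float(esc),
        photon_count=int(photon_count),
        seed=int(seed) & 0x7FFFFFFF,
        radial_edges=edges,
        reflected_profile=rprof,
        transmitted_profile=tprof,
    )


def spectral_sweep(model: TissueModel, beam: BeamSpec, grid: WavelengthGrid,
                   table: ExtinctionTable, photon_count: int, seed: int,
                   tag: str = "sample") -> list[DetectionRecord]:
    """Run :func:`simulate` per band in grid order.

    The vascular layer's mu_a follows whole-blood absorption per band;
    every other parameter is wavelength-independent. Per-band seeds are
    derived by hashing (master seed, band index, model tag), so results
    are reproducible and order-independent.
    """
    records = []
    for i, lam in enumerate(grid.centers):
        mu_a_v = None
        if model.vascular_layer_index is not None:
            blood = model.vascular_blood
            eps = (table.oxy(lam)[0] * blood.so2
                   + table.deoxy(lam)[0] * (1.0 - blood.so2))
            mu_blood = float(np.log(10.0) * blood.hemoglobin_molarity * eps)
            f = model.vascular_blood_fraction
            host = model.layers[model.vascular_layer_index].mu_a
            mu_a_v = f * mu_blood + (1.0 - f) * host
        sub = derive_seed(seed, i, tag)
        records.append(simulate(model, beam, lam, photon_count, sub,
                                mu_a_vascular=mu_a_v))
    return records


def paired_detection(sample_model: TissueModel, background_model: TissueModel,
                     beam: BeamSpec, grid: WavelengthGrid,
                     table: ExtinctionTable, photon_count: int,
                     seed: int) -> pd.DataFrame:
    """Sample and background sweeps tabulated for the absorbance ratio.

    Returns a tidy frame with one row per (wavelength, mode), mode in
    {reflective, transmissive}; background runs use independent derived
    seeds. Raises ConfigurationError if the two models differ anywhere but
    the vascular layer's absorption.
    """
    if not sample_model.same_geometry(background_model):
        raise ConfigurationError(
            "sample and background models must share geometry (layer "
            "thicknesses, mu_s, g, n, ambient index)"
        )
    if not np.isfinite(sample_model.total_thickness):
        raise ConfigurationError(
            "bottom layer is semi-infinite; transmissive detection "
            "requires a finite total thickness"
        )
    srec = spectral_sweep(sample_model, beam, grid, table, photon_count,
                          seed, tag="sample")
    brec = spectral_sweep(background_model, beam, grid, table, photon_count,
                          seed, tag="background")
    rows = []
    for s, b in zip(srec, brec):
        for mode, sf, bf in (
            ("reflective", s.reflected_fraction, b.reflected_fraction),
            ("transmissive", s.transmitted_fraction, b.transmitted_fraction),
        ):
            rows.append({
                "wavelength_nm": s.wavelength, "mode": mode,
                "sample_fraction": sf, "background_fraction": bf,
                "photons": s.photon_count, "seed": s.seed,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default layered skin model

#: Literature-typical skin layer optics for the VISIBLE band (500-720 nm),
#: overridable from config: epidermis 100 um (melanin-dominated absorption),
#: dermis split by the vascular layer (absorption includes baseline blood
#: content and sets the ~1 mm penetration depth that separates the two
#: detection geometries), 500 um vascular layer; forward scattering
#: (g 0.8-0.9) at n = 1.4.
EPIDERMIS = dict(thickness=0.01, mu_a=10.0, mu_s=150.0, g=0.8, n=1.4)
DERMIS = dict(mu_a=2.0, mu_s=120.0, g=0.9, n=1.4)
VASCULAR = dict(thickness=0.05, mu_s=120.0, g=0.9, n=1.4)
DEFAULT_TOTAL_THICKNESS = 0.3
#: Blood volume fraction of the vascular layer. A dermal vascular plexus is
#: perfused tissue, not bulk blood; a few percent blood by volume is the
#: literature-typical range and keeps the layer in the linear-absorbance
#: regime the band-ratio analysis assumes.
DEFAULT_BLOOD_FRACTION = 0.05


def skin_model(vessel_depth: float, blood: BloodSpec,
               total_thickness: float = DEFAULT_TOTAL_THICKNESS,
               epidermis: dict = EPIDERMIS, dermis: dict = DERMIS,
               vascular: dict = VASCULAR,
               blood_volume_fraction: float = DEFAULT_BLOOD_FRACTION
               ) -> TissueModel:
    """Build the default layered skin model with the vascular layer's top
    at ``vessel_depth`` cm below the surface.

    Stack: epidermis (thinned/omitted for very shallow vessels), dermis
    down to the vessel, the vascular layer, dermis to ``total_thickness``.
    The vascular layer's mu_a placeholder is the dermis value; spectral
    sweeps override it per band from ``blood``.
    """
    v_th = vascular["thickness"]
    if vessel_depth < 0:
        raise ConfigurationError("vessel depth must be non-negative")
    if vessel_depth + v_th > total_thickness:
        raise ConfigurationError(
            f"vessel at {vessel_depth:g} cm does not fit in a "
            f"{total_thickness:g} cm slab"
        )
    layers = []
    epi_th = min(epidermis["thickness"], vessel_depth)
    if epi_th > 0:
        layers.append(OpticalLayer(thickness=epi_th, mu_a=epidermis["mu_a"],
                                   mu_s=epidermis["mu_s"], g=epidermis["g"],
                                   n=epidermis["n"]))
    upper_dermis = vessel_depth - epi_th
    if upper_dermis > 1e-12:
        layers.append(OpticalLayer(thickness=upper_dermis, **dermis))
    v_index = len(layers)
    layers.append(OpticalLayer(mu_a=dermis["mu_a"], **vascular))
    lower = total_thickness - vessel_depth - v_th
    if lower > 1e-12:
        layers.append(OpticalLayer(thickness=lower, **dermis))
    return TissueModel(tuple(layers), vascular_layer_index=v_index,
                       vascular_blood=blood,
                       vascular_blood_fraction=blood_volume_fraction)
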
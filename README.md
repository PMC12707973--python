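# tdhsi — transmissive- and reflective-detected hyperspectral oximetry

Wide-field hyperspectral imaging (HSI) maps blood oxygen saturation
(SO₂ = oxyHb / (oxyHb + deoxyHb)) by exploiting the distinct visible
absorption spectra of oxy- and deoxyhemoglobin. Conventional HSI detects
*reflected* light, so strong superficial scattering buries the signal of
vessels deeper than about a millimetre. Detecting the *transmitted* light
instead — through thin anatomy such as a mouse ear or a dorsal skinfold —
forces every detected photon to cross the vascular plane, preserving the
hemoglobin signature at depth.

This package provides, for researchers in biomedical optics and
microcirculation imaging:

- **Monte Carlo photon transport** (`tdhsi.mc_transport`): MCML-style
  packet transport through layered slabs (implicit capture,
  Henyey–Greenstein scattering, Fresnel boundaries, Russian roulette) with
  reflective and transmissive tallies, paired sample/background sweeps over
  the 23-band 500–720 nm grid, and a configurable layered skin model with a
  vascular layer at adjustable depth.
- **Spectral unmixing** (`tdhsi.unmixing`): the modified Beer–Lambert
  model A(λ) = ξ + εoxy(λ)·B·SO₂·L + εdeoxy(λ)·B·(1−SO₂)·L, solved per
  spectrum by non-negative least squares (SO₂ = C₂/(C₂+C₃)) and gated by a
  Pearson goodness-of-fit threshold of 0.9. Exposed both as functions and
  as a scikit-learn-compatible `SO2Unmixer` estimator.
- **Imaging pipeline** (`tdhsi.imaging_pipeline`): reference/dark frame
  correction, per-pixel SO₂ mapping with accept/reject masks, relative SO₂
  dynamics (ΔSO₂ = (Sᵢ − S_BL)/S_BL), hypoxia peak-response and
  recovery-time metrics, and concentric-annulus quantification around a
  tumor center (0.5 mm rings to 4.5 mm; tumor ≤ 3 mm).
- **Synthetic data** (`tdhsi.synthetic`): intralipid-bath capillary
  phantoms with a diagonal depth ramp and known ground truth, plus the
  depth-study and sensitivity-study drivers comparing the two detection
  geometries.
- A `tdhsi` **command line** (simulate, map, dynamics, annuli, study,
  make-phantom).

Hemoglobin extinction spectra are vendored as a synthetic 1-nm compilation
(450–1000 nm) that is shape-faithful to the standard published data; all
forward and inverse steps share it, so round trips are exact.

## Worked example

```python
import numpy as np
from tdhsi import (BloodSpec, BeamSpec, WavelengthGrid, ExtinctionTable,
                   skin_model, paired_detection, vessel_absorbance,
                   build_design_matrix, solve)

grid, table = WavelengthGrid(), ExtinctionTable.vendored()
dm = build_design_matrix(grid, table)

for depth_mm in (0.0, 1.0, 2.0):
    model = skin_model(depth_mm / 10, BloodSpec(so2=0.98))
    det = paired_detection(model, model.background(), BeamSpec(),
                           grid, table, photon_count=20_000, seed=42)
    for mode in ("reflective", "transmissive"):
        sub = det[det["mode"] == mode]
        res = solve(vessel_absorbance(sub["sample_fraction"].to_numpy(),
                                      sub["background_fraction"].to_numpy(),
                                      grid), dm)
        print(f"depth {depth_mm} mm {mode:12s} SO2="
              f"{res.so2 if res.accepted else float('nan'):.3f} "
              f"r={res.pearson_r:.3f}")
```

Output (20 000 photons/band, seed 42):

```
depth 0.0 mm reflective   SO2=0.867 r=0.998
depth 0.0 mm transmissive SO2=0.914 r=0.998
depth 1.0 mm reflective   SO2=0.647 r=0.964
depth 1.0 mm transmissive SO2=0.933 r=0.998
depth 2.0 mm reflective   SO2=nan r=0.772
depth 2.0 mm transmissive SO2=0.920 r=0.997
```

At the surface both geometries read the arterial preset comparably; by
1–2 mm the reflective estimate collapses (and fails the Pearson gate at
2 mm) while the transmissive estimate is essentially depth-independent.
The residual negative bias of both modes reflects diffuse path-length
dispersion that the single-path modified Beer–Lambert model does not
capture; relative changes, which is what the sensitivity analysis scores,
largely cancel it.

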
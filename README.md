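# ppgmc — Monte Carlo finger photoplethysmography across skin pigmentation

`ppgmc` is a Monte Carlo simulator of light transport through a
multi-layered human finger at the two pulse-oximetry wavelengths (red,
660 nm; infrared, 940 nm), built to quantify how skin pigmentation
affects the photoplethysmography (PPG) signal in transmittance and
reflectance sensor geometries. It is aimed at biomedical-optics
researchers and sensor designers studying the pigmentation bias of
PPG-based devices.

## Model in brief

A 13.0 mm finger slab — six-sublayer skin (0.95 mm), fat (0.5 mm),
muscle with a cylindrical bone (10.1 mm), fat, mirrored skin — is
illuminated at normal incidence by a Gaussian beam. Pigmentation enters
through the epidermal melanosome volume fraction v_mel (light 0.0255,
moderate 0.155, dark 0.305), with epidermal absorption

    μa_epi(λ) = v_mel·(6.6×10¹⁰ λ⁻³·³³) + v_W·μa_W(λ) + (1 − v_mel − v_W)·μa_base(λ)   [mm⁻¹]

Cardiac pulsatility is the doubling of the dermal blood volume fraction
during systole at SpO₂ = 100%. Weighted photon packets undergo
exponential stepping, implicit-capture absorption, Henyey–Greenstein
scattering, Fresnel boundary handling and Russian roulette; disc
detectors score transmittance (opposite face) or reflectance (same face,
source–detector separation s = 1–9 mm). From paired systole/diastole
runs sharing one random seed the PPG components follow as

    AC = I_d − I_s,   DC = I_s,

with I the detected intensity, and run precision as the convergence rate
Q = 1/√N over the detected count N (pass: Q ≤ 0.001).

## Worked example

```python
from ppgmc import ScenarioConfig, run_scenario
from ppgmc.ppg_metrics import IntensityPair, ac_dc

cfg = ScenarioConfig(wavelength=660, skin_type="dark", phase="diastole",
                     mode="reflectance", sds=3.0, n_photons=300_000, seed=42)
dia = run_scenario(cfg)
sys_ = run_scenario(cfg.with_phase("systole"))
m = ac_dc(IntensityPair(I_s=sys_.intensity, I_d=dia.intensity))
print(f"N={dia.n_detected}  AC={m.AC:.3e}  DC={m.DC:.3e}  AC/DC={m.ratio:.4f}")
```

prints

```
N=674  AC=5.382e-06  DC=1.427e-04  AC/DC=0.0377
```

i.e. at a 3 mm separation on dark skin, 674 of 3×10⁵ red-light packets
reach the detector; the pulsatile component is ~3.8% of the baseline.
The same scenario on light skin gives AC/DC = 0.0578 — pigmentation
suppresses the pulsatile signal fraction.

The numbered drivers under `analysis/` run the study end to end and
write tables and figures under `results/`:

```bash
python analysis/01_optical_properties.py   # property tables + first-step diagnostics
python analysis/02_transmittance.py        # melanin vs detected light, per-layer absorbance
python analysis/03_reflectance.py          # separation sweep, AC/DC contrast, path stats
python analysis/04_report.py               # figures + summary tables
```

The `ppgmc` CLI offers the same entry points (`ppgmc grid`, `ppgmc
simulate`, `ppgmc report`, `ppgmc verify`).

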
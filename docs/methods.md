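# Methods

## Problem and model

`ppgmc` simulates how red (660 nm) and infrared (940 nm) light — the two
pulse-oximetry wavelengths — travels through a human finger, and how the
photoplethysmography (PPG) signal that a finger sensor records depends on
skin pigmentation. Pigmentation is represented by the melanosome volume
fraction of the epidermis, v_mel, at three Fitzpatrick-scale anchors:
light (v_mel = 0.0255), moderate (0.155), and dark (0.305).

The finger is a laterally unbounded slab stack of total thickness 13.0 mm
along the depth axis z:

| region | thickness (mm) |
|---|---|
| skin, six sublayers (stratum corneum 0.02, epidermis 0.08, papillary dermis 0.15, upper blood-net 0.08, reticular dermis 0.40, deep blood-net 0.22) | 0.95 |
| subcutaneous fat | 0.5 |
| muscle, containing a cylindrical bone (radius 2.5 mm, axis along the finger at mid-depth) | 10.1 |
| fat | 0.5 |
| skin, mirrored | 0.95 |

The light source illuminates z = 0 at normal incidence with a Gaussian
beam (σ = 0.25 mm). The detector is a disc of radius 0.5 mm: in
transmittance mode it faces the source across the finger at z = 13 mm; in
reflectance mode it sits on the illuminated surface at a source–detector
separation s ∈ {1, 3, 5, 7, 9} mm along x.

## Optical properties

Scattering (μs, g) is taken per bulk tissue at each wavelength; the six
skin sublayers share the tabulated skin scattering columns (μs =
25.62/15.68 mm⁻¹, g = 0.91/0.94 at 660/940 nm) in both cardiac phases.
Absorption is built from an additive chromophore mixture:

- melanin: μa = 6.6×10¹⁰ · λ⁻³·³³ mm⁻¹ (26.94 at 660 nm, 8.299 at 940 nm);
- whole blood: SpO₂-weighted oxy/deoxyhaemoglobin mix, evaluated at
  SpO₂ = 100%;
- water: 0.00036 / 0.02674 mm⁻¹;
- baseline pigment-free tissue: (0.244 + 85.3·e^(−(λ−154)/66.2)) cm⁻¹,
  converted to mm⁻¹.

Epidermis: μa = v_mel·μa_mel + v_W·μa_W + (1 − v_mel − v_W)·μa_base with
v_W = 0.65. Dermal sublayers: the same sum with the blood term
v_b·μa_blood, where v_b doubles during systole — this doubling is the
entire systole/diastole difference, so the AC component isolates the
pulsatile blood volume. The stratum corneum uses configured absorption
constants (0.05 / 0.02 mm⁻¹) chosen so that the largest step deviate that
clears the 0.02 mm layer, exp(−μt·d), reproduces the published diagnostic
values 0.5985 (660 nm) and 0.7305 (940 nm).

Sublayer blood and water fractions are a reconstruction (the source
models are not tabulated in full): diastolic blood fractions 0 / 0 /
0.04 / 0.30 / 0.04 / 0.10 and water fractions 0.05 / 0.65 / 0.65 / 0.40 /
0.65 / 0.65 through the stack. The upper blood-net water fraction is
0.40 rather than the 0.65 used elsewhere so that the doubled systolic
blood volume still fits in a unit volume; the two fractions' sum bounds
the mixture physically. Refractive index is 1.4 for all tissue and 1.0
for the surroundings: interior boundaries are index-matched (no internal
Fresnel events), the two outer surfaces reflect and refract.

## Transport algorithm

Weighted-packet Monte Carlo in the MCML tradition. Per packet: sample an
optical-depth step −ln ξ; convert to geometric length by the local
μt = μa + μs; truncate at layer planes or the bone-cylinder surface and
continue with the remaining optical depth (index-matched interfaces need
no re-scaling); at an interaction deposit w·μa/μt (implicit capture) into
the current region and sample a Henyey–Greenstein deflection
(inverse-CDF) with uniform azimuth; below weight 10⁻⁴ play Russian
roulette with survival factor 10. At the outer surfaces the unpolarised
Fresnel coefficient decides stochastically between internal reflection
and escape; escaping packets are scored as detected if they exit within
the detector disc, otherwise as escaped-undetected. Packets wandering
more than 20 mm laterally from the source axis are terminated as lost
weight. Specular reflection at launch (≈2.78% at normal incidence) is
deducted from the initial weight.

Every loss channel is tallied and the identity

    launched = specular + absorbed + detected + escaped + lateral
               + roulette-killed − roulette-gain

holds to floating-point rounding (~10⁻¹²; tests enforce 10⁻⁶) on every
run — the roulette gain term makes the accounting exact rather than
merely unbiased in expectation.

Randomness is counter-based: photon i of a run with seed S starts an
xorshift64* stream at splitmix64(S ⊕ i·φ64). Results are therefore
bit-reproducible for a (config, seed) pair, independent of batch size,
and paired systole/diastole runs that share a seed use identical launch
positions and random sequences. This common-random-number pairing is what
makes AC = I_d − I_s estimable at desk-scale photon budgets: the phases
differ only through dermal μa, so most trajectories coincide and the
difference estimator's variance collapses.

## Derived statistics

- AC = I_d − I_s, DC = I_s, with I the detected weight per launched
  packet. The AC sign is preserved; a negative value would flag a model
  error rather than be masked.
- Convergence rate Q = 1/√N over the detected packet count N; runs with
  Q > 0.001 (N < 10⁶) are flagged as non-converged but never dropped.
- Relative absorbance per layer: weight deposited along the histories of
  detected packets only, normalised to 100%.
- Mean optical pathlength and mean penetration depth: unweighted means of
  each detected packet's cumulative pathlength and maximum depth.
- Percentage differences between skin types use the symmetric form
  100·|a−b|/((a+b)/2), since no reference group is privileged.
- Photon profiles: 200-bin 2-D histograms over (x, z) of trajectory
  vertices of detected packets (recording is optional and off by default
  for memory reasons).

Packet counts vs intensities: with implicit capture, the number of
detected packets responds to absorption only weakly (through roulette) —
the unbiased analogue of a photon count in an analogue simulation is the
detected *weight*. All relative-detection statistics therefore compare
intensities, while Q uses the packet count as the statistical sample
size.

## Experiment grid

The full design is {light, moderate, dark} × {660, 940 nm} ×
({transmittance} ∪ {reflectance × s ∈ {1,3,5,7,9} mm}) = 36 scenario
pairs. Per-pair seeds derive from a base seed by a multiplicative-hash
counter; manifests (config + seed + version) reproduce any run
bit-identically. Grid runs default to 10⁶ photons per run with a `--full`
switch for the study-scale 10⁷; the analysis scripts default to
2–4 × 10⁵, where every reported trend (melanin ordering, pathlength and
penetration growth with separation, AC/DC contrast direction) is already
resolved. The acceptance script uses 8 × 10⁶ photons per transmittance
run (the detected-weight distribution there is broad, and this budget
brings the dark/light intensity percentage to ~2 points of standard
error) and 2 × 10⁶ per reflectance phase run.

## Numerical choices

- Geometry is half-open ([z_lo, z_hi)); positions snap exactly to layer
  edges on crossing, so no drift accumulates. Ray–cylinder intersections
  ignore roots below 10⁻⁹ mm to avoid re-detecting the surface just left.
- HG cosines are clamped to [−1, 1]; direction updates renormalise.
- A packet whose weight reaches exactly zero (possible only in
  scattering-free media) terminates as fully absorbed.
- A safety cap of 5×10⁶ interactions per packet guards against
  pathological loops; its tally is zero in all study scenarios.

## What the simulation does and does not capture

The generator emulates the study conditions: a static two-phase
(systole/diastole) finger at fixed SpO₂ = 100%, pigmentation differences
reduced to epidermal melanosome fraction, homogeneous sublayers, and a
slab geometry with an idealised bone cylinder. It does not model pulse
waveform dynamics, venous blood or SpO₂ below 100%, curved finger
surfaces, internal refractive-index mismatch, detector numerical
aperture, motion artifacts, or inter-individual variability in any
property. Absolute detected counts depend strongly on the beam/detector
dimensions, which the study does not specify; conclusions should be drawn
from the relative quantities (ratios across skin types, trends across
separation), which are robust to that choice.

## Known limitations

- The AC/DC pigmentation contrast at 660 nm, s = 3 mm (light vs dark
  skin) comes out near 0.5–0.7 in this reconstruction against the
  published 6.39: with the adopted sublayer composition, surviving
  packets in dark skin see only moderately less blood-bearing dermis than
  in light skin, so the ratio-of-ratios is far smaller than reported. The
  direction (light > moderate > dark) and the wavelength dependence
  (contrast larger at 660 nm than 940 nm) reproduce. The published value
  depends on the unprinted dermal blood fractions and detection geometry.
- Per-layer absolute absorbance shares deviate from the published
  percentages for the same reason (ordering reproduces).
- Detected-packet statistics at 10⁶ photons are sparse in the most
  absorbing scenarios (660 nm transmittance through dark skin detects
  only a handful of packets); intensity ratios there carry ~10% relative
  noise.
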
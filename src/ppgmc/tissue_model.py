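"""Optical model of a human finger for pulse-oximetry wavelengths.

The finger is a 13.0 mm slab stack — skin (six sublayers, 0.95 mm), fat
(0.5 mm), muscle (10.1 mm) containing a cylindrical bone, fat, and a
mirrored skin stack — illuminated at normal incidence on the z = 0 face.
Skin pigmentation enters through the melanosome volume fraction of the
epidermis; cardiac pulsatility through a doubling of the dermal blood
volume fraction during systole.

Absorption coefficients are built from an additive chromophore mixture
(melanin, haemoglobin, water, pigment-free baseline tissue); scattering
coefficients and anisotropies are bulk literature values per tissue at
660 nm and 940 nm.  All lengths are millimetres, all coefficients mm^-1.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

WAVELENGTHS = (660, 940)

N_TISSUE = 1.4
N_AMBIENT = 1.0

TOTAL_THICKNESS = 13.0
SKIN_THICKNESS = 0.95
FAT_THICKNESS = 0.5
MUSCLE_THICKNESS = 10.1

#: chromophore absorption coefficients, mm^-1
MUA_OXYHAEMOGLOBIN = {660: 0.15, 940: 0.65}
MUA_DEOXYHAEMOGLOBIN = {660: 1.64, 940: 0.43}
MUA_WATER = {660: 0.00036, 940: 0.02674}

#: melanin absorption power law, mu_a = A * lambda^B with lambda in nm
MELANIN_PREFACTOR = 6.6e10
MELANIN_EXPONENT = -3.33

#: bulk tissue optical properties (mua mm^-1, mus mm^-1, g) per wavelength
BULK_PROPERTIES = {
    "fat": {660: (0.0104, 6.20, 0.90), 940: (0.0170, 5.42, 0.90)},
    "muscle": {660: (0.0816, 8.61, 0.88), 940: (0.0401, 5.81, 0.91)},
    "bone": {660: (0.0351, 34.45, 0.92), 940: (0.0457, 24.70, 0.93)},
}

#: skin scattering is shared by all six sublayers and both cardiac phases
SKIN_MUS = {660: 25.62, 940: 15.68}
SKIN_G = {660: 0.91, 940: 0.94}

#: stratum corneum absorption, mm^-1 — configured constants chosen so the
#: first-interaction survival fraction exp(-mu_t * d_sc) matches the
#: model's diagnostic thresholds (0.5985 red, 0.7305 infrared)
SC_MUA = {660: 0.05, 940: 0.02}

#: default water fraction of the epidermis and its absorption partner table
EPIDERMIS_WATER_FRACTION = 0.65


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class MissingPropertyError(KeyError):
    """No tabulated optical property at the requested wavelength."""


def _require_wavelength(table: dict, wavelength: float) -> None:
    if wavelength not in table:
        raise MissingPropertyError(
            f"no tabulated value at {wavelength} nm; available: {sorted(table)}"
        )


def melanin_mua(wavelength: float) -> float:
    """Absorption coefficient of a melanosome interior, mm^-1.

    Power-law fit ``6.6e10 * lambda**-3.33`` (lambda in nm); 26.94 mm^-1
    at 660 nm and 8.299 mm^-1 at 940 nm.
    """
    if wavelength <= 0:
        raise InvalidParameterError(f"wavelength must be positive, got {wavelength}")
    return MELANIN_PREFACTOR * wavelength**MELANIN_EXPONENT


def baseline_mua(wavelength: float) -> float:
    """Absorption of pigment-free, bloodless baseline skin tissue, mm^-1.

    The literature fit ``0.244 + 85.3 * exp(-(lambda - 154) / 66.2)`` is in
    cm^-1 and is converted to mm^-1 here.
    """
    if wavelength <= 0:
        raise InvalidParameterError(f"wavelength must be positive, got {wavelength}")
    return (0.244 + 85.3 * math.exp(-(wavelength - 154.0) / 66.2)) / 10.0


def epidermis_mua(
    v_mel: float,
    wavelength: float,
    v_water: float = EPIDERMIS_WATER_FRACTION,
    mua_water: Optional[float] = None,
) -> float:
    """Epidermal absorption from the additive chromophore mixture, mm^-1.

    ``v_mel * mua_melanin + v_water * mua_water + (1 - v_mel - v_water) *
    baseline``.  With the three melanosome fractions 0.0255 / 0.155 / 0.305
    this yields 0.73 / 4.2 / 8.2 mm^-1 at 660 nm and 0.24 / 1.3 / 2.5 mm^-1
    at 940 nm.
    """
    if not (0.0 <= v_mel <= 1.0) or not (0.0 <= v_water <= 1.0):
        raise InvalidParameterError("volume fractions must lie in [0, 1]")
    if v_mel + v_water > 1.0:
        raise InvalidParameterError(
            f"v_mel + v_water = {v_mel + v_water:.3f} exceeds 1"
        )
    if mua_water is None:
        _require_wavelength(MUA_WATER, wavelength)
        mua_water = MUA_WATER[wavelength]
    return (
        v_mel * melanin_mua(wavelength)
        + v_water * mua_water
        + (1.0 - v_mel - v_water) * baseline_mua(wavelength)
    )


def blood_mua(wavelength: float, spo2: float = 1.0) -> float:
    """Whole-blood absorption as an SpO2-weighted haemoglobin mixture, mm^-1."""
    if not (0.0 <= spo2 <= 1.0):
        raise InvalidParameterError(f"spo2 must lie in [0, 1], got {spo2}")
    _require_wavelength(MUA_OXYHAEMOGLOBIN, wavelength)
    return spo2 * MUA_OXYHAEMOGLOBIN[wavelength] + (1.0 - spo2) * MUA_DEOXYHAEMOGLOBIN[wavelength]


@dataclass(frozen=True)
class SkinTypePreset:
    """Fitzpatrick-scale pigmentation group with its melanosome fraction."""

    name: str
    v_mel: float

    def __post_init__(self):
        if not (0.0 < self.v_mel < 1.0):
            raise InvalidParameterError(f"v_mel must lie in (0, 1), got {self.v_mel}")


SKIN_TYPES = {
    "light": SkinTypePreset("light", 0.0255),
    "moderate": SkinTypePreset("moderate", 0.155),
    "dark": SkinTypePreset("dark", 0.305),
}


@dataclass(frozen=True)
class SkinSublayer:
    """One of the six skin sublayers with its composition at diastole."""

    name: str
    thickness: float  # mm
    v_blood_diastole: float
    v_water: float

    def __post_init__(self):
        if self.thickness <= 0:
            raise InvalidParameterError(f"{self.name}: thickness must be positive")
        if not (0.0 <= self.v_blood_diastole <= 1.0 and 0.0 <= self.v_water <= 1.0):
            raise InvalidParameterError(f"{self.name}: fractions must lie in [0, 1]")
        if 2.0 * self.v_blood_diastole + self.v_water > 1.0:
            raise InvalidParameterError(
                f"{self.name}: systolic doubling would exceed unit volume "
                f"(2*{self.v_blood_diastole} + {self.v_water} > 1)"
            )


# Composition is adapted from multilayer skin models in the literature;
# thicknesses sum to the 0.95 mm skin slab.  The upper blood-net water
# fraction is reduced so the doubled systolic blood volume still fits in
# the unit cell.
DEFAULT_SUBLAYERS = (
    SkinSublayer("stratum_corneum", 0.02, 0.00, 0.05),
    SkinSublayer("epidermis", 0.08, 0.00, 0.65),
    SkinSublayer("papillary_dermis", 0.15, 0.04, 0.65),
    SkinSublayer("upper_blood_net", 0.08, 0.30, 0.40),
    SkinSublayer("reticular_dermis", 0.40, 0.04, 0.65),
    SkinSublayer("deep_blood_net", 0.22, 0.10, 0.65),
)

DERMAL_SUBLAYERS = (
    "papillary_dermis",
    "upper_blood_net",
    "reticular_dermis",
    "deep_blood_net",
)


def dermal_mua(sublayer: SkinSublayer, phase: str, wavelength: float) -> float:
    """Dermal sublayer absorption with phase-dependent blood volume, mm^-1.

    Systole carries twice the diastolic blood volume fraction; blood is
    fully oxygenated.  The remaining volume splits between water and
    baseline tissue.
    """
    if sublayer.name not in DERMAL_SUBLAYERS:
        raise InvalidParameterError(f"{sublayer.name} is not a dermal sublayer")
    if phase not in ("systole", "diastole"):
        raise InvalidParameterError(f"unknown cardiac phase {phase!r}")
    v_b = sublayer.v_blood_diastole * (2.0 if phase == "systole" else 1.0)
    if v_b + sublayer.v_water > 1.0:
        raise InvalidParameterError(
            f"{sublayer.name}: blood + water fractions exceed 1 during {phase}"
        )
    _require_wavelength(MUA_WATER, wavelength)
    return (
        v_b * blood_mua(wavelength, 1.0)
        + sublayer.v_water * MUA_WATER[wavelength]
        + (1.0 - v_b - sublayer.v_water) * baseline_mua(wavelength)
    )


def stratum_corneum_mua(wavelength: float) -> float:
    """Configured stratum-corneum absorption, mm^-1."""
    _require_wavelength(SC_MUA, wavelength)
    return SC_MUA[wavelength]


_MODES = ("transmittance", "reflectance")
_PHASES = ("systole", "diastole")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario of the experiment grid."""

    wavelength: float = 660
    skin_type: str = "light"
    phase: str = "diastole"
    mode: str = "transmittance"
    sds: float = 3.0  # source-detector separation, mm (reflectance only)
    n_photons: int = 100_000
    seed: int = 0
    beam_radius: float = 0.25  # Gaussian beam sigma, mm
    detector_radius: float = 0.5  # mm
    bone_radius: float = 2.5  # mm
    lateral_kill_radius: float = 20.0  # mm from the source axis
    roulette_threshold: float = 1e-4
    roulette_survival: float = 10.0
    sublayers: tuple = DEFAULT_SUBLAYERS

    def __post_init__(self):
        _require_wavelength(MUA_WATER, self.wavelength)
        if self.skin_type not in SKIN_TYPES:
            raise InvalidParameterError(f"unknown skin type {self.skin_type!r}")
        if self.phase not in _PHASES:
            raise InvalidParameterError(f"unknown phase {self.phase!r}")
        if self.mode not in _MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.n_photons < 0:
            raise InvalidParameterError("n_photons must be non-negative")
        if self.beam_radius <= 0 or self.detector_radius <= 0:
            raise InvalidParameterError("beam and detector radii must be positive")
        if self.mode == "reflectance" and self.sds < 0:
            raise InvalidParameterError("sds must be non-negative")
        if not (0 < self.bone_radius < MUSCLE_THICKNESS / 2):
            raise InvalidParameterError("bone must fit strictly inside the muscle slab")
        thick = sum(s.thickness for s in self.sublayers)
        if abs(thick - SKIN_THICKNESS) > 1e-9:
            raise InvalidParameterError(
                f"sublayer thicknesses sum to {thick} mm, expected {SKIN_THICKNESS}"
            )

    _CONFIG_KEYS = {
        "wavelength_nm": "wavelength",
        "skin_type": "skin_type",
        "phase": "phase",
        "mode": "mode",
        "sds_mm": "sds",
        "n_photons": "n_photons",
        "seed": "seed",
        "beam_radius_mm": "beam_radius",
        "detector_radius_mm": "detector_radius",
        "bone_radius_mm": "bone_radius",
        "lateral_kill_radius_mm": "lateral_kill_radius",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        kwargs = {}
        for key, value in data.items():
            if key == "sublayers":
                kwargs["sublayers"] = tuple(
                    SkinSublayer(
                        s["name"],
                        s["thickness_mm"],
                        s["v_blood_diastole"],
                        s["v_water"],
                    )
                    for s in value
                )
            elif key in cls._CONFIG_KEYS:
                kwargs[cls._CONFIG_KEYS[key]] = value
            else:
                raise InvalidParameterError(f"unknown config key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        text = open(path).read()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {file_key: getattr(self, attr) for file_key, attr in self._CONFIG_KEYS.items()}
        out["sublayers"] = [
            {
                "name": s.name,
                "thickness_mm": s.thickness,
                "v_blood_diastole": s.v_blood_diastole,
                "v_water": s.v_water,
            }
            for s in self.sublayers
        ]
        return out

    def with_phase(self, phase: str) -> "ScenarioConfig":
        return replace(self, phase=phase)


@dataclass
class FingerModel:
    """Resolved slab geometry and per-region optical properties.

    Regions 0..14 are the plane-parallel layers ordered by depth; region 15
    is the bone cylinder (axis along y at the mid-depth of the muscle slab).
    """

    region_names: list
    z_edges: np.ndarray  # 16 layer edges, z_edges[0] = 0, z_edges[-1] = 13.0
    mua: np.ndarray  # per-region, index 15 = bone
    mus: np.ndarray
    g: np.ndarray
    n_tissue: float
    n_ambient: float
    muscle_layer: int
    bone_region: int
    bone_center_z: float
    bone_radius: float
    config: ScenarioConfig = field(repr=False, default=None)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def layer_at(self, z: float) -> int:
        """Plane-layer index containing depth z (half-open [lo, hi) bins)."""
        if not (0.0 <= z <= TOTAL_THICKNESS):
            raise InvalidParameterError(f"depth {z} outside [0, {TOTAL_THICKNESS}]")
        idx = int(np.searchsorted(self.z_edges, z, side="right")) - 1
        return min(max(idx, 0), len(self.region_names) - 2)

    def region_at(self, x: float, y: float, z: float) -> int:
        """Total region lookup: every interior point maps to one region."""
        layer = self.layer_at(z)
        if layer == self.muscle_layer:
            if x * x + (z - self.bone_center_z) ** 2 <= self.bone_radius**2:
                return self.bone_region
        return layer

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_names,
                "z_low_mm": list(self.z_edges[:-1]) + [np.nan],
                "z_high_mm": list(self.z_edges[1:]) + [np.nan],
                "mua_mm": self.mua,
                "mus_mm": self.mus,
                "g": self.g,
                "n": self.n_tissue,
            }
        )


def build_finger(config: ScenarioConfig) -> FingerModel:
    """Resolve the full finger model for one scenario.

    The skin stack on the far face mirrors the illuminated one, so the
    stratum corneum sits at both outer surfaces.  Only dermal absorption
    depends on the cardiac phase; only epidermal absorption depends on the
    skin type.
    """
    lam = config.wavelength
    preset = SKIN_TYPES[config.skin_type]
    subs = config.sublayers

    def skin_props(sub: SkinSublayer) -> tuple:
        if sub.name == "stratum_corneum":
            mua = stratum_corneum_mua(lam)
        elif sub.name == "epidermis":
            mua = epidermis_mua(preset.v_mel, lam, sub.v_water)
        else:
            mua = dermal_mua(sub, config.phase, lam)
        return mua, SKIN_MUS[lam], SKIN_G[lam]

    names, edges, props = [], [0.0], []
    for sub in subs:
        names.append(sub.name + "_top")
        edges.append(edges[-1] + sub.thickness)
        props.append(skin_props(sub))
    names.append("fat_top")
    edges.append(edges[-1] + FAT_THICKNESS)
    props.append(BULK_PROPERTIES["fat"][lam])
    muscle_layer = len(names)
    names.append("muscle")
    edges.append(edges[-1] + MUSCLE_THICKNESS)
    props.append(BULK_PROPERTIES["muscle"][lam])
    names.append("fat_bottom")
    edges.append(edges[-1] + FAT_THICKNESS)
    props.append(BULK_PROPERTIES["fat"][lam])
    for sub in reversed(subs):
        names.append(sub.name + "_bottom")
        edges.append(edges[-1] + sub.thickness)
        props.append(skin_props(sub))
    names.append("bone")
    props.append(BULK_PROPERTIES["bone"][lam])

    z_edges = np.asarray(edges)
    assert abs(z_edges[-1] - TOTAL_THICKNESS) < 1e-9
    z_edges[-1] = TOTAL_THICKNESS  # snap away accumulated rounding

    mua = np.array([p[0] for p in props])
    mus = np.array([p[1] for p in props])
    g = np.array([p[2] for p in props])
    if np.any(mua < 0) or np.any(mus < 0) or np.any(mua + mus <= 0):
        raise InvalidParameterError("every region needs mua >= 0, mus >= 0, mua + mus > 0")

    bone_center = z_edges[muscle_layer] + MUSCLE_THICKNESS / 2.0
    return FingerModel(
        region_names=names,
        z_edges=z_edges,
        mua=mua,
        mus=mus,
        g=g,
        n_tissue=N_TISSUE,
        n_ambient=N_AMBIENT,
        muscle_layer=muscle_layer,
        bone_region=len(names) - 1,
        bone_center_z=bone_center,
        bone_radius=config.bone_radius,
        config=config,
    )


def property_table() -> pd.DataFrame:
    """Tidy table of every tabulated optical property at both wavelengths."""
    rows = []
    for lam in WAVELENGTHS:
        rows.append(("skin_scattering", lam, np.nan, SKIN_MUS[lam], SKIN_G[lam]))
        for tissue, table in BULK_PROPERTIES.items():
            mua, mus, g = table[lam]
            rows.append((tissue, lam, mua, mus, g))
        rows.append(("oxyhaemoglobin", lam, MUA_OXYHAEMOGLOBIN[lam], np.nan, np.nan))
        rows.append(("deoxyhaemoglobin", lam, MUA_DEOXYHAEMOGLOBIN[lam], np.nan, np.nan))
        rows.append(("water", lam, MUA_WATER[lam], np.nan, np.nan))
        rows.append(("melanin", lam, melanin_mua(lam), np.nan, np.nan))
        for name, preset in SKIN_TYPES.items():
            rows.append((f"epidermis_{name}", lam, epidermis_mua(preset.v_mel, lam), np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["tissue", "wavelength_nm", "mua_mm", "mus_mm", "g"])
    df["n"] = N_TISSUE
    return df
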
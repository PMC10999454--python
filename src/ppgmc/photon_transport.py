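"""Monte Carlo photon transport through the layered finger model.

Weighted-packet transport in the MCML tradition: exponential step
sampling, implicit capture (each interaction deposits ``w * mua / mut``),
Henyey-Greenstein scattering, Fresnel reflection at the two outer
air-tissue surfaces (interior boundaries are index-matched), Russian
roulette for low-weight packets, and disc detectors in transmittance or
reflectance geometry.

Every photon owns a counter-based random stream derived from the run seed
and its launch index, so a photon's history is reproducible regardless of
batching, and paired systole/diastole runs sharing a seed see identical
launch positions and random sequences (common random numbers — essential
because the pulsatile signal is a small difference of large intensities).

The inner loop is numba-compiled; the small sampling primitives it uses
(`hg_cos_theta`, `fresnel`, `update_direction`, ...) are module-level
njit functions that are equally callable from plain Python, so tests
exercise exactly the code the kernel runs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .tissue_model import FingerModel, ScenarioConfig, build_finger

__all__ = [
    "sample_step",
    "first_step_crossing_probability",
    "hg_cos_theta",
    "update_direction",
    "fresnel",
    "TransportTallies",
    "run_scenario",
]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MAX_STEPS = 5_000_000
_TRAJ_PER_PHOTON = 8192


@njit(cache=True)
def _mix64(z):
    """splitmix64 finalizer: bijective avalanche mix of a 64-bit word."""
    z = np.uint64(z)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _photon_state(seed, index):
    """Initial xorshift64* state for photon `index` of run `seed`."""
    s = _mix64(np.uint64(seed) ^ (np.uint64(index) * _GOLDEN))
    if s == np.uint64(0):
        s = _GOLDEN
    return s


@njit(cache=True)
def _next_u64(state):
    """xorshift64* step; returns (new_state, 64 random bits)."""
    s = state
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    return s, s * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True)
def _uniform(state):
    """(new_state, uniform deviate in [0, 1))."""
    s, bits = _next_u64(state)
    return s, float(bits >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _uniform_pos(state):
    """(new_state, uniform deviate in (0, 1]) — safe for log sampling."""
    s, u = _uniform(state)
    return s, 1.0 - u


@njit(cache=True)
def _gauss_pair(state):
    """Box-Muller: (new_state, n1, n2) standard normal deviates."""
    s, u1 = _uniform_pos(state)
    s, u2 = _uniform(s)
    r = math.sqrt(-2.0 * math.log(u1))
    return s, r * math.cos(2.0 * math.pi * u2), r * math.sin(2.0 * math.pi * u2)


def sample_step(xi: float, mu_t: float) -> float:
    """Free-path length ``-ln(xi) / mu_t`` in mm for a uniform deviate xi."""
    if mu_t <= 0:
        raise ValueError(f"mu_t must be positive, got {mu_t}")
    if not (0.0 < xi <= 1.0):
        raise ValueError(f"xi must lie in (0, 1], got {xi}")
    return -math.log(xi) / mu_t


def first_step_crossing_probability(mu_t_sc: float, d_sc: float) -> float:
    """Largest uniform deviate whose sampled first step clears the stratum corneum.

    A normally incident photon crosses a slab of total attenuation
    ``mu_t_sc`` and thickness ``d_sc`` on its first hop iff its step deviate
    satisfies ``-ln(xi)/mu_t >= d``, i.e. ``xi <= exp(-mu_t * d)``.
    Diagnostic used to validate the stratum-corneum parameterisation.
    """
    return math.exp(-mu_t_sc * d_sc)


@njit(cache=True)
def hg_cos_theta(g, xi):
    """Sample the deflection-angle cosine from the Henyey-Greenstein law.

    Inverse-CDF sampling; the isotropic limit g = 0 falls back to a uniform
    cosine.  The result is clamped to [-1, 1] against rounding.
    """
    if abs(g) < 1e-8:
        ct = 2.0 * xi - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


@njit(cache=True)
def update_direction(ux, uy, uz, cos_theta, phi):
    """Rotate a unit direction by polar angle acos(cos_theta), azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = cos_theta if uz > 0.0 else -cos_theta
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * cos_theta
        ny = st * (uy * uz * cp + ux * sp) / den + uy * cos_theta
        nz = -st * cp * den + uz * cos_theta
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def fresnel(n1, n2, cos_incident):
    """Unpolarised Fresnel reflectance for incidence cosine ``cos_incident``.

    Returns 1.0 beyond the critical angle.
    """
    if n1 == n2:
        return 0.0
    ci = min(1.0, max(0.0, cos_incident))
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


def roulette(w: float, u: float, threshold: float = 1e-4, survival: float = 10.0) -> float:
    """Russian-roulette a packet weight; returns the post-game weight.

    Weights at or above `threshold` are untouched.  Below it the packet
    survives with probability ``1/survival`` (weight multiplied by
    `survival`, keeping the expectation unbiased) and dies otherwise
    (returns 0.0).  `u` is a uniform deviate.  The transport kernel plays
    the identical game inline.
    """
    if survival <= 1.0:
        raise ValueError("survival factor must exceed 1")
    if w >= threshold:
        return w
    return w * survival if u < 1.0 / survival else 0.0


@njit(cache=True)
def _bone_distance(x, z, ux, uz, zc, r):
    """Distance along the ray to the bone cylinder surface (inf if missed).

    The cylinder axis runs along y through (x, z) = (0, zc); only the x-z
    components of the direction matter.
    """
    a = ux * ux + uz * uz
    if a < 1e-300:
        return np.inf
    dz = z - zc
    b = x * ux + dz * uz
    c = x * x + dz * dz - r * r
    disc = b * b - a * c
    if disc <= 0.0:
        return np.inf
    sq = math.sqrt(disc)
    t1 = (-b - sq) / a
    t2 = (-b + sq) / a
    if t1 > 1e-9:
        return t1
    if t2 > 1e-9:
        return t2
    return np.inf


@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed,
    n_photons,
    z_edges,
    mua,
    mus,
    g,
    n_tissue,
    n_ambient,
    muscle_layer,
    bone_region,
    bone_zc,
    bone_r,
    reflect_mode,
    sds,
    det_r,
    beam_sigma,
    kill_r,
    w_threshold,
    survival,
    record_traj,
    absorbed,
    det_absorbed,
    det_x,
    det_y,
    det_w,
    det_L,
    det_zmax,
    traj_x,
    traj_z,
    loss,
):
    """Trace `n_photons` packets; fill tallies in place.

    loss slots: 0 specular, 1 escaped-undetected, 2 lateral, 3 roulette
    killed, 4 roulette gain, 5 safety-cap terminations.
    """
    n_layers = len(z_edges) - 1
    z_top = z_edges[0]
    z_bottom = z_edges[n_layers]
    det_r2 = det_r * det_r
    kill_r2 = kill_r * kill_r
    r_sp = fresnel(n_ambient, n_tissue, 1.0)
    n_regions = len(mua)
    dep = np.zeros(n_regions)
    n_detected = 0
    traj_count = 0
    traj_cap = len(traj_x)
    ph_traj_x = np.zeros(_TRAJ_PER_PHOTON)
    ph_traj_z = np.zeros(_TRAJ_PER_PHOTON)

    for i in range(n_photons):
        state = _photon_state(seed, i)
        state, g1, g2 = _gauss_pair(state)
        x = beam_sigma * g1
        y = beam_sigma * g2
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0 - r_sp
        loss[0] += r_sp
        L = 0.0
        zmax = 0.0
        layer = 0
        in_bone = False
        alive = True
        detected = False
        exited = False
        dep[:] = 0.0
        n_vertex = 0
        if record_traj:
            ph_traj_x[0] = x
            ph_traj_z[0] = 0.0
            n_vertex = 1
        nsteps = 0

        while alive:
            state, xi = _uniform_pos(state)
            s_opt = -math.log(xi)
            while s_opt > 1e-12:
                region = bone_region if in_bone else layer
                mut = mua[region] + mus[region]
                d_need = s_opt / mut
                # distance to the bounding z-plane of the current layer
                if uz > 1e-12:
                    d_plane = (z_edges[layer + 1] - z) / uz
                    plane_up = True
                elif uz < -1e-12:
                    d_plane = (z_edges[layer] - z) / uz
                    plane_up = False
                else:
                    d_plane = np.inf
                    plane_up = False
                if d_plane < 0.0:
                    d_plane = 0.0
                # distance to the bone surface while inside the muscle slab
                d_bone = np.inf
                if layer == muscle_layer:
                    d_bone = _bone_distance(x, z, ux, uz, bone_zc, bone_r)
                d_boundary = d_plane if d_plane < d_bone else d_bone

                if d_boundary < d_need:
                    x += ux * d_boundary
                    y += uy * d_boundary
                    z += uz * d_boundary
                    L += d_boundary
                    if z > zmax:
                        zmax = z
                    s_opt -= d_boundary * mut
                    if d_bone < d_plane:
                        in_bone = not in_bone
                    else:
                        if plane_up:
                            if layer == n_layers - 1:
                                # far external surface
                                z = z_bottom
                                rf = fresnel(n_tissue, n_ambient, abs(uz))
                                state, u = _uniform(state)
                                if u < rf:
                                    uz = -uz
                                else:
                                    exited = True
                                    if (not reflect_mode) and (x * x + y * y <= det_r2):
                                        detected = True
                                    alive = False
                                    break
                            else:
                                layer += 1
                                z = z_edges[layer]
                                in_bone = False
                        else:
                            if layer == 0:
                                # illuminated external surface
                                z = z_top
                                rf = fresnel(n_tissue, n_ambient, abs(uz))
                                state, u = _uniform(state)
                                if u < rf:
                                    uz = -uz
                                else:
                                    exited = True
                                    if reflect_mode:
                                        dxs = x - sds
                                        if dxs * dxs + y * y <= det_r2:
                                            detected = True
                                    alive = False
                                    break
                            else:
                                layer -= 1
                                z = z_edges[layer + 1]
                                in_bone = False
                else:
                    x += ux * d_need
                    y += uy * d_need
                    z += uz * d_need
                    L += d_need
                    if z > zmax:
                        zmax = z
                    s_opt = 0.0
            if not alive:
                break
            if x * x + y * y > kill_r2:
                loss[2] += w
                alive = False
                break
            # implicit capture: deposit the absorbed share of the packet
            region = bone_region if in_bone else layer
            mut = mua[region] + mus[region]
            da = w * mua[region] / mut
            dep[region] += da
            absorbed[region] += da
            w -= da
            if w <= 0.0:
                # scattering-free region: the whole residual weight deposits
                alive = False
                break
            # Henyey-Greenstein scattering
            state, xi = _uniform(state)
            ct = hg_cos_theta(g[region], xi)
            state, xi = _uniform(state)
            ux, uy, uz = update_direction(ux, uy, uz, ct, 2.0 * math.pi * xi)
            if record_traj and n_vertex < _TRAJ_PER_PHOTON:
                ph_traj_x[n_vertex] = x
                ph_traj_z[n_vertex] = z
                n_vertex += 1
            # Russian roulette
            if w < w_threshold:
                state, u = _uniform(state)
                if u < 1.0 / survival:
                    loss[4] += (survival - 1.0) * w
                    w *= survival
                else:
                    loss[3] += w
                    alive = False
            nsteps += 1
            if nsteps > _MAX_STEPS:
                loss[5] += w
                alive = False

        if exited:
            if detected:
                det_x[n_detected] = x
                det_y[n_detected] = y
                det_w[n_detected] = w
                det_L[n_detected] = L
                det_zmax[n_detected] = zmax
                for r in range(n_regions):
                    det_absorbed[r] += dep[r]
                if record_traj:
                    for v in range(n_vertex):
                        if traj_count >= traj_cap:
                            break
                        traj_x[traj_count] = ph_traj_x[v]
                        traj_z[traj_count] = ph_traj_z[v]
                        traj_count += 1
                    if traj_count < traj_cap:
                        traj_x[traj_count] = x
                        traj_z[traj_count] = z
                        traj_count += 1
                n_detected += 1
            else:
                loss[1] += w
    return n_detected, traj_count


@dataclass
class TransportTallies:
    """Weight-accounted outcome of one transport run."""

    config: ScenarioConfig
    region_names: list
    n_launched: int
    n_detected: int
    detected_weight: float
    specular_weight: float
    escaped_weight: float
    lateral_weight: float
    roulette_killed: float
    roulette_gain: float
    safety_terminated: float
    absorbed: np.ndarray  # per region, all photons
    detected_absorbed: np.ndarray  # per region, detected photons only
    det_x: np.ndarray = field(repr=False, default=None)
    det_y: np.ndarray = field(repr=False, default=None)
    det_w: np.ndarray = field(repr=False, default=None)
    det_L: np.ndarray = field(repr=False, default=None)
    det_zmax: np.ndarray = field(repr=False, default=None)
    traj_x: np.ndarray = field(repr=False, default=None)
    traj_z: np.ndarray = field(repr=False, default=None)

    @property
    def intensity(self) -> float:
        """Detected intensity: detected weight per unit launched weight."""
        if self.n_launched == 0:
            return 0.0
        return self.detected_weight / self.n_launched

    def weight_balance(self) -> tuple[float, float]:
        """(accounted weight, launched weight) — equal up to rounding."""
        accounted = (
            self.specular_weight
            + float(self.absorbed.sum())
            + self.detected_weight
            + self.escaped_weight
            + self.lateral_weight
            + self.roulette_killed
            - self.roulette_gain
            + self.safety_terminated
        )
        return accounted, float(self.n_launched)

    def conservation_residual(self) -> float:
        """Relative weight-accounting error; ~1e-12 in practice."""
        accounted, launched = self.weight_balance()
        if launched == 0:
            return abs(accounted)
        return abs(accounted - launched) / launched

    def summary(self) -> dict:
        per_region = {
            name: float(a) for name, a in zip(self.region_names, self.absorbed)
        }
        return {
            "n_launched": self.n_launched,
            "n_detected": self.n_detected,
            "detected_weight": self.detected_weight,
            "intensity": self.intensity,
            "specular_weight": self.specular_weight,
            "escaped_weight": self.escaped_weight,
            "lateral_weight": self.lateral_weight,
            "roulette_killed": self.roulette_killed,
            "roulette_gain": self.roulette_gain,
            "safety_terminated": self.safety_terminated,
            "conservation_residual": self.conservation_residual(),
            "absorbed_per_region": per_region,
        }


def run_scenario(
    config: ScenarioConfig,
    model: FingerModel | None = None,
    record_trajectories: bool = False,
    trajectory_cap: int = 2_000_000,
) -> TransportTallies:
    """Run one full scenario and return its weight-accounted tallies.

    Identical (config, seed) pairs produce bit-identical tallies; the
    per-photon random streams make the result independent of batching.
    """
    if model is None:
        model = build_finger(config)
    n = config.n_photons
    n_regions = model.n_regions
    absorbed = np.zeros(n_regions)
    det_absorbed = np.zeros(n_regions)
    det_x = np.empty(n)
    det_y = np.empty(n)
    det_w = np.empty(n)
    det_L = np.empty(n)
    det_zmax = np.empty(n)
    cap = trajectory_cap if record_trajectories else 1
    traj_x = np.empty(cap)
    traj_z = np.empty(cap)
    loss = np.zeros(6)

    n_detected, traj_count = _transport_kernel(
        np.uint64(config.seed),
        n,
        model.z_edges,
        model.mua,
        model.mus,
        model.g,
        model.n_tissue,
        model.n_ambient,
        model.muscle_layer,
        model.bone_region,
        model.bone_center_z,
        model.bone_radius,
        config.mode == "reflectance",
        config.sds,
        config.detector_radius,
        config.beam_radius,
        config.lateral_kill_radius,
        config.roulette_threshold,
        config.roulette_survival,
        record_trajectories,
        absorbed,
        det_absorbed,
        det_x,
        det_y,
        det_w,
        det_L,
        det_zmax,
        traj_x,
        traj_z,
        loss,
    )

    return TransportTallies(
        config=config,
        region_names=model.region_names,
        n_launched=n,
        n_detected=n_detected,
        detected_weight=float(det_w[:n_detected].sum()),
        specular_weight=float(loss[0]),
        escaped_weight=float(loss[1]),
        lateral_weight=float(loss[2]),
        roulette_killed=float(loss[3]),
        roulette_gain=float(loss[4]),
        safety_terminated=float(loss[5]),
        absorbed=absorbed,
        detected_absorbed=det_absorbed,
        det_x=det_x[:n_detected].copy(),
        det_y=det_y[:n_detected].copy(),
        det_w=det_w[:n_detected].copy(),
        det_L=det_L[:n_detected].copy(),
        det_zmax=det_zmax[:n_detected].copy(),
        traj_x=traj_x[:traj_count].copy() if record_trajectories else None,
        traj_z=traj_z[:traj_count].copy() if record_trajectories else None,
    )
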
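"""Derived photoplethysmography statistics from paired transport runs.

The instantaneous PPG decomposition uses the two simulated cardiac
phases: the pulsatile component is the diastolic-minus-systolic detected
intensity, AC = I_d - I_s, and the quasi-static baseline is the systolic
intensity, DC = I_s.  Run precision is summarised by the convergence
rate Q = 1/sqrt(N) over the detected-photon count N, with Q <= 0.001
(N >= 10^6) as the pass threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photon_transport import TransportTallies
from .tissue_model import TOTAL_THICKNESS

CONVERGENCE_Q_THRESHOLD = 1e-3
CONVERGENCE_N_THRESHOLD = 1_000_000


class UndefinedRatioError(ZeroDivisionError):
    """AC/DC requested with zero baseline intensity (non-converged run)."""


@dataclass(frozen=True)
class IntensityPair:
    """Detected intensities of a paired systole/diastole scenario."""

    I_s: float
    I_d: float

    def __post_init__(self):
        if not (0.0 <= self.I_s <= 1.0 and 0.0 <= self.I_d <= 1.0):
            raise ValueError("intensities must lie in [0, 1]")


@dataclass(frozen=True)
class PPGMetrics:
    AC: float
    DC: float
    ratio: float


@dataclass(frozen=True)
class ConvergenceStats:
    N: int
    Q: float
    passed: bool


@dataclass(frozen=True)
class PathStats:
    mean_pathlength: float  # mm
    mean_penetration_depth: float  # mm


@dataclass(frozen=True)
class ProfileHistogram:
    """Trajectory-vertex occupancy of detected photons over the (x, z) plane."""

    counts: np.ndarray  # (n_bins, n_bins), x rows, z columns
    x_edges: np.ndarray
    z_edges: np.ndarray

    def save(self, path) -> None:
        """Write the grid as a portable text matrix with axis metadata."""
        header = (
            f"x_edges_mm: {self.x_edges[0]:.6g} .. {self.x_edges[-1]:.6g} "
            f"({len(self.x_edges) - 1} bins)\n"
            f"z_edges_mm: {self.z_edges[0]:.6g} .. {self.z_edges[-1]:.6g} "
            f"({len(self.z_edges) - 1} bins)\n"
            "rows: x bins, columns: z bins"
        )
        np.savetxt(path, self.counts, fmt="%.6g", header=header)


def ac_dc(pair: IntensityPair) -> PPGMetrics:
    """AC = I_d - I_s, DC = I_s, and their ratio.

    The sign of AC is preserved: a negative value would mean systole let
    more light through than diastole and is surfaced, not masked.
    """
    if pair.I_s <= 0.0:
        raise UndefinedRatioError("DC = 0: run did not converge")
    ac = pair.I_d - pair.I_s
    return PPGMetrics(AC=ac, DC=pair.I_s, ratio=ac / pair.I_s)


def convergence(N: int) -> ConvergenceStats:
    """Convergence rate Q = 1/sqrt(N) and the N >= 10^6 pass flag."""
    if N < 0:
        raise ValueError("N must be non-negative")
    q = math.inf if N == 0 else 1.0 / math.sqrt(N)
    return ConvergenceStats(N=N, Q=q, passed=N >= CONVERGENCE_N_THRESHOLD)


def relative_absorbance(
    tallies: TransportTallies, aggregate_mirrored: bool = True
) -> pd.Series:
    """Percentage of detected-photon absorption deposited in each region.

    Only weight deposited along the histories of photons that were
    eventually detected counts; the percentages sum to 100.  With
    ``aggregate_mirrored`` the two skin stacks and fat slabs merge by
    tissue name (e.g. ``epidermis_top`` + ``epidermis_bottom``).
    """
    if tallies.n_detected == 0:
        raise ValueError("no detected photons: relative absorbance undefined")
    dep = pd.Series(tallies.detected_absorbed, index=tallies.region_names)
    if aggregate_mirrored:
        dep = dep.groupby(
            dep.index.str.replace(r"_(top|bottom)$", "", regex=True)
        ).sum()
    total = dep.sum()
    if total <= 0:
        raise ValueError("detected photons deposited no weight")
    return 100.0 * dep / total


def path_stats(tallies: TransportTallies) -> PathStats:
    """Unweighted means of total pathlength and maximum depth over detected photons."""
    if tallies.n_detected == 0:
        raise ValueError("no detected photons: path statistics undefined")
    return PathStats(
        mean_pathlength=float(np.mean(tallies.det_L)),
        mean_penetration_depth=float(np.mean(tallies.det_zmax)),
    )


def percent_difference(a: float, b: float) -> float:
    """Symmetric percentage difference, 100*|a-b| / mean(a, b)."""
    if a <= 0 or b <= 0:
        raise ValueError("percent difference needs positive inputs")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)


def profile_histogram(
    tallies: TransportTallies,
    n_bins: int = 200,
    x_range: tuple[float, float] = (-12.0, 12.0),
    z_range: tuple[float, float] = (0.0, TOTAL_THICKNESS),
) -> ProfileHistogram:
    """2-D occupancy histogram of detected-photon trajectory vertices.

    Requires the run to have recorded trajectories; an empty record set
    yields an all-zero grid.
    """
    if tallies.traj_x is None:
        raise ValueError("run was executed without trajectory recording")
    counts, x_edges, z_edges = np.histogram2d(
        tallies.traj_x, tallies.traj_z, bins=n_bins, range=[x_range, z_range]
    )
    return ProfileHistogram(counts=counts, x_edges=x_edges, z_edges=z_edges)
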
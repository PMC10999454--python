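"""End-to-end experiment grid: paired runs, result tables, reports.

The full design is {light, moderate, dark} x {660, 940 nm} x
{transmittance, reflectance at s = 1, 3, 5, 7, 9 mm} — 36 scenario pairs,
each pair a systole and a diastole run sharing one seed so the pulsatile
component is a common-random-number estimate.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .photon_transport import TransportTallies, run_scenario
from .ppg_metrics import (
    IntensityPair,
    UndefinedRatioError,
    ac_dc,
    convergence,
    path_stats,
)
from .tissue_model import SKIN_TYPES, WAVELENGTHS, ScenarioConfig, build_finger

log = logging.getLogger(__name__)

SDS_VALUES = (1.0, 3.0, 5.0, 7.0, 9.0)
_SEED_STRIDE = 2_654_435_761  # Knuth multiplicative-hash constant


@dataclass(frozen=True)
class ScenarioPair:
    """Systole and diastole configurations sharing one seed."""

    systole: ScenarioConfig
    diastole: ScenarioConfig

    def __post_init__(self):
        if self.systole.seed != self.diastole.seed:
            raise ValueError("phase pairs must share a seed")


@dataclass(frozen=True)
class ExperimentGrid:
    pairs: tuple
    base_seed: int
    n_photons: int


def pair_seed(base_seed: int, pair_index: int) -> int:
    """Deterministic per-pair seed: a counter hashed off the base seed."""
    return (base_seed * _SEED_STRIDE + pair_index) % (2**63)


def build_grid(base_seed: int, n_photons: int, **overrides) -> ExperimentGrid:
    """Enumerate the full 36-pair experiment design deterministically."""
    if n_photons < 1:
        raise ValueError("n_photons must be at least 1")
    pairs = []
    index = 0
    for skin in SKIN_TYPES:
        for lam in WAVELENGTHS:
            modes = [("transmittance", 0.0)] + [("reflectance", s) for s in SDS_VALUES]
            for mode, sds in modes:
                cfg = ScenarioConfig(
                    wavelength=lam,
                    skin_type=skin,
                    phase="diastole",
                    mode=mode,
                    sds=sds,
                    n_photons=n_photons,
                    seed=pair_seed(base_seed, index),
                    **overrides,
                )
                pairs.append(ScenarioPair(cfg.with_phase("systole"), cfg))
                index += 1
    return ExperimentGrid(pairs=tuple(pairs), base_seed=base_seed, n_photons=n_photons)


def run_pair(pair: ScenarioPair) -> dict:
    """Run both phases of a scenario and derive its PPG metrics row."""
    t0 = time.perf_counter()
    sys_t = run_scenario(pair.systole)
    dia_t = run_scenario(pair.diastole)
    elapsed = time.perf_counter() - t0
    cfg = pair.diastole
    row = {
        "skin_type": cfg.skin_type,
        "wavelength_nm": cfg.wavelength,
        "mode": cfg.mode,
        "sds_mm": cfg.sds if cfg.mode == "reflectance" else np.nan,
        "seed": cfg.seed,
        "n_photons": cfg.n_photons,
        "N_systole": sys_t.n_detected,
        "N_diastole": dia_t.n_detected,
        "I_s": sys_t.intensity,
        "I_d": dia_t.intensity,
    }
    conv = convergence(dia_t.n_detected)
    row["Q"] = conv.Q
    row["converged"] = conv.passed
    try:
        metrics = ac_dc(IntensityPair(I_s=sys_t.intensity, I_d=dia_t.intensity))
        row["AC"] = metrics.AC
        row["DC"] = metrics.DC
        row["ac_dc_ratio"] = metrics.ratio
    except UndefinedRatioError:
        row["AC"] = np.nan
        row["DC"] = np.nan
        row["ac_dc_ratio"] = np.nan
    if dia_t.n_detected > 0:
        ps = path_stats(dia_t)
        row["mean_pathlength_mm"] = ps.mean_pathlength
        row["mean_penetration_depth_mm"] = ps.mean_penetration_depth
    else:
        row["mean_pathlength_mm"] = np.nan
        row["mean_penetration_depth_mm"] = np.nan
    row["conservation_residual"] = max(
        sys_t.conservation_residual(), dia_t.conservation_residual()
    )
    row["runtime_s"] = elapsed
    log.info(
        "%s %dnm %s sds=%.0f: N=%d, %.0f photons/s",
        cfg.skin_type,
        cfg.wavelength,
        cfg.mode,
        cfg.sds,
        dia_t.n_detected,
        2 * cfg.n_photons / max(elapsed, 1e-9),
    )
    return row


def manifest_for(pair: ScenarioPair) -> dict:
    """Machine-readable record sufficient to reproduce a pair bit-identically."""
    return {
        "version": __version__,
        "config": pair.diastole.to_dict(),
        "seed": pair.diastole.seed,
    }


def pair_from_manifest(manifest: dict) -> ScenarioPair:
    cfg = ScenarioConfig.from_dict(manifest["config"])
    return ScenarioPair(cfg.with_phase("systole"), cfg.with_phase("diastole"))


def run_grid(grid: ExperimentGrid, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run every pair; one metrics row per pair, Q failures flagged not dropped."""
    rows = []
    manifests = []
    for pair in grid.pairs:
        manifests.append(manifest_for(pair))
        try:
            rows.append(run_pair(pair))
        except Exception as exc:  # pragma: no cover - defensive per-run isolation
            log.error("run failed for %s: %s", pair.diastole, exc)
            manifests[-1]["error"] = str(exc)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "metrics.csv", index=False)
        with open(out / "manifests.json", "w") as fh:
            json.dump(manifests, fh, indent=2)
    return df


def relative_count_table(df: pd.DataFrame) -> pd.DataFrame:
    """Detected light as a percentage of light skin per wavelength/mode/sds.

    Percentages are taken on the detected intensity (weight fraction):
    with implicit capture that is the unbiased analogue of a photon count
    in an analogue simulation, whereas surviving-packet counts respond to
    absorption only through roulette.
    """
    def _relative(group: pd.DataFrame) -> pd.DataFrame:
        ref = group.loc[group.skin_type == "light", "I_d"]
        base = float(ref.iloc[0]) if len(ref) and ref.iloc[0] > 0 else np.nan
        out = group[["skin_type", "N_diastole", "I_d"]].copy()
        out["percent_of_light"] = 100.0 * group["I_d"] / base
        return out

    keys = ["wavelength_nm", "mode", "sds_mm"]
    return (
        df.groupby(keys, dropna=False)[df.columns]
        .apply(_relative)
        .reset_index(level=keys)
        .reset_index(drop=True)
    )


def percent_difference_table(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Symmetric percentage differences between skin-type pairs of `column`."""
    from .ppg_metrics import percent_difference

    combos = [("light", "moderate"), ("light", "dark"), ("moderate", "dark")]
    rows = []
    sub = df[df["mode"] == "reflectance"]
    for (lam, sds), group in sub.groupby(["wavelength_nm", "sds_mm"]):
        values = group.set_index("skin_type")[column]
        for a, b in combos:
            if a in values.index and b in values.index:
                va, vb = float(values[a]), float(values[b])
                pd_val = (
                    percent_difference(va, vb)
                    if va > 0 and vb > 0
                    else np.nan
                )
                rows.append(
                    {
                        "wavelength_nm": lam,
                        "sds_mm": sds,
                        "pair": f"{a}-{b}",
                        "percent_difference": pd_val,
                    }
                )
    return pd.DataFrame(rows)


def report(df: pd.DataFrame, out_dir: str | Path) -> list:
    """Regenerate the summary figures and tables from a grid results table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rel = relative_count_table(df)
    rel.to_csv(out / "relative_detected_counts.csv", index=False)
    written.append(out / "relative_detected_counts.csv")

    for column, stem in [
        ("mean_penetration_depth_mm", "percent_difference_penetration_depth"),
        ("mean_pathlength_mm", "percent_difference_pathlength"),
    ]:
        tab = percent_difference_table(df, column)
        tab.to_csv(out / f"{stem}.csv", index=False)
        written.append(out / f"{stem}.csv")

    trans = df[df["mode"] == "transmittance"]
    if len(trans):
        fig, ax = plt.subplots(figsize=(6, 4))
        for lam, group in trans.groupby("wavelength_nm"):
            g = group.set_index("skin_type").reindex(["light", "moderate", "dark"])
            ax.semilogy(g.index, g["AC"].clip(lower=1e-12), "o--", label=f"AC {lam} nm")
            ax.semilogy(g.index, g["DC"].clip(lower=1e-12), "s-", label=f"DC {lam} nm")
        ax.set_ylabel("transmittance")
        ax.set_title("AC and DC vs skin type")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "transmittance_ac_dc.png", dpi=150)
        plt.close(fig)
        written.append(out / "transmittance_ac_dc.png")

    refl = df[df["mode"] == "reflectance"]
    if len(refl):
        for column, fname in [
            ("mean_pathlength_mm", "pathlength_vs_sds.png"),
            ("mean_penetration_depth_mm", "penetration_vs_sds.png"),
        ]:
            fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
            for ax, lam in zip(axes, sorted(refl["wavelength_nm"].unique())):
                sub = refl[refl["wavelength_nm"] == lam]
                for skin, group in sub.groupby("skin_type"):
                    g = group.sort_values("sds_mm")
                    ax.plot(g["sds_mm"], g[column], "o-", label=skin)
                ax.set_title(f"{lam} nm")
                ax.set_xlabel("source-detector separation (mm)")
            axes[0].set_ylabel(column.replace("_", " "))
            axes[0].legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(out / fname, dpi=150)
            plt.close(fig)
            written.append(out / fname)

        bars = refl[refl["sds_mm"].isin([1.0, 3.0])]
        if len(bars):
            fig, ax = plt.subplots(figsize=(7, 4))
            labels, values = [], []
            for (lam, sds, skin), group in bars.groupby(
                ["wavelength_nm", "sds_mm", "skin_type"]
            ):
                labels.append(f"{skin}\n{lam}nm s={sds:.0f}")
                values.append(float(group["ac_dc_ratio"].iloc[0]))
            ax.bar(range(len(values)), values)
            ax.set_xticks(range(len(values)), labels, fontsize=6)
            ax.set_ylabel("AC/DC ratio")
            fig.tight_layout()
            fig.savefig(out / "ac_dc_ratio_bars.png", dpi=150)
            plt.close(fig)
            written.append(out / "ac_dc_ratio_bars.png")

    return written
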
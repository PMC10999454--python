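#!/usr/bin/env python
"""Assemble figures and summary tables from the grid results.

Reads the metrics written by 02_transmittance.py / 03_reflectance.py and
regenerates the report artefacts (AC/DC charts, pathlength and
penetration-depth sweeps, relative-count and percentage-difference
tables) under results/report/.
"""
from pathlib import Path

import pandas as pd

from ppgmc.experiment_runner import report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = []
    for name in ("transmittance_metrics.csv", "reflectance_metrics.csv"):
        path = OUT / name
        if path.exists():
            frames.append(pd.read_csv(path))
        else:
            print(f"missing {path} - run the corresponding analysis script first")
    if not frames:
        raise SystemExit(1)
    df = pd.concat(frames, ignore_index=True)
    written = report(df, OUT / "report")
    for path in written:
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
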
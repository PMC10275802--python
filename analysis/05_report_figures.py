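#!/usr/bin/env python
"""Render the standard diagnostic figures for the calibrated reference campaign.

Requires 01 and 02 to have been run (campaign + calibration under results/);
reuses results/volume_pairs.csv from 04 when present. Figures and caption
sidecars are written to results/figures/.
"""

import json
from pathlib import Path

import pandas as pd

from viacal import CalibrationResult, read_dataset
from viacal.cli import render_report

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    dataset = read_dataset(
        RESULTS / "campaign" / "samples.csv", RESULTS / "campaign" / "mixes.csv"
    )
    calib = CalibrationResult.from_dict(
        json.loads((RESULTS / "calibration.json").read_text())
    )
    pairs_path = RESULTS / "volume_pairs.csv"
    pairs = pd.read_csv(pairs_path) if pairs_path.exists() else None
    outdir = RESULTS / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    written = render_report(dataset, calib, pairs, outdir)
    print(f"wrote {len(written)} report file(s) to {outdir}:")
    for p in written:
        print(f"  {p.name}")


if __name__ == "__main__":
    main()
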
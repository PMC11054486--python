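#!/usr/bin/env python
"""Carboxylate S/AS band gaps for every system, through the full IR pipeline.

For each defined system: generate a spectra-grade trajectory (8 anions,
8192 frames at 0.5 fs, 2 ps reorientation dwell), compute per-anion dipole
series, maximum-entropy spectra, average them, apply the -200 cm^-1
force-field shift, and read off the S/AS band maxima. Writes
results/band_gaps.tsv.

The generated gap should recover each system's prescribed nu_AS - nu_S
splitting to within a few cm^-1, and the shift must leave it untouched.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from ldhtraj.pipeline import RunConfig, run
from ldhtraj.synthgen import PRESETS, preset

RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name in PRESETS:
        cfg = RunConfig(
            preset=name,
            analyses=("spectra",),
            seed=SEED,
            n_frames=8192,
            state_dwell_frames=4000.0,
            shift_cm1=-200.0,
        )
        rep = run(cfg)
        target = preset(name)
        if rep.band_gap is None:
            print(f"[02] {name}: spectra failed: {rep.errors}")
            continue
        rows.append(
            {
                "system": name,
                "nu_S_cm1": rep.band_gap.nu_S,
                "nu_AS_cm1": rep.band_gap.nu_AS,
                "gap_cm1": rep.band_gap.gap,
                "prescribed_gap_cm1": target.nu_AS - target.nu_S,
                "shift_applied_cm1": rep.spectrum.shift_applied,
            }
        )
        print(f"[02] {name}: gap {rep.band_gap.gap:.0f} cm^-1 "
              f"(prescribed {target.nu_AS - target.nu_S:.0f})")
    df = pd.DataFrame(rows)
    out = RESULTS / "band_gaps.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.8g")
    err = (df["gap_cm1"] - df["prescribed_gap_cm1"]).abs()
    print(f"[02] wrote {out}; max |gap - prescribed| = {err.max():.0f} cm^-1")


if __name__ == "__main__":
    main()
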
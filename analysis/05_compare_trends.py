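#!/usr/bin/env python
"""Cross-system trends: band gap and parallel population versus hydration.

Joins the band-gap table (02) with the orientation table (03) and flags,
per anion, whether the computed gap is non-increasing with water content —
the qualitative signature of hydration in these systems (strongest for
succinate, which flips from all-parallel to perpendicular as soon as the
gallery widens). Writes results/trends.tsv.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"


def main() -> None:
    gaps = pd.read_csv(RESULTS / "band_gaps.tsv", sep="\t")
    orient = pd.read_csv(RESULTS / "orientation.tsv", sep="\t")
    df = gaps.merge(orient[["system", "parallel_pct"]], on="system")
    df["anion"] = df["system"].str.split("_").str[0]
    df["hydration_X"] = df["system"].str.split("_").str[1].astype(float)
    df = df.sort_values(["anion", "hydration_X"]).reset_index(drop=True)
    flags = {}
    for anion, grp in df.groupby("anion"):
        g = grp.sort_values("hydration_X")["gap_cm1"].to_numpy()
        flags[anion] = bool((g[1:] <= g[:-1] + 5.0).all())  # 5 cm^-1 slack
    df["gap_non_increasing"] = df["anion"].map(flags)
    out = RESULTS / "trends.tsv"
    df[["system", "anion", "hydration_X", "gap_cm1", "parallel_pct",
        "gap_non_increasing"]].to_csv(out, sep="\t", index=False,
                                      float_format="%.8g")
    print(f"[05] wrote {out}")
    print(df[["system", "gap_cm1", "parallel_pct", "gap_non_increasing"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
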
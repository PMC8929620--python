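"""Summarize the six landscape layers derived from the synthetic DEM.

Reads the fixture written by 01_simulate_landscape.py, recomputes nothing:
the layers were derived once at scenario build time (slope/aspect by Horn
differences, D8 drainage distance, 2 km cumulative viewshed from a 1 km
observer grid at 1.6 m eye height, windowed convexity). Writes a per-layer
summary table to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lamap.raster import read_grid

ROOT = Path(__file__).resolve().parents[1]
LAYER_DIR = ROOT / "scratch" / "analysis" / "scenario" / "layers"


def main() -> None:
    if not LAYER_DIR.exists():
        raise SystemExit("run 01_simulate_landscape.py first")
    rows = []
    for path in sorted(LAYER_DIR.glob("*.asc")):
        g = read_grid(path)
        v = g.values[~np.isnan(g.values)]
        rows.append({
            "layer": path.stem,
            "n_valid": v.size,
            "min": v.min(),
            "mean": v.mean(),
            "max": v.max(),
            "sd": v.std(),
        })
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "terrain_layer_summary.csv"
    df.to_csv(out, index=False)
    print(df.round(3).to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
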
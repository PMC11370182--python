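#!/usr/bin/env python
"""Render retention line charts from the grid CSVs written by step 03.

Figures go to scratch/figures/ (binary artifacts are kept out of results/).
"""
from pathlib import Path

import pandas as pd

from phenodq.experiment import GridResult, _retention_figure

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "scratch" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    for path in sorted((ROOT / "results").glob("retention_*.csv")):
        axis = path.stem.replace("retention_", "")
        grid = GridResult(axis=axis, rows=pd.read_csv(path))
        fig = _retention_figure(grid, out)
        print(f"{path.name} -> {fig}")


if __name__ == "__main__":
    main()
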
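"""Build the aggregative quality indicator and fit K-t memberships.

Normalizes the four compound contents into the equal-weight indicator,
fits one K-t membership function per ecological factor, and standardizes
each factor raster to a [0, 1] quality-suitability layer.
"""

from pathlib import Path

import pandas as pd

from pinehab.cli import main

OUT = Path(__file__).resolve().parent.parent / "scratch" / "run"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def keep(*names: str) -> None:
    """Copy the small summary tables into results/ (rasters stay in scratch/)."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        (RESULTS / name).write_bytes((OUT / name).read_bytes())


if __name__ == "__main__":
    main(["fuzzy", "--out-dir", str(OUT), "--seed", "1"], standalone_mode=False)
    keep("membership_params.csv", "weights.csv", "indicator.csv")
    params = pd.read_csv(OUT / "membership_params.csv")
    print("fitted K-t membership parameters (a, b, c, d, K):")
    print(params[["factor", "a", "b", "c", "d", "K"]].round(1).to_string(index=False))
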
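"""Weighted overlay, land-cover masking and 3-class regionalization.

Overlays the per-factor quality layers with the normalized weights,
combines growth and quality suitability (cellwise minimum), masks to the
coniferous-forest land-cover class, cuts the result into highly /
marginally / unsuitable classes, and tabulates class areas.
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
    main(["overlay", "--out-dir", str(OUT), "--seed", "1"], standalone_mode=False)
    main(["classify", "--out-dir", str(OUT), "--seed", "1"], standalone_mode=False)
    keep("area_stats.csv")
    stats = pd.read_csv(OUT / "area_stats.csv")
    print("class areas over the masked production map:")
    print(stats.round(2).to_string(index=False))
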
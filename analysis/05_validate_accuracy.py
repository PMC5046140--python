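"""RMSE accuracy test of the quality-suitability map.

Compares the quality map at the sample sites against the observed
aggregative indicator and reports the RMSE.
"""

import json
from pathlib import Path

from pinehab.cli import main

OUT = Path(__file__).resolve().parent.parent / "scratch" / "run"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def keep(*names: str) -> None:
    """Copy the small summary tables into results/ (rasters stay in scratch/)."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        (RESULTS / name).write_bytes((OUT / name).read_bytes())


if __name__ == "__main__":
    main(["validate", "--out-dir", str(OUT), "--seed", "1"], standalone_mode=False)
    keep("validation.csv", "validation_summary.json")
    summary = json.loads((OUT / "validation_summary.json").read_text())
    print(f"map RMSE {summary['rmse']:.4f} over {summary['n_points']} sample sites")
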
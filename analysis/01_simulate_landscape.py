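"""Generate the synthetic study landscape.

Writes five ecological-factor rasters (April/June precipitation, February/
August mean temperature, altitude), a categorical land-cover layer, the
true composite suitability, and 200 sample points with simulated compound
contents to scratch/run/ (tables copied to results/).
"""

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
    main(["simulate", "--out-dir", str(OUT), "--seed", "1"], standalone_mode=False)
    keep("samples.csv")
    n_files = len(list(OUT.glob("*.asc")))
    print(f"landscape written to {OUT} ({n_files} rasters + samples.csv)")
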
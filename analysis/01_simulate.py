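#!/usr/bin/env python
"""Generate the study-shaped synthetic dataset.

Emits one full measurement batch for the eight-analyte milk demo panel —
matrix-matched and solvent calibration series, 3x/30x-LOQ spikes in
triplicate over three days, six same-day repeat injections, triplicate
matrix and water blanks, and 20 unknown milk samples — plus a 90-day
longitudinal concentration series with irregular sampling. The truth
manifest (slopes, matrix effects, recoveries, contamination, closed-form
LOQs) is written alongside so every later stage can be checked against it.
"""
import json
from pathlib import Path

from xenoquant.io import write_peak_table, write_table
from xenoquant.simulate import demo_inputs, generate_batch, generate_longitudinal

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel, truths, profiles = demo_inputs()
    peaks, manifest = generate_batch(panel, truths, {"unknowns": 20}, seed=SEED)
    write_peak_table(peaks, OUT / "peaks.csv")
    longi = generate_longitudinal(profiles, n_days=90, sampling_gaps=True,
                                  seed=SEED + 1)
    write_table(longi, OUT / "longitudinal.csv")
    with open(OUT / "truth_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    print(f"peak table: {len(peaks)} measurements for {len(panel)} analytes")
    print(f"longitudinal: {len(longi)} sampled days "
          f"({longi['censored'].mean():.0%} censored)")
    print(f"wrote {OUT}/peaks.csv, longitudinal.csv, truth_manifest.json")


if __name__ == "__main__":
    main()
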
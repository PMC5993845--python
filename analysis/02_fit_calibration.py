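#!/usr/bin/env python
"""Fit per-(scanner, condition) calibration curves from the phantom series.

Regresses measured SBR on true (aliquot) SBR for every scanner and
reconstruction condition, prints the equation list, and writes the
calibration table to results/calibration_curves.json.  Run after
01_simulate_phantoms.py.
"""

from pathlib import Path

import pandas as pd

from datnorm.calibration import fit_table_from_manifest

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manifest = pd.read_csv(RESULTS / "phantom_measurements.csv")
    table = fit_table_from_manifest(manifest)
    out = RESULTS / "calibration_curves.json"
    table.to_json(out)
    print(f"{len(table.curves)} calibration curves -> {out}\n")
    print("calibration equations (measured = a * true + b):")
    for (scanner, condition), c in sorted(table.curves.items()):
        print(
            f"  {scanner:10s} {condition:12s} Y = {c.slope:.3f} X {c.intercept:+.3f}"
            f"   (r = {c.r:.4f}, n = {c.n_points})"
        )
    print(
        "\nNote: no-scatter-correction conditions under-recover contrast "
        "(slope < 1); scatter-corrected conditions overshoot with a positive "
        "intercept, mirroring their higher raw SBR."
    )


if __name__ == "__main__":
    main()
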
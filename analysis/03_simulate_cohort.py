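#!/usr/bin/env python
"""Simulate the healthy-control cohort and its scanner measurements.

Generates 510 scans (ages 30-83, 55% women, start time ~ N(3.5 h, 0.5 h))
whose average SBR follows the normative linear model with residual SD 1.38
and whose left/right split follows the asymmetry-index model, assigns each
scan a scanner/condition, and passes the true SBRs through the per-condition
bias plus measurement noise.  Writes the measured cohort to
results/cohort_measured.csv and the ground-truth cohort to
results/cohort_truth.csv.
"""

from pathlib import Path

from datnorm import generate_cohort, measure_cohort
from datnorm.cohort import records_to_frame, write_cohort_csv
from datnorm.scanner import CONDITIONS

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921

# same emulated systems as 01_simulate_phantoms.py
import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "sim_phantoms", Path(__file__).with_name("01_simulate_phantoms.py")
)
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
SCANNERS = {s.name: s for s in _mod.SCANNERS}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = generate_cohort(
        510,
        residual_sd=1.38,
        seed=SEED,
        scanners=tuple(SCANNERS),
        conditions=CONDITIONS,
    )
    measured = measure_cohort(truth, SCANNERS, noise_sd=0.2, seed=SEED + 1)
    write_cohort_csv(truth, RESULTS / "cohort_truth.csv")
    write_cohort_csv(measured, RESULTS / "cohort_measured.csv")
    df = records_to_frame(measured)
    print(f"510 scans -> {RESULTS / 'cohort_measured.csv'}")
    print("\nmean measured average SBR by condition (before calibration):")
    avg = 0.5 * (df.sbr_right + df.sbr_left)
    print(avg.groupby(df.condition).mean().round(2).to_string())
    print(
        "\nThe spread across conditions is the harmonization problem the "
        "phantom calibration has to solve."
    )


if __name__ == "__main__":
    main()
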
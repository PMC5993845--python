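#!/usr/bin/env python
"""Arithmetic consistency checks on the published normative tables.

Recomputes the headline percentages directly from the published decade and
condition tables bundled with the package, and compares the same
quantities measured on the synthetic cohort of this analysis (when the
upstream scripts have been run).
"""

from pathlib import Path

from datnorm.published import (
    CONDITION_SUMMARIES,
    percent_condition_difference,
    percent_decline_per_decade_published,
    percent_sex_difference,
    pi_half_width,
    reduction_to_lower_pi,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    print("published-table arithmetic:")
    print(f"  women vs men SBR at 30-39:            +{percent_sex_difference(0):.1f}%")
    print(f"  SBR decline per decade (both sexes):   {percent_decline_per_decade_published('both'):.1f}%")
    print(f"  SBR decline per decade (men):          {percent_decline_per_decade_published('men'):.1f}%")
    print(f"  SBR decline per decade (women):        {percent_decline_per_decade_published('women'):.1f}%")
    print(f"  calibrated uncorrected grand mean:     {CONDITION_SUMMARIES['calibrated']['NOACNOSC'].mean_sbr:.2f}")
    print(f"  calibrated NOACNOSC below ChangACSC:   {percent_condition_difference('NOACNOSC', 'ChangACSC', 'calibrated'):.0f}%")
    print(f"  original  NOACNOSC below ChangACSC:    {percent_condition_difference('NOACNOSC', 'ChangACSC', 'original'):.0f}%")
    print(f"  95% PI half-width (30-39, both):       {pi_half_width('both', 0):.2f}")
    print(f"  reduction to lower PI limit at 60-69:  {reduction_to_lower_pi('both', 3):.0f}%")

    decade_csv = RESULTS / "decade_summary.csv"
    if decade_csv.exists():
        import pandas as pd

        from datnorm.normative import percent_decline_per_decade

        table = pd.read_csv(decade_csv)
        both = table[(table.group == "both") & (table.n_scans > 0)]
        decline = percent_decline_per_decade(both.mean_sbr.to_numpy())
        print(f"\nsynthetic cohort (this analysis): decline per decade {decline:.1f}%")
    else:
        print("\n(run 03-05 first to compare the synthetic cohort)")


if __name__ == "__main__":
    main()
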
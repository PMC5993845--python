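#!/usr/bin/env python
"""Fit the normative models on the calibrated cohort.

Multiple regression of average SBR and of the asymmetry index on age, scan
start time and sex; ANOVA effect tests; the decade x sex summary table with
95% prediction limits; and the age-regression scatter plots with CI/PI
bands.  Writes results/normative_models.json, results/decade_summary.csv
and figures under results/figures/.  Run after 04.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from datnorm.cohort import read_cohort_csv
from datnorm.normative import (
    anova_effects,
    decade_summary,
    fit_normative_model,
    fit_simple_regression,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
FIGURES = RESULTS / "figures"


def plot_regression(df, sel, label, fname):
    age = df.loc[sel, "age"].to_numpy()
    avg = 0.5 * (df.loc[sel, "sbr_calibrated_right"] + df.loc[sel, "sbr_calibrated_left"]).to_numpy()
    line = fit_simple_regression(age, avg)
    xs = np.linspace(30, 85, 100)
    ci = line.confidence_interval(xs)
    pi = line.prediction_interval(xs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(age, avg, s=8, alpha=0.4, color="tab:blue")
    ax.plot(xs, line.predict(xs), color="tab:red",
            label=f"Y = {line.slope:.4f}X + {line.intercept:.2f} (r = {line.r:.3f})")
    ax.plot(xs, ci[0], "r--", lw=0.8)
    ax.plot(xs, ci[1], "r--", lw=0.8, label="95% CI")
    ax.plot(xs, pi[0], "r:", lw=0.8)
    ax.plot(xs, pi[1], "r:", lw=0.8, label="95% PI")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("average striatal SBR (calibrated)")
    ax.set_title(label)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(FIGURES / fname, dpi=120)
    plt.close(fig)
    return line


def main() -> None:
    FIGURES.mkdir(parents=True, exist_ok=True)
    df = read_cohort_csv(RESULTS / "cohort_calibrated.csv")

    report = {}
    for outcome in ("average_sbr", "ai"):
        model = fit_normative_model(df, outcome)
        report[outcome] = {
            "coefficients": model.coefficients.as_dict(),
            "coef_se": model.coef_se,
            "p_values": model.p_values,
            "residual_sd": model.residual_sd,
            "n": model.n,
        }
        print(f"\n{outcome} ~ age + start_time + sex  (n = {model.n}):")
        for name, b in model.coefficients.as_dict().items():
            print(f"  {name:12s} {b:+.4f}  (SE {model.coef_se[name]:.4f}, "
                  f"p {model.p_values[name]:.2g})")

    anova = anova_effects(df, "average_sbr")
    print("\nANOVA (average SBR):")
    print(anova[["effect", "F", "p_text"]].to_string(index=False))
    report["anova_average_sbr"] = anova.drop(columns="p_text").to_dict(orient="records")

    table = decade_summary(df, mode="predicted")
    table.round(3).to_csv(RESULTS / "decade_summary.csv", index=False)
    both = table[(table.group == "both") & (table.n_scans > 0)]
    print("\ndecade summary (both sexes, regression-predicted at midpoints):")
    print(both.to_string(index=False))

    female = df.sex == "F"
    line_all = plot_regression(df, df.index, "all subjects", "sbr_age_all.png")
    plot_regression(df, female, "women", "sbr_age_women.png")
    plot_regression(df, ~female, "men", "sbr_age_men.png")
    print(f"\npooled age line: Y = {line_all.slope:.4f}X + {line_all.intercept:.2f}, "
          f"r = {line_all.r:.3f}")
    decline = -line_all.slope * 10 / line_all.predict(34.5) * 100
    print(f"SBR decline per decade (relative to the 30-39 mean): {decline:.1f}%")

    (RESULTS / "normative_models.json").write_text(
        json.dumps(report, indent=2, default=float) + "\n"
    )
    print(f"\nmodels -> {RESULTS / 'normative_models.json'}; "
          f"figures -> {FIGURES}")


if __name__ == "__main__":
    main()
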
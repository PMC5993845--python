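"""Published multicenter normative reference values.

The printed results of the 510-scan Japanese healthy-control [123I]FP-CIT
SPECT database: the fitted normative regression models, the per-sex and
pooled age-regression lines, the decade x sex summary table, and the
per-condition SBR summaries with their cross-condition ICCs.  These serve
two roles: they are the default generative parameters of the synthetic
cohort (so simulations reproduce the study conditions), and they are the
inputs of the in-table arithmetic consistency checks (sex differences,
percent decline per decade, condition differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normative import DECADE_LABELS, LinearCoefficients

__all__ = [
    "SBR_MODEL",
    "AI_MODEL",
    "SBR_MODEL_T",
    "AI_MODEL_T",
    "SimpleLine",
    "SBR_AGE_LINE_POOLED",
    "SBR_AGE_LINE_MEN",
    "SBR_AGE_LINE_WOMEN",
    "AI_AGE_LINE_POOLED",
    "AI_AGE_LINE_MEN",
    "AI_AGE_LINE_WOMEN",
    "DecadeTable",
    "DECADE_TABLE",
    "ConditionSummary",
    "CONDITION_SUMMARIES",
    "percent_sex_difference",
    "percent_decline_per_decade_published",
    "percent_condition_difference",
    "pi_half_width",
    "reduction_to_lower_pi",
]

#: Multiple regression of the average left/right striatal SBR on age,
#: scan start time (hours) and sex (female = 1).
SBR_MODEL = LinearCoefficients(intercept=10.610, age=-0.063, start_time=0.263, sex_female=0.461)
#: t-statistics of the SBR model coefficients, same order.
SBR_MODEL_T = {"intercept": 22.134, "age": -15.18, "start_time": 2.024, "sex_female": 3.819}

#: Multiple regression of the asymmetry index (AI) on the same covariates.
AI_MODEL = LinearCoefficients(intercept=2.885, age=0.031, start_time=-0.037, sex_female=-0.546)
AI_MODEL_T = {"intercept": 2.306, "age": 2.875, "start_time": -0.108, "sex_female": -1.731}


@dataclass(frozen=True)
class SimpleLine:
    """A published simple age-regression line Y = slope * age + intercept."""

    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, age):
        return self.slope * np.asarray(age, dtype=float) + self.intercept


SBR_AGE_LINE_POOLED = SimpleLine(slope=-0.0603, intercept=11.6, r=-0.539, n=510)
SBR_AGE_LINE_WOMEN = SimpleLine(slope=-0.0763, intercept=12.74, r=-0.620, n=280)
SBR_AGE_LINE_MEN = SimpleLine(slope=-0.0479, intercept=10.66, r=-0.479, n=230)
AI_AGE_LINE_POOLED = SimpleLine(slope=0.029, intercept=2.592, r=0.119, n=510)
AI_AGE_LINE_MEN = SimpleLine(slope=0.0528, intercept=1.58, r=0.216, n=230)
AI_AGE_LINE_WOMEN = SimpleLine(slope=0.0098, intercept=3.47, r=0.039, n=280)

#: Mean right/left SBR by sex (paired right-dominance finding).
MEAN_SBR_RIGHT = {"men": 8.07, "women": 8.31}
MEAN_SBR_LEFT = {"men": 7.97, "women": 8.24}


@dataclass(frozen=True)
class DecadeTable:
    """One group's row block of the decade summary table (index = decade)."""

    n_subjects: tuple[int, ...]
    n_scans: tuple[int, ...]
    mean_sbr: tuple[float, ...]
    sbr_lower_pi: tuple[float, ...]
    mean_ai: tuple[float, ...]
    ai_upper_pi: tuple[float, ...]


#: Calibrated SBRs (no attenuation/scatter correction condition) by age
#: group, decades 30-39 ... 80-89.
DECADE_TABLE: dict[str, DecadeTable] = {
    "both": DecadeTable(
        n_subjects=(45, 43, 39, 71, 48, 10),
        n_scans=(90, 86, 78, 142, 95, 19),
        mean_sbr=(9.52, 8.91, 8.31, 7.71, 7.10, 6.50),
        sbr_lower_pi=(6.82, 6.22, 5.62, 5.01, 4.41, 3.80),
        mean_ai=(3.59, 3.88, 4.17, 4.46, 4.75, 5.04),
        ai_upper_pi=(10.53, 10.81, 11.09, 11.38, 11.68, 11.99),
    ),
    "men": DecadeTable(
        n_subjects=(30, 15, 17, 31, 18, 5),
        n_scans=(60, 30, 34, 62, 35, 9),
        mean_sbr=(9.01, 8.53, 8.05, 7.57, 7.09, 6.61),
        sbr_lower_pi=(6.36, 5.89, 5.41, 4.93, 4.44, 3.95),
        mean_ai=(3.40, 3.93, 4.46, 4.98, 5.51, 6.04),
        ai_upper_pi=(10.58, 11.09, 11.61, 12.14, 12.69, 13.25),
    ),
    "women": DecadeTable(
        n_subjects=(15, 28, 22, 40, 30, 5),
        n_scans=(30, 56, 44, 80, 60, 10),
        mean_sbr=(10.11, 9.35, 8.58, 7.82, 7.06, 6.30),
        sbr_lower_pi=(7.46, 6.71, 5.95, 5.18, 4.42, 3.64),
        mean_ai=(3.81, 3.91, 4.00, 4.10, 4.20, 4.30),
        ai_upper_pi=(10.55, 10.62, 10.71, 10.81, 10.92, 11.05),
    ),
}

assert all(len(t.mean_sbr) == len(DECADE_LABELS) for t in DECADE_TABLE.values())


@dataclass(frozen=True)
class ConditionSummary:
    """Per-reconstruction-condition summary vs the uncorrected condition."""

    condition: str
    n_scans: int
    mean_sbr: float
    sbr_range: tuple[float, float]
    regression_vs_noacnosc: tuple[float, float] | None  # (slope, intercept) or None
    icc: float | None
    icc_ci: tuple[float, float] | None


#: Original and calibrated per-condition SBR summaries; ICCs are against
#: the NOACNOSC condition (two-way absolute agreement, single measure).
CONDITION_SUMMARIES: dict[str, dict[str, ConditionSummary]] = {
    "original": {
        "CTACSC": ConditionSummary("CTACSC", 292, 9.12, (4.41, 14.31), (1.200, 2.334), 0.438, (-0.096, 0.781)),
        "ChangACSC": ConditionSummary("ChangACSC", 510, 10.48, (5.41, 19.08), (1.445, 2.138), 0.333, (-0.075, 0.698)),
        "CTACNOSC": ConditionSummary("CTACNOSC", 292, 6.72, (3.32, 11.46), (0.996, 1.091), 0.860, (-0.126, 0.963)),
        "ChangACNOSC": ConditionSummary("ChangACNOSC", 510, 7.09, (3.40, 12.21), (1.121, 0.618), 0.808, (-0.159, 0.945)),
        "NOACNOSC": ConditionSummary("NOACNOSC", 510, 5.77, (2.18, 10.94), None, None, None),
    },
    "calibrated": {
        "CTACSC": ConditionSummary("CTACSC", 292, 8.96, (4.37, 13.76), (1.053, 0.517), 0.832, (0.372, 0.928)),
        "ChangACSC": ConditionSummary("ChangACSC", 510, 9.31, (4.10, 17.05), (1.103, 0.297), 0.820, (0.222, 0.928)),
        "CTACNOSC": ConditionSummary("CTACNOSC", 292, 7.63, (3.35, 11.83), (0.825, 1.011), 0.926, (0.839, 0.959)),
        "ChangACNOSC": ConditionSummary("ChangACNOSC", 510, 7.95, (3.97, 14.66), (0.927, 0.380), 0.958, (0.940, 0.969)),
        "NOACNOSC": ConditionSummary("NOACNOSC", 510, 8.16, (3.81, 13.89), None, None, None),
    },
}


# ---------------------------------------------------------------------------
# In-table arithmetic consistency figures

def percent_sex_difference(decade_index: int = 0, ndigits: int = 1) -> float:
    """Percent by which women's mean SBR exceeds men's in a decade.

    Decade 0 (30-39) gives the headline young-adult sex difference.
    """
    w = DECADE_TABLE["women"].mean_sbr[decade_index]
    m = DECADE_TABLE["men"].mean_sbr[decade_index]
    return round((w - m) / m * 100.0, ndigits)


def percent_decline_per_decade_published(group: str = "both", ndigits: int = 1) -> float:
    """Mean per-decade SBR decrement as % of the 30-39 mean, from the table."""
    means = DECADE_TABLE[group].mean_sbr
    decrement = (means[0] - means[-1]) / (len(means) - 1)
    return round(decrement / means[0] * 100.0, ndigits)


def percent_condition_difference(
    condition_low: str = "NOACNOSC",
    condition_high: str = "ChangACSC",
    which: str = "calibrated",
    ndigits: int = 0,
) -> float:
    """Percent by which one condition's mean SBR falls below another's."""
    lo = CONDITION_SUMMARIES[which][condition_low].mean_sbr
    hi = CONDITION_SUMMARIES[which][condition_high].mean_sbr
    return round((hi - lo) / hi * 100.0, ndigits)


def pi_half_width(group: str = "both", decade_index: int = 0, ndigits: int = 2) -> float:
    """Gap between the decade mean SBR and its 95% lower prediction limit."""
    t = DECADE_TABLE[group]
    return round(t.mean_sbr[decade_index] - t.sbr_lower_pi[decade_index], ndigits)


def reduction_to_lower_pi(group: str = "both", decade_index: int = 3, ndigits: int = 0) -> float:
    """Percent reduction from the decade mean down to the lower PI limit.

    At the 60-69 decade this is the reduction a scan must show to fall
    outside the normative range (~35%).
    """
    t = DECADE_TABLE[group]
    return round((1.0 - t.sbr_lower_pi[decade_index] / t.mean_sbr[decade_index]) * 100.0, ndigits)
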
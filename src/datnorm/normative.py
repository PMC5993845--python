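"""Normative statistical layer for striatal SBR databases.

Implements the regression machinery a normative DAT-SPECT database needs:

* simple linear regression of SBR (or AI) on age with t-based confidence
  and prediction intervals, as drawn on normative scatter plots;
* the multiple regression of the average striatal SBR on age, scan start
  time and sex (female indicator), whose fitted coefficients define the
  expected-value formula used to judge individual scans;
* decade x sex summary tables with 95% lower prediction limits for SBR and
  upper limits for AI;
* intraclass correlation (two-way, absolute agreement, single measure —
  ICC(2,1), with ICC(3,1) available) with F-based confidence intervals,
  used to assess agreement between reconstruction conditions before and
  after phantom calibration;
* Type-III ANOVA effect tests (sex, age, sex x age, start time);
* z-scoring of new subjects against the fitted model.

Sex is coded female = 1, male = 0 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import (
    DegenerateModelError,
    DomainError,
    RankError,
    UndefinedIccError,
)

__all__ = [
    "LinearCoefficients",
    "RegressionLine",
    "NormativeModel",
    "IccResult",
    "fit_simple_regression",
    "fit_normative_model",
    "predict_expected",
    "prediction_interval",
    "decade_summary",
    "percent_decline_per_decade",
    "icc_between_conditions",
    "anova_effects",
    "zscore_subject",
    "paired_lr_ttest",
    "format_p",
    "DECADE_EDGES",
]

#: Decade bins of the normative table: [30, 40), ..., [80, 90).
DECADE_EDGES = tuple(range(30, 100, 10))
DECADE_LABELS = tuple(f"{lo}-{lo + 9}" for lo in DECADE_EDGES[:-1])


@dataclass(frozen=True)
class LinearCoefficients:
    """Coefficients of the normative linear model.

    outcome = intercept + age * (years) + start_time * (hours post
    injection) + sex_female * 1[female].
    """

    intercept: float
    age: float
    start_time: float
    sex_female: float

    def predict(self, age, sex_female, start_time):
        return (
            self.intercept
            + self.age * np.asarray(age, dtype=float)
            + self.start_time * np.asarray(start_time, dtype=float)
            + self.sex_female * np.asarray(sex_female, dtype=float)
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "intercept": self.intercept,
            "age": self.age,
            "start_time": self.start_time,
            "sex_female": self.sex_female,
        }


def _coerce_sex(sex) -> np.ndarray:
    """Map M/F strings (or 0/1) to the female indicator."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "USO":
        mapping = {"F": 1.0, "M": 0.0, "female": 1.0, "male": 0.0}
        try:
            return np.asarray([mapping[str(v)] for v in arr.ravel()], dtype=float).reshape(arr.shape)
        except KeyError as exc:
            raise DomainError(f"unknown sex code {exc.args[0]!r}; expected M/F") from exc
    return arr.astype(float)


@dataclass
class RegressionLine:
    """A simple y-on-x least-squares line with interval evaluators."""

    slope: float
    intercept: float
    r: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def _se_terms(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx

    def _t(self, level: float) -> float:
        if not 0 < level < 1:
            raise DomainError(f"level must be in (0, 1), got {level}")
        return float(stats.t.ppf(0.5 + level / 2.0, self.n - 2))

    def confidence_interval(self, x, level: float = 0.95):
        """CI of the mean response at x."""
        mean = self.predict(x)
        half = self._t(level) * self.residual_sd * np.sqrt(self._se_terms(x))
        return mean - half, mean + half

    def prediction_interval(self, x, level: float = 0.95):
        """PI of a new individual observation at x."""
        mean = self.predict(x)
        half = self._t(level) * self.residual_sd * np.sqrt(1.0 + self._se_terms(x))
        return mean - half, mean + half


def fit_simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionLine:
    """Ordinary least squares of y on x via the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise RankError("x is constant; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    syy = float(np.sum((y - y.mean()) ** 2))
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    residual_sd = float(np.sqrt(sse / (n - 2)))
    return RegressionLine(
        slope=float(slope),
        intercept=intercept,
        r=float(r),
        n=int(n),
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        sxx=sxx,
    )


_DESIGN_COLS = ("intercept", "age", "start_time", "sex_female")


@dataclass
class NormativeModel:
    """Fitted multiple regression of an outcome on age, start time, sex.

    Carries the design cross-products needed to evaluate t-based prediction
    intervals at arbitrary covariates.
    """

    outcome: str
    coefficients: LinearCoefficients
    residual_sd: float
    n: int
    dof: int
    xtx_inv: np.ndarray  # (X'X)^-1, column order _DESIGN_COLS
    coef_se: dict[str, float] = field(default_factory=dict)
    t_values: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)

    def design_row(self, age: float, sex, start_time: float) -> np.ndarray:
        female = float(_coerce_sex(sex))
        return np.array([1.0, float(age), float(start_time), female])

    def predict(self, age, sex, start_time):
        female = _coerce_sex(sex)
        return self.coefficients.predict(age, female, start_time)

    def prediction_interval(self, age, sex, start_time, level: float = 0.95):
        if not 0 < level < 1:
            raise DomainError(f"level must be in (0, 1), got {level}")
        x0 = self.design_row(age, sex, start_time)
        mean = float(x0 @ np.array([
            self.coefficients.intercept,
            self.coefficients.age,
            self.coefficients.start_time,
            self.coefficients.sex_female,
        ]))
        t = float(stats.t.ppf(0.5 + level / 2.0, self.dof))
        half = t * self.residual_sd * float(np.sqrt(1.0 + x0 @ self.xtx_inv @ x0))
        return mean - half, mean + half


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": getattr(r, "subject_id", None),
                "age": r.age,
                "sex": r.sex,
                "scan_start_time": r.scan_start_time,
                "sbr_right": r.sbr_right,
                "sbr_left": r.sbr_left,
                "sbr_calibrated_right": getattr(r, "sbr_calibrated_right", None),
                "sbr_calibrated_left": getattr(r, "sbr_calibrated_left", None),
            }
        )
    return pd.DataFrame(rows)


def _outcome_values(df: pd.DataFrame, outcome: str, use_calibrated: bool | None = None) -> np.ndarray:
    """Average SBR or AI per record; calibrated SBRs preferred when present."""
    if use_calibrated is None:
        use_calibrated = (
            "sbr_calibrated_right" in df
            and df["sbr_calibrated_right"].notna().all()
        )
    right = df["sbr_calibrated_right" if use_calibrated else "sbr_right"].to_numpy(float)
    left = df["sbr_calibrated_left" if use_calibrated else "sbr_left"].to_numpy(float)
    if outcome == "average_sbr":
        return 0.5 * (right + left)
    if outcome == "ai":
        total = right + left
        if np.any(total <= 0):
            raise DomainError("AI undefined for records with R + L <= 0")
        return np.abs(right - left) / total * 200.0
    raise ValueError(f"unknown outcome {outcome!r}; expected 'average_sbr' or 'ai'")


def fit_normative_model(
    records, outcome: str = "average_sbr", use_calibrated: bool | None = None
) -> NormativeModel:
    """OLS of the outcome on age, scan start time, and the female indicator."""
    df = _records_to_frame(records)
    y = _outcome_values(df, outcome, use_calibrated)
    female = _coerce_sex(df["sex"].to_numpy())
    age = df["age"].to_numpy(float)
    start = df["scan_start_time"].to_numpy(float)
    n_female = int(female.sum())
    if n_female < 2 or (len(female) - n_female) < 2:
        raise RankError("need at least 2 subjects of each sex")
    if np.ptp(age) == 0:
        raise RankError("age is constant")
    X = np.column_stack([np.ones_like(age), age, start, female])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient (collinear covariates)")
    fit = sm.OLS(y, X).fit()
    names = _DESIGN_COLS
    coeffs = LinearCoefficients(*[float(b) for b in fit.params])
    return NormativeModel(
        outcome=outcome,
        coefficients=coeffs,
        residual_sd=float(np.sqrt(fit.scale)),
        n=int(fit.nobs),
        dof=int(fit.df_resid),
        xtx_inv=np.asarray(fit.normalized_cov_params),
        coef_se=dict(zip(names, map(float, fit.bse))),
        t_values=dict(zip(names, map(float, fit.tvalues))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
    )


def predict_expected(model: NormativeModel, age: float, sex, start_time: float) -> float:
    """Expected outcome for given covariates under the fitted model."""
    return float(model.predict(age, sex, start_time))


def prediction_interval(model_or_line, x0, level: float = 0.95) -> tuple[float, float]:
    """t-based interval expected to contain a new observation.

    ``x0`` is a scalar x for a :class:`RegressionLine`, or an
    (age, sex, start_time) tuple for a :class:`NormativeModel`.
    """
    if isinstance(model_or_line, RegressionLine):
        lo, hi = model_or_line.prediction_interval(x0, level)
        return float(lo), float(hi)
    if isinstance(model_or_line, NormativeModel):
        age, sex, start_time = x0
        return model_or_line.prediction_interval(age, sex, start_time, level)
    raise TypeError(f"unsupported model type {type(model_or_line)!r}")


def percent_decline_per_decade(decade_means: Sequence[float]) -> float:
    """Mean decade-to-decade decrement as a percentage of the first decade mean."""
    m = np.asarray(decade_means, dtype=float)
    m = m[~np.isnan(m)]
    if m.size < 2:
        raise ValueError("need at least two decade means")
    return float((m[0] - m[-1]) / (m.size - 1) / m[0] * 100.0)


def decade_summary(
    records,
    mode: str = "predicted",
    level: float = 0.95,
    use_calibrated: bool | None = None,
) -> pd.DataFrame:
    """Decade x sex-group normative table.

    One row per (group in {both, men, women}) x (decade 30-39 ... 80-89):
    subject and scan counts, mean SBR with its 95% lower prediction limit,
    and mean AI with its 95% upper prediction limit.  In ``mode="predicted"``
    (default) the means are the per-group age-regression values at decade
    midpoints, which is how tabulated normative values stay exactly linear
    across decades; ``mode="raw"`` reports raw group means instead.  PI
    limits always come from the per-group age regression at the decade
    midpoint.
    """
    if mode not in ("predicted", "raw"):
        raise ValueError(f"mode must be 'predicted' or 'raw', got {mode!r}")
    df = _records_to_frame(records)
    df["avg_sbr"] = _outcome_values(df, "average_sbr", use_calibrated)
    df["ai_val"] = _outcome_values(df, "ai", use_calibrated)
    df["female"] = _coerce_sex(df["sex"].to_numpy())

    groups = {"both": df, "men": df[df["female"] == 0], "women": df[df["female"] == 1]}
    rows = []
    for gname, g in groups.items():
        line_sbr = line_ai = None
        if len(g) >= 3 and np.ptp(g["age"].to_numpy()) > 0:
            line_sbr = fit_simple_regression(g["age"], g["avg_sbr"])
            line_ai = fit_simple_regression(g["age"], g["ai_val"])
        for lo, label in zip(DECADE_EDGES[:-1], DECADE_LABELS):
            sel = g[(g["age"] >= lo) & (g["age"] < lo + 10)]
            n_scans = len(sel)
            n_subjects = sel["subject_id"].nunique() if "subject_id" in sel and n_scans else n_scans
            row = {
                "group": gname,
                "decade": label,
                "n_subjects": int(n_subjects),
                "n_scans": int(n_scans),
                "mean_sbr": np.nan,
                "sbr_lower_pi": np.nan,
                "mean_ai": np.nan,
                "ai_upper_pi": np.nan,
            }
            mid = lo + 4.5
            if n_scans and line_sbr is not None:
                if mode == "predicted":
                    row["mean_sbr"] = float(line_sbr.predict(mid))
                    row["mean_ai"] = float(line_ai.predict(mid))
                else:
                    row["mean_sbr"] = float(sel["avg_sbr"].mean())
                    row["mean_ai"] = float(sel["ai_val"].mean())
                row["sbr_lower_pi"] = float(line_sbr.prediction_interval(mid, level)[0])
                row["ai_upper_pi"] = float(line_ai.prediction_interval(mid, level)[1])
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its F-based confidence interval."""

    estimate: float
    ci_lower: float
    ci_upper: float
    n_pairs: int
    form: str = "icc2"

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.estimate <= self.ci_upper + 1e-12):
            raise ValueError("ICC estimate outside its confidence interval")


def icc_between_conditions(
    pairs: Iterable[tuple[float, float]] | np.ndarray,
    form: str = "icc2",
    level: float = 0.95,
) -> IccResult:
    """ICC between two paired measurement conditions.

    ``form="icc2"`` (default) is the two-way random-effects, absolute
    agreement, single-measure ICC — sensitive to systematic offsets between
    conditions, which is what matters when asking whether two
    reconstruction conditions give interchangeable SBRs.  ``form="icc3"``
    is the consistency form.  Confidence intervals use the standard
    F-distribution construction.
    """
    data = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if form not in ("icc2", "icc3"):
        raise ValueError(f"form must be 'icc2' or 'icc3', got {form!r}")
    alpha = 1.0 - level

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((data - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    if msr == 0 and msc == 0 and mse == 0:
        raise UndefinedIccError("no variance in either member of the pairs")

    if form == "icc3":
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else 0.0
        if mse == 0:
            return IccResult(1.0, 1.0, 1.0, n, form)
        f_obs = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return IccResult(float(est), float(min(lo, est)), float(max(hi, est)), n, form)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom if denom > 0 else 0.0
    if mse == 0 and abs(msc) < 1e-30:
        return IccResult(1.0, 1.0, 1.0, n, form)
    rho = min(est, 1.0 - 1e-12)
    a = k * rho / (n * (1.0 - rho))
    b = 1.0 + k * rho * (n - 1) / (n * (1.0 - rho))
    denom_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    if denom_v <= 0:
        return IccResult(float(est), float(est), float(est), n, form)
    v = (a * msc + b * mse) ** 2 / denom_v
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return IccResult(float(est), float(min(lo, est)), float(max(hi, est)), n, form)


def anova_effects(records, outcome: str = "average_sbr", use_calibrated: bool | None = None) -> pd.DataFrame:
    """Type-III ANOVA of the outcome: sex, age, sex x age, start time.

    Age and start time enter as continuous covariates; the model includes
    the sex x age interaction.  Returns a table of (effect, df, mean_sq, F,
    p_value, p_text).
    """
    df = _records_to_frame(records)
    df["y"] = _outcome_values(df, outcome, use_calibrated)
    df["female"] = _coerce_sex(df["sex"].to_numpy())
    if np.ptp(df["age"].to_numpy()) == 0 or df["female"].nunique() < 2:
        raise RankError("design not estimable (constant age or single sex)")
    model = smf.ols("y ~ female + age + female:age + scan_start_time", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    rename = {
        "female": "sex",
        "age": "age",
        "female:age": "sex_x_age",
        "scan_start_time": "start_time",
    }
    rows = []
    for key, label in rename.items():
        rows.append(
            {
                "effect": label,
                "df": float(table.loc[key, "df"]),
                "mean_sq": float(table.loc[key, "sum_sq"] / table.loc[key, "df"]),
                "F": float(table.loc[key, "F"]),
                "p_value": float(table.loc[key, "PR(>F)"]),
                "p_text": format_p(float(table.loc[key, "PR(>F)"])),
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Report p-values below machine-representable resolution as '< 1e-15'."""
    if p < 1e-15:
        return "< 1e-15"
    return f"{p:.3g}"


@dataclass(frozen=True)
class SubjectAssessment:
    expected: float
    observed: float
    z: float
    lower_pi: float
    below_lower_pi: bool


def zscore_subject(model: NormativeModel, record, level: float = 0.95) -> SubjectAssessment:
    """Standardized residual of a subject against the normative model.

    ``record`` needs age, sex, scan_start_time and the (calibrated, when
    available) left/right SBRs.  The flag is true when the observed value
    falls below the lower prediction limit at the stated level.
    """
    if model.residual_sd <= 1e-10:
        raise DegenerateModelError("model residual scale is (numerically) zero; z-score undefined")
    df = _records_to_frame([record] if not isinstance(record, pd.DataFrame) else record)
    observed = float(_outcome_values(df, model.outcome)[0])
    age = float(df["age"].iloc[0])
    sex = df["sex"].iloc[0]
    start = float(df["scan_start_time"].iloc[0])
    expected = predict_expected(model, age, sex, start)
    z = (observed - expected) / model.residual_sd
    lo, _ = model.prediction_interval(age, sex, start, level)
    return SubjectAssessment(
        expected=expected,
        observed=observed,
        z=float(z),
        lower_pi=float(lo),
        below_lower_pi=bool(observed < lo),
    )


def paired_lr_ttest(records, use_calibrated: bool | None = None):
    """Paired t-test of right vs left striatal SBR (right-dominance check)."""
    df = _records_to_frame(records)
    if use_calibrated is None:
        use_calibrated = "sbr_calibrated_right" in df and df["sbr_calibrated_right"].notna().all()
    r = df["sbr_calibrated_right" if use_calibrated else "sbr_right"].to_numpy(float)
    l = df["sbr_calibrated_left" if use_calibrated else "sbr_left"].to_numpy(float)
    return stats.ttest_rel(r, l)
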
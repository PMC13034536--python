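"""Clinical-evaluation statistics for the MDS biomarker.

Survival analysis on a fully observed cohort (every patient followed to
death, so no censoring): Pearson correlation of MDS against overall
survival, a Cox proportional-hazards model with MDS standardized to unit
SD (so the coefficient exponentiates to a hazard ratio per 1 SD of MDS)
and age as a separate predictor, Kaplan-Meier survival summaries, and
the scan-rescan repeatability statistics used on healthy volunteers:
the repeated-measures coefficient of variation

    RMCoV = sd(x1_i - x2_i) / mean((x1_i + x2_i) / 2),

the two-way random single-measure intraclass correlation ICC(2,1),
Bland-Altman bias and limits of agreement, and a one-way ANOVA for
group comparisons of regional ADC.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import validate_cohort

__all__ = [
    "CoxResult",
    "RepeatabilityPair",
    "pearson_mds_os",
    "fit_cox",
    "survival_summary",
    "rmcov",
    "icc_and_bland_altman",
    "group_anova",
]


@dataclasses.dataclass(frozen=True)
class CoxResult:
    hr_per_sd: float
    ci95: tuple[float, float]
    p_mds: float
    p_age: float | None
    model_p: float  # likelihood-ratio test of the whole model
    ph_test_p: float  # Schoenfeld-residual proportional-hazards check (MDS term)
    beta_per_sd: float
    n: int


@dataclasses.dataclass(frozen=True)
class RepeatabilityPair:
    """Paired same-scale measurements (e.g. scan-rescan regional ADC)."""

    x1: np.ndarray
    x2: np.ndarray
    subject_ids: np.ndarray | None = None
    region: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x1", np.asarray(self.x1, dtype=float))
        object.__setattr__(self, "x2", np.asarray(self.x2, dtype=float))
        if self.x1.shape != self.x2.shape or self.x1.ndim != 1:
            raise ValueError("x1 and x2 must be equal-length 1D vectors")
        if len(self.x1) < 2:
            raise ValueError("need at least 2 subjects")


def pearson_mds_os(cohort: pd.DataFrame) -> dict:
    """Pearson correlation of per-patient MDS against overall survival (days)."""
    cohort = validate_cohort(cohort)
    mds = cohort["mds"].to_numpy(dtype=float)
    os_days = cohort["os_days"].to_numpy(dtype=float)
    if len(cohort) < 3:
        raise ValueError("need at least 3 patients")
    if np.ptp(mds) == 0 or np.ptp(os_days) == 0:
        raise ValueError("zero variance in mds or os_days")
    r, p = stats.pearsonr(mds, os_days)
    return {"r": float(r), "p": float(p), "n": int(len(cohort))}


def fit_cox(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age",),
) -> CoxResult:
    """Cox proportional-hazards fit of overall survival on standardized MDS.

    MDS is standardized to zero mean and unit (sample, n-1) SD before
    fitting, so ``exp(beta)`` is the hazard ratio per 1 SD increase in
    MDS — invariant to any affine rescaling of the raw slope values.
    Partial likelihood with Efron handling of tied death days.  Reports
    the Wald CI and p for the MDS term, the age p when age is included,
    the likelihood-ratio p for the whole model, and the Schoenfeld
    residual proportional-hazards p for the MDS term.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    cohort = validate_cohort(cohort)
    n = len(cohort)
    if n < 10:
        warnings.warn(f"only {n} subjects: Cox estimates will be unstable", stacklevel=2)
    mds = cohort["mds"].to_numpy(dtype=float)
    sd = mds.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in mds")
    df = pd.DataFrame(
        {
            "os_days": cohort["os_days"].to_numpy(dtype=float),
            "event": np.ones(n, dtype=int),
            "mds_z": (mds - mds.mean()) / sd,
        }
    )
    include_age = "age" in covariates
    if include_age:
        age_col = "age_years" if "age_years" in cohort.columns else "age"
        df["age"] = cohort[age_col].to_numpy(dtype=float)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_days", event_col="event")
    summ = cph.summary
    hr = float(summ.loc["mds_z", "exp(coef)"])
    ci = (
        float(summ.loc["mds_z", "exp(coef) lower 95%"]),
        float(summ.loc["mds_z", "exp(coef) upper 95%"]),
    )
    p_mds = float(summ.loc["mds_z", "p"])
    p_age = float(summ.loc["age", "p"]) if include_age else None
    model_p = float(cph.log_likelihood_ratio_test().p_value)
    ph = proportional_hazard_test(cph, df, time_transform="km").summary
    ph = ph.reset_index()
    name_col = "index" if "index" in ph.columns else ph.columns[0]
    ph_p = float(ph.loc[ph[name_col].astype(str).str.startswith("mds_z"), "p"].min())
    return CoxResult(
        hr_per_sd=hr,
        ci95=ci,
        p_mds=p_mds,
        p_age=p_age,
        model_p=model_p,
        ph_test_p=ph_p,
        beta_per_sd=float(summ.loc["mds_z", "coef"]),
        n=n,
    )


def survival_summary(cohort: pd.DataFrame) -> dict:
    """Median (with Kaplan-Meier log-log 95% CI), mean, and range of OS.

    With no censoring the Kaplan-Meier estimator reduces to the
    empirical survival function; the point estimate reported here is the
    plain sample median (midpoint convention for even n, which
    coincides with the Kaplan-Meier median for odd n).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    cohort = validate_cohort(cohort)
    os_days = cohort["os_days"].to_numpy(dtype=float)
    if len(os_days) == 0:
        raise ValueError("empty cohort")
    out = {
        "median_days": float(np.median(os_days)),
        "mean_days": float(np.mean(os_days)),
        "min_days": float(np.min(os_days)),
        "max_days": float(np.max(os_days)),
        "n": int(len(os_days)),
        "ci95_median": (float("nan"), float("nan")),
        "ci_degenerate": True,
    }
    if len(os_days) >= 2:
        kmf = KaplanMeierFitter()
        kmf.fit(os_days, event_observed=np.ones_like(os_days))
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        out["ci95_median"] = (lo, hi)
        out["ci_degenerate"] = not (np.isfinite(lo) and np.isfinite(hi))
    return out


def rmcov(pairs: RepeatabilityPair, ddof: int = 1) -> float:
    """Repeated-measures coefficient of variation.

    Sample standard deviation (n-1 denominator by default) of the
    within-subject differences, divided by the mean of the
    within-subject means.  Dimensionless; invariant to a common positive
    rescaling of both measurements.
    """
    diffs = pairs.x1 - pairs.x2
    denom = float(np.mean((pairs.x1 + pairs.x2) / 2.0))
    if denom == 0:
        raise ZeroDivisionError("mean of within-subject means is zero")
    return float(np.std(diffs, ddof=ddof) / denom)


def icc_and_bland_altman(pairs: RepeatabilityPair) -> dict:
    """ICC(2,1) plus Bland-Altman bias and 95% limits of agreement.

    The ICC is the two-way random-effects, absolute-agreement,
    single-measure form, computed from the standard mean-squares
    decomposition.  Bland-Altman bias is the mean difference
    (x2 - x1); limits are bias +/- 1.96 * sd(differences).
    """
    import pingouin as pg

    n = len(pairs.x1)
    if n < 3:
        raise ValueError("need at least 3 subjects for the ICC")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "session": np.tile([1, 2], n),
            "value": np.column_stack([pairs.x1, pairs.x2]).ravel(),
        }
    )
    if np.ptp(long["value"].to_numpy()) == 0:
        icc = 1.0  # identical constant measurements agree perfectly
    else:
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="session", ratings="value"
        ).set_index("Type")
        # absolute-agreement single-measure row: "ICC2" (Shrout & Fleiss
        # naming) or "ICC(A,1)" (McGraw & Wong naming), version-dependent
        row = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
        icc = float(table.loc[row, "ICC"])
    diffs = pairs.x2 - pairs.x1
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return {
        "icc_2_1": icc,
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "n": n,
    }


def group_anova(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across labelled value sets (e.g. patients vs volunteers)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays.append(arr)
    if np.ptp(np.concatenate(arrays)) == 0:
        raise ValueError("all values identical: ANOVA undefined")
    f, p = stats.f_oneway(*arrays)
    return {"F": float(f), "p": float(p), "k_groups": len(arrays)}
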
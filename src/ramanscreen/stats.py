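"""Cohort statistics: Pearson / point-biserial correlation with strength
bands, pooled-variance (homoscedastic) Student's t-tests with star
annotations, and a clinical summary table.

Conventions follow the study design: correlations against the 0/1 class
coding are plain Pearson (point-biserial), correlation strength is banded at
|r| < 0.295 weak, < 0.505 moderate, else strong (midpoints bridging the
published 0.29/0.30 and 0.50/0.51 band edges), and no multiple-testing
correction is applied anywhere.  t-tests are unpaired and homoscedastic with
df = n1 + n2 - 2; tail mode is explicit with a two-sided default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ZeroVarianceError
from .features import FeatureTable

WEAK_MODERATE_CUT = 0.295
MODERATE_STRONG_CUT = 0.505


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2)),
    df = n-2.  With y a 0/1 class coding this is the point-biserial
    correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def strength_category(r: float) -> str:
    """Band |r| into weak / moderate / strong."""
    a = abs(float(r))
    if a > 1:
        raise ParameterError(f"|r| = {a} > 1")
    if a < WEAK_MODERATE_CUT:
        return "weak"
    if a < MODERATE_STRONG_CUT:
        return "moderate"
    return "strong"


def annotate_significance(p: float) -> str:
    """Star annotation: p < 0.001 -> ***, < 0.01 -> **, < 0.05 -> * (strict)."""
    if not 0 <= p <= 1:
        raise ParameterError(f"p = {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    """Two-group pooled-variance t-test outcome."""

    variable: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: int
    p: float
    tails: str
    stars: str


def _pooled_t(
    mean_a, sd_a, n_a, mean_b, sd_b, n_b, tails: str, variable: str
) -> GroupComparison:
    if n_a < 2 or n_b < 2:
        raise ParameterError("each group needs n >= 2")
    if tails not in ("one", "two"):
        raise ParameterError(f"tails must be 'one' or 'two', got {tails!r}")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 <= 0:
        raise ZeroVarianceError(f"{variable}: zero pooled variance")
    t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    if tails == "two":
        p = 2 * sps.t.sf(abs(t), df)
    else:
        p = sps.t.sf(abs(t), df)
    return GroupComparison(
        variable=variable,
        mean_a=float(mean_a), mean_b=float(mean_b),
        sd_a=float(sd_a), sd_b=float(sd_b),
        n_a=int(n_a), n_b=int(n_b),
        t=float(t), df=int(df), p=float(p), tails=tails,
        stars=annotate_significance(float(min(p, 1.0))),
    )


def ttest_two_sample(a, b, tails: str = "two", variable: str = "") -> GroupComparison:
    """Unpaired homoscedastic Student's t-test on raw vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return _pooled_t(
        a.mean(), a.std(ddof=1), a.size,
        b.mean(), b.std(ddof=1), b.size,
        tails, variable,
    )


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    tails: str = "two", variable: str = "",
) -> GroupComparison:
    """Same test from summary statistics; identical to the raw-vector path
    given matching means/SDs/sizes."""
    return _pooled_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b, tails, variable)


#: the clinical variables summarized per cohort, in report order
CLINICAL_VARIABLES = (
    "maternal_age",
    "bmi",
    "gestational_age",
    "gravida",
    "parity",
    "pregnancy_loss",
    "blood_sugar",
    "comorbidity",
)


def summary_table(cohort: pd.DataFrame, tails: str = "two") -> pd.DataFrame:
    """Per-variable class means +/- sample SDs and the two-sample p.

    ``cohort`` needs a binary ``class`` column plus the clinical variables.
    Comorbidity is reported as a percentage, with its p from the t-test on
    the 0/1 indicator.  A constant variable is reported with p = "n/a".
    """
    classes = np.sort(cohort["class"].unique())
    if classes.size != 2:
        raise ParameterError(f"need exactly 2 classes, got {classes.tolist()}")
    g0 = cohort[cohort["class"] == classes[0]]
    g1 = cohort[cohort["class"] == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ParameterError("need >= 2 records per class")
    rows = []
    for var in CLINICAL_VARIABLES:
        a = g1[var].to_numpy(dtype=float)  # disease cohort first, as published
        b = g0[var].to_numpy(dtype=float)
        try:
            cmp_ = ttest_two_sample(a, b, tails=tails, variable=var)
            p: float | str = cmp_.p
        except ZeroVarianceError:
            p = "n/a"
        if var == "comorbidity":
            rows.append(
                dict(variable="comorbidity_pct",
                     healthy_mean=100 * b.mean(), healthy_sd=100 * b.std(ddof=1),
                     disease_mean=100 * a.mean(), disease_sd=100 * a.std(ddof=1),
                     p=p)
            )
        else:
            rows.append(
                dict(variable=var,
                     healthy_mean=b.mean(), healthy_sd=b.std(ddof=1),
                     disease_mean=a.mean(), disease_sd=a.std(ddof=1),
                     p=p)
            )
    return pd.DataFrame(rows)


def correlation_matrix(table: FeatureTable, targets) -> pd.DataFrame:
    """All pairwise feature-target Pearson correlations with strength bands.

    ``targets`` is a second :class:`FeatureTable` aligned on sample_ids, or a
    plain vector (e.g. the 0/1 class labels, giving point-biserial
    correlations).  No multiple-testing adjustment is applied.
    """
    if isinstance(targets, FeatureTable):
        if table.sample_ids != targets.sample_ids:
            extra = sorted(
                set(table.sample_ids).symmetric_difference(targets.sample_ids)
            )
            raise ParameterError(f"sample_id mismatch: {extra or 'ordering differs'}")
        tnames = targets.feature_names
        tcols = [targets.column(n) for n in tnames]
    else:
        arr = np.asarray(targets, dtype=float)
        if arr.shape != (table.n_samples,):
            raise ParameterError("target vector length must match sample count")
        tnames = ["target"]
        tcols = [arr]
    rows = []
    for fname in table.feature_names:
        x = table.column(fname)
        for tname, y in zip(tnames, tcols):
            try:
                r, p = pearson(x, y)
            except ZeroVarianceError:
                continue
            rows.append(
                dict(feature=fname, target=tname, r=r, p=p,
                     category=strength_category(r),
                     sign="+" if r >= 0 else "-")
            )
    return pd.DataFrame(rows)
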
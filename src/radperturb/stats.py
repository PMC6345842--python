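"""Robustness statistics: ICC(1,1) with 95% confidence interval, averaging
over test/retest replicates, threshold classification, and comparison of
test-retest vs perturbation robustness.

The intraclass correlation coefficient (1, 1) comes from a one-way
random-effects ANOVA on an n subjects × k repeated-measurements panel:

    ICC = (MSB − MSW) / (MSB + (k − 1) MSW)

with MSB/MSW the between-/within-subject mean squares.  Its confidence
interval follows Shrout & Fleiss: with F0 = MSB/MSW,

    F_L = F0 / F(1 − α/2; n − 1, n(k − 1)),
    F_U = F0 · F(1 − α/2; n(k − 1), n − 1),
    bound(F) = (F − 1) / (F + k − 1),

clipped to [−1, 1].  Negative estimates (MSB < MSW) are retained rather than
truncated at 0, since classification compares CI bounds, not the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "MeasurementPanel",
    "IccRecord",
    "ComparisonRecord",
    "icc_1_1",
    "icc_ci",
    "icc_record",
    "perturbation_icc",
    "classify_robustness",
    "compare_conditions",
]

ROBUST, NON_ROBUST, INDETERMINATE = "robust", "non_robust", "indeterminate"
_LABEL_TO_SIGN = {ROBUST: "+", NON_ROBUST: "-", INDETERMINATE: "0"}


@dataclass
class MeasurementPanel:
    """n subjects × k repeated measurements of one feature (no missing cells)."""

    values: np.ndarray
    subject_ids: list | None = None
    measurement_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("panel must be a 2D (subjects x measurements) array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ParameterError(f"panel needs n >= 2 subjects and k >= 2 measurements, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("panel contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class IccRecord:
    """Per-feature ICC estimate with CI bounds and robustness label."""

    feature_id: str
    estimate: float
    lower: float
    upper: float
    n: int
    k: int
    msb: float
    msw: float
    alpha: float = 0.05
    undefined: bool = False
    label: str = INDETERMINATE


@dataclass
class ComparisonRecord:
    """Feature-wise comparison of test-retest (T) and perturbation (P) robustness."""

    feature_id: str
    test_retest: str  # one of + - 0
    perturbation: str
    category: str
    sub_state: str


def icc_1_1(panel: MeasurementPanel) -> tuple[float, float, float]:
    """One-way random-effects ICC(1,1).

    Returns ``(estimate, MSB, MSW)``.  When MSW = 0 with MSB > 0 the
    measurements are perfectly repeatable and the estimate is exactly 1; when
    the panel is entirely constant the ICC is undefined and NaN is returned.
    """
    x = panel.values
    n, k = x.shape
    subject_means = x.mean(axis=1)
    grand = x.mean()
    ssb = k * float(((subject_means - grand) ** 2).sum())
    ssw = float(((x - subject_means[:, None]) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0.0:
        est = 1.0 if msb > 0 else float("nan")
    else:
        est = (msb - msw) / (msb + (k - 1) * msw)
    return est, msb, msw


def icc_ci(
    msb: float, msw: float, n: int, k: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Shrout–Fleiss confidence interval for ICC(1,1); bounds in [-1, 1]."""
    if msw == 0.0:
        return (1.0, 1.0) if msb > 0 else (float("nan"), float("nan"))
    df1, df2 = n - 1, n * (k - 1)
    f0 = msb / msw
    f_l = f0 / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f0 * sps.f.ppf(1 - alpha / 2, df2, df1)
    lower = (f_l - 1.0) / (f_l + k - 1.0)
    upper = (f_u - 1.0) / (f_u + k - 1.0)
    return max(lower, -1.0), min(upper, 1.0)


def icc_record(
    panel: MeasurementPanel,
    feature_id: str = "",
    alpha: float = 0.05,
    threshold: float = 0.90,
) -> IccRecord:
    """ICC(1,1) + CI + robustness label for one panel."""
    est, msb, msw = icc_1_1(panel)
    undefined = math.isnan(est)
    if undefined:
        lower = upper = float("nan")
    else:
        lower, upper = icc_ci(msb, msw, panel.n, panel.k, alpha)
    rec = IccRecord(
        feature_id, est, lower, upper, panel.n, panel.k, msb, msw, alpha, undefined
    )
    rec.label = classify_robustness(rec, threshold)
    return rec


def perturbation_icc(
    panel_test: MeasurementPanel,
    panel_retest: MeasurementPanel,
    feature_id: str = "",
    alpha: float = 0.05,
    threshold: float = 0.90,
) -> IccRecord:
    """Average the perturbation ICC over test and retest replicate images.

    The estimate and both CI bounds are averaged element-wise between the two
    per-image ICCs; if either is undefined the result is flagged and the
    classification is indeterminate.
    """
    r1 = icc_record(panel_test, feature_id, alpha, threshold)
    r2 = icc_record(panel_retest, feature_id, alpha, threshold)
    undefined = r1.undefined or r2.undefined
    rec = IccRecord(
        feature_id,
        (r1.estimate + r2.estimate) / 2.0,
        (r1.lower + r2.lower) / 2.0,
        (r1.upper + r2.upper) / 2.0,
        min(r1.n, r2.n),
        min(r1.k, r2.k),
        (r1.msb + r2.msb) / 2.0,
        (r1.msw + r2.msw) / 2.0,
        alpha,
        undefined,
    )
    rec.label = classify_robustness(rec, threshold)
    return rec


def classify_robustness(record: IccRecord, threshold: float = 0.90) -> str:
    """Three-state classification of the 95% CI against the threshold.

    The whole interval at/above the threshold → robust; the whole interval
    below → non-robust; an interval straddling the threshold (or an undefined
    ICC) → indeterminate.
    """
    if record.undefined or math.isnan(record.lower) or math.isnan(record.upper):
        return INDETERMINATE
    if record.lower >= threshold:
        return ROBUST
    if record.upper < threshold:
        return NON_ROBUST
    return INDETERMINATE


_CATEGORY = {
    ("+", "+"): "true_positive",
    ("-", "-"): "true_negative",
    ("-", "+"): "false_positive",
    ("+", "-"): "false_negative",
}


def compare_conditions(
    test_retest: str, perturbation: str, feature_id: str = ""
) -> ComparisonRecord:
    """Map (T, P) robustness signs onto comparison categories.

    Signs are '+' (robust), '-' (non-robust) or '0' (indeterminate); full
    labels are also accepted.  Test-retest robustness is the reference, so
    T−P+ is a false positive and T+P− a false negative; any '0' yields an
    indeterminate category with the sub-state (e.g. ``T0P+``) retained.
    """
    t = _LABEL_TO_SIGN.get(test_retest, test_retest)
    p = _LABEL_TO_SIGN.get(perturbation, perturbation)
    for s in (t, p):
        if s not in ("+", "-", "0"):
            raise ParameterError(f"invalid robustness sign {s!r}")
    category = _CATEGORY.get((t, p), "indeterminate")
    return ComparisonRecord(feature_id, t, p, category, f"T{t}P{p}")
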
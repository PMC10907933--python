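"""Method-comparison statistics: Bland-Altman, ICC(2,1), MAE, subgroups.

The device's respiratory rates are compared against a reference method
on paired readings.  Agreement is summarized by the Bland-Altman bias
and 1.96-SD limits of agreement, the fraction of differences inside a
clinical +-2 bpm band, the two-way random-effects absolute-agreement
single-measures intraclass correlation ICC(2,1) with its F-based 95% CI,
and the per-subject mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltmanReport",
    "ICCReport",
    "MAEReport",
    "bland_altman",
    "icc_absolute_agreement",
    "mae",
    "subgroup_agreement",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltmanReport:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_clinical: float
    clinical_limit: float
    n_pairs: int
    slope_vs_mean: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ICCReport:
    icc: float
    ci_low: float
    ci_high: float
    model_label: str = "two-way random, absolute agreement, single measures"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MAEReport:
    mae_overall: float
    per_subject_mae: dict
    mae_range: tuple

    def to_dict(self) -> dict:
        return asdict(self)


def _diffs(pairs: pd.DataFrame, device_col: str) -> np.ndarray:
    return (pairs[device_col] - pairs["rr_reference"]).to_numpy(dtype=float)


def bland_altman(
    pairs: pd.DataFrame, device_col: str = "rr_device", clinical_limit: float = 2.0
) -> BlandAltmanReport:
    """Bland-Altman agreement of device vs reference readings.

    Bias is the mean of the differences d_i = device - reference,
    sd_diff the sample SD (n-1 denominator), limits of agreement
    bias +- 1.96 sd, and ``pct_within_clinical`` the percentage of |d_i|
    inside the clinical limit.  ``slope_vs_mean`` is the least-squares
    slope of d on the pair means (proportional-bias trend).
    """
    d = _diffs(pairs, device_col)
    if d.size < 2:
        raise ValueError("at least 2 pairs required for Bland-Altman analysis")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    means = (pairs[device_col].to_numpy(float) + pairs["rr_reference"].to_numpy(float)) / 2.0
    slope = 0.0 if np.ptp(means) == 0 else float(np.polyfit(means, d, 1)[0])
    return BlandAltmanReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        pct_within_clinical=float(100.0 * np.mean(np.abs(d) <= clinical_limit)),
        clinical_limit=float(clinical_limit),
        n_pairs=int(d.size),
        slope_vs_mean=slope,
    )


def icc_absolute_agreement(
    pairs: pd.DataFrame, device_col: str = "rr_device", alpha: float = 0.05
) -> ICCReport:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Rows are measurement occasions, columns the two methods.  From the
    two-way ANOVA mean squares (rows MSR, columns MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the standard F-based 95% confidence interval.
    """
    y = np.column_stack(
        [pairs[device_col].to_numpy(float), pairs["rr_reference"].to_numpy(float)]
    )
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells are not allowed in the ICC table")
    n, k = y.shape
    if n < 3:
        raise ValueError("at least 3 measurement occasions required")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and msc == 0 and mse == 0):
        raise ValueError("ICC undefined: no between-occasion variance in the table")
    icc = (msr - mse) / denom

    # F-based CI for ICC(A,1) (two-way random, absolute agreement)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    return ICCReport(icc=float(icc), ci_low=float(lower), ci_high=float(upper))


def mae(pairs: pd.DataFrame, device_col: str = "rr_device") -> MAEReport:
    """Per-subject mean absolute error and its across-subject summary.

    The overall MAE is the unweighted mean of the per-subject MAEs (each
    subject counts once regardless of how many readings they have).
    """
    if len(pairs) < 1:
        raise ValueError("at least 1 pair required")
    d = pairs.assign(_absd=np.abs(_diffs(pairs, device_col)))
    per_subject = d.groupby("subject_id")["_absd"].mean()
    return MAEReport(
        mae_overall=float(per_subject.mean()),
        per_subject_mae={str(k): float(v) for k, v in per_subject.items()},
        mae_range=(float(per_subject.min()), float(per_subject.max())),
    )


def subgroup_agreement(
    pairs: pd.DataFrame,
    by: str,
    device_col: str = "rr_device",
    clinical_limit: float = 2.0,
) -> dict:
    """Per-group Bland-Altman and ICC reports, keyed by group label.

    ``by`` is ``"sex"`` or ``"dx_group"``.  Groups too small for a given
    statistic are reported with that entry ``None`` plus a flag.
    """
    if by not in ("sex", "dx_group"):
        raise ValueError(f"unknown grouping key {by!r}; expected 'sex' or 'dx_group'")
    out: dict = {}
    for label, grp in pairs.groupby(by, sort=True):
        entry: dict = {"n_pairs": int(len(grp)), "flags": []}
        if len(grp) < 2:
            entry["bland_altman"] = None
            entry["icc"] = None
            entry["flags"].append("group_too_small")
        else:
            entry["bland_altman"] = bland_altman(grp, device_col, clinical_limit)
            try:
                entry["icc"] = icc_absolute_agreement(grp, device_col)
            except ValueError as exc:
                entry["icc"] = None
                entry["flags"].append(f"icc_undefined:{exc}")
        out[str(label)] = entry
    return out
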
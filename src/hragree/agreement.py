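"""Method-agreement statistics for a paired HR stream.

The statistics follow the standard device-validation toolkit:

* Bland-Altman: bias = mean(test - criterion), limits of agreement
  LOA = bias +/- 1.96 * SD of the differences (sample SD, n-1), LOA
  width = upper - lower = 3.92 * SD.
* MAE / MAPE: mean absolute (percentage) error, criterion in the
  denominator, each reported with the SD across samples.
* ICC(2,1): single-measure two-way random-effects absolute-agreement
  intraclass correlation (McGraw & Wong "A,1"), subjects = time
  samples, raters = the two devices, with the standard F-based 95% CI.
  A consistency variant ICC(3,1) is available behind a switch.
* Lin's concordance correlation coefficient with 1/n moment
  estimators, penalizing both imprecision and location/scale shift.

Qualitative labels use the conventional bands (ICC: 0.5/0.75/0.9;
CCC: 0.90/0.95/0.99); a value exactly at a cut belongs to the higher
band, since the usual strict-inequality phrasing leaves cut points
unassigned.

No autocorrelation correction is applied to LOA or ICC confidence
intervals: 1 Hz HR is strongly autocorrelated, so the CIs are
anti-conservative. This is a documented limitation, not an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .artifact import DEFAULT_THRESHOLD, artifact_ratio, flag_artifacts
from .sync import AlignedPair

__all__ = [
    "BlandAltman",
    "ErrorStats",
    "ReliabilityStats",
    "AgreementSummary",
    "bland_altman",
    "error_stats",
    "icc_two_way",
    "lin_ccc",
    "label_icc",
    "label_ccc",
    "summarize_stratum",
]

Z_LOA = 1.96  # normal quantile fixed by the Bland-Altman convention


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    upper_loa: float
    lower_loa: float
    loa_width: float
    n: int


@dataclass(frozen=True)
class ErrorStats:
    mae: float
    mae_sd: float
    mape: float
    mape_sd: float


@dataclass(frozen=True)
class ReliabilityStats:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    ccc: float
    icc_label: str
    ccc_label: str
    icc_variant: str = "absolute_agreement"


@dataclass(frozen=True)
class AgreementSummary:
    stratum: str
    bland_altman: BlandAltman
    errors: ErrorStats
    reliability: ReliabilityStats
    artifact_pct: float
    n_sessions: int = 1


def bland_altman(pair: AlignedPair) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement of test - criterion."""
    d = pair.differences
    if len(d) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired samples")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    upper = bias + Z_LOA * sd
    lower = bias - Z_LOA * sd
    return BlandAltman(
        bias=bias, sd_diff=sd, upper_loa=upper, lower_loa=lower,
        loa_width=upper - lower, n=len(d),
    )


def error_stats(pair: AlignedPair) -> ErrorStats:
    """MAE (bpm) and MAPE (% of criterion), each with its across-sample SD."""
    c = pair.criterion_hr
    if np.any(c <= 0):
        raise ValueError("criterion HR must be strictly positive for MAPE")
    abs_d = np.abs(pair.differences)
    ape = 100.0 * abs_d / c
    return ErrorStats(
        mae=float(np.mean(abs_d)),
        mae_sd=float(np.std(abs_d, ddof=1)),
        mape=float(np.mean(ape)),
        mape_sd=float(np.std(ape, ddof=1)),
    )


def _mean_squares(x: np.ndarray):
    """Two-way ANOVA mean squares for an n x k ratings matrix."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(pair: AlignedPair, variant: str = "absolute_agreement", alpha: float = 0.05):
    """Single-measure two-way ICC of the device pair with its 95% CI.

    ``variant="absolute_agreement"`` gives ICC(2,1) (McGraw & Wong A,1),
    the default and the scientifically relevant choice for device
    interchangeability since a constant offset between devices lowers
    it. ``variant="consistency"`` gives ICC(3,1), which ignores the
    device main effect.

    Subjects are the aligned time samples and raters the two devices.
    Values <= 0 (possible when between-sample variance is small) are
    returned as computed, never clamped.
    """
    x = np.column_stack([pair.test_hr, pair.criterion_hr])
    n, k = x.shape
    if n < 30:
        warnings.warn(f"ICC computed on only {n} paired samples", stacklevel=2)
    msr, msc, mse = _mean_squares(x)
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: zero within-sample variance, degenerate CI
        return 1.0, 1.0, 1.0
    if variant == "absolute_agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        icc = (msr - mse) / denom
        # Satterthwaite df for the CI (McGraw & Wong 1996)
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        fl = f_dist.ppf(1 - alpha / 2, n - 1, v)
        fu = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    elif variant == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        fobs = msr / mse
        fl = f_dist.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f_dist.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fobs / fl - 1) / (fobs / fl + k - 1)
        hi = (fobs * fu - 1) / (fobs * fu + k - 1)
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return float(icc), float(lo), float(hi)


def lin_ccc(pair: AlignedPair) -> float:
    """Lin's concordance correlation coefficient with 1/n moment estimators.

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2). Degenerate
    cases: two equal constant series are perfectly concordant (1, with
    a warning); a constant against a varying series has no concordance (0).
    """
    x, y = pair.test_hr, pair.criterion_hr
    if len(x) < 2:
        raise ValueError("CCC needs at least 2 paired samples")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    mx, my = float(np.mean(x)), float(np.mean(y))
    if sx2 == 0.0 and sy2 == 0.0:
        if mx == my:
            warnings.warn("both series constant and equal; CCC defined as 1", stacklevel=2)
            return 1.0
        return 0.0
    if sx2 == 0.0 or sy2 == 0.0:
        return 0.0
    sxy = float(np.mean((x - mx) * (y - my)))
    return 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)


_ICC_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))
_CCC_BANDS = ((0.99, "almost_perfect"), (0.95, "very_good"), (0.90, "moderate"))


def label_icc(icc: float) -> str:
    """Qualitative reliability band; a value exactly at a cut takes the higher band."""
    for cut, name in _ICC_BANDS:
        if icc >= cut:
            return name
    return "poor"


def label_ccc(ccc: float) -> str:
    """McBride-style strength-of-agreement band for Lin's CCC."""
    for cut, name in _CCC_BANDS:
        if ccc >= cut:
            return name
    return "poor"


def summarize_stratum(
    pairs,
    stratum: str,
    artifact_threshold: float = DEFAULT_THRESHOLD,
    icc_variant: str = "absolute_agreement",
    exclude_artifacts: bool = False,
) -> AgreementSummary:
    """All agreement statistics for one stratum (activity or pooled group).

    Sessions are pooled sample-wise: every statistic is computed on the
    concatenated grid samples, not by averaging per-session statistics.
    The artifact percentage always refers to the full pooled samples;
    when ``exclude_artifacts`` is set the remaining statistics are
    computed with flagged samples removed (an explicit deviation from
    the default convention of keeping them).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError(f"stratum {stratum!r} has no aligned sessions")
    pooled = AlignedPair.concat(pairs)
    mask = flag_artifacts(pooled, artifact_threshold)
    pct = artifact_ratio(mask)
    if exclude_artifacts:
        keep = ~mask.flags
        if keep.sum() < 2:
            raise ValueError("fewer than 2 samples left after artifact exclusion")
        pooled = AlignedPair(
            grid_times=pooled.grid_times[keep],
            test_hr=pooled.test_hr[keep],
            criterion_hr=pooled.criterion_hr[keep],
            lag_applied=0,
        )
    icc, lo, hi = icc_two_way(pooled, variant=icc_variant)
    ccc = lin_ccc(pooled)
    return AgreementSummary(
        stratum=stratum,
        bland_altman=bland_altman(pooled),
        errors=error_stats(pooled),
        reliability=ReliabilityStats(
            icc=icc, icc_ci_low=lo, icc_ci_high=hi, ccc=ccc,
            icc_label=label_icc(icc), ccc_label=label_ccc(ccc),
            icc_variant=icc_variant,
        ),
        artifact_pct=pct,
        n_sessions=len(pairs),
    )
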
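"""Placing a test/criterion pair of HR series on a common 1 Hz grid.

Pipeline (order frozen): linear resampling to integer seconds, an
exhaustive integer-lag search minimizing the mean squared difference,
intersection of the overlapping span, then a centered moving-average
smoothing applied symmetrically to both series. Every downstream
statistic (Bland-Altman, MAE/MAPE, ICC, CCC, artifact ratio) consumes
the resulting :class:`AlignedPair`, so the smoothed pair is the single
source of truth.

A single global lag is assumed: 1 Hz data cannot resolve sub-second
offsets, and start-button clock offsets between two consumer devices
are constant within a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import HRRecord

__all__ = [
    "SyncConfig",
    "ResampledSeries",
    "AlignedPair",
    "resample_1hz",
    "find_lag",
    "smooth",
    "align_pair",
    "SyncError",
]


class SyncError(ValueError):
    pass


@dataclass(frozen=True)
class SyncConfig:
    """Synchronization parameters.

    max_lag : largest clock offset searched, seconds (both signs).
    smooth_window : smoothing span in seconds; even values are widened
        to the next odd point count so the window stays centered
        (10 -> 11 points, i.e. +/- 5 s).
    min_overlap : minimum usable overlap after alignment, seconds.
    max_gap : native sampling gaps longer than this are treated as
        missing data rather than interpolated across.
    """

    max_lag: int = 120
    smooth_window: int = 10
    grid_rate: float = 1.0
    min_overlap: int = 60
    max_gap: float = 30.0

    def __post_init__(self):
        if self.max_lag < 0:
            raise SyncError("max_lag must be >= 0")
        if self.smooth_window < 1:
            raise SyncError("smooth_window must be >= 1")
        if self.grid_rate != 1.0:
            raise SyncError("only the 1 Hz grid is supported")
        if self.min_overlap < 2:
            raise SyncError("min_overlap must be >= 2")

    @property
    def smooth_points(self) -> int:
        w = int(self.smooth_window)
        return w if w % 2 == 1 else w + 1


@dataclass(frozen=True)
class ResampledSeries:
    """A record interpolated onto integer seconds.

    ``hr`` is NaN at grid points that fall strictly inside a native
    sampling gap longer than ``max_gap``; ``gaps`` lists those native
    (start, end) intervals.
    """

    time: np.ndarray
    hr: np.ndarray
    gaps: tuple = ()

    def __len__(self):
        return len(self.time)


def resample_1hz(record: HRRecord, cfg: SyncConfig = SyncConfig()) -> ResampledSeries:
    """Linearly interpolate a record onto integer seconds.

    The grid covers ceil(t0)..floor(t_end); there is no extrapolation
    beyond the native span. Gaps longer than ``cfg.max_gap`` are left
    missing (NaN) and reported in the result.
    """
    if record.duration < cfg.min_overlap:
        raise SyncError(
            f"record duration {record.duration:.0f}s is shorter than min_overlap {cfg.min_overlap}s"
        )
    t0, t1 = record.time[0], record.time[-1]
    grid = np.arange(np.ceil(t0), np.floor(t1) + 1.0)
    hr = np.interp(grid, record.time, record.hr)
    gaps = []
    dt = np.diff(record.time)
    for i in np.nonzero(dt > cfg.max_gap)[0]:
        lo, hi = record.time[i], record.time[i + 1]
        gaps.append((float(lo), float(hi)))
        hr[(grid > lo) & (grid < hi)] = np.nan
    return ResampledSeries(time=grid, hr=hr, gaps=tuple(gaps))


def _mse_at_lag(test_hr, test_t0, crit_hr, crit_t0, lag):
    """Mean squared difference between test shifted back by ``lag`` and criterion.

    Grid index i of the criterion is compared with the test value at
    absolute second ``crit_t0 + i + lag``. Returns (mse, n_valid).
    """
    # overlap in criterion grid indices
    off = int(round(test_t0 - crit_t0))  # test grid start relative to criterion grid
    lo = max(0, off - lag)
    hi = min(len(crit_hr), len(test_hr) + off - lag)
    if hi - lo <= 0:
        return np.inf, 0
    c = crit_hr[lo:hi]
    t = test_hr[lo - off + lag : hi - off + lag]
    d = t - c
    valid = np.isfinite(d)
    n = int(valid.sum())
    if n == 0:
        return np.inf, 0
    return float(np.mean(d[valid] ** 2)), n


def _as_series(obj) -> ResampledSeries:
    if isinstance(obj, ResampledSeries):
        return obj
    return ResampledSeries(time=np.asarray(obj.time, float), hr=np.asarray(obj.hr, float))


def find_lag(test, criterion, cfg: SyncConfig = SyncConfig()) -> int:
    """Exhaustive least-squares search for the integer lag of the test series.

    Returns the lag L in [-max_lag, +max_lag] minimizing the mean squared
    difference between ``test`` advanced by L seconds and ``criterion``
    over their overlap. A positive L means the test stream trails the
    criterion by L seconds. Ties are broken toward smaller |L|, then
    toward negative L.
    """
    test = _as_series(test)
    criterion = _as_series(criterion)
    best = None
    for lag in range(-cfg.max_lag, cfg.max_lag + 1):
        mse, n = _mse_at_lag(test.hr, test.time[0], criterion.hr, criterion.time[0], lag)
        if n < cfg.min_overlap:
            continue
        key = (mse, abs(lag), lag)
        if best is None or key < best[0]:
            best = (key, lag)
    if best is None:
        raise SyncError(
            f"no candidate lag in [-{cfg.max_lag}, {cfg.max_lag}] leaves at least "
            f"{cfg.min_overlap}s of overlap"
        )
    return best[1]


def smooth(values, window: int) -> np.ndarray:
    """Centered moving average over ``window`` seconds of a 1 Hz series.

    Even windows are widened to the next odd point count. Near the
    edges the window truncates to the available samples, so the output
    has the same length as the input; missing values (NaN) are skipped
    and left missing in the output.
    """
    if window < 1:
        raise SyncError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    pts = int(window) if int(window) % 2 == 1 else int(window) + 1
    if pts == 1:
        return values.copy()
    s = pd.Series(values)
    out = s.rolling(pts, center=True, min_periods=1).mean().to_numpy()
    out[np.isnan(values)] = np.nan
    return out


@dataclass(frozen=True)
class AlignedPair:
    """Two HR series on a shared 1 Hz grid after lag correction and smoothing."""

    grid_times: np.ndarray
    test_hr: np.ndarray
    criterion_hr: np.ndarray
    lag_applied: int
    n_excluded: int = 0  # grid points dropped because of native gaps

    def __post_init__(self):
        if not (len(self.grid_times) == len(self.test_hr) == len(self.criterion_hr)):
            raise SyncError("aligned series must have identical length")
        if np.any(~np.isfinite(self.test_hr)) or np.any(~np.isfinite(self.criterion_hr)):
            raise SyncError("aligned pair must not contain missing values")

    @property
    def n_overlap(self) -> int:
        return len(self.grid_times)

    @property
    def differences(self) -> np.ndarray:
        """Per-second test - criterion differences (negative = underestimation)."""
        return self.test_hr - self.criterion_hr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.grid_times,
                "test_hr": self.test_hr,
                "criterion_hr": self.criterion_hr,
            }
        )

    @classmethod
    def concat(cls, pairs) -> "AlignedPair":
        """Pool several aligned pairs sample-wise (for stratum-level statistics).

        Grid times are re-indexed consecutively; the pooled object only
        serves sample-level statistics, not further alignment.
        """
        pairs = list(pairs)
        if not pairs:
            raise SyncError("cannot pool an empty list of pairs")
        t = np.concatenate([p.test_hr for p in pairs])
        c = np.concatenate([p.criterion_hr for p in pairs])
        return cls(
            grid_times=np.arange(len(t), dtype=float),
            test_hr=t,
            criterion_hr=c,
            lag_applied=0,
            n_excluded=sum(p.n_excluded for p in pairs),
        )


def align_pair(test: HRRecord, criterion: HRRecord, cfg: SyncConfig = SyncConfig()) -> AlignedPair:
    """Full synchronization pipeline: resample, lag-correct, intersect, smooth.

    Grid points falling inside a reported gap of either series are
    excluded from the overlap and counted in ``n_excluded``.
    """
    rt = resample_1hz(test, cfg)
    rc = resample_1hz(criterion, cfg)
    lag = find_lag(rt, rc, cfg)

    off = int(round(rt.time[0] - rc.time[0]))
    lo = max(0, off - lag)
    hi = min(len(rc), len(rt) + off - lag)
    if hi - lo < cfg.min_overlap:
        raise SyncError(f"overlap after lag correction is {hi - lo}s (< {cfg.min_overlap}s)")
    c_raw = rc.hr[lo:hi]
    t_raw = rt.hr[lo - off + lag : hi - off + lag]
    grid = rc.time[lo:hi]

    t_sm = smooth(t_raw, cfg.smooth_window)
    c_sm = smooth(c_raw, cfg.smooth_window)
    keep = np.isfinite(t_sm) & np.isfinite(c_sm)
    n_excluded = int((~keep).sum())
    if keep.sum() < cfg.min_overlap:
        raise SyncError("fewer than min_overlap usable grid points after gap exclusion")
    return AlignedPair(
        grid_times=grid[keep],
        test_hr=t_sm[keep],
        criterion_hr=c_sm[keep],
        lag_applied=lag,
        n_excluded=n_excluded,
    )
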
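"""Cross-activity comparisons and covariate modelling of device bias.

Four procedures operate above the per-stratum agreement statistics:

* a normality check of the paired differences (one-sample
  Kolmogorov-Smirnov against a normal with plug-in mean and SD,
  i.e. the Lilliefors construction);
* a Kruskal-Wallis test comparing the per-sample differences across
  activities;
* a location test of the differences against zero. The scientifically
  sound construction for a one-sample question is the Wilcoxon
  signed-rank test, which is the default; a literal Mann-Whitney U of
  the differences against an all-zeros sample of equal size is
  available as ``method="mannwhitney-vs-zero"`` for fidelity with
  reports that phrase the comparison that way;
* an ordinary least-squares model of per-session bias on the
  Fitzpatrick skin-tone score (numeric covariate) while controlling
  for activity through indicator terms.

No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TestResult",
    "SessionBias",
    "ks_normality",
    "kruskal_wallis",
    "bias_vs_zero",
    "skin_tone_model",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    df: float | None = None
    stratum: str = "all"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class SessionBias:
    """Per-session Bland-Altman bias with the covariates the linear model uses."""

    session_id: str
    participant_id: str
    activity: str
    skin_tone: int
    bias: float


def ks_normality(differences, stratum: str = "all") -> TestResult:
    """Kolmogorov-Smirnov normality check with estimated mean and SD.

    Uses the Lilliefors correction for the plug-in parameters; the raw
    KS table would be badly anti-conservative here.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 10:
        raise ValueError("normality check needs at least 10 values")
    if np.ptp(d) == 0:
        raise ValueError("constant input has no defined normality statistic")
    stat, p = lilliefors(d, dist="norm", pvalmethod="table")
    return TestResult("ks_normality", float(stat), float(p), n=len(d), stratum=stratum)


def kruskal_wallis(groups: dict) -> TestResult:
    """Kruskal-Wallis H across per-activity difference samples (tie-corrected)."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    total = sum(len(s) for s in samples)
    if total < 5:
        raise ValueError("Kruskal-Wallis needs at least 5 values in total")
    stat, p = st.kruskal(*samples)
    return TestResult(
        "kruskal_wallis", float(stat), float(p), n=total, df=len(groups) - 1
    )


def _signed_rank_statistic(d: np.ndarray) -> float:
    """W+ = sum of ranks of the positive differences (zeros dropped)."""
    nz = d[d != 0]
    ranks = st.rankdata(np.abs(nz))
    return float(ranks[nz > 0].sum())


def bias_vs_zero(differences, stratum: str = "all", method: str = "wilcoxon") -> TestResult:
    """Test whether the device differences are centred on zero.

    Default: one-sample Wilcoxon signed-rank on the differences,
    reporting W+ (the positive-rank sum). ``method="mannwhitney-vs-zero"``
    instead runs a two-sample Mann-Whitney U of the differences against
    an equal-size all-zeros sample.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 5:
        raise ValueError("need at least 5 differences")
    if np.all(d == 0):
        warnings.warn("all differences are zero; degenerate test", stacklevel=2)
        return TestResult(f"{method}_bias_vs_zero", 0.0, 1.0, n=len(d), stratum=stratum)
    if method == "wilcoxon":
        stat = _signed_rank_statistic(d)
        p = float(st.wilcoxon(d, zero_method="wilcox", alternative="two-sided").pvalue)
    elif method == "mannwhitney-vs-zero":
        res = st.mannwhitneyu(d, np.zeros_like(d), alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(f"{method}_bias_vs_zero", stat, p, n=len(d), stratum=stratum)


def skin_tone_model(rows) -> pd.DataFrame:
    """OLS of per-session bias on skin tone, controlling for activity.

    Skin tone enters as a numeric covariate; activities as indicator
    terms against the first activity (alphabetical) as reference. With a
    single activity present the model reduces to a simple regression.
    Returns the statsmodels coefficient table as a DataFrame
    (coef, std err, t, p, CI bounds) indexed by term.
    """
    rows = list(rows)
    if len(rows) < 10:
        raise ValueError("skin-tone model needs at least 10 sessions")
    df = pd.DataFrame(
        {
            "bias": [r.bias for r in rows],
            "skin_tone": [float(r.skin_tone) for r in rows],
            "activity": [r.activity for r in rows],
        }
    )
    if df["skin_tone"].nunique() < 2:
        raise ValueError("skin-tone model needs at least 2 distinct skin tones")
    X = pd.DataFrame({"const": 1.0, "skin_tone": df["skin_tone"]})
    if df["activity"].nunique() >= 2:
        dummies = pd.get_dummies(df["activity"], prefix="activity", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix (columns: {list(X.columns)})")
    fit = sm.OLS(df["bias"].to_numpy(), X).fit()
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "std_err": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
            "ci_low": fit.conf_int()[0],
            "ci_high": fit.conf_int()[1],
        }
    )
    return out
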
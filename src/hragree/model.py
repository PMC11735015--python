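"""Study-level agreement model: many sessions in, one results object out.

:class:`DeviceAgreement` plays the role a statsmodels model class plays:
it is constructed from data (paired HR records plus session metadata),
holds the analysis configuration, and ``fit()`` runs the full pipeline —
synchronization, artifact flagging, per-stratum agreement statistics,
and the cohort-level tests — returning an :class:`AgreementResults`
carrying every estimate with its uncertainty, a ``summary()`` table and
report writers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import AgreementSummary, bland_altman, summarize_stratum
from .artifact import DEFAULT_THRESHOLD
from .cohort import SessionBias, TestResult, bias_vs_zero, kruskal_wallis, ks_normality, skin_tone_model
from .records import ACTIVITIES, ACTIVITY_GROUPS, HRRecord, SessionMetadata, read_session_dir
from .sync import AlignedPair, SyncConfig, SyncError, align_pair

logger = logging.getLogger(__name__)

__all__ = ["Session", "DeviceAgreement", "AgreementResults", "samples_to_minutes"]


def samples_to_minutes(n_samples: int, rate: float = 1.0) -> float:
    """Convert a sample count at ``rate`` (per second) into minutes.

    6,000 samples at 1 s^-1 are 100 minutes of recording.
    """
    if rate <= 0:
        raise ValueError("sample rate must be positive")
    if n_samples < 0:
        raise ValueError("sample count must be non-negative")
    return n_samples / (rate * 60.0)


@dataclass(frozen=True)
class Session:
    test: HRRecord
    criterion: HRRecord
    meta: SessionMetadata


class DeviceAgreement:
    """Agreement analysis of a test HR device against a criterion device.

    Parameters
    ----------
    sessions : iterable of :class:`Session`
    sync : :class:`SyncConfig`
        Synchronization settings (lag search range, smoothing window).
    artifact_threshold : float
        Deviation (bpm) beyond which a sample counts as an artifact.
    icc_variant : {"absolute_agreement", "consistency"}
    exclude_artifacts : bool
        Drop flagged samples before the agreement statistics. Off by
        default; flagged samples are reported but kept.
    """

    def __init__(
        self,
        sessions,
        sync: SyncConfig = SyncConfig(),
        artifact_threshold: float = DEFAULT_THRESHOLD,
        icc_variant: str = "absolute_agreement",
        exclude_artifacts: bool = False,
    ):
        self.sessions = list(sessions)
        if not self.sessions:
            raise ValueError("need at least one session")
        self.sync = sync
        self.artifact_threshold = float(artifact_threshold)
        self.icc_variant = icc_variant
        self.exclude_artifacts = bool(exclude_artifacts)

    @classmethod
    def from_directory(cls, root, **kwargs) -> "DeviceAgreement":
        """Build the model from a tree of session directories.

        Every subdirectory of ``root`` holding ``test.csv``,
        ``criterion.csv`` and ``meta.json`` becomes one session.
        """
        root = Path(root)
        sessions = []
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            if (sub / "meta.json").exists():
                test, criterion, meta = read_session_dir(sub)
                sessions.append(Session(test, criterion, meta))
        if not sessions:
            raise ValueError(f"no session directories under {root}")
        return cls(sessions, **kwargs)

    def fit(self) -> "AgreementResults":
        """Run the full pipeline and collect per-stratum and cohort results.

        Sessions that fail alignment are skipped with a logged reason;
        fitting fails only if no session aligns.
        """
        aligned: list[tuple[AlignedPair, SessionMetadata]] = []
        failures: list[tuple[str, str]] = []
        for s in self.sessions:
            try:
                pair = align_pair(s.test, s.criterion, self.sync)
            except (SyncError, ValueError) as exc:
                logger.warning("session %s skipped: %s", s.meta.session_id, exc)
                failures.append((s.meta.session_id, str(exc)))
                continue
            aligned.append((pair, s.meta))
        if not aligned:
            raise SyncError("every session failed alignment")

        by_activity: dict[str, list[AlignedPair]] = {}
        for pair, meta in aligned:
            by_activity.setdefault(meta.activity, []).append(pair)

        summaries: dict[str, AgreementSummary] = {}
        strata = [(act, [act]) for act in ACTIVITIES]
        strata += [(g, list(members)) for g, members in ACTIVITY_GROUPS.items()]
        for name, members in strata:
            pairs = [p for act in members for p in by_activity.get(act, [])]
            if pairs:
                summaries[name] = summarize_stratum(
                    pairs,
                    name,
                    artifact_threshold=self.artifact_threshold,
                    icc_variant=self.icc_variant,
                    exclude_artifacts=self.exclude_artifacts,
                )

        session_bias = [
            SessionBias(
                session_id=meta.session_id,
                participant_id=meta.participant_id,
                activity=meta.activity,
                skin_tone=meta.skin_tone,
                bias=bland_altman(pair).bias,
            )
            for pair, meta in aligned
        ]

        tests = self._cohort_tests(aligned, by_activity)
        skin_table = None
        df_bias = pd.DataFrame([vars(r) for r in session_bias])
        if (
            len(session_bias) >= 10
            and df_bias["skin_tone"].nunique() >= 2
        ):
            try:
                skin_table = skin_tone_model(session_bias)
            except ValueError as exc:
                logger.warning("skin-tone model skipped: %s", exc)

        return AgreementResults(
            model=self,
            summaries=summaries,
            aligned=aligned,
            session_bias=session_bias,
            tests=tests,
            skin_tone_table=skin_table,
            failures=failures,
        )

    def _cohort_tests(self, aligned, by_activity) -> list[TestResult]:
        tests: list[TestResult] = []
        all_diffs = np.concatenate([p.differences for p, _ in aligned])
        if len(all_diffs) >= 10 and np.ptp(all_diffs) > 0:
            tests.append(ks_normality(all_diffs))
        groups = {
            act: np.concatenate([p.differences for p in pairs])
            for act, pairs in by_activity.items()
        }
        if len(groups) >= 2:
            tests.append(kruskal_wallis(groups))
        for act, d in groups.items():
            if len(d) >= 5:
                tests.append(bias_vs_zero(d, stratum=act))
        return tests


# report rounding mirrors the conventional presentation: bias/LOA/MAE to
# 1 decimal, percentages to 1 decimal, ICC/CCC to 3 decimals
def _fmt(x, nd=1):
    return f"{x:.{nd}f}"


class AgreementResults:
    """Fitted agreement results: per-stratum statistics plus cohort tests.

    Attributes
    ----------
    summaries : dict of stratum name -> :class:`AgreementSummary`
    session_bias : list of :class:`SessionBias`
    tests : list of :class:`TestResult`
    skin_tone_table : DataFrame or None
    failures : list of (session_id, reason) for sessions that did not align
    """

    def __init__(self, model, summaries, aligned, session_bias, tests, skin_tone_table, failures):
        self.model = model
        self.summaries = summaries
        self.aligned = aligned
        self.session_bias = session_bias
        self.tests = tests
        self.skin_tone_table = skin_tone_table
        self.failures = failures

    # ---- tabular views -------------------------------------------------
    def agreement_frame(self) -> pd.DataFrame:
        """Bland-Altman / error / artifact table, one row per stratum."""
        rows = []
        for name, s in self.summaries.items():
            ba, er = s.bland_altman, s.errors
            rows.append(
                {
                    "stratum": name,
                    "n": ba.n,
                    "n_sessions": s.n_sessions,
                    "minutes": samples_to_minutes(ba.n),
                    "bias": ba.bias,
                    "sd_diff": ba.sd_diff,
                    "upper_loa": ba.upper_loa,
                    "lower_loa": ba.lower_loa,
                    "loa_width": ba.loa_width,
                    "artifact_pct": s.artifact_pct,
                    "mae": er.mae,
                    "mae_sd": er.mae_sd,
                    "mape": er.mape,
                    "mape_sd": er.mape_sd,
                }
            )
        return pd.DataFrame(rows).set_index("stratum")

    def reliability_frame(self) -> pd.DataFrame:
        """ICC (with CI) and CCC table, one row per stratum."""
        rows = []
        for name, s in self.summaries.items():
            r = s.reliability
            rows.append(
                {
                    "stratum": name,
                    "icc": r.icc,
                    "icc_ci_low": r.icc_ci_low,
                    "icc_ci_high": r.icc_ci_high,
                    "icc_label": r.icc_label,
                    "ccc": r.ccc,
                    "ccc_label": r.ccc_label,
                    "icc_variant": r.icc_variant,
                }
            )
        return pd.DataFrame(rows).set_index("stratum")

    def tests_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test_name": t.test_name,
                "stratum": t.stratum,
                "statistic": t.statistic,
                "df": t.df,
                "n": t.n,
                "p_value": t.p_value,
            }
            for t in self.tests
        ]
        return pd.DataFrame(rows)

    def bland_altman_points(self, stratum: str) -> pd.DataFrame:
        """Plot coordinates (pairwise mean vs difference) for one stratum."""
        members = ACTIVITY_GROUPS.get(stratum, (stratum,))
        pairs = [p for p, m in self.aligned if m.activity in members]
        if not pairs:
            raise KeyError(f"no aligned sessions in stratum {stratum!r}")
        pooled = AlignedPair.concat(pairs)
        return pd.DataFrame(
            {
                "mean_hr": (pooled.test_hr + pooled.criterion_hr) / 2.0,
                "difference": pooled.differences,
            }
        )

    # ---- presentation --------------------------------------------------
    def summary(self) -> str:
        """Human-readable report mirroring the usual validation tables."""
        lines = ["Device agreement summary (test - criterion, bpm)", ""]
        header = (
            f"{'stratum':<16}{'n':>8}{'bias':>8}{'LOA':>16}{'width':>8}"
            f"{'artif%':>8}{'MAE(SD)':>13}{'MAPE(SD)':>13}"
        )
        lines += [header, "-" * len(header)]
        for name, s in self.summaries.items():
            ba, er = s.bland_altman, s.errors
            loa = f"{_fmt(ba.upper_loa)}; {_fmt(ba.lower_loa)}"
            lines.append(
                f"{name:<16}{ba.n:>8}{_fmt(ba.bias):>8}{loa:>16}{_fmt(ba.loa_width):>8}"
                f"{_fmt(s.artifact_pct):>8}"
                f"{_fmt(er.mae) + ' (' + _fmt(er.mae_sd) + ')':>13}"
                f"{_fmt(er.mape) + ' (' + _fmt(er.mape_sd) + ')':>13}"
            )
        lines += ["", f"{'stratum':<16}{'ICC (95% CI)':>24}{'label':>11}{'CCC':>8}{'label':>15}"]
        for name, s in self.summaries.items():
            r = s.reliability
            ci = f"{r.icc:.3f} ({r.icc_ci_low:.3f}-{r.icc_ci_high:.3f})"
            lines.append(f"{name:<16}{ci:>24}{r.icc_label:>11}{r.ccc:>8.3f}{r.ccc_label:>15}")
        if self.tests:
            lines += ["", f"{'test':<34}{'stratum':<16}{'statistic':>12}{'p':>10}"]
            for t in self.tests:
                lines.append(
                    f"{t.test_name:<34}{t.stratum:<16}{t.statistic:>12.3f}{t.p_value:>10.2g}"
                )
        if self.skin_tone_table is not None:
            coef = self.skin_tone_table.loc["skin_tone"]
            lines += [
                "",
                "skin tone effect on session bias (OLS, activity-controlled): "
                f"{coef['coef']:+.2f} bpm per Fitzpatrick unit "
                f"(95% CI {coef['ci_low']:.2f} to {coef['ci_high']:.2f}, p={coef['p_value']:.2g})",
            ]
        if self.failures:
            lines += ["", f"{len(self.failures)} session(s) failed alignment:"]
            lines += [f"  {sid}: {reason}" for sid, reason in self.failures]
        return "\n".join(lines)

    def to_report(self, out_dir) -> Path:
        """Write the full report: CSV + JSON tables and plot coordinates.

        Every number in the CSV/JSON files is the full-precision value
        behind the rounded ``summary()`` rendering.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.agreement_frame().to_csv(out / "agreement.csv")
        self.reliability_frame().to_csv(out / "reliability.csv")
        self.tests_frame().to_csv(out / "cohort_tests.csv", index=False)
        pd.DataFrame([vars(r) for r in self.session_bias]).to_csv(
            out / "session_bias.csv", index=False
        )
        if self.skin_tone_table is not None:
            self.skin_tone_table.to_csv(out / "skin_tone_model.csv")
        for name in self.summaries:
            self.bland_altman_points(name).to_csv(
                out / f"bland_altman_{name}.csv", index=False
            )
        payload = {
            "agreement": self.agreement_frame().reset_index().to_dict(orient="records"),
            "reliability": self.reliability_frame().reset_index().to_dict(orient="records"),
            "tests": self.tests_frame().to_dict(orient="records"),
            "failures": [{"session_id": s, "reason": r} for s, r in self.failures],
        }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=float)
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
        return out
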
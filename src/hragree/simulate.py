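"""Synthetic paired HR sessions with a controlled error structure.

The generator emulates what a wrist PPG sensor and a chest-strap
criterion record during one training session:

* a shared "true" HR trajectory — piecewise exercise targets approached
  with a first-order exponential (time constant 30 s) plus an
  Ornstein-Uhlenbeck perturbation for spontaneous HR variability;
* the criterion stream: truth plus small Gaussian noise at 1 Hz;
* the test stream: truth delayed by a constant clock lag, plus a
  constant device bias and Gaussian noise, except during motion-artifact
  bursts. Bursts follow a two-state Markov chain (enter/exit
  probabilities per second); within a burst the test device holds a
  plateau-like offset drawn once per burst, mimicking the sudden
  uncoupling seen in wrist-PPG recordings under sharp arm movements.

The test stream can be emitted at a coarser sampling period to exercise
the resampling stage. Both emitted series are rounded to 0.1 bpm, as a
consumer device export would be.

Everything is deterministic under ``SimConfig.seed``; cohorts spawn
independent per-session streams from one root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .records import (
    ACTIVITIES,
    HRRecord,
    SessionMetadata,
    write_hr_csv,
    write_session_metadata,
)

__all__ = ["SimConfig", "SimTruth", "make_hr_profile", "simulate_pair", "make_cohort"]

#: Fitzpatrick skin-tone sampling weights for synthetic participants
#: (scores 2, 3, 4 with frequencies 6/26, 17/26, 3/26; cohort mean 2.9).
SKIN_TONE_VALUES = (2, 3, 4)
SKIN_TONE_WEIGHTS = (6 / 26, 17 / 26, 3 / 26)

_TRANSITION_TAU = 30.0  # s, exponential approach to a new HR target
_CLIP_LO, _CLIP_HI = 40.0, 220.0  # physiological clamp on the true trajectory


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic session pair."""

    activity_preset: str = "custom"
    duration: int = 3600  # seconds
    seed: int = 0
    lag: int = 7  # s; positive = test stream trails the criterion
    bias: float = 0.0  # bpm added to the test stream in the normal state
    noise_sd_test: float = 3.0
    noise_sd_criterion: float = 1.0
    artifact_enter_prob: float = 0.0  # per second
    artifact_exit_prob: float = 0.1  # per second
    artifact_offset_range: tuple = (-34.0, -26.0)  # bpm, held per burst
    hr_profile: tuple = ((600, 130.0), (600, 165.0), (600, 145.0))
    ou_sd: float = 5.0
    ou_timescale: float = 60.0
    test_sample_period: int = 5  # s between emitted test samples

    def __post_init__(self):
        if self.duration < 120:
            raise ValueError("duration must be at least 120 s")
        if not (0.0 <= self.artifact_enter_prob <= 1.0):
            raise ValueError("artifact_enter_prob must lie in [0, 1]")
        if not (0.0 < self.artifact_exit_prob <= 1.0):
            raise ValueError("artifact_exit_prob must lie in (0, 1]")
        if self.noise_sd_test < 0 or self.noise_sd_criterion < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.artifact_offset_range[0] > self.artifact_offset_range[1]:
            raise ValueError("artifact_offset_range must be (low, high)")
        if abs(self.lag) >= self.duration:
            raise ValueError("|lag| must be smaller than duration")
        if self.test_sample_period < 1:
            raise ValueError("test_sample_period must be >= 1 s")
        if not self.hr_profile:
            raise ValueError("hr_profile must contain at least one segment")
        for seg_len, target in self.hr_profile:
            if seg_len <= 0:
                raise ValueError("profile segment lengths must be positive")
            if not (40.0 < target < 220.0):
                raise ValueError("profile targets must lie in (40, 220) bpm")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated pair, for recovery tests."""

    true_hr: np.ndarray  # 1 Hz, criterion clock
    artifact_state: np.ndarray  # bool per second, test clock
    applied_lag: int
    applied_bias: float


def make_hr_profile(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """The true 1 Hz HR trajectory for one session.

    Profile segments are cycled until the session duration is covered.
    With ``ou_sd=0`` the trajectory is the deterministic piecewise
    exponential approach to the segment targets.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(cfg.duration)
    targets = np.empty(n)
    t = 0
    while t < n:
        for seg_len, target in cfg.hr_profile:
            take = min(int(seg_len), n - t)
            targets[t : t + take] = target
            t += take
            if t >= n:
                break
    decay = np.exp(-1.0 / _TRANSITION_TAU)
    base = np.empty(n)
    base[0] = targets[0]
    for i in range(1, n):
        base[i] = targets[i] + (base[i - 1] - targets[i]) * decay
    if cfg.ou_sd > 0:
        rho = np.exp(-1.0 / cfg.ou_timescale)
        innov = rng.normal(0.0, cfg.ou_sd * np.sqrt(1 - rho**2), n)
        ou = np.empty(n)
        ou[0] = rng.normal(0.0, cfg.ou_sd)
        for i in range(1, n):
            ou[i] = rho * ou[i - 1] + innov[i]
    else:
        ou = np.zeros(n)
    return np.clip(base + ou, _CLIP_LO, _CLIP_HI)


def _markov_states(n: int, enter: float, exit_: float, rng: np.random.Generator) -> np.ndarray:
    """Two-state artifact chain, started from its stationary distribution."""
    s = np.zeros(n, dtype=bool)
    if enter <= 0:
        return s
    u = rng.random(n)
    pi1 = enter / (enter + exit_)
    s[0] = u[0] < pi1
    stay = 1.0 - exit_
    for t in range(1, n):
        s[t] = u[t] < (stay if s[t - 1] else enter)
    return s


def _burst_offsets(states: np.ndarray, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """One uniform offset per burst, held across the burst."""
    starts = states & ~np.concatenate(([False], states[:-1]))
    n_bursts = int(starts.sum())
    offsets = rng.uniform(lo, hi, n_bursts)
    out = np.zeros(len(states))
    if n_bursts:
        burst_id = np.cumsum(starts) - 1
        out[states] = offsets[burst_id[states]]
    return out


def _emit(values: np.ndarray) -> np.ndarray:
    """Round to the 0.1 bpm a device export carries; keep values in range."""
    return np.clip(np.round(values, 1), 20.1, 249.9)


def simulate_pair(cfg: SimConfig) -> tuple[HRRecord, HRRecord, SimTruth]:
    """Simulate one session: (test record, criterion record, ground truth).

    The criterion is emitted at 1 Hz on its own clock. The test stream
    runs on a clock of the same span; its value at second t reflects
    the truth at t - lag (held at the session edge), so the alignment
    stage must recover ``cfg.lag`` exactly. In the normal state the
    test adds ``bias`` and Gaussian noise; inside an artifact burst it
    holds truth plus the burst offset.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.duration)
    truth = make_hr_profile(cfg, rng)

    criterion_hr = truth + rng.normal(0.0, cfg.noise_sd_criterion, n)
    states = _markov_states(n, cfg.artifact_enter_prob, cfg.artifact_exit_prob, rng)
    offsets = _burst_offsets(states, *cfg.artifact_offset_range, rng)
    test_noise = rng.normal(0.0, cfg.noise_sd_test, n)

    idx = np.clip(np.arange(n) - cfg.lag, 0, n - 1)
    test_hr = np.where(
        states,
        truth[idx] + offsets,
        truth[idx] + cfg.bias + test_noise,
    )

    step = int(cfg.test_sample_period)
    t_test = np.arange(0, n, step, dtype=float)
    test = HRRecord("test", time=t_test, hr=_emit(test_hr[::step]))
    criterion = HRRecord("criterion", time=np.arange(n, dtype=float), hr=_emit(criterion_hr))
    return test, criterion, SimTruth(
        true_hr=truth, artifact_state=states, applied_lag=cfg.lag, applied_bias=cfg.bias
    )


def make_cohort(
    out_dir,
    n_participants: int,
    sessions_per_activity: int,
    seed: int,
    duration: int = 600,
    activities=ACTIVITIES,
    with_artifacts: bool = True,
):
    """Write a synthetic cohort as a tree of session directories.

    Each session directory holds ``test.csv``, ``criterion.csv`` and
    ``meta.json``. Activities use their calibrated presets (see
    :mod:`hragree.presets`); participants get Fitzpatrick skin tones
    sampled from {2, 3, 4} with the study-like weights. Deterministic
    under ``seed``. Returns the list of created directories.
    """
    from .presets import build_sim_config  # deferred: presets import simulate

    if n_participants < 1 or sessions_per_activity < 1:
        raise ValueError("need at least one participant and one session per activity")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    participants = [f"P{i + 1:02d}" for i in range(n_participants)]
    tones = cohort_rng.choice(SKIN_TONE_VALUES, size=n_participants, p=SKIN_TONE_WEIGHTS)
    skin = dict(zip(participants, (int(t) for t in tones)))

    dirs = []
    counter = 0
    for act in activities:
        for k in range(sessions_per_activity):
            child = root.spawn(1)[0]
            session_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = build_sim_config(
                act, duration=duration, seed=session_seed, with_artifacts=with_artifacts
            )
            test, criterion, _ = simulate_pair(cfg)
            pid = participants[counter % n_participants]
            counter += 1
            sdir = out_dir / f"session_{act}_{k + 1:02d}"
            sdir.mkdir(exist_ok=True)
            write_hr_csv(test, sdir / "test.csv")
            write_hr_csv(criterion, sdir / "criterion.csv")
            write_session_metadata(
                SessionMetadata(
                    session_id=f"{act}-{k + 1}",
                    participant_id=pid,
                    activity=act,
                    skin_tone=skin[pid],
                    recorded_hours=duration / 3600.0,
                ),
                sdir / "meta.json",
            )
            dirs.append(sdir)
    return dirs
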
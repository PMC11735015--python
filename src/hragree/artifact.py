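"""Motion-artifact flagging for wrist-PPG HR streams.

A test-device sample is called an artifact when its smoothed value
deviates from the criterion by more than a fixed threshold (default
20 bpm, strict inequality at the boundary). Flags are computed on the
same smoothed :class:`~hragree.sync.AlignedPair` the agreement
statistics use, and flagged samples are reported but NOT removed from
those statistics by default; exclusion is an explicit opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sync import AlignedPair

DEFAULT_THRESHOLD = 20.0


@dataclass(frozen=True)
class ArtifactMask:
    flags: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))

    @property
    def ratio(self) -> float:
        """Fraction of flagged samples in [0, 1]."""
        return float(np.mean(self.flags))

    def __len__(self):
        return len(self.flags)


def flag_artifacts(pair: AlignedPair, threshold: float = DEFAULT_THRESHOLD) -> ArtifactMask:
    """Flag samples where |test - criterion| strictly exceeds ``threshold`` bpm."""
    if threshold <= 0:
        raise ValueError("artifact threshold must be positive")
    flags = np.abs(pair.differences) > threshold
    return ArtifactMask(flags=flags, threshold=float(threshold))


def artifact_ratio(mask: ArtifactMask) -> float:
    """Artifact ratio as a percentage of aligned samples."""
    if len(mask) == 0:
        raise ValueError("empty artifact mask")
    return 100.0 * mask.ratio
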
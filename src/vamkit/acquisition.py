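"""Acquisition timing for dual-echo (spin- and gradient-echo) dynamic series.

A SAGE-EPI bolus-tracking acquisition samples gradient-echo (GE) and
spin-echo (SE) images of the same slice stack at every repetition time,
so the two echoes share one time grid.  Defaults follow a 3 T protocol
with a 15 s pre-bolus baseline and 75 s of bolus passage sampled at
TR = 1.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionParams"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing of a dual-echo dynamic acquisition.

    Parameters
    ----------
    tr : float
        Repetition time in seconds.
    te_ge, te_se : float
        Gradient-echo and spin-echo echo times in seconds.  The spin
        echo is always the later echo (``te_ge < te_se``).
    n_baseline : int
        Number of pre-bolus frames used to estimate baseline signal.
    n_frames : int
        Total number of frames in the dynamic series.
    """

    tr: float = 1.5
    te_ge: float = 0.022
    te_se: float = 0.090
    n_baseline: int = 10
    n_frames: int = 60

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not 0 < self.te_ge < self.te_se:
            raise ValueError(
                f"require 0 < TE_GE < TE_SE, got {self.te_ge}, {self.te_se}"
            )
        if not 0 < self.n_baseline < self.n_frames:
            raise ValueError(
                f"require 0 < n_baseline < n_frames, got "
                f"{self.n_baseline}, {self.n_frames}"
            )

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.tr

    @property
    def baseline_end(self) -> float:
        """Time (s) at which the baseline window ends."""
        return self.n_baseline * self.tr

    @property
    def duration(self) -> float:
        """Time (s) of the last frame."""
        return (self.n_frames - 1) * self.tr
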
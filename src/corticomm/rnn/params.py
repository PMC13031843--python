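"""Simulator and training constants.

Trial timeline (seconds from episode start; the episode spans 5.5 s, from
0.5 s before stimulus onset to the delay offset):

====================  ==========
baseline (ITI read)    [0.0, 0.5)
stimulus (triangular)  [0.5, 1.5)
cue pulse              [1.4, 1.5)
delay                  [1.5, 5.5)
distractor             [3.2, 3.7)
pre-action window      [4.5, 5.5)
====================  ==========

The stimulus spans -5.0 to -4.0 s and the cue -4.1 to -4.0 s relative to the
action (= delay offset); the 0.5-s distractor spans -2.3 to -1.8 s.
"""

from __future__ import annotations

from dataclasses import dataclass

from corticomm.synthio.session import REGIONS


@dataclass
class RNNParams:
    n: int = 1024  # units (128 per region at the default size)
    tau: float = 0.010  # s
    dt: float = 0.001  # s
    g: float = 1.2
    beta: float = 1.0
    theta: float = 3.0
    alpha: float = 0.005  # P initialized literally as alpha * I
    alpha_learn: float = 0.05
    noise_sd: float = 0.15
    epochs: int = 1500
    seed: int = 0
    #: 'literal' reads P = alpha I verbatim; 'inverse' uses the conventional
    #: recursive-least-squares initialization P = I / alpha.
    p_init: str = "literal"

    # trial timeline (s from episode start)
    duration_s: float = 5.5
    stim_onset_s: float = 0.5
    stim_offset_s: float = 1.5
    cue_onset_s: float = 1.4
    cue_offset_s: float = 1.5
    delay_onset_s: float = 1.5
    distractor_onset_s: float = 3.2
    distractor_offset_s: float = 3.7
    pre_action_s: tuple[float, float] = (4.5, 5.5)
    baseline_s: tuple[float, float] = (0.0, 0.5)

    # input amplitudes
    stim_peak_mean: float = 1.0
    stim_peak_sd: float = 0.1
    cue_peak: float = 1.0
    distractor_peak_mean: float = 2.5
    distractor_peak_sd: float = 0.25

    # target construction
    target_rate_hz: float = 93.5
    source_rate_hz: float = 9.35
    target_boxcar_s: float = 0.4
    clip_lo: float = 0.01
    clip_hi: float = 4.99
    clip_scale: float = 5.0

    def __post_init__(self) -> None:
        if not self.tau > self.dt > 0:
            raise ValueError("must satisfy tau > dt > 0")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.p_init not in ("literal", "inverse"):
            raise ValueError("p_init must be 'literal' or 'inverse'")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.dt))

    @property
    def units_per_region(self) -> int:
        if self.n % len(REGIONS):
            raise ValueError("n must be divisible by the region count")
        return self.n // len(REGIONS)
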
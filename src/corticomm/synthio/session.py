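"""Core data model: trial records, sessions, and task-epoch frame windows.

Conventions
-----------
* All frame indices are 0-based.
* Time origin ``t = 0`` is the stimulus onset of a trial.
* Epoch windows are half-open ``[start, end)`` intervals in frames, with
  ``frame = floor(t_seconds * frame_rate) + onset_frame``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: The eight dorsal-cortex regions recorded simultaneously.
REGIONS = ("ALM", "M1a", "M1p", "M2", "S1fl", "vS1", "RSC", "PPC")

STIMULUS_SIDES = ("left", "right")
CHOICE_SIDES = ("left", "right", "none")
OUTCOMES = ("correct", "incorrect", "no_response")
DISTRACTORS = ("none", "early", "middle", "late")
COHORT_TAGS = ("control", "reduced_connectivity", "other")

#: Epoch boundaries in seconds relative to stimulus onset, half-open.
#: Task structure: 1-s stimulus, 4-s delay, 4-s action epoch.
EPOCH_WINDOWS_S = {
    "stimulus": (0.0, 1.0),
    "delay": (1.0, 5.0),
    "early_delay": (1.0, 3.0),
    "late_delay": (3.0, 5.0),
    "action": (5.0, 9.0),
    "iti_window": (-5.0, -1.0),
    "trial_window": (-1.0, 7.0),
}

#: Seconds after delay onset at which each distractor type is delivered.
DISTRACTOR_ONSETS_S = {"early": 1.0, "middle": 2.0, "late": 3.0}

#: Distractor pulse duration in seconds.
DISTRACTOR_DURATION_S = 0.2

#: Delay onset in seconds relative to stimulus onset.
DELAY_ONSET_S = 1.0


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    Attributes
    ----------
    onset_frame:
        Frame index of stimulus onset (0-based).
    stimulus_side:
        Instructed side, ``left`` or ``right``.
    choice_side:
        Licked side; ``none`` iff the mouse did not respond.
    outcome:
        ``correct``, ``incorrect``, or ``no_response``.
    distractor:
        ``none`` or the delivery time point ``early``/``middle``/``late``
        (1, 2, 3 s after delay onset).
    """

    onset_frame: int
    stimulus_side: str
    choice_side: str
    outcome: str

    distractor: str = "none"

    def __post_init__(self) -> None:
        if self.onset_frame < 0:
            raise ValueError(f"onset_frame must be >= 0, got {self.onset_frame}")
        if self.stimulus_side not in STIMULUS_SIDES:
            raise ValueError(f"stimulus_side: unknown value {self.stimulus_side!r}")
        if self.choice_side not in CHOICE_SIDES:
            raise ValueError(f"choice_side: unknown value {self.choice_side!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome: unknown value {self.outcome!r}")
        if self.distractor not in DISTRACTORS:
            raise ValueError(f"distractor: unknown value {self.distractor!r}")
        if (self.outcome == "no_response") != (self.choice_side == "none"):
            raise ValueError(
                "outcome == 'no_response' must coincide with choice_side == 'none'"
            )
        if self.outcome == "correct" and self.choice_side != self.stimulus_side:
            raise ValueError("correct outcome requires choice_side == stimulus_side")
        if self.outcome == "incorrect" and self.choice_side == self.stimulus_side:
            raise ValueError("incorrect outcome requires choice_side != stimulus_side")

    @property
    def responded(self) -> bool:
        return self.outcome != "no_response"


@dataclass
class Session:
    """A recorded (or generated) imaging session.

    Attributes
    ----------
    activity:
        ``(n_neurons, n_frames)`` z-scored deconvolved event amplitudes.
    region_of:
        Length-``n_neurons`` array of region labels drawn from :data:`REGIONS`.
    frame_rate_hz:
        Imaging frame rate (~9.35 Hz in the source recordings).
    trials:
        Ordered trial table; onsets strictly increasing.
    cohort_tag:
        ``control``, ``reduced_connectivity``, or ``other``.
    """

    activity: np.ndarray
    region_of: np.ndarray
    frame_rate_hz: float
    trials: list[TrialRecord]
    cohort_tag: str = "other"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.float64)
        if self.activity.ndim != 2:
            raise ValueError("activity must be a 2-d (neurons x frames) array")
        self.region_of = np.asarray(self.region_of, dtype=object)
        if self.region_of.shape[0] != self.activity.shape[0]:
            raise ValueError("region_of length must equal the number of neurons")
        bad = set(self.region_of) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(map(str, bad))}")
        if self.cohort_tag not in COHORT_TAGS:
            raise ValueError(f"cohort_tag: unknown value {self.cohort_tag!r}")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        onsets = [t.onset_frame for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onset frames must be strictly increasing")
        for tr in self.trials:
            lo = int(math.floor(-5.0 * self.frame_rate_hz)) + tr.onset_frame
            hi = int(math.floor(9.0 * self.frame_rate_hz)) + tr.onset_frame
            if lo < 0 or hi > self.n_frames:
                raise ValueError(
                    f"recording does not span [-5 s, +9 s] around trial at "
                    f"frame {tr.onset_frame}"
                )

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    def neurons_in(self, region: str) -> np.ndarray:
        """Indices of neurons recorded in ``region``."""
        return np.flatnonzero(self.region_of == region)

    def zscored(self) -> "Session":
        """Copy with each neuron's trace z-scored across frames."""
        mu = self.activity.mean(axis=1, keepdims=True)
        sd = self.activity.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return Session(
            activity=(self.activity - mu) / sd,
            region_of=self.region_of.copy(),
            frame_rate_hz=self.frame_rate_hz,
            trials=list(self.trials),
            cohort_tag=self.cohort_tag,
            meta=dict(self.meta),
        )

    def seconds_to_frames(self, t: float) -> int:
        return int(math.floor(t * self.frame_rate_hz))


def epoch_frames(session: Session, trial: TrialRecord, epoch: str) -> tuple[int, int]:
    """Half-open ``[start, end)`` frame interval of a task epoch for one trial.

    ``frame = floor(t_seconds * frame_rate) + onset_frame`` with ``t = 0`` at
    stimulus onset.

    Raises
    ------
    KeyError
        For an unknown epoch name.
    ValueError
        If the interval exceeds the recording bounds.
    """
    t0, t1 = EPOCH_WINDOWS_S[epoch]
    fr = session.frame_rate_hz
    start = int(math.floor(t0 * fr)) + trial.onset_frame
    end = int(math.floor(t1 * fr)) + trial.onset_frame
    if start < 0 or end > session.n_frames:
        raise ValueError(
            f"epoch {epoch!r} of trial at frame {trial.onset_frame} "
            f"([{start}, {end})) exceeds recording bounds [0, {session.n_frames})"
        )
    return start, end


def distractor_window_frames(
    session: Session,
    trial: TrialRecord,
    *,
    anchor: str = "offset",
    duration_s: float = 1.0,
) -> tuple[int, int]:
    """Frame window used to quantify distractor-mediated modulation.

    The 1-s analysis window is anchored at the distractor *offset*
    (onset + 0.2 s) by default; ``anchor='onset'`` starts it at delivery.
    """
    if trial.distractor not in DISTRACTOR_ONSETS_S:
        raise ValueError(f"trial has no distractor (distractor={trial.distractor!r})")
    t = DELAY_ONSET_S + DISTRACTOR_ONSETS_S[trial.distractor]
    if anchor == "offset":
        t += DISTRACTOR_DURATION_S
    elif anchor != "onset":
        raise ValueError("anchor must be 'onset' or 'offset'")
    fr = session.frame_rate_hz
    start = int(math.floor(t * fr)) + trial.onset_frame
    end = int(math.floor((t + duration_s) * fr)) + trial.onset_frame
    return start, end


def distractor_window_for_type(
    session: Session,
    trial: TrialRecord,
    distractor_type: str,
    *,
    anchor: str = "offset",
    duration_s: float = 1.0,
) -> tuple[int, int]:
    """Window of ``distractor_type`` timing applied to any trial (e.g. to read
    the matched window out of non-distractor trials)."""
    if distractor_type not in DISTRACTOR_ONSETS_S:
        raise ValueError(f"unknown distractor type {distractor_type!r}")
    t = DELAY_ONSET_S + DISTRACTOR_ONSETS_S[distractor_type]
    if anchor == "offset":
        t += DISTRACTOR_DURATION_S
    elif anchor != "onset":
        raise ValueError("anchor must be 'onset' or 'offset'")
    fr = session.frame_rate_hz
    start = int(math.floor(t * fr)) + trial.onset_frame
    end = int(math.floor((t + duration_s) * fr)) + trial.onset_frame
    return start, end
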
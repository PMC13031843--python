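"""Per-trial input traces: triangular stimulus, square cue, optional distractor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from corticomm.rnn.params import RNNParams


@dataclass
class TrialInputs:
    i_stimulus: np.ndarray  # (n_steps,) triangular pulse; peak 0 on left trials
    i_cue: np.ndarray  # (n_steps,) square pulse, peak 1.0
    i_distractor: np.ndarray  # (n_steps,) triangular pulse or zeros
    trial_type: str
    trial_index: int = 0
    stim_peak: float = 0.0
    distractor_peak: float = 0.0

    @property
    def total_stimulus(self) -> np.ndarray:
        """Drive delivered through the stimulus weight vector."""
        return self.i_stimulus + self.i_distractor


def _triangle(times: np.ndarray, onset: float, offset: float, peak: float) -> np.ndarray:
    mid = 0.5 * (onset + offset)
    up = np.clip((times - onset) / (mid - onset), 0.0, 1.0)
    down = np.clip((offset - times) / (offset - mid), 0.0, 1.0)
    return peak * np.minimum(up, down) * ((times >= onset) & (times < offset))


def make_trial_inputs(
    trial_type: str,
    with_distractor: bool = False,
    params: RNNParams | None = None,
    rng: np.random.Generator | int | None = None,
    trial_index: int = 0,
    distractor_peak_mean: float | None = None,
) -> TrialInputs:
    """Build the input traces for one trial.

    Right trials draw the stimulus peak from N(1.0, 0.1); left trials fix it
    at exactly 0. The cue peak is exactly 1.0. The optional 0.5-s distractor
    peak is drawn from N(2.5, 0.25) unless overridden.
    """
    if trial_type not in ("left", "right"):
        raise ValueError("trial_type must be 'left' or 'right'")
    params = params or RNNParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    times = (np.arange(params.n_steps) + 0.5) * params.dt
    if trial_type == "right":
        stim_peak = float(rng.normal(params.stim_peak_mean, params.stim_peak_sd))
    else:
        stim_peak = 0.0
    i_stim = _triangle(times, params.stim_onset_s, params.stim_offset_s, stim_peak)
    i_cue = params.cue_peak * (
        (times >= params.cue_onset_s) & (times < params.cue_offset_s)
    ).astype(float)
    if with_distractor:
        mean = (
            params.distractor_peak_mean
            if distractor_peak_mean is None
            else distractor_peak_mean
        )
        d_peak = float(rng.normal(mean, params.distractor_peak_sd)) if mean > 0 else 0.0
        i_dist = _triangle(
            times, params.distractor_onset_s, params.distractor_offset_s, d_peak
        )
    else:
        d_peak = 0.0
        i_dist = np.zeros_like(times)
    return TrialInputs(
        i_stimulus=i_stim,
        i_cue=i_cue,
        i_distractor=i_dist,
        trial_type=trial_type,
        trial_index=trial_index,
        stim_peak=stim_peak,
        distractor_peak=d_peak,
    )
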
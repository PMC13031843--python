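"""Choice-axis projection, decision-switch detection, synaptic strength."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from corticomm.rnn.params import RNNParams


@dataclass
class ChoiceProjection:
    """Projections of population activity onto the l2-normalized choice axis.

    ``projections[cond]`` is (n_trials, n_timepoints); ``mean_traces`` are
    baseline-subtracted, max-right-normalized trial averages per condition.
    """

    axis: np.ndarray  # (n,) unit norm
    times: np.ndarray  # (n_timepoints,) s
    projections: dict  # condition -> (n_trials, n_timepoints), raw
    baselines: dict  # condition -> scalar ITI baseline
    mean_traces: dict  # condition -> (n_timepoints,), normalized
    norm_const: float
    degenerate: bool = False
    params: RNNParams = field(default_factory=RNNParams)


def choice_axis_projection(
    activities: dict,
    times: np.ndarray,
    params: RNNParams | None = None,
    pre_action_s: tuple[float, float] | None = None,
) -> ChoiceProjection:
    """Compute the choice axis and per-trial projections.

    ``activities`` maps condition names to (n_trials, n_timepoints, n_units)
    arrays and must contain the reference conditions ``left`` and ``right``.
    The axis is the right-minus-left difference of trial-averaged activity
    in the pre-action window (1 s before the go cue by default; 0.5-s and
    1.5-s variants via ``pre_action_s``), l2-normalized. Mean traces are
    baseline-subtracted (0.5-s ITI window per condition) and normalized by
    the maximum right-trial choice activity.
    """
    params = params or RNNParams()
    if "left" not in activities or "right" not in activities:
        raise ValueError("activities must contain 'left' and 'right' conditions")
    times = np.asarray(times, dtype=float)
    win = pre_action_s or params.pre_action_s
    pre_mask = (times >= win[0]) & (times < win[1])
    base_mask = (times >= params.baseline_s[0]) & (times < params.baseline_s[1])
    if not pre_mask.any() or not base_mask.any():
        raise ValueError("time axis does not cover the pre-action/baseline windows")
    r_bar = activities["right"].mean(axis=0)[pre_mask].mean(axis=0)
    l_bar = activities["left"].mean(axis=0)[pre_mask].mean(axis=0)
    delta = r_bar - l_bar
    norm = float(np.linalg.norm(delta))
    degenerate = norm < 1e-12
    axis = delta / norm if not degenerate else np.zeros_like(delta)

    projections = {c: a @ axis for c, a in activities.items()}
    baselines = {
        c: float(p.mean(axis=0)[base_mask].mean()) for c, p in projections.items()
    }
    raw_means = {c: p.mean(axis=0) - baselines[c] for c, p in projections.items()}
    norm_const = float(np.max(raw_means["right"])) if not degenerate else 1.0
    if norm_const == 0:
        norm_const = 1.0
    mean_traces = {c: m / norm_const for c, m in raw_means.items()}
    return ChoiceProjection(
        axis=axis,
        times=times,
        projections=projections,
        baselines=baselines,
        mean_traces=mean_traces,
        norm_const=norm_const,
        degenerate=degenerate,
        params=params,
    )


def _end_of_delay_mask(proj: ChoiceProjection, readout_s: float) -> np.ndarray:
    end = proj.params.duration_s
    mask = (proj.times >= end - readout_s) & (proj.times < end)
    if not mask.any():  # fall back to the single last sample
        mask = np.zeros_like(proj.times, dtype=bool)
        mask[-1] = True
    return mask


def detect_switch(
    proj: ChoiceProjection,
    trial_trace: np.ndarray,
    condition: str = "left_distractor",
    readout_s: float = 0.010,
) -> bool:
    """Whether a (left-distractor) trial ended closer to the right attractor.

    The trial's normalized choice activity, read out as the mean over the
    final ``readout_s`` of the delay, is compared with the midpoint between
    the non-distractor right and left reference traces at the same time.
    An exact midpoint does not count as switched (strict inequality).
    """
    if proj.degenerate:
        raise ValueError("degenerate choice axis: left/right means are identical")
    mask = _end_of_delay_mask(proj, readout_s)
    base = proj.baselines.get(condition, proj.baselines["left"])
    value = float((np.asarray(trial_trace) - base)[mask].mean()) / proj.norm_const
    mid = float(
        0.5 * (proj.mean_traces["right"][mask] + proj.mean_traces["left"][mask]).mean()
    )
    return value > mid


def switch_mask(
    proj: ChoiceProjection, condition: str = "left_distractor", readout_s: float = 0.010
) -> np.ndarray:
    """Vectorized :func:`detect_switch` over all trials of one condition."""
    trials = proj.projections[condition]
    return np.array(
        [detect_switch(proj, tr, condition=condition, readout_s=readout_s) for tr in trials]
    )


def synaptic_strength(J: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Mean absolute recurrent weight, overall and split by sign.

    ``mask`` optionally restricts the computation to a boolean subset of
    connections. Empty sign classes are reported as NaN.
    """
    J = np.asarray(J, dtype=float)
    w = J[mask] if mask is not None else J.ravel()
    pos = w[w > 0]
    neg = w[w < 0]
    return {
        "overall": float(np.abs(w).mean()) if w.size else float("nan"),
        "excitatory": float(pos.mean()) if pos.size else float("nan"),
        "inhibitory": float(np.abs(neg).mean()) if neg.size else float("nan"),
    }
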
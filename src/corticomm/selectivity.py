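"""Single-neuron selectivity: epoch labels, trial-type profiles, distractor
modulation.

A neuron is *epoch selective* if its per-trial mean activity in that epoch
differs between left and right correct trials (two-tailed Wilcoxon rank-sum,
P < 0.01). Regions with fewer than 10 recorded neurons in a session are
excluded from classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ranksums

from corticomm.synthio.session import (
    REGIONS,
    Session,
    TrialRecord,
    distractor_window_for_type,
    epoch_frames,
)

CLASSIFIED_EPOCHS = ("stimulus", "delay", "early_delay", "late_delay", "action")


@dataclass(frozen=True)
class SelectivityLabel:
    neuron: int
    epoch: str
    preferred_side: str
    p_value: float


def _epoch_means(
    session: Session, trials: list[TrialRecord], epoch: str
) -> np.ndarray:
    """(n_neurons, n_trials) per-trial mean activity within an epoch."""
    out = np.empty((session.n_neurons, len(trials)))
    for i, tr in enumerate(trials):
        a, b = epoch_frames(session, tr, epoch)
        out[:, i] = session.activity[:, a:b].mean(axis=1)
    return out


def classify_epoch_selectivity(
    session: Session,
    epochs=CLASSIFIED_EPOCHS,
    p_threshold: float = 0.01,
    min_neurons: int = 10,
) -> list[SelectivityLabel]:
    """Classify epoch selectivity for every neuron in eligible regions.

    Uses correct trials only. Emits one label per (neuron, epoch) with
    ``p < p_threshold``; the preferred side is the higher-mean side.
    """
    correct = [t for t in session.trials if t.outcome == "correct"]
    left = [t for t in correct if t.stimulus_side == "left"]
    right = [t for t in correct if t.stimulus_side == "right"]
    if not left or not right:
        warnings.warn("no correct trials on one side; no labels emitted")
        return []
    eligible = np.zeros(session.n_neurons, dtype=bool)
    for region in REGIONS:
        idx = session.neurons_in(region)
        if idx.size >= min_neurons:
            eligible[idx] = True
    labels: list[SelectivityLabel] = []
    for epoch in epochs:
        ml = _epoch_means(session, left, epoch)
        mr = _epoch_means(session, right, epoch)
        for n in np.flatnonzero(eligible):
            stat = ranksums(mr[n], ml[n])
            if stat.pvalue < p_threshold:
                side = "right" if mr[n].mean() > ml[n].mean() else "left"
                labels.append(
                    SelectivityLabel(
                        neuron=int(n),
                        epoch=epoch,
                        preferred_side=side,
                        p_value=float(stat.pvalue),
                    )
                )
    return labels


def selectivity_fraction(
    labels: list[SelectivityLabel],
    session: Session,
    region: str,
    epoch: str,
    min_neurons: int = 10,
) -> float | None:
    """Fraction of analyzed neurons in ``region`` labeled selective for ``epoch``.

    Returns ``None`` for regions excluded from analysis (< ``min_neurons``).
    """
    idx = session.neurons_in(region)
    if idx.size < min_neurons:
        return None
    members = set(idx.tolist())
    labeled = {l.neuron for l in labels if l.epoch == epoch and l.neuron in members}
    return len(labeled) / idx.size


def _boxcar_smooth(trace: np.ndarray, window: int) -> np.ndarray:
    """Centered odd-width boxcar with symmetric edge reflection (mean-exact)."""
    if window <= 1:
        return trace
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.pad(trace, ((half, half),) if trace.ndim == 1 else ((0, 0), (half, half)), mode="symmetric")
    kernel = np.ones(window) / window
    if trace.ndim == 1:
        return np.convolve(padded, kernel, mode="valid")
    return np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, padded
    )


def smoothing_window_frames(frame_rate_hz: float, smooth_s: float = 0.5) -> int:
    w = int(round(smooth_s * frame_rate_hz))
    return max(w + (1 - w % 2), 1)  # force odd


@dataclass
class SelectivityProfile:
    """Trial-type selectivity of delay-selective neurons.

    ``right_trace``/``left_trace`` are the mean right-minus-left activity
    differences of right-/left-preferring neurons (upward and downward
    deflections respectively); ``selectivity`` is their difference. All
    traces share ``time_axis`` (seconds relative to stimulus onset) and the
    same smoothing window.
    """

    time_axis: np.ndarray
    right_trace: np.ndarray
    left_trace: np.ndarray
    selectivity: np.ndarray
    neuron_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    neuron_diffs: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    normalized_traces: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    peak_order: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def empty(self) -> bool:
        return self.neuron_ids.size == 0


def _mean_trace(
    session: Session, trials: list[TrialRecord], neurons: np.ndarray, epoch: str
) -> np.ndarray:
    """(len(neurons), n_frames_in_epoch) trial-averaged activity."""
    acc = None
    for tr in trials:
        a, b = epoch_frames(session, tr, epoch)
        seg = session.activity[np.ix_(neurons, np.arange(a, b))]
        acc = seg if acc is None else acc + seg
    return acc / len(trials)


def _select_trials(session: Session, trial_filter: str, distractor: str):
    def keep(t: TrialRecord) -> bool:
        if t.distractor != distractor and distractor != "any":
            return False
        if trial_filter == "correct":
            return t.outcome == "correct"
        if trial_filter == "incorrect":
            return t.outcome == "incorrect"
        if trial_filter == "both":
            return t.responded
        raise ValueError("trial_filter must be correct|incorrect|both")

    left = [t for t in session.trials if keep(t) and t.stimulus_side == "left"]
    right = [t for t in session.trials if keep(t) and t.stimulus_side == "right"]
    return left, right


def trial_type_selectivity_profile(
    session: Session,
    delay_labels: list[SelectivityLabel],
    trial_filter: str = "correct",
    smooth_s: float = 0.5,
    epoch: str = "trial_window",
) -> SelectivityProfile:
    """Trial-type selectivity profile of delay-selective neurons.

    Non-distractor trials only. Per neuron, the left-trial mean trace is
    subtracted from the right-trial mean trace and smoothed with a 0.5-s
    boxcar; right-/left-preferring groups are averaged separately and the
    selectivity trace is the between-group difference. Per-neuron
    concatenated left/right mean traces, normalized so their extremes map to
    exactly 0 and 1, are attached together with the peak-sorted ordering.
    """
    delay_labels = [l for l in delay_labels if l.epoch == "delay"]
    fr = session.frame_rate_hz
    left, right = _select_trials(session, trial_filter, "none")
    t0, _ = epoch_frames(session, session.trials[0], epoch)
    n_frames = epoch_frames(session, session.trials[0], epoch)[1] - t0
    time_axis = (np.arange(n_frames) + (t0 - session.trials[0].onset_frame)) / fr
    if not delay_labels or not left or not right:
        if not delay_labels:
            z = np.zeros(n_frames)
            return SelectivityProfile(time_axis, z, z.copy(), z.copy())
        raise ValueError("no non-distractor trials of one side")
    neurons = np.array(sorted({l.neuron for l in delay_labels}))
    pref = {l.neuron: l.preferred_side for l in delay_labels}
    window = smoothing_window_frames(fr, smooth_s)
    mr = _mean_trace(session, right, neurons, epoch)
    ml = _mean_trace(session, left, neurons, epoch)
    diffs = _boxcar_smooth(mr - ml, window)
    right_mask = np.array([pref[n] == "right" for n in neurons])
    zeros = np.zeros(diffs.shape[1])
    right_trace = diffs[right_mask].mean(axis=0) if right_mask.any() else zeros
    left_trace = diffs[~right_mask].mean(axis=0) if (~right_mask).any() else zeros

    concat = np.concatenate([_boxcar_smooth(ml, window), _boxcar_smooth(mr, window)], axis=1)
    span = concat.max(axis=1, keepdims=True) - concat.min(axis=1, keepdims=True)
    span[span == 0] = 1.0
    normalized = (concat - concat.min(axis=1, keepdims=True)) / span
    peak_order = np.argsort(np.argmax(normalized, axis=1), kind="stable")
    return SelectivityProfile(
        time_axis=time_axis,
        right_trace=right_trace,
        left_trace=left_trace,
        selectivity=right_trace - left_trace,
        neuron_ids=neurons,
        neuron_diffs=diffs,
        normalized_traces=normalized,
        peak_order=peak_order,
    )


def distractor_modulation(
    session: Session,
    labels: list[SelectivityLabel],
    distractor_type: str,
    trial_filter: str = "both",
    anchor: str = "offset",
    window_s: float = 1.0,
    smooth_s: float = 0.5,
) -> dict[str, float]:
    """Distractor-mediated modulation of delay selectivity, per region.

    Selectivity (right-preferring minus left-preferring group difference of
    right-minus-left traces) is averaged within a 1-s window following the
    distractor (anchored at its offset by default), separately for
    distractor trials of ``distractor_type`` and for non-distractor trials;
    the non-distractor value is subtracted. Correct and incorrect trials are
    combined by default.
    """
    delay_labels = [l for l in labels if l.epoch == "delay"]
    if not delay_labels:
        return {}
    left_d, right_d = _select_trials(session, trial_filter, distractor_type)
    left_n, right_n = _select_trials(session, trial_filter, "none")
    if not left_d or not right_d:
        raise ValueError(f"no {distractor_type!r} distractor trials on both sides")
    if not left_n or not right_n:
        raise ValueError("no non-distractor trials on both sides")
    fr = session.frame_rate_hz
    window = smoothing_window_frames(fr, smooth_s)
    out: dict[str, float] = {}
    for region in REGIONS:
        region_neurons = set(session.neurons_in(region).tolist())
        neurons = np.array(
            sorted({l.neuron for l in delay_labels if l.neuron in region_neurons})
        )
        if neurons.size == 0:
            continue
        pref_right = np.array(
            [
                next(l.preferred_side for l in delay_labels if l.neuron == n)
                == "right"
                for n in neurons
            ]
        )

        def windowed_selectivity(left, right):
            diffs = _boxcar_smooth(
                _mean_trace(session, right, neurons, "trial_window")
                - _mean_trace(session, left, neurons, "trial_window"),
                window,
            )
            zeros = np.zeros(diffs.shape[1])
            rt = diffs[pref_right].mean(axis=0) if pref_right.any() else zeros
            lt = diffs[~pref_right].mean(axis=0) if (~pref_right).any() else zeros
            sel = rt - lt
            ref = session.trials[0]
            a, b = distractor_window_for_type(
                session, ref, distractor_type, anchor=anchor, duration_s=window_s
            )
            t0 = epoch_frames(session, ref, "trial_window")[0]
            return float(sel[a - t0 : b - t0].mean())

        out[region] = windowed_selectivity(left_d, right_d) - windowed_selectivity(
            left_n, right_n
        )
    return out
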
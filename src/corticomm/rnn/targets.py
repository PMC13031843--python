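"""Target-current construction for FORCE training.

Trial-averaged activity (z-scored, 9.35 Hz, 5.5-s span starting 0.5 s before
stimulus onset) is turned into target membrane currents ``f`` via the inverse
sigmoid, upsampled to 93.5 Hz by linear interpolation and smoothed with a
400-ms boxcar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from corticomm.rnn.params import RNNParams
from corticomm.synthio.session import REGIONS

TRIAL_TYPES = ("left", "right")


def sigmoid(x: np.ndarray, beta: float = 1.0, theta: float = 3.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-beta * (np.asarray(x, dtype=float) - theta)))


def inverse_sigmoid(r: np.ndarray, beta: float = 1.0, theta: float = 3.0) -> np.ndarray:
    """f = theta + (1/beta) ln(r / (1 - r)); finite only for interior r."""
    r = np.asarray(r, dtype=float)
    return theta + np.log(r / (1.0 - r)) / beta


@dataclass
class TargetSet:
    """Per-unit target currents at ``rate_hz`` over the training span."""

    f: dict  # trial type -> (n_units, n_samples)
    rate_hz: float
    provenance: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    region_of: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=object))

    @property
    def n_units(self) -> int:
        return next(iter(self.f.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.f.values())).shape[1]

    def resample(self, n_steps: int) -> dict:
        """Linear interpolation of each target onto an ``n_steps`` grid."""
        out = {}
        src = np.arange(self.n_samples) / self.rate_hz
        dst = np.linspace(src[0], src[-1], n_steps)
        for k, F in self.f.items():
            out[k] = np.stack([np.interp(dst, src, row) for row in F])
        return out


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    half = width // 2
    padded = np.pad(x, ((0, 0), (half, width - 1 - half)), mode="edge")
    return np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, padded
    )


def build_target_functions(
    traces: dict,
    params: RNNParams | None = None,
    rng: np.random.Generator | int | None = None,
    region_of: np.ndarray | None = None,
    sample: bool = True,
    eligibility_sd: float = 1.0,
) -> TargetSet:
    """Build target currents from trial-averaged activity traces.

    Parameters
    ----------
    traces:
        ``{'left': (n_neurons, n_samples), 'right': ...}`` trial-averaged
        z-scored activity at 9.35 Hz over the 5.5-s training span.
    region_of:
        Optional per-neuron region labels; sampling then draws
        ``params.n / 8`` units per region with replacement.
    sample:
        If False, keep the (eligible) neuron pool as-is without resampling.

    Neurons whose activity never reaches ``eligibility_sd`` (1 SD by
    default) in either trial type are excluded. Values are clipped to ``[0.01, 4.99]``, scaled by 1/5,
    passed through the inverse sigmoid, upsampled to 93.5 Hz and smoothed
    with a 400-ms boxcar.
    """
    params = params or RNNParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if set(traces) != set(TRIAL_TYPES):
        raise ValueError("traces must have exactly the keys 'left' and 'right'")
    left = np.asarray(traces["left"], dtype=float)
    right = np.asarray(traces["right"], dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right traces must share a shape")
    peak = np.maximum(np.abs(left).max(axis=1), np.abs(right).max(axis=1))
    eligible = np.flatnonzero(peak >= eligibility_sd)
    if eligible.size == 0:
        raise ValueError("no neuron reaches the 1-SD activity criterion")
    if sample:
        if region_of is not None:
            region_of = np.asarray(region_of, dtype=object)
            per_region = params.units_per_region
            picks = []
            for r in REGIONS:
                pool = np.array(
                    [i for i in eligible if region_of[i] == r], dtype=int
                )
                if pool.size == 0:
                    raise ValueError(f"region {r}: no eligible neurons to sample")
                picks.append(rng.choice(pool, size=per_region, replace=True))
            chosen = np.concatenate(picks)
            regions = np.array(
                [r for r in REGIONS for _ in range(per_region)], dtype=object
            )
        else:
            chosen = rng.choice(eligible, size=params.n, replace=True)
            per = params.n // len(REGIONS)
            regions = np.array(
                [REGIONS[min(i // max(per, 1), 7)] for i in range(params.n)],
                dtype=object,
            )
    else:
        chosen = eligible
        regions = (
            np.asarray(region_of, dtype=object)[eligible]
            if region_of is not None
            else np.zeros(eligible.size, dtype=object)
        )

    n_out = int(round(params.duration_s * params.target_rate_hz))
    width = max(int(round(params.target_boxcar_s * params.target_rate_hz)), 1)
    src_t = np.arange(left.shape[1]) / params.source_rate_hz
    dst_t = np.linspace(src_t[0], src_t[-1], n_out)
    out: dict[str, np.ndarray] = {}
    for key, arr in (("left", left), ("right", right)):
        sel = arr[chosen]
        r = np.clip(sel, params.clip_lo, params.clip_hi) / params.clip_scale
        f = inverse_sigmoid(r, params.beta, params.theta)
        f_up = np.stack([np.interp(dst_t, src_t, row) for row in f])
        out[key] = _boxcar(f_up, width)
    return TargetSet(
        f=out, rate_hz=params.target_rate_hz, provenance=chosen, region_of=regions
    )


def make_synthetic_targets(
    params: RNNParams,
    seed: int = 0,
    separation: float = 0.55,
    baseline: float = 0.15,
) -> TargetSet:
    """Smooth two-trial-type targets with a bistable delay structure.

    Half the units prefer right trials, half left; a preferring unit's
    normalized activity rises smoothly from ``baseline`` to
    ``baseline + separation`` across the delay on its preferred trials and
    stays near baseline otherwise. Unit-specific amplitudes and latencies
    keep the target ensemble diverse enough for FORCE training.
    """
    rng = np.random.default_rng(seed)
    n = params.n
    n_out = int(round(params.duration_s * params.target_rate_hz))
    t = np.linspace(0, params.duration_s, n_out)
    prefers_right = np.arange(n) % 2 == 0
    amp = separation * (0.8 + 0.4 * rng.random(n))
    latency = params.delay_onset_s + 0.4 * rng.random(n)
    tau_rise = 0.3 + 0.4 * rng.random(n)
    bump_amp = 0.15 * rng.random(n)
    base = baseline * (0.8 + 0.4 * rng.random(n))

    ramp = 1.0 / (1.0 + np.exp(-(t[None, :] - latency[:, None]) / tau_rise[:, None]))
    stim_mid = 0.5 * (params.stim_onset_s + params.stim_offset_s)
    bump = np.exp(-0.5 * ((t[None, :] - stim_mid) / 0.2) ** 2) * bump_amp[:, None]

    r_pref = base[:, None] + amp[:, None] * ramp + bump
    r_anti = base[:, None] + 0.1 * amp[:, None] * ramp
    r_right = np.where(prefers_right[:, None], r_pref, r_anti)
    r_left = np.where(prefers_right[:, None], r_anti, r_pref + bump * 0.0)
    f = {
        "right": inverse_sigmoid(
            np.clip(r_right, 0.002, 0.998), params.beta, params.theta
        ),
        "left": inverse_sigmoid(
            np.clip(r_left, 0.002, 0.998), params.beta, params.theta
        ),
    }
    per = n // len(REGIONS) if n % len(REGIONS) == 0 else None
    regions = (
        np.array([r for r in REGIONS for _ in range(per)], dtype=object)
        if per
        else np.zeros(n, dtype=object)
    )
    return TargetSet(
        f=f,
        rate_hz=params.target_rate_hz,
        provenance=np.arange(n),
        region_of=regions,
    )
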
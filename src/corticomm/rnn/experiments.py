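"""Perturbation and ablation experiments on trained networks."""

from __future__ import annotations

import numpy as np

from corticomm.rnn.analysis import choice_axis_projection, switch_mask
from corticomm.rnn.inputs import make_trial_inputs
from corticomm.rnn.model import RNNModel, force_train, init_network, simulate
from corticomm.rnn.params import RNNParams
from corticomm.rnn.targets import TargetSet, make_synthetic_targets


def train_convergence_fixture(
    n: int = 64, epochs: int = 300, seed: int = 0
) -> tuple[RNNModel, TargetSet, np.ndarray]:
    """Small noise-free network trained on smooth two-trial-type targets.

    Converges within a few hundred epochs (final MSE well below 10% of the
    epoch-1 MSE) and reproduces its targets with correlation > 0.99.
    """
    params = RNNParams(
        n=n, epochs=epochs, seed=seed, alpha_learn=0.2, noise_sd=0.0,
        p_init="inverse",
    )
    targets = make_synthetic_targets(params, seed=seed)
    model = init_network(params)
    mse = force_train(model, targets, rng=np.random.default_rng([seed, 1]))
    return model, targets, mse


def train_bistable_fixture(
    n: int = 64,
    epochs: int = 300,
    seed: int = 0,
    noise_sd: float = 0.25,
    targets: TargetSet | None = None,
) -> tuple[RNNModel, TargetSet, np.ndarray]:
    """Noise-robust bistable network for perturbation/ablation experiments.

    Trained with state noise and the teacher-forced state update, which keeps
    the recursive-least-squares regression stationary; the resulting network
    holds left/right delay attractors, never switches without a distractor,
    and switches increasingly often as the distractor amplitude grows.
    """
    params = RNNParams(
        n=n, epochs=epochs, seed=seed, alpha_learn=1.0, noise_sd=noise_sd,
        p_init="inverse",
    )
    if targets is None:
        targets = make_synthetic_targets(params, seed=seed)
    model = init_network(params)
    mse = force_train(
        model, targets, rng=np.random.default_rng([seed, 1]),
        state_update="teacher",
    )
    return model, targets, mse


def run_trials(
    model: RNNModel,
    n_reference: int = 20,
    n_distractor: int = 100,
    rng: np.random.Generator | int | None = None,
    distractor_peak_mean: float | None = None,
    noise_on: bool = True,
    record_every: int = 10,
):
    """Simulate left / right / left-with-distractor trials in one batch.

    Returns ``(activities, times)`` with ``activities`` keyed ``left``,
    ``right``, ``left_distractor``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = model.params
    inputs = (
        [make_trial_inputs("left", params=p, rng=rng) for _ in range(n_reference)]
        + [make_trial_inputs("right", params=p, rng=rng) for _ in range(n_reference)]
        + [
            make_trial_inputs(
                "left",
                with_distractor=True,
                params=p,
                rng=rng,
                distractor_peak_mean=distractor_peak_mean,
            )
            for _ in range(n_distractor)
        ]
    )
    sim = simulate(model, inputs, noise_on=noise_on, rng=rng, record_every=record_every)
    acts = {
        "left": sim.r[:n_reference],
        "right": sim.r[n_reference : 2 * n_reference],
        "left_distractor": sim.r[2 * n_reference :],
    }
    return acts, sim.times


def switching_proportion(
    model: RNNModel,
    n_trials: int = 100,
    n_reference: int = 20,
    seed: int | None = None,
    distractor_peak_mean: float | None = None,
) -> float:
    """Fraction of left-with-distractor trials whose end-of-delay choice
    activity crosses the left/right midpoint."""
    acts, times = run_trials(
        model,
        n_reference=n_reference,
        n_distractor=n_trials,
        rng=seed,
        distractor_peak_mean=distractor_peak_mean,
    )
    proj = choice_axis_projection(acts, times, model.params)
    if proj.degenerate:
        return float("nan")
    return float(switch_mask(proj).mean())


def _ablate(
    model: RNNModel,
    mode: str,
    level: float,
    rng: np.random.Generator,
    region: str | None,
    subset_frac: float,
) -> RNNModel:
    ablated = model.copy()
    if level == 0:
        return ablated
    if mode == "random":
        pick = rng.random(ablated.J.shape) < subset_frac
        ablated.J[pick] *= 1.0 - level
    elif mode == "region":
        if region is None:
            raise ValueError("region mode requires a region name")
        units = np.flatnonzero(ablated.region_of == region)
        if units.size == 0:
            raise ValueError(f"model has no units tagged {region!r}")
        # outgoing connections (to other regions and within-region alike)
        ablated.J[:, units] *= 1.0 - level
    else:
        raise ValueError("mode must be 'random' or 'region'")
    return ablated


def ablate_and_test(
    model: RNNModel,
    mode: str = "random",
    level: float = 0.1,
    repeats: int = 20,
    n_trials: int = 100,
    seed: int | None = None,
    region: str | None = None,
    subset_frac: float = 0.5,
    n_reference: int = 20,
    distractor_peak_mean: float | None = None,
) -> np.ndarray:
    """Per-repeat switching proportions after connection-strength reduction.

    ``mode='random'`` reduces a random ``subset_frac`` of all connections by
    ``level`` (10% or 20%); ``mode='region'`` reduces the outgoing and
    within-region connections of ``region``. ``level=0`` reproduces the
    unablated baseline for matched seeds. References and the choice axis are
    recomputed on the ablated network.
    """
    if level < 0 or level >= 1:
        raise ValueError("level must lie in [0, 1)")
    props = np.empty(repeats)
    for rep in range(repeats):
        rng = np.random.default_rng(None if seed is None else [seed, rep])
        ablated = _ablate(model, mode, level, rng, region, subset_frac)
        trial_rng = np.random.default_rng(None if seed is None else [seed, rep, 1])
        acts, times = run_trials(
            ablated,
            n_reference=n_reference,
            n_distractor=n_trials,
            rng=trial_rng,
            distractor_peak_mean=distractor_peak_mean,
        )
        proj = choice_axis_projection(acts, times, ablated.params)
        # a collapsed (degenerate-axis) network yields no readout: NaN repeat
        props[rep] = (
            float("nan") if proj.degenerate else float(switch_mask(proj).mean())
        )
    return props
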
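"""Network state, Euler simulation, and FORCE (recursive least squares) training.

Dynamics: ``tau x' = -x + J r + W_stim I_stim + W_cue I_cue + eps`` integrated
with Euler steps of ``dt``; activity ``r = sigmoid(beta (x - theta))``.

Training follows the recursive-least-squares pseudocode: per timestep the
recurrent drive ``z`` is compared with the target current ``f`` and both ``J``
and the inverse-correlation matrix ``P`` are updated. ``P`` is initialized
literally as ``alpha * I`` with ``alpha = 0.005``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from corticomm.rnn.inputs import TrialInputs, make_trial_inputs
from corticomm.rnn.params import RNNParams
from corticomm.rnn.targets import TargetSet

try:  # optional fast path
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def sigmoid(x, beta: float = 1.0, theta: float = 3.0):
    return 1.0 / (1.0 + np.exp(-beta * (x - theta)))


@dataclass
class RNNModel:
    J: np.ndarray
    w_stimulus: np.ndarray
    w_cue: np.ndarray
    P: np.ndarray
    params: RNNParams
    region_of: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=object))

    @property
    def n(self) -> int:
        return self.J.shape[0]

    def copy(self) -> "RNNModel":
        return RNNModel(
            J=self.J.copy(),
            w_stimulus=self.w_stimulus.copy(),
            w_cue=self.w_cue.copy(),
            P=self.P.copy(),
            params=self.params,
            region_of=self.region_of.copy(),
        )


def init_network(params: RNNParams, region_of: np.ndarray | None = None) -> RNNModel:
    """Initialize a chaotic network: J ~ N(0, g/sqrt(n)) (SD), W_stim ~ N(0, 1),
    W_cue ~ N(0, 0.1), P = alpha I. The same seed yields a bit-identical model."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    J = rng.normal(0.0, params.g / np.sqrt(n), size=(n, n))
    w_stim = rng.normal(0.0, 1.0, size=n)
    w_cue = rng.normal(0.0, 0.1, size=n)
    if params.p_init == "literal":
        P = params.alpha * np.eye(n)
    else:  # conventional RLS reading
        P = np.eye(n) / params.alpha
    if region_of is None:
        from corticomm.synthio.session import REGIONS

        per = n // len(REGIONS) if n % len(REGIONS) == 0 else 0
        region_of = (
            np.array([r for r in REGIONS for _ in range(per)], dtype=object)
            if per
            else np.zeros(n, dtype=object)
        )
    return RNNModel(
        J=J, w_stimulus=w_stim, w_cue=w_cue, P=P, params=params,
        region_of=np.asarray(region_of, dtype=object),
    )


# ---------------------------------------------------------------------------
# simulation (batched over trials)
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    r: np.ndarray  # (n_trials, n_recorded, n_units) activity
    z: np.ndarray  # (n_trials, n_recorded, n_units) recurrent drive
    times: np.ndarray  # (n_recorded,) seconds from episode start


def simulate(
    model: RNNModel,
    inputs: list[TrialInputs] | TrialInputs,
    noise_on: bool = True,
    rng: np.random.Generator | int | None = None,
    record_every: int = 10,
    x0: np.ndarray | None = None,
) -> SimResult:
    """Euler-integrate a batch of trials from a common initial state.

    Aborts with diagnostics if the state becomes non-finite.
    """
    if isinstance(inputs, TrialInputs):
        inputs = [inputs]
    p = model.params
    n, K, T = model.n, len(inputs), p.n_steps
    istim = np.stack([inp.total_stimulus for inp in inputs])  # (K, T)
    icue = np.stack([inp.i_cue for inp in inputs])
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.zeros((n, K)) if x0 is None else np.tile(np.asarray(x0)[:, None], (1, K))
    r = sigmoid(x, p.beta, p.theta)
    dt_tau = p.dt / p.tau
    n_rec = (T + record_every - 1) // record_every
    r_rec = np.empty((K, n_rec, n))
    z_rec = np.empty((K, n_rec, n))
    t_rec = np.empty(n_rec)
    ptr = 0
    for t in range(T):
        z = model.J @ r + model.w_stimulus[:, None] * istim[:, t]
        z += model.w_cue[:, None] * icue[:, t]
        if noise_on and p.noise_sd > 0:
            z += rng.normal(0.0, p.noise_sd, size=(n, K))
        x += dt_tau * (z - x)
        r = sigmoid(x, p.beta, p.theta)
        if t % record_every == 0:
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"non-finite network state at step {t} "
                    f"(|x|max={np.nanmax(np.abs(x)):.3g})"
                )
            r_rec[:, ptr] = r.T
            z_rec[:, ptr] = z.T
            t_rec[ptr] = (t + 0.5) * p.dt
            ptr += 1
    return SimResult(r=r_rec[:, :ptr], z=z_rec[:, :ptr], times=t_rec[:ptr])


# ---------------------------------------------------------------------------
# FORCE training
# ---------------------------------------------------------------------------


def _force_episode_numpy(J, P, wstim, wcue, istim, icue, noise, f, dt_tau, beta, theta, alpha_learn, teacher):
    n = J.shape[0]
    T = istim.shape[0]
    x = np.zeros(n)
    r = 1.0 / (1.0 + np.exp(-beta * (x - theta)))
    mse = 0.0
    for t in range(T):
        z = J @ r + wstim * istim[t] + wcue * icue[t] + noise[t]
        e = z - f[t]
        # RLS update paired with the r that produced z
        Pr = P @ r
        denom = 1.0 + r @ Pr
        J -= np.outer((alpha_learn / denom) * e, Pr)
        P -= np.outer(Pr / denom, Pr)
        if teacher:
            x += dt_tau * (f[t] + noise[t] - x)
        else:
            x += dt_tau * (z - x)
        r = 1.0 / (1.0 + np.exp(-beta * (x - theta)))
        mse += float(e @ e) / n
    return mse / T


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _force_episode_numba(J, P, wstim, wcue, istim, icue, noise, f, dt_tau, beta, theta, alpha_learn, teacher):  # pragma: no cover - numba
        n = J.shape[0]
        T = istim.shape[0]
        x = np.zeros(n)
        r = 1.0 / (1.0 + np.exp(-beta * (x - theta)))
        mse = 0.0
        for t in range(T):
            z = J @ r + wstim * istim[t] + wcue * icue[t] + noise[t]
            e = z - f[t]
            Pr = P @ r
            denom = 1.0 + np.dot(r, Pr)
            coef = alpha_learn / denom
            inv = 1.0 / denom
            err = 0.0
            for i in range(n):
                ei = coef * e[i]
                pi = inv * Pr[i]
                for k in range(n):
                    J[i, k] -= ei * Pr[k]
                    P[i, k] -= pi * Pr[k]
                err += e[i] * e[i]
            for i in range(n):
                if teacher:
                    x[i] += dt_tau * (f[t, i] + noise[t, i] - x[i])
                else:
                    x[i] += dt_tau * (z[i] - x[i])
                r[i] = 1.0 / (1.0 + np.exp(-beta * (x[i] - theta)))
            mse += err / n
        return mse / T


def force_train(
    model: RNNModel,
    targets: TargetSet,
    epochs: int | None = None,
    rng: np.random.Generator | int | None = None,
    use_numba: bool | None = None,
    state_update: str = "network",
) -> np.ndarray:
    """FORCE-train the network in place; returns per-epoch MSE.

    Each epoch is one episode alternating trial type (right, left, right,
    ...). Per timestep the recursive-least-squares update is applied to ``J``
    and ``P`` exactly as in the pseudocode; the epoch MSE is the squared
    error between ``z`` and the target current averaged across trial time
    and units.

    ``state_update='network'`` integrates ``x`` from the network drive ``z``
    (the pseudocode's update). ``state_update='teacher'`` integrates ``x``
    from the target current plus noise instead — the stationary limit of the
    error-clamped pseudocode — which keeps the regression target fixed and
    is required for noise-robust attractors at small network sizes.
    """
    p = model.params
    if targets.n_units != model.n:
        raise ValueError("target set and model sizes disagree")
    epochs = p.epochs if epochs is None else int(epochs)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    f_grid = targets.resample(p.n_steps)  # trial type -> (n, T)
    if state_update not in ("network", "teacher"):
        raise ValueError("state_update must be 'network' or 'teacher'")
    teacher = state_update == "teacher"
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    episode = _force_episode_numba if use_numba and _HAVE_NUMBA else _force_episode_numpy
    dt_tau = p.dt / p.tau
    mses = np.empty(epochs)
    for ep in range(epochs):
        ttype = "right" if ep % 2 == 0 else "left"
        inp = make_trial_inputs(ttype, params=p, rng=rng)
        noise = (
            rng.normal(0.0, p.noise_sd, size=(p.n_steps, model.n))
            if p.noise_sd > 0
            else np.zeros((p.n_steps, model.n))
        )
        mses[ep] = episode(
            model.J,
            model.P,
            model.w_stimulus,
            model.w_cue,
            inp.total_stimulus,
            inp.i_cue,
            noise,
            np.ascontiguousarray(f_grid[ttype].T),
            dt_tau,
            p.beta,
            p.theta,
            p.alpha_learn,
            teacher,
        )
        if not np.isfinite(mses[ep]) or not np.all(np.isfinite(model.P[0])):
            raise FloatingPointError(
                f"training diverged at epoch {ep} (MSE={mses[ep]:.3g}); "
                "P lost positive-definiteness"
            )
    return mses


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: RNNModel, path: str | Path) -> Path:
    import dataclasses

    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h:
        h.create_dataset("J", data=model.J)
        h.create_dataset("w_stimulus", data=model.w_stimulus)
        h.create_dataset("w_cue", data=model.w_cue)
        h.create_dataset("P", data=model.P)
        h.create_dataset(
            "region_of", data=np.asarray([str(r) for r in model.region_of], dtype="S8")
        )
        for k, v in dataclasses.asdict(model.params).items():
            h.attrs[k] = v if not isinstance(v, tuple) else list(v)
    return path


def load_model(path: str | Path) -> RNNModel:
    import h5py

    with h5py.File(path, "r") as h:
        attrs = dict(h.attrs)
        for k in ("pre_action_s", "baseline_s"):
            if k in attrs:
                attrs[k] = tuple(float(v) for v in attrs[k])
        for k in ("n", "epochs", "seed"):
            if k in attrs:
                attrs[k] = int(attrs[k])
        params = RNNParams(**attrs)
        return RNNModel(
            J=np.asarray(h["J"]),
            w_stimulus=np.asarray(h["w_stimulus"]),
            w_cue=np.asarray(h["w_cue"]),
            P=np.asarray(h["P"]),
            params=params,
            region_of=np.asarray([r.decode() for r in h["region_of"][()]], dtype=object),
        )
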
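"""Task-performance computation and logistic learning-curve fitting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from corticomm.synthio.session import TrialRecord


def task_performance(trials: list[TrialRecord], condition: str = "all") -> float:
    """Fraction of correct responses among responded trials.

    ``condition`` restricts the computation to one distractor condition
    (``none``/``early``/``middle``/``late``) or ``all``. No-response trials
    are excluded from the denominator.

    Raises
    ------
    ValueError
        If no responded trial exists under the condition.
    """
    if condition != "all":
        trials = [t for t in trials if t.distractor == condition]
    responded = [t for t in trials if t.responded]
    if not responded:
        raise ValueError(
            f"performance undefined: no responded trials for condition {condition!r}"
        )
    n_correct = sum(t.outcome == "correct" for t in responded)
    return n_correct / len(responded)


def _logistic(t, L, k, t0):
    return L / (1.0 + np.exp(-k * (t - t0)))


@dataclass(frozen=True)
class LearningCurveFit:
    """Logistic learning curve y(t) = L / (1 + exp(-k (t - t0)))."""

    L: float
    k: float
    t0: float
    residual_norm: float
    degenerate: bool = False
    message: str = ""

    def predict(self, t) -> np.ndarray:
        return _logistic(np.asarray(t, dtype=float), self.L, self.k, self.t0)


def fit_learning_curve(
    performance_by_session,
    sessions=None,
    *,
    k_max: float = 10.0,
) -> LearningCurveFit:
    """Nonlinear least-squares fit of the logistic learning curve.

    Parameters
    ----------
    performance_by_session:
        Per-session performance fractions (>= 4 sessions).
    sessions:
        Session indices; defaults to ``1..n``.
    k_max:
        Upper bound for the learning rate ``k``.

    The fit is bounded (``L`` in [0, 1], ``k`` in [0, k_max], ``t0`` within
    the observed session range) and multi-started from three deterministic
    initializations; the best residual wins. A constant input is flagged
    degenerate (``k`` unidentifiable) rather than fitted.
    """
    y = np.asarray(performance_by_session, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("need at least 4 sessions to fit a learning curve")
    t = (
        np.arange(1, y.size + 1, dtype=float)
        if sessions is None
        else np.asarray(sessions, dtype=float)
    )
    if np.ptp(y) < 1e-12:
        return LearningCurveFit(
            L=float(y[0]),
            k=0.0,
            t0=float(t[y.size // 2]),
            residual_norm=0.0,
            degenerate=True,
            message="constant performance: k unidentifiable",
        )
    lo, hi = float(t.min()), float(t.max())
    bounds = ([0.0, 0.0, lo], [1.0, k_max, hi])
    inits = [
        (min(max(y.max(), 1e-3), 1.0), 1.0, 0.5 * (lo + hi)),
        (min(max(y.max(), 1e-3), 1.0), 0.2, lo + 0.25 * (hi - lo)),
        (0.8, 3.0, lo + 0.75 * (hi - lo)),
    ]
    best = None
    errors = []
    for p0 in inits:
        try:
            popt, _ = curve_fit(
                _logistic, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:  # non-convergence from one start
            errors.append(str(exc))
            continue
        resid = float(np.linalg.norm(y - _logistic(t, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return LearningCurveFit(
            L=float("nan"),
            k=float("nan"),
            t0=float("nan"),
            residual_norm=float("inf"),
            degenerate=True,
            message="no initialization converged: " + "; ".join(errors),
        )
    (L, k, t0), resid = best
    return LearningCurveFit(L=float(L), k=float(k), t0=float(t0), residual_norm=resid)
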
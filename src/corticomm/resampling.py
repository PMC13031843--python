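"""Resampling machinery: one-tailed bootstrap group comparison and BH-FDR.

The bootstrap resamples each group with replacement at its own size, uses the
difference of means as the statistic, applies the plus-one correction
``p = (1 + #violations) / (n_boot + 1)``, and counts exact ties as half a
violation. The resampling unit is whatever the caller passes (per-session
values, per-mouse values, ...); the procedure itself is agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BootstrapResult:
    observed_diff: float
    p_value: float
    n_boot: int
    tail: str


def bootstrap_diff_test(
    a,
    b,
    n_boot: int = 10_000,
    tail: str = "greater",
    seed: int | None = None,
) -> BootstrapResult:
    """One-tailed bootstrap test on ``mean(b) - mean(a)``.

    ``tail='greater'`` tests the alternative ``mean(b) > mean(a)``;
    ``tail='less'`` the opposite. A resampled difference on the
    non-alternative side of 0 counts as a violation; exact zeros count half.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = b[idx_b].mean(axis=1) - a[idx_a].mean(axis=1)
    ties = np.count_nonzero(diffs == 0.0)
    if tail == "greater":
        violations = np.count_nonzero(diffs < 0.0) + 0.5 * ties
    else:
        violations = np.count_nonzero(diffs > 0.0) + 0.5 * ties
    p = (1.0 + violations) / (n_boot + 1.0)
    return BootstrapResult(
        observed_diff=float(b.mean() - a.mean()),
        p_value=float(min(p, 1.0)),
        n_boot=int(n_boot),
        tail=tail,
    )


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    Rejects all hypotheses with rank <= the largest ``k`` such that
    ``p_(k) <= k q / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, m + 1) / m)
    passing = np.flatnonzero(p[order] <= thresholds)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison threshold under Bonferroni correction."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
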
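"""Functional-interaction metrics between cortical regions.

Three independent metrics over the same sessions:

* ITI functional connectivity — pairwise Pearson correlation of activity
  concatenated over inter-trial windows (-5 to -1 s from trial onset);
* trial-by-trial correlation — the same on trial windows (-1 to 7 s);
* population prediction — cross-validated ridge regression predicting one
  10-neuron population from another, repeated over random samplings.

Correlation cells are averaged over neuron pairs within a region pair and
then across sessions (unweighted); cells with fewer than 10 pairs are left
absent (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from corticomm.subspace import DEFAULT_LAMBDA_GRID, cv_ridge_performance
from corticomm.synthio.session import REGIONS, Session, epoch_frames

MIN_PAIRS = 10


@dataclass
class RegionPairMatrix:
    """8x8 matrix keyed (source, target); NaN marks absent cells."""

    value: np.ndarray
    n: np.ndarray
    metric_name: str

    def cell(self, source: str, target: str) -> float:
        return float(self.value[REGIONS.index(source), REGIONS.index(target)])

    def mean_inter(self) -> float:
        off = ~np.eye(len(REGIONS), dtype=bool)
        return float(np.nanmean(self.value[off]))

    def mean_intra(self) -> float:
        return float(np.nanmean(np.diag(self.value)))


def concatenated_frames(session: Session, epoch: str = "trial_window") -> np.ndarray:
    """Frame indices of ``epoch`` concatenated over all trials, in order."""
    parts = [np.arange(*epoch_frames(session, t, epoch)) for t in session.trials]
    return np.concatenate(parts) if parts else np.zeros(0, dtype=int)


def activity_threshold_gate(
    activity: np.ndarray, frame_rate_hz: float, threshold: float = 10.0,
    span_min: float = 10.0,
) -> np.ndarray:
    """Inclusion gate: activity must exceed ``threshold`` at least once in
    every ``span_min``-minute span. Returns a boolean neuron mask."""
    span = max(int(round(span_min * 60 * frame_rate_hz)), 1)
    n_frames = activity.shape[1]
    keep = np.ones(activity.shape[0], dtype=bool)
    for start in range(0, n_frames, span):
        seg = activity[:, start : start + span]
        if seg.shape[1] == 0:
            continue
        keep &= (seg > threshold).any(axis=1)
    return keep


def subsample_matched(
    sessions_a: list[Session],
    sessions_b: list[Session],
    threshold_rule="pooled_median",
    epoch: str = "iti_window",
    seed: int | None = None,
    tolerance_sd: float = 0.1,
):
    """Activity-matched neuron subsampling across two cohorts.

    Per region, neurons above a preset activity threshold (default: the
    pooled-cohort median of per-neuron mean activity over ``epoch`` frames)
    are nearest-neighbor matched on mean activity across cohorts; the worst
    pairs are pruned until cohort means differ by less than
    ``tolerance_sd`` pooled SDs. Returns
    ``(kept_a, kept_b)`` where each is a list (one per session) of neuron
    index arrays. Regions that cannot be matched are dropped with a warning.
    """
    rng = np.random.default_rng(seed)

    def pool(sessions):
        entries = {r: [] for r in REGIONS}
        for si, s in enumerate(sessions):
            frames = concatenated_frames(s, epoch)
            means = s.activity[:, frames].mean(axis=1)
            for r in REGIONS:
                for n in s.neurons_in(r):
                    entries[r].append((si, int(n), float(means[n])))
        return entries

    pa, pb = pool(sessions_a), pool(sessions_b)
    kept_a = [set() for _ in sessions_a]
    kept_b = [set() for _ in sessions_b]
    for region in REGIONS:
        ea, eb = pa[region], pb[region]
        acts = np.array([e[2] for e in ea + eb])
        if acts.size == 0:
            continue
        if threshold_rule == "pooled_median":
            thr = float(np.median(acts))
        elif callable(threshold_rule):
            thr = float(threshold_rule(acts))
        else:
            thr = float(threshold_rule)
        ca = sorted((e for e in ea if e[2] > thr), key=lambda e: e[2])
        cb = sorted((e for e in eb if e[2] > thr), key=lambda e: e[2])
        if not ca or not cb:
            warnings.warn(f"region {region}: no neurons pass threshold; dropped")
            continue
        # greedy nearest-neighbor matching on sorted activity
        pairs = []
        j = 0
        for e in ca:
            while j + 1 < len(cb) and abs(cb[j + 1][2] - e[2]) <= abs(
                cb[j][2] - e[2]
            ):
                j += 1
            if j < len(cb):
                pairs.append((e, cb[j], abs(cb[j][2] - e[2])))
                j += 1
            if j >= len(cb):
                break
        pooled_sd = float(np.std(acts, ddof=1)) if acts.size > 1 else 1.0
        pairs.sort(key=lambda p: p[2])
        while pairs:
            ma = np.mean([p[0][2] for p in pairs])
            mb = np.mean([p[1][2] for p in pairs])
            if abs(ma - mb) < tolerance_sd * max(pooled_sd, 1e-12):
                break
            pairs.pop()  # drop the worst-matched pair
        if not pairs:
            warnings.warn(f"region {region}: activity matching failed; dropped")
            continue
        rng.shuffle(pairs)
        for (sa, na, _), (sb, nb, _), _gap in pairs:
            kept_a[sa].add(na)
            kept_b[sb].add(nb)
    return (
        [np.array(sorted(s), dtype=int) for s in kept_a],
        [np.array(sorted(s), dtype=int) for s in kept_b],
    )


def _pairwise_matrix(
    sessions: list[Session],
    epoch: str,
    metric_name: str,
    kept: list[np.ndarray] | None = None,
    min_pairs: int = MIN_PAIRS,
    min_neurons: int = 10,
) -> RegionPairMatrix:
    n_reg = len(REGIONS)
    sums = np.zeros((n_reg, n_reg))
    counts = np.zeros((n_reg, n_reg), dtype=int)
    session_values = np.full((len(sessions), n_reg, n_reg), np.nan)
    for si, s in enumerate(sessions):
        frames = concatenated_frames(s, epoch)
        neurons = (
            kept[si]
            if kept is not None
            else np.arange(s.n_neurons, dtype=int)
        )
        sub = s.activity[np.ix_(neurons, frames)]
        variances = sub.var(axis=1)
        ok = variances > 0
        region_idx = np.array([REGIONS.index(r) for r in s.region_of[neurons]])
        eligible_regions = {
            g for g in range(n_reg) if np.count_nonzero(region_idx == g) >= min_neurons
        }
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        for gi in range(n_reg):
            if gi not in eligible_regions:
                continue
            idx_i = np.flatnonzero((region_idx == gi) & ok)
            for gj in range(gi, n_reg):
                if gj not in eligible_regions:
                    continue
                idx_j = np.flatnonzero((region_idx == gj) & ok)
                if gi == gj:
                    if idx_i.size < 2:
                        continue
                    iu = np.triu_indices(idx_i.size, k=1)
                    vals = corr[np.ix_(idx_i, idx_i)][iu]
                else:
                    vals = corr[np.ix_(idx_i, idx_j)].ravel()
                if vals.size < min_pairs:
                    continue
                session_values[si, gi, gj] = session_values[si, gj, gi] = vals.mean()
                counts[gi, gj] += vals.size
                counts[gj, gi] = counts[gi, gj]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        value = np.nanmean(session_values, axis=0)
    return RegionPairMatrix(value=value, n=counts, metric_name=metric_name)


def iti_functional_connectivity(
    sessions: list[Session], kept: list[np.ndarray] | None = None
) -> RegionPairMatrix:
    """Pairwise Pearson correlation of concatenated ITI activity."""
    return _pairwise_matrix(sessions, "iti_window", "iti_correlation", kept)


def trial_by_trial_correlation(
    sessions: list[Session], kept: list[np.ndarray] | None = None
) -> RegionPairMatrix:
    """Pairwise Pearson correlation of concatenated trial-window activity."""
    return _pairwise_matrix(sessions, "trial_window", "trial_correlation", kept)


def population_prediction(
    source: np.ndarray,
    target: np.ndarray | None = None,
    repeats: int = 20,
    n_sample: int = 10,
    seed: int | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
) -> float:
    """Ridge prediction performance between neuron populations.

    ``source``/``target`` are (neurons, frames) matrices. With
    ``target=None`` the intra-regional variant is used: source and target
    samples are disjoint 10-neuron subsets of the same population (which must
    hold at least ``2 * n_sample`` neurons). Performance is ``1 - cvl``
    averaged over ``repeats`` random samplings.
    """
    source = np.asarray(source, dtype=float)
    rng = np.random.default_rng(seed)
    intra = target is None
    if intra:
        if source.shape[0] < 2 * n_sample:
            raise ValueError(
                f"intra-regional prediction needs >= {2 * n_sample} neurons"
            )
    else:
        target = np.asarray(target, dtype=float)
        if source.shape[0] < n_sample or target.shape[0] < n_sample:
            raise ValueError(f"both populations need >= {n_sample} neurons")
    perfs = []
    for _ in range(repeats):
        if intra:
            pick = rng.choice(source.shape[0], size=2 * n_sample, replace=False)
            X = source[pick[:n_sample]].T
            Y = source[pick[n_sample:]].T
        else:
            X = source[rng.choice(source.shape[0], n_sample, replace=False)].T
            Y = target[rng.choice(target.shape[0], n_sample, replace=False)].T
        perf, _ = cv_ridge_performance(X, Y, lambda_grid=lambda_grid, folds=folds)
        perfs.append(perf)
    return float(np.mean(perfs))


def prediction_matrix(
    sessions: list[Session],
    repeats: int = 20,
    seed: int | None = None,
    epoch: str = "trial_window",
    kept: list[np.ndarray] | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
) -> RegionPairMatrix:
    """8x8 matrix of population-prediction performance, averaged over sessions."""
    n_reg = len(REGIONS)
    rng = np.random.default_rng(seed)
    session_values = np.full((len(sessions), n_reg, n_reg), np.nan)
    for si, s in enumerate(sessions):
        frames = concatenated_frames(s, epoch)
        neurons = kept[si] if kept is not None else np.arange(s.n_neurons)
        by_region = {}
        for g, r in enumerate(REGIONS):
            idx = np.array([n for n in neurons if s.region_of[n] == r], dtype=int)
            by_region[g] = s.activity[np.ix_(idx, frames)] if idx.size else None
        for gi in range(n_reg):
            src = by_region[gi]
            if src is None:
                continue
            for gj in range(n_reg):
                tgt = by_region[gj]
                if tgt is None:
                    continue
                try:
                    if gi == gj:
                        val = population_prediction(
                            src, None, repeats=repeats,
                            seed=int(rng.integers(2**31)),
                            lambda_grid=lambda_grid, folds=folds,
                        )
                    else:
                        val = population_prediction(
                            src, tgt, repeats=repeats,
                            seed=int(rng.integers(2**31)),
                            lambda_grid=lambda_grid, folds=folds,
                        )
                except ValueError:
                    continue
                session_values[si, gi, gj] = val
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        value = np.nanmean(session_values, axis=0)
    counts = np.sum(~np.isnan(session_values), axis=0)
    return RegionPairMatrix(value=value, n=counts, metric_name="population_prediction")


def metric_consistency(
    m1: RegionPairMatrix, m2: RegionPairMatrix
) -> tuple[float, float]:
    """Squared Pearson correlation (and p value) across matched matrix cells."""
    v1, v2 = m1.value.ravel(), m2.value.ravel()
    mask = ~(np.isnan(v1) | np.isnan(v2))
    if mask.sum() < 3:
        raise ValueError("need at least 3 matched cells")
    r, p = pearsonr(v1[mask], v2[mask])
    return float(r**2), float(p)
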
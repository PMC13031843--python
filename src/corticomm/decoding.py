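"""Pseudo-mouse decoding pipeline.

Pseudo-mice stack fixed numbers of cells per region across sessions, aligned
on canonical trial slots (per session: ``trials_per_side`` left/right
non-distractor trials plus ``distractor_trials_per_side`` per side and
distractor condition), restricted to delay-period frames. A pluggable 3-d
embedding backend is tuned on a balanced 80/20 trial split with 5-fold
cross-validation, and a cosine-distance kNN (k=5) decodes the side label.
An optional contrastive-embedding backend wrapper is provided; the default
backend is a deterministic supervised linear projection so the pipeline
runs offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from corticomm.synthio.session import (
    DISTRACTOR_ONSETS_S,
    REGIONS,
    Session,
    epoch_frames,
)

DISTRACTOR_TYPES = ("early", "middle", "late")

#: Row counts per region by mode (stimulus: 1600 total; choice: 1160 total).
DEFAULT_CELLS_PER_REGION = {"stimulus": 200, "choice": 145, "unsupervised": 200}


# ---------------------------------------------------------------------------
# pseudo-mouse construction
# ---------------------------------------------------------------------------


@dataclass
class PseudoMouse:
    activity: np.ndarray  # (n_cells, n_frames)
    time: np.ndarray  # (n_frames,) seconds within the delay
    side: np.ndarray  # (n_frames,) 1 = left, 0 = right (stimulus or choice)
    condition: np.ndarray  # (n_frames,) none|early|middle|late
    trial_slot: np.ndarray  # (n_frames,) canonical trial index
    region_of_row: np.ndarray  # (n_cells,)
    mode: str
    partitions: dict = field(default_factory=dict)  # filled by split_and_tune

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    def frames_of(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.condition == condition)

    def slots_of(self, condition: str) -> np.ndarray:
        return np.unique(self.trial_slot[self.condition == condition])


def _session_trial_sets(
    session: Session,
    mode: str,
    trials_per_side: int,
    distractor_trials_per_side: int,
    rng: np.random.Generator,
):
    """Sample the canonical trial slots for one session, or None if short."""
    label_of = (
        (lambda t: t.stimulus_side)
        if mode in ("stimulus", "unsupervised")
        else (lambda t: t.choice_side)
    )
    chosen: list = []
    for cond in ("none",) + DISTRACTOR_TYPES:
        want = trials_per_side if cond == "none" else distractor_trials_per_side
        for side in ("left", "right"):
            pool = [
                t
                for t in session.trials
                if t.responded and t.distractor == cond and label_of(t) == side
            ]
            if len(pool) < want:
                return None
            idx = rng.choice(len(pool), size=want, replace=False)
            chosen.extend((pool[i], cond, side) for i in idx)
    return chosen


def region_pools_from_sessions(
    sessions: list[Session],
    mode: str = "stimulus",
    trials_per_side: int = 40,
    distractor_trials_per_side: int = 4,
    seed: int | None = None,
):
    """Aggregate delay-period activity per region across sessions.

    Returns ``(pools, slot_meta)``: ``pools[region]`` is a (cells, frames)
    matrix aligned on canonical trial slots, and ``slot_meta`` carries the
    per-frame time / side / condition / slot labels. Sessions lacking the
    required trial counts are excluded.
    """
    rng = np.random.default_rng(seed)
    pools: dict[str, list[np.ndarray]] = {r: [] for r in REGIONS}
    slot_meta = None
    for session in sessions:
        sets = _session_trial_sets(
            session, mode, trials_per_side, distractor_trials_per_side, rng
        )
        if sets is None:
            continue
        segs, times, sides, conds = [], [], [], []
        for slot, (trial, cond, side) in enumerate(sets):
            a, b = epoch_frames(session, trial, "delay")
            seg = session.activity[:, a:b]
            segs.append(seg)
            n = seg.shape[1]
            times.append(np.arange(n) / session.frame_rate_hz)
            sides.append(np.full(n, 1.0 if side == "left" else 0.0))
            conds.append(np.full(n, cond, dtype=object))
        mat = np.concatenate(segs, axis=1)
        if slot_meta is None:
            slot_meta = {
                "time": np.concatenate(times),
                "side": np.concatenate(sides),
                "condition": np.concatenate(conds),
                "trial_slot": np.concatenate(
                    [
                        np.full(segs[i].shape[1], i, dtype=int)
                        for i in range(len(segs))
                    ]
                ),
            }
        elif mat.shape[1] != slot_meta["time"].size:
            raise ValueError("sessions produced inconsistent frame counts")
        for r in REGIONS:
            idx = session.neurons_in(r)
            if idx.size:
                pools[r].append(mat[idx])
    if slot_meta is None:
        raise ValueError("no session met the required trial counts")
    return {r: np.concatenate(v, axis=0) if v else np.zeros((0, 0)) for r, v in pools.items()}, slot_meta


def build_pseudo_mouse(
    region_pools: dict,
    slot_meta: dict,
    mode: str = "stimulus",
    seed: int | None = None,
    cells_per_region: int | None = None,
) -> PseudoMouse:
    """Sample fixed per-region cell counts and stack them into a pseudo-mouse.

    Raises a ``ValueError`` naming the deficient region if a pool holds fewer
    cells than required (200 in stimulus/unsupervised mode, 145 in choice
    mode; 1600 and 1160 rows total).
    """
    if mode not in DEFAULT_CELLS_PER_REGION:
        raise ValueError(f"unknown mode {mode!r}")
    want = cells_per_region or DEFAULT_CELLS_PER_REGION[mode]
    rng = np.random.default_rng(seed)
    blocks, rows = [], []
    for r in REGIONS:
        pool = region_pools[r]
        if pool.shape[0] < want:
            raise ValueError(
                f"region {r}: pool holds {pool.shape[0]} cells, needs {want}"
            )
        pick = rng.choice(pool.shape[0], size=want, replace=False)
        blocks.append(pool[pick])
        rows.extend([r] * want)
    return PseudoMouse(
        activity=np.concatenate(blocks, axis=0),
        time=np.asarray(slot_meta["time"], dtype=float),
        side=np.asarray(slot_meta["side"], dtype=float),
        condition=np.asarray(slot_meta["condition"], dtype=object),
        trial_slot=np.asarray(slot_meta["trial_slot"], dtype=int),
        region_of_row=np.array(rows, dtype=object),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# embedding backends
# ---------------------------------------------------------------------------


class LinearProjectionBackend:
    """Deterministic supervised linear 3-d projection.

    Dimension 1 is a shrinkage-regularized discriminant axis for the side
    label; dimensions 2-3 are the top principal components of the residual.
    In unsupervised mode (``labels=None``) all three dimensions are
    principal components.
    """

    def __init__(self, shrinkage: float = 0.1):
        self.shrinkage = float(shrinkage)
        self._mean = None
        self._scale = None
        self._components = None

    def fit(self, activity: np.ndarray, labels: np.ndarray | None = None):
        X = np.asarray(activity, dtype=float)
        self._mean = X.mean(axis=0)
        self._scale = X.std(axis=0)
        self._scale[self._scale == 0] = 1.0
        Z = (X - self._mean) / self._scale
        comps = []
        if labels is not None:
            y = np.asarray(labels).astype(float)
            classes = np.unique(y)
            if classes.size != 2:
                raise ValueError("supervised fit needs exactly two classes")
            Z0, Z1 = Z[y == classes[0]], Z[y == classes[1]]
            Sw = 0.5 * (np.cov(Z0, rowvar=False) + np.cov(Z1, rowvar=False))
            Sw = Sw + self.shrinkage * np.eye(Z.shape[1])
            w = np.linalg.solve(Sw, Z1.mean(axis=0) - Z0.mean(axis=0))
            w /= np.linalg.norm(w)
            comps.append(w)
            Z = Z - np.outer(Z @ w, w)
        n_pc = 3 - len(comps)
        _, _, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
        comps.extend(Vt[:n_pc])
        self._components = np.stack(comps)
        return self

    def transform(self, activity: np.ndarray) -> np.ndarray:
        if self._components is None:
            raise RuntimeError("backend is not fitted")
        Z = (np.asarray(activity, dtype=float) - self._mean) / self._scale
        return Z @ self._components.T


class CebraBackend:  # pragma: no cover - optional heavy dependency
    """Optional contrastive-embedding backend (requires the ``cebra`` package).

    Configured with the published parameters: offset1 model architecture,
    cosine distance, temperature 1, 2000 iterations, output dimension 3.
    """

    def __init__(self, weight_decay: float = 1e-5, learning_rate: float = 0.01,
                 num_hidden_units: int = 512, max_iterations: int = 2000):
        import cebra  # noqa: F401  (lazy; raises if unavailable)

        self._kw = dict(
            model_architecture="offset1-model",
            batch_size=None,
            learning_rate=learning_rate,
            temperature=1,
            output_dimension=3,
            max_iterations=max_iterations,
            distance="cosine",
            conditional="time_delta",
            time_offsets=1,
            num_hidden_units=num_hidden_units,
        )
        self._weight_decay = weight_decay
        self._model = None

    def fit(self, activity, labels=None):
        import cebra

        self._model = cebra.CEBRA(**self._kw)
        if labels is None:
            self._model.fit(activity)
        else:
            self._model.fit(activity, labels)
        return self

    def transform(self, activity):
        return self._model.transform(activity)


# ---------------------------------------------------------------------------
# split / tune / decode
# ---------------------------------------------------------------------------


def _balanced_slots(pm: PseudoMouse, rng: np.random.Generator) -> np.ndarray:
    slots = pm.slots_of("none")
    sides = np.array([pm.side[pm.trial_slot == s][0] for s in slots])
    left, right = slots[sides == 1.0], slots[sides == 0.0]
    n = min(left.size, right.size)
    keep = np.concatenate(
        [
            rng.choice(left, size=n, replace=False),
            rng.choice(right, size=n, replace=False),
        ]
    )
    return np.sort(keep)


def split_and_tune(
    pm: PseudoMouse,
    backend_factory=LinearProjectionBackend,
    grid=({"shrinkage": 0.01}, {"shrinkage": 0.1}, {"shrinkage": 1.0}),
    seed: int | None = None,
    test_fraction: float = 0.2,
    n_folds: int = 5,
    k: int = 5,
):
    """Balanced 80/20 split of non-distractor trials plus hyperparameter tuning.

    Five-fold cross-validation on the training trials selects the grid point
    with the lowest mean validation loss (1 - kNN accuracy for the default
    backend); ties resolve to the first grid point in declared order. The
    backend is refit on the full training set.
    """
    rng = np.random.default_rng(seed)
    slots = _balanced_slots(pm, rng)
    sides = np.array([pm.side[pm.trial_slot == s][0] for s in slots])
    if min(np.sum(sides == 1.0), np.sum(sides == 0.0)) < n_folds:
        raise ValueError(f"need at least {n_folds} trials per class")
    test_slots = []
    for side in (1.0, 0.0):
        s = slots[sides == side]
        n_test = max(int(round(test_fraction * s.size)), 1)
        test_slots.extend(rng.choice(s, size=n_test, replace=False))
    test_slots = np.sort(np.asarray(test_slots))
    train_slots = np.setdiff1d(slots, test_slots)

    supervised = pm.mode != "unsupervised"

    def frames_for(slot_set):
        return np.flatnonzero(np.isin(pm.trial_slot, slot_set))

    losses = []
    folds = np.array_split(rng.permutation(train_slots), n_folds)
    for point in grid:
        fold_losses = []
        for i in range(n_folds):
            val = folds[i]
            fit_slots = np.setdiff1d(train_slots, val)
            fi, vi = frames_for(fit_slots), frames_for(val)
            backend = backend_factory(**point)
            backend.fit(
                pm.activity[:, fi].T, pm.side[fi] if supervised else None
            )
            emb_fit = backend.transform(pm.activity[:, fi].T)
            emb_val = backend.transform(pm.activity[:, vi].T)
            acc, _ = knn_decode(emb_fit, pm.side[fi], emb_val, pm.side[vi], k=k)
            fold_losses.append(1.0 - acc)
        losses.append(float(np.mean(fold_losses)))
    best = grid[int(np.argmin(losses))]  # argmin takes the first minimum
    backend = backend_factory(**best)
    ti = frames_for(train_slots)
    backend.fit(pm.activity[:, ti].T, pm.side[ti] if supervised else None)
    pm.partitions = {"train": train_slots, "test": test_slots}
    return backend, {
        "train": train_slots,
        "test": test_slots,
        "grid_losses": dict(zip(range(len(grid)), losses)),
        "selected": best,
    }


def knn_decode(
    train_embedding: np.ndarray,
    train_labels: np.ndarray,
    query_embedding: np.ndarray,
    query_labels: np.ndarray | None = None,
    k: int = 5,
):
    """Cosine-distance kNN decoding.

    Returns ``(accuracy, correct_mask)`` when query labels are given, else
    ``(None, predictions)``.
    """
    train_embedding = np.asarray(train_embedding, dtype=float)
    query_embedding = np.asarray(query_embedding, dtype=float)
    if k % 2 == 0:
        raise ValueError("k must be odd")
    for name, emb in (("train", train_embedding), ("query", query_embedding)):
        if np.any(np.linalg.norm(emb, axis=1) == 0):
            raise ValueError(f"{name} embedding contains a zero-norm row")
    clf = KNeighborsClassifier(n_neighbors=k, metric="cosine")
    clf.fit(train_embedding, np.asarray(train_labels).astype(int))
    pred = clf.predict(query_embedding)
    if query_labels is None:
        return None, pred
    correct = pred == np.asarray(query_labels).astype(int)
    return float(correct.mean()), correct


def accuracy_by_time(
    correct: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame-time accuracy time series over the delay."""
    times = np.asarray(times)
    axis = np.unique(times)
    series = np.array([correct[times == t].mean() for t in axis])
    return axis, series


def relative_accuracy(
    distractor_series: np.ndarray,
    test_series: np.ndarray,
    time_axis: np.ndarray,
    distractor_type: str,
    window_s: float = 1.0,
    anchor: str = "offset",
):
    """Distractor-minus-test accuracy and its post-distractor window mean.

    Times are seconds from delay onset; the window starts at the distractor
    offset (onset + 0.2 s) by default and is clipped to the delay.
    """
    distractor_series = np.asarray(distractor_series, dtype=float)
    test_series = np.asarray(test_series, dtype=float)
    diff = distractor_series - test_series
    t0 = DISTRACTOR_ONSETS_S[distractor_type] + (0.2 if anchor == "offset" else 0.0)
    mask = (time_axis >= t0 - 1e-9) & (time_axis < t0 + window_s)
    if not mask.any():
        raise ValueError("post-distractor window contains no frames")
    return diff, float(diff[mask].mean())


def region_contribution(
    backend,
    pm: PseudoMouse,
    region: str,
    train_frames: np.ndarray,
    query_frames: np.ndarray,
    k: int = 5,
):
    """Decoding accuracy with only ``region`` intact.

    The activity of every other region's cells is replaced by its own mean
    (per cell, over the query frames); the fitted backend and a kNN trained
    on the unablated training embedding are then applied.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    ablated = pm.activity[:, query_frames].copy()
    other = pm.region_of_row != region
    ablated[other] = ablated[other].mean(axis=1, keepdims=True)
    emb_train = backend.transform(pm.activity[:, train_frames].T)
    emb_query = backend.transform(ablated.T)
    acc, _ = knn_decode(
        emb_train, pm.side[train_frames], emb_query, pm.side[query_frames], k=k
    )
    return acc


def decode_pseudo_mouse(
    pm: PseudoMouse,
    backend_factory=LinearProjectionBackend,
    grid=({"shrinkage": 0.01}, {"shrinkage": 0.1}, {"shrinkage": 1.0}),
    seed: int | None = None,
    k: int = 5,
    window_anchor: str = "offset",
) -> dict:
    """Full per-pseudo-mouse pipeline: tune, embed, decode, relative accuracy."""
    backend, info = split_and_tune(
        pm, backend_factory=backend_factory, grid=grid, seed=seed, k=k
    )
    train_frames = np.flatnonzero(np.isin(pm.trial_slot, info["train"]))
    test_frames = np.flatnonzero(np.isin(pm.trial_slot, info["test"]))
    emb_train = backend.transform(pm.activity[:, train_frames].T)
    emb_test = backend.transform(pm.activity[:, test_frames].T)
    test_acc, test_correct = knn_decode(
        emb_train, pm.side[train_frames], emb_test, pm.side[test_frames], k=k
    )
    t_axis, test_series = accuracy_by_time(test_correct, pm.time[test_frames])
    out = {
        "backend": backend,
        "info": info,
        "test_accuracy": test_acc,
        "time_axis": t_axis,
        "test_series": test_series,
        "relative": {},
        "window_mean": {},
    }
    for dtype in DISTRACTOR_TYPES:
        frames = pm.frames_of(dtype)
        if frames.size == 0:
            continue
        emb_d = backend.transform(pm.activity[:, frames].T)
        acc_d, correct_d = knn_decode(
            emb_train, pm.side[train_frames], emb_d, pm.side[frames], k=k
        )
        _, d_series = accuracy_by_time(correct_d, pm.time[frames])
        diff, wmean = relative_accuracy(
            d_series, test_series, t_axis, dtype, anchor=window_anchor
        )
        out["relative"][dtype] = diff
        out["window_mean"][dtype] = wmean
    return out
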
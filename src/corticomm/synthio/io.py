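"""Session and configuration file I/O.

A session is stored as an HDF5 container with datasets ``/activity``,
``/region_of``, ``/frame_rate`` and a root attribute ``cohort_tag``; the trial
table lives under ``/trials/<column>`` and is additionally mirrored as a
sibling CSV file (``<stem>.trials.csv``) for inspection with standard tools.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from corticomm.synthio.session import (
    COHORT_TAGS,
    DISTRACTORS,
    OUTCOMES,
    REGIONS,
    Session,
    TrialRecord,
)

_TRIAL_COLUMNS = ("onset_frame", "stimulus_side", "choice_side", "outcome", "distractor")


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_frame": [t.onset_frame for t in trials],
            "stimulus_side": [t.stimulus_side for t in trials],
            "choice_side": [t.choice_side for t in trials],
            "outcome": [t.outcome for t in trials],
            "distractor": [t.distractor for t in trials],
        }
    )


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Build validated trial records from a table, naming the offending field."""
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for col, vocab in (
        ("distractor", DISTRACTORS),
        ("outcome", OUTCOMES),
        ("stimulus_side", ("left", "right")),
        ("choice_side", ("left", "right", "none")),
    ):
        bad = set(df[col].astype(str)) - set(vocab)
        if bad:
            raise ValueError(f"unknown {col} value(s): {sorted(bad)}")
    return [
        TrialRecord(
            onset_frame=int(row.onset_frame),
            stimulus_side=str(row.stimulus_side),
            choice_side=str(row.choice_side),
            outcome=str(row.outcome),
            distractor=str(row.distractor),
        )
        for row in df.itertuples(index=False)
    ]


def read_trial_csv(path: str | Path) -> list[TrialRecord]:
    return trials_from_frame(pd.read_csv(path, dtype=str).astype({"onset_frame": int}))


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session container; returns the HDF5 path.

    ``write_session`` followed by :func:`read_session` is the identity on all
    fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=session.activity)
        f.create_dataset(
            "region_of",
            data=np.asarray([str(r) for r in session.region_of], dtype="S8"),
        )
        f.create_dataset("frame_rate", data=float(session.frame_rate_hz))
        f.attrs["cohort_tag"] = session.cohort_tag
        g = f.create_group("trials")
        df = trials_to_frame(session.trials)
        g.create_dataset("onset_frame", data=df["onset_frame"].to_numpy(dtype=np.int64))
        for col in _TRIAL_COLUMNS[1:]:
            g.create_dataset(col, data=df[col].to_numpy(dtype="S12"))
    df.to_csv(path.with_suffix(".trials.csv"), index=False)
    return path


def read_session(path: str | Path) -> Session:
    """Read a session container written by :func:`write_session`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("activity", "region_of", "frame_rate", "trials"):
            if name not in f:
                raise KeyError(f"session container missing dataset {name!r}")
        activity = np.asarray(f["activity"], dtype=np.float64)
        region_of = np.asarray([r.decode() for r in f["region_of"][()]], dtype=object)
        frame_rate = float(f["frame_rate"][()])
        cohort_tag = str(f.attrs.get("cohort_tag", "other"))
        g = f["trials"]
        df = pd.DataFrame(
            {
                "onset_frame": np.asarray(g["onset_frame"], dtype=np.int64),
                **{
                    col: [v.decode() for v in g[col][()]]
                    for col in _TRIAL_COLUMNS[1:]
                },
            }
        )
    bad = set(region_of) - set(REGIONS)
    if bad:
        raise ValueError(f"region label(s) outside vocabulary: {sorted(map(str, bad))}")
    if not np.all(np.isfinite(activity)):
        raise ValueError("activity contains non-finite values")
    if cohort_tag not in COHORT_TAGS:
        raise ValueError(f"unknown cohort_tag {cohort_tag!r}")
    return Session(
        activity=activity,
        region_of=region_of,
        frame_rate_hz=frame_rate,
        trials=trials_from_frame(df),
        cohort_tag=cohort_tag,
    )


def load_deposited_dataset(path: str | Path):
    """Stub loader for externally deposited processed sessions (not bundled).

    Expected layout: one HDF5 container per session in the format written by
    :func:`write_session` — ``/activity`` (neurons x frames, z-scored
    deconvolved event amplitudes at ~9.35 Hz), ``/region_of`` (one of the
    eight region labels per neuron), ``/frame_rate``, a ``/trials`` group
    (onset_frame, stimulus_side, choice_side, outcome, distractor), and a
    ``cohort_tag`` attribute. Downloading and converting the deposit is out
    of scope; point this loader at a directory of such files once prepared.
    """
    path = Path(path)
    files = sorted(path.glob("*.h5")) if path.is_dir() else []
    if not files:
        raise NotImplementedError(
            "no prepared session containers found; see docstring for the "
            "expected layout"
        )
    return [read_session(f) for f in files]


def write_config(config, path: str | Path) -> Path:
    """Serialize a generator config dataclass to YAML."""
    import dataclasses

    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=False)
    return path


def read_config(path: str | Path):
    from corticomm.synthio.generate import GeneratorConfig

    with open(path) as f:
        d = yaml.safe_load(f)
    return GeneratorConfig(**d)
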
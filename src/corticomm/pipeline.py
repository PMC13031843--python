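"""Configuration-driven orchestration of the full analysis suite.

``run_experiment`` generates matched-seed control and reduced-connectivity
cohorts, runs the enabled stages, writes per-module CSV tables plus a JSON
summary of cohort contrasts (direction and one-tailed bootstrap p per
metric), and logs per-stage timing. A stage failure is isolated: it is
recorded in the summary and the remaining stages still run.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from corticomm import behavior, connectivity, decoding, selectivity, subspace
from corticomm.resampling import bootstrap_diff_test
from corticomm.rnn import (
    RNNParams,
    ablate_and_test,
    build_target_functions,
    force_train,
    init_network,
    switching_proportion,
)
from corticomm.synthio import (
    GeneratorConfig,
    Session,
    control_config,
    generate_cohort,
    reduced_connectivity_config,
)
from corticomm.synthio.session import REGIONS, epoch_frames

ALL_STAGES = ("behavior", "selectivity", "connectivity", "subspace", "decoding", "rnn")

log = logging.getLogger("corticomm.pipeline")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    n_sessions: int = 2
    neurons_per_region: int = 40
    n_trials: int = 120  # >= ~120 gives the decoding stage enough trials
    stages: tuple = ALL_STAGES
    n_boot: int = 2000
    # subspace stage
    # ring-coupled triple: S1fl sends to both M1p and M2 under the default graph
    degeneracy_source: str = "S1fl"
    degeneracy_targets: tuple = ("M1p", "M2")
    degeneracy_dims: int = 2
    degeneracy_repeats: int = 5
    # decoding stage
    pseudo_mice: int = 3
    trials_per_side: int = 12
    distractor_trials_per_side: int = 2
    # rnn stage
    rnn_units: int = 64
    rnn_epochs: int = 120
    rnn_test_trials: int = 50
    rnn_ablation_level: float = 0.1
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _cohort_configs(cfg: RunConfig) -> dict[str, GeneratorConfig]:
    common = dict(
        neurons_per_region=cfg.neurons_per_region,
        n_trials=cfg.n_trials,
        seed=cfg.seed,
        **cfg.generator_overrides,
    )
    return {
        "control": control_config(**common),
        "reduced_connectivity": reduced_connectivity_config(**common),
    }


def generate_cohorts(cfg: RunConfig) -> dict[str, list[Session]]:
    return {
        name: generate_cohort(gc, cfg.n_sessions)
        for name, gc in _cohort_configs(cfg).items()
    }


def _frames_for_window(session: Session, window_s, trials) -> np.ndarray:
    fr = session.frame_rate_hz
    parts = []
    for t in trials:
        a = int(math.floor(window_s[0] * fr)) + t.onset_frame
        b = int(math.floor(window_s[1] * fr)) + t.onset_frame
        parts.append(np.arange(a, b))
    return np.concatenate(parts)


def _region_sample(session: Session, region: str, n: int, rng) -> np.ndarray:
    idx = session.neurons_in(region)
    if idx.size < n:
        raise ValueError(f"region {region} has {idx.size} < {n} neurons")
    return rng.choice(idx, size=n, replace=False)


# ---------------------------------------------------------------------------
# stages (each returns per-cohort scalar samples used for contrasts)
# ---------------------------------------------------------------------------


def stage_behavior(cohorts, cfg: RunConfig, out: Path) -> dict:
    rows, samples = [], {}
    for name, sessions in cohorts.items():
        perf_d = []
        for si, s in enumerate(sessions):
            for cond in ("all", "none", "early", "middle", "late"):
                try:
                    p = behavior.task_performance(s.trials, cond)
                except ValueError:
                    p = float("nan")
                rows.append(
                    {"cohort": name, "session": si, "condition": cond, "performance": p}
                )
            d = [r["performance"] for r in rows[-3:]]  # early/middle/late
            perf_d.append(float(np.nanmean(d)))
        samples[name] = perf_d
    pd.DataFrame(rows).to_csv(out / "behavior_performance.csv", index=False)
    return {"distractor_performance": samples}


def stage_selectivity(cohorts, cfg: RunConfig, out: Path) -> dict:
    frac_rows, mod_rows, samples = [], [], {}
    for name, sessions in cohorts.items():
        mods = []
        for si, s in enumerate(sessions):
            labels = selectivity.classify_epoch_selectivity(s)
            for region in REGIONS:
                for epoch in ("stimulus", "delay", "action"):
                    f = selectivity.selectivity_fraction(labels, s, region, epoch)
                    frac_rows.append(
                        {
                            "cohort": name,
                            "session": si,
                            "region": region,
                            "epoch": epoch,
                            "fraction": f if f is not None else float("nan"),
                        }
                    )
            per_session = []
            for dtype in ("early", "middle", "late"):
                try:
                    mod = selectivity.distractor_modulation(s, labels, dtype)
                except ValueError:
                    continue
                for region, v in mod.items():
                    mod_rows.append(
                        {
                            "cohort": name,
                            "session": si,
                            "distractor": dtype,
                            "region": region,
                            "modulation": v,
                        }
                    )
                    per_session.append(v)
            if per_session:
                mods.append(float(np.mean(per_session)))
        samples[name] = mods
    pd.DataFrame(frac_rows).to_csv(out / "selectivity_fractions.csv", index=False)
    pd.DataFrame(mod_rows).to_csv(out / "distractor_modulation.csv", index=False)
    return {"distractor_modulation": samples}


def _matrix_rows(m: connectivity.RegionPairMatrix, cohort: str):
    rows = []
    for i, src in enumerate(REGIONS):
        for j, tgt in enumerate(REGIONS):
            rows.append(
                {
                    "cohort": cohort,
                    "metric": m.metric_name,
                    "source": src,
                    "target": tgt,
                    "value": m.value[i, j],
                    "n": int(m.n[i, j]),
                }
            )
    return rows


def stage_connectivity(cohorts, cfg: RunConfig, out: Path) -> dict:
    rows, samples = [], {}
    matrices = {}
    kept = dict.fromkeys(cohorts)
    if set(cohorts) == {"control", "reduced_connectivity"}:
        # activity-matched neuron subsampling across the two cohorts
        kept["control"], kept["reduced_connectivity"] = (
            connectivity.subsample_matched(
                cohorts["control"], cohorts["reduced_connectivity"],
                seed=cfg.seed,
            )
        )
    for name, sessions in cohorts.items():
        iti = connectivity.iti_functional_connectivity(sessions, kept=kept[name])
        tbt = connectivity.trial_by_trial_correlation(sessions, kept=kept[name])
        pred = connectivity.prediction_matrix(
            sessions, repeats=3, seed=cfg.seed, folds=5, kept=kept[name]
        )
        matrices[name] = {"iti": iti, "trial": tbt, "prediction": pred}
        for m in (iti, tbt, pred):
            rows.extend(_matrix_rows(m, name))
        # per-session inter-regional correlation values for the contrast
        vals = []
        for s in sessions:
            m = connectivity.trial_by_trial_correlation([s])
            vals.append(m.mean_inter())
        samples[name] = vals
    pd.DataFrame(rows).to_csv(out / "connectivity_matrices.csv", index=False)
    consistency = {}
    for name, ms in matrices.items():
        r2, p = connectivity.metric_consistency(ms["iti"], ms["trial"])
        consistency[name] = {"iti_vs_trial_r2": r2, "p": p}
    return {"inter_regional_correlation": samples, "consistency": consistency}


def stage_subspace(cohorts, cfg: RunConfig, out: Path) -> dict:
    rows = []
    spatial, temporal = {}, {}
    dims = cfg.degeneracy_dims
    for name, sessions in cohorts.items():
        sp_vals, tm_vals = [], []
        for si, s in enumerate(sessions):
            rng = np.random.default_rng(
                [cfg.seed, si, 0 if name == "control" else 1]
            )
            trials = s.trials
            frames = connectivity.concatenated_frames(s, "trial_window")
            sims_sp, sims_tm = [], []
            for _ in range(cfg.degeneracy_repeats):
                src = _region_sample(s, cfg.degeneracy_source, 10, rng)
                tgt_a = _region_sample(s, cfg.degeneracy_targets[0], 10, rng)
                tgt_b = _region_sample(s, cfg.degeneracy_targets[1], 10, rng)
                X = s.activity[np.ix_(src, frames)].T
                Ya = s.activity[np.ix_(tgt_a, frames)].T
                Yb = s.activity[np.ix_(tgt_b, frames)].T
                sims_sp.append(
                    subspace.spatial_degeneracy(X, Ya, Yb, dims=dims, folds=5)
                )
                windows = [(-2.0, -1.0), (0.0, 1.0), (1.0, 2.0), (2.0, 3.0),
                           (3.0, 4.0), (4.0, 5.0), (5.0, 6.0)]
                pairs = []
                for w in windows:
                    f = _frames_for_window(s, w, trials)
                    pairs.append(
                        (s.activity[np.ix_(src, f)].T, s.activity[np.ix_(tgt_a, f)].T)
                    )
                sim_m = subspace.temporal_degeneracy(pairs, dims=dims, folds=5)
                sims_tm.append(float(sim_m[np.triu_indices_from(sim_m, k=1)].mean()))
            sp_vals.append(float(np.mean(sims_sp)))
            tm_vals.append(float(np.mean(sims_tm)))
            rows.append(
                {"cohort": name, "session": si, "kind": "spatial",
                 "value": sp_vals[-1]}
            )
            rows.append(
                {"cohort": name, "session": si, "kind": "temporal",
                 "value": tm_vals[-1]}
            )
        spatial[name] = sp_vals
        temporal[name] = tm_vals
    pd.DataFrame(rows).to_csv(out / "subspace_degeneracy.csv", index=False)
    return {"spatial_similarity": spatial, "temporal_similarity": temporal}


def stage_decoding(cohorts, cfg: RunConfig, out: Path) -> dict:
    rows, samples = [], {}
    for name, sessions in cohorts.items():
        pools, meta = decoding.region_pools_from_sessions(
            sessions,
            mode="stimulus",
            trials_per_side=cfg.trials_per_side,
            distractor_trials_per_side=cfg.distractor_trials_per_side,
            seed=cfg.seed,
        )
        n_cells = min(
            min(p.shape[0] for p in pools.values()),
            decoding.DEFAULT_CELLS_PER_REGION["stimulus"],
        )
        vals = []
        for pmi in range(cfg.pseudo_mice):
            pm = decoding.build_pseudo_mouse(
                pools, meta, mode="stimulus", seed=cfg.seed + pmi,
                cells_per_region=n_cells,
            )
            res = decoding.decode_pseudo_mouse(pm, seed=cfg.seed + pmi)
            wmeans = list(res["window_mean"].values())
            vals.append(float(np.mean(wmeans)))
            for dtype, w in res["window_mean"].items():
                rows.append(
                    {
                        "cohort": name,
                        "pseudo_mouse": pmi,
                        "distractor": dtype,
                        "relative_accuracy": w,
                        "test_accuracy": res["test_accuracy"],
                    }
                )
        samples[name] = vals
    pd.DataFrame(rows).to_csv(out / "decoding_relative_accuracy.csv", index=False)
    return {"post_distractor_drop": samples}


def _cohort_targets(sessions: list[Session], params: RNNParams, rng):
    """Trial-averaged correct left/right traces over the 5.5-s training span."""
    traces = {"left": [], "right": []}
    regions = []
    for s in sessions:
        z = s.zscored()
        fr = z.frame_rate_hz
        a0 = int(math.floor(-0.5 * fr))
        a1 = int(math.floor(5.0 * fr))
        for side in ("left", "right"):
            trials = [
                t
                for t in z.trials
                if t.outcome == "correct"
                and t.stimulus_side == side
                and t.distractor == "none"
            ]
            acc = np.zeros((z.n_neurons, a1 - a0))
            for t in trials:
                acc += z.activity[:, t.onset_frame + a0 : t.onset_frame + a1]
            traces[side].append(acc / max(len(trials), 1))
        regions.append(z.region_of)
    return (
        {k: np.concatenate(v, axis=0) for k, v in traces.items()},
        np.concatenate(regions),
    )


def stage_rnn(cohorts, cfg: RunConfig, out: Path) -> dict:
    rows = {}
    switching, ablated = {}, {}
    params = RNNParams(n=cfg.rnn_units, epochs=cfg.rnn_epochs, seed=cfg.seed)
    for name, sessions in cohorts.items():
        rng = np.random.default_rng([cfg.seed, 7])
        traces, region_of = _cohort_targets(sessions, params, rng)
        targets = build_target_functions(
            traces, params, rng=rng, region_of=region_of, eligibility_sd=0.5
        )
        model = init_network(params)  # same seed -> paired initialization
        mse = force_train(model, targets, rng=np.random.default_rng([cfg.seed, 8]))
        base = switching_proportion(
            model, n_trials=cfg.rnn_test_trials, seed=cfg.seed
        )
        abl = ablate_and_test(
            model,
            mode="random",
            level=cfg.rnn_ablation_level,
            repeats=5,
            n_trials=cfg.rnn_test_trials,
            seed=cfg.seed,
        )
        switching[name] = [base]
        ablated[name] = abl.tolist()
        rows[name] = {
            "final_mse": float(mse[-1]),
            "first_mse": float(mse[0]),
            "baseline_switching": base,
            "ablated_switching_mean": float(abl.mean()),
        }
    with open(out / "rnn_summary.json", "w") as f:
        json.dump(rows, f, indent=2)
    return {"rnn_switching_after_ablation": ablated, "rnn_baseline_switching": switching}


# ---------------------------------------------------------------------------
# contrasts and driver
# ---------------------------------------------------------------------------

#: Source regions with two ring-coupled targets under the default graph.
_DEGENERACY_TRIPLES = (("S1fl", "M1p", "M2"), ("vS1", "M2", "S1fl"))


def _degeneracy_values(session: Session, seed: int, dims: int = 2, reps: int = 5):
    """(spatial, temporal) subspace-similarity means for one session.

    Spatial similarity is averaged over the two ring triples and ``reps``
    neuron samplings; temporal similarity over ``reps`` samplings of the
    first triple's source-target pair.
    """
    rng = np.random.default_rng([seed, 21])
    frames = connectivity.concatenated_frames(session, "trial_window")
    windows = [(-2.0, -1.0), (0.0, 1.0), (1.0, 2.0), (2.0, 3.0),
               (3.0, 4.0), (4.0, 5.0), (5.0, 6.0)]
    sp, tm = [], []
    for src_r, ta_r, tb_r in _DEGENERACY_TRIPLES:
        for _ in range(reps):
            src = _region_sample(session, src_r, 10, rng)
            ta = _region_sample(session, ta_r, 10, rng)
            tb = _region_sample(session, tb_r, 10, rng)
            X = session.activity[np.ix_(src, frames)].T
            Ya = session.activity[np.ix_(ta, frames)].T
            Yb = session.activity[np.ix_(tb, frames)].T
            sp.append(subspace.spatial_degeneracy(X, Ya, Yb, dims=dims, folds=5))
            if (src_r, ta_r, tb_r) != _DEGENERACY_TRIPLES[0]:
                continue
            pairs = []
            for w in windows:
                f = _frames_for_window(session, w, session.trials)
                pairs.append(
                    (
                        session.activity[np.ix_(src, f)].T,
                        session.activity[np.ix_(ta, f)].T,
                    )
                )
            sim_m = subspace.temporal_degeneracy(pairs, dims=dims, folds=5)
            tm.append(float(sim_m[np.triu_indices_from(sim_m, k=1)].mean()))
    return float(np.mean(sp)), float(np.mean(tm))


def _decoding_drop(sessions: list[Session], seed: int) -> float:
    pools, meta = decoding.region_pools_from_sessions(
        sessions, mode="stimulus", trials_per_side=12,
        distractor_trials_per_side=2, seed=seed,
    )
    n_cells = min(
        min(p.shape[0] for p in pools.values()),
        decoding.DEFAULT_CELLS_PER_REGION["stimulus"],
    )
    pm = decoding.build_pseudo_mouse(
        pools, meta, mode="stimulus", seed=seed, cells_per_region=n_cells
    )
    res = decoding.decode_pseudo_mouse(pm, seed=seed)
    return float(np.mean(list(res["window_mean"].values())))


def _rnn_switching(sessions: list[Session], seed: int, rnn_epochs: int = 120,
                   distractor_amp: float = 1.5) -> float:
    params = RNNParams(
        n=64, epochs=rnn_epochs, seed=seed, alpha_learn=1.0, noise_sd=0.25,
        p_init="inverse",
    )
    rng = np.random.default_rng([seed, 7])
    traces, region_of = _cohort_targets(sessions, params, rng)
    targets = build_target_functions(
        traces, params, rng=rng, region_of=region_of, eligibility_sd=0.5
    )
    model = init_network(params)  # shared seed -> paired initialization
    force_train(
        model, targets, rng=np.random.default_rng([seed, 8]),
        state_update="teacher",
    )
    props = ablate_and_test(
        model, mode="random", level=0.1, repeats=5, n_trials=30,
        n_reference=12, seed=seed, distractor_peak_mean=distractor_amp,
    )
    return float(np.nanmean(props))


def end_to_end_directions(seed: int, include_rnn: bool = True) -> dict:
    """Direction checks between matched-seed control / reduced cohorts.

    Returns booleans per contrast: lower inter-regional connectivity, lower
    spatial/temporal subspace similarity, larger distractor-induced decoding
    drop, and higher post-ablation RNN switching in the reduced cohort.
    """
    kw = dict(neurons_per_region=40, n_trials=120, seed=seed)
    ctl = generate_cohort(control_config(**kw), 1)
    red = generate_cohort(reduced_connectivity_config(**kw), 1)
    out = {}
    out["connectivity"] = (
        connectivity.trial_by_trial_correlation(ctl).mean_inter()
        > connectivity.trial_by_trial_correlation(red).mean_inter()
    )
    sp_c, tm_c = _degeneracy_values(ctl[0], seed)
    sp_r, tm_r = _degeneracy_values(red[0], seed)
    out["spatial"] = sp_c > sp_r
    out["temporal"] = tm_c > tm_r
    out["decoding"] = _decoding_drop(red, seed) < _decoding_drop(ctl, seed)
    if include_rnn:
        out["rnn"] = _rnn_switching(red, seed) > _rnn_switching(ctl, seed)
    return out


#: Expected direction of each contrast: 'reduced_lower' or 'reduced_higher'.
CONTRAST_DIRECTIONS = {
    "distractor_performance": "reduced_lower",
    "distractor_modulation": "reduced_lower",
    "inter_regional_correlation": "reduced_lower",
    "spatial_similarity": "reduced_lower",
    "temporal_similarity": "reduced_lower",
    "post_distractor_drop": "reduced_lower",  # drop is negative: more negative
    "rnn_switching_after_ablation": "reduced_higher",
}


def _contrast(samples: dict, expected: str, n_boot: int, seed: int) -> dict:
    a = np.asarray(samples.get("control", []), dtype=float)
    b = np.asarray(samples.get("reduced_connectivity", []), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    result = {
        "control_mean": float(a.mean()) if a.size else None,
        "reduced_mean": float(b.mean()) if b.size else None,
        "expected": expected,
    }
    if a.size and b.size:
        diff = float(b.mean() - a.mean())
        result["direction_matches"] = (
            diff < 0 if expected == "reduced_lower" else diff > 0
        )
        if a.size > 1 and b.size > 1:
            tail = "less" if expected == "reduced_lower" else "greater"
            bt = bootstrap_diff_test(a, b, n_boot=n_boot, tail=tail, seed=seed)
            result["bootstrap_p"] = bt.p_value
    return result


def run_experiment(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"config": {**cfg.__dict__, "stages": list(cfg.stages)},
                     "stages": {}, "contrasts": {}, "timing_s": {}}
    try:
        t0 = time.perf_counter()
        cohorts = generate_cohorts(cfg)
        summary["timing_s"]["generate"] = round(time.perf_counter() - t0, 2)
        log.info("generated cohorts in %.1fs", summary["timing_s"]["generate"])
    except Exception as exc:  # generation failure is fatal
        log.exception("cohort generation failed")
        summary["error"] = f"generation failed: {exc}"
        _write_summary(summary, out)
        raise

    stage_fns = {
        "behavior": stage_behavior,
        "selectivity": stage_selectivity,
        "connectivity": stage_connectivity,
        "subspace": stage_subspace,
        "decoding": stage_decoding,
        "rnn": stage_rnn,
    }
    collected: dict = {}
    for stage in cfg.stages:
        fn = stage_fns.get(stage)
        if fn is None:
            log.warning("unknown stage %s skipped", stage)
            continue
        t0 = time.perf_counter()
        try:
            result = fn(cohorts, cfg, out)
            collected.update(
                {k: v for k, v in result.items() if isinstance(v, dict)}
            )
            summary["stages"][stage] = "ok"
        except Exception as exc:  # isolate per-stage failures
            log.exception("stage %s failed", stage)
            summary["stages"][stage] = f"failed: {exc}"
        summary["timing_s"][stage] = round(time.perf_counter() - t0, 2)
        log.info("stage %s: %s (%.1fs)", stage, summary["stages"].get(stage),
                 summary["timing_s"][stage])

    for metric, expected in CONTRAST_DIRECTIONS.items():
        if metric in collected and isinstance(collected[metric], dict):
            if {"control", "reduced_connectivity"} <= set(collected[metric]):
                summary["contrasts"][metric] = _contrast(
                    collected[metric], expected, cfg.n_boot, cfg.seed
                )
    summary["samples"] = {
        k: v
        for k, v in collected.items()
        if isinstance(v, dict) and "control" in v
    }
    _write_summary(summary, out)
    log.removeHandler(handler)
    handler.close()
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, default=default)
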
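"""Synthetic two-cohort session generator.

Generative model
----------------
Each region carries a latent vector split into six *drive* channels
(stimulus +/-, choice +/-, action +/-) and ``latent_dim_per_region``
*background* channels. Latents evolve as AR(1) processes; task drives are
added per frame according to the trial state:

* stimulus channels receive a 1-s pulse (side-signed) during the stimulus
  epoch, strongest in the sensory regions (S1fl, vS1);
* choice channels of the choice-source regions (ALM, M2) integrate a
  side-signed ramp across the delay; other regions receive choice content
  only through inter-regional relay, so weaker coupling yields weaker
  delay selectivity outside the source regions;
* action channels receive a choice-signed pulse during the action epoch;
* distractor trials add a 0.2-s pulse to the sensory stimulus channels and
  leak into the opposite-side choice channels with gain
  ``distractor_susceptibility``.

Inter-regional transmission is a low-rank linear map on background channels
applied with a one-frame lag and gain ``coupling[target, source]``. The map
selects ``coupling_rank`` source channels; ``spatial_channel_overlap``
controls whether different targets of the same source tap the same channels,
and ``temporal_drift`` rotates the tapped channels across the trial.

Neuron activity is ``nonnegative loadings @ latents + private Gaussian
noise``. The behavioral outcome is a logistic readout of the end-of-delay
choice latent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from corticomm.synthio.session import REGIONS, Session, TrialRecord

# Drive-channel layout within each region's latent block.
_STIM_P, _STIM_N, _CHOICE_P, _CHOICE_N, _ACT_P, _ACT_N = range(6)
_N_DRIVE = 6

#: Regions that generate the choice signal directly.
CHOICE_SOURCE_REGIONS = ("ALM", "M2")
#: Regions receiving the strongest direct stimulus drive.
SENSORY_REGIONS = ("S1fl", "vS1")

_DEFAULT_SELECTIVITY = {"stimulus": 0.2, "delay": 0.3, "action": 0.2}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator. ``seed`` fully determines output."""

    neurons_per_region: int = 40
    n_trials: int = 180
    distractor_fractions: tuple[float, float, float] = (0.1, 0.1, 0.1)
    latent_dim_per_region: int = 6
    coupling: object = None  # None -> default uniform gain; scalar; or 8x8 array
    coupling_rank: int = 2
    selectivity_fractions: dict | None = None
    private_noise_sd: float = 0.5
    distractor_susceptibility: float = 0.6
    iti_range_s: tuple[int, int] = (6, 8)
    seed: int = 0
    frame_rate_hz: float = 9.35
    cohort_tag: str = "other"

    # Structural knobs beyond the base contract
    spatial_channel_overlap: float = 1.0  # 1: targets share source channels
    temporal_drift: float = 0.0  # 1: tapped channels rotate across the trial
    choice_relay: float = 0.12  # gain of choice relay from source to other regions
    distractor_allocation: str = "deterministic"  # or "multinomial"
    loading_mode: str = "random"  # or "identity" (unit loading on 1st bg channel)
    store_latents: bool = False  # stash latents/loadings in Session.meta

    # Dynamics / amplitude knobs
    ar_coef: float = 0.9  # drive channels (choice integration)
    ar_bg: float = 0.65  # background channels (leaves headroom for coupling)
    latent_noise_sd: float = 1.0
    drive_noise_sd: float = 0.2
    stim_amp: float = 1.2
    stim_gain_nonsensory: float = 0.3
    choice_ramp: float = 0.18
    action_amp: float = 1.0
    distractor_amp: float = 1.5
    decision_gain: float = 0.8
    no_response_p: float = 0.03
    tuned_loading: float = 1.0
    bg_loading: float = 0.8

    def __post_init__(self) -> None:
        if self.neurons_per_region <= 0:
            raise ValueError("neurons_per_region must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        fr = tuple(self.distractor_fractions)
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr) or sum(fr) >= 1:
            raise ValueError(
                "distractor_fractions must be three values in [0, 1] summing to < 1"
            )
        self.distractor_fractions = fr
        if self.selectivity_fractions is None:
            self.selectivity_fractions = dict(_DEFAULT_SELECTIVITY)
        if any(not 0 <= f <= 1 for f in self.selectivity_fractions.values()):
            raise ValueError("selectivity_fractions must lie in [0, 1]")
        if self.latent_dim_per_region < 1:
            raise ValueError("latent_dim_per_region must be >= 1")
        if not 0 <= self.spatial_channel_overlap <= 1:
            raise ValueError("spatial_channel_overlap must lie in [0, 1]")
        if self.distractor_allocation not in ("deterministic", "multinomial"):
            raise ValueError("distractor_allocation must be deterministic|multinomial")
        if self.loading_mode not in ("random", "identity"):
            raise ValueError("loading_mode must be random|identity")

    def coupling_matrix(self) -> np.ndarray:
        """8x8 nonnegative gain matrix keyed (target, source); zero diagonal.

        The default graph is ring-sparse: each region receives from its two
        ring neighbors ``g+1`` and ``g+2``. Sparse in-degree keeps the
        forward transmission channel dominant over aggregate mixtures, which
        would otherwise swamp pair-specific communication subspaces.
        """
        n = len(REGIONS)
        if self.coupling is None:
            c = np.zeros((n, n))
            for g in range(n):
                c[g, (g + 1) % n] = c[g, (g + 2) % n] = 1.0
        elif np.isscalar(self.coupling):
            c = float(self.coupling) * (np.ones((n, n)) - np.eye(n))
        else:
            c = np.array(self.coupling, dtype=float)
            if c.shape != (n, n):
                raise ValueError("coupling must be an 8x8 matrix")
            np.fill_diagonal(c, 0.0)
        if np.any(c < 0):
            raise ValueError("coupling gains must be nonnegative")
        return c


def control_config(**overrides) -> GeneratorConfig:
    """Preset emulating the intact cohort."""
    kw: dict = dict(cohort_tag="control", distractor_susceptibility=0.6)
    kw.update(overrides)
    return GeneratorConfig(**kw)


#: Factor by which the reduced-connectivity preset scales coupling gains.
REDUCED_COUPLING_SCALE = 0.35


def reduced_connectivity_config(**overrides) -> GeneratorConfig:
    """Preset emulating the reduced-connectivity cohort.

    Coupling gains are scaled by :data:`REDUCED_COUPLING_SCALE`, cross-target
    channel overlap is removed, tapped channels drift within the trial, and
    distractor leakage into the choice latents is stronger.
    """
    base = control_config().coupling_matrix() * REDUCED_COUPLING_SCALE
    kw: dict = dict(
        cohort_tag="reduced_connectivity",
        coupling=base,
        spatial_channel_overlap=0.0,
        temporal_drift=1.0,
        distractor_susceptibility=1.4,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def _allocate_distractors(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_trials
    fe, fm, fl = cfg.distractor_fractions
    if cfg.distractor_allocation == "deterministic":
        ne, nm, nl = (int(round(f * n)) for f in (fe, fm, fl))
        types = ["early"] * ne + ["middle"] * nm + ["late"] * nl
        types += ["none"] * (n - len(types))
    else:
        p = [1 - fe - fm - fl, fe, fm, fl]
        draw = rng.choice(4, size=n, p=p)
        types = [("none", "early", "middle", "late")[i] for i in draw]
    order = rng.permutation(n)
    return [types[i] for i in order]


def _pair_maps(cfg: GeneratorConfig) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Per (target, source) pair: list of (target_channel, source_channel).

    Background channels are split into ``d - r`` *sender* channels (0-based
    index < ``d - r``) and ``r`` *receiver* channels. Transmission taps
    sender channels of the source and writes into receiver channels of the
    target, so at the channel level the coupling graph is feedforward and the
    latent system is stable for any gain. ``spatial_channel_overlap`` sets
    how many tapped channels are shared across all targets of a source.
    """
    d, r = cfg.latent_dim_per_region, min(cfg.coupling_rank, cfg.latent_dim_per_region)
    n_send = d - r
    n_shared = int(round(r * cfg.spatial_channel_overlap))
    maps: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for j in range(len(REGIONS)):  # source
        t_idx = 0
        for g in range(len(REGIONS)):  # target
            if g == j:
                continue
            pairs = []
            for k in range(r):
                if k < n_shared or n_send <= n_shared:
                    col = k % max(n_send, 1)
                else:
                    span = n_send - n_shared
                    col = n_shared + (t_idx * (r - n_shared) + (k - n_shared)) % span
                pairs.append((n_send + k, col))  # (target receiver, source sender)
            maps[(g, j)] = pairs
            t_idx += 1
    return maps


def _coupling_operator(cfg: GeneratorConfig, phase: float) -> np.ndarray:
    """Full (8K x 8K) one-frame-lag coupling operator at trial phase in [0, 1].

    Transmission taps sender channels and writes into receiver channels
    (see :func:`_pair_maps`), so the channel-level graph is feedforward. The
    choice relay likewise runs only from source regions to non-source
    regions. ``temporal_drift`` rotates each tapped sender channel toward a
    partner sender channel as the trial progresses.
    """
    n_reg, d = len(REGIONS), cfg.latent_dim_per_region
    r = min(cfg.coupling_rank, d)
    n_send = d - r
    K = _N_DRIVE + d
    C = np.zeros((n_reg * K, n_reg * K))
    gains = cfg.coupling_matrix()
    maps = _pair_maps(cfg)
    phi = cfg.temporal_drift * phase * (math.pi / 2.0)
    cphi, sphi = math.cos(phi), math.sin(phi)
    src_idx = [REGIONS.index(x) for x in CHOICE_SOURCE_REGIONS]
    for g in range(n_reg):
        for j in range(n_reg):
            if g == j or gains[g, j] == 0:
                continue
            c = gains[g, j]
            base_g, base_j = g * K, j * K
            for row, col in maps[(g, j)]:
                partner = (col + r) % n_send if n_send > 0 else col
                C[base_g + _N_DRIVE + row, base_j + _N_DRIVE + col] += c * cphi
                if partner != col:
                    C[base_g + _N_DRIVE + row, base_j + _N_DRIVE + partner] += c * sphi
            if j in src_idx and g not in src_idx and cfg.choice_relay > 0:
                relay = gains[g, j] * cfg.choice_relay
                C[base_g + _CHOICE_P, base_j + _CHOICE_P] += relay
                C[base_g + _CHOICE_N, base_j + _CHOICE_N] += relay
    return C


def _build_loadings(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-diagonal nonnegative loading matrix (neurons x 8K)."""
    n_reg, d = len(REGIONS), cfg.latent_dim_per_region
    K = _N_DRIVE + d
    n = cfg.neurons_per_region
    L = np.zeros((n_reg * n, n_reg * K))
    if cfg.loading_mode == "identity":
        for g in range(n_reg):
            L[g * n : (g + 1) * n, g * K + _N_DRIVE] = cfg.bg_loading
        return L
    sf = cfg.selectivity_fractions
    ns = int(round(sf.get("stimulus", 0.0) * n))
    nd = int(round(sf.get("delay", 0.0) * n))
    na = int(round(sf.get("action", 0.0) * n))
    if ns + nd + na > n:
        raise ValueError("selectivity fractions exceed the neuron budget")
    for g in range(n_reg):
        base = g * K
        rows = slice(g * n, (g + 1) * n)
        Lg = np.zeros((n, K))
        # epoch-tuned neurons, half preferring each side
        cursor = 0
        for count, (chan_p, chan_n) in (
            (ns, (_STIM_P, _STIM_N)),
            (nd, (_CHOICE_P, _CHOICE_N)),
            (na, (_ACT_P, _ACT_N)),
        ):
            for i in range(count):
                chan = chan_p if i % 2 == 0 else chan_n
                Lg[cursor, chan] = cfg.tuned_loading * abs(rng.normal(1.0, 0.15))
                cursor += 1
        # every neuron mixes background channels (nonnegative weights)
        for i in range(n):
            primary = i % d
            Lg[i, _N_DRIVE + primary] = abs(rng.normal(cfg.bg_loading, 0.2))
            if d > 1:
                Lg[i, _N_DRIVE + (primary + 1) % d] = 0.3 * cfg.bg_loading
        L[rows, base : base + K] = Lg
    return L


def generate_session(cfg: GeneratorConfig, rng: np.random.Generator) -> Session:
    """Generate one session from an explicit random generator."""
    n_reg, d = len(REGIONS), cfg.latent_dim_per_region
    K = _N_DRIVE + d
    fr = cfg.frame_rate_hz
    f_stim = int(math.floor(1.0 * fr))
    f_delay_end = int(math.floor(5.0 * fr))
    f_action_end = int(math.floor(9.0 * fr))
    pre = int(math.ceil(5.0 * fr)) + 1

    # trial skeleton
    iti_lo, iti_hi = int(cfg.iti_range_s[0]), int(cfg.iti_range_s[1])
    sides = ["right" if x < 0.5 else "left" for x in rng.random(cfg.n_trials)]
    distractors = _allocate_distractors(cfg, rng)
    onsets = []
    t = pre
    for _ in range(cfg.n_trials):
        onsets.append(t)
        iti = int(rng.integers(iti_lo, iti_hi + 1))
        t += f_action_end + int(math.floor(iti * fr))
    n_frames = onsets[-1] + f_action_end + 1

    # distractor pulse frames (0.2 s) per trial
    pulse_len = max(1, int(round(0.2 * fr)))
    d_onset_s = {"early": 2.0, "middle": 3.0, "late": 4.0}  # rel. stimulus onset

    if np.any(cfg.coupling_matrix() > 0) and d < min(cfg.coupling_rank, d) + 1:
        raise ValueError(
            "latent_dim_per_region must exceed coupling_rank when coupling is active"
        )

    # coupling operators discretized over trial phase
    n_bins = 8
    if cfg.temporal_drift != 0:
        Cs = [_coupling_operator(cfg, b / (n_bins - 1)) for b in range(n_bins)]
    else:
        Cs = [_coupling_operator(cfg, 0.0)] * n_bins

    rho = np.empty(n_reg * K)
    noise_scale = np.empty(n_reg * K)
    for g in range(n_reg):
        base = g * K
        rho[base : base + _N_DRIVE] = cfg.ar_coef
        rho[base + _N_DRIVE : base + K] = cfg.ar_bg
        noise_scale[base : base + _N_DRIVE] = cfg.drive_noise_sd * math.sqrt(
            1 - cfg.ar_coef**2
        )
        noise_scale[base + _N_DRIVE : base + K] = cfg.latent_noise_sd * math.sqrt(
            1 - cfg.ar_bg**2
        )
    for C in {id(c): c for c in Cs}.values():
        radius = float(np.max(np.abs(np.linalg.eigvals(np.diag(rho) + C))))
        if radius >= 0.995:
            raise ValueError(
                f"latent dynamics unstable (spectral radius {radius:.3f}); "
                "reduce coupling gains or AR coefficients"
            )
    lat_noise = rng.normal(size=(n_frames, n_reg * K)) * noise_scale

    stim_gain = np.array(
        [1.0 if r in SENSORY_REGIONS else cfg.stim_gain_nonsensory for r in REGIONS]
    )
    src_idx = [REGIONS.index(r) for r in CHOICE_SOURCE_REGIONS]
    sens_idx = [REGIONS.index(r) for r in SENSORY_REGIONS]

    S = np.zeros((n_frames, n_reg * K))
    s = np.zeros(n_reg * K)
    trial_ptr = 0
    active: dict | None = None
    records: list[TrialRecord] = []

    choice_p_cols = np.array([g * K + _CHOICE_P for g in range(n_reg)])
    choice_n_cols = np.array([g * K + _CHOICE_N for g in range(n_reg)])

    for t in range(n_frames):
        # trial state machine
        if active is None and trial_ptr < cfg.n_trials and t == onsets[trial_ptr]:
            side = sides[trial_ptr]
            dtype = distractors[trial_ptr]
            active = {
                "onset": t,
                "side": side,
                "distractor": dtype,
                "index": trial_ptr,
                "choice": None,
            }
            trial_ptr += 1

        bin_idx = 0
        drive = np.zeros(n_reg * K)
        if active is not None:
            rel = t - active["onset"]
            bin_idx = min(int(rel / f_action_end * n_bins), n_bins - 1)
            sgn_p = _STIM_P if active["side"] == "right" else _STIM_N
            if rel < f_stim:  # stimulus epoch
                for g in range(n_reg):
                    drive[g * K + sgn_p] += (
                        (1 - cfg.ar_coef) * cfg.stim_amp * stim_gain[g]
                    )
            elif rel < f_delay_end:  # delay epoch
                chan = _CHOICE_P if active["side"] == "right" else _CHOICE_N
                for g in src_idx:
                    drive[g * K + chan] += cfg.choice_ramp
                if active["distractor"] != "none":
                    d0 = int(math.floor(d_onset_s[active["distractor"]] * fr))
                    if d0 <= rel < d0 + pulse_len:
                        for g in sens_idx:
                            drive[g * K + _STIM_P] += cfg.distractor_amp
                            drive[g * K + _STIM_N] += cfg.distractor_amp
                        anti = _CHOICE_N if active["side"] == "right" else _CHOICE_P
                        for g in src_idx:
                            drive[g * K + anti] += (
                                cfg.distractor_susceptibility * cfg.distractor_amp
                            )
            else:  # action epoch
                if active["choice"] is None:
                    # decide at delay offset from the end-of-delay choice latent
                    v = float(s[choice_p_cols].sum() - s[choice_n_cols].sum())
                    if rng.random() < cfg.no_response_p:
                        choice = "none"
                    else:
                        p_right = 1.0 / (1.0 + math.exp(-cfg.decision_gain * v))
                        choice = "right" if rng.random() < p_right else "left"
                    active["choice"] = choice
                if active["choice"] in ("left", "right"):
                    chan = _ACT_P if active["choice"] == "right" else _ACT_N
                    for g in range(n_reg):
                        drive[g * K + chan] += (1 - cfg.ar_coef) * cfg.action_amp
                if rel >= f_action_end - 1:
                    side, choice = active["side"], active["choice"]
                    outcome = (
                        "no_response"
                        if choice == "none"
                        else ("correct" if choice == side else "incorrect")
                    )
                    records.append(
                        TrialRecord(
                            onset_frame=active["onset"],
                            stimulus_side=side,
                            choice_side=choice,
                            outcome=outcome,
                            distractor=active["distractor"],
                        )
                    )
                    active = None

        s = rho * s + Cs[bin_idx] @ s + drive + lat_noise[t]
        S[t] = s

    L = _build_loadings(cfg, rng)
    activity = L @ S.T
    if cfg.private_noise_sd > 0:
        activity = activity + rng.normal(
            scale=cfg.private_noise_sd, size=activity.shape
        )
    region_of = np.array(
        [r for r in REGIONS for _ in range(cfg.neurons_per_region)], dtype=object
    )
    meta = {}
    if cfg.store_latents:
        meta = {"latents": S, "loadings": L, "coupling_ops": Cs}
    return Session(
        activity=activity,
        region_of=region_of,
        frame_rate_hz=fr,
        trials=records,
        cohort_tag=cfg.cohort_tag,
        meta=meta,
    )


def generate_cohort(cfg: GeneratorConfig, n_sessions: int) -> list[Session]:
    """Generate a deterministic cohort of sessions.

    Identical ``(config, seed)`` yield bit-identical cohorts; session ``i``
    uses the child stream ``[cfg.seed, i]``.
    """
    if n_sessions <= 0:
        raise ValueError("n_sessions must be positive")
    return [
        generate_session(cfg, np.random.default_rng([cfg.seed, i]))
        for i in range(n_sessions)
    ]
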
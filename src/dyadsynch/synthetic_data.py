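"""Synthetic transmission-chain sessions.

Generates full three-block chain sessions (G1→G2, G2→G3, G3→G4) with the
statistical structure the downstream analysis assumes:

* pseudorandomised 12-trial cue sequences (6 Tx / 6 NT) under the run-length,
  half-balance and transition-balance rules, sampled uniformly from the valid
  set;
* coupled dyadic electrodermal arousal — a shared and an independent
  Ornstein–Uhlenbeck tonic process mixed with weight ``κ`` / ``√(1−κ²)`` —
  plus skin-conductance responses (Bateman bi-exponential kernel) at cue and
  heat onsets;
* demonstrator pain built from a nociceptive temperature term and a
  cue-contingent nocebo shift whose sign follows the subject's responder
  type (responder / non-responder / reverse-responder);
* observer expectancies tracking the demonstrator's expressed pain through a
  per-cue delta rule, gated by the 50% pain-rating display schedule;
* facial action-unit channels whose pain-expression composite tracks felt
  (demonstrator) or vicarious (observer) pain;
* missing expectancy ratings injected at a configurable rate.

The generator is the test bed for every downstream module; identical seeds
produce bit-identical sessions.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import lfilter

from dyadsynch.io_formats import (
    BlockData,
    ContinuousRecording,
    REQUIRED_AUS,
    Session,
    SessionManifest,
    TrialEvent,
)

__all__ = [
    "GeneratorConfig",
    "generate_trial_sequence",
    "valid_trial_sequences",
    "scr_kernel",
    "simulate_dyad_block",
    "simulate_chain_session",
    "inject_missingness",
]

RESPONDER_TYPES = ("responder", "non_responder", "reverse_responder")
_SIGN = {"responder": 1.0, "non_responder": 0.0, "reverse_responder": -1.0}


@dataclass
class GeneratorConfig:
    """All tunable quantities of the synthetic study.

    Defaults reproduce the study conditions: 12-trial blocks, 45/54 °C
    stimuli, a 7-point (VAS) nocebo shift for responders, a responder /
    non-responder / reverse-responder mixture near the observed proportions,
    8.2% missing expectancy ratings, and 1 kHz EDA.
    """

    n_sessions: int = 1
    # dyadic coupling of tonic arousal
    kappa: float = 0.6
    kappa_sd: float = 0.2
    # nocebo structure (VAS points)
    nocebo_effect_size: float = 7.0
    synchrony_nocebo_slope: float = 4.0  # VAS per SD of dyad coupling
    responder_mix: dict = field(
        default_factory=lambda: {
            "responder": 0.44,
            "non_responder": 0.46,
            "reverse_responder": 0.10,
        }
    )
    baseline_pain: dict = field(default_factory=lambda: {45.0: 36.0, 54.0: 75.0})
    rating_noise_sd: float = 10.0
    initial_expectancy: float = 30.0
    expectancy_learning_rate: float = 0.5
    face_weight: float = 0.5  # delta-rule attenuation when the rating is hidden
    expectancy_noise_sd: float = 8.0
    missing_expectancy_rate: float = 0.082
    # electrodermal model
    sampling_rate: float = 1000.0
    eda_base_level: float = 5.0  # µS
    eda_scale_sd: float = 0.25  # lognormal sd of per-subject tonic gain
    ou_tau: float = 3.0  # s, arousal mean-reversion time (keeps power in-band)
    eda_tonic_sd: float = 0.1  # µS, stationary SD of each OU component
    nsscr_rate: float = 0.15  # Hz, spontaneous (non-specific) SCR rate ≈ 9/min
    nsscr_amplitude: float = 0.5  # µS, median spontaneous SCR peak
    nsscr_amplitude_sd: float = 0.4  # lognormal sd of spontaneous SCR peaks
    scr_amplitude_by_temperature: dict = field(
        default_factory=lambda: {45.0: 0.35, 54.0: 1.0}
    )
    scr_amplitude_sd: float = 0.5  # lognormal sd of SCR amplitudes
    anticipatory_scr_gain: float = 0.4  # cue SCR per unit expectancy/100
    vicarious_scr_gain: float = 0.5  # observer heat SCR per unit observed pain/100
    measurement_noise_sd: float = 0.01  # µS
    # facial action units
    fau_rate: float = 60.0
    fau_gain: float = 3.0  # composite intensity per unit pain/100
    fau_vicarious_gain: float = 1.5
    fau_noise_sd: float = 0.05
    fau_dropout: float = 0.02  # probability a frame's face detection fails
    # trial timing (seconds)
    fixation_s: float = 2.0
    cue_s: float = 6.0
    expectancy_s: float = 6.0
    iti1_range: tuple = (7.0, 10.0)
    post_heat_s: float = 5.0
    rating_s: float = 4.0
    iti2_s: float = 12.0
    tail_s: float = 20.0
    # which channels to synthesise (ratings are always produced)
    generate_eda: bool = True
    generate_fau: bool = True

    def validate(self) -> None:
        probs = [self.responder_mix.get(k, 0.0) for k in RESPONDER_TYPES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("responder_mix must be non-negative and sum to 1")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        for name in ("missing_expectancy_rate", "expectancy_learning_rate", "fau_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sampling_rate <= 0 or self.fau_rate <= 0:
            raise ValueError("sampling rates must be positive")


# ---------------------------------------------------------------------------
# trial sequences


def _sequence_valid(seq: tuple[str, ...]) -> bool:
    if len(seq) != 12 or seq.count("Tx") != 6:
        return False
    # no more than 3 identical cues in a row
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > 3:
            return False
    # each cue 2-4 times in each half
    for half in (seq[:6], seq[6:]):
        if not 2 <= half.count("Tx") <= 4:
            return False
    # transitions from each cue split as evenly as possible
    for a in ("Tx", "NT"):
        stay = sum(1 for x, y in zip(seq, seq[1:]) if x == a and y == a)
        switch = sum(1 for x, y in zip(seq, seq[1:]) if x == a and y != a)
        if abs(stay - switch) > 1:
            return False
    return True


@lru_cache(maxsize=1)
def valid_trial_sequences() -> tuple[tuple[str, ...], ...]:
    """Every 12-trial cue sequence satisfying the pseudorandomisation rules."""
    out = []
    for tx_pos in itertools.combinations(range(12), 6):
        seq = tuple("Tx" if i in tx_pos else "NT" for i in range(12))
        if _sequence_valid(seq):
            out.append(seq)
    return tuple(out)


def generate_trial_sequence(rng: np.random.Generator | int) -> list[str]:
    """Draw a cue sequence uniformly from the valid set."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    pool = valid_trial_sequences()
    return list(pool[int(rng.integers(len(pool)))])


def _display_schedule(cues: list[str], rng: np.random.Generator) -> list[bool]:
    """Which trials show the demonstrator's pain rating to the observer.

    Exactly half are shown: the first Tx and first NT always, three per
    six-trial half, and never more than two shown in succession.
    """
    first_tx = cues.index("Tx")
    first_nt = cues.index("NT")
    idx = np.arange(12)
    for _ in range(10_000):
        shown_set = set(rng.choice(idx, size=6, replace=False).tolist())
        shown_set |= {first_tx, first_nt}
        if len(shown_set) != 6:
            continue
        shown = [i in shown_set for i in range(12)]
        if sum(shown[:6]) != 3:
            continue
        run = 0
        ok = True
        for s in shown:
            run = run + 1 if s else 0
            if run > 2:
                ok = False
                break
        if ok:
            return shown
    raise RuntimeError("could not build a display schedule")  # pragma: no cover


# ---------------------------------------------------------------------------
# signal building blocks


def scr_kernel(
    fs: float, rise_s: float = 0.75, decay_s: float = 2.0, latency_s: float = 1.0
) -> np.ndarray:
    """Unit-peak Bateman bi-exponential skin-conductance response kernel."""
    t = np.arange(0.0, latency_s + decay_s * 8.0, 1.0 / fs)
    shifted = np.clip(t - latency_s, 0.0, None)
    h = np.exp(-shifted / decay_s) - np.exp(-shifted / rise_s)
    h[t < latency_s] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


def _ou_series(n: int, fs: float, tau: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path: AR(1) with coefficient exp(-dt/τ)."""
    if sd == 0.0:
        return np.zeros(n)
    a = np.exp(-1.0 / (fs * tau))
    innov_sd = sd * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # start in the stationary distribution
    return lfilter([1.0], [1.0, -a], eps)


def _latent_arousal(
    config: GeneratorConfig,
    n: int,
    duration: float,
    kernel: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One latent arousal path: in-band OU drift plus spontaneous SCR bursts.

    The burst train is what lets dyadic coupling survive the 0.05–1 Hz
    synchrony band: shared bursts give both members matched state-space
    excursions, which is where cross-recurrence structure lives.
    """
    sig = _ou_series(n, config.sampling_rate, config.ou_tau, config.eda_tonic_sd, rng)
    n_ev = rng.poisson(config.nsscr_rate * duration)
    if n_ev and config.nsscr_amplitude > 0:
        events = [
            (
                rng.uniform(0.0, duration),
                config.nsscr_amplitude * np.exp(rng.normal(0.0, config.nsscr_amplitude_sd)),
            )
            for _ in range(n_ev)
        ]
        _add_events(sig, kernel, config.sampling_rate, events)
    return sig


def _add_events(signal: np.ndarray, kernel: np.ndarray, fs: float, events) -> None:
    for onset, amp in events:
        i = int(round(onset * fs))
        if i >= signal.size:
            continue
        seg = kernel[: signal.size - i]
        signal[i : i + seg.size] += amp * seg


# ---------------------------------------------------------------------------
# participants and blocks


@dataclass
class ParticipantState:
    """Evolving per-participant state carried along the chain."""

    participant_id: str
    generation: str
    gender: str
    responder_type: str
    expectancy: dict = field(default_factory=dict)  # cue -> learned expectancy
    observed_kappa: float | None = None  # coupling of the dyad they observed in
    eda_scale: float = 1.0

    def nocebo_effect(self, config: GeneratorConfig) -> float:
        """Cue-contingent pain shift (VAS) once this person demonstrates."""
        effect = config.nocebo_effect_size
        if self.observed_kappa is not None and config.kappa_sd > 0:
            z = (self.observed_kappa - config.kappa) / config.kappa_sd
            effect += config.synchrony_nocebo_slope * z
        return max(0.0, effect) * _SIGN[self.responder_type]


def _draw_participant(
    pid: str, generation: str, config: GeneratorConfig, rng: np.random.Generator
) -> ParticipantState:
    probs = [config.responder_mix[k] for k in RESPONDER_TYPES]
    rtype = RESPONDER_TYPES[int(rng.choice(len(RESPONDER_TYPES), p=probs))]
    gender = ["female", "male", "non_binary"][int(rng.choice(3, p=[0.69, 0.24, 0.07]))]
    e0 = config.initial_expectancy
    return ParticipantState(
        participant_id=pid,
        generation=generation,
        gender=gender,
        responder_type=rtype,
        expectancy={"Tx": e0, "NT": e0},
        eda_scale=float(np.exp(rng.normal(0.0, config.eda_scale_sd))),
    )


def _trial_timing(config: GeneratorConfig, rng: np.random.Generator):
    """Cue and heat onsets for 12 trials plus the total block duration."""
    cue_onsets, heat_onsets = [], []
    t = 0.0
    for _ in range(12):
        cue_on = t + config.fixation_s
        iti1 = rng.uniform(*config.iti1_range)
        heat_on = cue_on + config.cue_s + config.expectancy_s + iti1
        cue_onsets.append(cue_on)
        heat_onsets.append(heat_on)
        t = heat_on + config.post_heat_s + config.rating_s + config.iti2_s
    return cue_onsets, heat_onsets, t + config.tail_s


def simulate_dyad_block(
    config: GeneratorConfig,
    demonstrator: ParticipantState,
    observer: ParticipantState,
    *,
    block_index: int,
    temperatures_by_cue: dict,
    kappa: float,
    rng: np.random.Generator,
) -> BlockData:
    """Simulate one testing block and update both members' learned expectancies."""
    config.validate()
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    cues = generate_trial_sequence(rng)
    shown = _display_schedule(cues, rng)
    cue_onsets, heat_onsets, duration = _trial_timing(config, rng)

    lam = config.expectancy_learning_rate
    effect = demonstrator.nocebo_effect(config)
    trials: list[TrialEvent] = []
    dem_pain, obs_seen_pain = [], []
    dem_exp_at_cue, obs_exp_at_cue = [], []
    for i, cue in enumerate(cues):
        temp = float(temperatures_by_cue[cue])
        dem_e = demonstrator.expectancy[cue]
        obs_e = observer.expectancy[cue]
        dem_exp_at_cue.append(dem_e)
        obs_exp_at_cue.append(obs_e)
        pain = (
            config.baseline_pain[temp]
            + effect * (cue == "Tx")
            + rng.normal(0.0, config.rating_noise_sd)
        )
        pain = float(np.clip(pain, 0.0, 100.0))
        dem_pain.append(pain)
        # demonstrator learns their own cue-contingent pain
        demonstrator.expectancy[cue] = dem_e + lam * (pain - dem_e)
        # observer learns from the rating when shown, else from the face alone
        expressed = pain if shown[i] else float(
            np.clip(pain + rng.normal(0.0, config.rating_noise_sd), 0.0, 100.0)
        )
        weight = lam if shown[i] else lam * config.face_weight
        observer.expectancy[cue] = obs_e + weight * (expressed - obs_e)
        obs_seen_pain.append(expressed)
        trials.append(
            TrialEvent(
                trial_index=i + 1,
                cue=cue,
                temperature=temp,
                cue_onset=cue_onsets[i],
                heat_onset=heat_onsets[i],
                demonstrator_expectancy=float(
                    np.clip(dem_e + rng.normal(0.0, config.expectancy_noise_sd), 0, 100)
                ),
                observer_expectancy=float(
                    np.clip(obs_e + rng.normal(0.0, config.expectancy_noise_sd), 0, 100)
                ),
                pain_rating=pain,
                rating_shown_to_observer=shown[i],
            )
        )

    eda: dict[str, ContinuousRecording] = {}
    if config.generate_eda:
        fs = config.sampling_rate
        n = int(round(duration * fs))
        kern = scr_kernel(fs)
        shared = _latent_arousal(config, n, duration, kern, rng)
        amp = config.scr_amplitude_by_temperature
        # stimulus-locked SCR magnitudes co-fluctuate across the dyad with
        # correlation kappa (empathic coupling of response size), on top of the
        # kappa-mixed tonic arousal
        z_shared = rng.standard_normal((len(trials), 2))
        mix = np.sqrt(max(0.0, 1.0 - kappa * kappa))
        for role, person, exps, pains, gain in (
            ("demonstrator", demonstrator, dem_exp_at_cue, dem_pain, 1.0),
            ("observer", observer, obs_exp_at_cue, obs_seen_pain, config.vicarious_scr_gain),
        ):
            own = _latent_arousal(config, n, duration, kern, rng)
            tonic = kappa * shared + mix * own
            sig = config.eda_base_level + person.eda_scale * tonic
            z_own = rng.standard_normal((len(trials), 2))
            z = kappa * z_shared + mix * z_own
            events = []
            for i, t in enumerate(trials):
                jitter = float(np.exp(config.scr_amplitude_sd * z[i, 0]))
                a_cue = config.anticipatory_scr_gain * (exps[i] / 100.0) * jitter
                events.append((t.cue_onset, a_cue))
                jitter = float(np.exp(config.scr_amplitude_sd * z[i, 1]))
                base = amp[t.temperature] if role == "demonstrator" else amp[45.0]
                a_heat = gain * base * (pains[i] / 100.0 + 0.2) * jitter
                events.append((t.heat_onset, a_heat))
            _add_events(sig, kern, fs, events)
            if config.measurement_noise_sd > 0:
                sig = sig + rng.normal(0.0, config.measurement_noise_sd, size=n)
            eda[role] = ContinuousRecording(sig, fs, channel=f"eda_{role}")

    fau: dict[str, dict[str, ContinuousRecording]] = {}
    if config.generate_fau:
        fau["demonstrator"] = _fau_channels(
            config, trials, dem_exp_at_cue, dem_pain, config.fau_gain, duration, rng
        )
        fau["observer"] = _fau_channels(
            config, trials, obs_exp_at_cue, obs_seen_pain, config.fau_vicarious_gain,
            duration, rng,
        )

    return BlockData(
        index=block_index,
        demonstrator=demonstrator.participant_id,
        observer=observer.participant_id,
        trials=trials,
        eda=eda,
        fau=fau,
        gender_match=demonstrator.gender == observer.gender,
    )


# weights splitting the composite across AUs; within each max() pair the first
# member dominates, so the composite of the noise-free trace equals the trace
_FAU_WEIGHTS = {
    "AU04_r": 0.25,
    "AU06_r": 0.20,
    "AU07_r": 0.10,
    "AU09_r": 0.15,
    "AU10_r": 0.07,
    "AU12_r": 0.15,
    "AU25_r": 0.25,
    "AU26_r": 0.12,
}


def _fau_channels(
    config: GeneratorConfig,
    trials: list[TrialEvent],
    expectancies: list[float],
    pains: list[float],
    gain: float,
    duration: float,
    rng: np.random.Generator,
) -> dict[str, ContinuousRecording]:
    fs = config.fau_rate
    n = int(round(duration * fs))
    trace = np.zeros(n)
    # facial bump: fast rise, ~2 s fall, peaking ~1 s after onset
    kern = scr_kernel(fs, rise_s=0.3, decay_s=1.2, latency_s=0.3)
    events = []
    for i, t in enumerate(trials):
        events.append((t.cue_onset, gain * 0.3 * expectancies[i] / 100.0))
        events.append((t.heat_onset, gain * pains[i] / 100.0))
    _add_events(trace, kern, fs, events)
    dropped = rng.random(n) < config.fau_dropout
    out = {}
    for au in REQUIRED_AUS:
        vals = np.clip(
            _FAU_WEIGHTS[au] * trace + rng.normal(0.0, config.fau_noise_sd, size=n),
            0.0,
            5.0,
        )
        vals[dropped] = np.nan
        out[au] = ContinuousRecording(vals, fs, channel=au)
    return out


# ---------------------------------------------------------------------------
# chain sessions


def _truncnorm01(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, 0.0, 1.0))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 1.0:
            return float(v)
    return float(np.clip(mean, 0.0, 1.0))  # pragma: no cover


def simulate_chain_session(
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    *,
    session_id: str = "S001",
) -> Session:
    """Simulate one full three-block transmission chain.

    Block 1 pairs temperature with the cue (Tx→54 °C, NT→45 °C); blocks 2 and
    3 deliver 45 °C throughout. Each observer's learned cue expectancies seed
    their own demonstration block. Ground-truth responder types, couplings and
    injected nocebo effects are retained on the session.
    """
    config.validate()
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    people = {
        "G1": _draw_participant(f"{session_id}_G1", "G1", config, rng),
        "G2": _draw_participant(f"{session_id}_G2", "G2", config, rng),
        "G3": _draw_participant(f"{session_id}_G3", "G3", config, rng),
        "G4": _draw_participant(f"{session_id}_G4", "G4", config, rng),
    }
    # G1 demonstrators respond to genuine nociceptive differences
    people["G1"].responder_type = "responder"

    chain = [
        (1, "G1", "G2", {"Tx": 54.0, "NT": 45.0}),
        (2, "G2", "G3", {"Tx": 45.0, "NT": 45.0}),
        (3, "G3", "G4", {"Tx": 45.0, "NT": 45.0}),
    ]
    blocks = []
    kappas = {}
    for index, dem, obs, temps in chain:
        kappa = _truncnorm01(config.kappa, config.kappa_sd, rng)
        kappas[index] = kappa
        blk = simulate_dyad_block(
            config,
            people[dem],
            people[obs],
            block_index=index,
            temperatures_by_cue=temps,
            kappa=kappa,
            rng=rng,
        )
        people[obs].observed_kappa = kappa
        blocks.append(blk)

    manifest = SessionManifest(
        session_id=session_id,
        participants=[
            {"id": p.participant_id, "generation": g, "gender": p.gender}
            for g, p in people.items()
        ],
        blocks=[
            {
                "index": b.index,
                "demonstrator": b.demonstrator,
                "observer": b.observer,
                "gender_match": b.gender_match,
            }
            for b in blocks
        ],
        cue_colour_assignment="green_tx" if rng.random() < 0.5 else "blue_tx",
    )
    ground_truth = {
        "responder_type": {p.participant_id: p.responder_type for p in people.values()},
        "kappa": {int(k): float(v) for k, v in kappas.items()},
        "nocebo_effect": {
            p.participant_id: float(p.nocebo_effect(config))
            for g, p in people.items()
            if g in ("G2", "G3")
        },
    }
    session = Session(manifest=manifest, blocks=blocks, ground_truth=ground_truth)
    session.validate()
    return session


def inject_missingness(
    session: Session,
    config: GeneratorConfig | float,
    seed: int | np.random.Generator,
) -> Session:
    """Delete expectancy ratings uniformly at random at the configured rate.

    Returns a new session; the input is untouched. Each expectancy rating
    (demonstrator and observer, every trial) is removed independently with
    probability ``missing_expectancy_rate``.
    """
    rate = config if isinstance(config, float) else config.missing_expectancy_rate
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missing_expectancy_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    out = copy.deepcopy(session)
    for blk in out.blocks:
        for t in blk.trials:
            if rng.random() < rate:
                t.demonstrator_expectancy = None
            if rng.random() < rate:
                t.observer_expectancy = None
    return out
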
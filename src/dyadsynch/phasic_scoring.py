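"""Per-trial phasic scoring of EDA and facial action-unit recordings.

The electrodermal pipeline follows the standard peak-to-peak convention:
band-pass filter (0.0159–5 Hz), epoch around cue and heat onsets
([−2, +6] s), downsample to 100 Hz, jack-knife outlier exclusion (4.89 SD),
then score each trial as the maximum amplitude over [onset+3 s, onset+6 s]
minus the minimum from that maximum back to the onset, floored at 0.02 µS and
ln(1+x)-transformed.

Facial action units are reduced to a PSPI-style pain-expression composite
``AU04 + max(AU06, AU07) + max(AU09, AU10) + AU12 + max(AU25, AU26)`` and
scored as the maximum composite in the 3 s following cue or heat onset
(epochs [−1, +3] s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from dyadsynch.io_formats import ContinuousRecording, REQUIRED_AUS, Session

__all__ = [
    "EpochSet",
    "PhasicScore",
    "bandpass_filter",
    "epoch_and_downsample",
    "jackknife_outlier_mask",
    "peak_to_peak_score",
    "fau_pain_expression",
    "pain_expression_series",
    "epoch_max_fau",
    "average_trial_pairs",
    "score_session",
]

EDA_WINDOW = (-2.0, 6.0)
FAU_WINDOW = (-1.0, 3.0)
EDA_BAND = (0.0159, 5.0)
JACKKNIFE_SD = 4.89
EDA_FLOOR_US = 0.02


@dataclass
class EpochSet:
    """Trials × samples windows around one event type for one participant."""

    event_type: str  # "cue" or "heat"
    window: tuple  # (start, end) seconds relative to onset
    sampling_rate: float
    data: np.ndarray  # (n_trials, n_samples); excluded rows may be NaN
    excluded: np.ndarray  # bool per trial
    reasons: list = field(default_factory=list)

    @property
    def onset_index(self) -> int:
        """Column holding the sample at the event onset."""
        return int(round(-self.window[0] * self.sampling_rate))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class PhasicScore:
    trial_index: int
    outcome: str  # EDA_cue | EDA_heat | FAU_cue | FAU_heat
    raw: float
    transformed: float
    excluded: bool = False
    reason: str = ""


def bandpass_filter(
    recording: ContinuousRecording,
    low_hz: float,
    high_hz: float,
    *,
    order: int = 2,
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, recording.samples)
    return ContinuousRecording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        t0=recording.t0,
        channel=recording.channel,
    )


def epoch_and_downsample(
    recording: ContinuousRecording,
    events: Sequence[float],
    window: tuple = EDA_WINDOW,
    target_hz: float = 100.0,
    *,
    event_type: str = "event",
) -> EpochSet:
    """Cut windows around event onsets and decimate to ``target_hz``.

    Endpoints are inclusive, so a [−2, +6] s window at 100 Hz yields 801
    samples with the onset at column 200. Decimation picks the nearest source
    sample (the series is low-pass filtered beforehand in the EDA pipeline).
    Events whose window leaves the recording span are flagged excluded.
    """
    n_out = int(round((window[1] - window[0]) * target_hz)) + 1
    offsets = window[0] + np.arange(n_out) / target_hz
    fs = recording.sampling_rate
    data = np.full((len(events), n_out), np.nan)
    excluded = np.zeros(len(events), dtype=bool)
    reasons = [""] * len(events)
    for i, onset in enumerate(events):
        idx = np.round((onset - recording.t0 + offsets) * fs).astype(int)
        if idx[0] < 0 or idx[-1] >= recording.samples.size:
            excluded[i] = True
            reasons[i] = "window outside recording"
            continue
        data[i] = recording.samples[idx]
    return EpochSet(
        event_type=event_type,
        window=tuple(window),
        sampling_rate=target_hz,
        data=data,
        excluded=excluded,
        reasons=reasons,
    )


def jackknife_outlier_mask(epochs: EpochSet, *, n_sd: float = JACKKNIFE_SD) -> np.ndarray:
    """Flag trials containing samples beyond ``n_sd`` leave-one-trial-out SDs.

    For each candidate trial the mean and SD are pooled over all samples of
    the *other* non-excluded trials, so an extreme trial cannot inflate its
    own exclusion threshold. Requires at least 3 usable trials; otherwise no
    exclusions are made and a warning is issued. Returns the new flags only
    (already-excluded trials stay untouched).
    """
    usable = ~epochs.excluded
    flags = np.zeros(epochs.n_trials, dtype=bool)
    idx = np.flatnonzero(usable)
    if idx.size < 3:
        warnings.warn("fewer than 3 usable trials; skipping outlier exclusion")
        return flags
    for t in idx:
        others = epochs.data[idx[idx != t]].ravel()
        mu = others.mean()
        sd = others.std(ddof=1)
        if np.any(np.abs(epochs.data[t] - mu) > n_sd * sd):
            flags[t] = True
    return flags


def apply_exclusions(epochs: EpochSet, flags: np.ndarray, reason: str) -> None:
    for t in np.flatnonzero(flags):
        if not epochs.excluded[t]:
            epochs.excluded[t] = True
            epochs.reasons[t] = reason


def peak_to_peak_score(
    epochs: EpochSet,
    trial: int,
    *,
    search_start_s: float = 3.0,
    floor: float = EDA_FLOOR_US,
    outcome: str = "EDA",
) -> PhasicScore:
    """Peak-to-peak SCR amplitude for one trial.

    ``m`` is the maximum over the closed window [onset+3 s, end of epoch]; at
    its (first) time τ, ``v`` is the minimum over [onset, τ]. ``raw = m − v``
    is non-negative because τ lies in the min window; values below the 0.02 µS
    floor are set to 0 and the transformed score is ln(1 + raw).
    """
    if epochs.excluded[trial]:
        return PhasicScore(trial + 1, outcome, np.nan, np.nan, True,
                           epochs.reasons[trial] or "excluded")
    row = epochs.data[trial]
    on = epochs.onset_index
    start = on + int(round(search_start_s * epochs.sampling_rate))
    seg = row[start:]
    tau = start + int(np.argmax(seg))
    m = row[tau]
    v = row[on : tau + 1].min()
    raw = m - v
    if raw < floor:
        raw = 0.0
    return PhasicScore(trial + 1, outcome, float(raw), float(np.log1p(raw)))


def fau_pain_expression(au_values: Mapping[str, float]) -> float:
    """PSPI-style composite at a single frame; NaN if any required AU is missing."""
    vals = [au_values.get(au, np.nan) for au in REQUIRED_AUS]
    if np.any(np.isnan(vals)):
        return float("nan")
    a04, a06, a07, a09, a10, a12, a25, a26 = vals
    return float(a04 + max(a06, a07) + max(a09, a10) + a12 + max(a25, a26))


def pain_expression_series(
    au_series: Mapping[str, ContinuousRecording]
) -> ContinuousRecording:
    """Frame-wise pain-expression composite; frames with any missing AU are NaN."""
    stack = np.vstack([au_series[au].samples for au in REQUIRED_AUS])
    a04, a06, a07, a09, a10, a12, a25, a26 = stack
    composite = (
        a04
        + np.maximum(a06, a07)
        + np.maximum(a09, a10)
        + a12
        + np.maximum(a25, a26)
    )
    composite[np.isnan(stack).any(axis=0)] = np.nan
    first = au_series[REQUIRED_AUS[0]]
    return ContinuousRecording(
        composite, first.sampling_rate, t0=first.t0, channel="pain_expression"
    )


def epoch_max_fau(
    epochs: EpochSet, trial: int, *, horizon_s: float = 3.0, outcome: str = "FAU"
) -> PhasicScore:
    """Maximum pain expression in the ``(onset, onset+3 s]`` window.

    Frames with failed detections (NaN) are skipped; a trial with no valid
    frame in the window is excluded.
    """
    if epochs.excluded[trial]:
        return PhasicScore(trial + 1, outcome, np.nan, np.nan, True,
                           epochs.reasons[trial] or "excluded")
    on = epochs.onset_index
    end = on + int(round(horizon_s * epochs.sampling_rate))
    seg = epochs.data[trial, on + 1 : end + 1]
    if seg.size == 0 or np.all(np.isnan(seg)):
        return PhasicScore(trial + 1, outcome, np.nan, np.nan, True,
                           "no valid frames in window")
    val = float(np.nanmax(seg))
    return PhasicScore(trial + 1, outcome, val, val)


def average_trial_pairs(
    values: Sequence[float], excluded: Sequence[bool] | None = None
) -> np.ndarray:
    """Collapse 6 per-cue trials into 3 sequential-pair averages.

    A pair with one excluded member takes the surviving value; a pair with
    both excluded yields NaN.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size != 6:
        raise ValueError("expected 6 per-cue trial values")
    mask = np.asarray(excluded, dtype=bool) if excluded is not None else np.isnan(vals)
    mask = mask | np.isnan(vals)
    out = np.empty(3)
    for level in range(3):
        pair = vals[2 * level : 2 * level + 2]
        keep = ~mask[2 * level : 2 * level + 2]
        out[level] = pair[keep].mean() if keep.any() else np.nan
    return out


# ---------------------------------------------------------------------------
# session-level pipeline


def _score_block_eda(rec, trials, event_type, rows, meta):
    onsets = [t.cue_onset if event_type == "cue" else t.heat_onset for t in trials]
    filtered = bandpass_filter(rec, *EDA_BAND)
    epochs = epoch_and_downsample(
        filtered, onsets, EDA_WINDOW, 100.0, event_type=event_type
    )
    apply_exclusions(epochs, jackknife_outlier_mask(epochs), "jackknife outlier")
    outcome = f"EDA_{event_type}"
    for i, t in enumerate(trials):
        s = peak_to_peak_score(epochs, i, outcome=outcome)
        rows.append({**meta, "trial": t.trial_index, "cue": t.cue, "outcome": outcome,
                     "raw": s.raw, "transformed": s.transformed,
                     "excluded": s.excluded, "reason": s.reason})


def _score_block_fau(series, trials, event_type, rows, meta):
    composite = pain_expression_series(series)
    onsets = [t.cue_onset if event_type == "cue" else t.heat_onset for t in trials]
    epochs = epoch_and_downsample(
        composite, onsets, FAU_WINDOW, composite.sampling_rate, event_type=event_type
    )
    outcome = f"FAU_{event_type}"
    for i, t in enumerate(trials):
        s = epoch_max_fau(epochs, i, outcome=outcome)
        rows.append({**meta, "trial": t.trial_index, "cue": t.cue, "outcome": outcome,
                     "raw": s.raw, "transformed": s.transformed,
                     "excluded": s.excluded, "reason": s.reason})


def score_session(session: Session) -> pd.DataFrame:
    """Score every block of a session into a tidy per-trial table.

    Columns: session, block, participant, role, generation, trial, cue,
    outcome, raw, transformed, excluded, reason. EDA outcomes are scored for
    both dyad members; FAU outcomes likewise where AU tables are present.
    """
    rows: list[dict] = []
    gen_of = session.manifest.generation_of
    for blk in session.blocks:
        for role in ("demonstrator", "observer"):
            pid = getattr(blk, role)
            meta = {
                "session": session.manifest.session_id,
                "block": blk.index,
                "participant": pid,
                "role": role,
                "generation": gen_of(pid),
            }
            if role in blk.eda:
                for event_type in ("cue", "heat"):
                    _score_block_eda(blk.eda[role], blk.trials, event_type, rows, meta)
            if role in blk.fau:
                for event_type in ("cue", "heat"):
                    _score_block_fau(blk.fau[role], blk.trials, event_type, rows, meta)
    return pd.DataFrame(rows)
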
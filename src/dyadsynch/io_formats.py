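"""Reading, writing and validation of session data.

A *session* is one testing appointment: a manifest (who sat where in the
transmission chain), and per block a continuous EDA recording for each dyad
member, optional facial action-unit (FAU) intensity tables, and a trial log.

On-disk layout (all plain text):

* manifest — YAML, referencing the per-block files by relative path
* recordings — delimited text with a time column (seconds from block start)
  and one amplitude column per channel
* AU tables — delimited text with a timestamp column and one intensity column
  per action unit, OpenFace 2.x column naming by default (``AU04_r`` ...),
  plus an optional ``success`` column flagging failed face detections
* trial log — delimited text, one row per cue→heat trial

Missing values are empty fields on disk and ``NaN`` (floats) / ``None`` in
memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "ContinuousRecording",
    "TrialEvent",
    "SessionManifest",
    "BlockData",
    "Session",
    "REQUIRED_AUS",
    "read_recording",
    "write_recording",
    "read_au_table",
    "write_au_table",
    "read_trial_log",
    "write_trial_log",
    "load_session",
    "write_session",
]

#: Action units entering the pain-expression composite, OpenFace naming.
REQUIRED_AUS = (
    "AU04_r",
    "AU06_r",
    "AU07_r",
    "AU09_r",
    "AU10_r",
    "AU12_r",
    "AU25_r",
    "AU26_r",
)

GENERATIONS = ("G1", "G2", "G3", "G4")

#: Chain order: block index -> (demonstrator generation, observer generation).
CHAIN_ROLES = {1: ("G1", "G2"), 2: ("G2", "G3"), 3: ("G3", "G4")}


class FormatError(ValueError):
    """A file does not have the expected structure."""


class ValidationError(ValueError):
    """A session violates one or more structural invariants.

    ``errors`` lists every violation found, not just the first.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class ContinuousRecording:
    """A uniformly sampled amplitude series (EDA in µS, or AU intensity)."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise FormatError(f"channel {self.channel!r}: empty or non-1D samples")
        if not self.sampling_rate > 0:
            raise FormatError(f"channel {self.channel!r}: sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class TrialEvent:
    """One cue→heat trial. Times are seconds from block start, 0-based."""

    trial_index: int
    cue: str  # "Tx" or "NT"
    temperature: float  # °C, 45 or 54
    cue_onset: float
    heat_onset: float
    demonstrator_expectancy: float | None = None
    observer_expectancy: float | None = None
    pain_rating: float | None = None
    rating_shown_to_observer: bool = True

    def violations(self) -> list[str]:
        out = []
        tag = f"trial {self.trial_index}"
        if self.cue not in ("Tx", "NT"):
            out.append(f"{tag}: cue {self.cue!r} not in {{Tx, NT}}")
        if self.temperature not in (45.0, 54.0):
            out.append(f"{tag}: temperature {self.temperature} not in {{45, 54}}")
        if not self.heat_onset > self.cue_onset:
            out.append(f"{tag}: heat_onset must follow cue_onset")
        for name in ("demonstrator_expectancy", "observer_expectancy", "pain_rating"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not (0.0 <= v <= 100.0):
                out.append(f"{tag}: {name}={v} outside [0, 100]")
        return out


@dataclass
class SessionManifest:
    """Who occupied which chain position, and which files hold each block."""

    session_id: str
    participants: list[dict]  # {id, generation, gender}
    blocks: list[dict]  # {index, demonstrator, observer, gender_match, files...}
    cue_colour_assignment: str = "green_tx"

    def generation_of(self, participant_id: str) -> str | None:
        for p in self.participants:
            if p["id"] == participant_id:
                return p["generation"]
        return None

    def violations(self) -> list[str]:
        out: list[str] = []
        for p in self.participants:
            if p.get("generation") not in GENERATIONS:
                out.append(
                    f"participant {p.get('id')}: generation {p.get('generation')!r}"
                    f" not in {GENERATIONS}"
                )
        for blk in self.blocks:
            idx = blk.get("index")
            dem, obs = blk.get("demonstrator"), blk.get("observer")
            if dem is None or obs is None:
                out.append(f"block {idx}: needs exactly one demonstrator and one observer")
                continue
            g_dem, g_obs = self.generation_of(dem), self.generation_of(obs)
            if g_dem == "G4":
                out.append(f"block {idx}: G4 ({dem}) can never demonstrate")
            if idx in CHAIN_ROLES:
                want_dem, want_obs = CHAIN_ROLES[idx]
                if g_dem is not None and g_dem != want_dem:
                    out.append(
                        f"block {idx}: demonstrator {dem} is {g_dem}, chain requires {want_dem}"
                    )
                if g_obs is not None and g_obs != want_obs:
                    out.append(
                        f"block {idx}: observer {obs} is {g_obs}, chain requires {want_obs}"
                    )
        return out


@dataclass
class BlockData:
    """All measured data for one testing block."""

    index: int
    demonstrator: str
    observer: str
    trials: list[TrialEvent]
    eda: dict[str, ContinuousRecording] = field(default_factory=dict)  # role -> rec
    fau: dict[str, dict[str, ContinuousRecording]] = field(default_factory=dict)
    gender_match: bool | None = None

    def violations(self) -> list[str]:
        out: list[str] = []
        tag = f"block {self.index}"
        n_tx = sum(t.cue == "Tx" for t in self.trials)
        n_nt = sum(t.cue == "NT" for t in self.trials)
        if (n_tx, n_nt) != (6, 6):
            out.append(f"{tag}: expected 6 Tx and 6 NT trials, got {n_tx} Tx / {n_nt} NT")
        for t in self.trials:
            out.extend(f"{tag}, {v}" for v in t.violations())
        return out


@dataclass
class Session:
    manifest: SessionManifest
    blocks: list[BlockData]
    ground_truth: dict | None = None

    def validate(self) -> None:
        errors = list(self.manifest.violations())
        gen_of = self.manifest.generation_of
        for blk in self.blocks:
            errors.extend(blk.violations())
            # Socially conditioned demonstrators only ever receive the low temperature.
            if gen_of(blk.demonstrator) in ("G2", "G3"):
                for t in blk.trials:
                    if t.temperature != 45.0:
                        errors.append(
                            f"block {blk.index}: {gen_of(blk.demonstrator)} demonstrator"
                            f" trial {t.trial_index} at {t.temperature} °C (must be 45)"
                        )
        if errors:
            raise ValidationError(errors)

    def block(self, index: int) -> BlockData:
        for blk in self.blocks:
            if blk.index == index:
                return blk
        raise KeyError(f"no block {index}")


# ---------------------------------------------------------------------------
# recordings


def _read_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_recording(
    path: str | Path,
    channel: str,
    *,
    delimiter: str = ",",
    time_column: str | None = None,
    rtol: float = 1e-6,
) -> ContinuousRecording:
    """Read one channel of a delimited-text recording.

    The first column (or ``time_column``) holds time in seconds; remaining
    columns are channels named by the header. Timestamps must be strictly
    increasing and uniform to within ``rtol`` of the median step.
    """
    df = _read_table(path, delimiter)
    tcol = time_column or df.columns[0]
    if tcol not in df.columns:
        raise FormatError(f"{path}: no time column {tcol!r}")
    if channel not in df.columns:
        raise FormatError(
            f"{path}: channel {channel!r} not found (have {list(df.columns)})"
        )
    t = df[tcol].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > rtol * step + 1e-12):
        raise FormatError(f"{path}: non-uniform sampling beyond tolerance")
    rate = 1.0 / step
    # snap to integer acquisition rates blurred by decimal timestamps
    if abs(rate - round(rate)) < 1e-6 * rate:
        rate = float(round(rate))
    return ContinuousRecording(
        samples=df[channel].to_numpy(dtype=float),
        sampling_rate=rate,
        t0=float(t[0]),
        channel=channel,
    )


def write_recording(
    path: str | Path,
    recordings: Mapping[str, ContinuousRecording],
    *,
    delimiter: str = ",",
) -> None:
    """Write channels sharing a clock to one delimited file."""
    recs = dict(recordings)
    first = next(iter(recs.values()))
    for r in recs.values():
        if r.samples.size != first.samples.size or r.sampling_rate != first.sampling_rate:
            raise FormatError("channels in one file must share length and rate")
    df = pd.DataFrame({"t": first.times()})
    for name, rec in recs.items():
        df[name] = rec.samples
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# AU tables


def read_au_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    time_column: str = "timestamp",
    success_column: str = "success",
    column_map: Mapping[str, str] | None = None,
    required: Sequence[str] = REQUIRED_AUS,
) -> dict[str, ContinuousRecording]:
    """Read a frame-timestamped AU intensity table into one series per AU.

    Frames with ``success == 0`` are marked missing (NaN) in every series.
    ``column_map`` renames dialects onto the OpenFace names in ``required``.
    """
    df = _read_table(path, delimiter)
    df.columns = [c.strip() for c in df.columns]
    if column_map:
        df = df.rename(columns=dict(column_map))
    if time_column not in df.columns:
        raise FormatError(f"{path}: no timestamp column {time_column!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required AU columns {missing}")
    t = df[time_column].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 frames")
    step = float(np.median(np.diff(t)))
    if step <= 0:
        raise FormatError(f"{path}: non-monotone timestamps")
    frame_rate = 1.0 / step
    if abs(frame_rate - round(frame_rate)) < 1e-6 * frame_rate:
        frame_rate = float(round(frame_rate))
    bad = None
    if success_column in df.columns:
        bad = df[success_column].to_numpy(dtype=float) == 0
    out = {}
    for au in required:
        vals = df[au].to_numpy(dtype=float)
        if bad is not None:
            vals = np.where(bad, np.nan, vals)
        out[au] = ContinuousRecording(
            samples=vals, sampling_rate=frame_rate, t0=float(t[0]), channel=au
        )
    return out


def write_au_table(
    path: str | Path,
    au_series: Mapping[str, ContinuousRecording],
    *,
    delimiter: str = ",",
) -> None:
    first = next(iter(au_series.values()))
    df = pd.DataFrame({"timestamp": first.times()})
    df["success"] = (~np.isnan(first.samples)).astype(int)
    for name, rec in au_series.items():
        # keep a parseable number in failed frames; success=0 masks them on read
        df[name] = np.nan_to_num(rec.samples, nan=0.0)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# trial logs

_TRIAL_COLUMNS = [
    "trial_index",
    "cue",
    "temperature",
    "cue_onset",
    "heat_onset",
    "demonstrator_expectancy",
    "observer_expectancy",
    "pain_rating",
    "rating_shown_to_observer",
]


def read_trial_log(path: str | Path, *, delimiter: str = ",") -> list[TrialEvent]:
    df = _read_table(path, delimiter)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing trial-log columns {missing}")

    def opt(v) -> float | None:
        return None if pd.isna(v) else float(v)

    return [
        TrialEvent(
            trial_index=int(row.trial_index),
            cue=str(row.cue),
            temperature=float(row.temperature),
            cue_onset=float(row.cue_onset),
            heat_onset=float(row.heat_onset),
            demonstrator_expectancy=opt(row.demonstrator_expectancy),
            observer_expectancy=opt(row.observer_expectancy),
            pain_rating=opt(row.pain_rating),
            rating_shown_to_observer=bool(row.rating_shown_to_observer),
        )
        for row in df.itertuples()
    ]


def write_trial_log(
    path: str | Path, trials: Sequence[TrialEvent], *, delimiter: str = ","
) -> None:
    df = pd.DataFrame(
        [
            {
                "trial_index": t.trial_index,
                "cue": t.cue,
                "temperature": t.temperature,
                "cue_onset": t.cue_onset,
                "heat_onset": t.heat_onset,
                "demonstrator_expectancy": t.demonstrator_expectancy,
                "observer_expectancy": t.observer_expectancy,
                "pain_rating": t.pain_rating,
                "rating_shown_to_observer": int(t.rating_shown_to_observer),
            }
            for t in trials
        ],
        columns=_TRIAL_COLUMNS,
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# sessions


def write_session(session: Session, out_dir: str | Path, *, delimiter: str = ",") -> Path:
    """Write a session (manifest + per-block files) under ``out_dir``.

    Returns the manifest path. The written layout round-trips through
    :func:`load_session` to full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "session_id": session.manifest.session_id,
        "cue_colour_assignment": session.manifest.cue_colour_assignment,
        "delimiter": delimiter,
        "participants": session.manifest.participants,
        "blocks": [],
    }
    for blk in session.blocks:
        entry = {
            "index": blk.index,
            "demonstrator": blk.demonstrator,
            "observer": blk.observer,
            "gender_match": blk.gender_match,
            "trials_file": f"block{blk.index}_trials.csv",
        }
        write_trial_log(out / entry["trials_file"], blk.trials, delimiter=delimiter)
        if blk.eda:
            entry["eda_file"] = f"block{blk.index}_eda.csv"
            write_recording(
                out / entry["eda_file"],
                {f"eda_{role}": rec for role, rec in blk.eda.items()},
                delimiter=delimiter,
            )
        if blk.fau:
            entry["fau_files"] = {}
            for role, series in blk.fau.items():
                fname = f"block{blk.index}_fau_{role}.csv"
                entry["fau_files"][role] = fname
                write_au_table(out / fname, series, delimiter=delimiter)
        manifest["blocks"].append(entry)
    path = out / "manifest.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if session.ground_truth is not None:
        with open(out / "ground_truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(session.ground_truth, fh, sort_keys=False)
    return path


def load_session(manifest_path: str | Path, data_dir: str | Path | None = None) -> Session:
    """Load and validate a session.

    Raises :class:`ValidationError` listing *every* violated invariant, or
    :class:`FormatError`/``FileNotFoundError`` for malformed or absent files.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    base = Path(data_dir) if data_dir is not None else manifest_path.parent
    with open(manifest_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    delimiter = raw.get("delimiter", ",")
    manifest = SessionManifest(
        session_id=raw["session_id"],
        participants=raw.get("participants", []),
        blocks=raw.get("blocks", []),
        cue_colour_assignment=raw.get("cue_colour_assignment", "green_tx"),
    )
    blocks = []
    for entry in raw.get("blocks", []):
        trials = read_trial_log(base / entry["trials_file"], delimiter=delimiter)
        eda = {}
        if "eda_file" in entry:
            for role in ("demonstrator", "observer"):
                eda[role] = read_recording(
                    base / entry["eda_file"], f"eda_{role}", delimiter=delimiter
                )
        fau = {}
        for role, fname in entry.get("fau_files", {}).items():
            fau[role] = read_au_table(base / fname, delimiter=delimiter)
        blocks.append(
            BlockData(
                index=int(entry["index"]),
                demonstrator=entry["demonstrator"],
                observer=entry["observer"],
                trials=trials,
                eda=eda,
                fau=fau,
                gender_match=entry.get("gender_match"),
            )
        )
    gt_path = base / "ground_truth.yaml"
    ground_truth = None
    if gt_path.exists():
        with open(gt_path, "r", encoding="utf-8") as fh:
            ground_truth = yaml.safe_load(fh)
    session = Session(manifest=manifest, blocks=blocks, ground_truth=ground_truth)
    session.validate()
    return session
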
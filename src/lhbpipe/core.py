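"""Domain types, trial alignment, and on-disk formats.

Shared substrate for the whole pipeline.  All timestamps are seconds
(float); trial-relative time zero sits at cue (or unpredicted-US) onset and
windows are half-open ``[start, end)``.  Sample-index mapping is
``index = floor((t - t_start) * rate)``.

On-disk dialects (none are dictated by the recording hardware; they are
package conventions):

* schedule      — CSV ``trial_index,cue,onset_s,paired_us`` + JSON sidecar
                  (phase and timing constants).
* spikes        — one spike time per line (text), ``<stem>_events.csv``
                  with foot-shock onsets, ``<stem>.json`` metadata.
* traces /      — long CSV ``trial,t_s,value[,value_dff]`` + JSON sidecar,
  behavior        or an HDF5 file with ``trials x samples`` datasets.
* photometry    — CSV ``bin_start_s,count``, ``<stem>_events.csv`` with
                  ``onset_s,cue,phase``, JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lhbpipe")

# number of significant digits used for float fields in text formats
TEXT_FLOAT_DIGITS = 9
_FMT = f"%.{TEXT_FLOAT_DIGITS}g"


class ParseError(ValueError):
    """A file violated the documented dialect or a type invariant."""


class InsufficientDataError(ValueError):
    """Too little data to compute the requested statistic."""


class ExclusionError(ValueError):
    """Record fails an inclusion rule (e.g. too few stimulation trials)."""


class Cue(str, enum.Enum):
    CS_PLUS = "CS+"
    CS_MINUS = "CS-"
    US_UNPREDICTED = "US"

    @classmethod
    def parse(cls, s: str) -> "Cue":
        try:
            return cls(s)
        except ValueError:
            raise ParseError(f"unknown cue label {s!r}") from None


class Phase(str, enum.Enum):
    HABITUATION = "habituation"
    CONDITIONING = "conditioning"


class Klass(str, enum.Enum):
    """Response class of a neuron to a stimulus (rate or fluorescence)."""

    EXCITED = "excited"
    INHIBITED = "inhibited"
    NON_RESPONSIVE = "nonresponsive"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    trial_index: int
    cue: Cue
    onset_s: float
    paired_us: bool = False


@dataclass
class TrialSchedule:
    """Ordered trial list for one session.

    ``onset_s`` of CS trials marks cue onset; for unpredicted-US trials it
    marks airpuff onset.  ``paired_us`` is true only for CS+ trials in the
    conditioning phase (airpuff follows 0.5 s after cue offset).
    """

    trials: list[Trial]
    phase: Phase
    cs_duration_s: float = 1.0
    us_delay_s: float = 0.5
    us_duration_s: float = 0.5
    iti_bounds_s: tuple[float, float] = (30.0, 45.0)

    def __post_init__(self) -> None:
        onsets = np.array([t.onset_s for t in self.trials])
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ParseError("trial onsets not strictly increasing")
        for t in self.trials:
            if t.paired_us and (
                t.cue is not Cue.CS_PLUS or self.phase is not Phase.CONDITIONING
            ):
                raise ParseError(
                    f"trial {t.trial_index}: paired_us only valid for CS+ "
                    "trials in the conditioning phase"
                )

    @property
    def us_onset_delay_s(self) -> float:
        """Airpuff onset relative to cue onset for paired trials."""
        return self.cs_duration_s + self.us_delay_s

    def onsets(self, cue: Cue | None = None) -> np.ndarray:
        return np.array(
            [t.onset_s for t in self.trials if cue is None or t.cue is cue]
        )

    def cue_counts(self) -> dict[Cue, int]:
        out = {c: 0 for c in Cue}
        for t in self.trials:
            out[t.cue] += 1
        return out

    @property
    def duration_s(self) -> float:
        if not self.trials:
            return 0.0
        return self.trials[-1].onset_s + 20.0


@dataclass
class SpikeTrainRecording:
    """Spike times of one neuron with foot-shock stimulation events."""

    neuron_id: str
    spike_times_s: np.ndarray
    duration_s: float
    fs_event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    fs_duration_s: float = 0.5

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.fs_event_times_s = np.asarray(self.fs_event_times_s, dtype=float)
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ParseError(f"{self.neuron_id}: spike times not sorted")
        if self.spike_times_s.size and (
            self.spike_times_s[0] < 0 or self.spike_times_s[-1] > self.duration_s
        ):
            raise ParseError(
                f"{self.neuron_id}: spike times outside [0, duration]"
            )

    @property
    def n_fs_trials(self) -> int:
        return int(self.fs_event_times_s.size)


@dataclass(frozen=True)
class TrialTraceWindow:
    """Trial time axis: ``pre_s`` of pre-event baseline, ``total_s`` overall."""

    sample_rate_hz: float
    pre_s: float = 5.0
    total_s: float = 15.0

    def __post_init__(self) -> None:
        if not self.pre_s < self.total_s:
            raise ValueError("pre_s must be smaller than total_s")

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.sample_rate_hz))

    @property
    def t0_index(self) -> int:
        return int(round(self.pre_s * self.sample_rate_hz))

    def time_axis(self) -> np.ndarray:
        """Sample times relative to event onset (s)."""
        return (np.arange(self.n_samples) - self.t0_index) / self.sample_rate_hz

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        """Samples with event-relative time in ``[start_s, end_s)``."""
        eps = 1e-9
        lo = int(np.ceil((start_s - eps) * self.sample_rate_hz)) + self.t0_index
        hi = int(np.ceil((end_s - eps) * self.sample_rate_hz)) + self.t0_index
        lo, hi = max(lo, 0), min(hi, self.n_samples)
        if hi <= lo:
            raise ValueError(f"window [{start_s}, {end_s}) holds no samples")
        return slice(lo, hi)


@dataclass
class NeuronTraceSet:
    """Trial-aligned fluorescence of one neuron in one session."""

    neuron_id: str
    session_id: str
    phase: Phase
    window: TrialTraceWindow
    cue_per_trial: list[Cue]
    raw_f: np.ndarray
    dff_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_f = np.atleast_2d(np.asarray(self.raw_f, dtype=float))
        if len(self.cue_per_trial) != self.raw_f.shape[0]:
            raise ParseError(
                f"{self.neuron_id}/{self.session_id}: cue labels "
                f"({len(self.cue_per_trial)}) do not match trial count "
                f"({self.raw_f.shape[0]})"
            )
        if self.raw_f.shape[1] != self.window.n_samples:
            raise ParseError(
                f"{self.neuron_id}/{self.session_id}: rows of length "
                f"{self.raw_f.shape[1]}, window expects {self.window.n_samples}"
            )

    @property
    def n_trials(self) -> int:
        return self.raw_f.shape[0]

    def trial_mask(self, cue: Cue) -> np.ndarray:
        return np.array([c is cue for c in self.cue_per_trial])


@dataclass
class PhotometrySeries:
    """Photon counts per fixed-width bin for one sensor in one animal."""

    animal_id: str
    sensor: str
    counts: np.ndarray
    bin_width_s: float = 0.01
    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_cues: list[Cue] = field(default_factory=list)
    phase_per_event: list[Phase] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        if self.bin_width_s <= 0:
            raise ParseError("bin_width_s must be positive")
        if np.any(self.counts < 0):
            raise ParseError(f"{self.animal_id}: negative photon counts")
        dur = self.counts.size * self.bin_width_s
        if self.event_times_s.size and (
            self.event_times_s.min() < 0 or self.event_times_s.max() > dur
        ):
            raise ParseError(f"{self.animal_id}: events outside series duration")
        if not (
            len(self.event_cues)
            == len(self.phase_per_event)
            == self.event_times_s.size
        ):
            raise ParseError(f"{self.animal_id}: event metadata length mismatch")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.bin_width_s


@dataclass
class BehaviorSession:
    """Per-trial eye-area traces (pixels) for one mouse in one session."""

    mouse_id: str
    phase: Phase
    window: TrialTraceWindow
    cue_per_trial: list[Cue]
    eye_area: np.ndarray
    norm_eye_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eye_area = np.atleast_2d(np.asarray(self.eye_area, dtype=float))
        if self.window.sample_rate_hz != 10:
            raise ParseError("behavior traces are sampled at 10 Hz")
        if len(self.cue_per_trial) != self.eye_area.shape[0]:
            raise ParseError(
                f"{self.mouse_id}: cue labels do not match trial count"
            )

    @property
    def n_trials(self) -> int:
        return self.eye_area.shape[0]

    def trial_mask(self, cue: Cue) -> np.ndarray:
        return np.array([c is cue for c in self.cue_per_trial])


@dataclass
class AnalysisConfig:
    """Analysis-wide constants.

    ``cr_window_s`` covers cue onset to airpuff onset; the imaging baseline
    is the 1.5 s immediately preceding cue onset; fluorescence F0 windows are
    3 s (imaging/photometry) or 5 s (behavior) before the event.
    """

    alpha: float = 0.05
    cr_window_s: tuple[float, float] = (0.0, 1.5)
    imaging_baseline_window_s: float = 1.5
    anticipatory_window_s: tuple[float, float] = (0.0, 1.5)
    us_window_s: tuple[float, float] = (1.5, 2.0)
    dff_f0_window_s: float = 3.0
    behavior_f0_window_s: float = 5.0
    min_trials_per_cue: int = 5
    paired_test: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ParseError(f"{path}: unknown config keys {sorted(bad)}")
        for key in ("cr_window_s", "anticipatory_window_s", "us_window_s"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# trial alignment
# ---------------------------------------------------------------------------


def align_trials(
    series: np.ndarray,
    events_s: Sequence[float],
    window: TrialTraceWindow,
    *,
    series_start_s: float = 0.0,
    on_edge: str = "drop",
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a continuous series into trial rows around each event.

    Row ``t`` covers ``[event_t - pre_s, event_t + total_s - pre_s)``; the
    sample at column ``window.t0_index`` is the first sample at or after the
    event onset.

    Parameters
    ----------
    series
        1-D trace or count series sampled at ``window.sample_rate_hz``.
    events_s
        Event onsets in the same clock as the series.
    series_start_s
        Time of sample 0 of ``series``.
    on_edge
        ``"drop"`` logs and skips events whose window leaves the series;
        ``"error"`` raises instead.

    Returns
    -------
    (matrix, kept)
        ``matrix`` of shape (n_kept, window.n_samples) and the boolean mask
        of events that were kept.
    """
    if on_edge not in ("drop", "error"):
        raise ValueError("on_edge must be 'drop' or 'error'")
    series = np.asarray(series)
    rate = window.sample_rate_hz
    n = window.n_samples
    eps = 1e-9
    rows, kept = [], []
    for ev in np.asarray(events_s, dtype=float):
        start = int(np.floor((ev - window.pre_s - series_start_s) * rate + eps))
        ok = start >= 0 and start + n <= series.size
        if not ok:
            if on_edge == "error":
                raise ValueError(
                    f"event at {ev:.3f} s too close to the series edge"
                )
            logger.warning("dropping event at %.3f s: window leaves series", ev)
            kept.append(False)
            continue
        rows.append(series[start : start + n])
        kept.append(True)
    mat = (
        np.stack(rows)
        if rows
        else np.empty((0, n), dtype=series.dtype)
    )
    return mat, np.asarray(kept, dtype=bool)


def window_mean(trace: np.ndarray, window: TrialTraceWindow,
                span_s: tuple[float, float]) -> float:
    """Mean of a trial-aligned trace over event-relative span [start, end)."""
    return float(np.mean(np.asarray(trace)[window.sample_slice(*span_s)]))


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

_SCHEDULE_COLUMNS = ["trial_index", "cue", "onset_s", "paired_us"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1) + "\n")


def _read_json(path: Path) -> dict:
    if not path.exists():
        raise ParseError(f"{path}: missing metadata sidecar")
    return json.loads(path.read_text())


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_session(record, path: str | Path) -> None:
    """Write any typed record to disk; inverse of :func:`load_session`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(record, TrialSchedule):
        _write_schedule(record, path)
    elif isinstance(record, SpikeTrainRecording):
        _write_spikes(record, path)
    elif isinstance(record, (NeuronTraceSet, BehaviorSession)):
        _write_traces(record, path)
    elif isinstance(record, PhotometrySeries):
        _write_photometry(record, path)
    else:
        raise TypeError(f"cannot serialize {type(record).__name__}")


def load_session(path: str | Path, kind: str):
    """Load a typed record (``kind`` in spikes/traces/photometry/behavior/schedule)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    loaders = {
        "schedule": _load_schedule,
        "spikes": _load_spikes,
        "traces": _load_traces,
        "behavior": _load_behavior,
        "photometry": _load_photometry,
    }
    if kind not in loaders:
        raise ValueError(f"unknown kind {kind!r}")
    return loaders[kind](path)


def _write_schedule(s: TrialSchedule, path: Path) -> None:
    df = pd.DataFrame(
        [(t.trial_index, t.cue.value, t.onset_s, int(t.paired_us))
         for t in s.trials],
        columns=_SCHEDULE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FMT)
    _write_json(_sidecar(path), {
        "phase": s.phase.value,
        "cs_duration_s": s.cs_duration_s,
        "us_delay_s": s.us_delay_s,
        "us_duration_s": s.us_duration_s,
        "iti_bounds_s": list(s.iti_bounds_s),
    })


def _load_schedule(path: Path) -> TrialSchedule:
    df = pd.read_csv(path)
    if list(df.columns) != _SCHEDULE_COLUMNS:
        raise ParseError(f"{path}: malformed header {list(df.columns)}")
    meta = _read_json(_sidecar(path))
    trials = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            trials.append(Trial(int(row.trial_index), Cue.parse(row.cue),
                                float(row.onset_s), bool(row.paired_us)))
        except (ParseError, ValueError) as err:
            raise ParseError(f"{path}, data row {i + 1}: {err}") from None
    try:
        return TrialSchedule(
            trials=trials,
            phase=Phase(meta["phase"]),
            cs_duration_s=meta["cs_duration_s"],
            us_delay_s=meta["us_delay_s"],
            us_duration_s=meta["us_duration_s"],
            iti_bounds_s=tuple(meta["iti_bounds_s"]),
        )
    except ParseError as err:
        raise ParseError(f"{path}: {err}") from None


def _write_spikes(rec: SpikeTrainRecording, path: Path) -> None:
    np.savetxt(path, rec.spike_times_s, fmt=_FMT)
    pd.DataFrame({"onset_s": rec.fs_event_times_s}).to_csv(
        _events_path(path), index=False, float_format=_FMT)
    _write_json(_sidecar(path), {
        "neuron_id": rec.neuron_id,
        "duration_s": rec.duration_s,
        "fs_duration_s": rec.fs_duration_s,
    })


def _load_spikes(path: Path) -> SpikeTrainRecording:
    times = np.loadtxt(path, ndmin=1) if path.stat().st_size else np.empty(0)
    meta = _read_json(_sidecar(path))
    ev_path = _events_path(path)
    events = (
        pd.read_csv(ev_path)["onset_s"].to_numpy()
        if ev_path.exists()
        else np.empty(0)
    )
    if np.any(np.diff(times) < 0):
        bad = int(np.argmax(np.diff(times) < 0)) + 2
        raise ParseError(f"{path}, line {bad}: spike times not sorted")
    return SpikeTrainRecording(
        neuron_id=meta["neuron_id"],
        spike_times_s=times,
        duration_s=meta["duration_s"],
        fs_event_times_s=events,
        fs_duration_s=meta["fs_duration_s"],
    )


def _traces_meta(rec) -> dict:
    imaging = isinstance(rec, NeuronTraceSet)
    meta = {
        "kind": "traces" if imaging else "behavior",
        "phase": rec.phase.value,
        "sample_rate_hz": rec.window.sample_rate_hz,
        "pre_s": rec.window.pre_s,
        "total_s": rec.window.total_s,
        "cue_per_trial": [c.value for c in rec.cue_per_trial],
    }
    if imaging:
        meta |= {"neuron_id": rec.neuron_id, "session_id": rec.session_id}
    else:
        meta |= {"mouse_id": rec.mouse_id}
    return meta


def _write_traces(rec, path: Path) -> None:
    primary = rec.raw_f if isinstance(rec, NeuronTraceSet) else rec.eye_area
    secondary = rec.dff_pct if isinstance(rec, NeuronTraceSet) else rec.norm_eye_pct
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("primary", data=primary)
            if secondary is not None:
                fh.create_dataset("secondary", data=secondary)
            fh.attrs["meta"] = json.dumps(_traces_meta(rec))
        return
    t = rec.window.time_axis()
    n_tr, n_s = primary.shape
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(n_tr), n_s),
        "t_s": np.tile(t, n_tr),
        "value": primary.ravel(),
    })
    if secondary is not None:
        df["value_norm"] = secondary.ravel()
    df.to_csv(path, index=False, float_format=_FMT)
    _write_json(_sidecar(path), _traces_meta(rec))


def _read_trace_payload(path: Path):
    if _is_hdf5(path):
        import h5py

        with h5py.File(path, "r") as fh:
            meta = json.loads(fh.attrs["meta"])
            primary = fh["primary"][()]
            secondary = fh["secondary"][()] if "secondary" in fh else None
        return meta, primary, secondary
    df = pd.read_csv(path)
    if not {"trial", "t_s", "value"} <= set(df.columns):
        raise ParseError(f"{path}: malformed header {list(df.columns)}")
    meta = _read_json(_sidecar(path))
    n_tr = int(df["trial"].max()) + 1 if len(df) else 0
    primary = df["value"].to_numpy().reshape(n_tr, -1)
    secondary = (
        df["value_norm"].to_numpy().reshape(n_tr, -1)
        if "value_norm" in df.columns
        else None
    )
    return meta, primary, secondary


def _load_traces(path: Path) -> NeuronTraceSet:
    meta, primary, secondary = _read_trace_payload(path)
    window = TrialTraceWindow(meta["sample_rate_hz"], meta["pre_s"], meta["total_s"])
    try:
        return NeuronTraceSet(
            neuron_id=meta["neuron_id"],
            session_id=meta["session_id"],
            phase=Phase(meta["phase"]),
            window=window,
            cue_per_trial=[Cue.parse(c) for c in meta["cue_per_trial"]],
            raw_f=primary,
            dff_pct=secondary,
        )
    except (KeyError, ParseError) as err:
        raise ParseError(f"{path}: {err}") from None


def _load_behavior(path: Path) -> BehaviorSession:
    meta, primary, secondary = _read_trace_payload(path)
    window = TrialTraceWindow(meta["sample_rate_hz"], meta["pre_s"], meta["total_s"])
    try:
        return BehaviorSession(
            mouse_id=meta["mouse_id"],
            phase=Phase(meta["phase"]),
            window=window,
            cue_per_trial=[Cue.parse(c) for c in meta["cue_per_trial"]],
            eye_area=primary,
            norm_eye_pct=secondary,
        )
    except (KeyError, ParseError) as err:
        raise ParseError(f"{path}: {err}") from None


def _write_photometry(rec: PhotometrySeries, path: Path) -> None:
    starts = np.arange(rec.counts.size) * rec.bin_width_s
    pd.DataFrame({"bin_start_s": starts, "count": rec.counts}).to_csv(
        path, index=False, float_format=_FMT)
    pd.DataFrame({
        "onset_s": rec.event_times_s,
        "cue": [c.value for c in rec.event_cues],
        "phase": [p.value for p in rec.phase_per_event],
    }).to_csv(_events_path(path), index=False, float_format=_FMT)
    _write_json(_sidecar(path), {
        "animal_id": rec.animal_id,
        "sensor": rec.sensor,
        "bin_width_s": rec.bin_width_s,
    })


def _load_photometry(path: Path) -> PhotometrySeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["bin_start_s", "count"]:
        raise ParseError(f"{path}: malformed header {list(df.columns)}")
    meta = _read_json(_sidecar(path))
    ev = pd.read_csv(_events_path(path)) if _events_path(path).exists() else None
    try:
        return PhotometrySeries(
            animal_id=meta["animal_id"],
            sensor=meta["sensor"],
            counts=df["count"].to_numpy(),
            bin_width_s=meta["bin_width_s"],
            event_times_s=ev["onset_s"].to_numpy() if ev is not None else np.empty(0),
            event_cues=[Cue.parse(c) for c in ev["cue"]] if ev is not None else [],
            phase_per_event=[Phase(p) for p in ev["phase"]] if ev is not None else [],
        )
    except (KeyError, ParseError) as err:
        raise ParseError(f"{path}: {err}") from None
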
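"""Insole pressure streams, 8-step calibration and min-max normalization.

The insole carries 8 force-sensing resistors sampled at 200 Hz.  Raw
readings are in mbar within the device range [250, 7000].  Before the games
a participant performs 8 standardized calibration steps (minimal and
maximal pressure at all positions, 5 s of standing, 5 s single-leg balance
per side); the per-sensor pressure bounds derived from those windows map
every subsequent reading onto [0, 1].

Sensor-to-region convention (the hardware names 7 regions for 8 sensors):
``heel_med, heel_lat, arch, met1, met3, met5, hallux, toes``.  The
*forefoot aggregate* — the control signal of most games — is the mean of
the three metatarsal sensors; the heel aggregate is the mean of the two
heel sensors.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, SessionParseError
from .events import GameEvent, SessionLog

logger = logging.getLogger(__name__)

CHANNELS = ("heel_med", "heel_lat", "arch", "met1", "met3", "met5", "hallux", "toes")
FOREFOOT_CHANNELS = ("met1", "met3", "met5")
HEEL_CHANNELS = ("heel_med", "heel_lat")
N_CHANNELS = 8

DEVICE_MIN_MBAR = 250.0
DEVICE_MAX_MBAR = 7000.0
DEFAULT_RATE_HZ = 200.0

_FOREFOOT_IDX = tuple(CHANNELS.index(c) for c in FOREFOOT_CHANNELS)
_HEEL_IDX = tuple(CHANNELS.index(c) for c in HEEL_CHANNELS)

_CSV_HEADER = [
    "t_s", "foot", "s_heel_med", "s_heel_lat", "s_arch",
    "s_met1", "s_met3", "s_met5", "s_hallux", "s_toes",
]


@dataclass
class PressureStream:
    """Uniformly sampled 8-channel pressure time series for one foot.

    ``values`` has shape (n_frames, 8) in channel order ``CHANNELS``;
    units are mbar for raw streams and dimensionless [0, 1] after
    normalization.
    """

    values: np.ndarray
    rate: float = DEFAULT_RATE_HZ
    foot: str = "left"
    t0: float = 0.0
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"pressure stream needs shape (n, {N_CHANNELS}), "
                f"got {self.values.shape}"
            )
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be left/right, got {self.foot!r}")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    @property
    def duration(self) -> float:
        return len(self) / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNELS.index(name)]

    def region(self, name: str) -> np.ndarray:
        """Aggregate signal for 'forefoot' or 'heel' (cached; streams are
        treated as immutable once built)."""
        cache = self.__dict__.setdefault("_region_cache", {})
        if name not in cache:
            if name == "forefoot":
                cache[name] = self.values[:, _FOREFOOT_IDX].mean(axis=1)
            elif name == "heel":
                cache[name] = self.values[:, _HEEL_IDX].mean(axis=1)
            else:
                raise ValueError(f"unknown region {name!r}")
        return cache[name]

    def window(self, t_start: float, t_end: float) -> np.ndarray:
        """Frames with t in [t_start, t_end) relative to the stream clock."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.rate - 1e-9)))
        i1 = min(len(self), int(np.ceil((t_end - self.t0) * self.rate - 1e-9)))
        return self.values[i0:i1]

    def index_at(self, t: float) -> int:
        return int(np.clip(round((t - self.t0) * self.rate), 0, len(self) - 1))


@dataclass(frozen=True)
class StepWindow:
    """Annotation of one calibration step on the calibration stream."""

    kind: str  # 'min' | 'max' | 'stand' | 'balance_left' | 'balance_right'
    t_start: float
    t_end: float


CALIBRATION_STEP_KINDS = ("min", "max", "stand", "balance_left", "balance_right")


@dataclass
class CalibrationProfile:
    """Per-foot, per-sensor pressure bounds (mbar)."""

    p_min: dict[str, np.ndarray] = field(default_factory=dict)
    p_max: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for foot in self.p_min:
            bad = np.flatnonzero(self.p_max[foot] <= self.p_min[foot])
            if bad.size:
                names = ", ".join(CHANNELS[i] for i in bad)
                raise CalibrationError(
                    f"degenerate calibration for {foot} sensor(s) {names}: "
                    "p_max does not exceed p_min"
                )

    @classmethod
    def identity(cls, feet=("left", "right")) -> "CalibrationProfile":
        """Unit profile (p_min 0, p_max 1): normalization is the identity
        on already-normalized data."""
        return cls(
            p_min={f: np.zeros(N_CHANNELS) for f in feet},
            p_max={f: np.ones(N_CHANNELS) for f in feet},
        )

    def to_dict(self) -> dict:
        return {
            "p_min": {f: list(v) for f, v in self.p_min.items()},
            "p_max": {f: list(v) for f, v in self.p_max.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        return cls(
            p_min={f: np.asarray(v, float) for f, v in d["p_min"].items()},
            p_max={f: np.asarray(v, float) for f, v in d["p_max"].items()},
        )


# percentiles used instead of raw extremes: single-frame spikes in the
# calibration windows must not define the dynamic range
CALIB_LOW_PCTL = 5.0
CALIB_HIGH_PCTL = 95.0


def run_calibration(
    calib_streams: dict[str, PressureStream],
    step_annotations: list[StepWindow],
) -> CalibrationProfile:
    """Derive a calibration profile from the 8-step calibration recording.

    p_min is the per-sensor 5th percentile over all minimal-pressure
    windows; p_max the 95th percentile over all maximal-pressure windows.
    Raises :class:`CalibrationError` naming the sensor if any sensor's
    bounds are degenerate.
    """
    kinds = {w.kind for w in step_annotations}
    unknown = kinds - set(CALIBRATION_STEP_KINDS)
    if unknown:
        raise CalibrationError(f"unknown calibration step kind(s): {sorted(unknown)}")
    if "min" not in kinds or "max" not in kinds:
        raise CalibrationError("annotations must include min and max pressure steps")

    profile = CalibrationProfile()
    for foot, stream in calib_streams.items():
        lo_frames = [stream.window(w.t_start, w.t_end)
                     for w in step_annotations if w.kind == "min"]
        hi_frames = [stream.window(w.t_start, w.t_end)
                     for w in step_annotations if w.kind == "max"]
        lo = np.concatenate(lo_frames, axis=0)
        hi = np.concatenate(hi_frames, axis=0)
        if lo.size == 0 or hi.size == 0:
            raise CalibrationError(f"empty calibration window for foot {foot}")
        profile.p_min[foot] = np.percentile(lo, CALIB_LOW_PCTL, axis=0)
        profile.p_max[foot] = np.percentile(hi, CALIB_HIGH_PCTL, axis=0)
    profile.validate()
    return profile


def normalize(stream: PressureStream, profile: CalibrationProfile) -> PressureStream:
    """Min-max normalize a raw stream to [0, 1] using the profile.

    Raw values outside the device range are clipped first (a warning with
    the clip count is logged); output is clamped to [0, 1] so out-of-profile
    pressures cannot escape the unit interval.  Timestamps are unchanged.
    """
    if stream.foot not in profile.p_min:
        raise CalibrationError(f"no calibration profile for foot {stream.foot!r}")
    raw = stream.values
    if not stream.normalized:
        n_out = int(np.sum((raw < DEVICE_MIN_MBAR) | (raw > DEVICE_MAX_MBAR)))
        if n_out:
            logger.warning(
                "%d raw sample(s) outside device range [%g, %g] mbar clipped",
                n_out, DEVICE_MIN_MBAR, DEVICE_MAX_MBAR,
            )
            raw = np.clip(raw, DEVICE_MIN_MBAR, DEVICE_MAX_MBAR)
    lo = profile.p_min[stream.foot]
    hi = profile.p_max[stream.foot]
    out = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    return PressureStream(out, rate=stream.rate, foot=stream.foot,
                          t0=stream.t0, normalized=True)


def denormalize(stream: PressureStream, profile: CalibrationProfile) -> PressureStream:
    """Inverse of :func:`normalize` for synthetic raw-stream generation."""
    lo = profile.p_min[stream.foot]
    hi = profile.p_max[stream.foot]
    raw = lo + stream.values * (hi - lo)
    return PressureStream(raw, rate=stream.rate, foot=stream.foot,
                          t0=stream.t0, normalized=False)


# ---------------------------------------------------------------------------
# session files: one pressure CSV per foot, a metadata JSON and a JSONL log

def write_session(path: str,
                  streams: dict[str, PressureStream],
                  log: SessionLog,
                  metadata: dict | None = None,
                  profile: CalibrationProfile | None = None) -> None:
    os.makedirs(path, exist_ok=True)
    for foot, stream in streams.items():
        with open(os.path.join(path, f"pressure_{foot}.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_HEADER)
            for t, row in zip(stream.times, stream.values):
                w.writerow([f"{t:.6f}", foot] + [f"{v:.6f}" for v in row])
    with open(os.path.join(path, "session_log.jsonl"), "w") as fh:
        for ev in log:
            fh.write(ev.to_json() + "\n")
    meta = dict(metadata or {})
    meta.setdefault("rate_hz", next(iter(streams.values())).rate if streams else
                    DEFAULT_RATE_HZ)
    meta["normalized"] = {f: s.normalized for f, s in streams.items()}
    if profile is not None:
        meta["calibration"] = profile.to_dict()
    with open(os.path.join(path, "session.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_session(path: str):
    """Read a session directory -> (streams per foot, SessionLog, metadata).

    Raises :class:`SessionParseError` with a line number on malformed rows,
    wrong channel counts or non-monotone timestamps.
    """
    with open(os.path.join(path, "session.json")) as fh:
        meta = json.load(fh)
    rate = float(meta.get("rate_hz", DEFAULT_RATE_HZ))
    streams: dict[str, PressureStream] = {}
    for foot in ("left", "right"):
        fpath = os.path.join(path, f"pressure_{foot}.csv")
        if not os.path.exists(fpath):
            continue
        times, rows = [], []
        with open(fpath, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != _CSV_HEADER:
                raise SessionParseError(
                    f"bad header in {fpath}: expected {_CSV_HEADER}", line=1)
            for i, row in enumerate(reader, start=2):
                if len(row) != len(_CSV_HEADER):
                    raise SessionParseError(
                        f"expected {len(_CSV_HEADER)} columns, got {len(row)}",
                        line=i)
                try:
                    times.append(float(row[0]))
                    rows.append([float(v) for v in row[2:]])
                except ValueError as exc:
                    raise SessionParseError(str(exc), line=i) from exc
        t = np.asarray(times)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 3  # +2 header/1-based, +1 next row
            raise SessionParseError("non-monotone timestamps", line=bad)
        streams[foot] = PressureStream(
            np.asarray(rows), rate=rate, foot=foot,
            t0=float(t[0]) if len(t) else 0.0,
            normalized=bool(meta.get("normalized", {}).get(foot, False)),
        )
    log = SessionLog()
    lpath = os.path.join(path, "session_log.jsonl")
    if os.path.exists(lpath):
        with open(lpath) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    log.events.append(GameEvent.from_json(line))
                except (json.JSONDecodeError, KeyError) as exc:
                    raise SessionParseError(str(exc), line=i) from exc
    return streams, log, meta
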
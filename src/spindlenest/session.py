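"""Session container and directory-bundle I/O.

A session is a set of region-labelled LFP channels (600 Hz), per-unit spike
timestamp lists, and an optional 30 Hz position track.  The native on-disk
format is a plain directory bundle:

``session.json``
    ``{"session_id", "fs_lfp", "t0", "channels": {region: filename}, ...}``
``<region>.f32`` / ``<region>.csv``
    one LFP channel, float32 little-endian binary or a single-column CSV
``spikes.csv``
    columns ``unit_id, region, kind, time_s``
``position.csv`` (optional)
    columns ``t_s, x_cm, y_cm`` (missing samples as empty/NaN)

Times are seconds (floats); intervals throughout the package are half-open
``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A session bundle or result violated its type invariants."""


@dataclass
class SpikeTrain:
    """Spike timestamps of one isolated unit (or one electrode's MUA)."""

    unit_id: str
    region: str
    times: np.ndarray
    kind: str = "single-unit"  # or "multi-unit"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: times must be 1-D")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if self.kind not in ("single-unit", "multi-unit"):
            raise ValidationError(f"unit {self.unit_id}: bad kind {self.kind!r}")

    @property
    def n_spikes(self) -> int:
        return len(self.times)


@dataclass
class PositionTrack:
    """2-D head position at 30 samples/s; NaN in x/y flags missing samples."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("position arrays must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("position timestamps must be increasing")

    @property
    def missing(self) -> np.ndarray:
        return ~(np.isfinite(self.x) & np.isfinite(self.y))


@dataclass
class Session:
    """One recording session: LFP channels, spike trains, position."""

    session_id: str
    fs_lfp: float
    lfp: dict[str, np.ndarray]
    units: list[SpikeTrain] = field(default_factory=list)
    position: PositionTrack | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.fs_lfp > 0:
            raise ValidationError("fs_lfp must be positive")
        if not np.isfinite(self.t0):
            raise ValidationError("t0 must be finite")
        lengths = {region: len(ch) for region, ch in self.lfp.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"LFP channels differ in length: {lengths}")
        lo, hi = self.extent
        for u in self.units:
            if u.n_spikes and (u.times[0] < lo or u.times[-1] > hi):
                raise ValidationError(
                    f"unit {u.unit_id}: spike times outside session extent "
                    f"[{lo}, {hi})"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.lfp.values()))) if self.lfp else 0

    @property
    def extent(self) -> tuple[float, float]:
        """Half-open [t0, t0 + n/fs) time span covered by the LFP."""
        return self.t0, self.t0 + self.n_samples / self.fs_lfp

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_lfp

    def lfp_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_lfp


def load_session(path: str | Path) -> Session:
    """Load and validate a session bundle directory.

    Raises ``FileNotFoundError`` for missing files and ``ValidationError`` for
    schema or invariant violations; channels are never silently dropped.
    """
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no session.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in ("session_id", "fs_lfp", "channels"):
        if key not in meta:
            raise ValidationError(f"session.json missing key {key!r}")
    fs = float(meta["fs_lfp"])
    lfp: dict[str, np.ndarray] = {}
    for region, fname in meta["channels"].items():
        fpath = path / fname
        if not fpath.exists():
            raise FileNotFoundError(f"channel file {fpath} referenced but absent")
        if fpath.suffix == ".csv":
            lfp[region] = pd.read_csv(fpath, header=None).to_numpy().ravel().astype(float)
        else:
            lfp[region] = np.fromfile(fpath, dtype="<f4").astype(float)

    units: list[SpikeTrain] = []
    spikes_path = path / "spikes.csv"
    if spikes_path.exists():
        df = pd.read_csv(spikes_path, float_precision="round_trip")
        for col in ("unit_id", "region", "kind", "time_s"):
            if col not in df.columns:
                raise ValidationError(f"spikes.csv missing column {col!r}")
        for unit_id, grp in df.groupby("unit_id", sort=False):
            units.append(SpikeTrain(
                unit_id=str(unit_id),
                region=str(grp["region"].iloc[0]),
                kind=str(grp["kind"].iloc[0]),
                times=grp["time_s"].to_numpy(),
            ))

    position = None
    pos_path = path / "position.csv"
    if pos_path.exists():
        df = pd.read_csv(pos_path, float_precision="round_trip")
        position = PositionTrack(t=df["t_s"].to_numpy(),
                                 x=df["x_cm"].to_numpy(),
                                 y=df["y_cm"].to_numpy())

    return Session(session_id=str(meta["session_id"]), fs_lfp=fs, lfp=lfp,
                   units=units, position=position,
                   t0=float(meta.get("t0", 0.0)))


def save_session(session: Session, path: str | Path) -> None:
    """Write a session bundle; float32 binary channels round-trip bit-exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    channels = {}
    for region, ch in session.lfp.items():
        fname = f"{region}.f32"
        np.asarray(ch, dtype="<f4").tofile(path / fname)
        channels[region] = fname
    meta = {
        "session_id": session.session_id,
        "fs_lfp": session.fs_lfp,
        "t0": session.t0,
        "channels": channels,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2))
    rows = []
    for u in session.units:
        for t in u.times:
            rows.append((u.unit_id, u.region, u.kind, t))
    pd.DataFrame(rows, columns=["unit_id", "region", "kind", "time_s"]).to_csv(
        path / "spikes.csv", index=False, float_format="%.17g"
    )
    if session.position is not None:
        pd.DataFrame({
            "t_s": session.position.t,
            "x_cm": session.position.x,
            "y_cm": session.position.y,
        }).to_csv(path / "position.csv", index=False, float_format="%.17g")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return [None if (isinstance(v, float) and not np.isfinite(v)) else v
                for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_results(result, path: str | Path) -> list[Path]:
    """Save an analysis result to disk and return the written file paths.

    Tabular results (event series, spindle cycles, correlograms, state
    intervals) become CSVs with documented columns; everything else that is a
    dataclass becomes JSON.  See each result type for its column schema.
    """
    # local imports to avoid module cycles; classes imported directly because
    # the package namespace re-exports same-named functions
    from .correlogram import Correlogram
    from .events import EventSeries, SpindleCycle
    from .state import StateIntervals

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(result, EventSeries):
        df = pd.DataFrame({
            "time_s": result.times,
            "peak_amplitude": result.amplitudes,
            "duration_s": (result.durations_s if result.durations_s is not None
                           else np.full(len(result.times), np.nan)),
        })
        df.to_csv(path.with_suffix(".csv"), index=False)
        written.append(path.with_suffix(".csv"))
    elif isinstance(result, list) and result and isinstance(result[0], SpindleCycle):
        df = pd.DataFrame([{
            "trough_t": c.trough_t, "start_t": c.start_t, "end_t": c.end_t,
            "duration_s": c.duration_s, "p2t_amplitude": c.p2t_amplitude,
            "ripple_power": c.ripple_power,
            **{f"class_{k}": v for k, v in c.class_labels.items()},
        } for c in result])
        df.to_csv(path.with_suffix(".csv"), index=False)
        written.append(path.with_suffix(".csv"))
    elif isinstance(result, StateIntervals):
        rows = ([(s, e, "rest") for s, e in result.rest]
                + [(s, e, "wake") for s, e in result.wake])
        pd.DataFrame(sorted(rows), columns=["start_s", "end_s", "label"]).to_csv(
            path.with_suffix(".csv"), index=False)
        written.append(path.with_suffix(".csv"))
    elif isinstance(result, Correlogram):
        df = pd.DataFrame({"lag_s": result.lags, "count": result.counts,
                           "rate": result.rate})
        if result.z is not None:
            df["z"] = result.z
        df.to_csv(path.with_suffix(".csv"), index=False)
        written.append(path.with_suffix(".csv"))
    elif dataclasses.is_dataclass(result) and not isinstance(result, type):
        payload = _jsonify(dataclasses.asdict(result))
        path.with_suffix(".json").write_text(json.dumps(payload, indent=2))
        written.append(path.with_suffix(".json"))
    else:
        raise TypeError(f"unregistered result type: {type(result).__name__}")
    return written


def write_run_log(path: str | Path, params: dict) -> Path:
    """Record all parameters (including seeds) of a run as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(params), indent=2, sort_keys=True))
    return path
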
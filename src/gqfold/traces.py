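"""Trace containers, FRET-efficiency computation, photobleach detection,
analysis-window selection and trace I/O (per-molecule TSV + JSON manifest,
or a single HDF5 container).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trace",
    "FretSeries",
    "compute_fret",
    "detect_bleach",
    "select_window",
    "molecule_fret",
    "read_traces",
    "write_traces",
    "TraceSchemaError",
]

#: frames whose total intensity falls below this fraction of the molecule's
#: median total are marked invalid rather than divided
VALID_FLOOR_FRACTION = 0.10

#: molecules with fewer usable frames than this are flagged excluded
MIN_USABLE_FRAMES = 20

#: per-molecule snapshot FRET = mean over this many leading valid frames
SNAPSHOT_FRAMES = 10


class TraceSchemaError(ValueError):
    """Raised when a trace file or manifest violates the on-disk schema."""


@dataclass
class Trace:
    """One molecule's donor/acceptor intensity time series."""

    molecule_id: str
    dt: float
    donor: np.ndarray
    acceptor: np.ndarray
    state_path: np.ndarray | None = None  # ground truth, simulation only
    flow_onset_frame: int | None = None
    bleach_frame: int | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor series must have equal length")
        if self.donor.ndim != 1 or self.donor.size == 0:
            raise ValueError("intensity series must be non-empty 1-D arrays")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class FretSeries:
    """Per-frame FRET efficiency with a validity mask and analysis window."""

    molecule_id: str
    dt: float
    values: np.ndarray
    valid: np.ndarray
    window: tuple[int, int] = (0, 0)
    excluded: bool = False

    def windowed(self) -> np.ndarray:
        """Valid FRET values within the analysis window."""
        lo, hi = self.window
        v = self.values[lo:hi]
        return v[self.valid[lo:hi]]


def compute_fret(
    donor: np.ndarray,
    acceptor: np.ndarray,
    *,
    molecule_id: str = "",
    dt: float = 0.1,
    floor_fraction: float = VALID_FLOOR_FRACTION,
) -> FretSeries:
    """FRET efficiency E = acceptor / (donor + acceptor), per frame.

    Frames whose total intensity is below ``floor_fraction`` of the median
    total are flagged invalid (E set to NaN) instead of being divided.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor series must have equal length")
    if donor.size == 0:
        raise ValueError("empty intensity series")
    total = donor + acceptor
    floor = floor_fraction * np.median(total)
    valid = total > max(floor, 0.0)
    values = np.full(donor.shape, np.nan)
    np.divide(acceptor, total, out=values, where=valid)
    return FretSeries(
        molecule_id=molecule_id,
        dt=dt,
        values=values,
        valid=valid,
        window=(0, donor.size),
    )


def detect_bleach(
    trace: Trace,
    threshold_fraction: float = 0.3,
    min_below: int = 5,
) -> int | None:
    """First frame where total intensity drops below ``threshold_fraction``
    of the trace's live intensity level and stays below for at least
    ``min_below`` frames.  Returns None when no such frame exists.

    The live level is the 99th percentile of total intensity: a median (or
    low percentile) collapses to the post-bleach background whenever most
    of the trace is bleached, hiding early bleach events.
    """
    total = trace.total
    threshold = threshold_fraction * np.percentile(total, 99)
    below = total < threshold
    if not below.any():
        return None
    # run-length scan over the boolean mask
    n = below.size
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_below or j == n:
                return i
            i = j
        else:
            i += 1
    return None


def select_window(trace: Trace, min_frames: int = MIN_USABLE_FRAMES) -> FretSeries:
    """FRET restricted to the pre-bleach window; short windows are excluded."""
    series = compute_fret(
        trace.donor, trace.acceptor, molecule_id=trace.molecule_id, dt=trace.dt
    )
    bleach = detect_bleach(trace)
    end = trace.n_frames if bleach is None else bleach
    series.window = (0, end)
    usable = int(series.valid[:end].sum())
    series.excluded = usable < min_frames
    return series


def molecule_fret(series: FretSeries, n_frames: int = SNAPSHOT_FRAMES) -> float:
    """Per-molecule snapshot FRET: mean E over the first valid frames."""
    vals = series.windowed()
    if vals.size == 0:
        return float("nan")
    return float(vals[:n_frames].mean())


# ---------------------------------------------------------------------------
# on-disk dialects


def _rle_encode(states: np.ndarray) -> list[list]:
    runs: list[list] = []
    for s in states:
        s = int(s)
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    return runs


def _rle_decode(runs: list[list]) -> np.ndarray:
    return np.concatenate([np.full(n, s, dtype=int) for s, n in runs])


def _manifest_entry(trace: Trace, filename: str | None) -> dict:
    entry: dict = {"id": trace.molecule_id, "n_frames": int(trace.n_frames)}
    if filename is not None:
        entry["file"] = filename
    if trace.state_path is not None:
        entry["truth_rle"] = _rle_encode(trace.state_path)
    if trace.flow_onset_frame is not None:
        entry["flow_onset_frame"] = int(trace.flow_onset_frame)
    if trace.bleach_frame is not None:
        entry["bleach_frame"] = int(trace.bleach_frame)
    return entry


def _trace_from_entry(
    entry: dict, dt: float, donor: np.ndarray, acceptor: np.ndarray
) -> Trace:
    state_path = (
        _rle_decode(entry["truth_rle"]) if "truth_rle" in entry else None
    )
    return Trace(
        molecule_id=entry["id"],
        dt=dt,
        donor=donor,
        acceptor=acceptor,
        state_path=state_path,
        flow_onset_frame=entry.get("flow_onset_frame"),
        bleach_frame=entry.get("bleach_frame"),
    )


def write_traces(traces: list[Trace], path: str | Path, meta: dict | None = None) -> None:
    """Write traces to a directory (TSV + manifest.json) or to one ``.h5`` file."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        _write_h5(traces, path, meta)
        return
    path.mkdir(parents=True, exist_ok=True)
    if not traces:
        raise ValueError("no traces to write")
    dt = traces[0].dt
    entries = []
    for trace in traces:
        if trace.dt != dt:
            raise ValueError("all traces in one set must share dt")
        filename = f"{trace.molecule_id}.tsv"
        t = np.arange(trace.n_frames) * dt
        with open(path / filename, "w") as fh:
            fh.write("frame\ttime_s\tdonor\tacceptor\n")
            for i in range(trace.n_frames):
                fh.write(
                    f"{i}\t{t[i]:.6g}\t{trace.donor[i]:.6g}\t{trace.acceptor[i]:.6g}\n"
                )
        entries.append(_manifest_entry(trace, filename))
    manifest = {"dt": dt, "molecules": entries}
    if meta:
        manifest["meta"] = meta
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def read_traces(path: str | Path) -> list[Trace]:
    """Inverse of :func:`write_traces`; dialect chosen by the path suffix."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_h5(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise TraceSchemaError(f"{manifest_path}: manifest missing")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if "dt" not in manifest:
        raise TraceSchemaError(f"{manifest_path}: required key 'dt' missing")
    dt = float(manifest["dt"])
    traces = []
    for entry in manifest.get("molecules", []):
        tsv = path / entry["file"]
        donor, acceptor = _read_trace_tsv(tsv)
        traces.append(_trace_from_entry(entry, dt, donor, acceptor))
    return traces


def _read_trace_tsv(tsv: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["frame", "time_s", "donor", "acceptor"]:
            raise TraceSchemaError(f"{tsv}:1: unexpected header {header!r}")
        donor, acceptor = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise TraceSchemaError(
                    f"{tsv}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            donor.append(float(fields[2]))
            acceptor.append(float(fields[3]))
    return np.array(donor), np.array(acceptor)


def _write_h5(traces: list[Trace], path: Path, meta: dict | None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["dt"] = traces[0].dt
        if meta:
            fh.attrs["meta"] = json.dumps(meta)
        for trace in traces:
            grp = fh.create_group(trace.molecule_id)
            grp.create_dataset("donor", data=trace.donor)
            grp.create_dataset("acceptor", data=trace.acceptor)
            entry = _manifest_entry(trace, None)
            grp.attrs["entry"] = json.dumps(entry)


def _read_h5(path: Path) -> list[Trace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as fh:
        if "dt" not in fh.attrs:
            raise TraceSchemaError(f"{path}: required attribute 'dt' missing")
        dt = float(fh.attrs["dt"])
        for key in fh:
            grp = fh[key]
            entry = json.loads(grp.attrs["entry"])
            traces.append(
                _trace_from_entry(
                    entry, dt, grp["donor"][:], grp["acceptor"][:]
                )
            )
    return traces
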
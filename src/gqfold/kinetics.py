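"""State assignment, dwell-time collection, six-rate estimation and
initial-folding-rate measurement from buffer-flow experiments.

State assignment uses fixed thresholds at the midpoints between adjacent
FRET centers — matching a dwell-measurement workflow rather than an HMM.
Sojourns shorter than ``MIN_DWELL_FRAMES`` are merged into the flanking
state with the longer adjacent dwell (ties to the earlier).  Rates are
1/mean dwell (the exponential MLE) with a dt/2 discretization correction,
branch-split by transition counts; the first and last sojourn of every
trace are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import STATES, TRANSITIONS
from .traces import FretSeries, Trace, compute_fret

__all__ = [
    "StatePath",
    "DwellRecord",
    "RateEstimate",
    "RateEstimates",
    "assign_states",
    "collect_dwells",
    "estimate_rates",
    "detect_flow_onset",
    "initial_folding_rate",
    "FlowOnsetError",
]

MIN_DWELL_FRAMES = 2
MIN_DWELLS_PER_TRANSITION = 5
#: a folding event requires FRET above threshold for this many frames
SUSTAINED_FRAMES = 3

_CODE = {"UF": 0, "P": 1, "AP": 2}
_NAME = {v: k for k, v in _CODE.items()}
_SHORT = {"UF": "U", "P": "P", "AP": "AP"}  # transition-label spelling


@dataclass
class StatePath:
    molecule_id: str
    states: np.ndarray  # per-frame codes: 0=UF, 1=P, 2=AP, -1 invalid
    dt: float


@dataclass
class DwellRecord:
    state: str
    duration: float  # seconds
    transition: str | None  # one of the six labels; None when censored
    molecule_id: str

    @property
    def censored(self) -> bool:
        return self.transition is None


@dataclass
class RateEstimate:
    rate: float
    se: float
    n: int


@dataclass
class RateEstimates:
    rates: dict[str, RateEstimate]
    missing: dict[str, int] = field(default_factory=dict)

    def as_rate_matrix(self):
        from .registry import RateMatrix

        return RateMatrix(
            **{label: self.rates[label].rate if label in self.rates else 0.0
               for label in TRANSITIONS}
        )


def _runs(states: np.ndarray) -> list[list]:
    """Run-length segments [code, start, length]."""
    runs: list[list] = []
    for i, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1][2] += 1
        else:
            runs.append([int(s), i, 1])
    return runs


def _merge_short_runs(runs: list[list], min_frames: int) -> list[list]:
    runs = [r[:] for r in runs]
    changed = True
    while changed:
        changed = False
        for idx, run in enumerate(runs):
            if run[2] >= min_frames or len(runs) == 1:
                continue
            left = runs[idx - 1] if idx > 0 else None
            right = runs[idx + 1] if idx < len(runs) - 1 else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                target = left if left[2] >= right[2] else right
            target[2] += run[2]
            if target is right:
                target[1] = run[1]
            del runs[idx]
            # merging may create adjacent same-state runs; coalesce
            merged: list[list] = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][2] += r[2]
                else:
                    merged.append(r)
            runs = merged
            changed = True
            break
    return runs


def assign_states(
    series: FretSeries,
    centers: dict[str, float],
    min_dwell: int = MIN_DWELL_FRAMES,
) -> StatePath:
    """Per-frame nearest-state assignment with short-sojourn removal.

    Thresholds sit at the midpoints between adjacent centers, which must be
    strictly ordered UF < P < AP.
    """
    if not (centers["UF"] < centers["P"] < centers["AP"]):
        raise ValueError("centers must be strictly ordered UF < P < AP")
    thr_up = 0.5 * (centers["UF"] + centers["P"])
    thr_pa = 0.5 * (centers["P"] + centers["AP"])
    values = series.windowed()
    codes = np.where(values < thr_up, 0, np.where(values < thr_pa, 1, 2))
    if codes.size:
        runs = _merge_short_runs(_runs(codes), min_dwell)
        out = np.empty(codes.size, dtype=int)
        pos = 0
        for code, _, length in runs:
            out[pos : pos + length] = code
            pos += length
    else:
        out = codes.astype(int)
    return StatePath(molecule_id=series.molecule_id, states=out, dt=series.dt)


def collect_dwells(paths: list[StatePath]) -> list[DwellRecord]:
    """One record per sojourn; the first and last sojourn of each trace are
    censored (no transition label) and excluded from rate estimation."""
    records: list[DwellRecord] = []
    for path in paths:
        runs = _runs(path.states)
        for idx, (code, _, length) in enumerate(runs):
            duration = length * path.dt
            if idx == 0 or idx == len(runs) - 1:
                records.append(
                    DwellRecord(_NAME[code], duration, None, path.molecule_id)
                )
            else:
                nxt = runs[idx + 1][0]
                label = f"{_SHORT[_NAME[code]]}_{_SHORT[_NAME[nxt]]}"
                records.append(
                    DwellRecord(_NAME[code], duration, label, path.molecule_id)
                )
    return records


def estimate_rates(
    dwells: list[DwellRecord],
    dt: float,
    min_count: int = MIN_DWELLS_PER_TRANSITION,
) -> RateEstimates:
    """Six transition rates from completed dwells.

    Total exit rate per state is 1/(mean dwell - dt/2); the dt/2 term
    removes the positive bias from frame discretization.  Branch rates
    split the exit rate by transition counts; standard errors are
    rate/sqrt(n) (delta method for exponential dwells).
    """
    completed = [d for d in dwells if not d.censored]
    rates: dict[str, RateEstimate] = {}
    missing: dict[str, int] = {}
    for state in STATES:
        in_state = [d for d in completed if d.state == state]
        labels = [t for t in TRANSITIONS if t.startswith(_SHORT[state] + "_")]
        n_total = len(in_state)
        if n_total == 0:
            for label in labels:
                missing[label] = 0
            continue
        mean_dwell = float(np.mean([d.duration for d in in_state])) - dt / 2.0
        mean_dwell = max(mean_dwell, dt / 2.0)
        exit_rate = 1.0 / mean_dwell
        for label in labels:
            n_branch = sum(1 for d in in_state if d.transition == label)
            if n_branch < min_count:
                missing[label] = n_branch
                continue
            rate = exit_rate * n_branch / n_total
            rates[label] = RateEstimate(
                rate=rate, se=rate / np.sqrt(n_branch), n=n_branch
            )
    return RateEstimates(rates=rates, missing=missing)


class FlowOnsetError(RuntimeError):
    """Raised when no buffer-flow onset can be located in a trace."""


def detect_flow_onset(trace: Trace, min_shift: float = 0.1) -> int:
    """Flow-onset frame: the recorded manifest value when present, else a
    single change-point on the FRET baseline (largest standardized mean
    shift)."""
    if trace.flow_onset_frame is not None:
        return int(trace.flow_onset_frame)
    series = compute_fret(trace.donor, trace.acceptor, dt=trace.dt)
    e = series.values.copy()
    e[~series.valid] = np.nan
    n = e.size
    best_frame, best_shift = None, 0.0
    csum = np.nancumsum(e)
    cnt = np.cumsum(series.valid)
    for i in range(5, n - 5):
        left = csum[i - 1] / max(cnt[i - 1], 1)
        right = (csum[-1] - csum[i - 1]) / max(cnt[-1] - cnt[i - 1], 1)
        shift = abs(right - left)
        if shift > best_shift:
            best_shift, best_frame = shift, i
    if best_frame is None or best_shift < min_shift:
        raise FlowOnsetError("no FRET baseline shift found; not a flow trace")
    return best_frame


@dataclass
class FoldingRateResult:
    rate: float | None
    se: float | None
    n_folded: int
    n_censored: int  # molecules that never folded within the trace
    first_state_tally: dict[str, int]
    latencies: np.ndarray


def initial_folding_rate(
    traces: list[Trace],
    centers: dict[str, float],
    min_molecules: int = 20,
    sustained: int = SUSTAINED_FRAMES,
) -> FoldingRateResult:
    """Latency-based folding rate from buffer-flow traces.

    Per molecule, latency = time from flow onset to the first frame where
    FRET stays above the UF/P midpoint for ``sustained`` consecutive
    frames.  Rate = 1/mean(latency) — majority-of-frame binning makes the
    measured latency unbiased, so no discretization correction is applied
    (unlike dwell-based rates).  Molecules that never fold are counted
    separately, not silently dropped.  The first folded state (P vs AP,
    by proximity of the post-folding FRET level) is tallied.
    """
    thr_fold = 0.5 * (centers["UF"] + centers["P"])
    thr_pa = 0.5 * (centers["P"] + centers["AP"])
    latencies: list[float] = []
    tally = {"P": 0, "AP": 0}
    n_censored = 0
    for trace in traces:
        onset = detect_flow_onset(trace)
        series = compute_fret(trace.donor, trace.acceptor, dt=trace.dt)
        e = series.values
        above = (e > thr_fold) & series.valid
        fold_frame = None
        run = 0
        for i in range(onset, e.size):
            run = run + 1 if above[i] else 0
            if run >= sustained:
                fold_frame = i - sustained + 1
                break
        if fold_frame is None:
            n_censored += 1
            continue
        latencies.append((fold_frame - onset) * trace.dt)
        level = np.nanmean(e[fold_frame : fold_frame + sustained])
        tally["AP" if level > thr_pa else "P"] += 1
    n_folded = len(latencies)
    if n_folded == 0:
        return FoldingRateResult(None, None, 0, n_censored, tally, np.array([]))
    if n_folded < min_molecules:
        raise ValueError(
            f"only {n_folded} molecules with a folding event; "
            f"need >= {min_molecules}"
        )
    dt = traces[0].dt
    mean_latency = max(float(np.mean(latencies)), dt / 2.0)
    rate = 1.0 / mean_latency
    return FoldingRateResult(
        rate=rate,
        se=rate / np.sqrt(n_folded),
        n_folded=n_folded,
        n_censored=n_censored,
        first_state_tally=tally,
        latencies=np.array(latencies),
    )
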
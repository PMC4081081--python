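"""Synthetic smFRET data generator.

State trajectories are sampled exactly (Gillespie) from the three-state
continuous-time Markov chain and then binned to camera frames; each frame is
assigned the state that occupies the majority of it, since the 100-200 ms
camera resolution cannot resolve sub-frame events.  Donor/acceptor
intensities carry additive Gaussian noise with a sqrt-intensity component
plus a constant floor, tuned so the per-frame FRET noise is about 0.05.
Photobleaching is single-step and terminates both channels simultaneously.
"""

from __future__ import annotations

import numpy as np

from .registry import (
    STATES,
    ConstructParams,
    QuenchCurveParams,
    RateMatrix,
)
from .traces import Trace

__all__ = [
    "ctmc_equilibrium",
    "simulate_trajectory",
    "simulate_flow_experiment",
    "simulate_population",
    "snapshot_fret_values",
    "simulate_quench_curve",
    "hill",
    "ReducibleChainError",
]

#: default photophysics constants (none printed in the measurements; assumed)
DEFAULT_TOTAL_INTENSITY = 1000.0
DEFAULT_BLEACH_RATE = 0.01  # 1/s
NOISE_SCALE = 2.0  # per-channel sd contribution, a.u. per sqrt(a.u.)
NOISE_FLOOR = 15.0  # per-channel sd floor, a.u.
BACKGROUND = 15.0  # post-bleach per-channel mean, a.u.

_STATE_CODE = {name: i for i, name in enumerate(STATES)}


class ReducibleChainError(ValueError):
    """Raised when the three-state chain is not irreducible."""


def _check_unique_recurrent_class(q: np.ndarray) -> None:
    """The stationary distribution is unique iff there is exactly one
    recurrent communicating class; otherwise name the offending states."""
    adj = q > 0
    np.fill_diagonal(adj, True)
    reach = np.linalg.matrix_power(adj.astype(int), 3) > 0
    # state i is recurrent iff every state reachable from i reaches i back
    recurrent = [
        i for i in range(3)
        if all(reach[j, i] for j in range(3) if reach[i, j])
    ]
    classes = []
    for i in recurrent:
        if not any(reach[i, j] and reach[j, i] for cls in classes for j in cls):
            classes.append([j for j in recurrent if reach[i, j] and reach[j, i]])
    if len(classes) > 1:
        names = [", ".join(STATES[j] for j in cls) for cls in classes]
        raise ReducibleChainError(
            "chain is reducible: states {" + "} and {".join(names) + "} "
            "cannot reach each other"
        )


def ctmc_equilibrium(rates: RateMatrix) -> dict[str, float]:
    """Stationary distribution of the three-state generator.

    Solved from the null space of the generator transpose with the
    normalization constraint; requires a unique recurrent class (transient
    states get stationary mass 0).
    """
    q = rates.generator()
    _check_unique_recurrent_class(q)
    a = np.vstack([q.T, np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return {name: float(pi[i]) for i, name in enumerate(STATES)}


def _gillespie(
    rates: RateMatrix,
    start_code: int,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> tuple[list[float], list[int]]:
    """Exact CTMC sample path: entry times and state codes from t_start."""
    q = rates.generator()
    times = [t_start]
    states = [start_code]
    t = t_start
    s = start_code
    while True:
        exit_rate = -q[s, s]
        if exit_rate <= 0:
            break  # absorbing
        t = t + rng.exponential(1.0 / exit_rate)
        if t >= t_end:
            break
        probs = q[s].copy()
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(3, p=probs))
        times.append(t)
        states.append(s)
    return times, states


def _bin_majority(
    times: list[float], states: list[int], n_frames: int, dt: float
) -> np.ndarray:
    """Per-frame majority-occupancy state from an event timeline."""
    occupancy = np.zeros((n_frames, 3))
    bounds = times + [n_frames * dt]
    for (t0, s), t1 in zip(zip(times, states), bounds[1:]):
        t1 = min(t1, n_frames * dt)
        if t1 <= t0:
            continue
        f0 = int(t0 / dt)
        f1 = min(int(np.ceil(t1 / dt)), n_frames)
        for f in range(f0, f1):
            lo = max(t0, f * dt)
            hi = min(t1, (f + 1) * dt)
            if hi > lo:
                occupancy[f, s] += hi - lo
    return occupancy.argmax(axis=1)


def _render_intensities(
    state_path: np.ndarray,
    centers: np.ndarray,
    total_intensity: float,
    bleach_frame: int | None,
    rng: np.random.Generator,
    noise: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    fret = centers[state_path]
    acceptor_mean = total_intensity * fret
    donor_mean = total_intensity * (1.0 - fret)
    if bleach_frame is not None:
        acceptor_mean = acceptor_mean.copy()
        donor_mean = donor_mean.copy()
        acceptor_mean[bleach_frame:] = BACKGROUND
        donor_mean[bleach_frame:] = BACKGROUND
    if noise > 0:
        donor = donor_mean + rng.normal(
            0.0, noise * (NOISE_SCALE * np.sqrt(donor_mean) + NOISE_FLOOR)
        )
        acceptor = acceptor_mean + rng.normal(
            0.0, noise * (NOISE_SCALE * np.sqrt(acceptor_mean) + NOISE_FLOOR)
        )
    else:
        donor, acceptor = donor_mean, acceptor_mean
    return np.clip(donor, 0.0, None), np.clip(acceptor, 0.0, None)


def _centers_array(params: ConstructParams) -> np.ndarray:
    return np.array([params.centers[s] for s in STATES])


def _sample_start(params: ConstructParams, rng: np.random.Generator) -> int:
    try:
        eq = ctmc_equilibrium(params.rates)
        probs = np.array([eq[s] for s in STATES])
    except ReducibleChainError:
        probs = np.array(
            [params.fractions.get("UF", 0.0), params.fractions.get("P", 0.0),
             params.fractions.get("AP", 0.0)]
        )
    return int(rng.choice(3, p=probs))


def simulate_trajectory(
    params: ConstructParams,
    duration: float,
    dt: float,
    seed: int | np.random.Generator,
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
    bleach_rate: float = DEFAULT_BLEACH_RATE,
    start_state: str | None = None,
    molecule_id: str = "mol0",
    noise: float = 1.0,
) -> Trace:
    """One equilibrium smFRET trajectory of ``duration`` seconds.

    The state path starts from the stationary distribution (or from
    ``start_state`` when given, which is required for chains with absorbing
    states), photobleaching truncates the observable signal after an
    exponential time, and identical (params, seed) give identical output.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need duration >= dt > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(duration / dt))
    if start_state is not None:
        start = _STATE_CODE["UF" if start_state == "U" else start_state]
    else:
        start = _sample_start(params, rng)
    times, states = _gillespie(params.rates, start, 0.0, duration, rng)
    state_path = _bin_majority(times, states, n_frames, dt)
    bleach_frame: int | None = None
    if bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / bleach_rate)
        if t_bleach < duration:
            bleach_frame = int(t_bleach / dt)
    donor, acceptor = _render_intensities(
        state_path, _centers_array(params), total_intensity, bleach_frame, rng,
        noise,
    )
    return Trace(
        molecule_id=molecule_id,
        dt=dt,
        donor=donor,
        acceptor=acceptor,
        state_path=state_path,
        bleach_frame=bleach_frame,
    )


def simulate_flow_experiment(
    params: ConstructParams,
    pre_frames: int,
    duration: float,
    dt: float,
    seed: int | np.random.Generator,
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
    bleach_rate: float = 0.0,
    dead_time: float = 0.0,
    molecule_id: str = "mol0",
    noise: float = 1.0,
) -> Trace:
    """One folding-initiation trace: unfolded before buffer flow, then an
    exponential latency at ``initial_folding_rate`` to the construct's first
    folded state, then equilibrium dynamics.

    ``dead_time`` (s) adds a fixed flow-equilibration delay before the
    latency clock starts, for sensitivity checks.
    """
    if params.initial_folding_rate is None:
        raise ValueError(
            f"{params.name}: initial_folding_rate not configured"
        )
    if dt <= 0 or duration < dt:
        raise ValueError("need duration >= dt > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(duration / dt))
    onset_time = pre_frames * dt
    latency = rng.exponential(1.0 / params.initial_folding_rate)
    fold_time = onset_time + dead_time + latency
    first_state = _STATE_CODE[params.first_fold_state]
    if fold_time >= duration:
        times, states = [0.0], [_STATE_CODE["UF"]]
    else:
        times, states = _gillespie(params.rates, first_state, fold_time, duration, rng)
        times = [0.0] + times
        states = [_STATE_CODE["UF"]] + states
    state_path = _bin_majority(times, states, n_frames, dt)
    bleach_frame: int | None = None
    if bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / bleach_rate)
        if t_bleach < duration:
            bleach_frame = int(t_bleach / dt)
    donor, acceptor = _render_intensities(
        state_path, _centers_array(params), total_intensity, bleach_frame, rng,
        noise,
    )
    return Trace(
        molecule_id=molecule_id,
        dt=dt,
        donor=donor,
        acceptor=acceptor,
        state_path=state_path,
        flow_onset_frame=pre_frames,
        bleach_frame=bleach_frame,
    )


def simulate_population(
    params: ConstructParams,
    n_molecules: int,
    frames_per_molecule: int,
    seed: int,
    mode: str = "snapshot",
    dt: float | None = None,
    total_intensity: float = DEFAULT_TOTAL_INTENSITY,
    bleach_rate: float = DEFAULT_BLEACH_RATE,
    noise: float = 1.0,
) -> list[Trace]:
    """A population of traces for histogramming.

    ``snapshot`` mode freezes each molecule in a conformer drawn from the
    equilibrium fractions (histograms pool molecules regardless of
    dynamics); ``dynamic`` mode runs the full chain per molecule.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    dt = params.frame_time if dt is None else dt
    rng = np.random.default_rng(seed)
    duration = frames_per_molecule * dt
    traces = []
    if mode == "snapshot":
        probs = np.array(
            [params.fractions.get(s if s != "UF" else "UF", 0.0) for s in STATES]
        )
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        codes = rng.choice(3, size=n_molecules, p=probs)
        centers = _centers_array(params)
        for i, code in enumerate(codes):
            state_path = np.full(frames_per_molecule, code, dtype=int)
            bleach_frame: int | None = None
            if bleach_rate > 0:
                t_bleach = rng.exponential(1.0 / bleach_rate)
                if t_bleach < duration:
                    bleach_frame = int(t_bleach / dt)
            donor, acceptor = _render_intensities(
                state_path, centers, total_intensity, bleach_frame, rng, noise
            )
            traces.append(
                Trace(
                    molecule_id=f"mol{i}",
                    dt=dt,
                    donor=donor,
                    acceptor=acceptor,
                    state_path=state_path,
                    bleach_frame=bleach_frame,
                )
            )
    elif mode == "dynamic":
        for i in range(n_molecules):
            traces.append(
                simulate_trajectory(
                    params,
                    duration,
                    dt,
                    rng,
                    total_intensity=total_intensity,
                    bleach_rate=bleach_rate,
                    molecule_id=f"mol{i}",
                    noise=noise,
                )
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return traces


def snapshot_fret_values(
    params: ConstructParams,
    n_molecules: int,
    seed: int,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Per-molecule snapshot FRET values: conformer drawn from the
    equilibrium fractions, value = state center + Gaussian noise."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    sd = params.fret_noise_sd if noise_sd is None else noise_sd
    probs = np.array([params.fractions.get(s, 0.0) for s in STATES])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    codes = rng.choice(3, size=n_molecules, p=probs)
    centers = _centers_array(params)
    return centers[codes] + rng.normal(0.0, sd, size=n_molecules)


def hill(x, vmax, k, n):
    """Hill saturation y = vmax * x^n / (x^n + k^n)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        xn = np.power(x, n)
        kn = k**n
    return vmax * xn / (xn + kn)


def simulate_quench_curve(params: QuenchCurveParams, seed: int):
    """Table of (concentration_uM, percent_quench) from a noisy Hill truth."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    x = np.asarray(params.concentrations_uM, dtype=float)
    y = hill(x, params.vmax, params.kd_uM, params.hill_n)
    y = y + rng.normal(0.0, params.noise_sd, size=x.size)
    y = np.clip(y, 0.0, 100.0)
    return pd.DataFrame({"concentration_uM": x, "percent_quench": y})
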
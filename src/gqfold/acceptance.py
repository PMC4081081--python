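"""End-to-end recovery targets: simulate with the registry's printed
parameters, analyze with the standard pipeline, report the recovered
quantities on the scale the source measurements print.

Target ids:
  t1-t4  parallel-conformer percentage for 233 / 333 / TTA / TAA
         (3000-molecule snapshot populations, Gaussian-mixture fit)
  t5     mid-FRET component mean, cMyc-style single-conformer population
  t6     high-FRET (antiparallel) component mean, 233-style mixture
  t7     initial folding rate of 133 from 200 buffer-flow traces (1/s)
  t8     Hill dissociation constant from a noisy quench curve (uM)
  t9     ratio of recovered 133 to 199 initial folding rates
"""

from __future__ import annotations

import numpy as np

from .binding import QuenchCurve, fit_hill
from .kinetics import initial_folding_rate
from .populations import build_histogram, fit_gaussian_mixture, label_components
from .registry import QuenchCurveParams, get_params
from .simulate import (
    simulate_flow_experiment,
    simulate_quench_curve,
    snapshot_fret_values,
)

__all__ = ["compute_targets"]


def recovered_population(name: str, n: int, k: int, seed: int):
    """Simulate a snapshot population and fit a k-component mixture."""
    params = get_params(name)
    values = snapshot_fret_values(params, n, seed=seed, noise_sd=0.05)
    hist = build_histogram(values, bin_width=0.02)
    fit = fit_gaussian_mixture(hist, k=k, seed=seed)
    return label_components(fit, name)


def parallel_percent(name: str, k: int, seed: int, n: int = 3000) -> float:
    pop = recovered_population(name, n, k, seed)
    return 100.0 * pop.fractions["P"]


def flow_rate(name: str, seed: int, n: int = 200, duration: float = 30.0):
    params = get_params(name)
    rng = np.random.default_rng(seed)
    traces = [
        simulate_flow_experiment(
            params, pre_frames=50, duration=duration, dt=0.1, seed=rng,
            molecule_id=f"mol{i}",
        )
        for i in range(n)
    ]
    return initial_folding_rate(traces, params.centers)


def hill_kd(seed: int) -> float:
    """Recover the registry Kd for a highly parallel construct (cMyc/NMM)."""
    kd_truth = get_params("cMyc").kd_nmm_uM
    qp = QuenchCurveParams(
        vmax=80.0,
        kd_uM=kd_truth,
        hill_n=1.0,
        noise_sd=0.02 * 80.0,
        concentrations_uM=tuple(np.geomspace(0.01, 10.0, 12)),
    )
    table = simulate_quench_curve(qp, seed=seed)
    curve = QuenchCurve(
        "cMyc", "NMM",
        table["concentration_uM"].to_numpy(),
        table["percent_quench"].to_numpy(),
    )
    return fit_hill(curve).k


def compute_targets(seed: int) -> dict:
    """Recompute every target from scratch; sub-seeds derive from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(16)
    results: dict[str, dict] = {}

    for tid, name, k, s in (
        ("t1", "233", 2, seeds[0]),
        ("t2", "333", 2, seeds[1]),
        ("t3", "TTA", 3, seeds[2]),
        ("t4", "TAA", 3, seeds[3]),
    ):
        results[tid] = {"value": parallel_percent(name, k, int(s)), "n": 3000}

    pop5 = recovered_population("cMyc", 2000, k=1, seed=int(seeds[4]))
    results["t5"] = {"value": pop5.components[0].mean, "n": 2000}

    pop6 = recovered_population("233", 3000, k=2, seed=int(seeds[5]))
    results["t6"] = {"value": pop6.components[-1].mean, "n": 3000}

    res133 = flow_rate("133", int(seeds[6]), duration=30.0)
    results["t7"] = {"value": res133.rate, "n": res133.n_folded}

    results["t8"] = {"value": hill_kd(int(seeds[7])), "n": 12}

    res199 = flow_rate("199", int(seeds[8]), duration=150.0)
    results["t9"] = {
        "value": res133.rate / res199.rate,
        "n": res133.n_folded + res199.n_folded,
    }
    return results
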
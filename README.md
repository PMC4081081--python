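# gqfold

Single-molecule FRET analysis of G-quadruplex (GQ) folding: conformer-population
quantification, three-state folding kinetics, initial-folding-rate measurement
from buffer-flow experiments, and conformation-selective ligand/protein binding
analysis — together with a synthetic trace simulator so that every analysis
stage is verifiable by parameter recovery.

## What it does

| Module | Purpose |
|---|---|
| `gqfold.constructs` | Packaged DNA construct table, loop-descriptor parsing, GQ motif detection (`[G3 N1-7]x3 G3`) |
| `gqfold.registry` | Per-construct generative/kinetic parameters with `paper`/`assumed` provenance tags |
| `gqfold.simulate` | CTMC (Gillespie) smFRET trajectory simulator: equilibrium, buffer-flow and snapshot-population modes, photobleaching, quench-curve generator |
| `gqfold.traces` | FRET efficiency `E = A/(A+D)`, photobleach detection, analysis-window selection, TSV/HDF5 trace I/O |
| `gqfold.populations` | FRET histograms, unrestrained Gaussian-mixture fits, P/AP/UF labelling and area fractions |
| `gqfold.kinetics` | Threshold state assignment, dwell-time collection with flank censoring, six-rate estimation, flow-onset detection, initial folding rates |
| `gqfold.binding` | % quenching, T25 background subtraction, Hill fits (Kd), double-exponential saturation, EMSA bound fractions, parallel-fraction correlation |
| `gqfold.pipeline` / `gqfold.cli` | Config-driven orchestration and per-construct reports |

The three conformational states are unfolded (UF, FRET ~0.2–0.4 depending on
overhang length), parallel (P, ~0.55) and antiparallel (AP, ~0.75); the six
inter-conversion rates are labelled `P_AP, P_U, AP_P, AP_U, U_P, U_AP`.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter recovery
of the printed population fractions, peak positions, folding rates and Kd at
their stated tolerances); the other modules carry unit and property tests,
including independent oracles (matrix-exponential / long-run-simulation checks
for the stationary distribution, an exhaustive grid-search oracle for the
mixture fits).

## CLI

```sh
gqfold simulate --construct 233 --n 3000 --frames 600 --dt 0.1 --seed 7 \
    --mode snapshot --out traces_dir        # or --out traces.h5
gqfold fret --in traces_dir --out fret.json
gqfold populations --traces traces_dir --construct 233 --out fit.json
gqfold kinetics --traces traces_dir --construct 333 --out rates.json
gqfold flowrate --traces flow_dir --construct 133 --out folding.json
gqfold binding --quench quench.csv --background-construct T25 --out binding.json
gqfold correlate --populations pops.json --binding bind.json
gqfold report --config config.json          # full pipeline from a RunConfig
```

`quench.csv` columns: `construct,ligand,concentration_uM,fluorescence`;
EMSA CSV: `construct,shifted_area,unshifted_area`.

## Notes and limitations

- Registry values not printed in the source measurements (e.g. the six
  exchange rates, AP/UF splits for some constructs, photophysics constants)
  are tagged `assumed`; recovery tests treat them as generator truths only.
- No gamma correction or spectral crosstalk is applied to intensities.
- State assignment uses fixed midpoint thresholds (not an HMM); rates for
  quasi-static constructs (cMyc, 133–199, 233) are not reliably estimable
  from dwell times, mirroring the scarcity of transitions in such traces.
- Sub-frame (<100 ms) events are unresolvable by design; dwell-based rates
  carry a dt/2 discretization correction and remain slightly biased for fast
  (&gt;0.3 s⁻¹) transitions.
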
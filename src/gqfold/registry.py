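"""Per-construct generative and kinetic parameters with provenance tags.

Every numeric field carries a provenance tag: ``"paper"`` for values printed
in the source measurements (FRET centers, conformer percentages, initial
folding rates, Kd anchors) and ``"assumed"`` for plausible defaults filled in
where no number was printed.  Tests must never assert on assumed values as
facts about the measurements; they are generator truths for recovery checks
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STATES",
    "TRANSITIONS",
    "RateMatrix",
    "ConstructParams",
    "QuenchCurveParams",
    "REGISTRY",
    "get_params",
]

#: Canonical state order used for generator matrices and state codes.
STATES = ("UF", "P", "AP")

#: The six transition labels, `X_Y` = rate of leaving state X for state Y.
TRANSITIONS = ("P_AP", "P_U", "AP_P", "AP_U", "U_P", "U_AP")

_STATE_INDEX = {"UF": 0, "U": 0, "P": 1, "AP": 2}


@dataclass(frozen=True)
class RateMatrix:
    """Six inter-conversion rates (1/s) among UF, P and AP."""

    P_AP: float = 0.0
    P_U: float = 0.0
    AP_P: float = 0.0
    AP_U: float = 0.0
    U_P: float = 0.0
    U_AP: float = 0.0

    def __post_init__(self) -> None:
        for label in TRANSITIONS:
            if getattr(self, label) < 0:
                raise ValueError(f"rate {label} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {label: getattr(self, label) for label in TRANSITIONS}

    def generator(self) -> np.ndarray:
        """3x3 CTMC generator Q (rows sum to zero), state order UF, P, AP."""
        q = np.zeros((3, 3))
        for label, rate in self.as_dict().items():
            src, dst = label.split("_")
            i, j = _STATE_INDEX[src], _STATE_INDEX[dst]
            q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def exit_rate(self, state: str) -> float:
        i = _STATE_INDEX[state]
        return -self.generator()[i, i]

    def scaled(self, factor: float) -> "RateMatrix":
        return RateMatrix(**{k: v * factor for k, v in self.as_dict().items()})


@dataclass(frozen=True)
class ConstructParams:
    """Generative truth for one construct's simulated experiments."""

    name: str
    centers: dict[str, float]  # FRET centers keyed UF/P/AP
    fractions: dict[str, float]  # equilibrium conformer fractions
    rates: RateMatrix
    initial_folding_rate: float | None = None  # 1/s, flow experiments
    first_fold_state: str = "P"  # first folded state after K+ flow
    fret_noise_sd: float = 0.05
    frame_time: float = 0.1  # s
    kd_nmm_uM: float | None = None
    quench_vmax: float | None = None  # saturating % quench, NMM
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: fractions sum to {total}, expected 1"
            )
        c = self.centers
        if not (c["UF"] < c["P"] < c["AP"]):
            raise ValueError(f"{self.name}: centers must satisfy UF < P < AP")

    def with_overrides(self, **kwargs) -> "ConstructParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class QuenchCurveParams:
    """Hill-curve truth for a simulated ligand quenching titration."""

    vmax: float  # % quench at saturation
    kd_uM: float
    hill_n: float
    noise_sd: float  # absolute %, typically a few % of vmax
    concentrations_uM: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0 < self.vmax <= 100:
            raise ValueError("vmax must be in (0, 100]")
        if self.kd_uM <= 0 or self.hill_n <= 0:
            raise ValueError("kd and hill coefficient must be positive")
        if any(c < 0 for c in self.concentrations_uM):
            raise ValueError("concentrations must be non-negative")


# stable-parallel constructs show essentially constant folded FRET; their
# rare unfolding events refold about as fast as the initial K+ folding
_STABLE = RateMatrix(P_AP=0.002, P_U=0.002, AP_P=0.01, AP_U=0.005, U_P=1.0, U_AP=0.1)
_DYNAMIC_FAST = RateMatrix(P_AP=0.10, P_U=0.12, AP_P=0.12, AP_U=0.12, U_P=0.25, U_AP=0.15)
_DYNAMIC_SLOW = RateMatrix(P_AP=0.10, P_U=0.12, AP_P=0.12, AP_U=0.12, U_P=0.05, U_AP=0.04)


def _cp(name, uf, fractions, rates, fold_rate, first_state, kd, vmax, prov):
    return ConstructParams(
        name=name,
        centers={"UF": uf, "P": 0.55, "AP": 0.75},
        fractions=fractions,
        rates=rates,
        initial_folding_rate=fold_rate,
        first_fold_state=first_state,
        kd_nmm_uM=kd,
        quench_vmax=vmax,
        provenance=prov,
    )


def _registry() -> dict[str, ConstructParams]:
    # Published anchors: P center 0.55, AP center 0.75,
    # UF center 0.2 for 177/199, 0.3 for 433/533,
    # 0.4 for AAA; parallel fractions 233=0.91, 333=0.56 (AP 0.44),
    # TTA=0.35, TAA=0.16; initial folding ~2/s for 7-8 nt total loops,
    # 0.5-0.8/s for 9-10 nt, <0.1/s above 11 nt; Kd ~0.1 uM for highly
    # parallel constructs, 10-500 uM otherwise.  Everything else assumed.
    reg: dict[str, ConstructParams] = {}
    paper_centers = {"centers.P": "paper", "centers.AP": "paper"}

    reg["cMyc"] = _cp(
        "cMyc", 0.30, {"P": 1.0, "AP": 0.0, "UF": 0.0}, _STABLE,
        2.0, "P", 0.1, 80.0,
        paper_centers | {"fractions.P": "paper", "kd_nmm_uM": "paper",
                         "centers.UF": "assumed", "rates": "assumed",
                         "initial_folding_rate": "assumed",
                         "quench_vmax": "assumed"},
    )
    reg["133"] = _cp(
        "133", 0.25, {"P": 1.0, "AP": 0.0, "UF": 0.0}, _STABLE,
        2.0, "P", 0.1, 78.0,
        paper_centers | {"fractions.P": "paper",
                         "initial_folding_rate": "paper",
                         "centers.UF": "assumed", "rates": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["144"] = _cp(
        "144", 0.25, {"P": 1.0, "AP": 0.0, "UF": 0.0}, _STABLE,
        0.8, "P", 0.2, 75.0,
        paper_centers | {"fractions.P": "paper",
                         "initial_folding_rate": "paper",
                         "centers.UF": "assumed", "rates": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["155"] = _cp(
        "155", 0.22, {"P": 1.0, "AP": 0.0, "UF": 0.0}, _STABLE,
        0.3, "P", 0.3, 72.0,
        paper_centers | {"fractions.P": "paper",
                         "centers.UF": "assumed", "rates": "assumed",
                         "initial_folding_rate": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["177"] = _cp(
        "177", 0.20, {"P": 0.85, "AP": 0.0, "UF": 0.15}, _STABLE,
        0.08, "P", 0.5, 68.0,
        paper_centers | {"centers.UF": "paper",
                         "initial_folding_rate": "paper",
                         "fractions": "assumed", "rates": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["199"] = _cp(
        "199", 0.20, {"P": 0.70, "AP": 0.0, "UF": 0.30}, _STABLE,
        0.05, "P", 1.0, 60.0,
        paper_centers | {"centers.UF": "paper",
                         "initial_folding_rate": "paper",
                         "fractions": "assumed", "rates": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["233"] = _cp(
        "233", 0.25, {"P": 0.91, "AP": 0.09, "UF": 0.0}, _STABLE,
        2.0, "AP", 0.12, 78.0,
        paper_centers | {"fractions.P": "paper",
                         "initial_folding_rate": "paper",
                         "first_fold_state": "paper",
                         "fractions.AP": "assumed", "centers.UF": "assumed",
                         "rates": "assumed", "kd_nmm_uM": "assumed",
                         "quench_vmax": "assumed"},
    )
    reg["333"] = _cp(
        "333", 0.25, {"P": 0.56, "AP": 0.44, "UF": 0.0}, _DYNAMIC_FAST,
        0.8, "AP", 5.0, 55.0,
        paper_centers | {"fractions.P": "paper", "fractions.AP": "paper",
                         "initial_folding_rate": "paper",
                         "first_fold_state": "paper",
                         "centers.UF": "assumed", "rates": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["433"] = _cp(
        "433", 0.30, {"P": 0.45, "AP": 0.35, "UF": 0.20}, _DYNAMIC_SLOW,
        0.5, "AP", 20.0, 45.0,
        paper_centers | {"centers.UF": "paper",
                         "initial_folding_rate": "paper",
                         "first_fold_state": "paper",
                         "fractions": "assumed", "rates": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["533"] = _cp(
        "533", 0.30, {"P": 0.35, "AP": 0.35, "UF": 0.30}, _DYNAMIC_SLOW,
        0.1, "AP", 50.0, 38.0,
        paper_centers | {"centers.UF": "paper",
                         "fractions": "assumed", "rates": "assumed",
                         "initial_folding_rate": "assumed",
                         "first_fold_state": "paper",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    # telomeric loop repeat; its exchanging antiparallel state is printed
    # at 0.75 alongside TTT/TAA/433/533 (the 0.70 level belongs to the
    # full telomere overhang construct, which is not in this registry)
    reg["TTA"] = ConstructParams(
        name="TTA",
        centers={"UF": 0.25, "P": 0.55, "AP": 0.75},
        fractions={"P": 0.35, "AP": 0.45, "UF": 0.20},
        rates=_DYNAMIC_FAST,
        initial_folding_rate=0.7,
        first_fold_state="AP",
        kd_nmm_uM=50.0,
        quench_vmax=35.0,
        provenance={"centers.P": "paper", "centers.AP": "paper",
                    "fractions.P": "paper", "first_fold_state": "paper",
                    "fractions.AP": "assumed", "fractions.UF": "assumed",
                    "centers.UF": "assumed", "rates": "assumed",
                    "initial_folding_rate": "assumed",
                    "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["TAA"] = _cp(
        "TAA", 0.30, {"P": 0.16, "AP": 0.44, "UF": 0.40}, _DYNAMIC_SLOW,
        0.6, "AP", 200.0, 20.0,
        paper_centers | {"fractions.P": "paper", "first_fold_state": "paper",
                         "fractions.AP": "assumed", "fractions.UF": "assumed",
                         "centers.UF": "assumed", "rates": "assumed",
                         "initial_folding_rate": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["AAA"] = _cp(
        "AAA", 0.40, {"P": 0.05, "AP": 0.05, "UF": 0.90}, _DYNAMIC_SLOW,
        0.1, "AP", 500.0, 12.0,
        paper_centers | {"centers.UF": "paper",
                         "fractions": "assumed", "rates": "assumed",
                         "initial_folding_rate": "assumed",
                         "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    reg["T25"] = ConstructParams(
        name="T25",
        centers={"UF": 0.15, "P": 0.55, "AP": 0.75},
        fractions={"P": 0.0, "AP": 0.0, "UF": 1.0},
        rates=RateMatrix(),
        initial_folding_rate=None,
        kd_nmm_uM=500.0,
        quench_vmax=8.0,
        provenance={"fractions.UF": "paper", "centers.UF": "assumed",
                    "kd_nmm_uM": "assumed", "quench_vmax": "assumed"},
    )
    return reg


REGISTRY: dict[str, ConstructParams] = _registry()

_ALIASES = {"TTT": "333", "c-Myc": "cMyc", "cmyc": "cMyc"}


def get_params(name: str) -> ConstructParams:
    """Look up registry parameters by construct name (aliases resolved)."""
    key = _ALIASES.get(name, name)
    try:
        return REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"no registry entry for construct {name!r}; "
            f"known: {sorted(REGISTRY)}"
        ) from None
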
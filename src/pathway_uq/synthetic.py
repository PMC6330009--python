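"""Fixture networks, synthetic calibration data, and GSA test functions.

Every stage of the workflow is testable without external data: a small
ligand-binding demo network with one thermodynamic cycle, a synthetic
reconstruction of a CaMKII/CaM/PP2B/PP1 synaptic-plasticity network, noisy
ground-truth dose-response curves, and analytic test functions for the
sensitivity estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .experiments import Curve, ExperimentSetup, simulate_setup
from .network import ReactionNetwork, parse_model

__all__ = [
    "SyntheticSpec",
    "demo_network",
    "demo_setups",
    "demo_theta_true",
    "camkii_network",
    "synth_data",
    "gsa_testfunctions",
]


@dataclass
class SyntheticSpec:
    """Ground-truth data generation: parameter vector (log10), noise model
    ('none' | 'additive_gaussian' | 'multiplicative_lognormal'), noise scale
    sigma (for additive noise: fraction of each curve's output range), seed."""

    theta_true: dict[str, float]
    noise: str = "additive_gaussian"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise not in ("none", "additive_gaussian", "multiplicative_lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")


_DEMO_TSV = """\
!!Species
Name\tRole\tDefaultTotal
L\telementary\t1
X\telementary\t1
P\telementary\t1
LX\tcomplex\t0
LP\tcomplex\t0
LXP\tcomplex\t0
!!Reaction
Id\tFormula\tKind\tRateExpression
R1\tL + X <=> LX\tmass_action_reversible\t
R2\tLX + P <=> LXP\tmass_action_reversible\t
R3\tL + P <=> LP\tmass_action_reversible\t
R4\tLP + X <=> LXP\tmass_action_reversible\t
!!Parameter
Name\tKind\tDefaultLog10
Kd1\tfree_kd\t0
Kd2\tfree_kd\t0.5
Kd3\tfree_kd\t-0.5
kf1\tkinetic_kf\t0
kf2\tkinetic_kf\t0
kf3\tkinetic_kf\t0
kf4\tkinetic_kf\t0
"""


def demo_network() -> ReactionNetwork:
    """Six-species ligand-binding network: protein L binds ligand X and
    partner P independently and jointly (complexes LX, LP, LXP).  The four
    reversible reactions close one thermodynamic cycle, so exactly one Kd is
    Wegscheider-constrained (Kd4 = Kd1*Kd2/Kd3)."""
    return parse_model(_DEMO_TSV)


def demo_theta_true() -> dict[str, float]:
    """Ground-truth log10 parameter vector for the demo network (the free-Kd
    and kf entries; values offset from the prior centers so recovery is a
    real test)."""
    return {
        "Kd1": 0.30,
        "Kd2": 0.10,
        "Kd3": -0.20,
        "kf1": 0.0,
        "kf2": 0.0,
        "kf3": 0.0,
        "kf4": 0.0,
    }


def demo_setups(n_points: int = 9) -> list[ExperimentSetup]:
    """Two steady-state titration phenotypes on the demo network.

    Phenotype d1 scans total X with P absent (constrains Kd1 alone);
    phenotype d2 repeats the scan with P present so the LXP branch is active
    (constrains Kd2 and Kd3; Kd4 follows from the cycle).  The observable is
    mol bound X per mol L.
    """
    grid = np.logspace(-2, 2, n_points)
    return [
        ExperimentSetup(
            id="d1",
            active_totals={"L": 1.0, "P": 0.0},
            input_name="X",
            input_grid=grid,
            observable="(LX + LXP) / L_total",
        ),
        ExperimentSetup(
            id="d2",
            active_totals={"L": 1.0, "P": 2.0},
            input_name="X",
            input_grid=grid,
            observable="(LXP + LP) / L_total",
        ),
    ]


def synth_data(
    net: ReactionNetwork,
    spec: SyntheticSpec,
    setups: Sequence[ExperimentSetup],
) -> list[ExperimentSetup]:
    """Attach ground-truth data curves (with the spec's noise model) to each
    setup; returns new setups carrying ``data``.  Seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for s in setups:
        curve = simulate_setup(net, spec.theta_true, s)
        y = curve.outputs.copy()
        if spec.noise == "additive_gaussian":
            scale = spec.sigma * max(np.ptp(y), 1e-12)
            y = y + rng.normal(0.0, scale, size=y.shape)
        elif spec.noise == "multiplicative_lognormal":
            y = y * rng.lognormal(0.0, spec.sigma, size=y.shape)
        out.append(s.with_data(Curve(inputs=curve.inputs, outputs=y)))
    return out


# ---------------------------------------------------------------------------
# CaMKII/CaM/PP2B/PP1 fixture
# ---------------------------------------------------------------------------

def _camkii_tsv() -> str:
    """Synthetic reconstruction of the CaMKII/CaM/PP2B/PP1 synaptic-plasticity
    network: 25 species, 34 reactions, all but two elementary reversible
    mass action.

    Structure: calmodulin (CaM) binds four Ca ions sequentially; the apo and
    Ca-loaded CaM forms bind either the phosphatase PP2B, the kinase CaMKII,
    or phosphorylated CaMKII (pCaMKII); each protein-CaM complex again binds
    Ca sequentially.  The two non-elementary reactions are CaMKII
    autophosphorylation (rate kautMax, quadratic in the fully activated
    kinase, modelling inter-subunit phosphorylation) and PP1-catalyzed
    dephosphorylation (rate kdeph, active only when PP1 is present; used for
    predictions).  The exact reaction tables of the published model are not
    redistributed here; this fixture reproduces the published structural
    counts and binding topology, not its fitted kinetics.
    """
    cam = ["CaM"] + [f"CaM_Ca{i}" for i in range(1, 5)]
    species = [("Ca", "elementary", 10.0), ("CaM", "elementary", 10.0)]
    species += [(f"CaM_Ca{i}", "complex", 0.0) for i in range(1, 5)]
    species += [("PP2B", "elementary", 1.0)]
    pp2b = ["PP2B_CaM"] + [f"PP2B_CaM_Ca{i}" for i in range(1, 5)]
    species += [(s, "complex", 0.0) for s in pp2b]
    species += [("CaMKII", "elementary", 20.0)]
    kk = ["CaMKII_CaM"] + [f"CaMKII_CaM_Ca{i}" for i in range(1, 5)]
    species += [(s, "complex", 0.0) for s in kk]
    species += [("pCaMKII", "elementary", 0.0)]
    pk = ["pCaMKII_CaM"] + [f"pCaMKII_CaM_Ca{i}" for i in range(1, 5)]
    species += [(s, "complex", 0.0) for s in pk]
    species += [("PP1", "elementary", 1.0)]

    reactions: list[tuple[str, str, str, str]] = []
    rid = 0

    def add(formula: str, kind: str = "mass_action_reversible", expr: str = "") -> None:
        nonlocal rid
        rid += 1
        reactions.append((f"R{rid}", formula, kind, expr))

    for i in range(4):  # R1-R4: CaM binds 4 Ca
        add(f"{cam[i]} + Ca <=> {cam[i + 1]}")
    for i in range(5):  # R5-R9: PP2B binds each CaM form
        add(f"PP2B + {cam[i]} <=> {pp2b[i]}")
    for i in range(4):  # R10-R13: PP2B-CaM binds Ca (R12, R13: 3rd/4th Ca)
        add(f"{pp2b[i]} + Ca <=> {pp2b[i + 1]}")
    for i in range(5):  # R14-R18: CaMKII binds each CaM form
        add(f"CaMKII + {cam[i]} <=> {kk[i]}")
    for i in range(4):  # R19-R22: CaMKII-CaM binds Ca (R19, R20: first two)
        add(f"{kk[i]} + Ca <=> {kk[i + 1]}")
    for i in range(5):  # R23-R27: pCaMKII binds each CaM form
        add(f"pCaMKII + {cam[i]} <=> {pk[i]}")
    for i in range(4):  # R28-R31: pCaMKII-CaM binds Ca
        add(f"{pk[i]} + Ca <=> {pk[i + 1]}")
    add("pCaMKII <=> CaMKII")  # R32: basal dephosphorylation equilibrium
    add(  # R33: autophosphorylation of the fully activated kinase
        "CaMKII_CaM_Ca4 -> pCaMKII_CaM_Ca4",
        "custom",
        "kautMax * CaMKII_CaM_Ca4**2",
    )
    add(  # R34: PP1-catalyzed dephosphorylation (prediction only)
        "pCaMKII_CaM_Ca4 -> CaMKII_CaM_Ca4",
        "custom",
        "kdeph * PP1 * pCaMKII_CaM_Ca4",
    )

    lines = ["!!Species", "Name\tRole\tDefaultTotal"]
    lines += [f"{n}\t{r}\t{format(t, '.10g')}" for n, r, t in species]
    lines += ["!!Reaction", "Id\tFormula\tKind\tRateExpression"]
    lines += [f"{i}\t{f}\t{k}\t{e}" for i, f, k, e in reactions]
    return "\n".join(lines) + "\n"


def camkii_network(from_file: bool = True) -> ReactionNetwork:
    """Load the synthetic CaMKII-pathway fixture (see :func:`_camkii_tsv`).

    With ``from_file`` the shipped ``data/camkii_synthetic.tsv`` is parsed;
    otherwise the table text is rebuilt programmatically (both must agree).
    """
    if from_file:
        text = (
            resources.files("pathway_uq") / "data" / "camkii_synthetic.tsv"
        ).read_text()
    else:
        text = _camkii_tsv()
    return parse_model(text)


# ---------------------------------------------------------------------------
# GSA oracle battery
# ---------------------------------------------------------------------------

def gsa_testfunctions(
    name: str, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Independent-input test functions with known sensitivity structure.

    linear:         Y = X1 + 2*X2 on U(0,1)^2; S = (0.2, 0.8).
    ishigami:       a=7, b=0.1 on U(-pi,pi)^3; analytic first-order indices.
    xor_classifier: labels = sign(X1*X2) > 0 on U(-1,1)^2 (+ a noise column);
                    only the pair (X1, X2) is informative.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    if name == "linear":
        x = rng.uniform(0.0, 1.0, size=(n, 2))
        return x, x[:, 0] + 2.0 * x[:, 1]
    if name == "ishigami":
        x = rng.uniform(-np.pi, np.pi, size=(n, 3))
        a, b = 7.0, 0.1
        y = (
            np.sin(x[:, 0])
            + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0])
        )
        return x, y
    if name == "xor_classifier":
        x = rng.uniform(-1.0, 1.0, size=(n, 3))
        labels = (x[:, 0] * x[:, 1] > 0).astype(int)
        return x, labels
    raise ValueError(f"unknown test function {name!r}")


def ishigami_indices(a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Analytic first-order Sobol indices of the Ishigami function."""
    v1 = 0.5 * (1.0 + b * np.pi**4 / 5.0) ** 2
    v2 = a**2 / 8.0
    vt = a**2 / 8.0 + b * np.pi**4 / 5.0 + b**2 * np.pi**8 / 18.0 + 0.5
    return np.array([v1 / vt, v2 / vt, 0.0])
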
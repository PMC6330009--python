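"""Experimental setups ("phenotypes") and the ABC distance.

A setup describes one experimentally engineered subsystem: which elementary
species are present and at what totals, which input is scanned over a grid
(e.g. total Ca), and which observable is read out (a symbolic expression over
the equilibrium or endpoint state, totals, and readout-scale parameters).
Simulating a setup yields a dose-response :class:`Curve`; the distance
between simulated and experimental curves is the root-mean-square pointwise
error after per-curve normalization, averaged over curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .network import ReactionNetwork, complete_kd, simulate_ode, solve_equilibrium

__all__ = [
    "Curve",
    "ExperimentSetup",
    "DistanceSpec",
    "simulate_setup",
    "distance",
    "parse_experiments",
    "serialize_experiments",
]


@dataclass
class Curve:
    inputs: np.ndarray
    outputs: np.ndarray
    scale_hint: float | None = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.inputs.shape != self.outputs.shape:
            raise ValueError("curve inputs/outputs length mismatch")
        if not (np.all(np.isfinite(self.inputs)) and np.all(np.isfinite(self.outputs))):
            raise ValueError("curve contains non-finite values")


@dataclass
class ExperimentSetup:
    id: str
    active_totals: dict[str, float]
    input_name: str
    input_grid: np.ndarray
    observable: str
    mode: str = "equilibrium"  # {equilibrium | ode_endpoint}
    data: Curve | None = None
    endpoint_time: float = 100.0

    def __post_init__(self) -> None:
        self.input_grid = np.asarray(self.input_grid, dtype=float)
        if self.mode not in ("equilibrium", "ode_endpoint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(np.diff(self.input_grid) <= 0):
            raise ValueError("input_grid must be strictly increasing")

    def with_data(self, curve: Curve) -> "ExperimentSetup":
        return replace(self, data=curve)


@dataclass
class DistanceSpec:
    summary: str = "identity"
    normalization: str = "max_abs_per_curve"  # or "scale_hint"
    aggregation: str = "mean"


def _observable_fn(net: ReactionNetwork, setup: ExperimentSetup):
    expr = sp.sympify(setup.observable, rational=False)
    syms = sorted(expr.free_symbols, key=lambda s: s.name)
    return syms, sp.lambdify(syms, expr, modules="numpy")


def _observable_env(
    net: ReactionNetwork,
    state: Mapping[str, float],
    totals: Mapping[str, float],
    theta: Mapping[str, float],
) -> dict[str, float]:
    env = dict(state)
    for s, t in totals.items():
        env[f"{s}_total"] = t
    for name, v in theta.items():
        if name not in env:
            env[name] = 10.0 ** v
    return env


def simulate_setup(
    net: ReactionNetwork, theta: Mapping[str, float], setup: ExperimentSetup
) -> Curve:
    """Simulate a setup's input-output curve at parameter point theta (log10).

    Equilibrium mode solves the detailed-balance equilibrium at every grid
    point (the observable then depends on mass-action parameters only through
    Kd); ode_endpoint mode integrates the full kinetics to ``endpoint_time``.
    """
    cached = getattr(setup, "_obs_fn", None)
    if cached is None:
        cached = _observable_fn(net, setup)
        object.__setattr__(setup, "_obs_fn", cached)
    syms, fn = cached
    full_kd = complete_kd(net.thermo, {k: theta[k] for k in net.thermo.free_names})
    out = np.empty(len(setup.input_grid))
    warm: Mapping[str, float] | None = None
    for i, val in enumerate(setup.input_grid):
        totals = {**setup.active_totals, setup.input_name: float(val)}
        if setup.mode == "equilibrium":
            try:
                state = solve_equilibrium(net, full_kd, totals, x0_log=warm)
            except Exception as e:  # pragma: no cover - error path
                raise RuntimeError(
                    f"setup {setup.id}: equilibrium failed at "
                    f"{setup.input_name}={val}: {e}"
                ) from e
            warm = {
                s: np.log10(max(c, 1e-300)) for s, c in state.items()
            }
        else:
            x0 = {s.name: totals.get(s.name, 0.0) for s in net.elementary_species()}
            traj = simulate_ode(
                net, theta, None, x0, [0.0, setup.endpoint_time]
            )
            state = dict(zip(net.species_names, traj[-1]))
        env = _observable_env(net, state, totals, theta)
        try:
            out[i] = float(fn(*[env[s.name] for s in syms]))
        except KeyError as e:
            raise ValueError(
                f"setup {setup.id}: observable references unknown symbol {e}"
            ) from e
    return Curve(inputs=setup.input_grid.copy(), outputs=out)


def distance(
    sim: Sequence[Curve],
    exp: Sequence[Curve],
    spec: DistanceSpec | None = None,
) -> float:
    """ABC distance rho: mean over curves of the RMS normalized pointwise
    error.  Zero iff every simulated curve equals its experimental curve."""
    spec = spec or DistanceSpec()
    if len(sim) != len(exp):
        raise ValueError("curve list length mismatch")
    vals = []
    for cs, ce in zip(sim, exp):
        if cs.inputs.shape != ce.inputs.shape or not np.allclose(
            cs.inputs, ce.inputs
        ):
            raise ValueError("input grids differ between simulated and data curve")
        if spec.normalization == "scale_hint":
            scale = ce.scale_hint
            if scale is None:
                raise ValueError("scale_hint normalization requires scale_hint")
        else:
            scale = np.max(np.abs(ce.outputs))
        if not scale or scale <= 0:
            raise ValueError("normalization constant must be positive")
        vals.append(np.sqrt(np.mean(((cs.outputs - ce.outputs) / scale) ** 2)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Tabular text format
# ---------------------------------------------------------------------------

def _parse_totals(s: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in s.split(";"):
        part = part.strip()
        if not part:
            continue
        k, v = part.split("=")
        out[k.strip()] = float(v)
    return out


def parse_experiments(text: str) -> list[ExperimentSetup]:
    """Parse ``!!Experiment`` (+ optional ``!!Data``) TSV tables."""
    tables: dict[str, list[list[str]]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("!!"):
            current = tables.setdefault(line.strip(), [])
            continue
        if current is None:
            raise ValueError("data before any !!table header")
        current.append(line.split("\t"))

    def rows(table: str) -> list[dict[str, str]]:
        data = tables.get(table, [])
        if not data:
            return []
        header = [h.strip() for h in data[0]]
        return [dict(zip(header, (c.strip() for c in r))) for r in data[1:]]

    data_by_exp: dict[str, list[tuple[float, float, float | None]]] = {}
    for r in rows("!!Data"):
        scale = float(r["Scale"]) if r.get("Scale") else None
        data_by_exp.setdefault(r["ExperimentId"], []).append(
            (float(r["Input"]), float(r["Output"]), scale)
        )

    setups: list[ExperimentSetup] = []
    for r in rows("!!Experiment"):
        eid = r["Id"]
        grid_field = r.get("InputGrid", "")
        points = data_by_exp.get(eid)
        if points:
            points.sort(key=lambda t: t[0])
            grid = np.array([p[0] for p in points])
        elif grid_field:
            grid = np.array([float(v) for v in grid_field.split(";") if v.strip()])
        else:
            raise ValueError(f"experiment {eid}: no input grid and no data")
        setup = ExperimentSetup(
            id=eid,
            active_totals=_parse_totals(r.get("ActiveTotals", "")),
            input_name=r["InputName"],
            input_grid=grid,
            observable=r["Observable"],
            mode=r.get("Mode", "equilibrium") or "equilibrium",
            endpoint_time=float(r.get("EndpointTime") or 100.0),
        )
        if points:
            setup = setup.with_data(
                Curve(
                    inputs=grid,
                    outputs=np.array([p[1] for p in points]),
                    scale_hint=points[0][2],
                )
            )
        setups.append(setup)
    return setups


def serialize_experiments(setups: Sequence[ExperimentSetup]) -> str:
    out = [
        "!!Experiment",
        "Id\tMode\tInputName\tActiveTotals\tObservable\tInputGrid\tEndpointTime",
    ]
    for s in setups:
        totals = ";".join(f"{k}={format(v, '.10g')}" for k, v in s.active_totals.items())
        grid = ";".join(format(v, ".10g") for v in s.input_grid)
        out.append(
            f"{s.id}\t{s.mode}\t{s.input_name}\t{totals}\t{s.observable}\t{grid}"
            f"\t{format(s.endpoint_time, '.10g')}"
        )
    if any(s.data is not None for s in setups):
        out.append("!!Data")
        out.append("ExperimentId\tInput\tOutput\tScale")
        for s in setups:
            if s.data is None:
                continue
            sc = "" if s.data.scale_hint is None else format(s.data.scale_hint, ".10g")
            for x, y in zip(s.data.inputs, s.data.outputs):
                out.append(
                    f"{s.id}\t{format(x, '.10g')}\t{format(y, '.17g')}\t{sc}"
                )
    return "\n".join(out) + "\n"
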
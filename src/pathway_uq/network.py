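"""Reversible mass-action reaction networks with thermodynamic structure.

A network is a set of species coupled by reversible elementary reactions
(``A + B <=> C``) obeying the law of mass action, plus an escape hatch for
non-elementary reactions given by an explicit rate expression.  The module
extracts the stoichiometric matrix, moiety conservation laws and Wegscheider
(cycle-closure) constraints on the dissociation constants, solves the
detailed-balance equilibrium in log-concentration space, and integrates the
mass-action ODE system.

Conventions
-----------
* Concentrations are in µM throughout.
* All sampled/stored parameters are log10 values; rate expressions for custom
  reactions reference *linear-scale* species concentrations and parameters.
* For a reaction with reactants R and products P the dissociation constant
  satisfies ``log10 Kd = sum_R log10[x] - sum_P log10[x]`` at equilibrium,
  i.e. ``Kd = kr/kf``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ParameterSpace",
    "ThermoConstraints",
    "ReactionNetwork",
    "ModelParseError",
    "EquilibriumError",
    "parse_model",
    "serialize_model",
    "stoichiometric_matrix",
    "conservation_laws",
    "wegscheider_decompose",
    "complete_kd",
    "solve_equilibrium",
    "simulate_ode",
]

MASS_ACTION = "mass_action_reversible"
CUSTOM = "custom"


class ModelParseError(ValueError):
    """Raised when a model table cannot be parsed or fails validation."""


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    role: str = "elementary"  # {elementary | complex}
    default_total: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("elementary", "complex"):
            raise ModelParseError(f"unknown species role {self.role!r}")
        if self.default_total < 0:
            raise ModelParseError(f"negative default total for {self.name}")


@dataclass(frozen=True)
class ReactionDef:
    rid: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kind: str = MASS_ACTION
    kf_name: str = ""
    kr_name: str = ""
    kd_name: str = ""
    rate_expression: str = ""

    @property
    def is_mass_action(self) -> bool:
        return self.kind == MASS_ACTION


@dataclass
class ParameterSpace:
    """Ordered parameter names with per-name kinds; log10 convention."""

    names: list[str]
    kinds: dict[str, str]
    defaults_log10: dict[str, float] = field(default_factory=dict)
    log_scale: int = 10

    def of_kind(self, *kinds: str) -> list[str]:
        return [n for n in self.names if self.kinds[n] in kinds]


@dataclass
class ThermoConstraints:
    """Wegscheider cycle constraints on log10 dissociation constants.

    ``constraint_matrix`` has one integer row per independent reaction cycle
    and one column per mass-action reaction (ordered as ``kd_names``); each
    row z satisfies ``sum_j z_j * log10 Kd_j = 0``.  ``solved_form`` expresses
    every constrained log-Kd as an exact rational combination of free log-Kds.
    """

    kd_names: list[str]
    constraint_matrix: np.ndarray  # shape (n_cycles, n_mass_action)
    free_names: list[str]
    constrained_names: list[str]
    solved_form: dict[str, dict[str, Fraction]]

    @property
    def n_cycles(self) -> int:
        return self.constraint_matrix.shape[0]


class ReactionNetwork:
    """Validated reaction network with cached thermodynamic structure."""

    def __init__(
        self,
        species: Sequence[SpeciesDef],
        reactions: Sequence[ReactionDef],
        free_choice: Sequence[str] | None = None,
    ) -> None:
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelParseError(f"duplicate species name(s): {', '.join(dup)}")
        self.species: list[SpeciesDef] = list(species)
        self.reactions: list[ReactionDef] = list(reactions)
        self._index = {n: i for i, n in enumerate(names)}
        rids = [r.rid for r in reactions]
        if len(set(rids)) != len(rids):
            raise ModelParseError("duplicate reaction ids")
        for r in reactions:
            for s in (*r.reactants, *r.products):
                if s not in self._index:
                    raise ModelParseError(
                        f"reaction {r.rid}: unknown species {s!r}"
                    )
            if r.kind == CUSTOM and not r.rate_expression:
                raise ModelParseError(
                    f"custom reaction {r.rid} lacks a rate expression"
                )
        self.thermo = wegscheider_decompose(self, free_choice)
        self.parameter_space = self._build_parameter_space()

    # -- basic accessors -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def mass_action_reactions(self) -> list[ReactionDef]:
        return [r for r in self.reactions if r.is_mass_action]

    @property
    def custom_reactions(self) -> list[ReactionDef]:
        return [r for r in self.reactions if not r.is_mass_action]

    @property
    def kd_names(self) -> list[str]:
        return [r.kd_name for r in self.mass_action_reactions]

    @property
    def kf_names(self) -> list[str]:
        return [r.kf_name for r in self.mass_action_reactions]

    def species_index(self, name: str) -> int:
        return self._index[name]

    def elementary_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if s.role == "elementary"]

    def custom_parameter_names(self) -> list[str]:
        syms: list[str] = []
        for r in self.custom_reactions:
            expr = sp.sympify(r.rate_expression, rational=False)
            for s in sorted(expr.free_symbols, key=lambda x: x.name):
                if s.name not in self._index and s.name not in syms:
                    syms.append(s.name)
        return syms

    def _build_parameter_space(self) -> ParameterSpace:
        names: list[str] = []
        kinds: dict[str, str] = {}
        constrained = set(self.thermo.constrained_names)
        for r in self.mass_action_reactions:
            names.append(r.kd_name)
            kinds[r.kd_name] = (
                "constrained_kd" if r.kd_name in constrained else "free_kd"
            )
        for r in self.mass_action_reactions:
            names.append(r.kf_name)
            kinds[r.kf_name] = "kinetic_kf"
        for p in self.custom_parameter_names():
            names.append(p)
            kinds[p] = "custom_rate"
        return ParameterSpace(names=names, kinds=kinds)


# ---------------------------------------------------------------------------
# Tabular text format
# ---------------------------------------------------------------------------

_ARROW_REV = "<=>"
_ARROW_IRR = "->"


def _parse_side(side: str, rid: str) -> tuple[str, ...]:
    parts = [p.strip() for p in side.split("+")]
    out: list[str] = []
    for p in parts:
        if not p or p == "0":
            continue
        m = re.fullmatch(r"(?:(\d+)\s*\*?\s*)?([A-Za-z_]\w*)", p)
        if not m:
            raise ModelParseError(f"reaction {rid}: cannot parse term {p!r}")
        out.extend([m.group(2)] * int(m.group(1) or 1))
    return tuple(out)


def parse_model(text: str, free_choice: Sequence[str] | None = None) -> ReactionNetwork:
    """Parse a model from the ``!!Species`` / ``!!Reaction`` / ``!!Parameter``
    TSV table text and return a validated :class:`ReactionNetwork`."""
    tables: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("!!"):
            current = tables.setdefault(line.strip(), [])
            continue
        if current is None:
            raise ModelParseError(f"line {lineno}: data before any !!table header")
        current.append(line.split("\t"))

    if "!!Species" not in tables or "!!Reaction" not in tables:
        raise ModelParseError("model must contain !!Species and !!Reaction tables")

    def rows(table: str) -> list[dict[str, str]]:
        data = tables.get(table, [])
        if not data:
            return []
        header = [h.strip() for h in data[0]]
        return [dict(zip(header, (c.strip() for c in r))) for r in data[1:]]

    species = [
        SpeciesDef(
            name=r["Name"],
            role=r.get("Role", "elementary") or "elementary",
            default_total=float(r.get("DefaultTotal") or 0.0),
        )
        for r in rows("!!Species")
    ]

    param_rows = {r["Name"]: r for r in rows("!!Parameter")}

    reactions: list[ReactionDef] = []
    ma_counter = 0
    for r in rows("!!Reaction"):
        rid = r["Id"]
        formula = r["Formula"]
        kind = r.get("Kind", "") or MASS_ACTION
        if kind in ("mass_action", MASS_ACTION):
            kind = MASS_ACTION
        elif kind != CUSTOM:
            raise ModelParseError(f"reaction {rid}: unknown kind {kind!r}")
        if _ARROW_REV in formula:
            lhs, rhs = formula.split(_ARROW_REV)
            if kind == CUSTOM:
                raise ModelParseError(
                    f"reaction {rid}: custom reactions must use '->'"
                )
        elif _ARROW_IRR in formula:
            lhs, rhs = formula.split(_ARROW_IRR)
            if kind == MASS_ACTION:
                raise ModelParseError(
                    f"reaction {rid}: mass-action reactions must be reversible"
                    " ('<=>')"
                )
        else:
            raise ModelParseError(f"reaction {rid}: no arrow in formula {formula!r}")
        reactants = _parse_side(lhs, rid)
        products = _parse_side(rhs, rid)
        if kind == MASS_ACTION:
            ma_counter += 1
            reactions.append(
                ReactionDef(
                    rid=rid,
                    reactants=reactants,
                    products=products,
                    kind=MASS_ACTION,
                    kf_name=f"kf{ma_counter}",
                    kr_name=f"kr{ma_counter}",
                    kd_name=f"Kd{ma_counter}",
                )
            )
        else:
            expr = r.get("RateExpression", "")
            reactions.append(
                ReactionDef(
                    rid=rid,
                    reactants=reactants,
                    products=products,
                    kind=CUSTOM,
                    rate_expression=expr,
                )
            )

    net = ReactionNetwork(species, reactions, free_choice=free_choice)
    for name, row in param_rows.items():
        if name not in net.parameter_space.kinds:
            raise ModelParseError(f"parameter table names unknown parameter {name!r}")
        if row.get("DefaultLog10"):
            net.parameter_space.defaults_log10[name] = float(row["DefaultLog10"])
    return net


def serialize_model(net: ReactionNetwork) -> str:
    """Serialize to the tabular text format; stable byte-identical output."""
    out: list[str] = ["!!Species", "Name\tRole\tDefaultTotal"]
    for s in net.species:
        out.append(f"{s.name}\t{s.role}\t{format(s.default_total, '.10g')}")
    out.append("!!Reaction")
    out.append("Id\tFormula\tKind\tRateExpression")
    for r in net.reactions:
        arrow = _ARROW_REV if r.is_mass_action else _ARROW_IRR
        lhs = " + ".join(r.reactants)
        rhs = " + ".join(r.products)
        out.append(f"{r.rid}\t{lhs} {arrow} {rhs}\t{r.kind}\t{r.rate_expression}")
    defaults = net.parameter_space.defaults_log10
    if defaults:
        out.append("!!Parameter")
        out.append("Name\tKind\tDefaultLog10")
        for name in net.parameter_space.names:
            if name in defaults:
                kind = net.parameter_space.kinds[name]
                out.append(f"{name}\t{kind}\t{format(defaults[name], '.10g')}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Stoichiometry and conservation
# ---------------------------------------------------------------------------

def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer matrix N with N[i, j] = net production of species i by unit
    forward progress of reaction j."""
    n_s, n_r = len(net.species), len(net.reactions)
    N = np.zeros((n_s, n_r), dtype=int)
    for j, r in enumerate(net.reactions):
        for s in r.reactants:
            N[net.species_index(s), j] -= 1
        for s in r.products:
            N[net.species_index(s), j] += 1
    return N


def _moiety_composition(net: ReactionNetwork) -> tuple[list[list[str]], np.ndarray]:
    """Moiety classes (groups of interconvertible elementary species) and the
    composition matrix C (classes x species): C[m, s] = copies of moiety m
    inside species s.  Raises if a species' composition cannot be resolved or
    a conservation vector fails c^T N = 0."""
    elem = [s.name for s in net.elementary_species()]
    parent = {e: e for e in elem}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # interconversions among elementary species merge their moieties
    for r in net.reactions:
        involved = set(r.reactants) | set(r.products)
        if involved and all(s in parent for s in involved):
            rep = find(next(iter(involved)))
            for s in involved:
                parent[find(s)] = rep

    classes: dict[str, int] = {}
    labels: list[list[str]] = []
    for e in elem:
        rep = find(e)
        if rep not in classes:
            classes[rep] = len(labels)
            labels.append([])
        labels[classes[rep]].append(e)

    comp: dict[str, np.ndarray] = {}
    m = len(labels)
    for e in elem:
        v = np.zeros(m, dtype=int)
        v[classes[find(e)]] = 1
        comp[e] = v
    # resolve complex compositions from reaction balance, to fixed point
    unresolved = {s.name for s in net.species if s.name not in comp}
    changed = True
    while unresolved and changed:
        changed = False
        for r in net.reactions:
            terms = list(r.reactants) + list(r.products)
            unknown = [s for s in set(terms) if s not in comp]
            if len(unknown) != 1:
                continue
            u = unknown[0]
            if r.reactants.count(u) + r.products.count(u) != 1:
                continue
            bal = np.zeros(m, dtype=int)
            for s in r.reactants:
                if s != u:
                    bal += comp[s]
            for s in r.products:
                if s != u:
                    bal -= comp[s]
            comp[u] = bal if u in r.products else -bal
            if np.any(comp[u] < 0):
                raise ModelParseError(
                    f"species {u}: negative moiety composition from {r.rid}"
                )
            unresolved.discard(u)
            changed = True
    if unresolved:
        raise ModelParseError(
            "cannot resolve moiety composition for: " + ", ".join(sorted(unresolved))
        )
    C = np.stack([np.array([comp[s.name][k] for s in net.species]) for k in range(m)])
    N = stoichiometric_matrix(net)
    bad = np.nonzero(np.any(C @ N != 0, axis=1))[0]
    if bad.size:
        raise ModelParseError(
            f"moiety vector(s) {bad.tolist()} are not conserved by the reactions"
        )
    return labels, C


def conservation_laws(net: ReactionNetwork) -> list[tuple[str, np.ndarray]]:
    """Moiety conservation laws: for each class of interconvertible elementary
    species, a nonnegative integer vector c over species with c^T N = 0.
    Returned labels name the class by its member elementary species."""
    labels, C = _moiety_composition(net)
    return [("+".join(lab), C[k]) for k, lab in enumerate(labels)]


# ---------------------------------------------------------------------------
# Wegscheider constraints
# ---------------------------------------------------------------------------

def wegscheider_decompose(
    net: ReactionNetwork, free_choice: Sequence[str] | None = None
) -> ThermoConstraints:
    """Cycle-closure constraints on log10 Kd from the null space of the
    mass-action stoichiometric columns.

    One Kd per independent cycle is designated constrained and solved for in
    terms of the free log-Kds.  With ``free_choice`` given (ordered Kd names
    preferred to stay free), the complement is constrained first; the default
    preference constrains the last-indexed reaction of each cycle.
    """
    ma = net.mass_action_reactions
    kd_names = [r.kd_name for r in ma]
    n = len(ma)
    N_full = stoichiometric_matrix(net)
    cols = [j for j, r in enumerate(net.reactions) if r.is_mass_action]
    N = sp.Matrix(N_full[:, cols])
    null = N.nullspace()
    if not null:
        Z = np.zeros((0, n), dtype=int)
        return ThermoConstraints(kd_names, Z, list(kd_names), [], {})

    # integer-scale each basis vector
    zrows = []
    for v in null:
        denoms = [sp.Rational(x).q for x in v]
        scale = sp.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
        w = [sp.Integer(x * scale) for x in v]
        g = sp.igcd(*[abs(x) for x in w if x != 0])
        zrows.append([int(x / g) for x in w])
    Z = sp.Matrix(zrows)
    m = Z.shape[0]

    # column order: candidates to constrain first (rref pivots = constrained)
    if free_choice is not None:
        pref_free = [kd_names.index(f) for f in free_choice if f in kd_names]
        rest = [j for j in range(n) if j not in pref_free]
        order = rest[::-1] + pref_free[::-1]
    else:
        order = list(range(n))[::-1]
    Zp = Z[:, order]
    R, pivots = Zp.rref()
    if len(pivots) != m:
        raise ModelParseError("degenerate cycle basis")
    constrained_idx = [order[p] for p in pivots]
    if free_choice is not None and any(
        kd_names[j] in free_choice for j in constrained_idx
    ):
        clash = [kd_names[j] for j in constrained_idx if kd_names[j] in free_choice]
        raise ModelParseError(
            "free_choice infeasible: forced to constrain " + ", ".join(clash)
        )
    constrained = [kd_names[j] for j in sorted(constrained_idx)]
    free = [nm for nm in kd_names if nm not in constrained]

    solved: dict[str, dict[str, Fraction]] = {}
    for row_i, p in enumerate(pivots):
        target = kd_names[order[p]]
        coeffs: dict[str, Fraction] = {}
        for c in range(Zp.shape[1]):
            if c == p:
                continue
            val = R[row_i, c]
            if val != 0:
                # pivot*logKd_target + sum val*logKd_other = 0
                coeffs[kd_names[order[c]]] = Fraction(-sp.Rational(val))
        solved[target] = coeffs

    # back-substitute so solved forms reference only free parameters
    for _ in range(m):
        dirty = False
        for t, coeffs in solved.items():
            for other in [k for k in coeffs if k in solved]:
                w = coeffs.pop(other)
                for k2, v2 in solved[other].items():
                    coeffs[k2] = coeffs.get(k2, Fraction(0)) + w * v2
                dirty = True
        if not dirty:
            break
    solved = {t: {k: v for k, v in c.items() if v != 0} for t, c in solved.items()}

    Zint = np.array(Z.tolist(), dtype=int)
    return ThermoConstraints(kd_names, Zint, free, constrained, solved)


def complete_kd(
    constraints: ThermoConstraints, free_log_kd: Mapping[str, float]
) -> dict[str, float]:
    """Fill constrained log10 Kd entries from the free ones via the solved
    cycle identities; returns the full {kd_name: log10 Kd} mapping."""
    missing = [f for f in constraints.free_names if f not in free_log_kd]
    if missing:
        raise KeyError(f"missing free Kd value(s): {', '.join(missing)}")
    full = {f: float(free_log_kd[f]) for f in constraints.free_names}
    for t in constraints.constrained_names:
        full[t] = float(
            sum(float(c) * full[k] for k, c in constraints.solved_form[t].items())
        )
    return {name: full[name] for name in constraints.kd_names}


# ---------------------------------------------------------------------------
# Detailed-balance equilibrium
# ---------------------------------------------------------------------------

class _EquilibriumPlan:
    """Resolution order expressing every species' log-concentration from the
    moiety-representative log-concentrations via detailed balance."""

    def __init__(self, net: ReactionNetwork):
        if net.custom_reactions:
            # custom reactions carry no detailed-balance structure; the
            # equilibrium solve applies to the mass-action subnetwork only
            pass
        labels, C = _moiety_composition(net)
        self.labels = labels
        self.C = C
        self.reps = [lab[0] for lab in labels]
        self.species = net.species_names
        known = set(self.reps)
        # steps: (target, [(name, coef), ...], kd_name, kd_coef)
        # log[target] = sum coef*log[name] + kd_coef*log10 Kd ... in log10
        steps: list[tuple[str, list[tuple[str, int]], str, int]] = []
        remaining = set(self.species) - known
        while remaining:
            progress = False
            for r in net.mass_action_reactions:
                terms = list(r.reactants) + list(r.products)
                unknown = [s for s in set(terms) if s in remaining]
                if len(unknown) != 1:
                    continue
                u = unknown[0]
                mult = r.reactants.count(u) - r.products.count(u)
                if abs(mult) != 1:
                    continue
                # log Kd = sum_R log x - sum_P log x
                # mult*log[u] = log Kd - (sum_R' - sum_P') log[known]
                coefs: dict[str, int] = {}
                for s in r.reactants:
                    if s != u:
                        coefs[s] = coefs.get(s, 0) - 1
                for s in r.products:
                    if s != u:
                        coefs[s] = coefs.get(s, 0) + 1
                if mult == 1:  # u on reactant side
                    steps.append((u, list(coefs.items()), r.kd_name, +1))
                else:  # u among products: log[u] = -logKd + sum_R - sum_P'
                    steps.append(
                        (u, [(k, -v) for k, v in coefs.items()], r.kd_name, -1)
                    )
                remaining.discard(u)
                progress = True
            if not progress:
                raise EquilibriumError(
                    "cannot express species from moiety representatives: "
                    + ", ".join(sorted(remaining))
                )
        self.steps = steps

    def log_concentrations(
        self, rep_log: np.ndarray, log_kd: Mapping[str, float]
    ) -> dict[str, float]:
        logs = {rep: rep_log[i] for i, rep in enumerate(self.reps)}
        for target, coefs, kd_name, kd_coef in self.steps:
            logs[target] = kd_coef * log_kd[kd_name] + sum(
                c * logs[s] for s, c in coefs
            )
        return logs


def solve_equilibrium(
    net: ReactionNetwork,
    log_kd: Mapping[str, float],
    totals: Mapping[str, float],
    x0_log: Mapping[str, float] | None = None,
    tol: float = 1e-12,
) -> dict[str, float]:
    """Detailed-balance equilibrium of the mass-action subnetwork.

    Solves for log10 concentrations of one representative elementary species
    per conserved moiety; all other species follow from the cycle-consistent
    dissociation constants.  ``totals`` maps elementary species to their
    conserved totals (µM); members of a merged moiety class may be given
    individually and are summed.
    """
    for s, t in totals.items():
        if t < 0:
            raise ValueError(f"negative total for {s}")
    plan = getattr(net, "_eq_plan", None)
    if plan is None:
        plan = _EquilibriumPlan(net)
        net._eq_plan = plan  # type: ignore[attr-defined]
    m = len(plan.reps)
    class_tot = np.zeros(m)
    for k, lab in enumerate(plan.labels):
        class_tot[k] = sum(float(totals.get(e, 0.0)) for e in lab)

    active = class_tot > 0.0
    zero_species = {
        s
        for i, s in enumerate(net.species_names)
        if np.any((plan.C[:, i] > 0) & ~active)
    }
    if not np.any(active):
        return {s: 0.0 for s in net.species_names}

    sub_idx = np.nonzero(active)[0]
    sp_names = net.species_names
    keep = [i for i, s in enumerate(sp_names) if s not in zero_species]

    def fill(rep_sub: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
        rep_log = np.full(m, -300.0)
        rep_log[sub_idx] = rep_sub
        logs = plan.log_concentrations(rep_log, log_kd)
        x = np.array([10.0 ** logs[s] if s not in zero_species else 0.0
                      for s in sp_names])
        return x, logs

    def residual(rep_sub: np.ndarray) -> np.ndarray:
        x, _ = fill(rep_sub)
        tot = plan.C[:, keep] @ x[keep]
        return np.log10(np.maximum(tot[sub_idx], 1e-300)) - np.log10(
            class_tot[sub_idx]
        )

    # initial guess: totals split evenly over the species of each class
    counts = (plan.C[:, keep] > 0).sum(axis=1)
    guess = np.log10(class_tot[sub_idx] / np.maximum(counts[sub_idx], 1))
    if x0_log is not None:
        for i, k in enumerate(sub_idx):
            rep = plan.reps[k]
            if rep in x0_log:
                guess[i] = x0_log[rep]

    sol = root(residual, guess, method="hybr", tol=tol)
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-7:
        sol = root(residual, guess, method="lm", tol=tol)
    res = np.max(np.abs(residual(sol.x)))
    if res > 1e-7:
        raise EquilibriumError(
            f"equilibrium solve failed: max |conservation residual| = {res:.3e}"
        )
    x, _ = fill(sol.x)
    return dict(zip(sp_names, x))


# ---------------------------------------------------------------------------
# ODE integration
# ---------------------------------------------------------------------------

def _rate_constants(
    net: ReactionNetwork, theta: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-scale (kf, kr) per mass-action reaction from log10 parameters;
    kr = Kd * kf."""
    full_kd = complete_kd(
        net.thermo, {k: theta[k] for k in net.thermo.free_names}
    )
    kf = np.array([10.0 ** theta[r.kf_name] for r in net.mass_action_reactions])
    kd = np.array([10.0 ** full_kd[r.kd_name] for r in net.mass_action_reactions])
    return kf, kd * kf


def _custom_rate_fns(
    net: ReactionNetwork, theta: Mapping[str, float]
) -> list[Callable[[np.ndarray], float]]:
    fns = []
    sp_syms = sp.symbols(net.species_names)
    for r in net.custom_reactions:
        expr = sp.sympify(r.rate_expression, rational=False)
        subs = {
            s: 10.0 ** theta[s.name]
            for s in expr.free_symbols
            if s.name in theta and s.name not in net.species_names
        }
        f = sp.lambdify(sp_syms, expr.subs(subs), modules="numpy")
        fns.append(lambda x, f=f: float(f(*x)))
    return fns


def simulate_ode(
    net: ReactionNetwork,
    theta: Mapping[str, float],
    input_schedule: Callable[[float], Mapping[str, float]] | None,
    x0: Mapping[str, float] | Sequence[float],
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate dx/dt = N v(x; θ) (+ input injection) on a stiff-capable
    solver; returns an array (len(times), n_species) ordered as the network's
    species list.  ``theta`` maps parameter names to log10 values."""
    sp_names = net.species_names
    if isinstance(x0, Mapping):
        y0 = np.array([float(x0.get(s, 0.0)) for s in sp_names])
    else:
        y0 = np.asarray(x0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("negative initial concentration")

    N = stoichiometric_matrix(net)
    ma_cols = [j for j, r in enumerate(net.reactions) if r.is_mass_action]
    cu_cols = [j for j, r in enumerate(net.reactions) if not r.is_mass_action]
    N_ma = N[:, ma_cols]
    N_cu = N[:, cu_cols]
    kf, kr = _rate_constants(net, theta)
    react_idx = [
        [net.species_index(s) for s in r.reactants]
        for r in net.mass_action_reactions
    ]
    prod_idx = [
        [net.species_index(s) for s in r.products]
        for r in net.mass_action_reactions
    ]
    custom_fns = _custom_rate_fns(net, theta)
    inj_idx: list[int] = []

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xp = np.maximum(x, 0.0)
        v = np.array(
            [
                kf[j] * np.prod(xp[react_idx[j]]) - kr[j] * np.prod(xp[prod_idx[j]])
                for j in range(len(kf))
            ]
        )
        dx = N_ma @ v
        if custom_fns:
            vc = np.array([f(xp) for f in custom_fns])
            dx = dx + N_cu @ vc
        if input_schedule is not None:
            for s, rate in input_schedule(t).items():
                dx[net.species_index(s)] += rate
        return dx

    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T
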
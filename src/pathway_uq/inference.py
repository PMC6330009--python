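"""Likelihood-free (ABC) inference for pathway model parameters.

The posterior f(theta | rho(y_sim, y_exp) <= delta) is sampled either by
plain rejection or by a Markov chain with the Marjoram acceptance rule:
a Gaussian random-walk proposal in log10 parameter space is accepted iff its
simulated distance passes the current threshold AND a Metropolis ratio on
the prior density passes.  The threshold starts at the chain's initial
distance and shrinks geometrically to the target, so the chain first finds
the viable space and then samples it.

Multiple datasets are merged sequentially: the posterior sample after each
group of experiments is compressed into a copula prior (see
:mod:`pathway_uq.copula`) and used as the prior for the next group.  For
semi-steady-state data the Kd-only posterior can be expanded to the kinetic
kf parameters by rejection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .copula import CopulaPrior, fit_vine
from .experiments import Curve, DistanceSpec, ExperimentSetup, distance, simulate_setup
from .network import ReactionNetwork

__all__ = [
    "PriorSpec",
    "ABCConfig",
    "PosteriorSample",
    "abc_rejection",
    "abc_mcmc",
    "sequential_fit",
    "expand_rates",
    "make_simulator",
    "default_prior",
]


class PriorSpec:
    """Parameter prior: a log-uniform box (centers +/- half_width in log10
    space, the default construction) or a fitted copula prior."""

    def __init__(
        self,
        names: Sequence[str],
        centers: Sequence[float] | None = None,
        half_width: float = 3.0,
        copula: CopulaPrior | None = None,
    ) -> None:
        self.names = list(names)
        if copula is not None:
            if copula.dim != len(self.names):
                raise ValueError("copula dimension does not match names")
            self.kind = "copula"
            self.copula = copula
            self.lo = np.array([m.lo for m in copula.marginals])
            self.hi = np.array([m.hi for m in copula.marginals])
        else:
            if centers is None:
                raise ValueError("box prior requires centers")
            if half_width <= 0:
                raise ValueError("half_width must be positive")
            self.kind = "log_uniform_box"
            self.copula = None
            c = np.asarray(centers, dtype=float)
            self.centers = c
            self.half_width = float(half_width)
            self.lo = c - half_width
            self.hi = c + half_width
        if not (np.all(np.isfinite(self.lo)) and np.all(np.isfinite(self.hi))):
            raise ValueError("prior bounds must be finite")

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "copula":
            return self.copula.sample(n, rng)
        return rng.uniform(self.lo, self.hi, size=(n, self.dim))

    def log_density(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < self.lo) or np.any(theta > self.hi):
            return -np.inf
        if self.kind == "copula":
            return float(self.copula.log_density(theta))
        return float(-np.sum(np.log(self.hi - self.lo)))

    def in_support(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lo) and np.all(theta <= self.hi))


def default_prior(
    net: ReactionNetwork,
    names: Sequence[str] | None = None,
    half_width: float = 3.0,
) -> PriorSpec:
    """Log-uniform box prior centered at the model's default log10 values
    (centers mu_i, bounds mu_i +/- half_width; half_width defaults to 3)."""
    if names is None:
        names = net.thermo.free_names
    defaults = net.parameter_space.defaults_log10
    centers = [defaults.get(n, 0.0) for n in names]
    return PriorSpec(names, centers, half_width)


@dataclass
class ABCConfig:
    delta_target: float = 0.05
    n_samples: int = 1000
    n_iterations: int = 2000
    proposal_step: float | np.ndarray = 0.15
    adapt_block: int = 200
    adapt_factor: float = 0.9
    burn_in: float = 0.2
    thin: int = 1
    seed: int = 0
    max_adapt_iterations: int = 200_000
    stuck_window: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 < self.adapt_factor < 1.0):
            raise ValueError("adapt_factor must be in (0, 1)")
        if self.delta_target < 0:
            raise ValueError("delta_target must be >= 0")


@dataclass
class PosteriorSample:
    """Accepted log10 parameter matrix with per-row distances and run
    provenance (which experiment groups it is conditioned on)."""

    matrix: np.ndarray
    names: list[str]
    distances: np.ndarray
    seed: int
    provenance: list[str] = field(default_factory=list)
    delta: float = np.inf
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.distances = np.asarray(self.distances, dtype=float)
        if self.matrix.shape[0] != self.distances.shape[0]:
            raise ValueError("matrix and distances row counts differ")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix width and names length differ")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def row_dict(self, i: int) -> dict[str, float]:
        return dict(zip(self.names, self.matrix[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df["_distance"] = self.distances
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "seed": self.seed,
            "delta": None if np.isinf(self.delta) else self.delta,
            "provenance": self.provenance,
            **{
                k: v
                for k, v in self.info.items()
                if isinstance(v, (int, float, str, list))
            },
        }
        with open(path + ".meta.json", "w") as f:
            json.dump(meta, f, indent=1)

    @classmethod
    def from_tsv(cls, path: str) -> "PosteriorSample":
        df = pd.read_csv(path, sep="\t")
        names = [c for c in df.columns if c != "_distance"]
        dist = (
            df["_distance"].to_numpy()
            if "_distance" in df
            else np.zeros(len(df))
        )
        return cls(df[names].to_numpy(), names, dist, seed=-1)


# ---------------------------------------------------------------------------
# Simulator plumbing
# ---------------------------------------------------------------------------

def make_simulator(
    net: ReactionNetwork,
    setups: Sequence[ExperimentSetup],
    names: Sequence[str],
    fixed: Mapping[str, float] | None = None,
    distance_spec: DistanceSpec | None = None,
) -> tuple[Callable[[np.ndarray], list[Curve]], Callable[[list[Curve]], float]]:
    """Build (simulator, distance_fn) closures for a parameter vector ordered
    as ``names``; ``fixed`` supplies log10 values for parameters not sampled
    (e.g. kf held constant during a Kd-only fit)."""
    data = [s.data for s in setups]
    if any(c is None for c in data):
        raise ValueError("every setup needs a data curve")
    fixed = dict(fixed or {})

    def simulator(theta: np.ndarray) -> list[Curve]:
        th = {**fixed, **dict(zip(names, np.asarray(theta, dtype=float)))}
        return [simulate_setup(net, th, s) for s in setups]

    def distance_fn(sim: list[Curve]) -> float:
        return distance(sim, data, distance_spec)

    return simulator, distance_fn


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def abc_rejection(
    prior: PriorSpec,
    simulator: Callable[[np.ndarray], object],
    distance_fn: Callable[[object], float],
    delta: float,
    n_target: int,
    seed: int = 0,
    max_proposals: int | None = None,
    min_acceptance: float = 1e-4,
) -> PosteriorSample:
    """Plain ABC rejection: draw from the prior, keep draws whose simulated
    distance is at most delta, until ``n_target`` rows are accepted."""
    rng = np.random.default_rng(seed)
    if max_proposals is None:
        max_proposals = max(int(n_target / min_acceptance), 100_000)
    rows, dists = [], []
    proposed = 0
    batch = max(n_target, 256)
    while len(rows) < n_target:
        if proposed >= max_proposals:
            rate = len(rows) / max(proposed, 1)
            raise RuntimeError(
                f"ABC rejection acceptance rate {rate:.2e} below floor after "
                f"{proposed} proposals; increase delta or narrow the prior"
            )
        thetas = prior.sample(batch, rng)
        for th in thetas:
            proposed += 1
            rho = distance_fn(simulator(th))
            if rho <= delta:
                rows.append(th)
                dists.append(rho)
                if len(rows) >= n_target:
                    break
    return PosteriorSample(
        np.array(rows),
        list(prior.names),
        np.array(dists),
        seed=seed,
        delta=delta,
        info={"n_proposals": proposed, "acceptance_rate": n_target / proposed},
    )


def abc_mcmc(
    prior: PriorSpec,
    simulator: Callable[[np.ndarray], object],
    distance_fn: Callable[[object], float],
    config: ABCConfig,
    start: np.ndarray | None = None,
) -> PosteriorSample:
    """ABC-MCMC with an adaptive acceptance threshold.

    The threshold delta starts at the initial state's distance and shrinks by
    ``adapt_factor`` every ``adapt_block`` iterations until it reaches
    ``delta_target``; only post-burn-in states sampled at the target
    threshold are retained.
    """
    rng = np.random.default_rng(config.seed)
    d = prior.dim
    step = np.broadcast_to(np.asarray(config.proposal_step, dtype=float), (d,))

    if start is not None:
        theta = np.asarray(start, dtype=float)
        rho = distance_fn(simulator(theta))
    else:
        theta, rho = None, np.inf
        for _ in range(200):
            cand = prior.sample(1, rng)[0]
            r = distance_fn(simulator(cand))
            if np.isfinite(r) and (theta is None or r < rho):
                theta, rho = cand, r
        if theta is None:
            raise RuntimeError("could not find a finite-distance start point")
    lp = prior.log_density(theta)
    delta = max(config.delta_target, rho)
    delta_trace = [delta]

    retained: list[np.ndarray] = []
    dists: list[float] = []
    n_accept = 0
    n_prop = 0
    since_accept = 0
    sampling_iter = 0
    burn = int(config.burn_in * config.n_iterations)

    while True:
        adapting = delta > config.delta_target
        theta_p = theta + step * rng.standard_normal(d)
        n_prop += 1
        lp_p = prior.log_density(theta_p)
        accept = False
        if np.isfinite(lp_p):
            rho_p = distance_fn(simulator(theta_p))
            if rho_p <= delta and np.log(rng.uniform()) < lp_p - lp:
                accept = True
        if accept:
            theta, rho, lp = theta_p, rho_p, lp_p
            n_accept += 1
            since_accept = 0
        else:
            since_accept += 1
            if since_accept >= config.stuck_window:
                raise RuntimeError(
                    f"chain stuck: no acceptance in {config.stuck_window} "
                    f"proposals (delta={delta:.4g}, distance={rho:.4g})"
                )
        if adapting:
            if n_prop % config.adapt_block == 0:
                delta = max(config.delta_target, config.adapt_factor * delta)
                delta_trace.append(delta)
            if n_prop >= config.max_adapt_iterations:
                raise RuntimeError(
                    f"threshold adaptation did not reach target after "
                    f"{n_prop} iterations (delta={delta:.4g})"
                )
        else:
            sampling_iter += 1
            if (
                sampling_iter > burn
                and rho <= config.delta_target
                and (sampling_iter - burn) % config.thin == 0
            ):
                retained.append(theta.copy())
                dists.append(rho)
            if sampling_iter >= config.n_iterations:
                break

    return PosteriorSample(
        np.array(retained),
        list(prior.names),
        np.array(dists),
        seed=config.seed,
        delta=config.delta_target,
        info={
            "acceptance_rate": n_accept / n_prop,
            "n_proposals": n_prop,
            "delta_trace": [float(x) for x in delta_trace],
        },
    )


def sequential_fit(
    net: ReactionNetwork,
    groups: Sequence[Sequence[ExperimentSetup]],
    prior0: PriorSpec,
    config: ABCConfig,
    fixed: Mapping[str, float] | None = None,
    distance_spec: DistanceSpec | None = None,
    copula_families: Sequence[str] | None = None,
) -> PosteriorSample:
    """Sequential multi-dataset fitting through the copula chain.

    Each group of experiments is fitted by :func:`abc_mcmc` with the current
    prior; the resulting sample is compressed into a :class:`CopulaPrior`
    (marginals bounded by the current prior's support) that becomes the prior
    for the next group.  Provenance lists all groups in order.
    """
    if not groups:
        raise ValueError("need at least one experiment group")
    prior = prior0
    provenance: list[str] = []
    sample: PosteriorSample | None = None
    for gi, group in enumerate(groups):
        simulator, distance_fn = make_simulator(
            net, group, prior0.names, fixed=fixed, distance_spec=distance_spec
        )
        cfg = ABCConfig(**{**config.__dict__, "seed": config.seed + gi})
        sample = abc_mcmc(prior, simulator, distance_fn, cfg)
        provenance.extend(s.id for s in group)
        sample.provenance = list(provenance)
        if gi < len(groups) - 1:
            bounds = list(zip(prior.lo, prior.hi))
            kwargs = {} if copula_families is None else {"families": copula_families}
            cop = fit_vine(
                sample.matrix, bounds=bounds, names=prior0.names, **kwargs
            )
            prior = PriorSpec(prior0.names, copula=cop)
    assert sample is not None
    return sample


def expand_rates(
    kd_posterior: PosteriorSample,
    kf_prior: PriorSpec,
    net: ReactionNetwork,
    dynamic_setups: Sequence[ExperimentSetup],
    delta: float,
    seed: int = 0,
    n_target: int | None = None,
    fixed: Mapping[str, float] | None = None,
    distance_spec: DistanceSpec | None = None,
    max_proposals: int | None = None,
) -> PosteriorSample:
    """Expand a Kd posterior to the kinetic kf parameters by rejection.

    Rows of the Kd posterior are resampled; kf vectors are drawn from their
    prior; the joint draw is kept iff the distance on the dynamic setups is
    at most delta (kr follows as Kd*kf).  With no dynamic setups every draw
    is accepted and the kf marginals reproduce the prior.
    """
    rng = np.random.default_rng(seed)
    if n_target is None:
        n_target = kd_posterior.n
    names = list(kd_posterior.names) + list(kf_prior.names)
    if dynamic_setups:
        simulator, distance_fn = make_simulator(
            net, dynamic_setups, names, fixed=fixed, distance_spec=distance_spec
        )
    if max_proposals is None:
        max_proposals = max(200 * n_target, 100_000)
    rows, dists = [], []
    proposed = 0
    while len(rows) < n_target:
        if proposed >= max_proposals:
            raise RuntimeError(
                f"rate expansion acceptance too low after {proposed} proposals"
            )
        i = rng.integers(kd_posterior.n)
        kf = kf_prior.sample(1, rng)[0]
        theta = np.concatenate([kd_posterior.matrix[i], kf])
        proposed += 1
        if dynamic_setups:
            rho = distance_fn(simulator(theta))
            if rho > delta:
                continue
        else:
            rho = 0.0
        rows.append(theta)
        dists.append(rho)
    return PosteriorSample(
        np.array(rows),
        names,
        np.array(dists),
        seed=seed,
        delta=delta,
        provenance=kd_posterior.provenance + [s.id for s in dynamic_setups],
        info={"n_proposals": proposed},
    )
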
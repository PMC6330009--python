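"""Posterior compression by marginal models + a vine pair-copula.

An accepted ABC sample is turned into a reusable, evaluable prior in two
layers: per-parameter kernel-density marginals (with reflection at the
support bounds, since posteriors often pile up at the prior edges), and a
canonical-vine copula capturing the dependence between parameters.  A
canonical vine (C-vine) is a valid regular vine: d-1 trees, each rooted at
the variable most strongly associated (by |Kendall tau|) with the rest.

Pair-copula families: independence, Gaussian, Clayton, Gumbel, Frank.
Parameters are estimated by inversion of Kendall's tau; the family is chosen
per edge by maximized pseudo-likelihood (equivalently AIC, all families
having one parameter), with an asymptotic independence test applied first.

All public entry points work on matrices whose columns are log10 parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats
from scipy.optimize import brentq

__all__ = [
    "MarginalModel",
    "PairCopula",
    "CopulaPrior",
    "fit_marginals",
    "fit_vine",
    "copula_sample",
    "log_density",
    "pseudo_observations",
]

_EPS = 1e-10
_FAMILIES = ("independence", "gaussian", "clayton", "gumbel", "frank")


def _clip(u: np.ndarray | float) -> np.ndarray:
    return np.clip(u, _EPS, 1.0 - _EPS)


# ---------------------------------------------------------------------------
# Marginals
# ---------------------------------------------------------------------------

class MarginalModel:
    """Gaussian-kernel density on a bounded support with boundary reflection.

    The density, CDF and quantile function are tabulated on a regular grid;
    CDF and quantile are exact piecewise-linear inverses of each other.
    """

    def __init__(
        self,
        data: np.ndarray,
        bounds: tuple[float, float] | None = None,
        n_grid: int = 512,
    ) -> None:
        x = np.asarray(data, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("marginal data must be a 1-D sample of size >= 2")
        if not np.all(np.isfinite(x)):
            raise ValueError("marginal data contains non-finite values")
        sd = float(np.std(x, ddof=1))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        if sd == 0.0:
            raise ValueError("degenerate (constant) marginal")
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        self.bandwidth = 0.9 * spread * x.size ** (-1 / 5)
        if bounds is not None:
            lo, hi = float(bounds[0]), float(bounds[1])
        else:
            lo = float(x.min()) - 3.0 * self.bandwidth
            hi = float(x.max()) + 3.0 * self.bandwidth
        if hi <= lo:
            raise ValueError("empty support")
        self.lo, self.hi = lo, hi
        self.grid = np.linspace(lo, hi, n_grid)
        g = self.grid[:, None]
        h = self.bandwidth
        pdf = (
            stats.norm.pdf(g, x[None, :], h)
            + stats.norm.pdf(g, 2 * lo - x[None, :], h)
            + stats.norm.pdf(g, 2 * hi - x[None, :], h)
        ).mean(axis=1)
        pdf = pdf + 1e-12  # keep the CDF strictly increasing
        area = np.trapezoid(pdf, self.grid)
        self.pdf_grid = pdf / area
        cdf = integrate.cumulative_trapezoid(self.pdf_grid, self.grid, initial=0.0)
        self.cdf_grid = cdf / cdf[-1]

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.grid, self.pdf_grid)
        return np.where((x < self.lo) | (x > self.hi), 0.0, out)

    def logpdf(self, x: np.ndarray | float) -> np.ndarray:
        p = self.pdf(x)
        with np.errstate(divide="ignore"):
            return np.log(p)

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.grid, self.cdf_grid)

    def ppf(self, p: np.ndarray | float) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return np.interp(p, self.cdf_grid, self.grid)

    def to_dict(self) -> dict:
        return {
            "lo": self.lo,
            "hi": self.hi,
            "bandwidth": self.bandwidth,
            "grid": self.grid.tolist(),
            "pdf": self.pdf_grid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalModel":
        obj = cls.__new__(cls)
        obj.lo, obj.hi = d["lo"], d["hi"]
        obj.bandwidth = d["bandwidth"]
        obj.grid = np.array(d["grid"])
        obj.pdf_grid = np.array(d["pdf"])
        cdf = integrate.cumulative_trapezoid(obj.pdf_grid, obj.grid, initial=0.0)
        obj.cdf_grid = cdf / cdf[-1]
        return obj


def fit_marginals(
    sample: np.ndarray, bounds: Sequence[tuple[float, float]] | None = None
) -> list[MarginalModel]:
    """One :class:`MarginalModel` per column of ``sample``."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    return [
        MarginalModel(sample[:, j], None if bounds is None else bounds[j])
        for j in range(sample.shape[1])
    ]


def pseudo_observations(sample: np.ndarray) -> np.ndarray:
    """Rank-based uniform scores u = rank/(n+1), columnwise."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    n = sample.shape[0]
    return (np.argsort(np.argsort(sample, axis=0), axis=0) + 1.0) / (n + 1.0)


# ---------------------------------------------------------------------------
# Pair copulas
# ---------------------------------------------------------------------------

def _debye1(t: float) -> float:
    if t == 0.0:
        return 1.0
    val, _ = integrate.quad(lambda x: x / np.expm1(x), 0.0, abs(t))
    d = val / abs(t)
    if t < 0:
        d = d + abs(t) / 2.0
    return d


def _frank_tau(theta: float) -> float:
    if abs(theta) < 1e-8:
        return theta / 9.0
    return 1.0 - 4.0 / theta * (1.0 - _debye1(theta))


@dataclass
class PairCopula:
    family: str
    par: float = 0.0

    # -- density ---------------------------------------------------------
    def logpdf(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u, v = _clip(u), _clip(v)
        f, t = self.family, self.par
        if f == "independence":
            return np.zeros(np.broadcast(u, v).shape)
        if f == "gaussian":
            a, b = stats.norm.ppf(u), stats.norm.ppf(v)
            r2 = t * t
            return -0.5 * np.log1p(-r2) - (
                r2 * (a * a + b * b) - 2 * t * a * b
            ) / (2 * (1 - r2))
        if f == "clayton":
            s = u ** (-t) + v ** (-t) - 1.0
            return (
                np.log1p(t)
                - (t + 1.0) * (np.log(u) + np.log(v))
                - (2.0 + 1.0 / t) * np.log(s)
            )
        if f == "gumbel":
            lu, lv = -np.log(u), -np.log(v)
            s = lu**t + lv**t
            lC = -(s ** (1.0 / t))
            return (
                lC
                + lu
                + lv
                + (2.0 / t - 2.0) * np.log(s)
                + (t - 1.0) * (np.log(lu) + np.log(lv))
                + np.log1p((t - 1.0) * s ** (-1.0 / t))
            )
        if f == "frank":
            a = np.expm1(-t * u)
            b = np.expm1(-t * v)
            d = np.expm1(-t)
            return (
                np.log(abs(t))
                + np.log(abs(-d))
                - t * (u + v)
                - 2.0 * np.log(np.abs(d + a * b))
            )
        raise ValueError(f"unknown family {f!r}")

    # -- conditional CDF h(u|v) = dC(u,v)/dv -----------------------------
    def h(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u, v = _clip(u), _clip(v)
        f, t = self.family, self.par
        if f == "independence":
            return np.broadcast_to(u, np.broadcast(u, v).shape).copy()
        if f == "gaussian":
            a, b = stats.norm.ppf(u), stats.norm.ppf(v)
            return _clip(stats.norm.cdf((a - t * b) / np.sqrt(1 - t * t)))
        if f == "clayton":
            s = u ** (-t) + v ** (-t) - 1.0
            return _clip(v ** (-t - 1.0) * s ** (-1.0 / t - 1.0))
        if f == "gumbel":
            lu, lv = -np.log(u), -np.log(v)
            s = lu**t + lv**t
            C = np.exp(-(s ** (1.0 / t)))
            return _clip(C / v * lv ** (t - 1.0) * s ** (1.0 / t - 1.0))
        if f == "frank":
            a = np.expm1(-t * u)
            b = np.expm1(-t * v)
            d = np.expm1(-t)
            return _clip(a * np.exp(-t * v) / (d + a * b))
        raise ValueError(f"unknown family {f!r}")

    # -- inverse conditional CDF in its first argument -------------------
    def hinv(self, w: np.ndarray, v: np.ndarray) -> np.ndarray:
        w, v = _clip(w), _clip(v)
        f, t = self.family, self.par
        if f == "independence":
            return np.broadcast_to(w, np.broadcast(w, v).shape).copy()
        if f == "gaussian":
            a, b = stats.norm.ppf(w), stats.norm.ppf(v)
            return _clip(stats.norm.cdf(a * np.sqrt(1 - t * t) + t * b))
        if f == "clayton":
            inner = (w * v ** (t + 1.0)) ** (-t / (t + 1.0)) + 1.0 - v ** (-t)
            return _clip(inner ** (-1.0 / t))
        if f == "frank":
            b = np.expm1(-t * v)
            d = np.expm1(-t)
            ev = np.exp(-t * v)
            a = w * d / (ev - w * b)
            return _clip(-np.log1p(a) / t)
        if f == "gumbel":
            # no closed form: vectorized bisection, h is increasing in u
            w_b, v_b = np.broadcast_arrays(w, v)
            lo = np.full(w_b.shape, _EPS)
            hi = np.full(w_b.shape, 1.0 - _EPS)
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                less = self.h(mid, v_b) < w_b
                lo = np.where(less, mid, lo)
                hi = np.where(less, hi, mid)
            return 0.5 * (lo + hi)
        raise ValueError(f"unknown family {f!r}")

    def loglik(self, u: np.ndarray, v: np.ndarray) -> float:
        return float(np.sum(self.logpdf(u, v)))


def _fit_family(family: str, tau: float) -> PairCopula | None:
    """Parameter by inversion of Kendall's tau; None if tau is outside the
    family's range."""
    if family == "independence":
        return PairCopula("independence")
    if family == "gaussian":
        rho = np.clip(np.sin(np.pi * tau / 2.0), -0.999, 0.999)
        return PairCopula("gaussian", float(rho))
    if family == "clayton":
        if tau <= 0.0:
            return None
        return PairCopula("clayton", float(min(2.0 * tau / (1.0 - tau), 50.0)))
    if family == "gumbel":
        if tau <= 0.0:
            return None
        return PairCopula("gumbel", float(min(1.0 / (1.0 - tau), 30.0)))
    if family == "frank":
        if abs(tau) < 1e-6:
            return PairCopula("frank", 1e-4 if tau >= 0 else -1e-4)
        if abs(tau) > 0.95:
            tau = np.sign(tau) * 0.95
        theta = brentq(lambda t: _frank_tau(t) - tau, -40.0, 40.0, xtol=1e-6)
        return PairCopula("frank", float(theta))
    raise ValueError(f"unknown family {family!r}")


def select_pair_copula(
    u: np.ndarray,
    v: np.ndarray,
    families: Sequence[str] = _FAMILIES,
    indep_level: float = 0.05,
) -> PairCopula:
    """Fit each admissible family by tau inversion and keep the one with the
    largest pseudo-likelihood; an insignificant Kendall tau short-circuits to
    the independence copula."""
    tau, pval = stats.kendalltau(u, v)
    if not np.isfinite(tau) or (
        "independence" in families and pval > indep_level
    ):
        return PairCopula("independence")
    best: PairCopula | None = None
    best_ll = -np.inf
    for fam in families:
        if fam == "independence":
            continue
        pc = _fit_family(fam, float(tau))
        if pc is None:
            continue
        ll = pc.loglik(u, v)
        if ll > best_ll:
            best, best_ll = pc, ll
    if best is None or best_ll <= 0.0:
        return PairCopula("independence")
    return best


# ---------------------------------------------------------------------------
# Canonical vine
# ---------------------------------------------------------------------------

class CopulaPrior:
    """Marginal models + canonical-vine copula over d parameters.

    ``order`` maps vine position -> original column; tree j (0-based) is
    rooted at position j.  ``pair_copulas[j][k]`` couples the root with
    position j+1+k conditional on positions 0..j-1.
    """

    FORMAT = "pathway-uq-copula-v1"

    def __init__(
        self,
        marginals: list[MarginalModel],
        order: list[int],
        pair_copulas: list[list[PairCopula]],
        names: list[str] | None = None,
    ) -> None:
        self.marginals = marginals
        self.order = list(order)
        self.pair_copulas = pair_copulas
        self.names = names
        self.dim = len(marginals)

    # -- vine internals (all on the permuted u-scale) --------------------
    def _copula_logdensity_u(self, u_perm: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u_perm).copy()
        d = self.dim
        ll = np.zeros(u.shape[0])
        for j in range(d - 1):
            for k, pc in enumerate(self.pair_copulas[j]):
                ll += pc.logpdf(u[:, j], u[:, j + 1 + k])
            if j < d - 2:
                for k, pc in enumerate(self.pair_copulas[j]):
                    u[:, j + 1 + k] = pc.h(u[:, j + 1 + k], u[:, j])
        return ll

    def _sample_u(self, n: int, rng: np.random.Generator) -> np.ndarray:
        d = self.dim
        w = rng.uniform(size=(n, d))
        u = np.empty((n, d))
        v = np.empty((d, d, n))
        u[:, 0] = w[:, 0]
        v[0, 0] = w[:, 0]
        for i in range(1, d):
            t = w[:, i]
            for k in range(i - 1, -1, -1):
                t = self.pair_copulas[k][i - k - 1].hinv(t, v[k, k])
            u[:, i] = t
            if i < d - 1:
                v[i, 0] = t
                for j in range(i):
                    v[i, j + 1] = self.pair_copulas[j][i - j - 1].h(
                        v[i, j], v[j, j]
                    )
        return u

    # -- public API ------------------------------------------------------
    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be positive")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        if self.dim == 1:
            u = rng.uniform(size=(n, 1))
        else:
            u = self._sample_u(n, rng)
        x = np.empty((n, self.dim))
        for pos, col in enumerate(self.order):
            x[:, col] = self.marginals[col].ppf(u[:, pos])
        return x

    def log_density(self, theta: np.ndarray) -> float | np.ndarray:
        theta = np.asarray(theta, dtype=float)
        single = theta.ndim == 1
        pts = np.atleast_2d(theta)
        if pts.shape[1] != self.dim:
            raise ValueError(
                f"dimension mismatch: got {pts.shape[1]}, expected {self.dim}"
            )
        ll = np.zeros(pts.shape[0])
        u = np.empty_like(pts)
        for pos, col in enumerate(self.order):
            m = self.marginals[col]
            ll += m.logpdf(pts[:, col])
            u[:, pos] = _clip(m.cdf(pts[:, col]))
        finite = np.isfinite(ll)
        if self.dim > 1 and np.any(finite):
            ll[finite] += self._copula_logdensity_u(u[finite])
        return float(ll[0]) if single else ll

    def support(self) -> list[tuple[float, float]]:
        return [(m.lo, m.hi) for m in self.marginals]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": self.FORMAT,
                "names": self.names,
                "order": [int(i) for i in self.order],
                "marginals": [m.to_dict() for m in self.marginals],
                "pair_copulas": [
                    [{"family": pc.family, "par": pc.par} for pc in tree]
                    for tree in self.pair_copulas
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CopulaPrior":
        d = json.loads(text)
        if d.get("format") != cls.FORMAT:
            raise ValueError(f"unrecognized copula format {d.get('format')!r}")
        return cls(
            [MarginalModel.from_dict(m) for m in d["marginals"]],
            d["order"],
            [
                [PairCopula(pc["family"], pc["par"]) for pc in tree]
                for tree in d["pair_copulas"]
            ],
            d["names"],
        )


def fit_vine(
    sample: np.ndarray,
    bounds: Sequence[tuple[float, float]] | None = None,
    names: Sequence[str] | None = None,
    families: Sequence[str] = _FAMILIES,
    truncate_after: int | None = None,
) -> CopulaPrior:
    """Fit marginals and a canonical-vine copula to a sample matrix.

    The vine position order is chosen greedily: the variable with the largest
    summed |Kendall tau| to all others becomes the first root, and so on on
    the h-transformed pseudo-observations.  ``truncate_after`` replaces all
    pair copulas beyond that tree with independence.
    """
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    n, d = sample.shape
    marginals = fit_marginals(sample, bounds)
    if d == 1:
        return CopulaPrior(marginals, [0], [], list(names) if names else None)

    u = pseudo_observations(sample)
    # one-shot root ordering: strongest overall dependence first
    tau_sum = np.zeros(d)
    for a in range(d):
        for b in range(a + 1, d):
            t, _ = stats.kendalltau(u[:, a], u[:, b])
            t = abs(t) if np.isfinite(t) else 0.0
            tau_sum[a] += t
            tau_sum[b] += t
    order = list(np.argsort(-tau_sum, kind="stable").astype(int))
    cur = u[:, order].copy()

    pair_copulas: list[list[PairCopula]] = []
    for tree in range(d - 1):
        truncated = truncate_after is not None and tree >= truncate_after
        pcs = []
        for i in range(tree + 1, d):
            if truncated:
                pcs.append(PairCopula("independence"))
            else:
                pcs.append(select_pair_copula(cur[:, i], cur[:, tree], families))
        pair_copulas.append(pcs)
        if tree < d - 2:
            for k, i in enumerate(range(tree + 1, d)):
                cur[:, i] = pcs[k].h(cur[:, i], cur[:, tree])
    return CopulaPrior(marginals, order, pair_copulas, list(names) if names else None)


def copula_sample(
    prior: CopulaPrior, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` rows from a fitted copula prior (seeded, reproducible)."""
    return prior.sample(n, seed)


def log_density(prior: CopulaPrior, theta: np.ndarray) -> float | np.ndarray:
    """Joint log density: sum of marginal log densities plus the vine copula
    log density at the CDF-transformed point; -inf outside the support."""
    return prior.log_density(theta)
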
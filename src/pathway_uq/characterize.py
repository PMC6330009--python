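"""Posterior characterization: entropy reduction, correlation structure,
credibility intervals, parallel-coordinate export.

The information gained about each parameter is summarized by the drop in
histogram entropy from prior to posterior, H_diff = H_prior - H_post, with
H = -sum_k p_k ln(p_k) Δb computed from the density-normalized sample
histogram (p_k the density in bin k, Δb the bin width; entropies in nats).
Shared bin edges between prior and posterior make H_diff comparable across
parameters.  Dependence structure is shown by hierarchically clustering the
parameters on their absolute-correlation profiles (Euclidean metric,
average linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import gaussian_kde

__all__ = [
    "EntropyReport",
    "CorrelationReport",
    "histogram_entropy",
    "entropy_reduction",
    "correlation_clustering",
    "credible_intervals",
    "parallel_coordinates",
]

DEFAULT_BINS = 50


@dataclass
class EntropyReport:
    names: list[str]
    h_prior: np.ndarray
    h_post: np.ndarray
    bin_edges: list[np.ndarray]

    @property
    def h_diff(self) -> np.ndarray:
        return self.h_prior - self.h_post

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "H_prior": self.h_prior,
                "H_post": self.h_post,
                "H_diff": self.h_diff,
            }
        )


@dataclass
class CorrelationReport:
    names: list[str]
    matrix: np.ndarray
    order: list[int]
    linkage: np.ndarray

    def ordered_names(self) -> list[str]:
        return [self.names[i] for i in self.order]

    def to_frame(self) -> pd.DataFrame:
        idx = self.order
        return pd.DataFrame(
            self.matrix[np.ix_(idx, idx)],
            index=self.ordered_names(),
            columns=self.ordered_names(),
        )


def histogram_entropy(values: np.ndarray, bins: int | np.ndarray = DEFAULT_BINS) -> float:
    """Histogram entropy H = -sum_k p_k ln(p_k) Δb in nats, with p_k the
    density estimate in bin k.  ``bins`` is a count or explicit edges; edges
    must cover the data."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    if np.isscalar(bins) or np.ndim(bins) == 0:
        edges = np.histogram_bin_edges(values, bins=int(bins))
    else:
        edges = np.asarray(bins, dtype=float)
        if values.min() < edges[0] or values.max() > edges[-1]:
            raise ValueError("bin edges do not cover the data")
    dens, edges = np.histogram(values, bins=edges, density=True)
    widths = np.diff(edges)
    occ = dens > 0
    return float(-np.sum(dens[occ] * np.log(dens[occ]) * widths[occ]))


def entropy_reduction(
    prior_sample: np.ndarray,
    post_sample: np.ndarray,
    names: list[str] | None = None,
    n_bins: int = DEFAULT_BINS,
    edges: list[np.ndarray] | None = None,
) -> EntropyReport:
    """Per-parameter prior/posterior entropies on shared bin edges spanning
    the union of both samples (or explicit ``edges``)."""
    prior_sample = np.atleast_2d(np.asarray(prior_sample, dtype=float))
    post_sample = np.atleast_2d(np.asarray(post_sample, dtype=float))
    if prior_sample.shape[1] != post_sample.shape[1]:
        raise ValueError("prior and posterior column counts differ")
    d = prior_sample.shape[1]
    if names is None:
        names = [f"p{j}" for j in range(d)]
    if len(names) != d:
        raise ValueError("names length does not match columns")
    h_prior = np.empty(d)
    h_post = np.empty(d)
    used_edges: list[np.ndarray] = []
    for j in range(d):
        if edges is not None:
            e = np.asarray(edges[j], dtype=float)
        else:
            lo = min(prior_sample[:, j].min(), post_sample[:, j].min())
            hi = max(prior_sample[:, j].max(), post_sample[:, j].max())
            if hi == lo:
                hi = lo + 1e-12
            e = np.linspace(lo, hi, n_bins + 1)
        h_prior[j] = histogram_entropy(prior_sample[:, j], e)
        h_post[j] = histogram_entropy(post_sample[:, j], e)
        used_edges.append(e)
    return EntropyReport(list(names), h_prior, h_post, used_edges)


def correlation_clustering(
    sample: np.ndarray, names: list[str] | None = None
) -> CorrelationReport:
    """Pearson correlation matrix, with parameters ordered by hierarchical
    clustering of their absolute-correlation profiles (Euclidean distance,
    average linkage); correlated parameters end up adjacent."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    n, d = sample.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    if names is None:
        names = [f"p{j}" for j in range(d)]
    sd = sample.std(axis=0)
    if np.any(sd == 0):
        bad = [names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant column(s): {', '.join(bad)}")
    corr = np.corrcoef(sample, rowvar=False)
    if d == 1:
        return CorrelationReport(list(names), np.atleast_2d(corr), [0], np.empty((0, 4)))
    profiles = np.abs(corr)
    link = hierarchy.linkage(profiles, method="average", metric="euclidean")
    order = list(hierarchy.leaves_list(link).astype(int))
    return CorrelationReport(list(names), corr, order, link)


def credible_intervals(
    sample: np.ndarray, level: float = 0.95, names: list[str] | None = None
) -> pd.DataFrame:
    """Equal-tailed quantile credibility intervals per parameter."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    if sample.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    d = sample.shape[1]
    if names is None:
        names = [f"p{j}" for j in range(d)]
    a = (1.0 - level) / 2.0
    lo = np.quantile(sample, a, axis=0)
    hi = np.quantile(sample, 1.0 - a, axis=0)
    med = np.quantile(sample, 0.5, axis=0)
    return pd.DataFrame(
        {"parameter": names, "lower": lo, "median": med, "upper": hi, "level": level}
    )


def parallel_coordinates(
    sample: np.ndarray,
    names: list[str] | None = None,
    bounds: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Data export for parallel-coordinate plots: each row's coordinates
    normalized to [0, 1] per parameter plus a kernel-density weight usable
    as line shading."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    n, d = sample.shape
    if names is None:
        names = [f"p{j}" for j in range(d)]
    coords = np.empty_like(sample)
    for j in range(d):
        lo, hi = (
            bounds[j]
            if bounds is not None
            else (sample[:, j].min(), sample[:, j].max())
        )
        span = hi - lo if hi > lo else 1.0
        coords[:, j] = (sample[:, j] - lo) / span
    try:
        dens = gaussian_kde(sample.T)(sample.T)
    except np.linalg.LinAlgError:
        dens = np.ones(n)
    df = pd.DataFrame(coords, columns=names)
    df["density_weight"] = dens / dens.max()
    return df
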
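"""Forward uncertainty propagation and global sensitivity analysis on a
dependent posterior sample.

The posterior sample is pushed through a predictor (one output curve per
parameter row) to form a prediction ensemble; the prediction uncertainty is
the per-grid-point variance V(Y_pred).  Two complementary sensitivity
analyses follow:

* First-order indices S_i = V(E(Y|Θ_i)) / V(Y), estimated by binning the
  sample on each parameter into equal-count bins and taking the
  occupancy-weighted variance of the within-bin output means.  The binned
  estimator needs no independence assumption, so it applies directly to the
  dependent ABC posterior.
* Monte Carlo filtering: the ensemble rows are classified by a qualitative
  criterion (monotonicity, or an LTD/LTP-style sign pattern), the parameter
  sample is split by the same labels, and parameters (pairs) are ranked by
  the two-sample Kolmogorov-Smirnov statistic (symmetrized Kullback-Leibler
  divergence of 2-D histograms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PosteriorSample

__all__ = [
    "PredictionEnsemble",
    "SensitivityResult",
    "FilterResult",
    "propagate",
    "prediction_variance",
    "first_order_indices",
    "classify",
    "ks_rank",
    "kld_pair_rank",
    "monte_carlo_filter",
]


@dataclass
class PredictionEnsemble:
    input_grid: np.ndarray
    outputs: np.ndarray  # (n_rows, n_grid)
    predictor_id: str = "prediction"
    failed_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.input_grid = np.asarray(self.input_grid, dtype=float)
        self.outputs = np.atleast_2d(np.asarray(self.outputs, dtype=float))

    @property
    def n(self) -> int:
        return self.outputs.shape[0]


@dataclass
class SensitivityResult:
    names: list[str]
    si: np.ndarray  # (n_params, n_grid), clamped to [0, 1]
    si_raw: np.ndarray
    total_variance: np.ndarray
    n_bins: int

    def aggregated(self) -> np.ndarray:
        """Variance-weighted average of S_i across the input grid."""
        w = self.total_variance / max(self.total_variance.sum(), 1e-300)
        return self.si @ w

    def to_frame(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        cols = (
            [f"g{k}" for k in range(self.si.shape[1])]
            if grid is None
            else [format(g, ".6g") for g in grid]
        )
        return pd.DataFrame(self.si, index=self.names, columns=cols)


@dataclass
class FilterResult:
    labels: np.ndarray
    ks_table: pd.DataFrame
    kld_table: pd.DataFrame
    class_counts: dict[int, int]


def propagate(
    posterior: PosteriorSample,
    predictor: Callable[[dict[str, float]], np.ndarray],
    input_grid: np.ndarray,
    predictor_id: str = "prediction",
    max_failure_fraction: float = 0.05,
) -> PredictionEnsemble:
    """Evaluate the predictor at every posterior row; one output vector per
    row.  Per-row failures are recorded; more than ``max_failure_fraction``
    of them aborts with a report."""
    input_grid = np.asarray(input_grid, dtype=float)
    out = np.full((posterior.n, len(input_grid)), np.nan)
    failed: list[int] = []
    for i in range(posterior.n):
        try:
            y = np.asarray(predictor(posterior.row_dict(i)), dtype=float)
            if y.shape != input_grid.shape or not np.all(np.isfinite(y)):
                raise ValueError("predictor returned invalid output")
            out[i] = y
        except Exception:
            failed.append(i)
    if len(failed) > max_failure_fraction * posterior.n:
        raise RuntimeError(
            f"{len(failed)}/{posterior.n} predictor rows failed: "
            f"rows {failed[:20]}{'...' if len(failed) > 20 else ''}"
        )
    keep = np.setdiff1d(np.arange(posterior.n), failed)
    return PredictionEnsemble(
        input_grid, out[keep], predictor_id, failed_rows=failed
    )


def prediction_variance(ensemble: PredictionEnsemble) -> np.ndarray:
    """Sample variance of the prediction at each input grid point."""
    if ensemble.n < 2:
        raise ValueError("need at least 2 ensemble rows")
    return ensemble.outputs.var(axis=0, ddof=1)


def first_order_indices(
    sample: np.ndarray,
    ensemble: PredictionEnsemble,
    n_bins: int = 20,
    min_occupancy: int = 20,
    names: list[str] | None = None,
) -> SensitivityResult:
    """Binned first-order sensitivity indices S_i per parameter and grid
    point: rows are partitioned into ``n_bins`` equal-count bins by each
    parameter; S_i is the occupancy-weighted variance of within-bin output
    means over the total output variance."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    n, d = sample.shape
    if n != ensemble.n:
        raise ValueError("sample rows do not align with ensemble rows")
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    if n // n_bins < min_occupancy:
        raise ValueError(
            f"bin occupancy {n // n_bins} below minimum {min_occupancy}; "
            "use fewer bins"
        )
    if names is None:
        names = [f"p{j}" for j in range(d)]
    y = ensemble.outputs
    var_y = y.var(axis=0)
    g = y.shape[1]
    si_raw = np.zeros((d, g))
    # equal-count bin assignment by rank
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bin_of_rank = np.repeat(np.arange(n_bins), sizes)
    for j in range(d):
        order = np.argsort(sample[:, j], kind="stable")
        bins = np.empty(n, dtype=int)
        bins[order] = bin_of_rank
        for k in range(g):
            if var_y[k] <= 0:
                si_raw[j, k] = 0.0
                continue
            means = np.array(
                [y[bins == b, k].mean() for b in range(n_bins)]
            )
            w = sizes / n
            grand = float(np.sum(w * means))
            si_raw[j, k] = float(np.sum(w * (means - grand) ** 2) / var_y[k])
    si = np.clip(si_raw, 0.0, 1.0)
    return SensitivityResult(list(names), si, si_raw, var_y, n_bins)


# ---------------------------------------------------------------------------
# Monte Carlo filtering
# ---------------------------------------------------------------------------

def classify(
    ensemble: PredictionEnsemble,
    criterion: str | Callable[[np.ndarray], bool],
    **params,
) -> np.ndarray:
    """Label each ensemble row by a qualitative criterion.

    Built-ins:
      ``monotonic`` -- true iff successive differences are all at least
      ``-tol`` times the curve's output range (tol default 0.02).
      ``sign_pattern`` -- LTD/LTP-style: near zero on the lowest-input
      window, below ``-theta_neg`` somewhere in the low window, above
      ``+theta_pos`` somewhere in the high window.  Windows are index
      ranges ``zero_window``, ``low_window``, ``high_window``.
    """
    y = ensemble.outputs
    if callable(criterion):
        return np.array([bool(criterion(row)) for row in y], dtype=int)
    if criterion == "monotonic":
        tol = params.get("tol", 0.02)
        rng_ = np.ptp(y, axis=1)
        thresh = -tol * np.maximum(rng_, 1e-300)
        return (np.diff(y, axis=1) >= thresh[:, None]).all(axis=1).astype(int)
    if criterion == "sign_pattern":
        theta_zero = params.get("theta_zero", 0.05)
        theta_neg = params.get("theta_neg", 0.05)
        theta_pos = params.get("theta_pos", 0.05)
        zero_w = params.get("zero_window", slice(0, 1))
        low_w = params.get("low_window")
        high_w = params.get("high_window")
        if low_w is None or high_w is None:
            raise ValueError("sign_pattern needs low_window and high_window")
        ok_zero = (np.abs(y[:, zero_w]) <= theta_zero).all(axis=1)
        ok_neg = (y[:, low_w] < -theta_neg).any(axis=1)
        ok_pos = (y[:, high_w] > theta_pos).any(axis=1)
        return (ok_zero & ok_neg & ok_pos).astype(int)
    raise ValueError(f"unknown criterion {criterion!r}")


def _split(sample: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes for ranking")
    a = sample[labels == classes[0]]
    b = sample[labels == classes[1]]
    for cls, part in ((classes[0], a), (classes[1], b)):
        if part.shape[0] < 5:
            warnings.warn(
                f"class {cls} has only {part.shape[0]} rows; "
                "rank statistics will be unstable"
            )
    return a, b


def ks_rank(
    sample: np.ndarray, labels: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Two-sample KS statistic per parameter between the class-conditional
    marginals, sorted by statistic descending."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    a, b = _split(sample, labels)
    if names is None:
        names = [f"p{j}" for j in range(sample.shape[1])]
    rows = []
    for j, name in enumerate(names):
        res = stats.ks_2samp(a[:, j], b[:, j])
        rows.append((name, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["parameter", "ks", "pvalue"])
    return df.sort_values("ks", ascending=False, ignore_index=True)


def _hist2d_kld(
    a: np.ndarray, b: np.ndarray, bins: tuple[np.ndarray, np.ndarray],
    pseudo_count: float,
) -> float:
    ha, _, _ = np.histogram2d(a[:, 0], a[:, 1], bins=bins)
    hb, _, _ = np.histogram2d(b[:, 0], b[:, 1], bins=bins)
    pa = (ha + pseudo_count).ravel()
    pb = (hb + pseudo_count).ravel()
    pa /= pa.sum()
    pb /= pb.sum()
    return float(np.sum((pa - pb) * np.log(pa / pb)))


def kld_pair_rank(
    sample: np.ndarray,
    labels: np.ndarray,
    grid_bins: int = 10,
    names: list[str] | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Symmetrized (Jeffreys) KL divergence between the class-conditional
    2-D histograms of every parameter pair, on a shared grid spanning the
    pooled range, with pseudo-count smoothing; sorted descending."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    if grid_bins < 5:
        raise ValueError("grid_bins must be >= 5")
    a, b = _split(sample, labels)
    d = sample.shape[1]
    if names is None:
        names = [f"p{j}" for j in range(d)]
    edges = [
        np.linspace(sample[:, j].min(), sample[:, j].max() + 1e-12, grid_bins + 1)
        for j in range(d)
    ]
    rows = []
    for i, j in combinations(range(d), 2):
        kld = _hist2d_kld(
            a[:, [i, j]], b[:, [i, j]], (edges[i], edges[j]), pseudo_count
        )
        rows.append((names[i], names[j], kld))
    df = pd.DataFrame(rows, columns=["parameter_1", "parameter_2", "kld"])
    return df.sort_values("kld", ascending=False, ignore_index=True)


def monte_carlo_filter(
    sample: np.ndarray,
    ensemble: PredictionEnsemble,
    criterion: str | Callable[[np.ndarray], bool],
    names: list[str] | None = None,
    grid_bins: int = 10,
    **criterion_params,
) -> FilterResult:
    """Classify the ensemble, split the parameter sample accordingly, and
    rank single parameters by KS and pairs by symmetrized KLD."""
    labels = classify(ensemble, criterion, **criterion_params)
    counts = {int(c): int(n) for c, n in zip(*np.unique(labels, return_counts=True))}
    ks = ks_rank(sample, labels, names)
    kld = kld_pair_rank(sample, labels, grid_bins, names)
    return FilterResult(labels, ks, kld, counts)
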
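"""Inter-participant correlation structure of Weber fractions.

The inter-individual covariance technique: if two targets are handled by a
shared channel, participants who are precise at one tend to be precise at
the other, so the across-participant Pearson correlation of Wfs is high
for nearby targets and falls off with numerical distance
(|log10(a/b)|).  This module builds the targets x targets correlation
matrix, the distance-binned correlation curve, the unbinned linear slope,
and the within-participant shuffle null that destroys any target structure
while preserving each participant's Wf distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocessing import WfMatrix
from .synthetic_data import as_rng

__all__ = [
    "DEFAULT_BIN_EDGES",
    "CorrMatrix",
    "DistanceBins",
    "SlopeFit",
    "ShuffleNull",
    "wf_correlation_matrix",
    "numerical_distance",
    "binned_correlation_curve",
    "distance_slope",
    "shuffle_null",
]

#: Inner edges of the six numerical-distance bins (log10-ratio units):
#: <0.08, 0.08-0.14, 0.14-0.21, 0.21-0.29, 0.29-0.39, >0.39.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.08, 0.14, 0.21, 0.29, 0.39)


@dataclass
class CorrMatrix:
    """Targets x targets Pearson correlation matrix (across participants)."""

    targets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        t = self.targets.size
        if self.values.shape != (t, t):
            raise ValueError("values must be square, one row/col per target")
        if np.any(np.diff(self.targets) <= 0):
            raise ValueError("targets must be strictly increasing")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_targets(self) -> int:
        return int(self.targets.size)

    def offdiag_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(distances, correlations, (i, j) index pairs) for each unordered
        off-diagonal pair, counted once."""
        iu, ju = np.triu_indices(self.n_targets, k=1)
        d = numerical_distance(self.targets[iu], self.targets[ju])
        return d, self.values[iu, ju], np.stack([iu, ju], axis=1)

    def mean_offdiag(self) -> float:
        _, r, _ = self.offdiag_pairs()
        return float(r.mean())

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{t:g}" for t in self.targets]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="target")

    @classmethod
    def from_csv(cls, path) -> "CorrMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(targets=np.array([float(c) for c in df.columns]),
                   values=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class DistanceBins:
    """Half-open numerical-distance bins partitioning (0, inf).

    ``inner_edges`` are the interior boundaries; bin k covers
    [edge_{k-1}, edge_k), with the first bin (0, edge_0) and the last
    [edge_last, inf).
    """

    inner_edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.inner_edges)
        if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])) or e[0] <= 0:
            raise ValueError("inner_edges must be positive and strictly increasing")
        object.__setattr__(self, "inner_edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.inner_edges) + 1

    def labels(self) -> list[str]:
        e = self.inner_edges
        mids = [f"{a:g}-{b:g}" for a, b in zip(e, e[1:])]
        return [f"<{e[0]:g}", *mids, f">{e[-1]:g}"]

    def assign(self, distances) -> np.ndarray:
        """Bin index (0-based) for each distance."""
        d = np.asarray(distances, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        return np.digitize(d, self.inner_edges, right=False)


def numerical_distance(a, b):
    """|log10(a/b)| — the numerical distance between two targets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("targets must be positive")
    out = np.abs(np.log10(a / b))
    return out if out.ndim else float(out)


def wf_correlation_matrix(wfm: WfMatrix) -> CorrMatrix:
    """Pearson correlation between the participant-vectors of every pair
    of targets."""
    if wfm.n_participants < 3:
        raise ValueError("need >= 3 participants for a correlation matrix")
    if wfm.n_targets < 2:
        raise ValueError("need >= 2 targets")
    X = wfm.values  # (P, T)
    # a target column is degenerate when every participant has the same Wf
    dead = np.flatnonzero(np.all(X == X[:1, :], axis=0))
    if dead.size:
        names = ", ".join(f"{wfm.targets[i]:g}" for i in dead)
        raise ValueError(
            f"target(s) {names} have zero between-participant variance; "
            "their correlations are undefined"
        )
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrMatrix(targets=wfm.targets.copy(), values=r)


def binned_correlation_curve(corr: CorrMatrix,
                             bins: DistanceBins | None = None) -> pd.DataFrame:
    """Mean off-diagonal correlation per numerical-distance bin.

    Each unordered pair enters exactly once (55 pairs for 11 targets); the
    diagonal is excluded.  Bins without pairs get n_pairs = 0 and NaN mean.
    """
    bins = bins or DistanceBins()
    d, r, _ = corr.offdiag_pairs()
    idx = bins.assign(d)
    mean_r = np.full(bins.n_bins, np.nan)
    n_pairs = np.zeros(bins.n_bins, dtype=int)
    for k in range(bins.n_bins):
        sel = idx == k
        n_pairs[k] = int(sel.sum())
        if n_pairs[k]:
            mean_r[k] = r[sel].mean()
    return pd.DataFrame({"bin": bins.labels(), "mean_r": mean_r,
                         "n_pairs": n_pairs})


@dataclass
class SlopeFit:
    """OLS fit of off-diagonal correlation against numerical distance."""

    slope: float
    stderr: float
    intercept: float
    p_value: float


def distance_slope(corr: CorrMatrix) -> SlopeFit:
    """Ordinary least squares of unbinned off-diagonal r on distance."""
    d, r, _ = corr.offdiag_pairs()
    if np.unique(d).size < 3:
        raise ValueError("need >= 3 distinct distances for a slope fit")
    fit = sps.linregress(d, r)
    return SlopeFit(slope=float(fit.slope), stderr=float(fit.stderr),
                    intercept=float(fit.intercept), p_value=float(fit.pvalue))


@dataclass
class ShuffleNull:
    """Within-participant permutation null of the distance dependence.

    Each iteration independently permutes every participant's Wf vector
    across targets (preserving the participant's multiset of Wfs),
    recomputes the correlation matrix, the binned curve, and the unbinned
    slope.
    """

    bins: DistanceBins
    bin_means: np.ndarray          # mean over iterations, per bin
    slopes: np.ndarray             # (n_iter,)
    observed_slope: float
    mean_offdiag: np.ndarray       # (n_iter,) grand mean off-diagonal r
    seed: int | None

    @property
    def n_iter(self) -> int:
        return int(self.slopes.size)

    @property
    def slope_mean(self) -> float:
        return float(self.slopes.mean())

    @property
    def slope_se(self) -> float:
        return float(self.slopes.std(ddof=1) / np.sqrt(self.n_iter))

    @property
    def p_value(self) -> float:
        """Two-sided empirical p of the observed slope under the null."""
        exceed = np.sum(np.abs(self.slopes) >= abs(self.observed_slope))
        return float((1 + exceed) / (1 + self.n_iter))

    def slope_band(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        return (float(np.quantile(self.slopes, lo)),
                float(np.quantile(self.slopes, 1 - lo)))

    def to_dict(self) -> dict:
        lo, hi = self.slope_band()
        return {
            "n_iter": self.n_iter,
            "bin_labels": self.bins.labels(),
            "bin_means": [None if np.isnan(v) else float(v)
                          for v in self.bin_means],
            "slope_mean": self.slope_mean,
            "slope_se": self.slope_se,
            "slope_band_95": [lo, hi],
            "observed_slope": self.observed_slope,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def shuffle_null(wfm: WfMatrix, n_iter: int = 10_000,
                 seed: int | np.random.Generator | None = None,
                 bins: DistanceBins | None = None) -> ShuffleNull:
    """Bootstrap-randomization null for the correlation-vs-distance curve."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    bins = bins or DistanceBins()
    rng = as_rng(seed)
    X = wfm.values
    observed = distance_slope(wf_correlation_matrix(wfm)).slope

    iu, ju = np.triu_indices(wfm.n_targets, k=1)
    d = numerical_distance(wfm.targets[iu], wfm.targets[ju])
    bin_idx = bins.assign(d)
    masks = [bin_idx == k for k in range(bins.n_bins)]
    counts = np.array([m.sum() for m in masks])
    dc = d - d.mean()
    denom = float(dc @ dc)

    bin_sums = np.zeros(bins.n_bins)
    slopes = np.empty(n_iter)
    grand = np.empty(n_iter)
    for it in range(n_iter):
        Xp = rng.permuted(X, axis=1)  # each participant's row shuffled
        R = np.corrcoef(Xp, rowvar=False)
        r = R[iu, ju]
        for k, m in enumerate(masks):
            if counts[k]:
                bin_sums[k] += r[m].mean()
        slopes[it] = (dc @ (r - r.mean())) / denom
        grand[it] = r.mean()
    bin_means = np.where(counts > 0, bin_sums / n_iter, np.nan)
    return ShuffleNull(bins=bins, bin_means=bin_means, slopes=slopes,
                       observed_slope=observed, mean_offdiag=grand,
                       seed=seed if isinstance(seed, int) else None)
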
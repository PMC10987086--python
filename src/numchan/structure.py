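"""Cluster and factor structure of the Weber-fraction matrix.

Targets are the items: each target carries its vector of participant Wfs
(z-scored per target), so targets processed by a shared channel sit close
together.  Ward/Euclidean hierarchical clustering with an
inconsistency-coefficient cut finds groups of targets; a permutation
control asks how often such groups would be contiguous number ranges by
chance.  Principal components of the targets' correlation structure,
rotated obliquely (promax) or orthogonally (varimax), expose bell-shaped
covariance channels whose loading profiles are summarised by log-Gaussian
tuning fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit
from statsmodels.multivariate.factor_rotation import promax as _promax
from statsmodels.multivariate.factor_rotation import rotate_factors as _rotate

from .preprocessing import WfMatrix
from .synthetic_data import as_rng

__all__ = [
    "ClusterResult",
    "ComponentSolution",
    "ContiguityNull",
    "LogGaussianFit",
    "zscore_targets",
    "hierarchical_clusters",
    "is_contiguous",
    "contiguity_null",
    "factor_solution",
    "loggaussian_fit",
]

logger = logging.getLogger(__name__)


def zscore_targets(wfm: WfMatrix) -> np.ndarray:
    """Standardize each target's participant-vector to mean 0, SD 1.

    Uses the sample SD.  Raises (naming the target) if a target has zero
    between-participant variance.  Idempotent.
    """
    if wfm.n_participants < 2:
        raise ValueError("need >= 2 participants to z-score")
    X = wfm.values
    dead = np.flatnonzero(np.all(X == X[:1, :], axis=0))
    if dead.size:
        names = ", ".join(f"{wfm.targets[i]:g}" for i in dead)
        raise ValueError(f"target(s) {names} have zero variance; cannot z-score")
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Ward/Euclidean dendrogram over targets with an inconsistency cut."""

    targets: np.ndarray
    linkage: np.ndarray            # scipy linkage matrix, (T-1, 4)
    inconsistency: np.ndarray      # scipy inconsistent() output, (T-1, 4)
    labels: np.ndarray             # cluster label per target at the cut
    threshold: float               # inconsistency threshold used
    depth: int

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def assignments(self) -> dict[float, int]:
        return {float(t): int(l) for t, l in zip(self.targets, self.labels)}

    def clusters(self) -> list[list[float]]:
        """Targets grouped by cluster, ordered by their smallest member."""
        groups: dict[int, list[float]] = {}
        for t, l in zip(self.targets, self.labels):
            groups.setdefault(int(l), []).append(float(t))
        return sorted(groups.values(), key=min)

    def merge_records(self) -> list[dict]:
        T = self.targets.size
        recs = []
        for k, (a, b, h, size) in enumerate(self.linkage):
            recs.append({"merge": k, "left": int(a), "right": int(b),
                         "height": float(h), "size": int(size),
                         "inconsistency": float(self.inconsistency[k, 3])})
        return recs

    def to_newick(self) -> str:
        """Dendrogram as a Newick string, targets as leaves and branch
        lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)
        labels = [f"{t:g}" for t in self.targets]

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def _cut_by_inconsistency(Z: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, float]:
    """Split exactly the maximally inconsistent merges.

    The threshold is set just below the largest inconsistency coefficient,
    which yields the smallest partition with >= 2 clusters consistent with
    the index (typically 2 on an 11-target set with two channels).
    """
    coeff = R[:, 3]
    t = float(coeff.max()) - 1e-8
    labels = hierarchy.fcluster(Z, t=t, criterion="inconsistent", R=R)
    return labels, t


def hierarchical_clusters(wfm: WfMatrix, depth: int = 3,
                          n_clusters: int | None = None) -> ClusterResult:
    """Cluster targets by their z-scored participant Wf vectors.

    Euclidean distances, Ward linkage.  By default the cut is chosen by
    the inconsistency coefficient (computed at ``depth``); pass
    ``n_clusters`` to force a maxclust cut instead.
    """
    if wfm.n_targets < 3:
        raise ValueError("need >= 3 targets to cluster")
    Xz = zscore_targets(wfm)  # (P, T)
    Z = hierarchy.linkage(Xz.T, method="ward", metric="euclidean")
    R = hierarchy.inconsistent(Z, d=depth)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        threshold = float("nan")
    else:
        labels, threshold = _cut_by_inconsistency(Z, R)
    return ClusterResult(targets=wfm.targets.copy(), linkage=Z,
                         inconsistency=R, labels=np.asarray(labels),
                         threshold=threshold, depth=depth)


def is_contiguous(assignments, targets=None) -> bool:
    """True iff every cluster is an interval in the target ordering."""
    if isinstance(assignments, dict):
        items = sorted(assignments.items())
        labels = np.array([l for _, l in items])
    else:
        labels = np.asarray(assignments)
        if targets is not None:
            order = np.argsort(np.asarray(targets, dtype=float))
            labels = labels[order]
    for lab in np.unique(labels):
        pos = np.flatnonzero(labels == lab)
        if pos[-1] - pos[0] + 1 != pos.size:
            return False
    return True


@dataclass
class ContiguityNull:
    """Permutation control for cluster contiguity."""

    proportion_contiguous: float
    n_iter: int
    n_contiguous: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"proportion_contiguous": self.proportion_contiguous,
                "n_contiguous": self.n_contiguous,
                "n_iter": self.n_iter, "seed": self.seed}


def contiguity_null(wfm: WfMatrix, n_iter: int = 10_000,
                    seed: int | np.random.Generator | None = None,
                    depth: int = 3) -> ContiguityNull:
    """How often do permuted Wfs yield all-contiguous clusters?

    Each iteration permutes every participant's Wf vector across targets
    independently, reclusters with the same Ward/inconsistency rule, and
    checks whether every resulting cluster is a contiguous number range.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = as_rng(seed)
    X = wfm.values
    hits = 0
    for _ in range(n_iter):
        Xp = rng.permuted(X, axis=1)
        sd = Xp.std(axis=0, ddof=1)
        if np.any(sd == 0):  # pathological permutation; count as non-contiguous
            continue
        Xz = (Xp - Xp.mean(axis=0)) / sd
        Z = hierarchy.linkage(Xz.T, method="ward", metric="euclidean")
        R = hierarchy.inconsistent(Z, d=depth)
        labels, _ = _cut_by_inconsistency(Z, R)
        if is_contiguous(labels):
            hits += 1
    return ContiguityNull(proportion_contiguous=hits / n_iter, n_iter=n_iter,
                          n_contiguous=hits,
                          seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# Principal components / factor analysis
# ---------------------------------------------------------------------------


@dataclass
class ComponentSolution:
    """Rotated principal components of the targets' correlation structure.

    Components are extracted from the targets x targets correlation matrix
    of z-scored Wfs; the number retained equals the count of eigenvalues
    exceeding 1 (Kaiser rule).  ``loadings`` is the rotated pattern
    matrix, one column per component, sign-fixed so each component's
    largest-magnitude loading is positive and ordered by variance
    explained.
    """

    targets: np.ndarray
    loadings: np.ndarray            # (T, k) rotated pattern loadings
    eigenvalues: np.ndarray         # all T eigenvalues, descending
    variance_explained: np.ndarray  # per retained component (unrotated)
    rotation: str

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])

    @property
    def total_variance_explained(self) -> float:
        return float(self.variance_explained.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.loadings,
            columns=[f"component_{k + 1}" for k in range(self.n_components)],
        )
        df.insert(0, "target", self.targets)
        return df


class RotationError(RuntimeError):
    """Raised when rotation fails; carries the unrotated solution."""

    def __init__(self, msg: str, unrotated: ComponentSolution):
        super().__init__(msg)
        self.unrotated = unrotated


def _fix_signs_and_order(L: np.ndarray) -> np.ndarray:
    # sign: largest-|loading| positive per component
    sign = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    sign[sign == 0] = 1.0
    return L * sign


def factor_solution(wfm: WfMatrix, rotation: str = "promax") -> ComponentSolution:
    """PCA of the targets' correlation matrix with oblique/orthogonal
    rotation.

    ``rotation`` is one of "promax", "varimax", "none".  The retained
    loadings (eigenvector * sqrt(eigenvalue) for eigenvalues > 1) are
    rotated; variance explained is reported from the unrotated
    eigenvalues, per component and in total.
    """
    if rotation not in ("promax", "varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    Xz = zscore_targets(wfm)
    if wfm.n_participants <= 2:
        raise ValueError("need more participants than components")
    Rmat = np.corrcoef(Xz, rowvar=False)
    eigval, eigvec = np.linalg.eigh(Rmat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = int(np.sum(eigval > 1.0))
    if k == 0:
        raise ValueError("no eigenvalue exceeds 1; no component retained")
    L = eigvec[:, :k] * np.sqrt(eigval[:k])
    var_exp = eigval[:k] / wfm.n_targets

    if k >= 2 and rotation != "none":
        unrot = ComponentSolution(targets=wfm.targets.copy(),
                                  loadings=_fix_signs_and_order(L.copy()),
                                  eigenvalues=eigval,
                                  variance_explained=var_exp,
                                  rotation="none")
        try:
            if rotation == "promax":
                L, _ = _promax(L)
            else:
                L, _ = _rotate(L, "varimax")
        except Exception as exc:  # non-convergent rotation
            raise RotationError(f"{rotation} rotation failed: {exc}", unrot) from exc
        L = np.asarray(L)
        # order rotated components by their sum of squared loadings
        ss = (L ** 2).sum(axis=0)
        L = L[:, np.argsort(ss)[::-1]]
    L = _fix_signs_and_order(L)
    return ComponentSolution(targets=wfm.targets.copy(), loadings=L,
                             eigenvalues=eigval, variance_explained=var_exp,
                             rotation=rotation if k >= 2 else "none")


# ---------------------------------------------------------------------------
# Log-Gaussian tuning fits to component loadings
# ---------------------------------------------------------------------------


@dataclass
class LogGaussianFit:
    """Log-Gaussian tuning curve fitted to a component's loading profile.

    ``a * exp(-(log10(n / peak))^2 / (2 width^2))`` — peak is the
    preferred numerosity, width the SD in log10-numerosity units.
    """

    peak: float
    width: float
    amplitude: float
    r2: float
    converged: bool = True

    def predict(self, n) -> np.ndarray:
        return _loggauss(np.asarray(n, dtype=float),
                         self.amplitude, self.peak, self.width)

    def to_dict(self) -> dict:
        return {"peak": self.peak, "width": self.width,
                "amplitude": self.amplitude, "r2": self.r2,
                "converged": self.converged}


def _loggauss(n, a, peak, width):
    return a * np.exp(-np.log10(n / peak) ** 2 / (2.0 * width ** 2))


def loggaussian_fit(loadings, targets) -> LogGaussianFit:
    """Least-squares log-Gaussian fit to a component's loading profile.

    Negative loadings are permitted (the fit runs on raw values).
    Degenerate profiles (e.g. constant loadings) do not raise: the fit
    returns with ``converged=False``, a large width, and r2 near 0.
    """
    y = np.asarray(loadings, dtype=float)
    n = np.asarray(targets, dtype=float)
    if y.size != n.size or y.size < 4:
        raise ValueError("need >= 4 targets with one loading each")
    if not np.all(np.isfinite(y)):
        raise ValueError("loadings must be finite")
    if np.any(n <= 0):
        raise ValueError("targets must be positive")

    w = np.clip(y, 0, None)
    if w.sum() > 0:
        peak0 = float(np.exp(np.sum(w * np.log(n)) / w.sum()))
    else:
        peak0 = float(np.exp(np.mean(np.log(n))))
    p0 = (float(y.max()) if y.max() > 0 else 1.0, peak0, 0.2)
    lo = (-10.0 * max(1.0, np.abs(y).max()), n.min() / 2.0, 1e-3)
    hi = (10.0 * max(1.0, np.abs(y).max()), n.max() * 2.0, 10.0)

    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def r2_of(params):
        resid = y - _loggauss(n, *params)
        ss_res = float(np.sum(resid ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    try:
        popt, _ = curve_fit(_loggauss, n, y, p0=p0, bounds=(lo, hi),
                            maxfev=20_000)
        a, peak, width = (float(v) for v in popt)
        return LogGaussianFit(peak=peak, width=width, amplitude=a,
                              r2=r2_of(popt), converged=True)
    except Exception as exc:
        logger.warning("log-Gaussian fit did not converge (%s); returning "
                       "degenerate fit", exc)
        fallback = (float(y.mean()), peak0, 10.0)
        return LogGaussianFit(peak=fallback[1], width=fallback[2],
                              amplitude=fallback[0], r2=r2_of(fallback),
                              converged=False)
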
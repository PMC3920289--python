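"""Non-metric multidimensional scaling (NMDS) on Euclidean distances.

NMDS embeds samples in k dimensions so that the rank order of configuration
distances matches the rank order of the input dissimilarities, minimising
Kruskal's stress formula 1,

    stress = 100 * sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where d are configuration distances and dhat the monotone (isotonic)
disparities fitted to the dissimilarity ranks.  Optimisation is by
majorization (SMACOF/Guttman transform) alternated with isotonic regression,
restarted from many random configurations plus one metric (classical scaling)
start.  Dimensionality is selected by the rule that an extra dimension must
reduce the best stress by at least ``stress_gain`` (default 5 on the x100
scale); a Monte-Carlo test compares the real stress against stress of
column-permuted data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from .io_profiles import ProfileMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with sample labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def euclidean_distances(matrix: ProfileMatrix | pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample abundance vectors."""
    if isinstance(matrix, ProfileMatrix):
        df = matrix.df
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix, float))
    X = df.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return DistanceMatrix([str(i) for i in df.index], squareform(pdist(X)))


@dataclass
class OrdinationResult:
    """Best NMDS configuration: centered coordinates, stress (formula 1 x 100)."""

    coordinates: pd.DataFrame
    stress: float
    k: int
    n_restarts: int
    converged: bool
    seed: int | None

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# kruskal stress-1 x100 = {self.stress!r}, k = {self.k}\n")
            out = self.coordinates.copy()
            out.index.name = "sample_id"
            out.to_csv(fh)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def _disparities(diss: np.ndarray, dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone disparities: isotonic regression of configuration distances in
    dissimilarity-rank order (primary tie approach: tied dissimilarities may
    receive unequal disparities)."""
    # within tied dissimilarities, sort by current distance so isotonic
    # regression need not pool them (primary approach)
    sub = np.lexsort((dist[order], diss[order]))
    o = order[sub]
    fit = isotonic_regression(dist[o]).x
    out = np.empty_like(fit)
    out[o] = fit
    return out


def _smacof_nonmetric(
    diss: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    stability_tol: float,
) -> tuple[np.ndarray, float, bool, int]:
    """One SMACOF run from ``init``; returns (config, stress_x100, converged, n_iter)."""
    n, _ = init.shape
    x = init - init.mean(axis=0)
    order = np.argsort(diss, kind="stable")
    history: list[float] = []
    stress = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(x)
        denom = (dist ** 2).sum()
        if denom <= 0:
            stress = 0.0
            converged = True
            break
        dhat = _disparities(diss, dist, order)
        # rescale so the Guttman transform keeps the configuration's size
        s2 = (dhat ** 2).sum()
        if s2 > 0:
            dhat = dhat * np.sqrt(denom / s2)
        stress = 100.0 * float(np.sqrt(((dist - dhat) ** 2).sum() / denom))
        history.append(stress)
        if len(history) >= 10 and (history[-10] - history[-1]) < stability_tol:
            converged = True
            break
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -squareform(ratio, checks=False)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        x -= x.mean(axis=0)
    return x, stress, converged, it


def nmds(
    d: DistanceMatrix,
    k: int,
    n_restarts: int = 250,
    max_iter: int = 500,
    stability_tol: float = 1e-7,
    seed: int | None = None,
    extra_inits: Sequence[np.ndarray] = (),
) -> OrdinationResult:
    """Best-of-restarts non-metric MDS.

    Runs SMACOF from ``n_restarts`` random starts (uniform in [-1, 1]^k,
    centered) plus one metric-scaling start plus any ``extra_inits``, and
    returns the lowest-stress configuration.  Iteration stops at ``max_iter``
    or when the stress (x100) decrease over the last 10 iterations falls
    below ``stability_tol``.
    """
    n = d.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n - 1:
        raise ValueError(f"k = {k} too large for {n} samples (need k < n - 1)")
    rng = np.random.default_rng(seed)
    diss = d.condensed()
    inits = [_classical_mds(d.d, k)]
    inits.extend(np.asarray(e, float) for e in extra_inits)
    for _ in range(n_restarts):
        start = rng.uniform(-1.0, 1.0, size=(n, k))
        inits.append(start - start.mean(axis=0))
    best = None
    for init in inits:
        x, stress, conv, _ = _smacof_nonmetric(diss, init, max_iter, stability_tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv)
    x, stress, conv = best
    coords = pd.DataFrame(x - x.mean(axis=0), index=d.labels,
                          columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult(coords, stress, k, n_restarts, conv, seed)


def select_dimensionality(
    d: DistanceMatrix,
    k_range: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_restarts: int = 250,
    stress_gain: float = 5.0,
    seed: int | None = None,
    max_iter: int = 500,
    stability_tol: float = 1e-7,
) -> tuple[int, dict[int, OrdinationResult]]:
    """Fit NMDS for each k and choose the useful dimensionality.

    An extra dimension is considered useful if it reduces the best stress by
    at least ``stress_gain`` (on the x100 scale); the chosen k is the smallest
    k whose step to k+1 gains less than that.  The k-solution padded with a
    zero column seeds the (k+1)-run, which makes best stress non-increasing
    in k.
    """
    ks = sorted(set(int(k) for k in k_range))
    ks = [k for k in ks if k < d.n - 1]
    if not ks:
        raise ValueError("no admissible dimensionality for this sample count")
    rng = np.random.default_rng(seed)
    results: dict[int, OrdinationResult] = {}
    prev = None
    for k in ks:
        extra = []
        if prev is not None and prev.k == k - 1:
            extra.append(np.hstack([prev.coordinates.to_numpy(), np.zeros((d.n, 1))]))
        res = nmds(d, k, n_restarts=n_restarts, max_iter=max_iter,
                   stability_tol=stability_tol,
                   seed=int(rng.integers(0, 2**31 - 1)), extra_inits=extra)
        results[k] = res
        prev = res
    chosen = ks[-1]
    for k, k_next in zip(ks[:-1], ks[1:]):
        if results[k].stress - results[k_next].stress < stress_gain:
            chosen = k
            break
    return chosen, results


def monte_carlo_stress_test(
    matrix: ProfileMatrix | pd.DataFrame,
    k: int,
    n_randomizations: int = 50,
    n_restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 500,
    stability_tol: float = 1e-7,
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo randomization test of NMDS structure.

    Each randomization independently permutes the values within every T-RF
    column of the abundance matrix, destroying between-sample structure while
    keeping per-T-RF marginals; NMDS is re-fitted and the randomized stresses
    compared with the real one.

    Returns
    -------
    (p, real_stress, random_stresses):
        ``p = (1 + #(stress_random <= stress_real)) / (1 + n_randomizations)``.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    df = matrix.df if isinstance(matrix, ProfileMatrix) else matrix
    X = df.to_numpy(float)
    rng = np.random.default_rng(seed)

    def _fit(values: np.ndarray) -> float:
        dm = DistanceMatrix([str(i) for i in range(values.shape[0])],
                            squareform(pdist(values)))
        return nmds(dm, k, n_restarts=n_restarts, max_iter=max_iter,
                    stability_tol=stability_tol,
                    seed=int(rng.integers(0, 2**31 - 1))).stress

    real = _fit(X)
    rand = np.empty(n_randomizations)
    for i in range(n_randomizations):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        rand[i] = _fit(Xp)
    p = (1.0 + np.count_nonzero(rand <= real)) / (1.0 + n_randomizations)
    return float(p), float(real), rand


def procrustes_error(reference: np.ndarray, recovered: np.ndarray) -> float:
    """Procrustes mismatch between two configurations, as a fraction of scale.

    Both configurations are standardised (centered, unit norm) and optimally
    rotated/reflected/scaled onto each other; the returned value is the root
    of the residual sum of squares, i.e. the relative recovery error.
    """
    _, _, disparity = _scipy_procrustes(np.asarray(reference, float), np.asarray(recovered, float))
    return float(np.sqrt(disparity))
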
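"""Permutational multivariate analysis of variance (PerMANOVA) on a distance matrix.

The squared distances are Gower-centered and partitioned by projections onto
the design subspaces of a crossed two-factor layout (main effects and
interaction, sequential Type I sums of squares).  Pseudo-F per term is

    F = (SS_term / df_term) / (SS_residual / df_residual)

and p-values come from unrestricted permutation of raw observation units
(whole sample rows).  With a Euclidean distance matrix the partition equals
the sum over variables of the classical univariate ANOVA partition, so on a
single column pseudo-F reproduces the classical one-way F exactly.

A two-moment gamma approximation to the permutation distribution provides an
asymptotic p-value when too few distinct permutations exist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import DistanceMatrix

_PERM_BATCH = 500


class DesignError(ValueError):
    """The factor layout cannot be analysed (single level, empty cell...)."""


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _proj(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto the column space of x, with its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps)) if s.size else 0
    u = u[:, :rank]
    return u @ u.T, rank


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels).to_numpy(float)


def _term_projections(
    meta: pd.DataFrame, factors: Sequence[str], interaction: bool
) -> tuple[list[tuple[str, int, np.ndarray]], np.ndarray, int]:
    """Sequential (Type I) term projections: [(name, df, delta_P)], residual projector, df_res."""
    n = len(meta)
    blocks = [np.ones((n, 1))]
    names = []
    for f in factors:
        blocks.append(_dummies(meta[f]))
        names.append(f)
    if interaction:
        d1 = _dummies(meta[factors[0]])
        d2 = _dummies(meta[factors[1]])
        inter = np.einsum("ni,nj->nij", d1, d2).reshape(n, -1)
        blocks.append(inter)
        names.append(f"{factors[0]}:{factors[1]}")
    terms = []
    prev_p, prev_rank = _proj(blocks[0])
    x = blocks[0]
    for name, block in zip(names, blocks[1:]):
        x = np.hstack([x, block])
        p, rank = _proj(x)
        terms.append((name, rank - prev_rank, p - prev_p))
        prev_p, prev_rank = p, rank
    resid = np.eye(n) - prev_p
    return terms, resid, n - prev_rank


def _permutations(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perms[i] = rng.permutation(n)
    return perms


def _permuted_traces(g: np.ndarray, mats: list[np.ndarray], perms: np.ndarray) -> np.ndarray:
    """traces[t, p] = tr(mats[t] @ G_pi) for each permutation pi, computed in batches."""
    out = np.empty((len(mats), len(perms)))
    for lo in range(0, len(perms), _PERM_BATCH):
        pp = perms[lo:lo + _PERM_BATCH]
        gp = g[pp[:, :, None], pp[:, None, :]]
        for t, m in enumerate(mats):
            out[t, lo:lo + len(pp)] = np.einsum("ij,pij->p", m, gp)
    return out


@dataclass
class PermanovaResult:
    """ANOVA-style table (term, df, SS, pseudo-F, p) plus permutation metadata."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    permuted_f: dict[str, np.ndarray]

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# n_permutations = {self.n_permutations}, seed = {self.seed}\n")
            self.table.to_csv(fh, index=False)


def _as_distance(d: DistanceMatrix | np.ndarray | pd.DataFrame) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    if isinstance(d, pd.DataFrame):
        return DistanceMatrix([str(i) for i in d.index], d.to_numpy(float))
    d = np.asarray(d, float)
    return DistanceMatrix([str(i) for i in range(len(d))], d)


def permanova(
    d: DistanceMatrix | np.ndarray | pd.DataFrame,
    meta: pd.DataFrame | pd.Series,
    factors: Sequence[str] | str = ("season", "treatment"),
    interaction: bool = True,
    n_perm: int = 4999,
    seed: int | None = None,
) -> PermanovaResult:
    """Crossed PerMANOVA with permutation p-values.

    Parameters
    ----------
    d:
        Distance matrix (rows aligned with ``meta``).
    meta:
        Sample metadata indexed (or ordered) like ``d``'s labels; a bare
        Series of group labels triggers a one-way analysis.
    factors:
        One or two metadata column names.  With two, the sequential order is
        as given (main effects then interaction).
    interaction:
        Include the two-way interaction term (requires >= 2 replicates per
        cell).
    n_perm:
        Permutations of raw sample units per term.

    Returns
    -------
    PermanovaResult
        Table with one row per term plus residual and total.
    """
    dm = _as_distance(d)
    if isinstance(meta, pd.Series):
        meta = meta.to_frame(name="group")
        factors = ("group",)
    elif isinstance(factors, str):
        factors = (factors,)
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    idx_str = [str(i) for i in meta.index]
    if idx_str != dm.labels and set(idx_str) == set(dm.labels):
        meta = meta.set_axis(idx_str).loc[dm.labels]
    if len(meta) != dm.n:
        raise DesignError("metadata does not match the distance matrix")
    factors = tuple(factors)
    for f in factors:
        if meta[f].nunique() < 2:
            raise DesignError(f"factor {f!r} has fewer than 2 levels")
    use_interaction = interaction and len(factors) == 2
    if use_interaction:
        cell_counts = meta.groupby(list(factors), observed=True).size()
        if (cell_counts < 2).any():
            raise DesignError("interaction term requires >= 2 replicates per cell")

    g = _gower_center(dm.d)
    total_ss = float(np.trace(g))
    if total_ss <= 1e-12:
        raise DesignError("all samples identical: total sum of squares is zero")

    n = dm.n
    if math.factorial(n) - 1 < 20:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations exist; "
            "consider the asymptotic (gamma) p-value",
            stacklevel=2,
        )

    terms, resid, df_res = _term_projections(meta, factors, use_interaction)
    if df_res < 1:
        raise DesignError("no residual degrees of freedom")
    mats = [dp for _, _, dp in terms] + [resid]
    dfs = np.array([df for _, df, _ in terms], float)

    rng = np.random.default_rng(seed)
    perms = _permutations(n, n_perm, rng)
    traces = _permuted_traces(g, mats, perms)
    ss_obs = np.array([float(np.sum(m * g)) for m in mats])
    ms_perm = traces[:-1] / dfs[:, None]
    msr_perm = traces[-1] / df_res
    f_perm = ms_perm / msr_perm
    f_obs = (ss_obs[:-1] / dfs) / (ss_obs[-1] / df_res)
    pvals = (1.0 + np.sum(f_perm >= f_obs[:, None], axis=1)) / (1.0 + n_perm)

    rows = []
    permuted = {}
    for i, (name, df, _) in enumerate(terms):
        rows.append((name, df, ss_obs[i], f_obs[i], pvals[i]))
        permuted[name] = f_perm[i]
    rows.append(("residual", df_res, ss_obs[-1], np.nan, np.nan))
    rows.append(("total", n - 1, total_ss, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "pseudo_F", "p"])
    return PermanovaResult(table, n_perm, seed, permuted)


def permanova_two_way(
    d, meta, factors: Sequence[str] = ("season", "treatment"),
    n_perm: int = 4999, seed: int | None = None,
) -> PermanovaResult:
    """Two-way crossed PerMANOVA with interaction (see :func:`permanova`)."""
    return permanova(d, meta, factors=factors, interaction=True, n_perm=n_perm, seed=seed)


@dataclass
class PairwiseComparison:
    """One level-pair comparison: t = sqrt(pseudo-F), permutation p, optional gamma p."""

    level_a: str
    level_b: str
    t: float
    p: float
    p_monte_carlo: float | None = None
    p_adjusted: float | None = None


def pairwise_comparisons(
    d: DistanceMatrix | np.ndarray | pd.DataFrame,
    meta: pd.DataFrame | pd.Series,
    factor: str | None = None,
    n_perm: int = 4999,
    seed: int | None = None,
    monte_carlo: bool = False,
    adjust: str | None = None,
) -> list[PairwiseComparison]:
    """One-way PerMANOVA restricted to each pair of factor levels.

    No multiplicity adjustment by default; ``adjust="holm"`` or
    ``"bonferroni"`` fills ``p_adjusted``.  Levels with fewer than 2 samples
    are skipped with a warning.
    """
    dm = _as_distance(d)
    if isinstance(meta, pd.Series):
        labels = meta
    else:
        m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
        labels = m[factor]
    labels = pd.Series(np.asarray(labels), index=dm.labels)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise DesignError("pairwise comparisons need >= 2 levels")
    rng = np.random.default_rng(seed)
    out: list[PairwiseComparison] = []
    for a, b in combinations(levels, 2):
        idx = np.where(labels.isin([a, b]).to_numpy())[0]
        if (labels.iloc[idx] == a).sum() < 2 or (labels.iloc[idx] == b).sum() < 2:
            warnings.warn(f"level pair ({a}, {b}) skipped: a level has < 2 samples", stacklevel=2)
            continue
        sub = DistanceMatrix([dm.labels[i] for i in idx], dm.d[np.ix_(idx, idx)])
        res = permanova(sub, labels.iloc[idx], n_perm=n_perm,
                        seed=int(rng.integers(0, 2**31 - 1)))
        row = res.table.iloc[0]
        mc = None
        if monte_carlo:
            mc = asymptotic_p(float(row["pseudo_F"]), res.permuted_f["group"])
        out.append(PairwiseComparison(str(a), str(b), float(np.sqrt(row["pseudo_F"])),
                                      float(row["p"]), p_monte_carlo=mc))
    if adjust:
        ps = np.array([c.p for c in out])
        adj = _adjust_p(ps, adjust)
        for c, pa in zip(out, adj):
            c.p_adjusted = float(pa)
    return out


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def asymptotic_p(f_obs: float, permuted_fs: np.ndarray) -> float:
    """Tail probability of ``f_obs`` under a two-moment gamma fit to permuted pseudo-F values.

    Used when too few distinct permutations exist for a resolved permutation
    p-value.  Requires at least 30 permuted statistics with positive spread.
    """
    fs = np.asarray(permuted_fs, float)
    if fs.size < 30:
        raise ValueError("need >= 30 permuted statistics to fit moments")
    mean = fs.mean()
    var = fs.var(ddof=1)
    if not np.isfinite(mean) or not np.isfinite(var) or var <= 0 or mean <= 0:
        raise ValueError("degenerate permutation distribution: cannot fit gamma moments")
    shape = mean ** 2 / var
    scale = var / mean
    return float(stats.gamma.sf(f_obs, a=shape, scale=scale))


def pairwise_table(comparisons: Sequence[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level_a": [c.level_a for c in comparisons],
            "level_b": [c.level_b for c in comparisons],
            "t": [c.t for c in comparisons],
            "p": [c.p for c in comparisons],
            "p_monte_carlo": [c.p_monte_carlo for c in comparisons],
            "p_adjusted": [c.p_adjusted for c in comparisons],
        }
    )
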
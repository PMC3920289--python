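"""Dufrêne-Legendre indicator species analysis (IndVal) on T-RFs, with the
univariate permutation ANOVA used to follow up significant indicators.

For T-RF i and group g,

    A_ig = mean abundance of i in g / sum over groups of mean abundance of i
    B_ig = fraction of samples in g where i is present (> 0)
    IndVal_ig = 100 * A_ig * B_ig

and the reported indicator value of a T-RF is the maximum over groups, tested
by random permutation of the group labels across samples (permutations shared
across T-RFs within a run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io_profiles import ProfileMatrix


def _coerce(matrix: ProfileMatrix | pd.DataFrame, groups) -> tuple[pd.DataFrame, pd.Series]:
    df = matrix.df if isinstance(matrix, ProfileMatrix) else matrix
    if isinstance(groups, str):
        if not isinstance(matrix, ProfileMatrix) or matrix.meta is None:
            raise ValueError("groups given as a column name requires matrix metadata")
        groups = matrix.meta[groups]
    groups = pd.Series(np.asarray(groups), index=df.index)
    return df, groups


def _indval_components(x: np.ndarray, z: np.ndarray, counts: np.ndarray):
    """(A, B, IndVal) arrays of shape (n_groups, n_trfs) for abundance matrix x
    and one-hot group matrix z."""
    means = (z.T @ x) / counts[:, None]
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / tot, 0.0)
    b = (z.T @ (x > 0)) / counts[:, None]
    return a, b, 100.0 * a * b


def indval(
    matrix: ProfileMatrix | pd.DataFrame,
    groups: Sequence | pd.Series | str,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Indicator value per T-RF (statistic only).

    Returns a DataFrame indexed by T-RF with ``indval`` (max over groups, in
    [0, 100]), ``indicator_group`` (argmax; ties broken by the declared group
    order and flagged in ``tied``), and per-group mean and sd of relative
    abundance.  All-zero T-RFs are excluded with a warning.
    """
    df, groups = _coerce(matrix, groups)
    levels = list(group_order) if group_order is not None else sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("indicator analysis needs >= 2 groups")
    zero = df.sum(axis=0) == 0
    if zero.any():
        warnings.warn(f"excluded {int(zero.sum())} all-zero T-RF(s)", stacklevel=2)
        df = df.loc[:, ~zero]
    x = df.to_numpy(float)
    z = np.column_stack([(groups == lv).to_numpy(float) for lv in levels])
    counts = z.sum(axis=0)
    if np.any(counts < 1):
        raise ValueError("every group needs >= 1 sample")
    a, b, iv = _indval_components(x, z, counts)
    best = iv.argmax(axis=0)
    tied = (iv == iv.max(axis=0)).sum(axis=0) > 1
    out = pd.DataFrame(index=df.columns)
    out.index.name = "trf"
    out["indval"] = iv.max(axis=0)
    out["indicator_group"] = [levels[i] for i in best]
    out["tied"] = tied
    for j, lv in enumerate(levels):
        sel = x[z[:, j] > 0]
        out[f"mean_{lv}"] = sel.mean(axis=0)
        out[f"sd_{lv}"] = sel.std(axis=0, ddof=1) if sel.shape[0] > 1 else 0.0
    return out


def indval_test(
    matrix: ProfileMatrix | pd.DataFrame,
    groups: Sequence | pd.Series | str,
    n_perm: int = 4999,
    seed: int | None = None,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """IndVal with a permutation p-value per T-RF.

    ``p = (1 + #(IndVal_perm >= IndVal_obs)) / (1 + n_perm)`` under random
    permutation of group labels across samples; one shared set of
    permutations serves all T-RFs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    out = indval(matrix, groups, group_order=group_order)
    df, groups = _coerce(matrix, groups)
    df = df.loc[:, out.index]
    levels = list(group_order) if group_order is not None else sorted(groups.unique())
    x = df.to_numpy(float)
    z = np.column_stack([(groups == lv).to_numpy(float) for lv in levels])
    counts = z.sum(axis=0)
    obs = out["indval"].to_numpy()
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    exceed = np.zeros(x.shape[1], dtype=int)
    presence = (x > 0).astype(float)
    batch = 250
    perms_left = n_perm
    while perms_left > 0:
        m = min(batch, perms_left)
        perms_left -= m
        idx = np.empty((m, n), dtype=np.intp)
        for i in range(m):
            idx[i] = rng.permutation(n)
        zp = z[idx]                                   # (m, n, g)
        means = np.einsum("png,nk->pgk", zp, x) / counts[None, :, None]
        tot = means.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(tot > 0, means / tot, 0.0)
        b = np.einsum("png,nk->pgk", zp, presence) / counts[None, :, None]
        iv = (100.0 * a * b).max(axis=1)              # (m, n_trfs)
        exceed += (iv >= obs[None, :]).sum(axis=0)
    out = out.copy()
    out["p"] = (1.0 + exceed) / (1.0 + n_perm)
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out


@dataclass
class UnivariateAnovaResult:
    """Permutation one-way ANOVA on one T-RF's abundances."""

    f: float
    p: float
    pairwise: pd.DataFrame
    n_permutations: int
    seed: int | None


def _one_way_f(x: np.ndarray, z: np.ndarray, counts: np.ndarray) -> float:
    grand = x.mean()
    means = (z.T @ x) / counts
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((x - z @ means) ** 2))
    df_b = len(counts) - 1
    df_w = len(x) - len(counts)
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("statistic undefined: no variance within or between groups")
        return np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def univariate_permutation_anova(
    values: Sequence[float] | np.ndarray,
    groups: Sequence | pd.Series,
    n_perm: int = 4999,
    seed: int | None = None,
    adjust: str | None = None,
) -> UnivariateAnovaResult:
    """Permutation-based one-way ANOVA with pairwise two-sample t follow-ups.

    The overall statistic is the classical one-way F; its p-value comes from
    label permutation.  Pairwise comparisons use the pooled-variance t
    statistic, two-sided, also by permutation, reported without multiplicity
    adjustment by default (``adjust`` as in :mod:`trflptools.permanova`).
    """
    x = np.asarray(values, float)
    groups = pd.Series(np.asarray(groups))
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    z = np.column_stack([(groups == lv).to_numpy(float) for lv in levels])
    counts = z.sum(axis=0)
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 samples")
    f_obs = _one_way_f(x, z, counts)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        try:
            if _one_way_f(xp, z, counts) >= f_obs:
                exceed += 1
        except ValueError:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for a, b in combinations(levels, 2):
        xa = x[(groups == a).to_numpy()]
        xb = x[(groups == b).to_numpy()]
        t_obs = abs(_pooled_t(xa, xb))
        pooled = np.concatenate([xa, xb])
        na = len(xa)
        ex = 0
        for _ in range(n_perm):
            xp = rng.permutation(pooled)
            ex += abs(_pooled_t(xp[:na], xp[na:])) >= t_obs
        rows.append((str(a), str(b), t_obs, (1.0 + ex) / (1.0 + n_perm)))
    pairwise = pd.DataFrame(rows, columns=["level_a", "level_b", "t", "p"])
    if adjust:
        from .permanova import _adjust_p

        pairwise["p_adjusted"] = _adjust_p(pairwise["p"].to_numpy(), adjust)
    return UnivariateAnovaResult(float(f_obs), float(p), pairwise, n_perm, seed)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    if s2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return (a.mean() - b.mean()) / np.sqrt(s2 * (1.0 / na + 1.0 / nb))


def responder_table(
    matrix: ProfileMatrix | pd.DataFrame,
    groups: Sequence | pd.Series | str,
    alpha: float = 0.05,
    n_perm: int = 4999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Indicator analysis followed by univariate permutation ANOVA per significant T-RF.

    Mirrors the workflow behind a responder table: T-RFs significant in the
    indicator analysis are re-analysed by a permutation one-way ANOVA with
    a-posteriori pairwise comparisons; per-group mean +/- sd columns are kept.
    """
    rng = np.random.default_rng(seed)
    iv = indval_test(matrix, groups, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)))
    df, g = _coerce(matrix, groups)
    rows = []
    for trf in iv.index[iv["p"] <= alpha]:
        res = univariate_permutation_anova(
            df[trf].to_numpy(), g, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        row = {"trf": trf, "indicator_group": iv.loc[trf, "indicator_group"],
               "indval": iv.loc[trf, "indval"], "indval_p": iv.loc[trf, "p"],
               "anova_p": res.p}
        for col in iv.columns:
            if col.startswith(("mean_", "sd_")):
                row[col] = iv.loc[trf, col]
        for _, pr in res.pairwise.iterrows():
            row[f"p_{pr['level_a']}_vs_{pr['level_b']}"] = pr["p"]
        rows.append(row)
    return pd.DataFrame(rows)
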
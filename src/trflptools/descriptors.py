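"""Fingerprint descriptors: Pareto-Lorenz evenness (PL20) and moving-window turnover (Δt).

The Pareto-Lorenz curve ranks a profile's T-RFs from most to least abundant
and plots the cumulative fraction of T-RFs (x) against the cumulative fraction
of abundance (y).  PL20, the curve's height at x = 20 %, scores community
dominance: 20 % for perfect evenness, approaching 100 % when a few T-RFs
dominate.

Moving-window analysis expresses community turnover between two groups of
samples (e.g. consecutive harvests) as the mean percent change,
100 × (1 − r), over all cross-group sample pairs, with r the Pearson
product-moment correlation between the two samples' abundance vectors over
the union of T-RF bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_profiles import PeakProfile, ProfileMatrix


@dataclass
class ParetoLorenzCurve:
    """Cumulative-band-fraction (x) vs cumulative-abundance-fraction (y), from (0,0) to (1,1)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x[0] != 0 or self.y[0] != 0 or abs(self.x[-1] - 1) > 1e-12 or abs(self.y[-1] - 1) > 1e-9:
            raise ValueError("Pareto-Lorenz curve must run from (0,0) to (1,1)")
        if np.any(np.diff(self.x) < 0) or np.any(np.diff(self.y) < -1e-12):
            raise ValueError("Pareto-Lorenz curve coordinates must be non-decreasing")

    @property
    def n_bands(self) -> int:
        return len(self.x) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cum_band_fraction": self.x, "cum_abundance_fraction": self.y})


def pareto_lorenz(profile: PeakProfile | Sequence[float] | np.ndarray) -> ParetoLorenzCurve:
    """Build the Pareto-Lorenz curve of one profile.

    Abundances are ranked high to low (ties broken by ascending T-RF size for
    determinism) and both axes cumulated and normalised; (0, 0) is prepended.
    Zero entries (T-RFs absent from the sample) are dropped.
    """
    if isinstance(profile, PeakProfile):
        sizes = np.array(sorted(profile.peaks), float)
        vals = np.array([profile.peaks[s] for s in sizes], float)
    else:
        vals = np.asarray(profile, float)
        sizes = np.arange(len(vals), dtype=float)
    pos = vals > 0
    vals, sizes = vals[pos], sizes[pos]
    if vals.size == 0:
        raise ValueError("profile has no positive abundances")
    # sort by (-abundance, size): descending abundance, ties by ascending size
    order = np.lexsort((sizes, -vals))
    vals = vals[order]
    n = len(vals)
    x = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    y = np.concatenate([[0.0], np.cumsum(vals) / vals.sum()])
    return ParetoLorenzCurve(x, y)


def pl20(curve: ParetoLorenzCurve, *, single_band: str = "step") -> float:
    """Evaluate the curve at the 20 %-of-bands line; returned on the 0-100 scale.

    Piecewise-linear interpolation between cumulative points.  A single-band
    profile is degenerate: its only interior point is (1, 1).  Under the
    default ``single_band="step"`` convention the curve is taken to jump to 1
    at the first band, giving PL20 = 100 (one band is maximal dominance);
    ``single_band="linear"`` interpolates the (0,0)-(1,1) segment instead,
    giving 20.
    """
    if curve.n_bands == 1:
        if single_band == "step":
            return 100.0
        if single_band == "linear":
            return 20.0
        raise ValueError(f"unknown single_band convention {single_band!r}")
    return 100.0 * float(np.interp(0.20, curve.x, curve.y))


def pl20_profile(profile: PeakProfile | Sequence[float], *, single_band: str = "step") -> float:
    """PL20 of one profile (convenience wrapper)."""
    return pl20(pareto_lorenz(profile), single_band=single_band)


def pl20_table(matrix: ProfileMatrix, *, single_band: str = "step") -> pd.Series:
    """PL20 per sample of a profile matrix, computed on each sample's present T-RFs."""
    out = {sid: pl20_profile(matrix.df.loc[sid].to_numpy(), single_band=single_band) for sid in matrix.samples}
    return pd.Series(out, name="pl20")


def percent_change_matrix(matrix: ProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Samples × samples percent-change matrix, 100 × (1 − Pearson r).

    r is computed between abundance vectors over the union of T-RF bins
    (absent T-RFs counted as 0).  Entries lie in [0, 200] with a zero
    diagonal.

    Raises
    ------
    ValueError
        If a sample's abundance vector has zero variance (correlation
        undefined), naming the sample.
    """
    df = matrix.df if isinstance(matrix, ProfileMatrix) else matrix
    X = df.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("percent_change_matrix needs at least 2 samples")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = df.index[np.where(sd == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero variance; Pearson correlation undefined")
    r = np.corrcoef(X)
    pc = 100.0 * (1.0 - r)
    np.fill_diagonal(pc, 0.0)
    pc = np.clip(pc, 0.0, 200.0)
    return pd.DataFrame(pc, index=df.index, columns=df.index)


@dataclass
class DeltaT:
    """Turnover between two consecutive groups: mean ± sd percent change over all cross pairs."""

    group_pair: tuple[str, str]
    mean_pct_change: float
    sd_pct_change: float
    n_pairs: int
    stratum: str | None = None


def moving_window_delta(
    matrix: ProfileMatrix,
    ordering: Sequence[str],
    factor: str = "season",
    within: str | None = None,
) -> list[DeltaT]:
    """Moving-window Δt between consecutive groups of a factor.

    For each consecutive pair (g, g+1) in ``ordering``, Δt is the mean and sd
    of percent change over *all* cross-group sample pairs (i in g, j in g+1).
    If ``within`` names a second metadata column (e.g. ``treatment``), one Δt
    series is produced per stratum.

    Returns a list of :class:`DeltaT`, one per window (× stratum).
    """
    if matrix.meta is None:
        raise ValueError("moving_window_delta requires sample metadata")
    known = set(matrix.meta[factor])
    for g in ordering:
        if g not in known:
            raise ValueError(f"unknown {factor} label {g!r}")
    pc = percent_change_matrix(matrix)
    strata = sorted(matrix.meta[within].unique()) if within else [None]
    out: list[DeltaT] = []
    for stratum in strata:
        meta = matrix.meta if stratum is None else matrix.meta[matrix.meta[within] == stratum]
        for a, b in zip(ordering[:-1], ordering[1:]):
            ids_a = meta.index[meta[factor] == a]
            ids_b = meta.index[meta[factor] == b]
            if len(ids_a) == 0 or len(ids_b) == 0:
                raise ValueError(f"no samples for {factor} level {a!r} or {b!r}"
                                 + (f" in stratum {stratum!r}" if stratum else ""))
            vals = pc.loc[ids_a, ids_b].to_numpy().ravel()
            out.append(
                DeltaT(
                    (str(a), str(b)),
                    float(vals.mean()),
                    float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    len(vals),
                    stratum=None if stratum is None else str(stratum),
                )
            )
    return out


def delta_t_table(deltas: Sequence[DeltaT]) -> pd.DataFrame:
    """Tidy table of Δt results."""
    return pd.DataFrame(
        {
            "stratum": [d.stratum for d in deltas],
            "group_a": [d.group_pair[0] for d in deltas],
            "group_b": [d.group_pair[1] for d in deltas],
            "delta_t": [d.mean_pct_change for d in deltas],
            "sd": [d.sd_pct_change for d in deltas],
            "n_pairs": [d.n_pairs for d in deltas],
        }
    )
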
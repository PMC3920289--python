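"""Reading, filtering, replicate averaging and cross-sample binning of T-RFLP peak tables.

A T-RFLP run yields, per sample, a list of detected peaks: terminal restriction
fragment (T-RF) size in base pairs and peak height in arbitrary fluorescence
units.  This module turns such peak tables into an analysis-ready samples ×
T-RFs matrix of relative abundances (%):

1. within each sample, peak heights are expressed relative to the total peak
   height and peaks below a relative-height threshold (default 0.5 %) are
   excluded, the survivors being re-normalised to 100 %;
2. fragment sizes are binned across samples by single-linkage clustering with
   a gap tolerance (default 0.5 bp), each bin labelled by its rounded mean
   size in bp;
3. duplicate DNA extractions of the same soil sample are averaged, a T-RF
   absent in one replicate contributing zero there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer", "autumn")
TREATMENTS = ("ambient", "ozone")

PEAK_COLUMNS = ("sample_id", "size", "height")
META_COLUMNS = ("sample_id", "pot_id", "season", "treatment", "extraction_replicate")

#: sum-to-100 tolerance on relative-abundance profiles
ROW_SUM_TOL = 1e-6


class FormatError(ValueError):
    """A required column is missing or a file cannot be parsed."""


class ConsistencyError(ValueError):
    """Peak table and metadata disagree (unknown sample, mismatched pots...)."""


class EmptyProfileError(ValueError):
    """No peak survives filtering."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 delimited table, comma for ``.csv`` else tab."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path))


def read_peak_table(path: str | Path, meta_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a peak table and its sample metadata.

    Parameters
    ----------
    path:
        Delimited file with columns ``sample_id``, ``size`` (bp), ``height``
        (fluorescence units), one row per detected peak.
    meta_path:
        Delimited file with columns ``sample_id``, ``pot_id``, ``season``,
        ``treatment``, ``extraction_replicate``.

    Returns
    -------
    (peaks, meta):
        Validated DataFrames.  Rows with non-positive size or height are
        dropped with a warning.

    Raises
    ------
    FormatError
        If a required column is missing.
    ConsistencyError
        If a sample appears in the peak table but not in the metadata.
    """
    peaks = read_delimited(path)
    meta = read_delimited(meta_path)
    return validate_peak_table(peaks, meta)


def validate_peak_table(peaks: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate in-memory peak and metadata tables (see :func:`read_peak_table`)."""
    for col in PEAK_COLUMNS:
        if col not in peaks.columns:
            raise FormatError(f"peak table is missing required column {col!r}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"metadata table is missing required column {col!r}")

    peaks = peaks.copy()
    peaks["size"] = pd.to_numeric(peaks["size"], errors="coerce")
    peaks["height"] = pd.to_numeric(peaks["height"], errors="coerce")
    bad = ~((peaks["size"] > 0) & (peaks["height"] > 0))
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} peak row(s) with non-positive or unparsable size/height",
            stacklevel=2,
        )
        peaks = peaks.loc[~bad]

    bad_season = ~meta["season"].isin(SEASONS)
    if bad_season.any():
        raise FormatError(f"unknown season value(s): {sorted(meta.loc[bad_season, 'season'].unique())}")
    bad_treat = ~meta["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        raise FormatError(f"unknown treatment value(s): {sorted(meta.loc[bad_treat, 'treatment'].unique())}")

    dup = meta.duplicated(subset=["pot_id", "season", "extraction_replicate"])
    if dup.any():
        raise ConsistencyError("duplicate (pot_id, season, extraction_replicate) in metadata")

    missing = set(peaks["sample_id"]) - set(meta["sample_id"])
    if missing:
        raise ConsistencyError(f"sample(s) present in peak table but not in metadata: {sorted(missing)}")
    return peaks.reset_index(drop=True), meta.reset_index(drop=True)


@dataclass
class PeakProfile:
    """One sample's filtered profile: T-RF size (bp) -> relative abundance (%)."""

    sample_id: str
    peaks: dict[float, float]
    pot_id: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.peaks.values())
        if self.peaks and abs(total - 100.0) > ROW_SUM_TOL:
            raise ValueError(f"profile {self.sample_id}: abundances sum to {total}, not 100")

    @property
    def sizes(self) -> list[float]:
        return sorted(self.peaks)


def relativize_and_filter(
    peaks: Mapping[float, float] | pd.DataFrame,
    threshold_pct: float = 0.5,
    *,
    sample_id: str = "",
    pot_id: str | None = None,
) -> PeakProfile:
    """Relativise one sample's peak heights and drop sub-threshold peaks.

    Each peak's relative height is computed against the total height of *all*
    detected peaks; peaks whose relative height falls below ``threshold_pct``
    are excluded and the survivors re-normalised to sum to 100 %.

    Parameters
    ----------
    peaks:
        Mapping size -> raw height, or a DataFrame with ``size`` and
        ``height`` columns (one sample only).
    threshold_pct:
        Exclusion threshold as percent of total peak height, in [0, 100).

    Raises
    ------
    EmptyProfileError
        If no peak reaches the threshold.
    """
    if not 0 <= threshold_pct < 100:
        raise ValueError(f"threshold_pct must be in [0, 100), got {threshold_pct}")
    if isinstance(peaks, pd.DataFrame):
        if "sample_id" in peaks.columns and peaks["sample_id"].nunique() > 1:
            raise ConsistencyError("relativize_and_filter expects peaks of a single sample")
        items = dict(zip(peaks["size"].to_numpy(float), peaks["height"].to_numpy(float)))
    else:
        items = {float(s): float(h) for s, h in peaks.items()}
    if not items:
        raise EmptyProfileError(f"sample {sample_id!r}: no peaks to filter")
    sizes = np.array(sorted(items))
    heights = np.array([items[s] for s in sizes])
    if np.any(heights <= 0) or np.any(sizes <= 0):
        raise ValueError("peak sizes and heights must be positive")
    rel = 100.0 * heights / heights.sum()
    keep = rel >= threshold_pct
    if not keep.any():
        raise EmptyProfileError(f"sample {sample_id!r}: all peaks below {threshold_pct}% threshold")
    kept = rel[keep]
    kept = 100.0 * kept / kept.sum()
    return PeakProfile(sample_id, dict(zip(sizes[keep], kept)), pot_id=pot_id)


def average_replicates(a: PeakProfile, b: PeakProfile) -> PeakProfile:
    """Average two extraction-replicate profiles of the same pot.

    T-RFs absent in one replicate contribute 0 % there; the mean profile is
    re-normalised to 100 %.  Requires both profiles to share a binned size
    grid (sizes are matched exactly).
    """
    if a.pot_id is not None and b.pot_id is not None and a.pot_id != b.pot_id:
        raise ConsistencyError(f"replicates come from different pots: {a.pot_id!r} vs {b.pot_id!r}")
    sizes = sorted(set(a.peaks) | set(b.peaks))
    mean = np.array([(a.peaks.get(s, 0.0) + b.peaks.get(s, 0.0)) / 2.0 for s in sizes])
    mean = 100.0 * mean / mean.sum()
    return PeakProfile(f"{a.sample_id}+{b.sample_id}", dict(zip(sizes, mean)), pot_id=a.pot_id or b.pot_id)


def _single_linkage_bins(sizes: np.ndarray, tol: float) -> np.ndarray:
    """Assign a bin index to each (sorted or unsorted) fragment size.

    Single-linkage in 1-D: sort sizes, start a new bin wherever the gap to the
    previous size exceeds ``tol``.
    """
    order = np.argsort(sizes, kind="stable")
    s = sizes[order]
    new_bin = np.ones(len(s), dtype=bool)
    new_bin[1:] = np.diff(s) > tol
    bin_of_sorted = np.cumsum(new_bin) - 1
    out = np.empty(len(s), dtype=int)
    out[order] = bin_of_sorted
    return out


@dataclass
class ProfileMatrix:
    """Samples × binned T-RFs relative-abundance matrix with sample metadata.

    ``df`` has sample ids as index and integer bin labels (bp) as columns,
    strictly increasing; every row sums to 100.  ``meta`` is indexed by
    sample id.
    """

    df: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.df = self.df.sort_index(axis=1)
        if self.meta is not None:
            if "sample_id" in self.meta.columns:
                self.meta = self.meta.set_index("sample_id")
            self.meta = self.meta.loc[self.df.index]
        self.validate()

    def validate(self) -> None:
        sums = self.df.to_numpy().sum(axis=1)
        if len(self.df) and not np.allclose(sums, 100.0, atol=ROW_SUM_TOL):
            raise ValueError("ProfileMatrix rows must sum to 100")
        cols = np.asarray(self.df.columns)
        if len(cols) > 1 and not np.all(np.diff(cols) > 0):
            raise ValueError("ProfileMatrix column labels must be strictly increasing")
        if len(self.df) and np.any(self.df.to_numpy().sum(axis=0) == 0):
            raise ValueError("ProfileMatrix must not contain all-zero columns")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def trfs(self) -> list[int]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(float)

    def profile(self, sample_id: str) -> PeakProfile:
        row = self.df.loc[sample_id]
        peaks = {float(s): float(v) for s, v in row.items() if v > 0}
        pot = None
        if self.meta is not None and "pot_id" in self.meta.columns:
            pot = self.meta.loc[sample_id, "pot_id"]
        return PeakProfile(sample_id, peaks, pot_id=pot)

    def average_replicates(self) -> "ProfileMatrix":
        """Average duplicate extractions per (pot, season); rows re-normalised.

        Returns a pot-level matrix whose sample ids are ``pot_id:season`` and
        whose metadata keeps pot_id, season, treatment.
        """
        if self.meta is None:
            raise ConsistencyError("replicate averaging requires sample metadata")
        meta = self.meta
        key = meta["pot_id"].astype(str) + ":" + meta["season"].astype(str)
        grouped = self.df.groupby(key.values).mean()
        vals = grouped.to_numpy()
        vals = 100.0 * vals / vals.sum(axis=1, keepdims=True)
        df = pd.DataFrame(vals, index=grouped.index, columns=grouped.columns)
        df = df.loc[:, df.sum(axis=0) > 0]
        new_meta = (
            meta.assign(_key=key.values)
            .groupby("_key")[["pot_id", "season", "treatment"]]
            .first()
        )
        new_meta.index.name = "sample_id"
        return ProfileMatrix(df, new_meta.loc[df.index])

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=_sep_for(Path(path)))

    @classmethod
    def from_csv(cls, path: str | Path, meta: pd.DataFrame | None = None) -> "ProfileMatrix":
        df = pd.read_csv(path, sep=_sep_for(Path(path)), index_col="sample_id")
        df.columns = [int(c) for c in df.columns]
        return cls(df, meta)


def bin_trfs(
    profiles: Sequence[PeakProfile],
    bin_tolerance_bp: float = 0.5,
    meta: pd.DataFrame | None = None,
) -> ProfileMatrix:
    """Bin T-RF sizes across samples and assemble the profile matrix.

    Sizes from all profiles are clustered by single linkage: a gap greater
    than ``bin_tolerance_bp`` between consecutive sorted sizes starts a new
    bin.  Each bin is labelled with the rounded mean of its member sizes
    (label collisions resolved by incrementing the later label).  Within one
    sample, peaks falling in the same bin have their abundances summed; rows
    are re-normalised to 100.
    """
    if not profiles:
        raise ValueError("no profiles to bin")
    sample_ids = [p.sample_id for p in profiles]
    all_sizes = np.concatenate([np.array(sorted(p.peaks), float) for p in profiles])
    all_vals = np.concatenate([np.array([p.peaks[s] for s in sorted(p.peaks)]) for p in profiles])
    all_rows = np.concatenate([np.full(len(p.peaks), i) for i, p in enumerate(profiles)])

    bins = _single_linkage_bins(all_sizes, bin_tolerance_bp)
    n_bins = bins.max() + 1
    # label = rounded mean of member sizes, deterministic collision handling
    labels = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        labels[b] = int(round(all_sizes[bins == b].mean()))
    for b in range(1, n_bins):
        if labels[b] <= labels[b - 1]:
            labels[b] = labels[b - 1] + 1

    mat = np.zeros((len(profiles), n_bins))
    np.add.at(mat, (all_rows.astype(int), bins), all_vals)
    mat = 100.0 * mat / mat.sum(axis=1, keepdims=True)
    df = pd.DataFrame(mat, index=sample_ids, columns=labels)
    return ProfileMatrix(df, meta)


def build_profile_matrix(
    peaks: pd.DataFrame,
    meta: pd.DataFrame,
    threshold_pct: float = 0.5,
    bin_tolerance_bp: float = 0.5,
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Full ingest pipeline: filter per extraction, bin across samples, average replicates.

    Returns
    -------
    (extraction_matrix, pot_matrix):
        The binned extraction-level matrix and the pot-level matrix obtained
        by averaging duplicate extractions (the matrix the study's statistics
        run on).
    """
    peaks, meta = validate_peak_table(peaks, meta)
    pot_of = dict(zip(meta["sample_id"], meta["pot_id"]))
    profiles = []
    for sid, grp in peaks.groupby("sample_id", sort=False):
        profiles.append(
            relativize_and_filter(grp, threshold_pct, sample_id=str(sid), pot_id=pot_of[sid])
        )
    order = [sid for sid in meta["sample_id"] if sid in {p.sample_id for p in profiles}]
    by_id = {p.sample_id: p for p in profiles}
    profiles = [by_id[sid] for sid in order]
    extraction = bin_trfs(profiles, bin_tolerance_bp, meta=meta)
    return extraction, extraction.average_replicates()
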
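"""Synthetic T-RFLP studies and digest fixtures with realistic statistical structure.

The study generator emulates a pot experiment: 2 treatments (ambient /
elevated ozone) x 3 seasons x 6 pots, duplicate DNA extractions per pot, and a
community of ~39 T-RFs strongly dominated by a handful of fragments
(pot-mean PL20 near 87).  A base composition is drawn once per study from a
Dirichlet prior; treatment/season cells modify it by planted multiplicative
fold changes (re-normalised); pots add multiplicative log-normal noise; each
extraction scales the pot composition to raw fluorescence peak heights with
log-normal noise calibrated so that duplicate extractions show a major-peak
coefficient of variation near the 6.5 % target.  Sub-threshold nuisance peaks
are sprinkled in so the 0.5 % filtering rule is exercised.

The sequence generator plants restriction recognition sites at exact cut
positions (and nowhere else) in random amplicon-like sequences behind a
labeled forward primer, returning FASTA fixtures plus a ground-truth table of
expected terminal fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .insilico_digest import (
    ENZYMES,
    IUPAC,
    Enzyme,
    find_cut_positions,
    reverse_complement,
)
from .io_profiles import SEASONS, TREATMENTS

#: labeled forward primers of the study's two assays
ACT_PRIMER = "CGCGGCCTATCAGCTTGTTG"          # actinobacterial 16S rRNA, S-C-Act-235a-S-20
PKS_PRIMER = "GGXTGCACSTCXGGXMTSGAC"          # PKS type II, 540f (X = inosine)

# base-community shape: a steep dominant block, a mid block of minor T-RFs
# sitting safely above the 0.5 % detection threshold (so their presence is
# stable across replicates), and a rare tail below it (so the filtering rule
# is exercised); calibrated so pot-mean profiles processed through the default
# pipeline have PL20 near 87
_MAJOR_N = 3
_MAJOR_RATIO = 0.45
_MAJOR_SHARE = 0.82
_MINOR_FRAC = 1 / 3          # fraction of non-major T-RFs in the mid block
_MINOR_RATIO = 0.97
_MINOR_SHARE = 0.14
#: Dirichlet concentration (sum of alphas): controls study-to-study wobble
_CONCENTRATION = 5000.0
#: multiplicative log-normal spread of pot compositions (per T-RF)
_POT_SIGMA = 0.15
#: extraction-level CV calibration: relativisation cancels part of the raw
#: height noise on major peaks, so raw noise is inflated by this factor
_CV_ADJUST = 1.15


class SpecError(ValueError):
    """The study design specification is not satisfiable."""


class GenerationError(RuntimeError):
    """Sequence generation could not satisfy the planted-site constraints."""


@dataclass
class PlantedEffect:
    """Multiplicative fold change on one T-RF in the cells matching season/treatment.

    ``rank`` indexes the base community by abundance rank (0 = most abundant
    T-RF).  ``season``/``treatment`` of None match every level of that factor.
    """

    rank: int
    fold: float
    season: str | None = None
    treatment: str | None = None


def compositional_fold(rank: int, observed_fold: float, n_trfs: int = 39,
                       dominance: np.ndarray | None = None) -> float:
    """Pre-normalisation fold that changes a T-RF's *observed* relative abundance
    by ``observed_fold``.

    Fingerprint studies report shifts on the relative-abundance scale (a peak
    going from 12 % to 22 % of total height), but a multiplicative fold f
    applied to one component of a composition is diluted by re-normalisation:
    the observed ratio is f / (1 + w (f - 1)) for a component of share w.
    This inverts that relation for the expected share of abundance rank
    ``rank`` under the given dominance preset.
    """
    alpha = dominance if dominance is not None else default_dominance(n_trfs)
    w = float(np.sort(alpha)[::-1][rank] / alpha.sum())
    denom = 1.0 - observed_fold * w
    if denom <= 0:
        raise SpecError(f"observed fold {observed_fold} unreachable for a share of {w:.2f}")
    return observed_fold * (1.0 - w) / denom


def default_planted_effects() -> list[PlantedEffect]:
    """The study-like defaults: one dominant seasonal responder whose relative
    abundance roughly doubles from spring to summer (and stays high in
    autumn), and one dominant T-RF depressed by ozone in summer only.

    Fold targets on the observed scale are 1.82 (summer) and 1.47 (autumn) for
    the seasonal responder and 0.60 for the ozone responder, converted to
    compositional folds via :func:`compositional_fold`.
    """
    return [
        PlantedEffect(rank=1, fold=compositional_fold(1, 1.82), season="summer"),
        PlantedEffect(rank=1, fold=compositional_fold(1, 1.47), season="autumn"),
        PlantedEffect(rank=2, fold=compositional_fold(2, 0.60), season="summer",
                      treatment="ozone"),
    ]


def default_dominance(n_trfs: int = 39) -> np.ndarray:
    """Dirichlet concentration vector of the default dominance preset."""
    if n_trfs < 2:
        raise SpecError("need >= 2 T-RFs")
    n_major = min(_MAJOR_N, n_trfs - 1)
    n_minor = max(1, round((n_trfs - n_major) * _MINOR_FRAC))
    n_rare = n_trfs - n_major - n_minor
    major = _MAJOR_RATIO ** np.arange(n_major)
    major *= _MAJOR_SHARE / major.sum()
    minor = _MINOR_RATIO ** np.arange(n_minor)
    minor_share = _MINOR_SHARE if n_rare else 1.0 - _MAJOR_SHARE
    minor *= minor_share / minor.sum()
    parts = [major, minor]
    if n_rare:
        parts.append(np.full(n_rare, (1.0 - _MAJOR_SHARE - minor_share) / n_rare))
    return np.concatenate(parts) * _CONCENTRATION


@dataclass
class StudyDesignSpec:
    """Design and noise parameters of a synthetic fingerprint study."""

    n_treatments: int = 2
    n_seasons: int = 3
    pots_per_cell: int = 6
    extractions_per_pot: int = 2
    n_trfs: int = 39
    dominance: np.ndarray | None = None
    replicate_cv: float = 6.5          # percent, major-peak CV of duplicate extractions
    planted_effects: list[PlantedEffect] = field(default_factory=default_planted_effects)
    noise_floor: float = 4.0           # expected sub-threshold nuisance peaks per extraction
    total_signal: float = 50_000.0     # fluorescence units per extraction (lognormal around this)
    size_jitter_sd: float = 0.15       # bp, fragment size-calling jitter
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_treatments", "n_seasons", "pots_per_cell", "extractions_per_pot", "n_trfs"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be >= 1")
        if self.replicate_cv < 0 or self.noise_floor < 0 or self.size_jitter_sd < 0:
            raise SpecError("noise parameters must be non-negative")
        for eff in self.planted_effects:
            if eff.fold <= 0:
                raise SpecError("planted folds must be positive")
            if not 0 <= eff.rank < self.n_trfs:
                raise SpecError(f"planted T-RF rank {eff.rank} outside 0..{self.n_trfs - 1}")
        if self.dominance is not None:
            self.dominance = np.asarray(self.dominance, float)
            if len(self.dominance) != self.n_trfs or np.any(self.dominance <= 0):
                raise SpecError("dominance vector must be positive with one entry per T-RF")

    @property
    def seasons(self) -> list[str]:
        if self.n_seasons <= len(SEASONS):
            return list(SEASONS[: self.n_seasons])
        return list(SEASONS) + [f"season{i}" for i in range(len(SEASONS), self.n_seasons)]

    @property
    def treatments(self) -> list[str]:
        if self.n_treatments <= len(TREATMENTS):
            return list(TREATMENTS[: self.n_treatments])
        return list(TREATMENTS) + [f"treatment{i}" for i in range(len(TREATMENTS), self.n_treatments)]


def generate_study(
    spec: StudyDesignSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate raw peak tables, sample metadata and the ground truth of one study.

    Returns
    -------
    (peaks, meta, truth):
        ``peaks`` has one row per emitted peak (sample_id, size, height);
        ``meta`` one row per extraction sample; ``truth`` records the T-RF
        sizes, base and per-cell compositions and the planted effects (with
        the concrete T-RF size each rank resolved to).
    """
    spec = spec or StudyDesignSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    # distinct integer fragment sizes on an even grid (gaps >= 2 bp, so the
    # default 0.5 bp binning tolerance can never merge two true T-RFs)
    sizes = np.sort(rng.choice(np.arange(60, 601, 2), size=spec.n_trfs, replace=False))
    alpha = spec.dominance if spec.dominance is not None else default_dominance(spec.n_trfs)
    base = rng.dirichlet(alpha)
    base = base[rng.permutation(spec.n_trfs)]  # abundance not ordered by size
    rank_to_index = np.argsort(-base, kind="stable")

    seasons, treatments = spec.seasons, spec.treatments
    cells: dict[tuple[str, str], np.ndarray] = {}
    for season in seasons:
        for treatment in treatments:
            comp = base.copy()
            for eff in spec.planted_effects:
                if (eff.season in (None, season)) and (eff.treatment in (None, treatment)):
                    comp[rank_to_index[eff.rank]] *= eff.fold
            cells[(season, treatment)] = comp / comp.sum()

    cv = spec.replicate_cv / 100.0 * _CV_ADJUST
    sigma_extr = np.sqrt(np.log1p(cv ** 2))

    peak_rows: list[tuple[str, float, float]] = []
    meta_rows: list[tuple[str, str, str, str, int]] = []
    for treatment in treatments:
        for p in range(1, spec.pots_per_cell + 1):
            pot_id = f"{treatment[:3]}-P{p}"
            for season in seasons:
                pot_comp = cells[(season, treatment)] * rng.lognormal(0.0, _POT_SIGMA, spec.n_trfs)
                pot_comp /= pot_comp.sum()
                for r in range(1, spec.extractions_per_pot + 1):
                    sid = f"{pot_id}-{season}-e{r}"
                    meta_rows.append((sid, pot_id, season, treatment, r))
                    total = spec.total_signal * rng.lognormal(0.0, 0.2)
                    heights = pot_comp * total * rng.lognormal(0.0, sigma_extr, spec.n_trfs)
                    obs_sizes = sizes + rng.normal(0.0, spec.size_jitter_sd, spec.n_trfs)
                    for s, h in zip(obs_sizes, heights):
                        peak_rows.append((sid, round(float(s), 2), round(float(h), 3)))
                    # nuisance peaks below the 0.5 % relative-height threshold
                    n_noise = rng.poisson(spec.noise_floor)
                    if n_noise:
                        tot = heights.sum()
                        for _ in range(n_noise):
                            size = float(rng.uniform(60.0, 600.0))
                            h = float(rng.uniform(0.0005, 0.0045) * tot)
                            peak_rows.append((sid, round(size, 2), round(h, 3)))

    peaks = pd.DataFrame(peak_rows, columns=["sample_id", "size", "height"])
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "pot_id", "season", "treatment", "extraction_replicate"],
    )
    truth = {
        "sizes": sizes,
        "base_composition": base,
        "cell_compositions": pd.DataFrame(
            {f"{s}:{t}": c for (s, t), c in cells.items()}, index=sizes
        ).T,
        "planted": [
            {
                "rank": eff.rank,
                "size": int(sizes[rank_to_index[eff.rank]]),
                "season": eff.season,
                "treatment": eff.treatment,
                "fold": eff.fold,
            }
            for eff in spec.planted_effects
        ],
        "seed": spec.seed,
    }
    return peaks, meta, truth


def write_study(peaks: pd.DataFrame, meta: pd.DataFrame, truth: dict, outdir: str | Path) -> None:
    """Write a generated study in the formats the ingest module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks.to_csv(outdir / "peaks.csv", index=False)
    meta.to_csv(outdir / "meta.csv", index=False)
    truth["cell_compositions"].to_csv(outdir / "truth_cell_compositions.csv")
    pd.DataFrame(truth["planted"]).to_csv(outdir / "truth_planted.csv", index=False)


@dataclass
class PlantedSite:
    """A recognition site to stamp so the labeled strand is cut at ``cut_position``."""

    enzyme: Enzyme
    cut_position: int
    strand: str = "+"


def _concretize(pattern: str, rng: np.random.Generator) -> str:
    return "".join(ch if ch in "ACGT" else rng.choice(list(IUPAC[ch])) for ch in pattern.upper())


def generate_sequences(
    n: int,
    length_range: tuple[int, int] = (200, 1500),
    planted_sites: Sequence[PlantedSite | tuple] = (),
    primer: str = ACT_PRIMER,
    enzymes: Sequence[Enzyme] = (),
    seed: int | None = None,
    out_fasta: str | Path | None = None,
    max_retries: int = 50,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random amplicon-like sequences with recognition sites exactly at planted positions.

    Every sequence starts with the (concretised) forward primer; position 0 is
    the primer's first base.  ``planted_sites`` gives the desired labeled-
    strand cut positions; the recognition sequence is stamped on the requested
    strand so the mapped cut lands exactly there.  For every enzyme in
    ``enzymes`` (plus all planted enzymes) the finished sequence contains *no*
    recognition site other than the planted ones; offending background bases
    are re-sampled, with bounded retries.

    Returns the records as (id, sequence) pairs plus a truth table of the
    expected terminal fragment per sequence and enzyme.
    """
    rng = np.random.default_rng(seed)
    sites = [s if isinstance(s, PlantedSite) else PlantedSite(*s) for s in planted_sites]
    watch = {e.name: e for e in enzymes}
    for s in sites:
        watch.setdefault(s.enzyme.name, s.enzyme)
    if not watch:
        watch = dict(ENZYMES)

    # every planted site (and its cut) must lie strictly inside the molecule
    needed = max(
        [s.cut_position + 1 for s in sites]
        + [start + len(stamp) for start, stamp in _stamps(sites)]
        + [len(primer) + 1]
    )
    lo, hi = int(length_range[0]), int(length_range[1])
    if hi < needed:
        raise GenerationError(
            f"length range {length_range} cannot accommodate planted sites (need >= {needed})"
        )
    lo = max(lo, needed)

    records: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = _generate_one(length, sites, primer, list(watch.values()), rng, max_retries)
        rid = f"synth{i + 1:04d}"
        records.append((rid, seq))
        for name, enz in watch.items():
            cuts = [s.cut_position for s in sites if s.enzyme.name == name]
            truth_rows.append((rid, name, min(cuts) if cuts else None))
    truth = pd.DataFrame(truth_rows, columns=["sequence_id", "enzyme", "expected_trf"])
    if out_fasta is not None:
        with open(out_fasta, "w", encoding="utf-8") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n")
                for j in range(0, len(seq), 70):
                    fh.write(seq[j:j + 70] + "\n")
    return records, truth


def _stamps(sites: Sequence[PlantedSite]) -> list[tuple[int, str]]:
    """(start, stamped string) for each planted site, in labeled-strand coordinates."""
    out = []
    for s in sites:
        rec = s.enzyme.recognition
        if s.strand == "+":
            start = s.cut_position - s.enzyme.cut_offset_top
            stamp = rec
        elif s.strand == "-":
            start = s.cut_position - len(rec) + s.enzyme.cut_offset_bottom
            stamp = reverse_complement(rec)
        else:
            raise ValueError(f"strand must be '+' or '-', got {s.strand!r}")
        out.append((start, stamp))
    return out


def _generate_one(
    length: int,
    sites: Sequence[PlantedSite],
    primer: str,
    watch: Sequence[Enzyme],
    rng: np.random.Generator,
    max_retries: int,
) -> str:
    stamps = _stamps(sites)
    planted_cuts = {e.name: sorted(s.cut_position for s in sites if s.enzyme.name == e.name)
                    for e in watch}
    for start, stamp in stamps:
        if start < len(primer):
            raise GenerationError("planted site would overlap the primer")
        if start + len(stamp) > length:
            raise GenerationError("planted site does not fit in the sequence length")
    spans = sorted((start, start + len(stamp)) for start, stamp in stamps)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise GenerationError("planted sites overlap")

    bases = np.array(list("ACGT"))
    for _ in range(max_retries):
        chars = list(_concretize(primer, rng)) + list(rng.choice(bases, length - len(primer)))
        stamped = np.zeros(length, dtype=bool)
        for start, stamp in stamps:
            chars[start:start + len(stamp)] = list(stamp)
            stamped[start:start + len(stamp)] = True
        seq = "".join(chars)
        ok = _repair(chars, stamped, watch, planted_cuts, len(primer), rng)
        if ok:
            return "".join(chars)
    raise GenerationError(f"could not satisfy planted-site constraints after {max_retries} retries")


def _repair(
    chars: list[str],
    stamped: np.ndarray,
    watch: Sequence[Enzyme],
    planted_cuts: dict[str, list[int]],
    primer_len: int,
    rng: np.random.Generator,
    max_rounds: int = 400,
) -> bool:
    """Mutate background bases until every watched enzyme cuts only at planted positions."""
    bases = "ACGT"
    for _ in range(max_rounds):
        seq = "".join(chars)
        offending: tuple[int, int] | None = None
        for enz in watch:
            want = planted_cuts[enz.name]
            got = find_cut_positions(seq, enz)
            extra = [c for c in got if c not in want]
            if extra:
                # locate the recognition window responsible for the first extra cut
                offending = _site_window(seq, enz, extra[0])
                break
            if any(w not in got for w in want):
                return False  # a stamp was destroyed; restart from scratch
        if offending is None:
            return True
        lo, hi = offending
        mutable = [j for j in range(max(lo, 0), min(hi, len(chars)))
                   if not stamped[j] and j >= primer_len]
        if not mutable:
            return False
        j = int(rng.choice(mutable))
        chars[j] = bases[(bases.index(chars[j]) + int(rng.integers(1, 4))) % 4]
    return False


def _site_window(seq: str, enzyme: Enzyme, cut: int) -> tuple[int, int]:
    """Recognition-window coordinates that produce a given labeled-strand cut."""
    L = len(enzyme.recognition)
    start = cut - enzyme.cut_offset_top
    if 0 <= start <= len(seq) - L and seq[start:start + L] and \
            _matches(seq[start:start + L], enzyme.recognition):
        return start, start + L
    start = cut - L + enzyme.cut_offset_bottom
    return max(start, 0), max(start, 0) + L


def _matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        w in IUPAC[p] for w, p in zip(window, pattern.upper())
    )
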
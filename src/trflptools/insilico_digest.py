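"""In-silico restriction digestion: predicted labeled terminal fragment (T-RF) sizes.

In T-RFLP the forward PCR primer carries a 5'-terminal fluorescent label, so
after digestion only the fragment between the labeled 5' end and the nearest
cut of the labeled (top) strand is sized.  This module finds recognition sites
on both strands with IUPAC-aware matching, maps each enzyme's strand-specific
cut offsets onto the labeled strand, takes the minimum cut position over one
or two enzymes (a double digest), anchors coordinates at the forward primer,
and matches predicted sizes against observed T-RFs with a drift tolerance
(capillary size calling typically runs a few bp below the true length).

Coordinate convention: position 0 is the first base of the labeled primer and
a cut position c means the labeled strand is cleaved *before* index c, giving
a labeled fragment of c nucleotides.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    # inosine in primer sequences pairs with any base
    "X": "ACGT", "I": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNXI", "TGCAYRSWMKVHDBNXI")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


_SEQ_CODES = "ACGTRYSWKMBDHVN"


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _SEQ_CODES:
            raise ValueError(f"invalid nucleotide {ch!r} at index {i}")
    return seq


def _iupac_regex(pattern: str) -> re.Pattern:
    """Regex finding every (overlapping) occurrence of an IUPAC pattern.

    A pattern character matches a sequence symbol iff the symbol's base set is
    contained in the pattern character's set, i.e. the site is certainly
    present (a G in the sequence matches pattern S, but an N does not match
    pattern A).
    """
    parts = []
    for ch in pattern.upper():
        try:
            exp = set(IUPAC[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern") from None
        allowed = [sym for sym in _SEQ_CODES if set(IUPAC[sym]) <= exp]
        parts.append(allowed[0] if len(allowed) == 1 else "[" + "".join(allowed) + "]")
    # lookahead so overlapping sites are all reported
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition sequence and strand-specific cut offsets.

    ``cut_offset_top`` / ``cut_offset_bottom`` are relative to the start of
    the recognition sequence on the strand that carries it: the recognition
    strand is cut before the base at ``start + cut_offset_top`` and the
    complementary strand before ``start + cut_offset_bottom`` (in
    recognition-strand coordinates).  For offset cutters such as FauI
    CCCGC(4/6) the offsets exceed the recognition length.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition sequence must be >= 4 nt")
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


# catalog definitions used in the study's two assays
MBOI = Enzyme("MboI", "GATC", 0, 4)          # ^GATC
HHAI = Enzyme("HhaI", "GCGC", 3, 1)          # GCG^C
FAUI = Enzyme("FauI", "CCCGC", 5 + 4, 5 + 6)  # CCCGC(4/6)

ENZYMES = {e.name: e for e in (MBOI, HHAI, FAUI)}


def find_cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """Positions where ``enzyme`` cleaves the labeled (given) strand.

    Recognition sites are searched on both strands (IUPAC-aware, overlapping
    sites included).  A top-strand site starting at p cuts the labeled strand
    at ``p + cut_offset_top``; a bottom-strand site (the given strand matches
    the reverse complement of the recognition at q) cuts it at
    ``q + len(recognition) - cut_offset_bottom``.  Only cuts falling strictly
    inside the molecule (0 < position < len) are realisable and returned,
    sorted ascending.
    """
    seq = _check_sequence(sequence)
    L = len(enzyme.recognition)
    cuts: set[int] = set()
    for m in _iupac_regex(enzyme.recognition).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset_top)
    rc_pattern = reverse_complement(enzyme.recognition)
    if rc_pattern != enzyme.recognition:  # palindromic sites are already covered
        for m in _iupac_regex(rc_pattern).finditer(seq):
            cuts.add(m.start() + L - enzyme.cut_offset_bottom)
    return sorted(c for c in cuts if 0 < c < len(seq))


NO_CUT = "no cut"


@dataclass
class DigestPrediction:
    """Expected labeled T-RF for one sequence under one or two enzymes."""

    sequence_id: str
    enzymes: tuple[str, ...]
    expected_trf: int | None          # None encodes the "no cut" sentinel
    cutting_enzyme: str | None = None
    anchoring: str = "given"          # given | primer | revcomp | assumed-start

    @property
    def no_cut(self) -> bool:
        return self.expected_trf is None

    @property
    def cut_position(self) -> int | None:
        return self.expected_trf


def terminal_fragment(
    sequence: str,
    enzymes: Enzyme | Sequence[Enzyme],
    sequence_id: str = "",
) -> DigestPrediction:
    """Labeled terminal fragment of a (single or double) digest.

    The expected T-RF is the smallest labeled-strand cut position across all
    enzymes; a double digest therefore equals the minimum of the single
    digests.  Returns the no-cut sentinel when no enzyme cuts.
    """
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    if not enzymes:
        raise ValueError("at least one enzyme required")
    if not sequence:
        raise ValueError("empty sequence")
    best: tuple[int, str] | None = None
    for enz in enzymes:
        cuts = find_cut_positions(sequence, enz)
        if cuts and (best is None or cuts[0] < best[0]):
            best = (cuts[0], enz.name)
    names = tuple(e.name for e in enzymes)
    if best is None:
        return DigestPrediction(sequence_id, names, None)
    return DigestPrediction(sequence_id, names, best[0], cutting_enzyme=best[1])


def _find_primer(seq: str, primer: str) -> int | None:
    m = _iupac_regex(primer).search(seq)
    return m.start() if m else None


def predict_from_fasta(
    fasta: str | Path | Iterable,
    primer: str,
    enzymes: Enzyme | Sequence[Enzyme],
) -> list[DigestPrediction]:
    """Predict T-RFs for every record of a FASTA file, anchored at the forward primer.

    The primer (IUPAC codes allowed; X/I = inosine matches any base) is
    located in each sequence; coordinates are re-anchored so position 0 is the
    primer's first base.  If the primer matches only the reverse strand the
    record is reverse-complemented (noted in ``anchoring``); if it is not
    found at all the sequence is assumed to start at the primer
    (``anchoring="assumed-start"``).
    """
    primer = primer.upper()
    if isinstance(fasta, (str, Path)):
        try:
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta), "fasta")]
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read FASTA {fasta}: {exc}") from exc
    else:
        records = [(rid, str(s)) for rid, s in fasta]
    if not records:
        warnings.warn("FASTA contains no records", stacklevel=2)
        return []
    out = []
    for rec_id, rec_seq in records:
        seq = rec_seq.upper()
        anchoring = "primer"
        pos = _find_primer(seq, primer)
        if pos is None:
            rc = reverse_complement(seq)
            pos = _find_primer(rc, primer)
            if pos is not None:
                seq = rc
                anchoring = "revcomp"
        if pos is None:
            pos = 0
            anchoring = "assumed-start"
        pred = terminal_fragment(seq[pos:], enzymes, sequence_id=rec_id)
        pred.anchoring = anchoring
        out.append(pred)
    return out


@dataclass
class TrfMatch:
    """Pairing of an observed T-RF with a predicted one, with size drift."""

    observed_trf: float
    prediction: DigestPrediction | None
    drift: float | None
    matched: bool


def match_trfs(
    observed: Sequence[float],
    predicted: Sequence[DigestPrediction],
    mode: str = "fixed-window",
    tolerance_bp: float = 5.0,
) -> list[TrfMatch]:
    """Match observed T-RF sizes to predictions.

    ``fixed-window``: an observed T-RF matches the nearest prediction with
    ``|observed - expected| <= tolerance_bp``.  ``linear-calibration``: a line
    ``observed ~ a + b * expected`` is fitted on the provisional fixed-window
    matches and matching is redone on residuals from that line (absorbing the
    systematic electrophoretic drift).  Each observed T-RF matches at most one
    prediction; unmatched entries are reported with ``matched=False``.
    """
    if not list(observed) or not list(predicted):
        raise ValueError("both observed and predicted lists must be non-empty")
    preds = [p for p in predicted if p.expected_trf is not None]

    def _match(offset_fn) -> list[TrfMatch]:
        out = []
        for obs in observed:
            best, best_resid = None, None
            for p in preds:
                resid = obs - offset_fn(p.expected_trf)
                if abs(resid) <= tolerance_bp and (best is None or abs(resid) < abs(best_resid)):
                    best, best_resid = p, resid
            if best is None:
                out.append(TrfMatch(float(obs), None, None, False))
            else:
                out.append(TrfMatch(float(obs), best, float(obs - best.expected_trf), True))
        return out

    first = _match(lambda e: e)
    if mode == "fixed-window":
        return first
    if mode != "linear-calibration":
        raise ValueError(f"unknown matching mode {mode!r}")
    pairs = [(m.prediction.expected_trf, m.observed_trf) for m in first if m.matched]
    if len(pairs) < 2:
        return first
    exp = np.array([p[0] for p in pairs], float)
    obs = np.array([p[1] for p in pairs], float)
    b, a = np.polyfit(exp, obs, 1)
    return _match(lambda e: a + b * e)


def prediction_table(predictions: Sequence[DigestPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": [p.sequence_id for p in predictions],
            "enzymes": ["+".join(p.enzymes) for p in predictions],
            "cutting_enzyme": [p.cutting_enzyme for p in predictions],
            "expected_trf": [p.expected_trf if p.expected_trf is not None else NO_CUT
                             for p in predictions],
            "anchoring": [p.anchoring for p in predictions],
        }
    )


def match_table(matches: Sequence[TrfMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "observed_trf": [m.observed_trf for m in matches],
            "sequence_id": [m.prediction.sequence_id if m.prediction else None for m in matches],
            "cutting_enzyme": [m.prediction.cutting_enzyme if m.prediction else None for m in matches],
            "expected_trf": [m.prediction.expected_trf if m.prediction else None for m in matches],
            "drift": [m.drift for m in matches],
            "matched": [m.matched for m in matches],
        }
    )
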
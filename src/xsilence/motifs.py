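"""Scanning for a short AT-rich silencer binding motif.

The motif is supplied, not discovered: either an IUPAC consensus string or
a position weight matrix (per-position base probabilities). PWM scanning
scores every window on both strands with a log-odds score against an
i.i.d. background of the stated GC content, keeping windows at or above a
threshold (by default 80% of the motif's maximal attainable score).
Consensus scanning is an exact IUPAC match.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, GenomicInterval
from .stretches import ATStretch

__all__ = [
    "Motif",
    "MotifHit",
    "DEFAULT_CONSENSUS",
    "scan_motif",
    "annotate_stretch_motifs",
    "motif_enrichment",
    "motif_bound_fraction",
]

#: Approximate consensus of the 10-bp AT-rich binding motif, transcribed
#: from the published sequence logo; the underlying matrix is not public,
#: so this consensus is an approximation and fully configurable.
DEFAULT_CONSENSUS = "WWTAWTAWWW"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A binding motif as IUPAC consensus and/or probability matrix.

    ``pwm`` has shape (length, 4) with columns ordered A, C, G, T; each row
    sums to 1. ``score_threshold_fraction`` sets the reporting threshold as
    a fraction of the maximal attainable log-odds score.
    """

    consensus: str | None = None
    pwm: np.ndarray | None = None
    score_threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError("motif needs a consensus or a PWM")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC symbols in consensus: {sorted(bad)}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("PWM must have shape (length, 4)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("PWM rows must each sum to 1")
        if len(self) < 4:
            raise ValueError("motif length must be >= 4")

    def __len__(self) -> int:
        if self.pwm is not None:
            return self.pwm.shape[0]
        return len(self.consensus)

    @classmethod
    def from_consensus_counts(cls, consensus: str,
                              pseudo: float = 0.05) -> "Motif":
        """Build a soft PWM from an IUPAC consensus: allowed bases share
        1 - 4*pseudo of the probability mass at each position."""
        L = len(consensus)
        pwm = np.full((L, 4), pseudo)
        for i, sym in enumerate(consensus.upper()):
            allowed = IUPAC[sym]
            for b in allowed:
                pwm[i, _BASE_INDEX[b]] += (1 - 4 * pseudo) / len(allowed)
        return cls(consensus=consensus, pwm=pwm)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(len(arr), 4, dtype=np.int8)  # 4 = N / unknown
    for b, i in _BASE_INDEX.items():
        code[arr == ord(b)] = i
    return code


def _logodds(pwm: np.ndarray, background_gc: float) -> np.ndarray:
    bg = np.array([(1 - background_gc) / 2, background_gc / 2,
                   background_gc / 2, (1 - background_gc) / 2])
    return np.log2(np.maximum(pwm, 1e-12) / bg)


def _window_scores(code: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = lo.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    # pad the log-odds table so code 4 (N) poisons the window score
    table = np.hstack([lo, np.full((L, 1), -np.inf)])
    for j in range(L):
        scores += table[j, code[j:j + n]]
    return scores


def scan_motif(genome: GenomeSequence, motif: Motif,
               background_gc: float | None = None) -> list[MotifHit]:
    """Scan both strands of a genome for motif occurrences.

    With a PWM, windows scoring at least ``score_threshold_fraction`` of
    the maximal attainable log-odds score (against an i.i.d. background of
    ``background_gc``, defaulting to the genome's own GC fraction) are
    reported; overlapping hits are allowed. With only a consensus, exact
    IUPAC matching is used and the threshold is ignored. Hit intervals are
    always given in forward-strand coordinates.
    """
    L = len(motif)
    if L > len(genome):
        raise ValueError("motif longer than genome")
    seq = genome.residues
    hits: list[MotifHit] = []
    if motif.pwm is not None:
        from .profiles import gc_fraction

        if background_gc is None:
            background_gc = gc_fraction(seq)
        lo = _logodds(motif.pwm, background_gc)
        max_score = float(lo.max(axis=1).sum())
        threshold = motif.score_threshold_fraction * max_score
        code = _encode(seq)
        fwd = _window_scores(code, lo)
        # reverse strand: score the reverse-complement motif on forward coords
        lo_rc = lo[::-1, ::-1]
        rev = _window_scores(code, lo_rc)
        for i in np.flatnonzero(fwd >= threshold):
            hits.append(MotifHit(GenomicInterval(genome.id, int(i), int(i) + L),
                                 "+", float(fwd[i])))
        for i in np.flatnonzero(rev >= threshold):
            hits.append(MotifHit(GenomicInterval(genome.id, int(i), int(i) + L),
                                 "-", float(rev[i])))
    else:
        code = _encode(seq)
        n = len(seq) - L + 1
        pats = (motif.consensus, reverse_complement(motif.consensus))
        for strand, pat in zip("+-", pats):
            ok = np.ones(n, dtype=bool)
            for j, sym in enumerate(pat):
                allowed = np.array([_BASE_INDEX[b] for b in IUPAC[sym]])
                ok &= np.isin(code[j:j + n], allowed)  # genome N never matches
            for i in np.flatnonzero(ok):
                hits.append(MotifHit(
                    GenomicInterval(genome.id, int(i), int(i) + L),
                    strand, float(L)))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def annotate_stretch_motifs(stretches: Iterable[ATStretch],
                            hits: Sequence[MotifHit]) -> list[ATStretch]:
    """Flag stretches that contain a motif hit entirely within them."""
    out = []
    for st in stretches:
        iv = st.interval
        contained = any(
            h.interval.seq_id == iv.seq_id
            and h.interval.start >= iv.start and h.interval.end <= iv.end
            for h in hits
        )
        out.append(replace(st, has_motif=contained))
    return out


def motif_enrichment(stretches: Sequence[ATStretch],
                     length_bins: Sequence[tuple[int, int]]) -> pd.DataFrame:
    """Bound fraction of motif-containing vs motif-free stretches per bin.

    ``fold`` is the ratio of the two fractions; NaN where either class is
    empty in a bin, inf where only motif-free stretches are never bound.
    """
    rows = []
    for lo, hi in length_bins:
        sel = [s for s in stretches if lo <= s.length <= hi]
        with_m = [s for s in sel if s.has_motif]
        without = [s for s in sel if not s.has_motif]
        f_with = (sum(s.is_bound for s in with_m) / len(with_m)
                  if with_m else np.nan)
        f_without = (sum(s.is_bound for s in without) / len(without)
                     if without else np.nan)
        if not with_m or not without:
            fold = np.nan
        elif f_without == 0:
            fold = np.inf if f_with > 0 else np.nan
        else:
            fold = f_with / f_without
        rows.append({
            "bin": f"{lo}-{hi}", "n_with_motif": len(with_m),
            "n_without_motif": len(without),
            "fraction_bound_with_motif": f_with,
            "fraction_bound_without": f_without,
            "fold": fold,
        })
    return pd.DataFrame(rows)


def motif_bound_fraction(hits: Sequence[MotifHit],
                         peaks: Sequence) -> tuple[int, int, float]:
    """Count motif hits overlapping any occupancy peak.

    Returns (n_bound, n_total, fraction_unbound); the fraction is NaN when
    there are no hits.
    """
    ivs = [p if isinstance(p, GenomicInterval) else p.interval for p in peaks]
    n_total = len(hits)
    n_bound = sum(
        1 for h in hits if any(h.interval.overlap(iv) >= 1 for iv in ivs)
    )
    frac_unbound = (n_total - n_bound) / n_total if n_total else np.nan
    return n_bound, n_total, frac_unbound
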
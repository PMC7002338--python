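"""Genome-wide detection of AT-rich stretches.

Xenogeneic silencers of the Lsr2/H-NS family nucleate on AT-rich DNA. The
scanner reports every *maximal* AT-rich stretch: an interval that starts and
ends on A or T, contains at most ``max_interruptions`` G/C/N residues, and
cannot be extended on either side without violating those rules. For each
stretch it counts G/C interruptions and A/T steps (adjacent A→T or T→A
dinucleotides, a proxy for DNA flexibility), and flags whether the stretch
overlaps a silencer occupancy peak.

Scanning is strandless: A/T content, interruption count and A/T-step count
are all invariant under reverse complementation. Circular topology is
recorded on the genome but the scan does not wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, GenomicInterval

__all__ = [
    "ATStretch",
    "StretchBinMatrix",
    "count_at_steps",
    "find_at_stretches",
    "mark_bound",
    "stretch_bin_matrix",
    "stretch_table",
]


@dataclass(frozen=True)
class ATStretch:
    """A maximal AT-rich interval.

    ``gc_interruptions`` counts G/C/N residues inside the stretch;
    ``at_steps`` counts adjacent pairs that alternate A→T or T→A.
    """

    interval: GenomicInterval
    gc_interruptions: int
    at_steps: int
    has_motif: bool = False
    is_bound: bool = False

    @property
    def length(self) -> int:
        return len(self.interval)


def count_at_steps(seq: str) -> int:
    """Count A/T steps: adjacent pairs reading A→T or T→A.

    Pairs involving G, C or N contribute nothing. Raises on empty input.
    """
    if not seq:
        raise ValueError("cannot count A/T steps of an empty sequence")
    s = seq.upper()
    return sum(1 for a, b in zip(s, s[1:]) if (a, b) in (("A", "T"), ("T", "A")))


def find_at_stretches(genome: GenomeSequence, max_interruptions: int = 5,
                      min_length: int = 10) -> list[ATStretch]:
    """Find all maximal AT-rich stretches of a genome.

    A stretch [s, e) qualifies when (i) the first and last residues are A or
    T, (ii) it contains at most ``max_interruptions`` non-A/T residues and
    (iii) its length is at least ``min_length``. Only maximal stretches are
    reported: none returned is properly contained in another interval
    satisfying (i)-(ii). With interruptions allowed, distinct maximal
    stretches may overlap; all are reported, sorted by start.
    """
    if max_interruptions < 0:
        raise ValueError("max_interruptions must be >= 0")
    if min_length < 2:
        raise ValueError("min_length must be >= 2")

    seq = genome.residues
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    # prefix[i] = number of non-A/T residues in seq[:i]
    prefix = np.concatenate(([0], np.cumsum(~is_at)))
    at_idx = np.flatnonzero(is_at)
    if len(at_idx) == 0:
        return []
    # prev_at[i] = index of the last A/T residue at position <= i, or -1
    prev_at = np.maximum.accumulate(np.where(is_at, np.arange(n), -1))

    k = max_interruptions
    out: list[ATStretch] = []
    for s in at_idx:
        # furthest position p with <= k interruptions in seq[s:p]:
        # prefix[p] - prefix[s] <= k  =>  p = searchsorted(prefix, prefix[s]+k, 'right') - 1
        p = int(np.searchsorted(prefix, prefix[s] + k, side="right")) - 1
        e = int(prev_at[min(p, n) - 1]) + 1  # retract to the last A/T terminus
        if e <= s:
            continue
        inner = int(prefix[e] - prefix[s])
        # left-maximality: nearest A/T start further left costs the run of
        # non-A/T residues between it and s; report only if that overruns k
        q = int(prev_at[s - 1]) if s > 0 else -1
        if q >= 0 and (s - q - 1) + inner <= k:
            continue
        if e - s < min_length:
            continue
        sub = seq[s:e]
        out.append(ATStretch(
            interval=GenomicInterval(genome.id, int(s), e),
            gc_interruptions=inner,
            at_steps=count_at_steps(sub),
        ))
    return out


def mark_bound(stretches: Iterable[ATStretch],
               peaks: Sequence["GenomicInterval | object"],
               min_overlap: int = 1) -> list[ATStretch]:
    """Flag each stretch bound when it overlaps any peak by >= min_overlap bp.

    ``peaks`` may be plain intervals or objects with an ``interval``
    attribute (occupancy peaks).
    """
    ivs = [p if isinstance(p, GenomicInterval) else p.interval for p in peaks]
    p_start = np.array([iv.start for iv in ivs], dtype=int)
    p_end = np.array([iv.end for iv in ivs], dtype=int)
    p_seq = np.array([iv.seq_id for iv in ivs])
    out = []
    for st in stretches:
        iv = st.interval
        ov = (np.minimum(p_end, iv.end) - np.maximum(p_start, iv.start))
        bound = bool(np.any((ov >= min_overlap) & (p_seq == iv.seq_id))) \
            if len(ivs) else False
        out.append(replace(st, is_bound=bound))
    return out


@dataclass
class StretchBinMatrix:
    """Counts and silencer-bound fractions of stretches, binned twice.

    Rows bin stretch length; columns bin either the G/C-interruption count
    or the A/T-step count. ``bound_fraction`` is NaN where a cell is empty.
    """

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    bound_fraction: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        c = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        f = pd.DataFrame(self.bound_fraction, index=self.row_labels,
                         columns=self.col_labels)
        return c, f


def _bin_index(value: int, bins: Sequence[tuple[int, int]]) -> int | None:
    for i, (lo, hi) in enumerate(bins):
        if lo <= value <= hi:
            return i
    return None


def _check_bins(bins: Sequence[tuple[int, int]]) -> None:
    for lo, hi in bins:
        if hi < lo:
            raise ValueError(f"empty bin ({lo}, {hi})")
    ordered = sorted(bins)
    for (_, hi1), (lo2, _) in zip(ordered, ordered[1:]):
        if lo2 <= hi1:
            raise ValueError("bins overlap")


def stretch_bin_matrix(stretches: Sequence[ATStretch],
                       length_bins: Sequence[tuple[int, int]],
                       second_axis: str = "interruptions",
                       step_bins: Sequence[tuple[int, int]] | None = None,
                       ) -> StretchBinMatrix:
    """Cross-tabulate stretches by length and a second property.

    ``second_axis`` selects "interruptions" (each count its own column when
    ``step_bins`` is None) or "at_steps" (binned by ``step_bins``). Each
    stretch is counted once; stretches falling outside all bins are dropped.
    """
    _check_bins(length_bins)
    if second_axis == "interruptions":
        values = [s.gc_interruptions for s in stretches]
        if step_bins is None:
            top = max(values, default=0)
            step_bins = [(i, i) for i in range(top + 1)]
    elif second_axis == "at_steps":
        values = [s.at_steps for s in stretches]
        if step_bins is None:
            raise ValueError("step_bins required for at_steps axis")
    else:
        raise ValueError(f"unknown second_axis {second_axis!r}")
    _check_bins(step_bins)

    counts = np.zeros((len(length_bins), len(step_bins)), dtype=int)
    bound = np.zeros_like(counts)
    for s, v in zip(stretches, values):
        i = _bin_index(s.length, length_bins)
        j = _bin_index(v, step_bins)
        if i is None or j is None:
            continue
        counts[i, j] += 1
        if s.is_bound:
            bound[i, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, bound / np.maximum(counts, 1), np.nan)

    def _label(lo: int, hi: int) -> str:
        return str(lo) if lo == hi else f"{lo}-{hi}"

    return StretchBinMatrix(
        row_labels=[_label(*b) for b in length_bins],
        col_labels=[_label(*b) for b in step_bins],
        counts=counts,
        bound_fraction=frac,
    )


def representative_stretches(stretches: Sequence[ATStretch],
                             regions: Sequence[GenomicInterval],
                             prefer_motif: bool = False) -> list[ATStretch]:
    """One stretch per region, for comparing regions on equal footing.

    A low-GC region fragments into several maximal stretches; its
    representative is the longest one overlapping it (ties leftmost). With
    ``prefer_motif`` the longest motif-tagged stretch wins when the region
    holds one — the motif marks the candidate nucleation site, so the
    tagged stretch is the natural representative. Regions without any
    overlapping stretch are skipped.
    """
    starts = np.array([s.interval.start for s in stretches])
    ends = np.array([s.interval.end for s in stretches])
    lengths = np.array([s.length for s in stretches])
    motif = np.array([s.has_motif for s in stretches], dtype=bool)
    out = []
    for region in regions:
        mask = (starts < region.end) & (ends > region.start)
        if prefer_motif and (mask & motif).any():
            mask &= motif
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        best = idx[np.lexsort((starts[idx], -lengths[idx]))[0]]
        out.append(stretches[int(best)])
    return out


def stretch_table(stretches: Sequence[ATStretch]) -> pd.DataFrame:
    """Flat table of stretches (TSV-ready)."""
    return pd.DataFrame({
        "seq_id": [s.interval.seq_id for s in stretches],
        "start": [s.interval.start for s in stretches],
        "end": [s.interval.end for s in stretches],
        "length": [s.length for s in stretches],
        "interruptions": [s.gc_interruptions for s in stretches],
        "at_steps": [s.at_steps for s in stretches],
        "has_motif": [s.has_motif for s in stretches],
        "bound": [s.is_bound for s in stretches],
    })
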
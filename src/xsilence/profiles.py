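"""Rolling GC/coverage profiles around silencer occupancy peaks.

Silencer target promoters are compared on a shared relative axis: the base
of maximal occupancy (the nucleation site) is position 0, and each profile
is mirrored where needed so the start codon of the silenced gene lies to
the right. On this axis, positions toward the gene start (downstream of the
nucleation site) are positive. The same axis is used for operator-insertion
positions in :mod:`xsilence.design`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import CoverageTrack, Gene, GenomicInterval, TSSRecord

__all__ = [
    "Profile",
    "OccupancyPeak",
    "gc_fraction",
    "rolling_profile",
    "locate_max",
    "locate_max_smoothed",
    "center_and_orient",
    "overlay_mean",
    "classify_peak",
    "assign_tss",
    "tss_relative_positions",
]

#: Peak widths (bp) delimiting the two promoter classes: class 1 peaks span
#: 500-850 bp (typically one distinct GC drop), class 2 peaks are wider.
CLASS1_RANGE = (500, 850)


@dataclass
class Profile:
    """A windowed track on a grid of window-start positions.

    Before centering, ``grid`` holds genomic window starts; after
    :func:`center_and_orient`, it holds window midpoints relative to the
    occupancy maximum (0 = window nearest the maximum), oriented so the
    gene start lies rightward.
    """

    grid: np.ndarray
    values: np.ndarray
    window: int
    step: int
    center_position: int | None = None
    orientation: str = "as_is"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must align")


@dataclass
class OccupancyPeak:
    """A silencer-bound region with its maximum and width class."""

    interval: GenomicInterval
    max_position: int
    promoter_id: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.max_position < self.interval.end):
            raise ValueError("max_position must lie inside the peak interval")

    @property
    def width(self) -> int:
        return len(self.interval)

    @property
    def width_class(self) -> str:
        return classify_peak(self.width)


def gc_fraction(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T) of a sequence; N is excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    total = gc + s.count("A") + s.count("T")
    if total == 0:
        raise ValueError("sequence contains no unambiguous residues")
    return gc / total


def _as_values(values_or_seq) -> np.ndarray:
    if isinstance(values_or_seq, str):
        arr = np.frombuffer(values_or_seq.upper().encode("ascii"), dtype=np.uint8)
        gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
        gc[arr == ord("N")] = np.nan  # excluded from window numerator & denominator
        return gc
    if isinstance(values_or_seq, CoverageTrack):
        return values_or_seq.values
    return np.asarray(values_or_seq, dtype=float)


def rolling_profile(values_or_seq, window: int = 50, step: int = 10,
                    start: int = 0) -> Profile:
    """Rolling mean with the given window and step (defaults 50 bp / 10 bp).

    Accepts a nucleotide string (GC fraction per window, N excluded), a
    coverage track, or a numeric vector. Only full windows are emitted:
    grid point g covers [g, g+window), giving floor((L-window)/step)+1
    points. ``start`` offsets the grid to genomic coordinates when the
    input is a slice of the genome.
    """
    v = _as_values(values_or_seq)
    L = len(v)
    if L < window:
        raise ValueError(f"input length {L} shorter than window {window}")
    n = (L - window) // step + 1
    offsets = np.arange(n) * step
    valid = ~np.isnan(v)
    num = np.concatenate(([0.0], np.cumsum(np.where(valid, v, 0.0))))
    den = np.concatenate(([0], np.cumsum(valid)))
    sums = num[offsets + window] - num[offsets]
    counts = den[offsets + window] - den[offsets]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Profile(grid=offsets + start, values=means, window=window, step=step)


def locate_max(track: CoverageTrack, interval: GenomicInterval) -> int:
    """Genomic index of maximal coverage within an interval (leftmost tie)."""
    sub = track.values[interval.start:interval.end]
    if len(sub) == 0:
        raise ValueError("empty interval")
    if np.all(sub == 0):
        warnings.warn(f"no coverage in [{interval.start}, {interval.end}); "
                      "returning leftmost base")
    return interval.start + int(np.argmax(sub))


def locate_max_smoothed(track: CoverageTrack, interval: GenomicInterval,
                        window: int = 50, step: int = 10) -> int:
    """Occupancy maximum called on the rolling-mean coverage.

    The raw per-base argmax is noise-sensitive on broad peaks; maxima are
    therefore called on the 50 bp / 10 bp rolling mean (the same smoothing
    used for plotting) and reported as the midpoint of the best window,
    leftmost on ties.
    """
    sub = track.values[interval.start:interval.end]
    if len(sub) < window:
        return locate_max(track, interval)
    prof = rolling_profile(sub, window=window, step=step, start=interval.start)
    return int(prof.grid[int(np.argmax(prof.values))] + window // 2)


def center_and_orient(profile: Profile, peak: OccupancyPeak,
                      gene_strand: str) -> Profile:
    """Re-express a profile relative to the occupancy maximum.

    The window whose midpoint lies nearest ``peak.max_position`` maps to
    relative position 0; other windows sit at multiples of the step. For a
    minus-strand gene the profile is mirrored (grid negated, values
    reversed) so the gene start lies to the right.
    """
    mids = profile.grid + profile.window // 2
    anchor = mids[np.argmin(np.abs(mids - peak.max_position))]
    rel = mids - anchor
    values = profile.values
    orientation = "as_is"
    if gene_strand == "-":
        rel = -rel[::-1]
        values = values[::-1]
        orientation = "flipped"
    return Profile(grid=rel, values=values, window=profile.window,
                   step=profile.step, center_position=peak.max_position,
                   orientation=orientation)


def overlay_mean(profiles: Sequence[Profile], min_profiles: int = 1) -> Profile:
    """Pointwise mean of centered profiles on their shared relative grid.

    Grid points covered by fewer than ``min_profiles`` profiles are
    dropped. All profiles must share one step size.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    steps = {p.step for p in profiles}
    if len(steps) != 1:
        raise ValueError(f"profiles mix step sizes {sorted(steps)}")
    step = steps.pop()
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p in profiles:
        for g, v in zip(p.grid, p.values):
            if np.isnan(v):
                continue
            sums[g] = sums.get(g, 0.0) + v
            counts[g] = counts.get(g, 0) + 1
    grid = np.array(sorted(g for g in counts if counts[g] >= min_profiles))
    values = np.array([sums[g] / counts[g] for g in grid])
    return Profile(grid=grid, values=values, window=profiles[0].window,
                   step=step, orientation="as_is")


def classify_peak(peak_width: int) -> str:
    """Width class of an occupancy peak: 500-850 bp inclusive is class 1,
    wider is class 2, narrower is unclassified."""
    if peak_width <= 0:
        raise ValueError("width must be positive")
    lo, hi = CLASS1_RANGE
    if peak_width < lo:
        return "unclassified"
    return "class1" if peak_width <= hi else "class2"


def assign_tss(tss: Iterable[TSSRecord], genes: Sequence[Gene],
               upstream: int = 500) -> list[TSSRecord]:
    """Assign TSS to genes and rank them by enrichment score.

    A TSS belongs to a gene when it shares the gene's strand and lies
    within ``upstream`` bp upstream of the start codon (the start codon
    position itself included). Within one promoter, TSS get dense ranks
    1..n by descending enrichment score. A TSS matching several genes is
    assigned to the one with the nearest start codon.
    """
    assigned: list[TSSRecord] = []
    for rec in tss:
        best: tuple[int, Gene] | None = None
        for g in genes:
            if rec.strand != g.strand or (rec.seq_id and rec.seq_id != g.seq_id):
                continue
            if g.strand == "+":
                dist = g.start_codon - rec.position
            else:
                dist = rec.position - g.start_codon
            if 0 <= dist <= upstream and (best is None or dist < best[0]):
                best = (dist, g)
        assigned.append(TSSRecord(
            position=rec.position, strand=rec.strand,
            enrichment_score=rec.enrichment_score,
            assigned_gene=best[1].gene_id if best else None,
            seq_id=rec.seq_id,
        ))
    # dense ranks per promoter, best score first
    by_gene: dict[str, list[TSSRecord]] = {}
    for rec in assigned:
        if rec.assigned_gene is not None:
            by_gene.setdefault(rec.assigned_gene, []).append(rec)
    for recs in by_gene.values():
        recs.sort(key=lambda r: -r.enrichment_score)
        for i, rec in enumerate(recs, start=1):
            rec.rank = i
    return assigned


def tss_relative_positions(assigned_tss: Sequence[TSSRecord],
                           peaks: dict[str, OccupancyPeak],
                           gene_strands: dict[str, str],
                           bin_width: int = 10,
                           ) -> tuple[list[int], np.ndarray, np.ndarray, list[bool]]:
    """Signed TSS positions relative to each promoter's occupancy maximum.

    Distances use the oriented promoter axis (downstream of the maximum,
    toward the gene start, is positive). Returns the distances, histogram
    counts and bin edges, and a top-ranked flag per distance. TSS whose
    promoter has no peak are skipped with a warning.
    """
    distances: list[int] = []
    top: list[bool] = []
    for rec in assigned_tss:
        if rec.assigned_gene is None:
            continue
        peak = peaks.get(rec.assigned_gene)
        if peak is None:
            warnings.warn(f"TSS at {rec.position} has no occupancy peak for "
                          f"promoter {rec.assigned_gene!r}; skipped")
            continue
        strand = gene_strands[rec.assigned_gene]
        d = rec.position - peak.max_position
        if strand == "-":
            d = -d
        distances.append(int(d))
        top.append(rec.rank == 1)
    if distances:
        lo = (min(distances) // bin_width) * bin_width
        hi = (max(distances) // bin_width + 1) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
    else:
        edges = np.array([0, bin_width])
    counts, edges = np.histogram(distances, bins=edges)
    return distances, counts, edges, top
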
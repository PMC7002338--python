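"""Synthetic genomes, occupancy tracks, TSS tables and reporter plates.

The generator emulates the statistical structure the analysis assumes for
a high-GC actinobacterial chromosome carrying horizontally acquired
low-GC islands silenced by a nucleoid-associated protein:

* an i.i.d. background at ~54% GC containing non-overlapping low-GC
  islands whose GC dips smoothly (cosine-shaped) to ~35% at the island
  center;
* a short AT-rich motif planted inside a configurable fraction of islands;
* occupancy coverage with a Gaussian-shaped peak centered on each bound
  island's GC minimum, on a noisy baseline;
* TSS scattered around peak maxima with random enrichment scores;
* plate-reader time series (logistic backscatter growth, fluorescence
  proportional to backscatter with multiplicative log-normal noise) under
  effector +/- conditions.

Islands are separated by at least twice the maximal peak width so that
peak-to-promoter assignment is unambiguous. All randomness flows from one
seed: the top-level seed is split into independent child streams (genome,
coverage, TSS, reporter) via `numpy.random.SeedSequence.spawn`, so each
emitted file is bit-reproducible and insensitive to the order in which
the other files are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome_io import (CoverageTrack, Gene, GenomeSequence, GenomicInterval,
                        TSSRecord, write_bed, write_bedgraph, write_fasta,
                        write_gff3_genes, write_tss_table, write_tsv)
from .motifs import DEFAULT_CONSENSUS, IUPAC
from .profiles import OccupancyPeak

__all__ = [
    "PeakModel",
    "SimulationSpec",
    "SimulationTruth",
    "default_binding_rule",
    "fold_binding_rule",
    "simulate_genome",
    "simulate_coverage",
    "simulate_tss",
    "simulate_reporter",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PeakModel:
    """Shape parameters of occupancy peaks (arbitrary coverage units)."""

    amplitude: float = 10.0
    width_range: tuple[int, int] = (500, 1500)  # spans both width classes
    noise_sd: float = 0.1
    baseline: float = 1.0


def default_binding_rule(length: int, has_motif: bool) -> float:
    """Bound probability increasing with island length, boosted 3x by the
    motif (capped at 0.95)."""
    base = min(0.95, length / 600.0)
    return min(0.95, base * (3.0 if has_motif else 1.0))


def fold_binding_rule(p0: float, fold: float) -> Callable[[int, bool], float]:
    """Length-independent rule: p0 without motif, min(1, fold*p0) with."""
    def rule(length: int, has_motif: bool) -> float:
        return min(1.0, p0 * fold) if has_motif else p0
    return rule


@dataclass
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    genome_length: int = 300_000
    background_gc: float = 0.54  # genome-wide GC of the emulated chromosome
    n_islands: int = 50
    island_length_range: tuple[int, int] = (200, 600)
    island_gc: float = 0.35
    motif_consensus: str = DEFAULT_CONSENSUS
    motif_plant_probability: float = 0.5
    peak_model: PeakModel = field(default_factory=PeakModel)
    binding_rule: Callable[[int, bool], float] = default_binding_rule
    tss_offset_sd: float = 15.0
    seed: int = 0
    seq_id: str = "sim"

    def __post_init__(self) -> None:
        if not 0 <= self.motif_plant_probability <= 1:
            raise ValueError("motif_plant_probability must be in [0, 1]")
        if self.island_gc >= self.background_gc:
            raise ValueError("island_gc must be below background_gc")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    islands: list[GenomicInterval]
    gc_minima: list[int]  # per-island position of the GC minimum
    motif_positions: list[int | None]  # start of planted motif, or None
    bound: list[bool]
    peaks: list[OccupancyPeak]  # only for bound islands
    peak_island_index: list[int]
    genes: list[Gene]
    tss_positions: list[list[int]]  # per peak
    gene_of_peak: list[str]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _place_islands(spec: SimulationSpec,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Island intervals separated by >= 2x the maximal peak width."""
    gap = 2 * spec.peak_model.width_range[1]
    lo, hi = spec.island_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_islands)
    needed = int(lengths.sum()) + gap * (spec.n_islands + 1)
    if needed > spec.genome_length:
        raise ValueError(
            f"{spec.n_islands} islands with separation {gap} bp need "
            f"{needed} bp but genome is {spec.genome_length} bp"
        )
    slack = spec.genome_length - needed
    # distribute the slack randomly over the n+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=spec.n_islands))
    extra = np.diff(np.concatenate(([0], cuts, [slack])))
    islands = []
    pos = 0
    for length, add in zip(lengths, extra[:-1]):
        pos += gap + int(add)
        islands.append((pos, pos + int(length)))
        pos += int(length)
    return islands


def _sample_motif(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[s])) for s in consensus.upper())


def simulate_genome(spec: SimulationSpec,
                    ) -> tuple[GenomeSequence, SimulationTruth]:
    """Draw a genome with low-GC islands, planted motifs and bound flags."""
    rng = _child_rngs(spec.seed, 4)[0]
    n = spec.genome_length
    gc_prob = np.full(n, spec.background_gc)
    islands = _place_islands(spec, rng)
    gc_minima = []
    for s, e in islands:
        x = np.arange(s, e)
        L = e - s
        depth = 0.5 * (1 - np.cos(2 * np.pi * (x - s) / L))  # 0 at edges, 1 mid
        gc_prob[s:e] = spec.background_gc - depth * (spec.background_gc
                                                     - spec.island_gc)
        gc_minima.append(s + int(np.argmin(gc_prob[s:e])))

    is_gc = rng.random(n) < gc_prob
    pick = rng.integers(0, 2, size=n)  # G vs C, A vs T
    codes = np.where(is_gc, np.where(pick == 0, 1, 2),  # C or G
                     np.where(pick == 0, 0, 3))          # A or T
    seq = np.array(list("ACGT"))[codes]

    motif_positions: list[int | None] = []
    margin = 10
    for (s, e) in islands:
        if rng.random() < spec.motif_plant_probability:
            word = _sample_motif(spec.motif_consensus, rng)
            lo_p, hi_p = s + margin, e - margin - len(word)
            p = int(rng.integers(lo_p, hi_p + 1)) if hi_p >= lo_p else s
            seq[p:p + len(word)] = list(word)
            motif_positions.append(p)
        else:
            motif_positions.append(None)

    bound = [
        bool(rng.random() < spec.binding_rule(e - s, m is not None))
        for (s, e), m in zip(islands, motif_positions)
    ]

    genome = GenomeSequence(spec.seq_id, "".join(seq))
    truth = SimulationTruth(
        islands=[GenomicInterval(spec.seq_id, s, e) for s, e in islands],
        gc_minima=gc_minima, motif_positions=motif_positions, bound=bound,
        peaks=[], peak_island_index=[], genes=[], tss_positions=[],
        gene_of_peak=[],
    )
    _add_peaks_and_genes(truth, spec, rng)
    return genome, truth


def _add_peaks_and_genes(truth: SimulationTruth, spec: SimulationSpec,
                         rng: np.random.Generator) -> None:
    """Peak intervals (bound islands only) and a gene downstream of each."""
    lo_w, hi_w = spec.peak_model.width_range
    n = spec.genome_length
    for idx, (iv, center, bound) in enumerate(
            zip(truth.islands, truth.gc_minima, truth.bound)):
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene_{idx:04d}"
        # start codon ~85 bp downstream of the occupancy maximum
        if strand == "+":
            g_start = min(center + 85, n - 900)
            gene = Gene(spec.seq_id, g_start, g_start + 900, "+", gene_id)
        else:
            g_end = max(center - 85, 900)
            gene = Gene(spec.seq_id, g_end - 900, g_end, "-", gene_id)
        truth.genes.append(gene)
        if not bound:
            continue
        width = int(rng.integers(lo_w, hi_w + 1))
        start = max(0, center - width // 2)
        end = min(n, start + width)
        truth.peaks.append(OccupancyPeak(
            interval=GenomicInterval(spec.seq_id, start, end),
            max_position=center, promoter_id=gene_id))
        truth.peak_island_index.append(idx)
        truth.gene_of_peak.append(gene_id)


def simulate_coverage(truth: SimulationTruth,
                      spec: SimulationSpec) -> CoverageTrack:
    """Occupancy track: Gaussian bump per bound island + baseline noise."""
    rng = _child_rngs(spec.seed, 4)[1]
    pm = spec.peak_model
    n = spec.genome_length
    values = np.full(n, pm.baseline)
    for peak in truth.peaks:
        s, e = peak.interval.start, peak.interval.end
        sd = len(peak.interval) / 6.0
        x = np.arange(s, e)
        values[s:e] += pm.amplitude * np.exp(
            -0.5 * ((x - peak.max_position) / sd) ** 2)
    if pm.noise_sd > 0:
        values = values + rng.normal(0, pm.noise_sd, size=n)
    return CoverageTrack(spec.seq_id, np.clip(values, 0, None))


def simulate_tss(truth: SimulationTruth, spec: SimulationSpec,
                 n_tss_range: tuple[int, int] = (1, 3)) -> list[TSSRecord]:
    """TSS scattered (Gaussian, sd = tss_offset_sd) around peak maxima.

    Enrichment scores are log-normal; offsets are applied on the oriented
    promoter axis so the TSS distribution is symmetric around the maximum
    regardless of gene strand.
    """
    rng = _child_rngs(spec.seed, 4)[2]
    records: list[TSSRecord] = []
    truth.tss_positions = []
    gene_by_id = {g.gene_id: g for g in truth.genes}
    for peak, gene_id in zip(truth.peaks, truth.gene_of_peak):
        gene = gene_by_id[gene_id]
        k = int(rng.integers(n_tss_range[0], n_tss_range[1] + 1))
        positions = []
        for _ in range(k):
            offset = (int(round(rng.normal(0, spec.tss_offset_sd)))
                      if spec.tss_offset_sd > 0 else 0)
            pos = (peak.max_position + offset if gene.strand == "+"
                   else peak.max_position - offset)
            score = float(np.round(rng.lognormal(mean=2.0, sigma=1.0), 3))
            records.append(TSSRecord(position=pos, strand=gene.strand,
                                     enrichment_score=score,
                                     seq_id=spec.seq_id))
            positions.append(pos)
        truth.tss_positions.append(positions)
    return records


def simulate_reporter(constructs: Sequence[str],
                      effects: dict[str, tuple[float, float]],
                      spec: SimulationSpec,
                      n_replicates: int = 3,
                      noise_cv: float = 0.10,
                      duration_h: float = 6.0) -> pd.DataFrame:
    """Plate-reader table for effector +/- reporter assays.

    ``effects`` maps construct -> (baseline specific output, true fold).
    Backscatter follows logistic growth sampled on a 15-min grid;
    fluorescence is baseline * condition effect * backscatter under
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv``. The minus-effector condition carries the planted fold
    (the TF counter-silences when bound, i.e. without effector).
    """
    rng = _child_rngs(spec.seed, 4)[3]
    t = np.arange(0, duration_h + 1e-9, 0.25)
    backscatter_curve = 5.0 + 45.0 / (1 + np.exp(-1.5 * (t - 3.0)))
    sigma = np.sqrt(np.log(1 + noise_cv ** 2))
    rows = []
    for construct in constructs:
        baseline, fold = effects[construct]
        for condition, level in (("minus_effector", baseline * fold),
                                 ("plus_effector", baseline)):
            for rep in range(1, n_replicates + 1):
                noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(t))
                fluo = level * backscatter_curve * noise
                for ti, bs, fl in zip(t, backscatter_curve, fluo):
                    rows.append((construct, construct, condition, rep,
                                 float(ti), float(bs), float(fl)))
    return pd.DataFrame(rows, columns=["strain", "construct", "condition",
                                       "replicate", "time_h", "backscatter",
                                       "fluorescence"])


def simulate_dataset(spec: SimulationSpec):
    """Genome, truth, coverage and TSS in one call."""
    genome, truth = simulate_genome(spec)
    coverage = simulate_coverage(truth, spec)
    tss = simulate_tss(truth, spec)
    return genome, truth, coverage, tss


def write_dataset(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit genome.fa, coverage.bedgraph, peaks.bed, genes.gff3, tss.tsv
    and truth.json; every file validates against the genome_io parsers."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, coverage, tss = simulate_dataset(spec)
    paths = {
        "genome": outdir / "genome.fa",
        "coverage": outdir / "coverage.bedgraph",
        "peaks": outdir / "peaks.bed",
        "genes": outdir / "genes.gff3",
        "tss": outdir / "tss.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta([genome], paths["genome"])
    write_bedgraph(coverage, paths["coverage"])
    write_bed([GenomicInterval(p.interval.seq_id, p.interval.start,
                               p.interval.end, ".", p.promoter_id)
               for p in truth.peaks], paths["peaks"])
    write_gff3_genes(truth.genes, paths["genes"])
    write_tss_table(tss, paths["tss"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "islands": [[iv.start, iv.end] for iv in truth.islands],
            "gc_minima": truth.gc_minima,
            "motif_positions": truth.motif_positions,
            "bound": truth.bound,
            "peaks": [[p.interval.start, p.interval.end, p.max_position,
                       p.promoter_id] for p in truth.peaks],
            "genes": [[g.start, g.end, g.strand, g.gene_id]
                      for g in truth.genes],
        }, fh, indent=1)
    return paths
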
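# xsilence

Sequence analysis and synthetic promoter design for **xenogeneic
silencing** by Lsr2-like nucleoid-associated proteins.

Bacteria silence horizontally acquired, AT-rich DNA with xenogeneic
silencer (XS) proteins such as H-NS, MvaT and Lsr2. In the actinobacterium
*Corynebacterium glutamicum* the Lsr2-like silencer CgpS blankets prophage
promoters; a transcription factor that binds inside a silenced promoter can
locally displace the silencer and switch the promoter on
(*counter-silencing*). `xsilence` implements the computational toolkit for
studying this system:

* **AT-stretch scanning** — find every maximal AT-rich stretch in a genome,
  allowing a bounded number of G/C interruptions, and count its **A/T steps**
  (adjacent A→T / T→A dinucleotides, a flexibility proxy). Cross-tabulate
  stretches by length × interruptions or length × A/T steps, with the
  silencer-bound fraction per cell.
* **Occupancy profiling** — rolling-mean GC and coverage profiles
  (window 50 bp, step 10 bp), centered on the base of maximal silencer
  occupancy (the nucleation site, relative position 0) and oriented so the
  silenced gene's start codon lies to the right; overlay means, peak-width
  classes (class 1: 500–850 bp, class 2: > 850 bp), TSS assignment (within
  500 bp upstream of a start codon, ranked by enrichment score) and
  TSS-to-nucleation-site distance histograms.
* **Motif analysis** — scan both strands for a supplied 10-bp AT-rich
  binding motif (IUPAC consensus or PWM, log-odds scored against a GC-matched
  background) and quantify how motif presence changes the bound fraction of
  AT stretches.
* **Promoter design grammar** — build synthetic silenced/counter-silenced
  promoter variants: A-T/G-C swaps that preserve the GC profile exactly,
  GC-targeted flank randomization, operator-site insertion at positions
  relative to the nucleation site (position 0 = immediately 5′ of the
  maximal-occupancy base), 5′ truncations, and a replayable edit log.
* **Reporter statistics** — specific reporter outputs
  (fluorescence/backscatter at 5 h), effector ± fold changes, and a
  Welch-t-test three-way call: counter-silenced / repressed / unchanged at
  P < 0.05.
* **Synthetic data** — seeded generators for genomes with low-GC islands,
  coverage tracks whose Gaussian peaks sit on the island GC minima, TSS
  tables and plate-reader time series, so the entire pipeline is testable
  without downloads.

## Worked example

```python
import xsilence as x

spec = x.SimulationSpec(seed=42)              # 300-kb genome, 50 low-GC islands
genome, truth, coverage, tss = x.simulate_dataset(spec)

stretches = x.find_at_stretches(genome, max_interruptions=5, min_length=10)
stretches = x.mark_bound(stretches, truth.peaks)
matrix = x.stretch_bin_matrix(
    stretches, length_bins=[(10, 13), (14, 30), (31, 10_000)],
    second_axis="interruptions", step_bins=[(0, 1), (2, 3), (4, 5)])
counts, frac = matrix.to_frames()
print(frac.round(3))
```

```
          0-1    2-3    4-5
10-13     0.0  0.105  0.109
14-30     0.0  0.180  0.179
31-10000  NaN    NaN  0.645
```

Rows bin stretch length (bp), columns bin G/C interruptions; each cell is
the fraction of stretches overlapping a silencer occupancy peak. The bound
fraction rises with stretch length (0.11 → 0.18 → 0.65), the silencer's
hallmark preference for long consecutive AT stretches; `NaN` marks empty
cells.

```python
peak = truth.peaks[0]
print(x.locate_max_smoothed(coverage, peak.interval), peak.max_position)
# 5460 5461  — occupancy maximum recovered 1 bp from the planted GC minimum

call = x.classify_response([9.8, 11.1, 10.4], [2.1, 1.9, 2.2])
print(f"fold={call.fold_change:.2f} p={call.p_value:.2g} call={call.call}")
# fold=5.05 p=0.0013 call=counter_silenced
```

The same steps are available from the shell:

```bash
xsl simulate --seed 42 --out sim/
xsl scan --fasta sim/genome.fa --peaks sim/peaks.bed \
    --out stretches.tsv --matrix matrix.tsv
xsl profile --fasta sim/genome.fa --coverage sim/coverage.bedgraph \
    --peaks sim/peaks.bed --genes sim/genes.gff3 --tss sim/tss.tsv --out prof/
```

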
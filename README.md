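# dsbquant

Absolute quantification of DNA double-strand breaks (DSBs) from
sequencing data, using restriction-enzyme spike-ins as an internal
standard.

Genome-wide DSB labeling methods (BLESS/i-BLESS, END-seq, Break-Seq,
BLISS, ...) map breaks at nucleotide resolution but only report
*relative* read densities: nothing ties read counts to the number of
breaks actually present in a cell. `dsbquant` implements the
spike-in-normalization strategy that closes this gap, for
bioinformaticians analyzing break-sequencing experiments in yeast,
human, or any organism with a reference genome.

## The model

Breaks are induced at the recognition sites of a restriction enzyme
(NotI, SrfI, AsiSI, BamHI, I-SceI, ...) before labeling.  The cutting
efficiency *f*<sub>cut</sub> — the fraction of molecules cleaved at a
site — is estimated from paired-end genomic-DNA fragments:

    f_cut = N_cut / (N_cut + 2 N_uncut) − f_bg

where *N*<sub>cut</sub> counts fragments ending inside a small vicinity
of the cut (a cleaved molecule contributes two), *N*<sub>uncut</sub>
counts fragments spanning it (an intact molecule contributes one), and
*f*<sub>bg</sub> is the same ratio in random windows, absorbing
sonication ends.  Alternatively, *f*<sub>cut</sub> = 1 − 2^(−ΔC_T) from
qPCR.  The spike-in break frequency per cell is then

    B_cut = f_cut · N_sites · p

(*p* = proportion of digested cells), and the labeled reads observed at
the sites calibrate the reads-per-break coefficient and the studied
breaks:

    α = R_cut / B_cut,   B_studied = R_studied / α

Because α and *R*<sub>studied</sub> scale together with sequencing
depth, the estimate is depth-invariant — unlike raw UMI totals, which
drop one-for-one with subsampling (the package's UMI-counting mode
demonstrates this directly).  Uncertainty combines a Poisson
finite-count term with the background SD, or is taken conservatively as
the spread of single-site quantifications.  One-ended breaks (broken
replication forks) are detected from Watson/Crick read imbalance with a
Bonferroni-corrected hypergeometric test and quantified as
|W − C| / α.

## Worked example

Simulate an experiment with known ground truth and quantify it:

```python
from dsbquant import ENZYMES, SpikeInQuantModel
from dsbquant.simulate import BreakLandscape, make_genome, simulate_dsb_reads, simulate_gdna

genome, placed = make_genome([200_000], embed_motifs=[(ENZYMES["NotI"], 10)], seed=1)
sites = placed["NotI"]
fragments, _ = simulate_gdna(genome, sites, f_cut=0.3, coverage=5000, seed=2)
landscape = BreakLandscape(uniform_background=10 / genome.total_length)
reads, truth = simulate_dsb_reads(genome, sites, 0.3, landscape, alpha_planted=500, seed=4)

result = SpikeInQuantModel(reads, fragments, genome, ENZYMES["NotI"], sites=sites, seed=5).fit()
print(result.summary())
```

```
Spike-in DSB quantification
====================================================
Spike-in enzyme                 NotI
Cut sites (N_sites)             10
Digested-cell proportion (p)    1
Vicinity half-width (bp)        3
----------------------------------------------------
Cutting efficiency f_cut        0.2879 +/- 0.0236
  sigma_Poisson                 0.002356
  sigma_background              0.02346
  background f_bg               0.01772
  sites in pool                 10
Spike-in breaks/cell (B_cut)    2.879
Reads at sites (R_cut)          1526
Reads per break (alpha)         530
Studied reads (R_studied)       4987
----------------------------------------------------
Studied DSBs per cell           9.41 +/- 0.792  (per_site SD)
====================================================
```

The planted truth was 10 DSBs per cell at 30% cutting efficiency; the
fit recovers 9.41 ± 0.79 DSBs per cell and f_cut = 0.288 ± 0.024.  The
alpha of 530 reads per break (500 planted) converts any read count —
genome-wide, per window, or per locus — into breaks per cell;
`result.window_track()` produces the corresponding bedGraph-ready
density track and `result.one_ended()` the strand-asymmetry analysis.

The same steps are available from the shell:

```sh
dsbquant simulate --out-dir sim --f-cut 0.3 --seed 1
dsbquant quantify --genome sim/genome.fa --reads sim/reads.bed \
    --fragments sim/fragments.bed --enzyme NotI --out-dir out
```

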
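# Methods

## Estimation model

`dsbquant` treats a break-sequencing experiment as a calibration
problem.  Spike-in breaks with a measurable per-cell frequency are
induced at restriction sites; the read count observed at those sites
determines how many labeled reads one break produces (α), and every
other read count is converted to breaks per cell by dividing by α.  The
chain is

1. classify paired-end gDNA fragments at each site as *cut* (an end
   inside the counting vicinity) or *uncut* (spanning it),
2. estimate the cutting efficiency
   f_cut = ΣN_cut / (ΣN_cut + 2 ΣN_uncut) − f_bg over sites passing
   filters (> `min_reads` fragments, positive corrected efficiency),
3. B_cut = f_cut · N_sites · p, α = R_cut / B_cut,
   B_studied = R_studied / α,

with R_studied the labeled reads remaining after removal of spike-in
reads, telomere-motif reads and masked intervals (rDNA etc.).

The factor 2 in step 2 reflects molecule accounting: a cleaved molecule
yields two sequenced fragments abutting the scission, an intact one a
single spanning fragment, so the ratio is an unbiased estimator of the
cleaved molecule fraction.  The background term f_bg — the same ratio
evaluated in randomly placed windows away from sites — absorbs
sonication ends that land in a vicinity by chance.  At very low
efficiencies the subtraction slightly over-corrects (the background
ratio is computed where no enzyme signal dilutes it); the residual bias
is about −8% of f_cut at f = 0.12 and shrinks rapidly with f.  This is
a property of the estimator itself, reproduced faithfully, and it stays
well inside the package's 15% recovery envelope.

Key assumptions: reads are proportional to break frequency with a
single genome-wide α (verified per experiment by the linearity
diagnostic, which flags Pearson r ≤ 0.5 between per-site reads and
per-site efficiencies); the digest and the labeled sample come from the
same population; counting vicinities capture all enzyme-derived signal
(in-vivo resection spreading beyond the vicinity is out of scope and
handled only by widening `vicinity_w`).

## Uncertainties

Two SD estimates are provided.  With ≥ 2 informative sites, B_studied
is recomputed from each site alone (α_i from R_cut,i and f_i · p) and
the sample SD across sites is reported; this is deliberately
conservative since it includes all site-to-site α variability.
Otherwise the efficiency SD is propagated through the quotient:
sd(B) = B · σ_total / f_cut, where σ_total² = σ_bg² + σ_Poisson², σ_bg
is the SD of per-window background ratios and σ_Poisson perturbs the
counts by one Poisson SD in opposite directions:

σ_P = ½ [ (N_c+√N_c)/((N_c+√N_c)+2(N_u−√N_u)) −
          (N_c−√N_c)/((N_c−√N_c)+2(N_u+√N_u)) ].

The formula requires N_cut, N_uncut ≥ 1 and errors out below that
rather than extrapolating.  The UMI-mode SD uses the analogous
perturbation of UMI and cell counts.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `vicinity_w` | 3 bp | half-width of the counting window around each cut; matches the empirically determined ±3 bp interval used for AsiSI in human cells, configurable per run |
| `min_reads` | 100 | fragments required for a site to enter the efficiency pool |
| `bg_windows` | 1500 | random windows for f_bg (mid-range of the 1000–2000 convention) |
| `p` | 1.0 | proportion of digested cells (e.g. 0.02 for a 2:98 in-vivo mix) |
| window/step | 500/50 bp | sliding-window density track |
| strand-test window | 500 nt | non-overlapping tiles for the Watson/Crick test |
| `p_threshold` | 1e−10 | applied to Bonferroni-corrected hypergeometric p (flag to apply pre-correction instead) |
| `k_sd` | 5 | Poisson band for between-sample comparison |
| `n_perm` | 1000 | permutations for annotation enrichment |
| UMI `half_window`/`merge_distance` | 100/200 bp | counting interval around sites; closer sites merge to avoid double-counting |

Background windows additionally exclude ± (vicinity + longest observed
fragment) around real sites so no enzyme-derived end can contaminate
f_bg; this margin is a package choice.

## One-ended breaks, enrichment, comparisons

The strand test draws each 500-nt window's (W + C) reads from the
genome-wide urn of all reads with Watson reads as successes, one-sided
in both polarities, Bonferroni-corrected over windows × 2.  Adjacent
significant windows of equal polarity merge before quantification so a
single broken fork split by a tile boundary is not double-counted; the
one-ended load is Σ|W − C| / α.  Fragile regions use the same
hypergeometric tail treatment-vs-control with Benjamini–Hochberg
correction at q < 0.05.  Annotation enrichment projects regions and
annotation into a concatenated "mappable" coordinate axis, computes
ratio = (region nt in annotation / region nt) / (annotation nt /
mappable nt), and re-places the regions uniformly and
length-preservingly in that axis for the permutation null; p =
(1 + #null ≥ observed)/(1 + n_perm), which floors at 1/(n_perm + 1).
Between-sample comparison rescales treated counts by α_control/α_treated
before the k_sd·√count Poisson band.

## What the synthetic data emulate

The generators plant explicit truth so every estimator is testable by
parameter recovery without external data:

- `make_genome` — random sequence with exactly the requested motif
  occurrences (accidental occurrences scrubbed, placements
  non-overlapping, verified by re-digestion).
- `simulate_gdna` — per site, `coverage` molecules spanning the cut;
  each is cleaved with probability f_cut into two fragments whose
  cut-adjacent ends carry ≤ 1 bp sequencer jitter, otherwise left as one
  spanning fragment placed uniformly over the cut so its sonication ends
  hit the vicinity at the same per-coverage rate as in uniform-coverage
  real data.  Sonication-only background fragments (default 0.05 per
  bp) are laid genome-wide, which is what makes random-window background
  estimation consistent with the contamination at sites.  Fragment
  lengths are Normal(400, 80) truncated at 100 bp, a typical
  post-sonication profile.
- `simulate_dsb_reads` — Poisson counts with mean α · frequency per
  source: spike-ins on both strands with 5′ ends at the cut ± 1 bp,
  two-ended breaks on both strands, one-ended breaks strictly on one
  strand, a uniform background class, and telomere-motif reads whose
  sequences match the whole-read C{0,3}AC{1,10} repeat rule.
- `simulate_umi_reads` — one (position, UMI) molecule per break plus
  Poisson-distributed PCR duplicates.

Each signal class draws from an independent seeded stream
(`SeedSequence(seed, stream)`), so adding one class never perturbs
another and all outputs are byte-reproducible.

Not emulated: sequencing errors, mappability structure, GC bias,
resection gradients around in-vivo cuts, replication-timing profiles.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to every
artifact of real libraries.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; SAM is converted on
  read; parsers reject out-of-range records instead of clamping.
- Cut-site assignment of reads uses the 5′ (break-proximal) end;
  equidistant ties go to the lower-coordinate site.
- Replication-background removal locates the mode of window values with
  a Freedman–Diaconis histogram (ties to the lowest bin) refined to the
  median of the modal bin, then clamps negatives to zero.  Track values
  are discrete multiples of 1/α, so the mode is resolvable only to
  max(bin width, 1/α).
- Negative efficiencies after background subtraction clamp to 0 (and
  such sites are excluded from pooling); negative ΔC_T clamps to 0 with
  a warning.
- Hypergeometric tails are evaluated once per distinct (count, draw)
  pair and broadcast back, which keeps genome-scale window tests fast;
  values are validated against exact enumeration in the test suite.
- qPCR efficiencies over several dilutions are averaged; a per-run
  `calibration_offset` accommodates empirical ΔC_T correction.

## Problem sizes used in validation

The recovery grid runs a 1 Mb genome with 20 sites at 10⁴ molecules per
site across f_cut ∈ {0.12, 0.30, 0.62} and 1–150 DSBs per cell; the
linearity diagnostic uses 300 molecules per site, the low-coverage
regime in which extreme efficiencies (2%, 95%) visibly destroy the
read-efficiency correlation while 12–62% retain it; strand-test
calibration uses 10⁴ balanced windows.  These sizes were chosen as the
smallest at which the tested properties are statistically unambiguous.

## Known limitations

- The α calibration is genome-wide; strong regional labeling biases
  would require a stratified α, which is not implemented.
- The low-f_cut estimator bias described above (~−8% at f = 0.12) is
  inherent to the background-subtraction form; efficiencies below ~4%
  should not be used for quantification.
- UMI handling is exact-match deduplication only; sequencing errors in
  UMIs would inflate unique counts.
- One-ended quantification attributes the whole |W − C| excess to
  broken forks; mixed two-/one-ended windows are not decomposed.
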
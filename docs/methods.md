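# Methods

`xover` analyses meiotic recombination from sparse haploid genotype calls of
single gametes (flow-sorted pollen nuclei, or double-haploid lines standing in
for gametes) from a biparental cross. This note records the models, the
defaults and why they were chosen, the numerical machinery, and the known
limits of what the synthetic tests demonstrate.

## The meiosis model

Crossovers on a bivalent (the four-chromatid bundle) are modelled as a
stationary gamma renewal process on the genetic scale: inter-event distances
are i.i.d. Gamma(shape ν, rate 2ν per Morgan), so the bundle intensity is 2
events/Morgan independently of ν. The shape ν is the interference parameter:
ν = 1 recovers a homogeneous Poisson process (no interference); ν > 1 makes
spacings more regular (positive interference); ν < 1 clusters events. The
first event is drawn from the equilibrium forward-recurrence distribution of
the gamma law, whose CDF has the closed form

    F_e(x) = 2x · S_ν(x) + F_{ν+1}(x)

(S_ν, F_ν the survival/CDF of Gamma(ν, 2ν); same rate for the ν+1 shape),
so event counts are stationary along the chromosome rather than biased near
the origin. A gamete carries one chromatid; each bundle event involves two of
the four chromatids, so events are thinned independently with probability
1/2 (no chromatid interference), leaving 1 crossover/Morgan on the gamete.
Consequently a chromosome's genetic length in Morgans equals the mean
crossover count per gamete, which is how the analysis anchors intensity when
refitting ν.

Genetic positions are projected to physical bp through a monotone
piecewise-linear map. Two map families are built in: `uniform`, and
`distal` (default), which places 45% of the genetic length in each distal
15% of the chromosome — the strongly telomere-biased landscape of large
cereal chromosomes, where the pericentromeric two-thirds of the genome
barely recombines.

Defaults and their basis:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 7, 558–767 Mbp | barley-like karyotype and size range |
| genetic length | 1.36 M/chromosome | ≈ 9.5 crossovers per gamete over 7 chromosomes |
| ν | 3.0 | pooled single-gamete estimates for barley are ≈ 3 |
| obligate crossover | off | 13–20% of observed chromatids carry zero detected events |
| markers | 1 per 100 kb, three 10-Mbp gaps/chromosome | GBS/POPSEQ-like density with monomorphic gaps |

## The observation model

Observation is modelled at the genotype-call level, not the read level. Each
marker yields a call with probability `detect_prob` (default 0.1, the
probability a site is covered at ~0.1× shotgun coverage); an observed call is
wrong with a probability that has two components:

* `error_rate` (default 5·10⁻⁴): independent per-call noise;
* error-prone regions (default 0.5% of each chromosome in 1-Mbp patches,
  40% error): systematic, position-anchored miscalls shared across samples,
  emulating mismapping and paralogy.

The split matters. Flip-rate curation (below) can only ever remove
position-anchored error; with purely independent noise it is vacuous, and
with purely systematic noise the independent-miscall artifacts that motivate
per-sample curation would never arise. Both failure modes exist in real
single-cell data, so both are simulated. Transmission bias is modelled by
whole-gamete rejection sampling: a gamete carrying the disfavoured allele at
a selection locus is rejected with the probability that makes the marginal
transmission equal the target, which automatically distorts linked loci with
decay governed by the local recombination fraction.

What the generator does **not** emulate: read-level artifacts (chimeric
PicoPLEX fragments, allele-specific amplification), gene conversion /
non-crossover tracts, marker ascertainment bias, and real marker spacing
heterogeneity beyond the fixed gaps. Passing tests therefore demonstrate
correctness of the analysis given genotype calls with these two error modes,
not robustness to every pathology of amplified single-cell libraries.

## Binned consensus genotypes

Calls are aggregated in 1-Mbp bins (0-based half-open; a 1-based marker at p
belongs to bin ⌊(p−1)/10⁶⌋). A bin is assigned the majority parent's code
(2 = parent 1 "Morex"-like, 0 = parent 2 "Barke"-like) when it has at least
`min_support` = 1 non-missing call and majority fraction ≥ `purity` = 0.8,
else missing. With ~1 call per bin at 0.1× sparsity, `min_support` 1 keeps
the data usable while `purity` censors multi-call conflicts — bins containing
a crossover or an error usually go missing rather than wrong. Bins missing
in more than half the samples are dropped before distortion scanning.

## Crossover calling and curation

Two curation passes precede event calling:

1. **Bin-level**: the singleton-flip motif (a bin differing from both
   agreeing nearest informative flanks, 0→2→0 / 2→0→2, missing bins
   bridged) is counted across samples; bins with flip rate > 0.1 are masked
   everywhere. Applied to a fixed point, since masking can bridge flanks and
   expose new motifs — the fixpoint makes the operation idempotent.
2. **Per-sample** (pipeline option `drop_singletons`, default on): remaining
   singleton flips are masked sample by sample. An isolated one-bin
   double-crossover is overwhelmingly a miscall: real double crossovers at
   this interference strength span many bins. The cost is that a true
   crossover pair whose inner segment was observed in exactly one bin is
   lost; such pairs are below the method's resolution regardless.

A crossover is then an adjacent pair of informative bins with different
codes; missing bins are skipped, never used as boundaries. The event
interval runs from the end of the last informative bin of the old parent to
the start of the first informative bin of the new parent; for directly
adjacent bins this collapses to the shared boundary. Event positions are
interval midpoints. Positional uncertainty is one bin: when the bin
containing the crossover is itself consensus-called to its majority side,
the reported interval shifts by < 1 Mbp, so recovery of true positions holds
at bin resolution (±1 bin), not at base-pair precision.

## Recombination landscape

Per chromosome, events (by midpoint) are counted in 5-Mbp windows sliding by
1 Mbp; cM = 100·count/N and cM/Mbp divides by the window span (the final
truncated window uses its actual span). With non-overlapping windows the
track sums exactly to the chromosome genetic length 100·total/N cM — an
identity the tests assert exactly.

## Interference estimation

Samples with ≥ 2 events on a chromosome contribute adjacent-pair midpoint
distances, pooled across chromosomes on length-normalised coordinates
(distance/L). ν is estimated on a grid (default 0.5–12 by 0.25) by
simulation: for each candidate, chromatids are simulated per chromosome at
the observed intensity (mean events per gamete over *all* samples — a
ν-free quantity because thinned renewal intensity is 1/Morgan for every ν),
conditioned on ≥ 2 events, projected through the data's genetic map when
known (uniform fallback otherwise), and compared with the observed distances
by the Cramér–von Mises two-sample statistic (KS optional); the estimate is
the grid argmin, ties toward smaller ν. Conditioning on the observed
intensity rather than a genetic length isolates interference (spacing shape)
from crossover rate.

Numerical choices: common random numbers across the grid — one fixed set of
uniforms per fit mapped through each candidate's inverse CDFs — make the
discrepancy profile smooth in ν and bit-reproducible given the seed. The
gamma gap quantile function and the closed-form equilibrium CDF are
tabulated on 4096-point grids and inverted by linear interpolation; the
interpolation error is far below the Monte-Carlo noise of a 200-chromatid
reference sample. With 200 simulated chromatids per grid point the estimator
recovers ν ∈ {1, 3, 5} within ±15% (median of 20 replicates) from
400-gamete data and within ±40% at the 40-gamete scale; single-fit scatter
at 40 gametes is large, which is why pooled estimates, not per-chromosome
ones, are reported.

The class-split fit repeats the estimation separately for distances < 100
Mbp and > 400 Mbp, censoring the *simulated* distances to the same physical
window — comparing a censored sample against uncensored simulations would be
biased. On a two-pathway population mixture the near-group estimate falls
below the far-group estimate; on homogeneous data the two censored fits are
individually noisy and no ordering is guaranteed.

## Segregation distortion

Allele frequencies are scanned in 10-Mbp windows sliding by 1 Mbp and tested
against 1:1 by a one-df χ² without continuity correction, uncorrected
P < 0.05 by default (Benjamini–Hochberg available). Two counting modes
exist; the default reduces each sample to one consensus call per window
before counting. The alternative "bin" mode pools raw bin calls across
samples and bins, directly testing the window's average allele frequency —
but adjacent bins of one gamete share parental origin, so pooled counts are
~10× overdispersed relative to the χ² reference and the nominal level is
meaningless. The sample mode holds its type-I error (significant fraction
within binomial noise of α on independent null windows), which is why it is
the default. Significant windows are merged into maximal same-direction
runs (SDRs) annotated with size, % of chromosome and minimum P; genome-wide
summaries count the union of significant base pairs, never double-counting
overlapping windows.

## Pipeline and reproducibility

`run_all` executes simulate (or load VCF) → read calls → bin → curate →
call → landscape → interference → distortion scan, writing TSV/BED/BedGraph
plus a manifest (config, input checksums) and a machine-readable summary.
All randomness descends from one seed; per-gamete streams are spawned by
counter, so results are independent of evaluation order and byte-identical
across reruns. `scripts/acceptance.py --seed N --out results/acceptance.json`
regenerates every headline quantity from scratch: the worked-example
population means (computed from the published totals 380/40 and 974/89), a
40-gamete pollen-like and an 89-sample DH-like run (three planted
transmission-biased loci, 0.90/0.85/0.15) with their event totals, ν fits,
class-split fits and SDR genome fractions, and ν recovery medians from
noiseless 400-gamete simulations. Problem sizes (10–20 replicates, 200
simulated chromatids per grid point) were chosen to keep a laptop-scale run
under a minute per stage while leaving Monte-Carlo error well inside the
tolerances quoted above.

## Known limitations

* Double crossovers tighter than ~1–2 bins are removed by curation or
  invisible by construction; detected distance distributions are truncated
  below ~2 Mbp.
* The χ² goodness-of-fit comparison of two event-class distributions
  conditions on the reference proportions; when the reference population is
  not much larger than the observed one its P-values are anticonservative
  (statistic inflated by ≈ 1 + n_obs/n_ref). `chi2_homogeneity` is the
  calibrated two-sample alternative.
* Uncorrected per-window P < 0.05 with ~4,500 sliding windows implies ~5%
  false-positive windows under the null; small SDRs at that scale are noise
  unless they replicate. The BH option exists for conservative scans.
* No imputation or HMM smoothing of genotypes; the method is consensus +
  curation by design, and sub-bin event positions are unidentifiable.
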
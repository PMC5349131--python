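# Methods

`occycle` analyzes protein/DNA-occupancy dynamics over the autonomous
respiratory oscillation of continuous budding-yeast cultures. This note
records the models, the numerical choices, and what the synthetic data can
and cannot establish about real experiments.

## Occupancy model and normalization

Each timepoint contributes a pair of two-channel tiling arrays:
protein-bound MNase-digested DNA (pDNA) and undigested genomic DNA (gDNA),
plus a small set of MNase-digested naked-DNA controls (mDNA). Per probe
*p* and array *t*,

    DNA occ(p, t) = log2 pDNA(p, t) − log2 gDNA(p, t) − bias(p)
    bias(p)       = mean_m log2 mDNA(p, m) − mean_n log2 gDNA(p, n)

`bias` captures the sequence preference of micrococcal nuclease and is
estimated once from the control arrays (three replicates by default, as in
the experimental design the generator emulates).

Arrays are first normalized by the least-variant-set (LVS) procedure:

1. **Selection.** Probes whose log2-intensity variance across arrays is
   below a threshold in *both* the pDNA and gDNA channels form the LVS.
   Variance is computed on log2 intensities (sample variance, ddof 1).
2. **LOESS.** For each array, the deviation of its log2 intensities from
   the across-array mean reference is smoothed against the reference level
   (locally weighted linear regression, span 0.3 by default, no
   robustness iterations so the smoother is linear in the data), fitted on
   LVS probes only, evaluated everywhere by interpolation, and subtracted.
   On large LVS sets the regression is fitted on an even-rank subsample
   (≤ 2000 points) and evaluated on a 200-point quantile grid; this
   changes results only at the level of the smoother's own estimation
   noise.
3. **Strand averaging.** Forward/reverse probes sharing (chrom, start,
   end) are averaged on the log2 scale; unpaired probes are kept with a
   warning.

Intensities ≤ 0 are treated as missing rather than clipped: fabricating a
log ratio from a floor value would bias low-signal probes.

### What LVS normalization identifies

Because every array is pulled toward the mean of the *selected* probes,
the procedure removes, along with technical array effects, the LVS set's
own mean temporal signal. If the selected probes are genuinely static this
term is zero; if the variance threshold cannot separate static from
dynamic probes (for instance when injected array-level distortions exceed
the biological variance, forcing a high threshold), recovered occupancy
differs from truth by a per-timepoint constant equal to the genome-mean
dynamic over the selected set. Likewise the absolute channel level is not
identifiable from ratios: occupancy is a relative quantity, and rescaling
one timepoint's channels by a common factor survives only as a single
global offset of order log2(c)/n_arrays. Accuracy statements in the test
suite are therefore made at the level of gene-averaged occupancy profiles,
where the identifiable spatial/temporal structure lives; the per-timepoint
constant is reported, not hidden.

## Phase-angle alignment

The residual dissolved-oxygen (DO) trace (0.1 Hz) is smoothed with a
centered 100 s running mean (a "0.01 Hz window" read as 1/0.01 Hz = 100 s,
i.e. 10 samples; edges use shrinking windows), differentiated with central
differences, and scanned for per-cycle extrema of the first derivative.
The derivative minimum (steepest DO drop) marks the oxidative-phase onset,
0°; the maximum marks the reductive onset, 94° by default (configurable).
Sample times map piecewise-linearly between consecutive anchors, which
absorbs the unequal durations of the oxidative and reductive phases.

Numerical details: the expected period for extremum detection comes from
the dominant DFT bin of the derivative; candidate extrema closer than half
that period are suppressed; flat-top extrema report their first sample
(earliest wins); a trace whose dominant spectral band carries < 10 % of
the non-DC power (flat or noise-dominated) raises an error rather than
fabricating anchors. Samples before the first or after the last anchor are
flagged and excluded from cycle averaging, not extrapolated.

## Average-cycle profiles

Observations pooled across cycles are smoothed against phase with a cubic
regression spline and resampled at 24 points (every 15°). The spline's
flexibility follows the samples-per-cycle rule: df = round(period /
sampling interval), e.g. 11 for a 67 min cycle sampled every 6 min,
realized as uniform interior knots every 360°/df. Approximate periodicity
comes from replicating the data at ±360° before fitting; the fit is linear
in the data, so profile arithmetic (sums, differences) commutes with
fitting. Degenerate phase coverage (fewer distinct phases than knots, as
with sampling exactly commensurate with the period) is rejected with an
explanatory error.

Rates of change are computed as consecutive differences in time order,
assigned the circular midpoint of the two sample phases, rescaled to units
of change per 15° of phase (multiplying by 15/mean inter-sample phase
step), and cycle-fitted like any other variable. Cluster expression series
are summed per cluster and per supercluster (anabolic: A, AB, B, B.C,
B.D, ab.n; catabolic: C, D, cd.n, cd.ab). ΔDNA occ profiles subtract each
series' own mean over the 24-point grid and report the removed means
separately.

## TSS- and dyad-relative mapping

Probes are indexed by signed distance from each gene's TSS (upstream
negative, strand-aware, ±1000 bp window) or from each nucleosome dyad
(±500 bp). Dyads are assigned to the nearest TSS within 1 kb upstream or
inside the transcript (ties to the + strand gene), then ordered along the
transcription direction: dyads at relative position ≥ −73 bp (half of the
~147 bp wrapped in a nucleosome) are genic, the first being +1 — this
covers both a TSS-covering dyad and a first dyad just downstream; the last
genic dyad of a gene with ≥ 2 is "terminal"; +2 through the penultimate
are gene-body (GB); the nearest strictly-upstream dyad is −1. The
NDR-flanking set {−1, +1, terminal} forms the "TSS" analysis class.

Profile medians are taken over genes, not probes: probes sharing a
position bin (default: the probe spacing) within one gene are averaged
first. Medians are robust to outlier genes but are a biased estimator at
bins where the cross-gene occupancy distribution is bimodal (e.g.
far-upstream bins overlapping neighboring genes); accuracy measurements in
the acceptance machinery use cross-gene means for that reason, while the
display pipeline keeps medians.

## Spectral statistics

The major period of a uniformly sampled series is the non-DC DFT bin with
maximal power after mean removal; no zero-padding or interpolation is
applied, so periods are quantized to the bin grid (33 samples at 6 min
report a 67 min oscillation as the 66 min bin). Amplitude is 2|X_k|/n;
SNR is the major-bin power over the median of the other non-DC bins.
Significance uses a permutation null that randomly shuffles the time
points (1000 permutations by default, seed-controlled), with the
statistic being the maximal non-DC power so the bin-selection step is
inside the null. A cyclic time shift is *not* a usable null here: it
leaves every |X_k|, and hence any spectrum-based statistic, exactly
invariant.

The band-pass filter zeroes DFT bins with |f| < f_osc or |f| > 4 f_osc
(boundaries pass), reconstructs by inverse transform, and is idempotent
and real-valued by construction; it is used for the 10 Hz NAD(P)H trace.

## Energetics

Relative remodeler activity under competitive product inhibition by ADP:

    v/Vmax = [ATP] / (Km (1 + [ADP]/Ki) + [ATP])

with in-vitro ISWI constants Km = 0.15 mM and Ki = 0.1 mM as defaults.
Over a cycle spanning ATP 21–51 mM and ATP:ADP 1.2–8 this yields activity
swinging between ~0.44 and ~0.84 — large regulatory leverage from the
energy state alone. The adenylate energy charge is Atkinson's
(ATP + ADP/2)/(ATP + ADP + AMP). Correlations between 24-point cycle
profiles use Pearson r with a two-sided cyclic-shift null over the 24 grid
offsets: cycle profiles are strongly autocorrelated, so i.i.d.-based
p-values would be anticonservative; the smallest attainable p is 1/24.

## Synthetic data: what it emulates, and what it does not

The generator lays out genes on one synthetic chromosome with paired
forward/reverse probes every 32 bp (a 360K-array-like density), a +1 dyad
~75 bp downstream of each TSS, further dyads every 165 bp to the gene end,
a −1 dyad upstream of the NDR, and a Gaussian NDR depletion centered at
−75 bp. Temporal dynamics are sums of von Mises bumps at class-specific
phases (gene body 60°/225°; TSS 75°/225°/330°; NDR depletion events at
45°/240° — NDR amplitudes are stored nonnegative and applied with a
negative sign since those events are depletions). Intensities are
lognormal: all noise is multiplicative, because intensities are positive
and analyzed in log2. Optional per-array distortions (offsets and
intensity-dependent slopes) exercise the normalization; they are drawn
centered within each channel because a channel-wide offset is
unidentifiable from two-channel ratios and would only re-express the
relative nature of occupancy.

The DO trace is a logistic-transition square-ish wave with derivative
extrema exactly at the phase-0 and phase-94° onsets and an oxidative
fraction of 94/360 of the 67 min period. Metabolite series are rescaled
onto their configured ranges after any noise (ATP 21–51 mM, ATP:ADP
1.2–8, energy charge 0.65–0.9; ratio and energy charge co-vary so AMP
stays nonnegative for every seed). Transcripts peak per cluster (A 30°,
AB 45°, B 60°, C 255°, D 285°) with a shared transient at 225°. The
NAD(P)H trace carries the respiratory fundamental plus 2nd–4th harmonics,
a sub-fundamental drift, and noise spectrally confined above 4× the
fundamental, with frequencies snapped to DFT bins of the window.

Deliberately not modeled: nucleotide sequence (no FASTA; MNase bias is a
per-probe draw, not a GC model), ChIP-qPCR chemistry, gene-to-gene phase
heterogeneity (every gene of a class shares the class phases, so
probe-level and gene-median amplitudes coincide — real data has larger
probe-level variance and genuinely quiet least-variant probes), and
chromosome structure beyond one linear contig. Passing tests on this
generator therefore demonstrate correctness of the estimators under the
stated statistical structure, not robustness to every failure mode of
real arrays.

## Problem sizes and test conditions

The default synthetic experiment is 60 genes (~130 kb, ~8000 probes
counting both strands), 33 arrays at 6 min over three 67 min cycles, and
noise 0.2 log2 — small enough that the full pipeline runs in about a
second while preserving the study's sampling structure. The normalization-
efficacy fixture uses 150 genes, channel noise 0.1, per-array offsets of
sd 0.5 log2 and an LVS threshold of 0.8 (the threshold must exceed the
injected distortion variance to select anything). Spectral period
recovery uses a fixture whose dominant bin is unambiguous: single-peak
near-sinusoidal dynamics (von Mises concentration 2) with 2-fold
amplitude and a 66 min period so 33 samples hold an integer number of
cycles; under the default multi-peak dynamics the dominant bin of a
gene-body probe is legitimately the second harmonic, and neighboring
harmonics lie within noise of each other, so "the" period bin is not
well-defined there. Calibration checks use 500 null replicates with 1000
permutations each.

## Known limitations

* LVS normalization removes the selected probes' mean dynamics (see
  above); genome-wide coherent occupancy changes are attenuated exactly
  when the least-variant set is contaminated by dynamic probes.
* Period estimates are bin-quantized; no refinement between bins is
  attempted.
* The dyad classifier trusts the supplied dyad positions; it does not
  call nucleosomes from the occupancy signal (array resolution makes
  single-nucleosome calls unreliable).
* The cyclic-shift correlation null has granularity 1/24; p-values below
  0.042 are not attainable on the 15° grid.
* Mixed inhibition of remodelers (ADP and ATP acting noncompetitively) is
  not modeled; the competitive form likely understates the effect of low
  energy states.
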
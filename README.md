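# occycle

Time-resolved nucleosome/DNA-occupancy dynamics over the yeast metabolic
(respiratory) oscillation.

Continuous budding-yeast cultures spontaneously alternate between an
oxidative and a reductive phase, visible as an oscillation in residual
dissolved oxygen (DO). `occycle` is a pipeline for asking how chromatin
occupancy, transcription, and cellular energetics move through that cycle
together. It is aimed at groups analyzing dual-channel MNase tiling-array
(or similar ratio-based) time series alongside physiological traces.

The pipeline:

1. **Normalization** — least-variant-set (LVS) selection of temporally
   stable probes, per-array LOESS correction against the across-array
   reference, forward/reverse strand-pair averaging, and MNase-bias
   subtraction, giving per-probe occupancy
   `DNA occ = log2(pDNA) − log2(gDNA) − MNase bias`.
2. **Phase alignment** — the DO trace is smoothed (100 s running mean) and
   differentiated; derivative minima/maxima anchor 0°/94° (oxidative and
   reductive onsets), and every dataset is mapped onto the common
   phase-angle axis piecewise-linearly.
3. **Cycle statistics** — cubic-spline average cycles resampled every 15°
   (df = samples per cycle), rates of change per 15°, cluster-summed
   transcript series ∑[mRNA] and ∑[mRNA]′.
4. **Genome maps** — TSS-aligned and nucleosome-dyad-aligned median
   occupancy profiles; dyads classified by ordinal (−1, +1, gene body,
   terminal) along the transcription direction.
5. **Spectral statistics** — per-probe Fourier major period, amplitude,
   SNR and permutation p-values; DFT band-pass filtering (f_osc to
   4·f_osc) for the 10 Hz NAD(P)H trace.
6. **Energetics** — adenylate energy charge `(ATP + ADP/2)/(ATP + ADP +
   AMP)`, ATP:ADP, and inferred remodeler (ISWI) activity under
   competitive product inhibition, `v/Vmax = ATP/(Km(1 + ADP/Ki) + ATP)`
   with Km = 0.15 mM, Ki = 0.1 mM.

A first-class synthetic-data generator (`occycle.simulate`) produces probe
tables, DO/metabolite/transcript/NAD(P)H series with the statistical
structure the analysis assumes, under full seed control; all tests are
built on it. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

Run a complete simulate-then-analyze experiment from the shell:

```sh
occycle run-all --seed 1 --outdir run1
# run complete; 21 outputs in run1
```

or drive the library directly:

```python
import numpy as np
import occycle as oc

cfg = oc.SyntheticConfig(seed=1)          # 60 genes, 33 arrays, 67 min cycle
genome = oc.generate_genome(cfg)
truth = oc.generate_occupancy_series(cfg, genome)

# normalize to occupancy
lvs = oc.select_least_variant(truth.pdna, truth.gdna, threshold=0.1)
pdna = oc.average_strand_pairs(oc.loess_normalize(truth.pdna, lvs))
gdna = oc.average_strand_pairs(oc.loess_normalize(truth.gdna, lvs))
mdna = oc.average_strand_pairs(oc.loess_normalize(truth.mdna, lvs))
bias = oc.compute_mnase_bias(mdna, gdna)
occ = oc.compute_occupancy(pdna, gdna, bias)

# phase-angle axis from the dissolved-oxygen trace
do = oc.generate_do_trace(cfg)
pm = oc.phase_from_do(do["time_s"].to_numpy(), do["value"].to_numpy(),
                      cfg.sample_times_min * 60.0)

# gene-body / TSS nucleosome dynamics on the 15-degree grid
cls = oc.classify_dyads(truth.dyads[["chrom", "pos"]], truth.annotations)
_, central = oc.dyad_aligned_profile(occ, cls)
prof = oc.fit_cycle_frame(central, pm.phase_deg, df=11)
grid = prof.columns.to_numpy(float)

def peak_phases(v, n):
    """Top-n circular local maxima of a 24-point cycle profile."""
    v = np.asarray(v)
    loc = np.where((v >= np.roll(v, 1)) & (v >= np.roll(v, -1)))[0]
    return sorted(grid[loc[np.argsort(-v[loc])][:n]])

print("GB peak phases:", peak_phases(prof.loc["GB"], 2))
print("TSS peak phases:", peak_phases(prof.loc["TSS"], 3))

# energetics
met = oc.generate_metabolites(cfg)
act = oc.remodeling_activity(met["atp_mm"], met["adp_mm"], oc.KineticParams())
print(f"ISWI activity over the cycle: {act.min():.3f}-{act.max():.3f}")
```

prints

```
GB peak phases: [np.float64(60.0), np.float64(225.0)]
TSS peak phases: [np.float64(90.0), np.float64(225.0), np.float64(330.0)]
ISWI activity over the cycle: 0.443-0.840
```

Gene-body nucleosomes show their two occupancy events per cycle (60° and
225°), TSS-class nucleosomes their three (near 75°, 225°, 330°), and the
inferred remodeler activity swings almost two-fold between the low-energy
(ATP 21 mM, ATP:ADP 1.2) and high-energy (ATP 51 mM, ATP:ADP 8) corners of
the cycle — energy state alone is enough to modulate remodeling strongly.

The CLI also exposes each stage separately (`occycle simulate`,
`normalize`, `phase`, `cycle`, `spectra`, `energetics`); see
`occycle --help`.

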
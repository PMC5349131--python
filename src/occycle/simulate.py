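"""Synthetic data generator for the respiratory-oscillation occupancy pipeline.

Emulates the statistical structure of a continuous-culture experiment in
which budding yeast undergoes an autonomous respiratory oscillation:

* a tiled two-channel array experiment (protein-bound pDNA, genomic gDNA,
  and an MNase-digested naked-DNA control mDNA) over an oscillating
  nucleosome-occupancy landscape with a nucleosome-depleted region (NDR)
  centered ~75 bp upstream of each TSS;
* a residual dissolved-oxygen (DO) trace whose first-derivative extrema
  mark the starts of the oxidative (0 deg) and reductive (94 deg) phases;
* adenine-nucleotide concentrations (ATP 21-51 mM, ATP:ADP 1.2-8, energy
  charge 0.65-0.9) peaking in the oxidative phase;
* cluster-phased transcript abundances with a shared transient near
  225 deg; and
* a 10 Hz NAD(P)H fluorescence trace carrying the respiratory fundamental
  plus harmonics, out-of-band drift and high-frequency noise.

Every generator is deterministic under ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: footprint half-width of nucleosomal DNA (~147 bp wrapped)
NUC_HALF_BP = 73

_ANABOLIC = ("A", "AB", "B")
_CATABOLIC = ("C", "D")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    Defaults reproduce the long-period oscillation conditions: 67 min
    period, 6 min sampling over 3 cycles (33 arrays), oxidative fraction
    94/360 of the cycle, gene-body occupancy peaks at 60/225 deg, TSS
    peaks at 75/225/330 deg, NDR depletion events at 45/240 deg.
    """

    n_genes: int = 60
    gene_length_mean_bp: float = 1500.0
    gene_length_sd_bp: float = 300.0
    probe_spacing_bp: int = 32
    n_cycles: int = 3
    period_min: float = 67.0
    sampling_min: float = 6.0
    oxidative_deg: float = 94.0
    class_phases: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "GB": (60.0, 225.0),
            "TSS": (75.0, 225.0, 330.0),
            "NDR": (45.0, 240.0),
        }
    )
    class_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"GB": 0.3, "TSS": 0.4, "NDR": 0.3}
    )
    peak_concentration: float = 8.0  # von Mises kappa of occupancy events
    noise_sd: float = 0.2            # log2-scale sd of multiplicative noise
    bias_amplitude: float = 0.5      # MNase bias drawn U(-b, +b) in log2
    scale_factor_sd: float = 0.0     # per-array log2 offset (off by default)
    distortion_slope_sd: float = 0.0  # per-array intensity-dependent slope
    nucleosome_spacing_bp: int = 165
    ndr_center_bp: int = -75
    ndr_depth: float = 1.2
    nuc_height: float = 0.4
    n_mdna_arrays: int = 3
    transition_tau_min: float = 1.5  # DO phase-transition time constant
    do_amplitude: float = 1.0
    do_noise_sd: float = 0.0
    atp_range_mm: tuple[float, float] = (21.0, 51.0)
    atp_adp_ratio_range: tuple[float, float] = (1.2, 8.0)
    energy_charge_range: tuple[float, float] = (0.65, 0.9)
    metabolite_amplitude: float = 1.0
    metabolite_noise_sd: float = 0.0
    metabolite_peak_deg: float = 47.0
    cluster_peak_deg: Mapping[str, float] = field(
        default_factory=lambda: {
            "A": 30.0, "AB": 45.0, "B": 60.0, "C": 255.0, "D": 285.0
        }
    )
    transcript_amplitude: float = 1.0   # log2 amplitude of cluster peaks
    shared_bump_amplitude: float = 0.3  # log2 amplitude of the 225 deg event
    nadph_harmonic_amps: Sequence[float] = (1.0, 0.4, 0.2, 0.1)
    nadph_drift_amplitude: float = 0.5
    nadph_noise_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.period_min <= 0:
            raise ValueError("period_min must be > 0")
        if not (0 < self.oxidative_deg < 360):
            raise ValueError("oxidative_deg must lie in (0, 360)")
        if self.probe_spacing_bp < 1:
            raise ValueError("probe_spacing_bp must be >= 1")
        if any(a < 0 for a in self.class_amplitudes.values()):
            raise ValueError("class amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.n_cycles * self.period_min / self.sampling_min))

    @property
    def sample_times_min(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_min

    @property
    def sample_phases_deg(self) -> np.ndarray:
        """True respiratory phase of each array sample (uniform angular rate)."""
        return (self.sample_times_min % self.period_min) / self.period_min * 360.0

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticGenome:
    annotations: pd.DataFrame   # gene_id, chrom, tss, transcript_end, strand, cluster
    dyads: pd.DataFrame         # chrom, pos, gene_id, ordinal, strand
    probes: pd.DataFrame        # probe_id, chrom, start, end, strand
    genome_length: int


@dataclass
class SyntheticTruth:
    true_occupancy: pd.DataFrame  # one row per probe position, time columns
    true_bias: pd.Series          # per probe position, log2
    true_phase: np.ndarray        # degrees per sample, in [0, 360)
    annotations: pd.DataFrame
    dyads: pd.DataFrame
    cluster_labels: pd.Series
    pdna: pd.DataFrame
    gdna: pd.DataFrame
    mdna: pd.DataFrame


def _vm_bump(phase_deg: np.ndarray, peaks_deg: Sequence[float], kappa: float) -> np.ndarray:
    """Sum of unit-height von Mises bumps at the given peak phases."""
    phi = np.deg2rad(np.asarray(phase_deg, dtype=float))
    out = np.zeros_like(phi)
    for mu in peaks_deg:
        out += np.exp(kappa * (np.cos(phi - np.deg2rad(mu)) - 1.0))
    return out


def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Lay out genes on a single synthetic chromosome with phased nucleosome
    arrays and paired forward/reverse tiling probes.

    Each gene receives a +1 dyad ~75 bp downstream of the TSS, further dyads
    at ``nucleosome_spacing_bp`` steps to the transcript end, and a -1 dyad
    upstream of the NDR. A gene shorter than one nucleosome keeps only its
    +1 dyad (degenerate but valid).
    """
    rng = np.random.default_rng(config.seed)
    chrom = "synI"
    spacing = config.nucleosome_spacing_bp
    first_dyad = abs(config.ndr_center_bp)  # +1 dyad sits at TSS + 75 by default

    genes, dyads = [], []
    cursor = 1
    clusters = ["A", "AB", "B", "C", "D"]
    for i in range(config.n_genes):
        length = int(
            max(150, rng.normal(config.gene_length_mean_bp, config.gene_length_sd_bp))
        )
        strand = "+" if rng.random() < 0.5 else "-"
        pad_up, pad_down = 400, 200
        pad_left = pad_up if strand == "+" else pad_down
        pad_right = pad_down if strand == "+" else pad_up
        gstart = cursor + pad_left
        gend = gstart + length - 1
        tss = gstart if strand == "+" else gend
        gid = f"g{i:04d}"
        genes.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "tss": tss,
                "transcript_end": gend if strand == "+" else gstart,
                "strand": strand,
                "cluster": clusters[i % len(clusters)],
            }
        )
        sign = 1 if strand == "+" else -1
        # genic dyad ladder from +1 to the transcript end
        pos = tss + sign * first_dyad
        ordinal = 1
        while (pos <= gend) if strand == "+" else (pos >= gstart):
            dyads.append(
                {"chrom": chrom, "pos": int(pos), "gene_id": gid,
                 "ordinal": ordinal, "strand": strand}
            )
            pos += sign * spacing
            ordinal += 1
        # -1 dyad upstream of the NDR
        up_pos = tss - sign * (abs(config.ndr_center_bp) + 2 * NUC_HALF_BP + 4)
        dyads.append(
            {"chrom": chrom, "pos": int(up_pos), "gene_id": gid,
             "ordinal": -1, "strand": strand}
        )
        cursor = gend + pad_right

    genome_length = cursor + 400
    positions = np.arange(1, genome_length - config.probe_spacing_bp + 1,
                          config.probe_spacing_bp, dtype=int)
    n = len(positions)
    base = pd.DataFrame(
        {
            "probe_id": [f"P{i:06d}" for i in range(n)],
            "chrom": chrom,
            "start": positions,
            "end": positions + config.probe_spacing_bp - 1,
        }
    )
    fwd = base.assign(strand="+")
    rev = base.assign(strand="-")
    probes = (
        pd.concat([fwd, rev], ignore_index=True)
        .sort_values(["start", "strand"], kind="stable")
        .reset_index(drop=True)
    )
    return SyntheticGenome(
        annotations=pd.DataFrame(genes),
        dyads=pd.DataFrame(dyads),
        probes=probes,
        genome_length=genome_length,
    )


def _true_occupancy_landscape(config: SyntheticConfig,
                              genome: SyntheticGenome) -> pd.DataFrame:
    """Per unique probe position: spatial baseline plus per-class temporal
    weights. Returns a frame indexed like the unique probe positions with
    columns baseline and one weight column per occupancy class."""
    uniq = genome.probes.drop_duplicates("probe_id").reset_index(drop=True)
    mid = (uniq["start"].to_numpy() + uniq["end"].to_numpy()) / 2.0

    baseline = np.zeros(len(uniq))
    weights = {cls: np.zeros(len(uniq)) for cls in config.class_phases}

    dy = genome.dyads
    # nucleosomal contributions: cosine-tapered footprint around each dyad
    for _, d in dy.iterrows():
        delta = np.abs(mid - d["pos"])
        in_fp = delta <= NUC_HALF_BP
        if not in_fp.any():
            continue
        shape = np.cos(0.5 * np.pi * delta[in_fp] / NUC_HALF_BP)
        baseline[in_fp] += config.nuc_height * shape
        n_genic = int((dy["gene_id"] == d["gene_id"]).sum()) - 1  # minus the -1 dyad
        if d["ordinal"] in (-1, 1) or (n_genic >= 2 and d["ordinal"] == n_genic):
            cls = "TSS"
        else:
            cls = "GB"
        if cls in weights:
            weights[cls][in_fp] += shape

    # NDR: Gaussian depletion centered at ndr_center_bp relative to TSS
    sigma = 45.0
    for _, g in genome.annotations.iterrows():
        sign = 1 if g["strand"] == "+" else -1
        center = g["tss"] + sign * config.ndr_center_bp
        delta = mid - center
        near = np.abs(delta) <= 3 * sigma
        if not near.any():
            continue
        shape = np.exp(-(delta[near] ** 2) / (2 * sigma**2))
        baseline[near] -= config.ndr_depth * shape
        if "NDR" in weights:
            weights["NDR"][near] += shape

    out = pd.DataFrame({"probe_id": uniq["probe_id"], "baseline": baseline})
    for cls, w in weights.items():
        out[f"w_{cls}"] = np.clip(w, 0.0, 1.0)
    return out


def generate_occupancy_series(
    config: SyntheticConfig, genome: SyntheticGenome
) -> SyntheticTruth:
    """Simulate pDNA/gDNA/mDNA probe intensity tables over the cycle.

    The generative model, all on log2 scale:

        gDNA[p, a] = base_p (+ scale_a + slope_a * (base_p - mean)) + noise
        mDNA[p, a] = base_p + bias_p + ...                          + noise
        pDNA[p, t] = base_p + bias_p + occ[p, t] + ...              + noise

    so that log2(pDNA) - log2(gDNA) - bias inverts to the true occupancy
    exactly at zero noise and zero scale factors. NDR-class events are
    depletions and enter with a negative sign.
    """
    if config.n_samples < 1:
        raise ValueError("configuration yields zero timepoints")
    rng = np.random.default_rng(config.seed + 1)
    land = _true_occupancy_landscape(config, genome)
    phases = config.sample_phases_deg
    n_pos = len(land)
    n_t = config.n_samples

    occ = np.tile(land["baseline"].to_numpy()[:, None], (1, n_t))
    for cls, peaks in config.class_phases.items():
        amp = config.class_amplitudes.get(cls, 0.0)
        if amp == 0 or f"w_{cls}" not in land.columns:
            continue
        bump = _vm_bump(phases, peaks, config.peak_concentration)  # (n_t,)
        signed = -amp if cls == "NDR" else amp
        occ = occ + signed * np.outer(land[f"w_{cls}"].to_numpy(), bump)

    bias = rng.uniform(-config.bias_amplitude, config.bias_amplitude, n_pos)
    base = rng.normal(10.0, 1.0, n_pos)

    probes = genome.probes
    pos_index = (
        land.reset_index().set_index("probe_id")["index"].loc[probes["probe_id"]].to_numpy()
    )

    def _channel(n_arrays: int, extra: np.ndarray, prefix: str) -> pd.DataFrame:
        # extra: (n_pos, n_arrays) log2 signal on top of base
        tab = probes[["probe_id", "chrom", "start", "end", "strand"]].copy()
        log2 = base[pos_index, None] + extra[pos_index, :]
        # Distortions are drawn centered within each channel: a channel-wide
        # offset is unidentifiable from two-channel log ratios (occupancy is
        # relative), so injected effects model array-to-array variation only.
        if config.scale_factor_sd > 0:
            offs = rng.normal(0.0, config.scale_factor_sd, n_arrays)
            log2 = log2 + (offs - offs.mean())[None, :]
        if config.distortion_slope_sd > 0:
            # intensity-dependent nonlinearity: bends each array's own clean
            # signal around the array mean (dye/hybridization style)
            slopes = rng.normal(0.0, config.distortion_slope_sd, n_arrays)
            slopes -= slopes.mean()
            clean = base[pos_index, None] + extra[pos_index, :]
            log2 = log2 + (clean - clean.mean(axis=0)) * slopes[None, :]
        if config.noise_sd > 0:
            log2 = log2 + rng.normal(0.0, config.noise_sd, log2.shape)
        for j in range(n_arrays):
            tab[f"{prefix}{j:02d}"] = np.exp2(log2[:, j])
        return tab

    zeros_t = np.zeros((n_pos, n_t))
    gdna = _channel(n_t, zeros_t, "t")
    mdna = _channel(config.n_mdna_arrays,
                    np.tile(bias[:, None], (1, config.n_mdna_arrays)), "m")
    pdna = _channel(n_t, bias[:, None] + occ, "t")

    true_occ = land[["probe_id"]].copy()
    for j in range(n_t):
        true_occ[f"t{j:02d}"] = occ[:, j]
    truth = SyntheticTruth(
        true_occupancy=true_occ,
        true_bias=pd.Series(bias, index=land["probe_id"], name="bias"),
        true_phase=phases,
        annotations=genome.annotations,
        dyads=genome.dyads,
        cluster_labels=genome.annotations.set_index("gene_id")["cluster"],
        pdna=pdna,
        gdna=gdna,
        mdna=mdna,
    )
    return truth


def generate_do_trace(config: SyntheticConfig, pad_cycles: float = 0.5
                      ) -> pd.DataFrame:
    """Residual dissolved-oxygen trace at 0.1 Hz.

    DO drops sharply at each oxidative-phase onset (first-derivative
    minimum, phase 0) and recovers at the reductive onset (first-derivative
    maximum, phase ``oxidative_deg``); transitions are logistic with time
    constant ``transition_tau_min`` so each cycle has exactly one derivative
    minimum and one maximum. The trace extends ``pad_cycles`` beyond the
    sampled window on both sides so edge cycles are anchored.
    """
    rng = np.random.default_rng(config.seed + 2)
    T = config.period_min
    dt_s = 10.0  # 0.1 Hz
    t0 = -pad_cycles * T
    t1 = (config.n_cycles + pad_cycles) * T
    t_min = np.arange(t0, t1, dt_s / 60.0)
    tau = config.transition_tau_min

    def sig(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))

    do = np.full_like(t_min, 1.0)
    frac = config.oxidative_deg / 360.0
    for c in range(-2, config.n_cycles + 3):
        fall = c * T
        rise = c * T + frac * T
        do -= config.do_amplitude * (sig((t_min - fall) / tau) - sig((t_min - rise) / tau))
    if config.do_noise_sd > 0:
        do = do + rng.normal(0.0, config.do_noise_sd, do.shape)
    return pd.DataFrame({"time_s": t_min * 60.0, "value": do})


def _rescaled_unit(config: SyntheticConfig, rng: np.random.Generator,
                   phases_deg: np.ndarray) -> np.ndarray:
    """Oscillation u in [0, 1] peaking at metabolite_peak_deg; amplitude 0
    collapses to the constant 0.5. Rescaling to [0, 1] happens after any
    noise, so configured metabolite ranges hold for every seed."""
    raw = np.cos(np.deg2rad(phases_deg - config.metabolite_peak_deg))
    if config.metabolite_noise_sd > 0:
        raw = raw + rng.normal(0.0, config.metabolite_noise_sd, raw.shape)
    ptp = raw.max() - raw.min()
    u = (raw - raw.min()) / ptp if ptp > 0 else np.full_like(raw, 0.5)
    return 0.5 + config.metabolite_amplitude * (u - 0.5)


def generate_metabolites(config: SyntheticConfig) -> pd.DataFrame:
    """ATP/ADP/AMP concentration series (mM) on the array sampling grid.

    ATP spans ``atp_range_mm`` peaking in the oxidative phase; ATP:ADP
    spans ``atp_adp_ratio_range`` in phase with ATP; AMP is set so the
    adenylate energy charge spans ``energy_charge_range``. Because ratio
    and energy charge co-vary, AMP stays nonnegative throughout.
    """
    rng = np.random.default_rng(config.seed + 3)
    t = config.sample_times_min
    u = _rescaled_unit(config, rng, config.sample_phases_deg)
    atp_lo, atp_hi = config.atp_range_mm
    r_lo, r_hi = config.atp_adp_ratio_range
    ec_lo, ec_hi = config.energy_charge_range
    atp = atp_lo + (atp_hi - atp_lo) * u
    ratio = r_lo + (r_hi - r_lo) * u
    ec = ec_lo + (ec_hi - ec_lo) * u
    adp = atp / ratio
    amp_ = np.maximum((atp + adp / 2.0) / ec - atp - adp, 0.0)
    return pd.DataFrame(
        {"time_min": t, "atp_mm": atp, "adp_mm": adp, "amp_mm": amp_}
    )


def generate_transcripts(
    config: SyntheticConfig, cluster_labels: pd.Series
) -> pd.DataFrame:
    """Gene x timepoint transcript abundances.

    Anabolic clusters (A, AB, B) peak in the oxidative phase and catabolic
    clusters (C, D) in the reductive phase, at ``cluster_peak_deg``; all
    genes share a transient bump near 225 deg. Noise is lognormal.
    """
    unknown = set(cluster_labels.unique()) - set(config.cluster_peak_deg)
    if unknown:
        raise ValueError(f"clusters without a configured peak phase: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed + 4)
    phases = config.sample_phases_deg
    shared = _vm_bump(phases, [225.0], config.peak_concentration)
    rows = {}
    base_log2 = rng.normal(8.0, 0.5, len(cluster_labels))
    for (gene, cl), b in zip(cluster_labels.items(), base_log2):
        bump = _vm_bump(phases, [config.cluster_peak_deg[cl]], config.peak_concentration)
        log2 = (
            b
            + config.transcript_amplitude * bump
            + config.shared_bump_amplitude * shared
        )
        if config.noise_sd > 0:
            log2 = log2 + rng.normal(0.0, config.noise_sd, log2.shape)
        rows[gene] = np.exp2(log2)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"t{j:02d}" for j in range(len(phases))])
    out.index.name = "gene_id"
    return out


def generate_nadph(config: SyntheticConfig) -> pd.DataFrame:
    """10 Hz NAD(P)H fluorescence: respiratory fundamental plus 2nd-4th
    harmonics (in-band), slow drift below the respiratory frequency, and
    broadband noise confined above 4x the fundamental.

    Frequencies are snapped to DFT bins of the generated window so the
    in-band/out-of-band split is exact for the matching band-pass filter.
    """
    rng = np.random.default_rng(config.seed + 5)
    fs = 10.0
    duration_s = config.n_cycles * config.period_min * 60.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    k_osc = max(1, int(round(duration_s / (config.period_min * 60.0))))  # = n_cycles
    f_osc = k_osc / duration_s
    x = np.zeros(n)
    for h, amp in enumerate(config.nadph_harmonic_amps, start=1):
        phi = rng.uniform(0, 2 * np.pi)
        x += amp * np.cos(2 * np.pi * h * f_osc * t + phi)
    if config.nadph_drift_amplitude > 0:
        k_drift = max(1, k_osc // 3)
        f_drift = k_drift / duration_s
        x += config.nadph_drift_amplitude * (
            1.0 + np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        )
    if config.nadph_noise_amplitude > 0:
        white = rng.normal(0.0, 1.0, n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        spec[freqs <= 4.0 * f_osc * (1 + 1e-12)] = 0.0
        hf = np.fft.irfft(spec, n=n)
        sd = hf.std()
        if sd > 0:
            x += config.nadph_noise_amplitude * hf / sd
    return pd.DataFrame({"time_s": t, "value": x})
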
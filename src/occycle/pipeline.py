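"""End-to-end orchestration: simulate or load inputs, normalize, phase,
profile, cycle-fit, Fourier, energetics; deterministic outputs plus a run
manifest with checksums."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arraynorm, cyclefit, energetics, genomemap, io, phasing, simulate, spectral

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single config for a full run; defaults are the study constants."""

    outdir: str = "occycle_run"
    simulate: bool = True
    seed: int = 0
    lvs_threshold: float = 0.1
    loess_span: float = 0.3
    reductive_anchor_deg: float = 94.0
    grid_step_deg: float = 15.0
    km_mm: float = 0.15
    ki_mm: float = 0.1
    tss_half_window_bp: int = 1000
    dyad_half_window_bp: int = 500
    synthetic: dict = field(default_factory=dict)
    # paths for real inputs (used when simulate is False)
    pdna: str | None = None
    gdna: str | None = None
    mdna: str | None = None
    annotations: str | None = None
    dyads: str | None = None
    do_trace: str | None = None
    metabolites: str | None = None
    transcripts: str | None = None
    sample_times_min: list[float] | None = None
    period_min: float = 67.0
    sampling_min: float = 6.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to
    ``outdir/manifest.json``). Any stage failure raises :class:`StageError`
    naming the stage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "outputs": {},
    }

    def _write(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        manifest["outputs"][name] = _sha256(path)
        return path

    # ---- inputs ---------------------------------------------------- #
    stage = "inputs"
    try:
        if config.simulate:
            scfg = simulate.SyntheticConfig(
                **{"seed": config.seed, **config.synthetic}
            )
            genome = simulate.generate_genome(scfg)
            truth = simulate.generate_occupancy_series(scfg, genome)
            do = simulate.generate_do_trace(scfg)
            metabolites = simulate.generate_metabolites(scfg)
            transcripts = simulate.generate_transcripts(scfg, truth.cluster_labels)
            pdna, gdna, mdna = truth.pdna, truth.gdna, truth.mdna
            annotations, dyads = truth.annotations, truth.dyads
            sample_times_min = scfg.sample_times_min
            period_min, sampling_min = scfg.period_min, scfg.sampling_min
            _write("pdna.tsv", io.write_probe_table, pdna)
            _write("gdna.tsv", io.write_probe_table, gdna)
            _write("mdna.tsv", io.write_probe_table, mdna)
            _write("annotations.gff3", io.write_annotations, annotations)
            _write("dyads.bed", io.write_dyads, dyads)
            _write("do_trace.csv",
                   lambda df, p: df.to_csv(p, index=False), do)
            _write("metabolites.csv",
                   lambda df, p: df.to_csv(p, index=False), metabolites)
            _write("transcripts.tsv", io.write_series_table, transcripts)
            _write("truth_occupancy.tsv", io.write_series_table,
                   truth.true_occupancy.set_index("probe_id"))
        else:
            for name in ("pdna", "gdna", "mdna", "annotations", "dyads",
                         "do_trace"):
                if getattr(config, name) is None:
                    raise FileNotFoundError(f"missing required input: {name}")
            pdna = io.read_probe_table(config.pdna)
            gdna = io.read_probe_table(config.gdna)
            mdna = io.read_probe_table(config.mdna)
            annotations = io.read_annotations(config.annotations)
            dyads = io.read_dyads(config.dyads)
            do = io.read_trace(config.do_trace)
            metabolites = (pd.read_csv(config.metabolites)
                           if config.metabolites else None)
            transcripts = (io.read_series_table(config.transcripts)
                           if config.transcripts else None)
            if config.sample_times_min is None:
                n = len(io.array_columns(pdna))
                sample_times_min = np.arange(n) * config.sampling_min
            else:
                sample_times_min = np.asarray(config.sample_times_min, float)
            period_min, sampling_min = config.period_min, config.sampling_min
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- normalize -------------------------------------------------- #
    stage = "normalize"
    try:
        lvs = arraynorm.select_least_variant(pdna, gdna, config.lvs_threshold)
        pdna_n = arraynorm.loess_normalize(pdna, lvs, config.loess_span)
        gdna_n = arraynorm.loess_normalize(gdna, lvs, config.loess_span)
        mdna_n = arraynorm.loess_normalize(mdna, lvs, config.loess_span)
        pdna_a = arraynorm.average_strand_pairs(pdna_n)
        gdna_a = arraynorm.average_strand_pairs(gdna_n)
        mdna_a = arraynorm.average_strand_pairs(mdna_n)
        bias = arraynorm.compute_mnase_bias(mdna_a, gdna_a)
        occupancy = arraynorm.compute_occupancy(pdna_a, gdna_a, bias)
        _write("occupancy.tsv", io.write_probe_table, occupancy)
        manifest["n_lvs_probes"] = int(len(lvs))
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- phase ------------------------------------------------------ #
    stage = "phase"
    try:
        phase_map = phasing.phase_from_do(
            do["time_s"].to_numpy(), do["value"].to_numpy(),
            np.asarray(sample_times_min) * 60.0,
            reductive_anchor_deg=config.reductive_anchor_deg,
        )
        _write("phase.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index=False),
               phase_map.to_frame())
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- profiles --------------------------------------------------- #
    stage = "profiles"
    try:
        classification = genomemap.classify_dyads(dyads, annotations)
        tss_index = genomemap.map_probes_to_tss(
            occupancy, annotations, config.tss_half_window_bp
        )
        tss_profile = genomemap.median_tss_profile(occupancy, tss_index)
        positional, central = genomemap.dyad_aligned_profile(
            occupancy, classification, config.dyad_half_window_bp
        )
        cluster_labels = annotations.set_index("gene_id")["cluster"].dropna()
        clus_positional, clus_central = genomemap.cluster_profiles(
            occupancy, classification, cluster_labels,
            config.dyad_half_window_bp,
        )
        _write("tss_profile.tsv", io.write_series_table, tss_profile)
        _write("dyad_profile.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index=False), positional)
        _write("class_central.tsv", io.write_series_table, central)
        _write("cluster_central.tsv", io.write_series_table, clus_central)
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- cycle ------------------------------------------------------ #
    stage = "cycle"
    try:
        df_spline = cyclefit.df_for(period_min, sampling_min)
        phases = phase_map.phase_deg
        class_cycles = cyclefit.fit_cycle_frame(central, phases, df_spline)
        delta, side_means = cyclefit.subtract_temporal_mean(class_cycles.T)
        _write("class_cycles.tsv", io.write_series_table, class_cycles)
        _write("class_cycles_delta.tsv", io.write_series_table, delta.T)
        results: dict = {"class_temporal_means": side_means.to_dict()}
        if transcripts is not None:
            sums = cyclefit.sum_clusters(
                transcripts, annotations.set_index("gene_id")["cluster"]
            )
            sums_cycle = cyclefit.fit_cycle_frame(sums, phases, df_spline)
            rates = pd.DataFrame(
                {
                    name: cyclefit.rate_of_change(
                        row.to_numpy(), phases, df_spline
                    )
                    for name, row in sums.iterrows()
                }
            ).T
            _write("cluster_sums_cycle.tsv", io.write_series_table, sums_cycle)
            _write("cluster_rates_cycle.tsv", io.write_series_table, rates)
        manifest.update(results)
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- spectra ----------------------------------------------------- #
    stage = "spectra"
    try:
        occ_vals = occupancy[io.array_columns(occupancy)].to_numpy()
        stats = spectral.fourier_stats_matrix(occ_vals, sampling_min)
        stats.insert(0, "probe_id", occupancy["probe_id"].to_numpy())
        _write("fourier_stats.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index=False), stats)
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- energetics --------------------------------------------------- #
    stage = "energetics"
    try:
        if metabolites is not None:
            params = energetics.KineticParams(config.km_mm, config.ki_mm)
            act = energetics.remodeling_activity(
                metabolites["atp_mm"].to_numpy(),
                metabolites["adp_mm"].to_numpy(), params,
            )
            ec = energetics.energy_charge(
                metabolites["atp_mm"].to_numpy(),
                metabolites["adp_mm"].to_numpy(),
                metabolites["amp_mm"].to_numpy(),
            )
            etab = metabolites.assign(activity=act, energy_charge=ec)
            _write("energetics.tsv",
                   lambda df, p: df.to_csv(p, sep="\t", index=False), etab)
    except Exception as err:
        raise StageError(stage, err) from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str))
    return manifest
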
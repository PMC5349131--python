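"""The synthetic generator must invert exactly at zero noise, respect its
configured ranges for any seed, and be bit-deterministic under a seed."""

import numpy as np
import pandas as pd
import pytest

import occycle as oc
from occycle.io import array_columns
from occycle.phasing import PhaseError


def test_config_validation():
    with pytest.raises(ValueError):
        oc.SyntheticConfig(n_genes=0)
    with pytest.raises(ValueError):
        oc.SyntheticConfig(oxidative_deg=360.0)
    with pytest.raises(ValueError):
        oc.SyntheticConfig(class_amplitudes={"GB": -0.1})


def test_dyad_ladder_counts():
    """A 1000 bp gene with 165 bp spacing gets 6 genic dyads (hand count:
    floor((1000-75)/165)+1) plus one upstream -1 dyad."""
    cfg = oc.SyntheticConfig(n_genes=1, gene_length_mean_bp=1000,
                             gene_length_sd_bp=0, seed=3)
    genome = oc.generate_genome(cfg)
    dy = genome.dyads
    assert (dy["ordinal"] > 0).sum() == 6
    assert (dy["ordinal"] == -1).sum() == 1


def test_minus_strand_dyads_decrease(default_truth):
    _, genome, _ = default_truth
    minus = genome.annotations[genome.annotations["strand"] == "-"]
    assert len(minus) > 0
    gid = minus.iloc[0]["gene_id"]
    dy = genome.dyads.query("gene_id == @gid and ordinal > 0").sort_values("ordinal")
    assert (np.diff(dy["pos"].to_numpy()) < 0).all()


def test_probe_tiling_paired(default_truth):
    cfg, genome, _ = default_truth
    probes = genome.probes
    counts = probes.groupby(["chrom", "start", "end"]).size()
    assert (counts == 2).all()  # forward/reverse pair at every position
    starts = np.sort(probes["start"].unique())
    assert (np.diff(starts) == cfg.probe_spacing_bp).all()


def test_noiseless_generative_inversion(small_noiseless):
    """log2(pDNA) - log2(gDNA) - bias reproduces the true occupancy exactly
    at zero noise and no scale factors."""
    _, _, truth = small_noiseless
    cols = array_columns(truth.pdna)[:33]
    ids = truth.pdna["probe_id"]
    occ = (np.log2(truth.pdna[cols].to_numpy())
           - np.log2(truth.gdna[cols].to_numpy())
           - truth.true_bias.reindex(ids).to_numpy()[:, None])
    expected = truth.true_occupancy.set_index("probe_id").loc[ids].to_numpy()
    assert np.abs(occ - expected).max() < 1e-9


def test_zero_amplitude_is_static():
    cfg = oc.SyntheticConfig(n_genes=5, seed=2, noise_sd=0.0,
                             class_amplitudes={"GB": 0, "TSS": 0, "NDR": 0})
    genome = oc.generate_genome(cfg)
    truth = oc.generate_occupancy_series(cfg, genome)
    vals = truth.true_occupancy.drop(columns="probe_id").to_numpy()
    assert np.ptp(vals, axis=1).max() == 0.0


def test_seed_determinism():
    cfg = oc.SyntheticConfig(n_genes=5, seed=7)
    a = oc.generate_occupancy_series(cfg, oc.generate_genome(cfg))
    b = oc.generate_occupancy_series(cfg, oc.generate_genome(cfg))
    pd.testing.assert_frame_equal(a.pdna, b.pdna)
    pd.testing.assert_frame_equal(a.mdna, b.mdna)
    c = oc.SyntheticConfig(n_genes=5, seed=8)
    other = oc.generate_occupancy_series(c, oc.generate_genome(c))
    assert not a.pdna.equals(other.pdna)


def test_zero_timepoints_rejected():
    cfg = oc.SyntheticConfig(n_genes=2, n_cycles=1, period_min=5.0,
                             sampling_min=6.0)
    with pytest.raises(ValueError, match="zero timepoints"):
        oc.generate_occupancy_series(cfg, oc.generate_genome(cfg))


class TestDOTrace:
    def test_one_derivative_minimum_per_cycle(self):
        cfg = oc.SyntheticConfig(seed=4)
        do = oc.generate_do_trace(cfg)
        t, v = do["time_s"].to_numpy(), do["value"].to_numpy()
        deriv = oc.do_derivative(t, oc.smooth_do(t, v))
        anchors = oc.find_anchors(t, deriv)
        mins = [at for at, k in anchors if k == "min_deriv"
                and 0 <= at < cfg.n_cycles * cfg.period_min * 60.0]
        assert len(mins) == cfg.n_cycles

    def test_oxidative_window_duration(self):
        """Derivative min to max spans 67*94/360 ~ 17.5 min."""
        cfg = oc.SyntheticConfig(seed=4)
        do = oc.generate_do_trace(cfg)
        t, v = do["time_s"].to_numpy(), do["value"].to_numpy()
        deriv = oc.do_derivative(t, oc.smooth_do(t, v))
        anchors = oc.find_anchors(t, deriv)
        mins = [at for at, k in anchors if k == "min_deriv"]
        maxs = [at for at, k in anchors if k == "max_deriv"]
        gap_min = (maxs[0] - mins[0]) / 60.0
        assert gap_min == pytest.approx(67 * 94 / 360, abs=0.2)

    def test_flat_trace_fails_cleanly(self):
        cfg = oc.SyntheticConfig(seed=4, do_amplitude=0.0)
        do = oc.generate_do_trace(cfg)
        t, v = do["time_s"].to_numpy(), do["value"].to_numpy()
        deriv = oc.do_derivative(t, oc.smooth_do(t, v))
        with pytest.raises(PhaseError):
            oc.find_anchors(t, deriv)


class TestMetabolites:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_ranges_hold_for_any_seed(self, seed):
        cfg = oc.SyntheticConfig(seed=seed, metabolite_noise_sd=0.1)
        met = oc.generate_metabolites(cfg)
        atp, adp, amp = (met[c].to_numpy() for c in ("atp_mm", "adp_mm", "amp_mm"))
        assert atp.min() == pytest.approx(21.0, rel=0.01)
        assert atp.max() == pytest.approx(51.0, rel=0.01)
        ratio = atp / adp
        assert ratio.min() == pytest.approx(1.2, rel=0.01)
        assert ratio.max() == pytest.approx(8.0, rel=0.01)
        ec = oc.energy_charge(atp, adp, amp)
        assert ec.min() == pytest.approx(0.65, rel=0.01)
        assert ec.max() == pytest.approx(0.9, rel=0.01)
        assert (amp >= 0).all()

    def test_ratio_span(self):
        met = oc.generate_metabolites(oc.SyntheticConfig(seed=0))
        ratio = met["atp_mm"] / met["adp_mm"]
        assert ratio.max() / ratio.min() == pytest.approx(8 / 1.2, rel=0.01)

    def test_zero_amplitude_constant(self):
        met = oc.generate_metabolites(
            oc.SyntheticConfig(seed=0, metabolite_amplitude=0.0)
        )
        for col in ("atp_mm", "adp_mm", "amp_mm"):
            assert np.ptp(met[col].to_numpy()) < 1e-12

    def test_atp_peaks_in_oxidative_phase(self):
        cfg = oc.SyntheticConfig(seed=0)
        met = oc.generate_metabolites(cfg)
        peak_phase = cfg.sample_phases_deg[met["atp_mm"].idxmax()]
        assert peak_phase < cfg.oxidative_deg


class TestTranscripts:
    def test_single_gene_cluster_equals_gene(self):
        cfg = oc.SyntheticConfig(seed=0, noise_sd=0.0)
        labels = pd.Series({"g1": "A", "g2": "C"})
        expr = oc.generate_transcripts(cfg, labels)
        sums = oc.sum_clusters(expr, labels, with_superclusters=False)
        np.testing.assert_allclose(sums.loc["A"], expr.loc["g1"])
        np.testing.assert_allclose(sums.loc["C"], expr.loc["g2"])

    def test_cluster_sums_peak_at_configured_phases(self):
        cfg = oc.SyntheticConfig(seed=0, noise_sd=0.0)
        labels = pd.Series({f"g{i}": cl for i, cl in
                            enumerate(["A", "AB", "B", "C", "D"] * 4)})
        expr = oc.generate_transcripts(cfg, labels)
        sums = oc.sum_clusters(expr, labels, with_superclusters=False)
        for cl, mu in cfg.cluster_peak_deg.items():
            peak = cfg.sample_phases_deg[int(np.argmax(sums.loc[cl].to_numpy()))]
            delta = abs((peak - mu + 180) % 360 - 180)
            assert delta <= 15, (cl, peak, mu)

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ValueError, match="without a configured peak"):
            oc.generate_transcripts(oc.SyntheticConfig(), pd.Series({"g": "Z"}))

    def test_seeds_differ(self):
        labels = pd.Series({"g1": "A"})
        a = oc.generate_transcripts(oc.SyntheticConfig(seed=0), labels)
        b = oc.generate_transcripts(oc.SyntheticConfig(seed=1), labels)
        assert not a.equals(b)


class TestNadph:
    def test_inband_only_filter_is_identity(self):
        cfg = oc.SyntheticConfig(seed=0, n_genes=1, nadph_drift_amplitude=0.0,
                                 nadph_noise_amplitude=0.0)
        tr = oc.generate_nadph(cfg)
        f_osc = 1.0 / (cfg.period_min * 60.0)
        out = oc.bandpass_filter(tr["value"].to_numpy(), 10.0, f_osc)
        assert np.abs(out - tr["value"].to_numpy()).max() < 1e-9

    def test_out_of_band_only_filters_to_zero(self):
        cfg = oc.SyntheticConfig(seed=0, n_genes=1, nadph_harmonic_amps=(),
                                 nadph_drift_amplitude=0.5,
                                 nadph_noise_amplitude=0.3)
        tr = oc.generate_nadph(cfg)
        f_osc = 1.0 / (cfg.period_min * 60.0)
        out = oc.bandpass_filter(tr["value"].to_numpy(), 10.0, f_osc)
        assert np.abs(out).max() < 1e-6 * max(1.0, np.abs(tr["value"]).max())

    def test_reproducible(self):
        cfg = oc.SyntheticConfig(seed=5, n_genes=1)
        pd.testing.assert_frame_equal(oc.generate_nadph(cfg), oc.generate_nadph(cfg))
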
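"""Least-variant-set selection, LOESS normalization, strand averaging, and
the occupancy equation, checked against brute-force oracles and the
noiseless synthetic truth."""

import numpy as np
import pytest

import occycle as oc
from occycle.io import array_columns
from tests.conftest import make_probe_table, normalize_chain, occupancy_error


class TestSelectLeastVariant:
    def test_brute_force_variance_selection(self):
        """3 constructed low-variance probes out of 10 are selected; the
        oracle is a direct per-probe variance computation."""
        rng = np.random.default_rng(0)
        log2 = np.zeros((10, 6))
        for i in range(10):
            sd = 0.2 if i < 3 else 0.65  # var 0.04 vs ~0.42
            row = rng.normal(8.0, sd, 6)
            row = (row - row.mean()) / row.std(ddof=1) * sd + 8.0  # exact sd
            log2[i] = row
        p = make_probe_table(log2)
        g = make_probe_table(log2)
        sel = oc.select_least_variant(p, g, threshold=0.1)
        oracle = {f"P{i:04d}" for i in range(10)
                  if np.var(log2[i], ddof=1) < 0.1}
        assert {pid for pid, _ in sel} == oracle == {"P0000", "P0001", "P0002"}

    def test_identical_arrays_all_selected(self):
        log2 = np.tile(np.linspace(6, 12, 20)[:, None], (1, 4))
        p = make_probe_table(log2)
        sel = oc.select_least_variant(p, p, threshold=0.01)
        assert len(sel) == 20

    def test_empty_selection_raises(self):
        rng = np.random.default_rng(1)
        p = make_probe_table(rng.normal(8, 2, (20, 5)))
        with pytest.raises(ValueError, match="increase the LVS threshold"):
            oc.select_least_variant(p, p, threshold=1e-6)

    def test_requires_low_variance_in_both_channels(self):
        quiet = np.tile(np.full((5, 1), 8.0), (1, 4))
        noisy = np.array([[7, 9, 7, 9]] * 5, dtype=float)
        p = make_probe_table(quiet)
        g = make_probe_table(noisy)
        with pytest.raises(ValueError):
            oc.select_least_variant(p, g, threshold=0.1)


class TestLoessNormalize:
    def _table(self, n=300, k=5, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(9, 1, n)
        return base, make_probe_table(np.tile(base[:, None], (1, k)))

    def test_identity_when_equal_to_reference(self):
        _, tab = self._table()
        lvs = oc.select_least_variant(tab, tab, 0.1)
        out = oc.loess_normalize(tab, lvs)
        np.testing.assert_allclose(
            out[array_columns(out)].to_numpy(),
            tab[array_columns(tab)].to_numpy(), rtol=1e-10,
        )

    def test_constant_offset_removed(self):
        """An array offset by a constant is pulled back onto the across-array
        mean reference (which absorbs 1/n of the offset)."""
        base, tab = self._table()
        cols = array_columns(tab)
        tab[cols[2]] = tab[cols[2]] * 2 ** 1.7  # +1.7 log2 on one array
        ref = np.log2(tab[cols].to_numpy()).mean(axis=1)
        lvs = oc.select_least_variant(tab, tab, 2.0)
        out = oc.loess_normalize(tab, lvs)
        for c in cols:
            np.testing.assert_allclose(np.log2(out[c].to_numpy()), ref,
                                       atol=1e-6)

    def test_smooth_distortion_variance_drop(self):
        """An injected intensity-dependent bend is removed >= 10-fold."""
        rng = np.random.default_rng(2)
        base = rng.normal(9, 1, 500)
        log2 = np.tile(base[:, None], (1, 6)) + rng.normal(0, 0.05, (500, 6))
        slopes = rng.normal(0, 0.3, 6)
        slopes -= slopes.mean()
        log2 += (base[:, None] - base.mean()) * slopes[None, :]
        tab = make_probe_table(log2)
        lvs = oc.select_least_variant(tab, tab, 2.0)
        out = oc.loess_normalize(tab, lvs)
        pre = np.var(log2, axis=1, ddof=1).mean()
        post = np.var(np.log2(out[array_columns(out)].to_numpy()),
                      axis=1, ddof=1).mean()
        assert pre / post >= 10

    def test_idempotent_after_clean_first_pass(self):
        base, tab = self._table()
        cols = array_columns(tab)
        for j, c in enumerate(cols):
            tab[c] = tab[c] * 2 ** (0.5 * (j - 2))
        lvs = oc.select_least_variant(tab, tab, 2.0)
        once = oc.loess_normalize(tab, lvs)
        twice = oc.loess_normalize(once, lvs)
        diff = np.abs(np.log2(twice[cols].to_numpy())
                      - np.log2(once[cols].to_numpy())).max()
        assert diff < 1e-6

    def test_too_few_lvs_probes(self):
        _, tab = self._table(n=20)
        lvs = oc.select_least_variant(tab, tab, 0.1)[:3]
        with pytest.raises(ValueError, match="LVS probes"):
            oc.loess_normalize(tab, lvs)


class TestStrandAveraging:
    def test_pair_log2_average(self):
        import pandas as pd
        tab = pd.DataFrame(
            {
                "probe_id": ["P1", "P1"],
                "chrom": ["c", "c"],
                "start": [1, 1],
                "end": [32, 32],
                "strand": ["+", "-"],
                "a00": [2.0, 8.0],  # log2 = 1 and 3 -> mean 2 -> intensity 4
            }
        )
        out = oc.average_strand_pairs(tab)
        assert len(out) == 1
        assert out["a00"].iloc[0] == pytest.approx(4.0)

    def test_unpaired_kept(self):
        log2 = np.full((5, 2), 8.0)
        tab = make_probe_table(log2)  # all + strand, unpaired
        out = oc.average_strand_pairs(tab)
        assert len(out) == 5
        np.testing.assert_allclose(out[array_columns(out)].to_numpy(),
                                   tab[array_columns(tab)].to_numpy())

    def test_paired_table_halves(self, small_noiseless):
        _, _, truth = small_noiseless
        out = oc.average_strand_pairs(truth.pdna)
        assert len(out) == len(truth.pdna) // 2


class TestBiasAndOccupancy:
    def test_identical_channels_zero_bias(self):
        tab = make_probe_table(np.full((6, 3), 9.0))
        bias = oc.compute_mnase_bias(tab, tab)
        np.testing.assert_allclose(bias.to_numpy(), 0.0)

    def test_twofold_bias(self):
        g = make_probe_table(np.full((6, 3), 9.0))
        m = g.copy()
        for c in array_columns(m):
            m[c] = m[c] * 2.0
        bias = oc.compute_mnase_bias(m, g)
        np.testing.assert_allclose(bias.to_numpy(), 1.0)

    def test_noiseless_bias_recovery(self, small_noiseless):
        _, _, truth = small_noiseless
        m = oc.average_strand_pairs(truth.mdna)
        g = oc.average_strand_pairs(truth.gdna)
        bias = oc.compute_mnase_bias(m, g)
        err = np.abs(bias - truth.true_bias.loc[bias.index]).max()
        assert err < 1e-9

    def test_occupancy_identities(self):
        g = make_probe_table(np.full((4, 2), 9.0))
        p2 = g.copy()
        for c in array_columns(p2):
            p2[c] = p2[c] * 2.0
        bias = oc.compute_mnase_bias(g, g)
        occ0 = oc.compute_occupancy(g, g, bias)
        np.testing.assert_allclose(
            occ0[array_columns(occ0)].to_numpy(), 0.0, atol=1e-12)
        occ1 = oc.compute_occupancy(p2, g, bias)
        np.testing.assert_allclose(
            occ1[array_columns(occ1)].to_numpy(), 1.0, atol=1e-12)

    def test_nonpositive_intensity_flagged_missing(self):
        g = make_probe_table(np.full((4, 2), 9.0))
        p = g.copy()
        p.loc[1, array_columns(p)[0]] = 0.0
        bias = oc.compute_mnase_bias(g, g)
        occ = oc.compute_occupancy(p, g, bias)
        vals = occ[array_columns(occ)]
        assert np.isnan(vals.iloc[1, 0])
        assert np.isfinite(vals.to_numpy()).sum() == 7


class TestPipelineProperties:
    def test_scale_invariance_of_one_timepoint(self, small_noiseless):
        """Multiplying both channels of one timepoint by a constant leaves
        post-normalization occupancy unchanged up to the global channel-level
        offset (occupancy is relative); mean-centered occupancy is exactly
        invariant."""
        import dataclasses
        _, _, truth = small_noiseless
        _, _, occ_ref = normalize_chain(truth, 0.1)
        col = array_columns(truth.pdna)[3]
        pdna = truth.pdna.copy()
        gdna = truth.gdna.copy()
        pdna[col] = pdna[col] * 7.0
        gdna[col] = gdna[col] * 7.0
        scaled = dataclasses.replace(truth, pdna=pdna, gdna=gdna)
        _, _, occ_scaled = normalize_chain(scaled, 0.3)
        a = occ_scaled[array_columns(occ_scaled)].to_numpy()
        b = occ_ref[array_columns(occ_ref)].to_numpy()
        np.testing.assert_allclose(a - a.mean(), b - b.mean(), atol=1e-9)
        # the residual global offset is bounded by log2(c)/n_arrays
        assert abs(a.mean() - b.mean()) <= np.log2(7.0) / 33 + 1e-9

    def test_noiseless_full_chain_recovers_truth(self, small_noiseless):
        _, _, truth = small_noiseless
        _, _, occ = normalize_chain(truth, 1e-9)
        assert np.abs(occupancy_error(occ, truth)).max() < 1e-9
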
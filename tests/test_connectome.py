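"""Seed-based connectivity, aggregation across the connectome, targeting."""

import numpy as np
import pytest

from lnmap.connectome import (NormativeConnectome, R_CLIP, SubjectTimeseries,
                              _aggregate_z, fisher_z, individualized_circuit_map,
                              lesion_network_map, load_connectome,
                              load_timeseries, pairwise_network_connectivity,
                              seed_map, select_peak_target,
                              site_to_circuit_connectivity, targeting_atlas,
                              within_circuit_connectivity)
from lnmap.errors import DegenerateDataError, EmptySeedError, NotEstimableError
from lnmap.volumes import BinaryMask, ScalarMap

from conftest import ball_mask


def _white_subject(grid, T=200, seed=0):
    rng = np.random.default_rng(seed)
    return SubjectTimeseries(grid, rng.standard_normal((T, grid.n_voxels)))


def _voxel_mask(grid, flat_index):
    ind = np.zeros(grid.shape, dtype=bool)
    ind.ravel()[flat_index] = True
    return BinaryMask(grid, ind.reshape(grid.shape))


class TestSeedMap:
    def test_self_correlation_clipped(self, grid10):
        subj = _white_subject(grid10, seed=1)
        z = seed_map(subj, _voxel_mask(grid10, 0))
        assert z.values.flat[0] == pytest.approx(np.arctanh(R_CLIP))

    def test_anticorrelated_voxel_hits_negative_clip(self, grid10):
        subj = _white_subject(grid10, seed=2)
        subj.data[:, 1] = -subj.data[:, 0]
        subj._std = None  # invalidate cache after manual edit
        z = seed_map(subj, _voxel_mask(grid10, 0))
        assert z.values.flat[1] == pytest.approx(-np.arctanh(R_CLIP))

    def test_white_noise_mean_z_near_zero(self, grid10):
        # null z has sd ~ 1/sqrt(T-3); the mean over ~1000 voxels is tiny
        subj = _white_subject(grid10, T=200, seed=3)
        z = seed_map(subj, _voxel_mask(grid10, 42))
        non_seed = np.ones(grid10.n_voxels, dtype=bool)
        non_seed[42] = False
        assert abs(z.values.ravel()[non_seed].mean()) < 0.05

    def test_empty_seed_raises(self, grid10):
        subj = _white_subject(grid10, seed=4)
        with pytest.raises(EmptySeedError):
            seed_map(subj, BinaryMask(grid10, np.zeros(grid10.shape, dtype=bool)))

    def test_weighted_point_mass_equals_binary_seed(self, grid10):
        subj = _white_subject(grid10, seed=5)
        weights = np.zeros(grid10.shape)
        weights.flat[17] = 2.5
        z_w = seed_map(subj, ScalarMap(grid10, weights))
        z_b = seed_map(subj, _voxel_mask(grid10, 17))
        assert np.allclose(z_w.values, z_b.values, atol=1e-10)

    def test_fisher_round_trip(self):
        r = np.linspace(-1 + 1e-6, 1 - 1e-6, 101)
        assert np.allclose(np.tanh(fisher_z(r)), r, atol=1e-12)

    def test_null_z_sd_matches_fisher_theory(self, grid10):
        # sd of z at independent voxels ~ 1/sqrt(T-3) within 15%
        T = 100
        subj = _white_subject(grid10, T=T, seed=6)
        z = seed_map(subj, _voxel_mask(grid10, 0))
        sd = z.values.ravel()[1:].std()
        assert sd == pytest.approx(1 / np.sqrt(T - 3), rel=0.15)


class TestAggregation:
    def test_hand_computed_t(self):
        # z = {0.1, 0.2, 0.3}: t = 0.2 / (0.1 / sqrt(3)) = 3.4641
        z = np.array([[0.1], [0.2], [0.3]])
        t = _aggregate_z(z, "tmap")
        assert t[0] == pytest.approx(3.4641, abs=1e-4)

    def test_mean_z_idempotent_for_identical_subjects(self, grid10):
        subj = _white_subject(grid10, seed=7)
        conn = NormativeConnectome([subj, subj, subj])
        seed = _voxel_mask(grid10, 3)
        mean_map = lesion_network_map(conn, seed, "mean_z")
        single = seed_map(subj, seed)
        assert np.allclose(mean_map.values, single.values, atol=1e-5)

    def test_tmap_and_mean_z_sign_consistent(self, grid10):
        conn = NormativeConnectome([_white_subject(grid10, seed=s) for s in range(4)])
        seed = _voxel_mask(grid10, 3)
        t = lesion_network_map(conn, seed, "tmap")
        m = lesion_network_map(conn, seed, "mean_z")
        nz = m.values != 0
        assert np.all(np.sign(t.values[nz]) == np.sign(m.values[nz]))

    def test_tmap_requires_two_subjects(self, grid10):
        conn = NormativeConnectome([_white_subject(grid10, seed=8)])
        with pytest.raises(DegenerateDataError):
            lesion_network_map(conn, _voxel_mask(grid10, 0), "tmap")

    def test_duplicated_subjects_leave_mean_z_unchanged(self, grid10):
        subs = [_white_subject(grid10, seed=s) for s in range(3)]
        seed = _voxel_mask(grid10, 9)
        m1 = lesion_network_map(NormativeConnectome(subs), seed, "mean_z")
        m2 = lesion_network_map(NormativeConnectome(subs + subs), seed, "mean_z")
        assert np.allclose(m1.values, m2.values, atol=1e-5)


class TestScalarConnectivity:
    def test_point_mass_circuit_reduces_to_self_correlation(self, grid10):
        subj = _white_subject(grid10, seed=9)
        weights = np.zeros(grid10.shape)
        weights.flat[11] = 1.0
        z = within_circuit_connectivity(subj, ScalarMap(grid10, weights))
        assert z == pytest.approx(np.arctanh(R_CLIP))

    def test_nonpositive_circuit_rejected(self, grid10):
        subj = _white_subject(grid10, seed=10)
        with pytest.raises(EmptySeedError):
            within_circuit_connectivity(subj, ScalarMap(grid10, -np.ones(grid10.shape)))

    def test_coupled_circuit_scores_higher_than_uncoupled(self, small_cfg, small_world):
        # subjects sharing a latent signal in the circuit voxels score
        # higher than pure-noise subjects, across seeded replicates
        conn, truth = small_world
        grid = small_cfg.grid
        circuit = truth.circuit.map
        flat = np.flatnonzero(circuit.values.ravel() > 0)
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            data = rng.standard_normal((80, grid.n_voxels))
            latent = rng.standard_normal(80)
            coupled = data.copy()
            coupled[:, flat] += 0.8 * latent[:, None]
            z_c = within_circuit_connectivity(
                SubjectTimeseries(grid, coupled), circuit)
            z_0 = within_circuit_connectivity(
                SubjectTimeseries(grid, data), circuit)
            wins += z_c > z_0
        assert wins >= 18

    def test_pairwise_symmetric(self, grid10):
        subj = _white_subject(grid10, seed=11)
        a = ball_mask(grid10, (3, 3, 3), 2)
        b = ball_mask(grid10, (7, 7, 7), 2)
        assert pairwise_network_connectivity(subj, a, b) == \
            pairwise_network_connectivity(subj, b, a)

    def test_identical_rois_hit_clip(self, grid10):
        subj = _white_subject(grid10, seed=12)
        a = ball_mask(grid10, (3, 3, 3), 2)
        b = ball_mask(grid10, (3, 3, 3), 2)
        assert pairwise_network_connectivity(subj, a, b) == \
            pytest.approx(np.arctanh(R_CLIP))

    def test_independent_rois_have_null_scale_z(self, grid10):
        a = ball_mask(grid10, (2, 2, 2), 1)
        b = ball_mask(grid10, (8, 8, 8), 1)
        inside = 0
        for s in range(100):
            subj = _white_subject(grid10, T=200, seed=200 + s)
            inside += abs(pairwise_network_connectivity(subj, a, b)) < 0.3
        assert inside >= 95

    def test_site_subset_of_uniform_circuit(self, grid10):
        subj = _white_subject(grid10, seed=13)
        circuit_vals = np.zeros(grid10.shape)
        circuit_vals[3:6, 3:6, 3:6] = 1.0
        circuit = ScalarMap(grid10, circuit_vals)
        site_ind = np.zeros(grid10.shape, dtype=bool)
        site_ind[3:6, 3:6, 3] = True
        z = site_to_circuit_connectivity(subj, BinaryMask(grid10, site_ind), circuit)
        assert np.isfinite(z)

    def test_empty_site_rejected(self, grid10):
        subj = _white_subject(grid10, seed=14)
        circuit = ScalarMap(grid10, np.ones(grid10.shape))
        with pytest.raises(EmptySeedError):
            site_to_circuit_connectivity(
                subj, BinaryMask(grid10, np.zeros(grid10.shape, dtype=bool)), circuit)

    def test_anticorrelated_site_yields_negative_z(self, grid10):
        rng = np.random.default_rng(15)
        latent = rng.standard_normal(150)
        data = rng.standard_normal((150, grid10.n_voxels))
        circuit_vals = np.zeros(grid10.shape)
        circuit_vals[2:5, 2:5, 2:5] = 1.0
        site_ind = np.zeros(grid10.shape, dtype=bool)
        site_ind[7:9, 7:9, 7:9] = True
        data[:, np.flatnonzero(circuit_vals.ravel())] += 2.0 * latent[:, None]
        data[:, np.flatnonzero(site_ind.ravel())] -= 2.0 * latent[:, None]
        subj = SubjectTimeseries(grid10, data)
        z = site_to_circuit_connectivity(subj, BinaryMask(grid10, site_ind),
                                         ScalarMap(grid10, circuit_vals))
        assert z < -0.5


class TestTargeting:
    def test_point_circuit_atlas_equals_seed_map_aggregate(self, grid10):
        conn = NormativeConnectome([_white_subject(grid10, seed=s) for s in range(3)])
        weights = np.zeros(grid10.shape)
        weights.flat[5] = 1.0
        atlas = targeting_atlas(conn, ScalarMap(grid10, weights), "mean_z")
        direct = lesion_network_map(conn, _voxel_mask(grid10, 5), "mean_z")
        assert np.allclose(atlas.values, direct.values, atol=1e-10)

    def test_atlas_peak_recovers_unseeded_network_region(self, small_cfg, small_world):
        # seed only half of the planted network; the atlas should still
        # peak inside the network, including its unseeded remainder
        conn, truth = small_world
        circuit = truth.circuit.map
        vals = circuit.values.copy()
        half = np.zeros_like(vals, dtype=bool)
        half[: small_cfg.shape[0] // 2] = True
        seed_vals = np.where(half, vals, 0.0)
        if not (seed_vals > 0).any():
            pytest.skip("planted circuit lies in one half only")
        atlas = targeting_atlas(conn, ScalarMap(circuit.grid, seed_vals))
        outside_seed = BinaryMask(circuit.grid,
                                  truth.planted_network_mask.indicator
                                  & ~(seed_vals > 0))
        restricted = ScalarMap(atlas.grid,
                               np.where(seed_vals > 0, -np.inf, atlas.values),
                               atlas.analysis_mask)
        peak = restricted.peak_voxel()
        assert truth.planted_network_mask.indicator[peak]

    def test_aggregations_sign_consistent(self, grid10):
        conn = NormativeConnectome([_white_subject(grid10, seed=s) for s in range(4)])
        weights = np.zeros(grid10.shape)
        weights.flat[:5] = 1.0
        t = targeting_atlas(conn, ScalarMap(grid10, weights), "tmap")
        m = targeting_atlas(conn, ScalarMap(grid10, weights), "mean_z")
        nz = m.values != 0
        assert np.all(np.sign(t.values[nz]) == np.sign(m.values[nz]))


class TestIndividualizedMap:
    def test_consistency_with_within_circuit_score(self, grid10):
        subj = _white_subject(grid10, seed=16)
        vals = np.zeros(grid10.shape)
        vals[2:5, 2:5, 2:5] = np.random.default_rng(17).random((3, 3, 3)) + 0.1
        circuit = ScalarMap(grid10, vals)
        imap = individualized_circuit_map(subj, circuit)
        w = vals.ravel()
        pos = w > 0
        expected = (imap.values.ravel()[pos] * w[pos]).sum() / w[pos].sum()
        assert within_circuit_connectivity(subj, circuit) == pytest.approx(
            expected, abs=1e-6)

    def test_planted_coupling_peak_in_coupled_region(self, grid10):
        hits = 0
        region = np.zeros(grid10.shape, dtype=bool)
        region[6:9, 6:9, 6:9] = True
        circuit_vals = np.zeros(grid10.shape)
        circuit_vals[1:4, 1:4, 1:4] = 1.0
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            latent = rng.standard_normal(120)
            data = rng.standard_normal((120, grid10.n_voxels))
            data[:, np.flatnonzero(circuit_vals.ravel())] += 1.5 * latent[:, None]
            data[:, np.flatnonzero(region.ravel())] += 1.5 * latent[:, None]
            subj = SubjectTimeseries(grid10, data)
            imap = individualized_circuit_map(subj, ScalarMap(grid10, circuit_vals))
            masked = np.where(circuit_vals.ravel() > 0, -np.inf,
                              imap.values.ravel())
            peak = np.unravel_index(int(np.argmax(masked)), grid10.shape)
            hits += bool(region[peak])
        assert hits >= 45


class TestPeakTargetSelection:
    def test_single_suprathreshold_voxel(self, grid10):
        vals = np.zeros(grid10.shape)
        vals[4, 4, 4] = 10.0
        cmap = ScalarMap(grid10, vals)
        acc = BinaryMask(grid10, np.ones(grid10.shape, dtype=bool))
        rec = select_peak_target(cmap, acc, 0.99)
        assert rec.peak_voxel == (4, 4, 4)
        assert rec.largest_cluster_size == 1
        assert rec.peak_in_largest_cluster

    def test_tie_breaks_by_scan_order(self, grid10):
        vals = np.zeros(grid10.shape)
        vals[2, 2, 2] = 5.0
        vals[7, 7, 7] = 5.0
        rec = select_peak_target(ScalarMap(grid10, vals),
                                 BinaryMask(grid10, np.ones(grid10.shape, bool)),
                                 0.99)
        assert rec.peak_voxel == (2, 2, 2)

    def test_disagreement_between_peak_and_largest_cluster(self, grid10):
        vals = np.zeros(grid10.shape)
        vals[0, 0, 0] = 10.0          # isolated peak
        vals[5:8, 5:8, 5:8] = 5.0     # large cluster elsewhere
        rec = select_peak_target(ScalarMap(grid10, vals),
                                 BinaryMask(grid10, np.ones(grid10.shape, bool)),
                                 0.9)
        assert not rec.peak_in_largest_cluster
        assert rec.largest_cluster_size == 27
        assert rec.peak_voxel == (0, 0, 0)

    def test_nothing_above_threshold(self, grid10):
        vals = np.full(grid10.shape, 1.0)
        with pytest.raises(NotEstimableError):
            select_peak_target(ScalarMap(grid10, vals),
                               BinaryMask(grid10, np.ones(grid10.shape, bool)), 0.5)


class TestTimeseriesIO:
    def test_round_trip_manifest(self, grid10, tmp_path):
        import json
        import nibabel as nib
        rng = np.random.default_rng(20)
        data = rng.standard_normal((4, 4, 4, 30)).astype(np.float32)
        p = tmp_path / "subj.nii.gz"
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(p))
        (tmp_path / "manifest.json").write_text(json.dumps(
            {"subjects": [{"path": "subj.nii.gz", "tr": 2.0}]}))
        conn = load_connectome(tmp_path / "manifest.json")
        assert conn.n == 1
        assert conn.subjects[0].n_timepoints == 30
        flat = data.reshape(-1, 30).T
        assert np.allclose(conn.subjects[0].data, flat, atol=1e-6)
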
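"""Circuit derivation, partial correlation, VLSM, and FWE localization."""

import numpy as np
import pandas as pd
import pytest

from lnmap.errors import DegenerateDataError, NotEstimableError
from lnmap.lesion_mapping import (CohortMaps, LesionCohort, cluster_extent_threshold,
                                  cohort_connectivity, derive_circuit, fwe_peak,
                                  outcome_permutation_null, partial_correlation,
                                  region_exclusion_robustness, vlsm_map,
                                  _partial_corr_columns)
from lnmap.volumes import BinaryMask, ScalarMap, spatial_correlation

from conftest import ball_mask


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 30))
        assert partial_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_y_equal_to_covariate_degenerate(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        z = rng.standard_normal(20)
        with pytest.raises(DegenerateDataError):
            partial_correlation(x, z, z)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(2)
        x, y, z = rng.standard_normal((3, 20))
        with pytest.raises(DegenerateDataError):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))

    def test_small_integer_example_matches_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        z = np.array([1, 1, 2, 2, 3.0])
        # independent oracle: residualize on [1, z] by lstsq, then Pearson
        D = np.column_stack([np.ones(5), z])
        rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        assert partial_correlation(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_on_random_instances(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            x, y, z = rng.standard_normal((3, n))
            ours = partial_correlation(x, y, z)
            ref = pingouin.partial_corr(
                pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y",
                covar="z")["r"].iloc[0]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_matches_recursive_formula_single_covariate(self):
        # r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(8, 30))
            x, y, z = rng.standard_normal((3, n))
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
            assert partial_correlation(x, y, z) == pytest.approx(expected, abs=1e-10)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 40))
        y = rng.standard_normal(25)
        C = rng.standard_normal((25, 2))
        r, flagged = _partial_corr_columns(X, y, C)
        assert not flagged.any()
        for j in range(0, 40, 7):
            assert r[j] == pytest.approx(partial_correlation(X[:, j], y, C),
                                         abs=1e-12)


def _toy_cohort_maps(values, outcome, grid):
    """One-voxel cohort maps for hand-checkable derivations."""
    n = len(values)
    matrix = np.asarray(values, dtype=float)[:, None]
    maps = CohortMaps(matrix=matrix, valid=np.array([True]),
                      voxel_index=np.array([0]), grid=grid, aggregation="tmap")
    lesions = [ball_mask(grid, (2, 2, 2), 1) for _ in range(n)]
    cohort = LesionCohort(ids=[str(i) for i in range(n)], lesions=lesions,
                          outcome=np.asarray(outcome, dtype=float),
                          covariates=pd.DataFrame(index=range(n)))
    return cohort, maps


class TestDeriveCircuit:
    def test_hand_computed_single_voxel_value(self, grid10):
        # connectivity 1..6 vs outcomes [0,0,0,1,2,2]: r = 8.5/sqrt(17.5*4.8333),
        # inverted to -0.924
        cohort, maps = _toy_cohort_maps([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 2, 2],
                                        grid10)
        cohort10, maps10 = _toy_cohort_maps(np.tile([1, 2, 3, 4, 5, 6], 2)[:10],
                                            np.tile([0, 0, 0, 1, 2, 2], 2)[:10],
                                            grid10)
        # the minimum-cohort rule needs n >= 10, so duplicate-extend
        circ = derive_circuit(cohort10, covariate_names=(), maps=maps10)
        expected = -np.corrcoef(np.tile([1, 2, 3, 4, 5, 6], 2)[:10],
                                np.tile([0, 0, 0, 1, 2, 2], 2)[:10])[0, 1]
        assert circ.map.values.flat[0] == pytest.approx(expected, abs=1e-10)
        # the 6-subject hand arithmetic, checked on the raw helper
        r, _ = _partial_corr_columns(maps.matrix, cohort.outcome, None)
        assert -r[0] == pytest.approx(-8.5 / np.sqrt(17.5 * 4.8333333333), abs=1e-6)
        assert -r[0] == pytest.approx(-0.924, abs=1e-3)

    def test_constant_connectivity_flagged_zero(self, grid10):
        cohort, maps = _toy_cohort_maps(np.ones(10), np.arange(10) % 3, grid10)
        circ = derive_circuit(cohort, covariate_names=(), maps=maps)
        assert circ.map.values.flat[0] == 0.0
        assert circ.flagged[0]

    def test_minimum_cohort_enforced(self, grid10):
        cohort, maps = _toy_cohort_maps(np.arange(5), np.arange(5), grid10)
        with pytest.raises(NotEstimableError):
            derive_circuit(cohort, covariate_names=(), maps=maps)

    def test_negated_outcome_flips_sign_exactly(self, small_cohort, small_maps):
        circ = derive_circuit(small_cohort, maps=small_maps)
        flipped_cohort = LesionCohort(
            ids=list(small_cohort.ids), lesions=list(small_cohort.lesions),
            outcome=-small_cohort.outcome,
            covariates=small_cohort.covariates.drop(columns=["lesion_size"]))
        flipped = derive_circuit(flipped_cohort, maps=small_maps)
        assert np.allclose(flipped.map.values, -circ.map.values, atol=1e-12)

    def test_invariant_to_covariate_rescaling(self, small_cohort, small_maps):
        circ = derive_circuit(small_cohort, maps=small_maps)
        rescaled = small_cohort.covariates.drop(columns=["lesion_size"]).copy()
        rescaled["BDI"] = 10.0 * rescaled["BDI"] - 7.0
        cohort2 = LesionCohort(ids=list(small_cohort.ids),
                               lesions=list(small_cohort.lesions),
                               outcome=small_cohort.outcome.copy(),
                               covariates=rescaled)
        circ2 = derive_circuit(cohort2, maps=small_maps)
        assert np.allclose(circ2.map.values, circ.map.values, atol=1e-9)

    def test_inputs_left_unmodified(self, small_cohort, small_maps):
        outcome_before = small_cohort.outcome.copy()
        cov_before = small_cohort.covariates.copy()
        matrix_before = small_maps.matrix.copy()
        derive_circuit(small_cohort, maps=small_maps)
        vlsm_map(small_cohort)
        assert np.array_equal(small_cohort.outcome, outcome_before)
        pd.testing.assert_frame_equal(small_cohort.covariates, cov_before)
        assert np.array_equal(small_maps.matrix, matrix_before)

    def test_planted_circuit_recovered(self, default_cohort, default_maps,
                                       default_world):
        _, truth = default_world
        circ = derive_circuit(default_cohort, maps=default_maps)
        r = spatial_correlation(circ.map, truth.circuit.map)
        assert r >= 0.6


class TestVLSM:
    def _cohort(self, grid, lesioned_outcomes, spared_outcomes):
        # lesioned subjects share one lesion voxel; spared lesions elsewhere
        les_ind = np.zeros(grid.shape, dtype=bool)
        les_ind[0, 0, 0] = True
        spa_ind = np.zeros(grid.shape, dtype=bool)
        spa_ind[9, 9, 9] = True
        lesions = ([BinaryMask(grid, les_ind)] * len(lesioned_outcomes)
                   + [BinaryMask(grid, spa_ind)] * len(spared_outcomes))
        n = len(lesions)
        return LesionCohort(ids=[str(i) for i in range(n)], lesions=lesions,
                            outcome=np.array(lesioned_outcomes + spared_outcomes,
                                             dtype=float),
                            covariates=pd.DataFrame(index=range(n)))

    def test_hand_computed_pooled_t(self, grid10):
        # lesioned [2,2] vs spared [0,0,1,1]: sp^2 = 0.25, |t| = 3.464, df 4;
        # spared-minus-lesioned orientation makes this harmful lesion negative
        cohort = self._cohort(grid10, [2, 2], [0, 0, 1, 1])
        stat = vlsm_map(cohort, min_lesioned=2, min_spared=2)
        t = stat.map.values[0, 0, 0]
        assert abs(t) == pytest.approx(3.464, abs=1e-3)
        assert t < 0
        assert stat.df[0, 0, 0] == 4

    def test_equal_means_give_zero(self, grid10):
        cohort = self._cohort(grid10, [1, 1], [1, 1])
        stat = vlsm_map(cohort, min_lesioned=2, min_spared=2)
        assert stat.map.values[0, 0, 0] == 0.0

    def test_undercovered_voxel_excluded(self, grid10):
        cohort = self._cohort(grid10, [2], [0, 0, 1, 1])
        stat = vlsm_map(cohort, min_lesioned=2, min_spared=2)
        assert not stat.map.analysis_mask[0, 0, 0]

    def test_welch_matches_scipy(self, grid10):
        from scipy import stats as sps
        cohort = self._cohort(grid10, [2, 1, 2], [0, 0, 1, 1])
        stat = vlsm_map(cohort, min_lesioned=2, min_spared=2, welch=True)
        ref = sps.ttest_ind([0, 0, 1, 1], [2, 1, 2], equal_var=False)
        assert stat.map.values[0, 0, 0] == pytest.approx(ref.statistic)


class TestRegionExclusion:
    def test_untouched_region_gives_exact_unity(self, small_cohort, small_maps):
        grid = small_cohort.grid
        # a region no lesion touches: outside the brain ellipsoid
        ind = np.zeros(grid.shape, dtype=bool)
        ind[0, 0, 0] = True
        table = region_exclusion_robustness(
            small_cohort, None, {"corner": BinaryMask(grid, ind)}, maps=small_maps)
        assert table.loc[0, "spatial_r"] == pytest.approx(1.0, abs=1e-12)
        assert table.loc[0, "n_retained"] == small_cohort.n

    def test_region_hitting_all_lesions_not_estimable(self, small_cohort,
                                                      small_maps):
        grid = small_cohort.grid
        everything = BinaryMask(grid, np.ones(grid.shape, dtype=bool))
        table = region_exclusion_robustness(
            small_cohort, None, {"all": everything}, maps=small_maps)
        assert not table.loc[0, "estimable"]

    def test_distributed_effect_robust_to_exclusions(self, default_cohort,
                                                     default_maps):
        # a fine parcellation (4-voxel blocks), mirroring atlas-based
        # exclusion where each region intersects only a few lesions
        grid = default_cohort.grid
        atlas = {}
        for i0 in range(0, grid.shape[0], 4):
            for j0 in range(0, grid.shape[1], 6):
                for k0 in range(0, grid.shape[2], 4):
                    ind = np.zeros(grid.shape, dtype=bool)
                    ind[i0:i0 + 4, j0:j0 + 6, k0:k0 + 4] = True
                    atlas[f"r{i0}_{j0}_{k0}"] = BinaryMask(grid, ind)
        table = region_exclusion_robustness(default_cohort, None, atlas,
                                            maps=default_maps)
        est = table[table["estimable"]]
        assert len(est) >= 10
        assert est["spatial_r"].median() > 0.9


class TestFWEPeak:
    def test_p_formula_when_observed_tops_all(self, grid10):
        rng = np.random.default_rng(7)
        n = 30
        signal = rng.standard_normal(n)
        matrix = np.column_stack([signal * 3 + rng.standard_normal(n) * 0.01,
                                  rng.standard_normal(n)])
        maps = CohortMaps(matrix=matrix, valid=np.array([True, True]),
                          voxel_index=np.array([0, 1]), grid=grid10,
                          aggregation="tmap")
        lesions = [ball_mask(grid10, (2, 2, 2), 1) for _ in range(n)]
        cohort = LesionCohort(ids=[str(i) for i in range(n)], lesions=lesions,
                              outcome=signal,
                              covariates=pd.DataFrame(index=range(n)))
        pmap, peak = fwe_peak(cohort, covariate_names=(), n_perm=99, seed=1,
                              maps=maps)
        assert peak.p_fwe == pytest.approx(0.01)
        assert peak.voxel == (0, 0, 0)

    def test_single_voxel_mask_equals_uncorrected_p(self, grid10):
        rng = np.random.default_rng(8)
        n = 24
        matrix = rng.standard_normal((n, 1))
        maps = CohortMaps(matrix=matrix, valid=np.array([True]),
                          voxel_index=np.array([0]), grid=grid10,
                          aggregation="tmap")
        lesions = [ball_mask(grid10, (2, 2, 2), 1) for _ in range(n)]
        cohort = LesionCohort(ids=[str(i) for i in range(n)], lesions=lesions,
                              outcome=rng.standard_normal(n),
                              covariates=pd.DataFrame(index=range(n)))
        pmap, peak = fwe_peak(cohort, covariate_names=(), n_perm=199, seed=2,
                              maps=maps)
        # with one voxel, the max statistic is the statistic itself
        obs = abs(partial_correlation(matrix[:, 0], cohort.outcome))
        rng2 = np.random.default_rng(2)
        null = []
        for _ in range(199):
            perm = rng2.permutation(n)
            null.append(abs(partial_correlation(matrix[:, 0],
                                                cohort.outcome[perm])))
        expected = (1 + np.sum(np.asarray(null) >= obs)) / 200
        assert peak.p_fwe == pytest.approx(expected)

    def test_n_perm_minimum_enforced(self, small_cohort, small_maps):
        with pytest.raises(ValueError):
            fwe_peak(small_cohort, n_perm=50, maps=small_maps)


class TestClusterExtent:
    def test_all_voxels_suprathreshold_single_cluster(self, grid10):
        mask = np.ones(grid10.shape, dtype=bool)
        smap = ScalarMap(grid10, np.full(grid10.shape, 10.0), mask)
        table = cluster_extent_threshold(
            smap, detection_p=0.01, n_perm=49, seed=0,
            null_generator=lambda rng: rng.standard_normal(mask.sum()))
        assert len(table) == 1
        assert table.loc[0, "size"] == grid10.n_voxels

    def test_nothing_suprathreshold_empty_table(self, grid10):
        smap = ScalarMap(grid10, np.zeros(grid10.shape))
        table = cluster_extent_threshold(
            smap, detection_p=0.01, n_perm=49, seed=0,
            null_generator=lambda rng: rng.standard_normal(grid10.n_voxels))
        assert table.empty

    def test_planted_focus_detected(self, default_cohort, default_maps,
                                    default_world):
        _, truth = default_world
        circ = derive_circuit(default_cohort, maps=default_maps)
        gen = outcome_permutation_null(default_cohort, default_maps)
        table = cluster_extent_threshold(circ, detection_p=0.01, n_perm=199,
                                         seed=3, null_generator=gen)
        assert not table.empty
        best = table.sort_values("size", ascending=False).iloc[0]
        assert truth.planted_network_mask.indicator[best["peak_voxel"]]
        assert best["p_fwe"] < 0.05
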
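"""Resampling machinery: split-half reproducibility, permutation nulls,
out-of-sample prediction, leave-one-out, network profiling, ROI overlap.

All permutation p-values follow the add-one convention
``p = (1 + exceedances) / (1 + n_perm)``, one-sided in the direction of the
alternative, so p is never exactly zero.  Because the lesion -> connectivity
step is permutation invariant, every resampling routine accepts a cached
:class:`~lnmap.lesion_mapping.CohortMaps` and shuffles only the outcome and
covariate rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, NotEstimableError
from .lesion_mapping import (CircuitMap, CohortMaps, DEFAULT_COVARIATES,
                             LesionCohort, _partial_corr_columns,
                             cohort_connectivity, vlsm_map)
from .connectome import NormativeConnectome
from .volumes import (BinaryMask, ScalarMap, _require_congruent, overlap_sum,
                      spatial_correlation)

logger = logging.getLogger(__name__)


def permutation_pvalue(observed: float, null_samples: np.ndarray,
                       sidedness: str = "right") -> float:
    """Add-one permutation p-value, one-sided."""
    null_samples = np.asarray(null_samples, dtype=float)
    n = null_samples.size
    if sidedness == "right":
        exceed = int(np.sum(null_samples >= observed))
    elif sidedness == "left":
        exceed = int(np.sum(null_samples <= observed))
    else:
        raise ValueError("sidedness must be 'right' or 'left'")
    return (1.0 + exceed) / (1.0 + n)


def variance_explained_pct(r: float) -> float:
    """Percent of variance in one map predictable from another at spatial r."""
    return 100.0 * float(r) ** 2


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the one-sided p-value."""

    observed: float
    null_samples: np.ndarray
    n_perm: int
    p: float
    sidedness: str = "right"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null_samples = np.asarray(self.null_samples, dtype=float)
        if self.null_samples.size != self.n_perm:
            raise ValueError("null_samples length must equal n_perm")
        expected = permutation_pvalue(self.observed, self.null_samples, self.sidedness)
        if not np.isclose(self.p, expected):
            raise ValueError("stored p does not satisfy the add-one p formula")

    @classmethod
    def from_null(cls, observed: float, null_samples: np.ndarray,
                  sidedness: str = "right", seed: int | None = None
                  ) -> "PermutationResult":
        null_samples = np.asarray(null_samples, dtype=float)
        p = permutation_pvalue(observed, null_samples, sidedness)
        return cls(observed=float(observed), null_samples=null_samples,
                   n_perm=null_samples.size, p=p, sidedness=sidedness, seed=seed)


@dataclass
class SplitResult:
    iteration: int
    half_a: np.ndarray
    spatial_r: float
    prediction_r: float | None = None


@dataclass
class SplitHalfResult:
    splits: list[SplitResult]
    mean_spatial_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": [s.iteration for s in self.splits],
                             "spatial_r": [s.spatial_r for s in self.splits]})


# ---------------------------------------------------------------------------
# internal: fast derivation on cached maps
# ---------------------------------------------------------------------------

def _derive_values(maps: CohortMaps, rows: np.ndarray, outcome: np.ndarray,
                   covars: np.ndarray | None) -> np.ndarray:
    """-1 x voxelwise partial r for a row subset, on valid voxels only."""
    sub = maps.matrix[rows]
    c = None if covars is None else covars[rows]
    r, _ = _partial_corr_columns(sub, outcome[rows], c)
    return -r[maps.valid]


def _map_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise DegenerateDataError("constant map in split-half correlation")
    return float((a @ b) / denom)


def _prepare(cohort: LesionCohort, conn, covariate_names, aggregation, maps):
    if maps is None:
        maps = cohort_connectivity(cohort, conn, aggregation)
    covars = cohort.covariate_matrix(covariate_names)
    return maps, covars


def _random_halves(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    return perm[: n // 2 + n % 2], perm[n // 2 + n % 2:]


# ---------------------------------------------------------------------------
# split-half similarity and its permutation null
# ---------------------------------------------------------------------------

def split_half_similarity(cohort: LesionCohort,
                          conn: NormativeConnectome | None = None,
                          covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                          n_splits: int = 100, seed: int = 0,
                          aggregation: str = "tmap",
                          maps: CohortMaps | None = None) -> SplitHalfResult:
    """Spatial correlation between circuits derived in random half-cohorts."""
    if cohort.n < 20:
        raise NotEstimableError("split-half validation needs >= 20 subjects")
    if n_splits < 10:
        raise ValueError("n_splits must be >= 10")
    maps, covars = _prepare(cohort, conn, covariate_names, aggregation, maps)
    outcome = cohort.outcome
    rng = np.random.default_rng(seed)
    splits: list[SplitResult] = []
    for it in range(n_splits):
        half_a, half_b = _random_halves(rng, cohort.n)
        try:
            va = _derive_values(maps, half_a, outcome, covars)
            vb = _derive_values(maps, half_b, outcome, covars)
            r = _map_correlation(va, vb)
        except DegenerateDataError as exc:
            logger.info("split %d skipped: %s", it, exc)
            continue
        splits.append(SplitResult(iteration=it, half_a=half_a, spatial_r=r))
    if not splits:
        raise NotEstimableError("every split failed to derive a circuit")
    mean_r = float(np.mean([s.spatial_r for s in splits]))
    return SplitHalfResult(splits=splits, mean_spatial_r=mean_r)


def permutation_null_similarity(cohort: LesionCohort,
                                conn: NormativeConnectome | None = None,
                                covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                                n_splits: int = 100, n_perm: int = 999,
                                seed: int = 0, aggregation: str = "tmap",
                                maps: CohortMaps | None = None) -> PermutationResult:
    """Is the observed mean split-half similarity larger than chance?

    The null re-runs the identical split-half procedure after randomly
    re-assigning each patient's connectivity map to a different patient's
    outcome (covariates travel with the outcome row); right-sided p.
    """
    maps, covars = _prepare(cohort, conn, covariate_names, aggregation, maps)
    observed = split_half_similarity(
        cohort, covariate_names=covariate_names, n_splits=n_splits,
        seed=seed, maps=maps).mean_spatial_r
    rng_perm = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng_perm.permutation(cohort.n)
        # the split allocation stream is held fixed (same seed as the
        # observed statistic): only the map-to-outcome pairing changes
        res = split_half_similarity(
            cohort, covariate_names=covariate_names, n_splits=n_splits,
            seed=seed, maps=_permuted_maps(maps, perm))
        null[b] = res.mean_spatial_r
    return PermutationResult.from_null(observed, null, "right", seed)


def _permuted_maps(maps: CohortMaps, perm: np.ndarray) -> CohortMaps:
    """Maps with rows re-assigned to different patients' outcome rows."""
    return CohortMaps(maps.matrix[perm], maps.valid, maps.voxel_index,
                      maps.grid, maps.aggregation)


# ---------------------------------------------------------------------------
# out-of-sample prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    prediction_r: np.ndarray
    p: float
    component: str
    mode: str
    n_splits: int
    estimable: bool = True

    @property
    def median_r(self) -> float:
        return float(np.median(self.prediction_r)) if self.prediction_r.size else np.nan


def _overlap_scores(circuit_vals: np.ndarray, lesion_rows: np.ndarray,
                    component: str) -> np.ndarray:
    """Overlap-sum scores of held-out lesions with a derived circuit.

    ``lesion_rows`` is a (m, Vvalid) boolean matrix of lesion coverage on
    the analysis voxels.
    """
    if component == "positive":
        comp = np.clip(circuit_vals, 0.0, None)
    elif component == "negative":
        comp = np.clip(-circuit_vals, 0.0, None)
    else:
        raise ValueError("component must be 'positive' or 'negative'")
    return lesion_rows.astype(float) @ comp


def overlap_prediction_cv(cohort: LesionCohort,
                          conn: NormativeConnectome | None = None,
                          covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                          component: str = "positive",
                          n_splits: int = 100, seed: int = 0,
                          mode: str = "overlap",
                          aggregation: str = "tmap",
                          maps: CohortMaps | None = None) -> PredictionResult:
    """Split-half out-of-sample prediction of outcome from circuit scores.

    Per split: derive a circuit in half A; score each held-out subject in
    half B by lesion overlap with the chosen circuit component
    (``mode="overlap"``) or by spatial correlation of the subject's own
    connectivity map with the circuit (``mode="connectivity_correlation"``);
    prediction r is the Pearson correlation of those scores with the
    *negated* outcome (protective scoring should predict lower scores).
    p is the fraction of splits with non-positive prediction r.
    """
    if cohort.n < 20:
        raise NotEstimableError("prediction CV needs >= 20 subjects")
    maps, covars = _prepare(cohort, conn, covariate_names, aggregation, maps)
    lesion_rows = np.stack([l.indicator.ravel()[maps.voxel_index[maps.valid]]
                            for l in cohort.lesions])
    rng = np.random.default_rng(seed)
    rs = []
    skipped = 0
    for it in range(n_splits):
        half_a, half_b = _random_halves(rng, cohort.n)
        try:
            vals = _derive_values(maps, half_a, cohort.outcome, covars)
        except DegenerateDataError:
            skipped += 1
            continue
        if mode == "overlap":
            scores = _overlap_scores(vals, lesion_rows[half_b], component)
        elif mode == "connectivity_correlation":
            sub = maps.matrix[half_b][:, maps.valid]
            comp_vals = vals if component == "positive" else -vals
            scores = np.array([_map_correlation(row, comp_vals) for row in sub])
        else:
            raise ValueError("mode must be 'overlap' or 'connectivity_correlation'")
        y = cohort.outcome[half_b]
        if np.std(scores) == 0 or np.std(y) == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(scores, -y)[0, 1])
        rs.append(r)
    if not rs:
        return PredictionResult(np.array([]), np.nan, component, mode,
                                n_splits, estimable=False)
    rs = np.asarray(rs)
    p = float(np.mean(rs <= 0.0))
    return PredictionResult(rs, p, component, mode, n_splits)


def loocv_prediction(cohort: LesionCohort,
                     map_builder: str = "lnm",
                     covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                     conn: NormativeConnectome | None = None,
                     component: str = "positive",
                     n_perm: int = 199, seed: int = 0,
                     aggregation: str = "tmap",
                     maps: CohortMaps | None = None,
                     min_lesioned: int = 2, min_spared: int = 2
                     ) -> tuple[float, PermutationResult]:
    """Leave-one-out prediction of outcome from per-subject circuit scores.

    For each subject the map (LNM circuit or VLSM t-map) is rebuilt without
    them and the held-out subject scored by overlap_sum; the held-out scores
    are correlated with the *negated* outcomes (protective convention, as in
    :func:`overlap_prediction_cv`); p by outcome permutation.
    """
    if cohort.n < 10:
        raise NotEstimableError("leave-one-out needs >= 10 subjects")
    if map_builder not in ("lnm", "vlsm"):
        raise ValueError("map_builder must be 'lnm' or 'vlsm'")

    if map_builder == "lnm":
        maps, covars = _prepare(cohort, conn, covariate_names, aggregation, maps)
        lesion_rows = np.stack([l.indicator.ravel()[maps.voxel_index[maps.valid]]
                                for l in cohort.lesions])

        def held_out_scores(outcome: np.ndarray) -> np.ndarray:
            scores = np.empty(cohort.n)
            for i in range(cohort.n):
                rows = np.delete(np.arange(cohort.n), i)
                vals = _derive_values(maps, rows, outcome, covars)
                scores[i] = _overlap_scores(vals, lesion_rows[i:i + 1], component)[0]
            return scores
    else:
        def held_out_scores(outcome: np.ndarray) -> np.ndarray:
            scores = np.empty(cohort.n)
            for i in range(cohort.n):
                rows = np.delete(np.arange(cohort.n), i)
                sub = LesionCohort(ids=[cohort.ids[j] for j in rows],
                                   lesions=[cohort.lesions[j] for j in rows],
                                   outcome=outcome[rows],
                                   covariates=cohort.covariates.iloc[rows])
                stat = vlsm_map(sub, min_lesioned=min_lesioned, min_spared=min_spared)
                scores[i] = overlap_sum(stat.map, cohort.lesions[i],
                                        positive_only=(component == "positive"))
            return scores

    def pred_r(outcome: np.ndarray) -> float:
        s = held_out_scores(outcome)
        if np.std(s) == 0:
            raise DegenerateDataError("constant held-out scores")
        return float(np.corrcoef(s, -outcome)[0, 1])

    observed = pred_r(cohort.outcome)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        try:
            null[b] = pred_r(cohort.outcome[rng.permutation(cohort.n)])
        except DegenerateDataError:
            # a permutation with constant held-out scores carries no
            # predictive information; record zero predictive correlation
            null[b] = 0.0
    return observed, PermutationResult.from_null(observed, null, "right", seed)


# ---------------------------------------------------------------------------
# network profiling and ROI overlap
# ---------------------------------------------------------------------------

def network_similarity_profile(circuit: CircuitMap | ScalarMap,
                               networks: Mapping[str, BinaryMask] | ScalarMap
                               ) -> pd.DataFrame:
    """Spatial correlation of a circuit with each canonical network indicator."""
    cmap = circuit.map if isinstance(circuit, CircuitMap) else circuit
    if isinstance(networks, ScalarMap):
        labels = np.unique(networks.values[networks.analysis_mask & (networks.values != 0)])
        networks = {str(int(lab)): BinaryMask(networks.grid, networks.values == lab)
                    for lab in labels}
    rows = []
    for name, net in networks.items():
        if net.voxel_count == 0:
            logger.warning("network %s is empty; skipped", name)
            continue
        try:
            r = spatial_correlation(cmap, net.to_scalar())
        except DegenerateDataError as exc:
            logger.warning("network %s skipped: %s", name, exc)
            continue
        rows.append({"network": name, "spatial_r": r})
    if not rows:
        return pd.DataFrame(columns=["network", "spatial_r"])
    return pd.DataFrame(rows).sort_values("spatial_r", ascending=False,
                                          ignore_index=True)


def roi_overlap_permutation_test(cohort: LesionCohort,
                                 conn: NormativeConnectome | None = None,
                                 covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                                 roi: BinaryMask | None = None,
                                 n_perm: int = 999, seed: int = 0,
                                 aggregation: str = "tmap",
                                 maps: CohortMaps | None = None) -> PermutationResult:
    """Does the unthresholded circuit overlap an a-priori ROI more than chance?

    Observed statistic: the sum of unthresholded circuit values inside the
    ROI.  Null: the same sum after re-deriving the circuit under an outcome
    permutation each iteration; right-sided p.
    """
    if roi is None or roi.voxel_count == 0:
        raise ValueError("roi must be a non-empty mask")
    maps, covars = _prepare(cohort, conn, covariate_names, aggregation, maps)
    _require_congruent(cohort.grid, roi.grid)
    roi_rows = roi.indicator.ravel()[maps.voxel_index[maps.valid]]
    all_rows = np.arange(cohort.n)
    vals = _derive_values(maps, all_rows, cohort.outcome, covars)
    observed = float(vals[roi_rows].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pm = _permuted_maps(maps, rng.permutation(cohort.n))
        nv = _derive_values(pm, all_rows, cohort.outcome, covars)
        null[b] = nv[roi_rows].sum()
    return PermutationResult.from_null(observed, null, "right", seed)
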
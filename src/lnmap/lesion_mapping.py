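"""Derive symptom circuits from lesions and outcomes; VLSM; permutation FWE.

Lesion network mapping (LNM) regresses, at every brain voxel, the lesions'
normative-connectome connectivity against the behavioural outcome across
patients, controlling for nuisance covariates with partial Pearson
correlation.  The resulting voxel-wise map is sign-inverted so that positive
values mark connectivity whose presence in a lesion's network predicts a
*lower* outcome score (protective connectivity).  Voxel lesion symptom
mapping (VLSM) instead compares outcome scores between patients whose
lesion does versus does not cover each voxel.  Peak localization uses
max-statistic permutation for voxel-level family-wise error control, and
cluster-extent thresholding against a permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import NormativeConnectome, _aggregate_z, batch_seed_z
from .errors import DegenerateDataError, NotEstimableError
from .volumes import (BinaryMask, ScalarMap, VolumeGrid, _require_congruent,
                      load_volume, spatial_correlation)

logger = logging.getLogger(__name__)

#: smallest cohort for which a circuit derivation is attempted
MIN_SUBJECTS = 10
#: default nuisance covariates (lesion size and depression severity)
DEFAULT_COVARIATES = ("lesion_size", "BDI")


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class LesionCohort:
    """Per-subject lesion masks, outcome scores, and covariates.

    ``lesion_size`` is always recomputed from the masks, never trusted from
    input; subjects with missing outcome are dropped (and counted) before
    any analysis.
    """

    ids: list[str]
    lesions: list[BinaryMask]
    outcome: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.lesions) == n and len(self.outcome) == n
                and len(self.covariates) == n):
            raise ValueError("cohort fields must have equal length")
        _require_congruent(*(l.grid for l in self.lesions))
        outcome = np.asarray(self.outcome, dtype=float)
        ok = np.isfinite(outcome)
        if not ok.all():
            logger.info("excluding %d subjects with missing outcome", int((~ok).sum()))
            self.ids = [i for i, k in zip(self.ids, ok) if k]
            self.lesions = [l for l, k in zip(self.lesions, ok) if k]
            self.covariates = self.covariates.loc[ok].reset_index(drop=True)
            outcome = outcome[ok]
        self.outcome = outcome
        cov = self.covariates.reset_index(drop=True).copy()
        cov["lesion_size"] = [l.voxel_count for l in self.lesions]
        self.covariates = cov

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def grid(self) -> VolumeGrid:
        return self.lesions[0].grid

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray | None:
        if not names:
            return None
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"covariates not in cohort table: {missing}")
        return self.covariates.loc[:, list(names)].to_numpy(dtype=float)

    def subset(self, keep: np.ndarray) -> "LesionCohort":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return LesionCohort(
            ids=[self.ids[i] for i in keep],
            lesions=[self.lesions[i] for i in keep],
            outcome=self.outcome[keep],
            covariates=self.covariates.iloc[keep].reset_index(drop=True),
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, base_dir: str | Path = ".") -> "LesionCohort":
        """Build a cohort from a table with id, lesion_path, outcome columns."""
        base = Path(base_dir)
        lesions = [load_volume(base / p, as_mask=True) for p in table["lesion_path"]]
        covars = table.drop(columns=["id", "lesion_path", "outcome"])
        return cls(ids=[str(i) for i in table["id"]], lesions=lesions,
                   outcome=table["outcome"].to_numpy(dtype=float), covariates=covars)


@dataclass
class CircuitMap:
    """A signed circuit map: positive values mark protective connectivity.

    The stored map equals -1 x the voxelwise partial correlation of lesion
    connectivity with the outcome, so positive values mark connections whose
    presence in a lesion's network predicts lower outcome scores.
    """

    map: ScalarMap
    sign_convention: str = "positive=protective"
    covariate_names: tuple[str, ...] = ()
    n_subjects: int = 0
    aggregation: str = "tmap"
    flagged: np.ndarray | None = None  # zero-variance voxels set to 0

    @property
    def grid(self) -> VolumeGrid:
        return self.map.grid

    def positive_part(self) -> ScalarMap:
        return self.map.positive_part()


@dataclass
class StatMap:
    """A voxel-wise statistic map with per-voxel sample-size bookkeeping."""

    map: ScalarMap
    statistic: str
    df: np.ndarray | None = None
    min_lesioned: int | None = None
    min_spared: int | None = None


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return np.column_stack([np.ones(n), covariates])


def _residualizer(design: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the design column space (for I - QQ')."""
    q, r = np.linalg.qr(design)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    if rank < design.shape[1]:
        raise DegenerateDataError("covariate design is rank deficient")
    return q


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None) -> float:
    """Pearson correlation of x and y after residualizing both on covariates.

    With no covariates this reduces to the plain Pearson correlation
    (both variables are still centred by the intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if covariates is None:
        p = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        p = 1 if cov.ndim == 1 else cov.shape[1]
    if n < p + 3:
        raise DegenerateDataError(f"need at least {p + 3} observations, got {n}")
    q = _residualizer(_design(n, covariates))
    xr = x - q @ (q.T @ x)
    yr = y - q @ (q.T @ y)
    sx = float(xr @ xr)
    sy = float(yr @ yr)
    # residual variance below numerical noise relative to the raw variance
    # means the variable is (near-)exactly explained by the covariates
    tol_x = 1e-12 * max(float(x @ x), 1.0)
    tol_y = 1e-12 * max(float(y @ y), 1.0)
    if sx <= tol_x or sy <= tol_y:
        raise DegenerateDataError("zero residual variance: partial correlation undefined")
    return float(np.clip((xr @ yr) / np.sqrt(sx * sy), -1.0, 1.0))


def _partial_corr_columns(X: np.ndarray, y: np.ndarray,
                          covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial correlation of y with every column of X.

    Returns (r, flagged): flagged columns had zero residual variance and
    carry r = 0.
    """
    n = X.shape[0]
    q = _residualizer(_design(n, covariates))
    Xr = X - q @ (q.T @ X)
    yr = y - q @ (q.T @ y)
    sy = float(yr @ yr)
    if sy <= 0:
        raise DegenerateDataError("outcome has zero residual variance")
    sx = np.einsum("ij,ij->j", Xr, Xr)
    flagged = sx <= 1e-12 * max(1.0, float(np.max(sx, initial=0.0)))
    denom = np.sqrt(np.where(flagged, 1.0, sx) * sy)
    r = np.clip((yr @ Xr) / denom, -1.0, 1.0)
    r[flagged] = 0.0
    return r, flagged


# ---------------------------------------------------------------------------
# cached cohort connectivity
# ---------------------------------------------------------------------------

@dataclass
class CohortMaps:
    """Per-lesion aggregated connectivity maps, cached for resampling.

    The lesion -> connectivity-map step is permutation invariant, so all
    resampling procedures reuse this matrix and shuffle only outcome and
    covariate rows.
    """

    matrix: np.ndarray          # n_subjects x V (aggregated across connectome)
    valid: np.ndarray           # V bool, valid in every connectome subject
    voxel_index: np.ndarray     # V flat grid indices
    grid: VolumeGrid
    aggregation: str

    def to_scalar_map(self, values: np.ndarray, flagged: np.ndarray | None = None) -> ScalarMap:
        vol = np.zeros(self.grid.n_voxels)
        msk = np.zeros(self.grid.n_voxels, dtype=bool)
        vol[self.voxel_index] = np.where(self.valid, values, 0.0)
        msk[self.voxel_index] = self.valid
        return ScalarMap(self.grid, vol.reshape(self.grid.shape),
                         msk.reshape(self.grid.shape))


def cohort_connectivity(cohort: LesionCohort, conn: NormativeConnectome,
                        aggregation: str = "tmap") -> CohortMaps:
    """Compute every lesion's aggregated connectivity map in one pass."""
    z, valid = batch_seed_z(conn, cohort.lesions)
    agg = _aggregate_z(z.astype(np.float64), aggregation)
    return CohortMaps(matrix=agg, valid=valid, voxel_index=conn.voxel_index,
                      grid=conn.grid, aggregation=aggregation)


# ---------------------------------------------------------------------------
# circuit derivation
# ---------------------------------------------------------------------------

def derive_circuit(cohort: LesionCohort, conn: NormativeConnectome | None = None,
                   covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                   aggregation: str = "tmap",
                   maps: CohortMaps | None = None) -> CircuitMap:
    """Derive the protective circuit from lesion connectivity and outcomes.

    At each analysis voxel, the partial Pearson correlation (controlling
    for the named covariates) between lesion connectivity and outcome is
    computed across patients and negated, so positive circuit values mark
    protective connectivity.  Voxels with zero connectivity variance across
    patients are set to 0 and flagged.
    """
    if cohort.n < MIN_SUBJECTS:
        raise NotEstimableError(f"circuit derivation needs >= {MIN_SUBJECTS} subjects")
    if maps is None:
        if conn is None:
            raise ValueError("provide either a connectome or precomputed maps")
        maps = cohort_connectivity(cohort, conn, aggregation)
    covars = cohort.covariate_matrix(covariate_names)
    r, flagged = _partial_corr_columns(maps.matrix, cohort.outcome, covars)
    smap = maps.to_scalar_map(-r)
    return CircuitMap(map=smap, covariate_names=tuple(covariate_names),
                      n_subjects=cohort.n, aggregation=maps.aggregation,
                      flagged=flagged)


# ---------------------------------------------------------------------------
# VLSM
# ---------------------------------------------------------------------------

#: t value substituted when the pooled variance is zero but means differ
#: (perfect group separation carries unbounded evidence)
VLSM_T_CAP = 100.0


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Two-sample pooled-variance t for mean(a) - mean(b)."""
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((a - a.mean()) @ (a - a.mean()) + (b - b.mean()) @ (b - b.mean())) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return float(np.sign(diff) * VLSM_T_CAP), df
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), df


def vlsm_map(cohort: LesionCohort, min_lesioned: int = 4, min_spared: int = 4,
             welch: bool = False) -> StatMap:
    """Voxel lesion symptom mapping: unpaired t at each sufficiently covered voxel.

    The statistic is mean(spared) - mean(lesioned), so positive t marks
    voxels where lesions associate with lower outcome (protective).  Voxels
    failing the minimum-overlap thresholds are excluded from the analysis
    mask.
    """
    from scipy import stats as sps
    if min_lesioned < 2 or min_spared < 2:
        raise ValueError("minimum counts must be >= 2")
    grid = cohort.grid
    L = np.stack([l.indicator.ravel() for l in cohort.lesions])  # n x Vfull
    y = cohort.outcome
    n_les = L.sum(axis=0)
    n_spa = cohort.n - n_les
    eligible = (n_les >= min_lesioned) & (n_spa >= min_spared)
    tvals = np.zeros(grid.n_voxels)
    dfs = np.zeros(grid.n_voxels)
    if not eligible.any():
        logger.warning("VLSM: no voxel meets the minimum-overlap thresholds")
    idx = np.flatnonzero(eligible)
    if welch:
        for v in idx:
            les = y[L[:, v]]
            spa = y[~L[:, v]]
            res = sps.ttest_ind(spa, les, equal_var=False)
            tvals[v], dfs[v] = res.statistic, res.df
    else:
        # vectorized pooled t over eligible voxels
        Le = L[:, idx].astype(float)
        nl = Le.sum(axis=0)
        ns = cohort.n - nl
        sum_les = y @ Le
        mean_les = sum_les / nl
        mean_spa = (y.sum() - sum_les) / ns
        sum2_les = (y ** 2) @ Le
        ss_les = sum2_les - nl * mean_les ** 2
        ss_spa = ((y ** 2).sum() - sum2_les) - ns * mean_spa ** 2
        df = nl + ns - 2
        sp2 = (ss_les + ss_spa) / df
        denom = np.sqrt(np.clip(sp2, 0.0, None) * (1 / nl + 1 / ns))
        diff = mean_spa - mean_les
        with np.errstate(invalid="ignore", divide="ignore"):
            # zero pooled variance with a mean difference is perfect
            # separation: substitute a signed cap rather than losing it
            t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                         np.sign(diff) * VLSM_T_CAP)
        tvals[idx] = t
        dfs[idx] = df
    smap = ScalarMap(grid, tvals.reshape(grid.shape),
                     eligible.reshape(grid.shape))
    return StatMap(map=smap, statistic="t", df=dfs.reshape(grid.shape),
                   min_lesioned=min_lesioned, min_spared=min_spared)


# ---------------------------------------------------------------------------
# robustness to region exclusion
# ---------------------------------------------------------------------------

def region_exclusion_robustness(cohort: LesionCohort,
                                conn: NormativeConnectome | None,
                                atlas: ScalarMap | Mapping[str, BinaryMask],
                                covariate_names: Sequence[str] = DEFAULT_COVARIATES,
                                aggregation: str = "tmap",
                                maps: CohortMaps | None = None) -> pd.DataFrame:
    """Re-derive the circuit after excluding lesions touching each region.

    For every atlas region, subjects whose lesion intersects it are dropped
    and the circuit re-derived; the spatial correlation with the full-cohort
    circuit is recorded.  Regions whose exclusion leaves fewer than the
    minimum number of subjects are marked not estimable.
    """
    if maps is None:
        maps = cohort_connectivity(cohort, conn, aggregation)
    full = derive_circuit(cohort, covariate_names=covariate_names, maps=maps)
    if isinstance(atlas, ScalarMap):
        labels = np.unique(atlas.values[atlas.analysis_mask & (atlas.values != 0)])
        regions = {str(int(lab)): BinaryMask(atlas.grid, atlas.values == lab)
                   for lab in labels}
    else:
        regions = dict(atlas)
    rows = []
    for name, region in regions.items():
        _require_congruent(cohort.grid, region.grid)
        hits = np.array([bool((l.indicator & region.indicator).any())
                         for l in cohort.lesions])
        keep = ~hits
        if keep.sum() < MIN_SUBJECTS:
            rows.append({"region": name, "n_retained": int(keep.sum()),
                         "spatial_r": np.nan, "estimable": False})
            continue
        sub_maps = CohortMaps(maps.matrix[keep], maps.valid, maps.voxel_index,
                              maps.grid, maps.aggregation)
        circ = derive_circuit(cohort.subset(keep), covariate_names=covariate_names,
                              maps=sub_maps)
        r = spatial_correlation(circ.map, full.map)
        rows.append({"region": name, "n_retained": int(keep.sum()),
                     "spatial_r": r, "estimable": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation FWE peak
# ---------------------------------------------------------------------------

@dataclass
class PeakRecord:
    voxel: tuple[int, int, int]
    mm: tuple[float, float, float]
    statistic: float
    p_fwe: float


def permute_rows(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.permutation(n)


def fwe_peak(cohort: LesionCohort, conn: NormativeConnectome | None = None,
             covariate_names: Sequence[str] = DEFAULT_COVARIATES,
             n_perm: int = 999, seed: int = 0,
             aggregation: str = "tmap",
             maps: CohortMaps | None = None) -> tuple[ScalarMap, PeakRecord]:
    """Voxel-level FWE-corrected p map by max-statistic permutation.

    The observed statistic is |partial r| per voxel; outcome and covariate
    rows are permuted jointly against the connectivity maps; the null is the
    per-permutation maximum over voxels.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if maps is None:
        maps = cohort_connectivity(cohort, conn, aggregation)
    covars = cohort.covariate_matrix(covariate_names)
    obs, _ = _partial_corr_columns(maps.matrix, cohort.outcome, covars)
    obs = np.abs(obs)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = permute_rows(rng, cohort.n)
        cperm = None if covars is None else covars[perm]
        r, _ = _partial_corr_columns(maps.matrix, cohort.outcome[perm], cperm)
        max_null[b] = np.abs(r).max()
    exceed = (max_null[None, :] >= obs[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + n_perm)
    pmap = maps.to_scalar_map(p)
    # outside-mask voxels carry p=0 placeholders; set them to 1 for safety
    pmap.values[~pmap.analysis_mask] = 0.0
    flat_p = np.where(pmap.analysis_mask.ravel(), pmap.values.ravel(), np.inf)
    peak_flat = int(np.argmin(flat_p))  # ties -> lowest scan-order index
    voxel = tuple(int(i) for i in np.unravel_index(peak_flat, maps.grid.shape))
    stat_map = maps.to_scalar_map(obs)
    return pmap, PeakRecord(
        voxel=voxel,
        mm=tuple(round(float(c)) for c in maps.grid.voxel_to_world(voxel)),
        statistic=float(stat_map.values[voxel]),
        p_fwe=float(pmap.values[voxel]),
    )


# ---------------------------------------------------------------------------
# cluster extent thresholding
# ---------------------------------------------------------------------------

def cluster_extent_threshold(stat_map: StatMap | CircuitMap | ScalarMap,
                             detection_p: float, n_perm: int, seed: int,
                             null_generator: Callable[[np.random.Generator], np.ndarray]
                             ) -> pd.DataFrame:
    """Cluster table (size, peak, cluster p_FWE) from a permutation null.

    ``null_generator(rng)`` must return one null statistic map (1-D array on
    the analysis mask) per call, consistent with the observed statistic.
    The voxel detection threshold is the (1 - detection_p) quantile of the
    pooled null magnitudes; cluster p_FWE comes from the permutation
    distribution of the largest null 26-connected cluster size.
    """
    from .connectome import label_clusters
    if not (0.0 < detection_p < 0.5):
        raise ValueError("detection_p must lie in (0, 0.5)")
    smap = stat_map.map if isinstance(stat_map, (StatMap, CircuitMap)) else stat_map
    mask = smap.analysis_mask
    rng = np.random.default_rng(seed)
    nulls = [np.abs(np.asarray(null_generator(rng), dtype=float)) for _ in range(n_perm)]
    pooled = np.concatenate(nulls)
    thr = float(np.quantile(pooled, 1.0 - detection_p))
    # null distribution of the largest suprathreshold cluster
    max_sizes = np.zeros(n_perm)
    shape = smap.grid.shape
    for b, nv in enumerate(nulls):
        vol = np.zeros(shape, dtype=bool)
        vol[mask] = nv > thr
        labels, k = label_clusters(vol)
        if k:
            max_sizes[b] = np.bincount(labels.ravel())[1:].max()
    supra = mask & (np.abs(smap.values) > thr)
    labels, k = label_clusters(supra)
    rows = []
    for lab in range(1, k + 1):
        in_cluster = labels == lab
        size = int(in_cluster.sum())
        vals = np.where(in_cluster, np.abs(smap.values), -np.inf)
        peak = tuple(int(i) for i in np.unravel_index(int(np.argmax(vals)), shape))
        p = float((1.0 + np.sum(max_sizes >= size)) / (1.0 + n_perm))
        rows.append({"cluster": lab, "size": size, "peak_voxel": peak,
                     "peak_value": float(smap.values[peak]), "p_fwe": p})
    return pd.DataFrame(rows, columns=["cluster", "size", "peak_voxel",
                                       "peak_value", "p_fwe"])


def outcome_permutation_null(cohort: LesionCohort, maps: CohortMaps,
                             covariate_names: Sequence[str] = DEFAULT_COVARIATES
                             ) -> Callable[[np.random.Generator], np.ndarray]:
    """A null generator for :func:`cluster_extent_threshold` on circuit maps.

    Each call re-derives the voxelwise partial-correlation map under a fresh
    outcome (plus covariate-row) permutation and returns it on the mask.
    """
    covars = cohort.covariate_matrix(covariate_names)

    def gen(rng: np.random.Generator) -> np.ndarray:
        perm = rng.permutation(cohort.n)
        cperm = None if covars is None else covars[perm]
        r, _ = _partial_corr_columns(maps.matrix, cohort.outcome[perm], cperm)
        return r[maps.valid] if maps.valid is not None else r

    return gen
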
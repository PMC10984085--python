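"""Seed-based functional connectivity against a normative connectome.

The normative-connectome approach estimates the whole-brain resting-state
functional connectivity (rsFC) of an arbitrary seed — a binary lesion
tracing or a weighted circuit map — from a reference set of healthy-subject
BOLD timeseries.  For each connectome subject the seed's reference
timecourse (the weighted mean of its voxel timecourses) is correlated with
every brain voxel, Fisher z-transformed, and the per-subject z-maps are
aggregated across subjects, by default as a one-sample t-map.

Conventions
-----------
* voxel timecourses are standardized (zero mean, unit variance over time)
  before any correlation; zero-variance voxels are excluded from targets;
* weighted seeds use only their positive weights, both for the reference
  timecourse and for weighted averages of z values;
* correlations are clipped to ``|r| <= 1 - 1e-6`` before ``atanh`` so the
  Fisher z values stay finite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import (DegenerateDataError, DimensionalityError, EmptySeedError,
                     GridError, NotEstimableError)
from .volumes import BinaryMask, ScalarMap, VolumeGrid, _require_congruent

logger = logging.getLogger(__name__)

#: correlation clip bound applied before the Fisher transform
R_CLIP = 1.0 - 1e-6
#: t value substituted at voxels with zero variance across subjects
T_CAP_DEFAULT = 100.0


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r) after clipping |r| to ``R_CLIP``.

    Computed in float64 so the clip bound survives single-precision inputs.
    """
    return np.arctanh(np.clip(np.asarray(r, dtype=np.float64), -R_CLIP, R_CLIP))


@dataclass
class SubjectTimeseries:
    """A T x V BOLD matrix for one subject on a shared grid.

    ``voxel_index`` maps matrix columns to flat (C-order) voxel indices of
    ``grid``.  Columns with zero temporal variance are flagged and excluded
    from correlation targets.
    """

    grid: VolumeGrid
    data: np.ndarray
    tr_seconds: float = 2.0
    voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim != 2:
            raise DimensionalityError("timeseries data must be a T x V matrix")
        if data.shape[0] < 3:
            raise DegenerateDataError("timeseries needs T >= 3 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.voxel_index is None:
            if data.shape[1] != self.grid.n_voxels:
                raise GridError("without voxel_index, V must equal the full grid size")
            vi = np.arange(self.grid.n_voxels)
        else:
            vi = np.asarray(self.voxel_index, dtype=np.intp)
            if vi.shape != (data.shape[1],):
                raise GridError("voxel_index length must match number of columns")
        self.data = data
        self.voxel_index = vi
        self._std: np.ndarray | None = None
        self._valid: np.ndarray | None = None

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def standardized(self) -> tuple[np.ndarray, np.ndarray]:
        """(T x V standardized data, valid-column flags); cached."""
        if self._std is None:
            x = self.data.astype(np.float32)
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            valid = sd > 0
            sd_safe = np.where(valid, sd, 1.0)
            self._std = (x - mu) / sd_safe
            self._std[:, ~valid] = 0.0
            self._valid = valid
        return self._std, self._valid

    def column_of_flat(self, flat_indices: np.ndarray) -> np.ndarray:
        """Columns corresponding to flat grid voxel indices (-1 if absent)."""
        lookup = np.full(self.grid.n_voxels, -1, dtype=np.intp)
        lookup[self.voxel_index] = np.arange(self.n_voxels)
        return lookup[flat_indices]


@dataclass
class NormativeConnectome:
    """An ordered set of subject timeseries on one shared grid."""

    subjects: list[SubjectTimeseries]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("a normative connectome needs at least one subject")
        _require_congruent(*(s.grid for s in self.subjects))
        ref = self.subjects[0].voxel_index
        for s in self.subjects[1:]:
            if not np.array_equal(s.voxel_index, ref):
                raise GridError("all connectome subjects must share one voxel index")

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def grid(self) -> VolumeGrid:
        return self.subjects[0].grid

    @property
    def voxel_index(self) -> np.ndarray:
        return self.subjects[0].voxel_index


@dataclass
class ConnectivityMap(ScalarMap):
    """A ScalarMap carrying connectivity provenance.

    ``aggregation`` is one of ``"per_subject"`` (Fisher z from one subject),
    ``"mean_z"`` or ``"tmap"`` (aggregated across connectome subjects).
    """

    aggregation: str = "per_subject"
    seed_descriptor: str = ""
    n_subjects: int = 1


# ---------------------------------------------------------------------------
# seed handling
# ---------------------------------------------------------------------------

def _seed_weights(seed: BinaryMask | ScalarMap) -> tuple[np.ndarray, np.ndarray]:
    """Flat voxel indices and positive weights defining a seed."""
    if isinstance(seed, BinaryMask):
        flat = np.flatnonzero(seed.indicator.ravel())
        w = np.ones(flat.size)
    else:
        vals = np.where(seed.analysis_mask, seed.values, 0.0).ravel()
        flat = np.flatnonzero(vals > 0)
        w = vals[flat]
    if flat.size == 0:
        raise EmptySeedError("seed has no voxels with positive weight")
    return flat, w


def _reference_timecourse(subject: SubjectTimeseries,
                          seed: BinaryMask | ScalarMap) -> np.ndarray:
    """Positive-weight-weighted mean of standardized seed-voxel timecourses."""
    flat, w = _seed_weights(seed)
    cols = subject.column_of_flat(flat)
    keep = cols >= 0
    x, valid = subject.standardized()
    cols, w = cols[keep], w[keep]
    if cols.size:
        vkeep = valid[cols]
        cols, w = cols[vkeep], w[vkeep]
    if cols.size == 0:
        raise EmptySeedError("seed lies entirely outside valid timeseries voxels")
    ref = x[:, cols] @ (w / w.sum())
    if ref.std() == 0:
        raise DegenerateDataError("seed reference timecourse has zero variance")
    return ref


def _corr_with_reference(subject: SubjectTimeseries, ref: np.ndarray) -> np.ndarray:
    """Pearson r of a reference timecourse with every valid voxel column."""
    x, valid = subject.standardized()
    t = x.shape[0]
    ref_std = (ref - ref.mean()) / ref.std()
    r = (ref_std.astype(np.float32) @ x) / t
    r[~valid] = np.nan
    return r


def seed_map(subject: SubjectTimeseries,
             seed: BinaryMask | ScalarMap) -> ConnectivityMap:
    """Per-subject whole-brain Fisher-z connectivity map of a seed.

    The reference timecourse is the (positive-weight) mean of the seed-voxel
    timecourses; the map value at voxel v is ``atanh(clip(r(ref, v)))``.
    Seed voxels are included in the output.
    """
    ref = _reference_timecourse(subject, seed)
    r = _corr_with_reference(subject, ref)
    z = fisher_z(np.nan_to_num(r))
    return _z_to_map(subject, z, ~np.isnan(r), "per_subject", _describe_seed(seed), 1)


def _describe_seed(seed: BinaryMask | ScalarMap) -> str:
    if isinstance(seed, BinaryMask):
        return f"binary seed ({seed.voxel_count} voxels)"
    return "weighted seed (positive part)"


def _z_to_map(subject_like, z_cols: np.ndarray, valid_cols: np.ndarray,
              aggregation: str, descriptor: str, n: int) -> ConnectivityMap:
    grid = subject_like.grid
    vol = np.zeros(grid.n_voxels)
    msk = np.zeros(grid.n_voxels, dtype=bool)
    vi = subject_like.voxel_index
    vol[vi] = np.where(valid_cols, z_cols, 0.0)
    msk[vi] = valid_cols
    return ConnectivityMap(grid, vol.reshape(grid.shape), msk.reshape(grid.shape),
                           aggregation=aggregation, seed_descriptor=descriptor,
                           n_subjects=n)


# ---------------------------------------------------------------------------
# batched per-subject maps (shared by lesion_network_map and lesion_mapping)
# ---------------------------------------------------------------------------

def batch_seed_z(conn: NormativeConnectome,
                 seeds: Sequence[BinaryMask | ScalarMap]) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject Fisher-z maps for many seeds at once.

    Returns ``(z, valid)`` where ``z`` has shape (n_subjects, n_seeds, V)
    and ``valid`` flags columns valid in every subject.  This is the hot
    path of cohort-level lesion network mapping: for each connectome subject
    all seed reference timecourses are formed jointly and correlated with
    all voxels in one matrix product.
    """
    n_seeds = len(seeds)
    sub0 = conn.subjects[0]
    weights = np.zeros((n_seeds, sub0.n_voxels), dtype=np.float32)
    for i, seed in enumerate(seeds):
        flat, w = _seed_weights(seed)
        cols = sub0.column_of_flat(flat)
        keep = cols >= 0
        if not keep.any():
            raise EmptySeedError(f"seed {i} lies outside the connectome voxels")
        weights[i, cols[keep]] = w[keep] / w[keep].sum()
    out = np.empty((conn.n, n_seeds, sub0.n_voxels), dtype=np.float32)
    valid_all = np.ones(sub0.n_voxels, dtype=bool)
    for s_idx, subject in enumerate(conn.subjects):
        x, valid = subject.standardized()
        valid_all &= valid
        refs = weights @ x.T                     # n_seeds x T
        mu = refs.mean(axis=1, keepdims=True)
        sd = refs.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateDataError("a seed produced a zero-variance reference")
        refs = (refs - mu) / sd
        r = (refs @ x) / x.shape[0]              # n_seeds x V
        out[s_idx] = fisher_z(r)
    return out, valid_all


def _aggregate_z(z: np.ndarray, aggregation: str,
                 t_cap: float = T_CAP_DEFAULT) -> np.ndarray:
    """Aggregate (n_subjects, ...) Fisher-z values across subjects."""
    n = z.shape[0]
    if aggregation == "mean_z":
        return z.mean(axis=0)
    if aggregation == "tmap":
        if n < 2:
            raise DegenerateDataError("tmap aggregation needs at least 2 subjects")
        mean = z.mean(axis=0)
        sd = z.std(axis=0, ddof=1)
        zero_sd = sd == 0
        if np.any(zero_sd):
            logger.warning("tmap: %d voxels with zero sd capped at +/-%g",
                           int(np.sum(zero_sd)), t_cap)
        t = np.where(zero_sd, np.sign(mean) * t_cap,
                     mean / np.where(zero_sd, 1.0, sd / np.sqrt(n)))
        return t
    raise ValueError(f"unknown aggregation {aggregation!r} (use 'tmap' or 'mean_z')")


def lesion_network_map(conn: NormativeConnectome,
                       seed: BinaryMask | ScalarMap,
                       aggregation: str = "tmap",
                       t_cap: float = T_CAP_DEFAULT) -> ConnectivityMap:
    """Aggregate a seed's per-subject connectivity across the connectome.

    ``aggregation="tmap"`` (default) returns the one-sample t statistic of
    the Fisher-z values across subjects; ``"mean_z"`` their mean.
    """
    z, valid = batch_seed_z(conn, [seed])
    agg = _aggregate_z(z[:, 0, :], aggregation, t_cap)
    return _z_to_map(conn.subjects[0], agg, valid, aggregation,
                     _describe_seed(seed), conn.n)


# ---------------------------------------------------------------------------
# scalar connectivity summaries
# ---------------------------------------------------------------------------

def within_circuit_connectivity(subject: SubjectTimeseries,
                                circuit: ScalarMap) -> float:
    """Weighted-mean Fisher z of a circuit's seed map over its own voxels.

    The positive part of the circuit is treated as a weighted seed; the
    returned scalar is the positive-weight-weighted mean of the z map over
    the circuit voxels (seed voxels included).
    """
    pos = circuit.positive_part() if isinstance(circuit, ScalarMap) else circuit
    zmap = seed_map(subject, pos)
    flat, w = _seed_weights(pos)
    cols = subject.column_of_flat(flat)
    keep = cols >= 0
    cols, w = cols[keep], w[keep]
    _, valid = subject.standardized()
    vkeep = valid[cols]
    cols, w = cols[vkeep], w[vkeep]
    if cols.size < 1:
        raise EmptySeedError("circuit has no valid positive voxels")
    zvals = zmap.values.ravel()[subject.voxel_index[cols]]
    return float(zvals @ (w / w.sum()))


def pairwise_network_connectivity(subject: SubjectTimeseries,
                                  roi_a: ScalarMap | BinaryMask,
                                  roi_b: ScalarMap | BinaryMask) -> float:
    """Fisher z between two ROI reference timecourses.

    The within-ROI case (identical ROIs) delegates to
    :func:`within_circuit_connectivity`.
    """
    if roi_a is roi_b:
        sa = roi_a if isinstance(roi_a, ScalarMap) else roi_a.to_scalar()
        return within_circuit_connectivity(subject, sa)
    ref_a = _reference_timecourse(subject, roi_a)
    ref_b = _reference_timecourse(subject, roi_b)
    # explicit symmetric formula: f(a, b) == f(b, a) exactly
    za = (ref_a - ref_a.mean()) / ref_a.std()
    zb = (ref_b - ref_b.mean()) / ref_b.std()
    r = float(za @ zb) / len(za)
    return float(fisher_z(r))


def site_to_circuit_connectivity(subject: SubjectTimeseries,
                                 site: BinaryMask,
                                 circuit: ScalarMap) -> float:
    """rsFC between a stimulation site and the positive circuit component."""
    return pairwise_network_connectivity(subject, site, circuit.positive_part())


def targeting_atlas(conn: NormativeConnectome, circuit: ScalarMap,
                    aggregation: str = "tmap") -> ConnectivityMap:
    """Whole-brain normative connectivity to a circuit (TMS targeting atlas).

    Positive peaks are candidate excitatory targets; negative peaks are
    candidate inhibitory targets.
    """
    return lesion_network_map(conn, circuit.positive_part(), aggregation)


def individualized_circuit_map(subject: SubjectTimeseries,
                               circuit: ScalarMap) -> ConnectivityMap:
    """A circuit's connectivity map on one individual's own data."""
    return seed_map(subject, circuit.positive_part())


# ---------------------------------------------------------------------------
# peak target selection
# ---------------------------------------------------------------------------

@dataclass
class TargetRecord:
    """Outcome of peak/cluster-based TMS target selection."""

    peak_voxel: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_value: float
    largest_cluster_id: int
    largest_cluster_size: int
    peak_in_largest_cluster: bool
    threshold: float


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def label_clusters(suprathreshold: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected component labelling of a boolean volume."""
    from scipy import ndimage
    return ndimage.label(suprathreshold, structure=_CONN26)


def select_peak_target(cmap: ScalarMap, accessibility: BinaryMask,
                       detection_quantile: float = 0.95) -> TargetRecord:
    """Choose a stimulation target from a connectivity map.

    Among accessible voxels the map is thresholded at the
    ``detection_quantile`` of accessible values; 26-connected clusters are
    labelled; the record reports the global accessible peak, the largest
    cluster, and whether they agree.  Ties break toward the lowest linear
    voxel index in scan order.
    """
    _require_congruent(cmap.grid, accessibility.grid)
    if not (0.0 < detection_quantile < 1.0):
        raise ValueError("detection_quantile must lie in (0, 1)")
    acc = accessibility.indicator & cmap.analysis_mask
    if not acc.any():
        raise EmptySeedError("accessibility mask is empty on the analysis mask")
    vals = cmap.values
    thr = float(np.quantile(vals[acc], detection_quantile))
    supra = acc & (vals > thr)
    if not supra.any():
        raise NotEstimableError("no accessible voxel above the detection threshold")
    labels, n_clusters = label_clusters(supra)
    sizes = np.bincount(labels.ravel())[1:]
    # largest cluster; size ties -> cluster containing the lowest flat index
    max_size = sizes.max()
    tied = np.flatnonzero(sizes == max_size) + 1
    if tied.size > 1:
        firsts = [np.flatnonzero((labels == lab).ravel())[0] for lab in tied]
        largest = int(tied[int(np.argmin(firsts))])
    else:
        largest = int(tied[0])
    flat_vals = np.where(supra.ravel(), vals.ravel(), -np.inf)
    peak_flat = int(np.argmax(flat_vals))  # argmax returns first (lowest) index on ties
    peak_voxel = tuple(int(i) for i in np.unravel_index(peak_flat, cmap.grid.shape))
    peak_mm = tuple(round(float(c)) for c in cmap.grid.voxel_to_world(peak_voxel))
    return TargetRecord(
        peak_voxel=peak_voxel,
        peak_mm=peak_mm,
        peak_value=float(vals[peak_voxel]),
        largest_cluster_id=largest,
        largest_cluster_size=int(max_size),
        peak_in_largest_cluster=bool(labels[peak_voxel] == largest),
        threshold=thr,
    )


# ---------------------------------------------------------------------------
# 4-D I/O and manifests
# ---------------------------------------------------------------------------

def load_timeseries(path: str | Path, tr_seconds: float | None = None,
                    mask: BinaryMask | None = None) -> SubjectTimeseries:
    """Read a 4-D NIfTI BOLD run as a :class:`SubjectTimeseries`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"{path} is {data.ndim}-D; expected a 4-D BOLD run")
    grid = VolumeGrid(tuple(data.shape[:3]), np.asarray(img.affine))
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    flat = data.reshape(-1, data.shape[3]).T  # T x V over the full grid
    if mask is not None:
        _require_congruent(grid, mask.grid)
        vi = np.flatnonzero(mask.indicator.ravel())
        return SubjectTimeseries(grid, flat[:, vi], tr_seconds, vi)
    return SubjectTimeseries(grid, flat, tr_seconds)


def load_connectome(manifest_path: str | Path,
                    mask: BinaryMask | None = None) -> NormativeConnectome:
    """Load a connectome from a JSON manifest: {"subjects": [{"path", "tr"}...]}."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    subjects = []
    for entry in manifest["subjects"]:
        p = Path(entry["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        subjects.append(load_timeseries(p, entry.get("tr"), mask=mask))
    return NormativeConnectome(subjects)
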
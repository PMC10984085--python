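"""Connectome-wide association via multivariate distance matrix regression.

MDMR asks, voxel by voxel, whether inter-subject differences in that
voxel's whole-brain connectivity profile are explained by a predictor of
interest (e.g. diagnosis) after adjusting for covariates.  For each voxel
the n x n matrix of profile distances is Gower-centred and a partial
pseudo-F is formed from hat-matrix traces; significance comes from
Freedman-Lane residual permutation.  A derived circuit can then be tested
for enrichment: the odds ratio that suprathreshold (PTSD-associated)
voxels fall inside the circuit rather than outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import SubjectTimeseries
from .errors import DegenerateDataError, NotEstimableError
from .validation import PermutationResult
from .volumes import BinaryMask, _require_congruent

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """An n x p design with an intercept, effect columns, and covariates."""

    matrix: np.ndarray
    effect_cols: tuple[int, ...]
    covariate_cols: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        self.matrix = X
        self.effect_cols = tuple(self.effect_cols)
        self.covariate_cols = tuple(self.covariate_cols)
        if set(self.effect_cols) & set(self.covariate_cols):
            raise ValueError("effect and covariate columns must be disjoint")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDataError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @property
    def reduced(self) -> np.ndarray:
        keep = [j for j in range(self.p) if j not in self.effect_cols]
        return self.matrix[:, keep]

    @classmethod
    def from_columns(cls, effect: np.ndarray,
                     covariates: np.ndarray | None = None) -> "DesignMatrix":
        effect = np.atleast_2d(np.asarray(effect, dtype=float).T).T
        n = effect.shape[0]
        cols = [np.ones((n, 1)), effect]
        eff_idx = tuple(range(1, 1 + effect.shape[1]))
        cov_idx: tuple[int, ...] = ()
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float).T).T
            cols.append(covariates)
            start = 1 + effect.shape[1]
            cov_idx = tuple(range(start, start + covariates.shape[1]))
        return cls(np.hstack(cols), eff_idx, cov_idx)


def validate_distance_matrix(d: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=atol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=atol):
        raise ValueError("distance matrix must have zero diagonal")
    if (d < -atol).any():
        raise ValueError("distance matrix must be non-negative")
    return d


def connectivity_profile_distance(subjects: Sequence[SubjectTimeseries],
                                  voxel: int) -> np.ndarray:
    """Inter-subject distances between one voxel's connectivity profiles.

    Per subject the profile is the Fisher-z seed map of that voxel on the
    subject's own data; d_ij = sqrt(2 * (1 - Pearson(profile_i, profile_j))).
    ``voxel`` is a flat grid index.
    """
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    profiles = profile_matrix(subjects, np.array([voxel]))[:, 0, :]
    return profile_distance_from_profiles(profiles)


def profile_matrix(subjects: Sequence[SubjectTimeseries],
                   voxels: np.ndarray) -> np.ndarray:
    """(n_subjects, n_voxels, V) Fisher-z profiles of seed voxels.

    Restricted to target voxels valid in every subject; each subject's own
    data provide the profiles.
    """
    from .connectome import fisher_z
    _require_congruent(*(s.grid for s in subjects))
    valid_all = np.ones(subjects[0].n_voxels, dtype=bool)
    for s in subjects:
        _, valid = s.standardized()
        valid_all &= valid
    out = np.empty((len(subjects), len(voxels), int(valid_all.sum())),
                   dtype=np.float32)
    for i, s in enumerate(subjects):
        x, _ = s.standardized()
        cols = s.column_of_flat(np.asarray(voxels))
        if (cols < 0).any():
            raise ValueError("a seed voxel is outside the subjects' voxel set")
        seeds = x[:, cols]  # already standardized; invalid columns are all-zero
        if (seeds.std(axis=0) == 0).any():
            raise DegenerateDataError("a seed voxel has constant timecourse")
        out[i] = fisher_z((seeds.T @ x[:, valid_all]) / x.shape[0])
    return out


def profile_distance_from_profiles(profiles: np.ndarray) -> np.ndarray:
    """d_ij = sqrt(2(1 - r_ij)) from an (n, V) profile matrix."""
    P = np.asarray(profiles, dtype=float)
    P = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(P, axis=1)
    if (norms == 0).any():
        raise DegenerateDataError("constant connectivity profile")
    R = (P @ P.T) / np.outer(norms, norms)
    R = np.clip(R, -1.0, 1.0)
    d = np.sqrt(np.clip(2.0 * (1.0 - R), 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# pseudo-F
# ---------------------------------------------------------------------------

def gower_center(d: np.ndarray) -> np.ndarray:
    """G = -1/2 H D^2 H with H = I - 11'/n (rows and columns sum to zero)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    h = np.eye(n) - np.ones((n, n)) / n
    return h @ a @ h


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def mdmr_pseudo_f(d: np.ndarray, design: DesignMatrix,
                  G: np.ndarray | None = None) -> float:
    """Partial pseudo-F for the design's effect columns.

    F = [tr((H_x - H_xr) G) / m] / [tr((I - H_x) G) / (n - p)] where H_x and
    H_xr are the hat matrices of the full and covariates-only designs and m
    is the number of effect columns.
    """
    if G is None:
        d = validate_distance_matrix(d)
        G = gower_center(d)
    n = design.n
    if n < design.p + 2:
        raise ValueError("need n >= p + 2 observations")
    if G.shape[0] != n:
        raise ValueError("distance matrix and design have different n")
    Hx = _hat(design.matrix)
    Hr = _hat(design.reduced)
    m = len(design.effect_cols)
    num = float(np.trace((Hx - Hr) @ G)) / m
    den = float(np.trace((np.eye(n) - Hx) @ G)) / (n - design.p)
    if den == 0:
        raise DegenerateDataError("zero residual trace in pseudo-F")
    return num / den


@dataclass
class MDMRResult:
    """Voxel-subset pseudo-F and permutation p maps from an MDMR run."""

    voxels: np.ndarray            # flat grid indices tested
    f: np.ndarray                 # observed pseudo-F per voxel
    p: np.ndarray                 # permutation p per voxel
    n_perm: int
    seed: int
    perm_f: np.ndarray | None = None   # n_perm x n_voxels null F values
    grid_shape: tuple[int, int, int] | None = None


def _freedman_lane_f(G: np.ndarray, design: DesignMatrix,
                     perms: np.ndarray) -> np.ndarray:
    """Null pseudo-F values under Freedman-Lane residual permutation.

    The reduced-model residual structure R = (I - Hr) G (I - Hr) is permuted
    jointly in rows and columns while the design stays fixed.
    """
    n = design.n
    Hx = _hat(design.matrix)
    Hr = _hat(design.reduced)
    R = (np.eye(n) - Hr) @ G @ (np.eye(n) - Hr)
    m = len(design.effect_cols)
    A = (Hx - Hr) / m
    B = (np.eye(n) - Hx) / (n - design.p)
    out = np.empty(len(perms))
    for b, perm in enumerate(perms):
        Rp = R[np.ix_(perm, perm)]
        den = float(np.sum(B * Rp.T))
        out[b] = float(np.sum(A * Rp.T)) / den if den != 0 else np.inf
    return out


def _simple_perm_f(G: np.ndarray, design: DesignMatrix,
                   perms: np.ndarray) -> np.ndarray:
    """Null pseudo-F by permuting the effect columns of the design."""
    out = np.empty(len(perms))
    for b, perm in enumerate(perms):
        X = design.matrix.copy()
        X[:, list(design.effect_cols)] = X[perm][:, list(design.effect_cols)]
        d2 = DesignMatrix(X, design.effect_cols, design.covariate_cols)
        out[b] = mdmr_pseudo_f(None, d2, G=G)
    return out


def precompute_gowers(subjects: Sequence[SubjectTimeseries],
                      voxel_subset: np.ndarray | None = None,
                      stride: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Gower-centred profile-distance matrices for a set of seed voxels.

    Returns ``(voxels, G)`` with ``G`` of shape (n_voxels, n, n).  The
    profile -> distance -> Gower step does not depend on the design, so a
    fixed scan set can be tested against many designs (or permutation
    replicates) without recomputation.
    """
    valid_all = np.ones(subjects[0].n_voxels, dtype=bool)
    for s in subjects:
        _, valid = s.standardized()
        valid_all &= valid
    candidates = subjects[0].voxel_index[valid_all]
    if voxel_subset is None:
        voxel_subset = candidates[::stride] if stride else candidates
    voxel_subset = np.asarray(voxel_subset)
    profiles = profile_matrix(subjects, voxel_subset)
    G = np.empty((len(voxel_subset), len(subjects), len(subjects)))
    for j in range(len(voxel_subset)):
        d = profile_distance_from_profiles(profiles[:, j, :])
        G[j] = gower_center(d)
    return voxel_subset, G


def mdmr_from_gowers(voxels: np.ndarray, G: np.ndarray, design: DesignMatrix,
                     n_perm: int = 999, seed: int = 0,
                     scheme: str = "freedman_lane",
                     keep_null: bool = True,
                     grid_shape: tuple[int, int, int] | None = None) -> MDMRResult:
    """Pseudo-F and permutation p per voxel from precomputed Gower matrices."""
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(design.n) for _ in range(n_perm)])
    f_obs = np.empty(len(voxels))
    p_obs = np.empty(len(voxels))
    null_store = np.empty((n_perm, len(voxels))) if keep_null else None
    null_fn = _freedman_lane_f if scheme == "freedman_lane" else _simple_perm_f
    for j in range(len(voxels)):
        f_obs[j] = mdmr_pseudo_f(None, design, G=G[j])
        null = null_fn(G[j], design, perms)
        p_obs[j] = (1.0 + np.sum(null >= f_obs[j])) / (1.0 + n_perm)
        if keep_null:
            null_store[:, j] = null
    return MDMRResult(voxels=voxels, f=f_obs, p=p_obs, n_perm=n_perm,
                      seed=seed, perm_f=null_store, grid_shape=grid_shape)


def mdmr_map(subjects: Sequence[SubjectTimeseries], design: DesignMatrix,
             n_perm: int = 999, seed: int = 0,
             voxel_subset: np.ndarray | None = None,
             stride: int | None = None,
             scheme: str = "freedman_lane",
             keep_null: bool = True) -> MDMRResult:
    """Pseudo-F and permutation p at each tested voxel.

    ``voxel_subset`` (flat grid indices) or ``stride`` (a regular grid
    subsample of the valid voxels) bounds the computation; the per-voxel
    null uses the same permutation streams across voxels so stored null F
    maps support map-level resampling shortcuts.
    """
    if len(subjects) != design.n:
        raise ValueError("design rows must match number of subjects")
    voxels, G = precompute_gowers(subjects, voxel_subset, stride)
    return mdmr_from_gowers(voxels, G, design, n_perm=n_perm, seed=seed,
                            scheme=scheme, keep_null=keep_null,
                            grid_shape=subjects[0].grid.shape)


# ---------------------------------------------------------------------------
# circuit enrichment odds ratio
# ---------------------------------------------------------------------------

def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with Haldane-Anscombe +0.5 on every cell if any is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def _enrichment_from_p(pvals: np.ndarray, in_circuit: np.ndarray,
                       threshold_p: float) -> float:
    sig = pvals <= threshold_p
    a = int(np.sum(sig & in_circuit))
    b = int(np.sum(sig & ~in_circuit))
    c = int(np.sum(~sig & in_circuit))
    d = int(np.sum(~sig & ~in_circuit))
    if a + b == 0:
        raise NotEstimableError("no suprathreshold voxels at this threshold")
    return odds_ratio(a, b, c, d)


def circuit_enrichment_or(result: MDMRResult, threshold_p: float,
                          circuit_mask: BinaryMask,
                          n_perm: int | None = None, seed: int = 0
                          ) -> tuple[float, PermutationResult]:
    """Odds ratio that PTSD-associated voxels fall inside the circuit.

    Voxels with permutation p <= ``threshold_p`` are cross-tabulated against
    circuit membership.  The permutation null re-scores each stored null F
    map against the remaining permutations (leave-one-out rank within the
    stored null ensemble) and recomputes the OR, so no MDMR re-runs are
    needed at desk scale.
    """
    if not (0.0 < threshold_p < 1.0):
        raise ValueError("threshold_p must lie in (0, 1)")
    in_circuit = circuit_mask.indicator.ravel()[result.voxels]
    observed = _enrichment_from_p(result.p, in_circuit, threshold_p)
    if result.perm_f is None:
        raise ValueError("MDMRResult carries no stored null F maps")
    B = result.perm_f.shape[0]
    n_perm = B if n_perm is None else min(n_perm, B)
    rng = np.random.default_rng(seed)
    pick = rng.choice(B, size=n_perm, replace=False)
    null = np.empty(n_perm)
    all_f = np.vstack([result.f[None, :], result.perm_f])
    for i, b in enumerate(pick):
        fb = result.perm_f[b]
        # rank of the permuted map within {observed} U {other perms},
        # mirroring the add-one formula used for the observed map
        others = np.delete(all_f, b + 1, axis=0)
        pb = (1.0 + np.sum(others >= fb[None, :], axis=0)) / (1.0 + others.shape[0])
        try:
            null[i] = _enrichment_from_p(pb, in_circuit, threshold_p)
        except NotEstimableError:
            null[i] = 1.0
    return observed, PermutationResult.from_null(observed, null, "right", seed)
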
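"""Synthetic data with the statistical structure the analyses assume.

The generator emulates, at desk scale, every input of the lesion-network
pipeline: a normative connectome whose voxels share latent network signals,
focal spherical lesions, ordinal outcomes driven by each lesion's
connectivity to a planted protective circuit plus a correlated depression
covariate, non-lesion patient scans whose circuit coupling depends on
diagnosis, and a two-arm pre/post TMS trial with a planted
group x connectivity-change interaction.

Generative model
----------------
Voxels inside an ellipsoidal "brain" mask receive soft memberships to
``n_networks`` latent networks via a softmax over smooth Gaussian random
fields.  A subject's BOLD signal is ``coupling * (membership @ network
signals) + white noise``.  The planted circuit is the first network's
membership map (thresholded to its core support).  A lesion's latent
liability is ``-beta * (standardized connectivity-to-circuit score)
+ gamma * depression + noise``; the ordinal 0/1/2 outcome cuts the
liability at Gaussian quantiles matching the configured prevalence, so
realized counts stay multinomial.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .connectome import NormativeConnectome, SubjectTimeseries, within_circuit_connectivity
from .lesion_mapping import CircuitMap, LesionCohort, cohort_connectivity
from .volumes import BinaryMask, ScalarMap, VolumeGrid


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic world.

    Defaults give an 18 x 22 x 18 grid of 3 mm voxels, a 40-subject
    normative connectome of 150-timepoint runs, 5 latent networks at
    coupling 0.6 with unit observation noise, and a 120-lesion cohort whose
    outcome-score partial correlation with the planted circuit score is
    approximately 0.3 after controlling for depression.
    """

    shape: tuple[int, int, int] = (18, 22, 18)
    voxel_mm: float = 3.0
    n_connectome: int = 40
    T: int = 150
    tr_seconds: float = 2.0
    n_networks: int = 5
    coupling: float = 0.6
    noise_sd: float = 1.0
    n_lesions: int = 120
    lesion_radius: tuple[int, int] = (2, 5)
    #: latent effect of the circuit score on liability; 0.3725 yields an
    #: outcome-score partial r of ~0.30 after ordinal discretization
    beta: float = 0.3725
    #: latent loading of depression on liability (outcome-BDI r of ~0.30)
    bdi_gamma: float = 0.40
    prevalence: tuple[float, float, float] = (0.48, 0.20, 0.32)
    #: smoothness (voxels) of the network random fields
    field_sigma: float = 2.5
    #: softmax sharpness of network memberships
    membership_sharpness: float = 3.0
    #: spatial autocorrelation (Gaussian sigma, voxels) of observation noise;
    #: real BOLD noise is locally correlated, which gives every seed map a
    #: seed-specific local component on top of the shared network patterns
    noise_sigma: float = 0.7
    #: membership level defining the planted circuit's core support
    circuit_threshold: float = 0.25
    aggregation: str = "tmap"
    seed: int = 7

    def __post_init__(self) -> None:
        if min(self.shape) <= 0 or self.n_connectome < 1 or self.T < 3:
            raise ValueError("invalid simulation sizes")
        if self.lesion_radius[1] * 2 + 1 > min(self.shape):
            raise ValueError("largest lesion radius does not fit in the grid")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ValueError("prevalence fractions must sum to 1")

    @property
    def grid(self) -> VolumeGrid:
        aff = np.diag([self.voxel_mm, self.voxel_mm, self.voxel_mm, 1.0])
        # centre the grid on the world origin, mirroring template conventions
        aff[:3, 3] = -self.voxel_mm * (np.asarray(self.shape) - 1) / 2.0
        return VolumeGrid(self.shape, aff, "synthetic")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    circuit: CircuitMap
    network_maps: list[ScalarMap]
    network_labels: ScalarMap
    brain_mask: BinaryMask
    memberships: np.ndarray          # V x K soft memberships (in-mask voxels)
    voxel_index: np.ndarray          # V flat grid indices
    outcome_params: dict = field(default_factory=dict)
    latent_scores: np.ndarray | None = None
    #: per-lesion aggregated connectivity maps, cached as a by-product of
    #: cohort generation (the outcome model needs them anyway)
    cohort_maps: "object | None" = None

    @property
    def planted_network_mask(self) -> BinaryMask:
        lab = self.network_labels
        return BinaryMask(lab.grid, (lab.values == 1) & lab.analysis_mask)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _correlated_noise(cfg: SimConfig, rng: np.random.Generator,
                      voxel_index: np.ndarray) -> np.ndarray:
    """(V, T) observation noise with mild spatial autocorrelation, unit sd.

    Each timepoint's noise field is smoothed with a small Gaussian kernel
    and rescaled to unit marginal variance, emulating the local correlation
    of real BOLD noise; ``noise_sigma=0`` recovers white noise.
    """
    if cfg.noise_sigma <= 0:
        return rng.standard_normal((voxel_index.size, cfg.T))
    field = rng.standard_normal((*cfg.shape, cfg.T))
    field = ndimage.gaussian_filter(field, sigma=(*([cfg.noise_sigma] * 3), 0.0))
    field /= field.std()
    return field.reshape(-1, cfg.T)[voxel_index]


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    centre = (np.asarray(shape) - 1) / 2.0
    radii = 0.48 * np.asarray(shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    dist = (((ii - centre[0]) / radii[0]) ** 2
            + ((jj - centre[1]) / radii[1]) ** 2
            + ((kk - centre[2]) / radii[2]) ** 2)
    return dist <= 1.0


def make_connectome(cfg: SimConfig, seed: int | None = None
                    ) -> tuple[NormativeConnectome, GroundTruth]:
    """Build the normative connectome and its planted network structure."""
    seed = cfg.seed if seed is None else seed
    rng_fields, rng_bold = _rng_streams(seed, 2)
    grid = cfg.grid
    mask3 = _brain_mask(cfg.shape)
    voxel_index = np.flatnonzero(mask3.ravel())
    V = voxel_index.size
    fields = np.empty((V, cfg.n_networks))
    for k in range(cfg.n_networks):
        f = ndimage.gaussian_filter(rng_fields.standard_normal(cfg.shape),
                                    sigma=cfg.field_sigma)
        fv = f.ravel()[voxel_index]
        fields[:, k] = (fv - fv.mean()) / fv.std()
    logits = cfg.membership_sharpness * fields
    logits -= logits.max(axis=1, keepdims=True)
    memberships = np.exp(logits)
    memberships /= memberships.sum(axis=1, keepdims=True)

    subjects = []
    child = np.random.SeedSequence(rng_bold.integers(2 ** 31)).spawn(cfg.n_connectome)
    for s in range(cfg.n_connectome):
        r = np.random.default_rng(child[s])
        eta = r.standard_normal((cfg.n_networks, cfg.T))
        noise = _correlated_noise(cfg, r, voxel_index)
        data = (cfg.coupling * (memberships @ eta) + cfg.noise_sd * noise).T
        subjects.append(SubjectTimeseries(grid, data.astype(np.float32),
                                          cfg.tr_seconds, voxel_index))
    conn = NormativeConnectome(subjects)

    def to_map(vals_v: np.ndarray) -> ScalarMap:
        vol = np.zeros(grid.n_voxels)
        vol[voxel_index] = vals_v
        return ScalarMap(grid, vol.reshape(cfg.shape), mask3)

    m0 = memberships[:, 0]
    circuit_vals = np.where(m0 >= cfg.circuit_threshold, m0, 0.0)
    circuit = CircuitMap(map=to_map(circuit_vals), covariate_names=("planted",),
                         n_subjects=0, aggregation="planted")
    labels = to_map(np.argmax(memberships, axis=1) + 1.0)
    truth = GroundTruth(
        circuit=circuit,
        network_maps=[to_map(memberships[:, k]) for k in range(cfg.n_networks)],
        network_labels=labels,
        brain_mask=BinaryMask(grid, mask3),
        memberships=memberships,
        voxel_index=voxel_index,
    )
    return conn, truth


# ---------------------------------------------------------------------------
# lesion cohort
# ---------------------------------------------------------------------------

def _spherical_lesion(grid: VolumeGrid, mask3: np.ndarray, centre: np.ndarray,
                      radius: int) -> BinaryMask:
    lo = np.maximum(centre - radius, 0)
    hi = np.minimum(centre + radius + 1, grid.shape)
    ind = np.zeros(grid.shape, dtype=bool)
    ii, jj, kk = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)),
                             indexing="ij")
    inside = ((ii - centre[0]) ** 2 + (jj - centre[1]) ** 2
              + (kk - centre[2]) ** 2) <= radius ** 2
    ind[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    ind &= mask3
    return BinaryMask(grid, ind)


def make_lesion_cohort(cfg: SimConfig, conn: NormativeConnectome,
                       truth: GroundTruth, beta: float | None = None,
                       n_lesions: int | None = None,
                       seed: int | None = None) -> LesionCohort:
    """Spherical lesions with outcomes driven by circuit connectivity.

    ``beta=0`` produces a null cohort (outcome independent of the maps).
    Updates ``truth.outcome_params`` and ``truth.latent_scores`` in place.
    """
    seed = (cfg.seed + 1) if seed is None else seed
    beta = cfg.beta if beta is None else beta
    n_lesions = cfg.n_lesions if n_lesions is None else n_lesions
    rng_geom, rng_out = _rng_streams(seed, 2)
    grid = cfg.grid
    mask3 = truth.brain_mask.indicator
    in_mask = np.argwhere(mask3)
    lesions = []
    while len(lesions) < n_lesions:
        centre = in_mask[rng_geom.integers(len(in_mask))]
        radius = int(rng_geom.integers(cfg.lesion_radius[0],
                                       cfg.lesion_radius[1] + 1))
        les = _spherical_lesion(grid, mask3, centre, radius)
        if les.voxel_count > 0:
            lesions.append(les)

    maps = cohort_connectivity(
        _bare_cohort(lesions), conn, cfg.aggregation)
    circ_vals = truth.circuit.map.values.ravel()[maps.voxel_index[maps.valid]]
    raw = maps.matrix[:, maps.valid] @ circ_vals
    s = (raw - raw.mean()) / raw.std()

    b = rng_out.standard_normal(n_lesions)
    e = rng_out.standard_normal(n_lesions)
    liability = -beta * s + cfg.bdi_gamma * b + e
    sd_l = np.sqrt(beta ** 2 + cfg.bdi_gamma ** 2 + 1.0)
    p0, p1, _ = cfg.prevalence
    cut0 = norm.ppf(p0) * sd_l
    cut1 = norm.ppf(p0 + p1) * sd_l
    outcome = np.where(liability <= cut0, 0, np.where(liability <= cut1, 1, 2))
    bdi = np.clip(np.round(12.0 + 7.0 * b), 0, 63)

    truth.outcome_params = {"beta": beta, "gamma": cfg.bdi_gamma,
                            "cuts": (float(cut0), float(cut1))}
    truth.latent_scores = s
    truth.cohort_maps = maps
    return LesionCohort(
        ids=[f"sub-{i:04d}" for i in range(n_lesions)],
        lesions=lesions,
        outcome=outcome.astype(float),
        covariates=pd.DataFrame({"BDI": bdi}),
    )


def resample_outcomes(cfg: SimConfig, cohort: LesionCohort, truth: GroundTruth,
                      beta: float | None = None,
                      seed: int = 0) -> LesionCohort:
    """Redraw outcomes and BDI for a fixed lesion set and connectome.

    Reuses the cohort's circuit scores (``truth.latent_scores``) and applies
    the same liability model as :func:`make_lesion_cohort`; with ``beta=0``
    this yields fresh null replicates at fixed connectivity maps, the basis
    of the permutation-calibration studies.
    """
    if truth.latent_scores is None:
        raise ValueError("truth carries no latent scores; build the cohort first")
    beta = cfg.beta if beta is None else beta
    rng = np.random.default_rng(seed)
    n = cohort.n
    s = truth.latent_scores
    b = rng.standard_normal(n)
    e = rng.standard_normal(n)
    liability = -beta * s + cfg.bdi_gamma * b + e
    sd_l = np.sqrt(beta ** 2 + cfg.bdi_gamma ** 2 + 1.0)
    p0, p1, _ = cfg.prevalence
    cut0 = norm.ppf(p0) * sd_l
    cut1 = norm.ppf(p0 + p1) * sd_l
    outcome = np.where(liability <= cut0, 0, np.where(liability <= cut1, 1, 2))
    bdi = np.clip(np.round(12.0 + 7.0 * b), 0, 63)
    return LesionCohort(ids=list(cohort.ids), lesions=list(cohort.lesions),
                        outcome=outcome.astype(float),
                        covariates=pd.DataFrame({"BDI": bdi}))


def _bare_cohort(lesions: list[BinaryMask]) -> LesionCohort:
    n = len(lesions)
    return LesionCohort(ids=[str(i) for i in range(n)], lesions=lesions,
                        outcome=np.zeros(n), covariates=pd.DataFrame(index=range(n)))


# ---------------------------------------------------------------------------
# non-lesion patient scans
# ---------------------------------------------------------------------------

def _patient_scan(cfg: SimConfig, truth: GroundTruth,
                  rng: np.random.Generator,
                  circuit_coupling_factor: float) -> SubjectTimeseries:
    m = truth.memberships
    V = m.shape[0]
    eta = rng.standard_normal((cfg.n_networks, cfg.T))
    per_net = np.full(cfg.n_networks, cfg.coupling)
    per_net[0] = cfg.coupling * circuit_coupling_factor
    noise = _correlated_noise(cfg, rng, truth.voxel_index)
    data = ((m * per_net) @ eta + cfg.noise_sd * noise).T
    return SubjectTimeseries(cfg.grid, data.astype(np.float32),
                             cfg.tr_seconds, truth.voxel_index)


def make_patient_scans(cfg: SimConfig, truth: GroundTruth,
                       n_patients: int = 60, diagnosis_effect: float = -0.3,
                       seed: int | None = None
                       ) -> tuple[list[SubjectTimeseries], pd.DataFrame]:
    """Non-lesion patients whose circuit coupling depends on diagnosis.

    A PTSD patient's coupling within the planted network is multiplied by
    ``1 + diagnosis_effect``; comorbidity flags use the base rates of the
    emulated Veteran cohort (PTSD 34%, TBI or subconcussive injury 56%,
    depression via BDI >= 20 in roughly a quarter).
    """
    seed = (cfg.seed + 2) if seed is None else seed
    rng_flags, rng_scan = _rng_streams(seed, 2)
    ptsd = (rng_flags.random(n_patients) < 0.34).astype(int)
    tbi = (rng_flags.random(n_patients) < 0.56).astype(int)
    bdi = np.clip(np.round(rng_flags.normal(14.0, 9.0, n_patients)), 0, 63)
    scans = []
    child = np.random.SeedSequence(rng_scan.integers(2 ** 31)).spawn(n_patients)
    for i in range(n_patients):
        factor = 1.0 + diagnosis_effect * ptsd[i]
        scans.append(_patient_scan(cfg, truth, np.random.default_rng(child[i]), factor))
    records = pd.DataFrame({
        "id": [f"pat-{i:04d}" for i in range(n_patients)],
        "ptsd": ptsd, "tbi": tbi, "BDI": bdi,
        "circuit_z": [within_circuit_connectivity(s, truth.circuit.map)
                      for s in scans],
    })
    return scans, records


# ---------------------------------------------------------------------------
# TMS trial
# ---------------------------------------------------------------------------

def make_tms_trial(cfg: SimConfig, truth: GroundTruth,
                   n_per_arm: int = 10, interaction_effect: float = 10.0,
                   pcl_noise_sd: float = 2.0,
                   seed: int | None = None
                   ) -> tuple[pd.DataFrame, dict[str, list[SubjectTimeseries]]]:
    """Two-arm pre/post trial with a planted group x connectivity-change effect.

    Active-arm subjects' post-treatment circuit coupling shifts by a
    per-subject random factor; their percent PCL-5 improvement equals
    ``interaction_effect * (-observed circuit-z change)`` plus noise, while
    the sham arm improves by noise alone.  PCL-5 stays within [0, 80].
    """
    seed = (cfg.seed + 3) if seed is None else seed
    rng_clin, rng_scan = _rng_streams(seed, 2)
    n = 2 * n_per_arm
    arms = ["active"] * n_per_arm + ["sham"] * n_per_arm
    child = np.random.SeedSequence(rng_scan.integers(2 ** 31)).spawn(2 * n)
    rows = []
    scans: dict[str, list[SubjectTimeseries]] = {"pre": [], "post": []}
    for i in range(n):
        pre_scan = _patient_scan(cfg, truth, np.random.default_rng(child[2 * i]), 1.0)
        if arms[i] == "active":
            shift = rng_clin.normal(-0.4, 0.4)
        else:
            shift = 0.0
        post_scan = _patient_scan(cfg, truth,
                                  np.random.default_rng(child[2 * i + 1]),
                                  max(1.0 + shift, 0.0))
        z_pre = within_circuit_connectivity(pre_scan, truth.circuit.map)
        z_post = within_circuit_connectivity(post_scan, truth.circuit.map)
        pre_pcl = float(rng_clin.integers(45, 71))
        if arms[i] == "active":
            impr_pct = (interaction_effect * (-(z_post - z_pre))
                        + rng_clin.normal(0.0, pcl_noise_sd))
        else:
            impr_pct = rng_clin.normal(1.0, pcl_noise_sd)
        post_pcl = float(np.clip(pre_pcl * (1.0 - impr_pct / 100.0), 0.0, 80.0))
        pre_ids = float(np.round(rng_clin.normal(35.0, 8.0)))
        d_ids = 0.2 * impr_pct + rng_clin.normal(0.0, 2.0)
        pre_stai = float(np.round(rng_clin.normal(45.0, 8.0)))
        d_stai = 0.1 * impr_pct + rng_clin.normal(0.0, 2.0)
        rows.append({"id": f"tms-{i:03d}", "arm": arms[i],
                     "pre_circuit_z": z_pre, "post_circuit_z": z_post,
                     "pre_pcl5": pre_pcl, "post_pcl5": post_pcl,
                     "pre_ids": pre_ids, "post_ids": pre_ids - d_ids,
                     "pre_stai": pre_stai, "post_stai": pre_stai - d_stai})
        scans["pre"].append(pre_scan)
        scans["post"].append(post_scan)
    return pd.DataFrame(rows), scans
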
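"""High-level study workflows: end-to-end planted-truth runs and
permutation-calibration studies on synthetic cohorts.

These drive the full pipeline — simulate, derive, validate, enrich,
target — the way the individual analyses are meant to be combined, and are
what the acceptance checks and the reproduction script execute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import targeting_atlas
from .lesion_mapping import derive_circuit, fwe_peak
from .mdmr import DesignMatrix, circuit_enrichment_or, mdmr_from_gowers, precompute_gowers
from .synthetic import (GroundTruth, SimConfig, make_connectome,
                        make_lesion_cohort, make_patient_scans, resample_outcomes)
from .validation import (permutation_null_similarity,
                         roi_overlap_permutation_test, split_half_similarity)
from .volumes import BinaryMask, spatial_correlation


@dataclass
class EndToEndResult:
    recovery_r: float
    split_half_mean_r: float
    split_half_p: float
    enrichment_or: float
    atlas_peak_in_network: bool

    @property
    def flags_planted_circuit(self) -> bool:
        return (self.recovery_r >= 0.6 and self.split_half_p <= 0.05
                and self.enrichment_or > 1.0 and self.atlas_peak_in_network)


def end_to_end_replicate(cfg: SimConfig, seed: int,
                         n_splits: int = 10, n_perm: int = 99,
                         n_patients: int = 20,
                         diagnosis_effect: float = -0.3,
                         mdmr_n_voxels: int = 60,
                         mdmr_n_perm: int = 199) -> EndToEndResult:
    """One full simulate -> derive -> validate -> enrich -> target run.

    Generates a fresh world from ``seed``, derives the circuit, tests its
    split-half reproducibility against the outcome-permutation null, runs
    the MDMR enrichment in a simulated non-lesion cohort, and builds the
    targeting atlas; reports whether each step flags the planted circuit.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(2 ** 31, size=4)]
    conn, truth = make_connectome(cfg, seed=sub[0])
    cohort = make_lesion_cohort(cfg, conn, truth, seed=sub[1])
    maps = truth.cohort_maps

    circ = derive_circuit(cohort, maps=maps)
    recovery = spatial_correlation(circ.map, truth.circuit.map)

    perm = permutation_null_similarity(cohort, maps=maps, n_splits=n_splits,
                                       n_perm=n_perm, seed=sub[2] % 100000)
    observed = split_half_similarity(cohort, maps=maps, n_splits=n_splits,
                                     seed=sub[2] % 100000).mean_spatial_r

    scans, records = make_patient_scans(cfg, truth, n_patients=n_patients,
                                        diagnosis_effect=diagnosis_effect,
                                        seed=sub[3])
    design = DesignMatrix.from_columns(records["ptsd"].to_numpy(float))
    circ_mask = BinaryMask(truth.circuit.grid, truth.circuit.map.values > 0)
    voxels, G = _balanced_gowers(scans, truth, mdmr_n_voxels,
                                 np.random.default_rng(sub[3]))
    mres = mdmr_from_gowers(voxels, G, design, n_perm=mdmr_n_perm,
                            seed=sub[3] % 100000,
                            grid_shape=cfg.shape)
    try:
        orr, _ = circuit_enrichment_or(mres, 0.05, circ_mask,
                                       seed=sub[3] % 100000)
    except Exception:
        orr = np.nan

    atlas = targeting_atlas(conn, circ.map)
    peak = atlas.peak_voxel()
    peak_in_network = bool(truth.planted_network_mask.indicator[peak])

    return EndToEndResult(recovery_r=float(recovery),
                          split_half_mean_r=float(observed),
                          split_half_p=float(perm.p),
                          enrichment_or=float(orr),
                          atlas_peak_in_network=peak_in_network)


def _balanced_gowers(scans, truth: GroundTruth, n_voxels: int,
                     rng: np.random.Generator):
    """Gower matrices for a voxel subset balanced in/out of the circuit."""
    circ_flat = np.flatnonzero(truth.circuit.map.values.ravel() > 0)
    out_flat = np.flatnonzero(truth.brain_mask.indicator.ravel()
                              & ~(truth.circuit.map.values.ravel() > 0))
    k = n_voxels // 2
    subset = np.concatenate([
        rng.choice(circ_flat, min(k, circ_flat.size), replace=False),
        rng.choice(out_flat, min(n_voxels - k, out_flat.size), replace=False)])
    return precompute_gowers(scans, voxel_subset=np.sort(subset))


# ---------------------------------------------------------------------------
# permutation calibration under the global null
# ---------------------------------------------------------------------------

@dataclass
class NullWorld:
    """A fixed null world (beta = 0) whose outcomes can be redrawn cheaply."""

    cfg: SimConfig
    conn: object
    truth: GroundTruth
    cohort: object
    maps: object

    @classmethod
    def build(cls, cfg: SimConfig) -> "NullWorld":
        conn, truth = make_connectome(cfg)
        cohort = make_lesion_cohort(cfg, conn, truth, beta=0.0)
        return cls(cfg=cfg, conn=conn, truth=truth, cohort=cohort,
                   maps=truth.cohort_maps)

    def null_cohort(self, seed: int):
        return resample_outcomes(self.cfg, self.cohort, self.truth,
                                 beta=0.0, seed=seed)


def calibration_rejection_rates(world: NullWorld, n_replicates: int = 100,
                                n_perm: int = 99, n_splits: int = 10,
                                alpha: float = 0.05,
                                seed: int = 0) -> dict[str, float]:
    """Type-I error of the three cohort-level permutation tests.

    For each replicate the outcome rows are redrawn under the global null
    (beta = 0; the connectivity maps stay fixed, which the permutation
    tests condition on anyway) and each test is run at ``n_perm``
    permutations; rates are the fraction of replicates with p <= alpha.
    """
    roi = BinaryMask(world.truth.circuit.grid,
                     world.truth.circuit.map.values > 0)
    rej = {"split_half": 0, "fwe_peak": 0, "roi_overlap": 0}
    for i in range(n_replicates):
        cohort = world.null_cohort(seed=seed + 17 * i)
        p_split = permutation_null_similarity(
            cohort, maps=world.maps, n_splits=n_splits, n_perm=n_perm,
            seed=seed + i).p
        _, peak = fwe_peak(cohort, covariate_names=("lesion_size", "BDI"),
                           n_perm=n_perm, seed=seed + i, maps=world.maps)
        p_roi = roi_overlap_permutation_test(
            cohort, roi=roi, n_perm=n_perm, seed=seed + i,
            maps=world.maps).p
        rej["split_half"] += p_split <= alpha
        rej["fwe_peak"] += peak.p_fwe <= alpha
        rej["roi_overlap"] += p_roi <= alpha
    return {k: v / n_replicates for k, v in rej.items()}


def mdmr_calibration_rate(cfg: SimConfig, n_replicates: int = 100,
                          n_perm: int = 99, n_voxels: int = 30,
                          n_patients: int = 20, alpha: float = 0.05,
                          seed: int = 0) -> float:
    """Voxel-level type-I error of the MDMR permutation test under the null.

    Scans are generated once with ``diagnosis_effect=0`` (so connectivity
    is independent of any labels); each replicate draws a fresh random
    design and the per-voxel p-values are pooled across replicates.
    """
    conn, truth = make_connectome(cfg)
    scans, _ = make_patient_scans(cfg, truth, n_patients=n_patients,
                                  diagnosis_effect=0.0, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    voxels, G = _balanced_gowers(scans, truth, n_voxels, rng)
    hits = 0
    total = 0
    for i in range(n_replicates):
        effect = (rng.random(n_patients) < 0.4).astype(float)
        covars = np.column_stack([(rng.random(n_patients) < 0.5).astype(float),
                                  rng.standard_normal(n_patients)])
        if effect.std() == 0 or covars[:, 0].std() == 0:
            continue
        design = DesignMatrix.from_columns(effect, covars)
        res = mdmr_from_gowers(voxels, G, design, n_perm=n_perm,
                               seed=seed + 3 + i, keep_null=False)
        hits += int(np.sum(res.p <= alpha))
        total += len(res.p)
    return hits / total
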
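"""Synthetic bilingual-reading dataset generator.

Emulates the study design the pipeline expects — three reading
conditions (Chinese word, English word, Chinese pinyin) with 40 trials
each, trial-wise beta volumes, an ROI atlas inside an analysis mask, and
a behavioral table — with *planted* representational geometry: inside
designated regions, the local multivoxel pattern geometry rank-correlates
with a chosen behavioral RDM at a chosen effect size; everywhere else the
betas are white noise.

Planting works by embedding the target behavioral RDM into a
low-dimensional latent configuration (classical metric multidimensional
scaling), giving every in-region voxel a random linear readout of the
latent coordinates, and mixing that signal with white noise.  The mixing
weight is calibrated empirically (Monte-Carlo, 200 draws per grid point)
so that the expected rank correlation between the local neural RDM and
the target RDM tracks the requested effect size; the attainable ceiling
of this construction is about 0.8, and higher requests clamp to the
ceiling with a logged warning.

No BOLD time-series, HRF, motion or physiological noise is simulated:
the generator emits first-level beta maps directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rdm import COMPONENTS, CONDITIONS, DissimilarityMatrix, StimulusItem, build_all_rdms
from .searchlight import BetaVolumeSet

log = logging.getLogger(__name__)

#: condition-wise geometric-mean reaction times (ms), shortest for Chinese
#: words and longest for pinyin, matching the reported behavioral ordering
RT_MEANS_MS = {"chinese_word": 968.0, "english_word": 1182.0, "chinese_pinyin": 1497.0}
ACCURACY_P = 0.98  # near-ceiling per-trial response accuracy

_BLOCK = 5  # regions are BLOCK^3 voxel cubes
# unlabeled pure-noise islands: 10 voxels each (a 2x2x3 box minus two
# corners), so every island voxel sees the full island inside a 6-mm
# searchlight (valid sphere), while a fully suprathreshold island is a
# 10-voxel cluster — never larger than the "cluster size > 10" extent
# rule admits, exactly the scale of noise that rule exists to discard
_ISLAND_DIMS = (2, 2, 3)
_ISLAND_DROP = {(0, 0, 2), (1, 1, 2)}
_N_NULL_ISLANDS = 20
_CALIB_DRAWS = 200
_CALIB_GRID = np.linspace(0.0, 1.0, 11)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    effect_map maps (region label, condition, component) to a planted
    effect size r in [0, 1]; subject_sd jitters that effect across
    subjects.  Defaults mirror the emulated design: 3 conditions x 40
    trials, 2-mm voxels, a 20^3 grid.
    """

    n_subjects: int = 20
    n_trials_per_condition: int = 40
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.0
    n_regions: int = 10
    effect_map: dict[tuple[int, str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    subject_sd: float = 0.05
    seed: int = 0
    embedding_dim: int = 50
    alphabet_size: int = 30
    #: empty voxels between region blocks; >= 4 keeps a 6-mm searchlight
    #: centered in one block from touching the next (no signal bleed)
    region_gap_voxels: int = 1
    #: number of 10-voxel pure-noise islands outside the atlas
    n_noise_islands: int = 20

    def __post_init__(self):
        if int(np.prod(self.grid_shape)) < 1000:
            raise ValueError("grid must contain at least 1000 voxels")
        if self.n_trials_per_condition < 8:
            raise ValueError("need at least 8 trials per condition")
        if not 1 <= self.n_regions <= 30:
            raise ValueError("n_regions must be in [1, 30]")
        if self.noise_sd <= 0 or self.subject_sd < 0:
            raise ValueError("noise_sd must be positive and subject_sd non-negative")
        for key, r in self.effect_map.items():
            region, cond, comp = key
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"effect size {r} for {key} outside [0, 1]")
            if cond not in CONDITIONS or comp not in COMPONENTS:
                raise ValueError(f"unknown condition/component in effect key {key}")
            if not 1 <= region <= self.n_regions:
                raise ValueError(f"region {region} outside 1..{self.n_regions}")


def default_effect_map(n_regions: int = 10, r: float = 0.6) -> dict[tuple[int, str, str], float]:
    """A condition-specific planting scheme: region k carries one
    (condition, component) pairing, cycling through all nine pairings, so
    conditions are separable and every component is represented."""
    out = {}
    for k in range(1, n_regions):
        cond = CONDITIONS[(k - 1) % 3]
        comp = COMPONENTS[((k - 1) // 3) % 3]
        out[(k, cond, comp)] = r
    return out  # the last region stays empty as an in-atlas null


@dataclass
class SyntheticDataset:
    stimuli: list[StimulusItem]
    beta: list[BetaVolumeSet]
    mask: np.ndarray
    atlas: np.ndarray
    affine: np.ndarray
    labels: pd.DataFrame
    behavior: pd.DataFrame
    truth: dict
    config: SimulationConfig
    behavioral_rdms: dict[tuple[str, str], DissimilarityMatrix]


def generate_stimuli(config: SimulationConfig) -> list[StimulusItem]:
    """Stimulus inventory: unit multisets over a finite alphabet (sizes
    3-8 so pairwise overlap varies) and unit-norm embeddings drawn from
    per-condition cluster centers plus noise.  Deterministic in the seed;
    errors if the alphabet cannot yield distinct decompositions."""
    rng = np.random.default_rng(config.seed)
    n = config.n_trials_per_condition
    A = config.alphabet_size
    # crude capacity check: multisets of size 3..8 over A symbols
    if A < 10:
        needed = 10
        raise ValueError(
            f"alphabet of {A} symbols too small to guarantee {n} distinct items; "
            f"use at least {needed}"
        )
    stimuli = []
    prefix = {"chinese_word": "cw", "english_word": "ew", "chinese_pinyin": "py"}
    for ci, cond in enumerate(CONDITIONS):
        center = rng.normal(size=config.embedding_dim)
        center /= np.linalg.norm(center)
        seen = set()
        for k in range(n):
            for attempt in range(200):
                logo = tuple(sorted(rng.choice(A, size=rng.integers(3, 9)).tolist()))
                phon = tuple(sorted(rng.choice(A, size=rng.integers(3, 9)).tolist()))
                if (logo, phon) not in seen:
                    seen.add((logo, phon))
                    break
            else:
                raise ValueError(
                    f"alphabet of {A} symbols too small to draw {n} distinct items; "
                    f"increase alphabet_size"
                )
            emb = center + 0.5 * rng.normal(size=config.embedding_dim)
            emb /= np.linalg.norm(emb)
            stimuli.append(
                StimulusItem(
                    id=f"{prefix[cond]}{k:03d}",
                    condition=cond,
                    logo_units=tuple(f"u{t:02d}" for t in logo),
                    phon_units=tuple(f"p{t:02d}" for t in phon),
                    embedding=emb,
                )
            )
    return stimuli


def _place_blocks(grid_shape, n_blocks, gap=1):
    """Non-overlapping BLOCK^3 cube origins on a coarse lattice."""
    step = _BLOCK + gap
    starts = [list(range(1, s - _BLOCK, step)) for s in grid_shape]
    slots = [(i, j, k) for i in starts[0] for j in starts[1] for k in starts[2]]
    if len(slots) < n_blocks:
        raise ValueError(
            f"grid {grid_shape} fits only {len(slots)} region blocks; "
            f"{n_blocks} requested — enlarge the grid"
        )
    return slots[:n_blocks]


def _cube_distance_dims(o1, d1, o2, d2) -> float:
    """Euclidean voxel distance between nearest voxels of two boxes."""
    gaps = []
    for a in range(3):
        lo1, hi1 = o1[a], o1[a] + d1[a] - 1
        lo2, hi2 = o2[a], o2[a] + d2[a] - 1
        gaps.append(max(0, lo2 - hi1, lo1 - hi2))
    return float(np.linalg.norm(gaps))


def _place_islands(grid_shape, region_slots, n_islands, region_sep):
    """Noise-island origins on a fine lattice, kept at least ``region_sep``
    voxels from every region block; island-island separation is 3 voxels
    by lattice construction."""
    step = [d + 3 for d in _ISLAND_DIMS]
    starts = [list(range(1, s - d + 1, st))
              for s, d, st in zip(grid_shape, _ISLAND_DIMS, step)]
    out = []
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                o = (i, j, k)
                if all(_cube_distance_dims(o, _ISLAND_DIMS, r, (_BLOCK,) * 3)
                       >= region_sep for r in region_slots):
                    out.append(o)
                if len(out) == n_islands:
                    return out
    raise ValueError(
        f"grid {grid_shape} fits only {len(out)} noise islands next to "
        f"{len(region_slots)} regions; enlarge the grid"
    )


def make_atlas(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Toy atlas: labeled region cubes plus unlabeled noise islands.

    The noise volume is split into several small, mutually distant islands
    rather than one large block: each island is an approximately
    independent spatial unit under the searchlight (whose spheres heavily
    overlap within a compact neighbourhood), which keeps the sampling
    variability of whole-map summaries at the level the island count
    suggests instead of being dominated by a single correlated blob.
    """
    atlas = np.zeros(config.grid_shape, dtype=int)
    mask = np.zeros(config.grid_shape, dtype=bool)
    region_slots = _place_blocks(config.grid_shape, config.n_regions,
                                 gap=config.region_gap_voxels)
    rows = []
    for idx, (x, y, z) in enumerate(region_slots):
        sl = (slice(x, x + _BLOCK), slice(y, y + _BLOCK), slice(z, z + _BLOCK))
        mask[sl] = True
        atlas[sl] = idx + 1
        rows.append({"label": idx + 1, "name": f"region_{idx + 1:02d}"})
    region_sep = max(2, config.region_gap_voxels)
    for o in _place_islands(config.grid_shape, region_slots,
                            config.n_noise_islands, region_sep):
        for i in range(_ISLAND_DIMS[0]):
            for j in range(_ISLAND_DIMS[1]):
                for k in range(_ISLAND_DIMS[2]):
                    if (i, j, k) not in _ISLAND_DROP:
                        mask[o[0] + i, o[1] + j, o[2] + k] = True
    labels = pd.DataFrame(rows)
    return atlas, mask, labels


def classical_mds(rdm: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson scaling of a dissimilarity matrix.  Negative eigenvalues
    (non-Euclidean RDMs) are clipped, which is the rank-preserving
    fallback for non-metric input."""
    D = np.asarray(rdm, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D**2) @ J
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w = w[order]
    if np.any(w < -1e-8 * max(1.0, abs(w[0]))):
        log.info("classical_mds: non-metric RDM, negative eigenvalues clipped")
    w = np.clip(w, 0.0, None)
    return U[:, order] * np.sqrt(w)


def _simulate_expected_corr(latent: np.ndarray, target_tri: np.ndarray,
                            weight: float, n_voxels: int,
                            rng: np.random.Generator,
                            n_draws: int = _CALIB_DRAWS) -> float:
    """Monte-Carlo expected Spearman between the local neural RDM and the
    target RDM at a given signal mixing weight."""
    n = latent.shape[0]
    tril = np.tril_indices(n, -1)
    target_ranks = sps.rankdata(target_tri)
    tr_c = target_ranks - target_ranks.mean()
    tr_n = np.linalg.norm(tr_c)
    acc = 0.0
    for _ in range(n_draws):
        W = rng.normal(size=(n_voxels, latent.shape[1]))
        S = W @ latent.T
        sd = S.std(axis=1, keepdims=True)
        S = np.divide(S, sd, out=np.zeros_like(S), where=sd > 0)
        P = weight * S + (1.0 - weight) * rng.normal(size=S.shape)
        ranked = sps.rankdata(P, axis=0)
        corr = np.corrcoef(ranked.T)
        v = sps.rankdata((1.0 - corr)[tril])
        vc = v - v.mean()
        acc += (vc @ tr_c) / (np.linalg.norm(vc) * tr_n)
    return acc / n_draws


def calibrate_mixing_curve(
    rdm: DissimilarityMatrix,
    n_voxels: int,
    seed: int,
    latent_dim: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Calibration curve weight -> expected neural/target rank correlation.

    Returns (weights, expected_r, latent).  The curve is forced monotone
    (cumulative max) so inversion by interpolation is well defined.
    """
    n = rdm.n
    d = latent_dim if latent_dim is not None else min(10, n - 1)
    latent = classical_mds(rdm.values, d)
    rng = np.random.default_rng(seed)
    tri = rdm.lower_triangle()
    expected = np.array([
        _simulate_expected_corr(latent, tri, w, n_voxels, rng) for w in _CALIB_GRID
    ])
    expected = np.maximum.accumulate(expected)
    return _CALIB_GRID.copy(), expected, latent


def weight_for_effect(weights: np.ndarray, expected: np.ndarray, r_target: float) -> float:
    """Invert the calibration curve; clamp above the attainable ceiling."""
    if r_target <= 0:
        return 0.0
    ceiling = expected[-1]
    if r_target > ceiling + 0.05:
        log.warning(
            "requested effect size %.2f exceeds the attainable ceiling %.2f of the "
            "MDS-readout construction; clamping to pure signal", r_target, ceiling,
        )
        return 1.0
    return float(np.interp(r_target, expected, weights))


def plant_beta_volumes(stimuli: list[StimulusItem], config: SimulationConfig) -> SyntheticDataset:
    """Beta volumes with planted representational geometry.

    In-region voxels carry a random linear readout of the MDS latent of
    the target behavioral RDM mixed with white noise at a calibrated
    weight; all other in-mask voxels (and all other conditions' trials)
    are pure noise scaled by ``noise_sd``.  Per-subject effect sizes are
    jittered by ``subject_sd`` and clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed + 1)
    atlas, mask, labels = make_atlas(config)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    rdms = build_all_rdms(stimuli)
    n = config.n_trials_per_condition

    # trial layout: condition-blocked; the events table carries the mapping
    trial_rows = []
    for ci, cond in enumerate(CONDITIONS):
        ids = rdms[(cond, "logo")].item_ids
        for k, item in enumerate(ids):
            trial_rows.append({"trial_index": ci * n + k, "condition": cond, "item_id": item})
    trial_table = pd.DataFrame(trial_rows)
    cond_slice = {cond: slice(ci * n, (ci + 1) * n) for ci, cond in enumerate(CONDITIONS)}

    region_size = _BLOCK**3
    curves: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (_, cond, comp), r in sorted(config.effect_map.items()):
        if r > 0 and (cond, comp) not in curves:
            curves[(cond, comp)] = calibrate_mixing_curve(
                rdms[(cond, comp)], region_size, seed=config.seed + 2
            )

    mask_idx = np.argwhere(mask)
    betas = []
    subject_effects = {}
    for si in range(config.n_subjects):
        subject = f"sub-{si + 1:02d}"
        data = np.zeros(config.grid_shape + (3 * n,))
        data[mask] = config.noise_sd * rng.normal(size=(mask.sum(), 3 * n))
        # per-region planted signal, grouped so co-planted components share noise weight
        per_region: dict[tuple[int, str], list[tuple[str, float]]] = {}
        for (region, cond, comp), r in sorted(config.effect_map.items()):
            if r <= 0:
                continue
            r_s = float(np.clip(r + config.subject_sd * rng.normal(), 0.0, 1.0))
            subject_effects[(subject, region, cond, comp)] = r_s
            per_region.setdefault((region, cond), []).append((comp, r_s))
        for (region, cond), plants in per_region.items():
            vox = np.argwhere(atlas == region)
            v = len(vox)
            sig = np.zeros((v, n))
            w_total = 0.0
            for comp, r_s in plants:
                weights, expected, latent = curves[(cond, comp)]
                w = weight_for_effect(weights, expected, r_s)
                W = rng.normal(size=(v, latent.shape[1]))
                S = W @ latent.T
                sd = S.std(axis=1, keepdims=True)
                S = np.divide(S, sd, out=np.zeros_like(S), where=sd > 0)
                sig += w * S
                w_total += w
            noise_w = max(1.0 - w_total, 0.05) if len(plants) > 1 else (1.0 - w_total)
            pattern = sig + noise_w * rng.normal(size=(v, n))
            data[vox[:, 0], vox[:, 1], vox[:, 2], cond_slice[cond]] = config.noise_sd * pattern
        betas.append(BetaVolumeSet(data=data, affine=affine, mask=mask,
                                   trial_table=trial_table, subject=subject))

    behavior = _behavior_table(config, rng)
    truth = {
        "effect_map": {f"{reg}:{cond}:{comp}": r
                       for (reg, cond, comp), r in sorted(config.effect_map.items())},
        "subject_effects": {f"{s}:{reg}:{cond}:{comp}": r
                            for (s, reg, cond, comp), r in sorted(subject_effects.items())},
        "calibration_ceiling": {f"{cond}:{comp}": float(c[1][-1])
                                for (cond, comp), c in curves.items()},
    }
    return SyntheticDataset(
        stimuli=stimuli, beta=betas, mask=mask, atlas=atlas, affine=affine,
        labels=labels, behavior=behavior, truth=truth, config=config,
        behavioral_rdms=rdms,
    )


def _behavior_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Condition-ordered log-normal RTs with subject offsets; accuracy at
    ceiling.  AOA split mirrors the emulated cohort's 45/55 early/late ratio."""
    n_early = int(round(0.45 * config.n_subjects))
    rows = []
    for si in range(config.n_subjects):
        subject = f"sub-{si + 1:02d}"
        offset = 0.10 * rng.normal()  # log-scale subject speed
        aoa = "early" if si < n_early else "late"
        for cond in CONDITIONS:
            mu = np.log(RT_MEANS_MS[cond]) + offset
            rt = float(np.exp(mu + 0.20 * rng.normal()))
            acc = float(rng.binomial(config.n_trials_per_condition, ACCURACY_P)
                        / config.n_trials_per_condition)
            rows.append({"subject": subject, "condition": cond,
                         "accuracy": acc, "rt_ms": rt, "aoa_group": aoa})
    return pd.DataFrame(rows)


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """One-call generation: stimuli, then beta volumes and behavior."""
    config = config if config is not None else SimulationConfig(effect_map=default_effect_map())
    stimuli = generate_stimuli(config)
    return plant_beta_volumes(stimuli, config)
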
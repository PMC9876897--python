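"""Searchlight RSA: local neural RDMs and their partial rank correlation
with behavioral RDMs.

For every retained voxel, the trial-wise beta patterns inside a 6-mm
sphere yield a neural RDM (one minus Spearman's rho between the patterns
of any two stimuli of one condition).  The neural RDM is then correlated
with one behavioral RDM while the other two are partialled out (partial
Spearman = partial Pearson on rank-transformed lower-triangle vectors),
and the coefficient is Fisher r-to-z transformed.  Subject-level
significance is one-tailed (positive) p < alpha with a cluster-extent
filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rdm import COMPONENTS, DissimilarityMatrix

log = logging.getLogger(__name__)


@dataclass
class BetaVolumeSet:
    """Per-subject trial-wise response amplitudes.

    data : 4D array (x, y, z, trial)
    affine : 4x4 voxel-to-mm map
    mask : 3D boolean analysis mask
    trial_table : DataFrame with columns trial_index, condition, item_id
    subject : subject identifier
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    trial_table: pd.DataFrame
    subject: str = "sub-01"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValueError("beta data must be 4D (x, y, z, trial)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match beta grid")
        idx = set(self.trial_table["trial_index"].astype(int))
        if idx != set(range(self.data.shape[3])):
            raise ValueError("trial_table must cover every 4th-dimension index exactly once")

    def trial_indices(self, condition: str, item_order: list[str]) -> np.ndarray:
        """4th-dim indices of one condition's trials, in the given item order."""
        tt = self.trial_table
        sub = tt[tt["condition"] == condition]
        if sub.empty:
            raise ValueError(f"condition {condition!r} absent from trial table")
        by_item = dict(zip(sub["item_id"], sub["trial_index"].astype(int)))
        missing = [i for i in item_order if i not in by_item]
        if missing:
            raise ValueError(f"trials missing for items {missing[:5]}")
        return np.array([by_item[i] for i in item_order], dtype=int)


@dataclass
class RepresentationMap:
    """Per-voxel Fisher-z partial-correlation map for one
    (subject, condition, component), with its significance mask."""

    z: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    subject: str
    condition: str
    component: str


def variation_filter(beta: BetaVolumeSet, fraction: float = 1.0 / 8.0) -> np.ndarray:
    """Drop voxels whose across-trial variation is small relative to the mean.

    A voxel is retained when its across-trial standard deviation is at
    least ``fraction`` times the absolute across-trial mean.  "Variation"
    is read as the SD of the trial-wise betas — the 1/8 rule fixes the
    ratio but not the variation measure, so this reading is logged.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    sd = beta.data.std(axis=3)
    mean = beta.data.mean(axis=3)
    keep = (sd >= fraction * np.abs(mean)) & beta.mask
    if not keep.any():
        raise ValueError(f"variation filter at fraction={fraction} discarded every voxel")
    log.info(
        "variation filter (SD >= %.3g * |mean| across trials): kept %d / %d mask voxels",
        fraction, int(keep.sum()), int(beta.mask.sum()),
    )
    return keep


def sphere_offsets(radius_mm: float, affine: np.ndarray) -> np.ndarray:
    """Integer voxel offsets whose center-to-center mm distance is <= radius."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    A = np.asarray(affine, dtype=float)[:3, :3]
    sizes = np.linalg.norm(A, axis=0)
    ranges = [np.arange(-int(np.floor(radius_mm / s)), int(np.floor(radius_mm / s)) + 1) for s in sizes]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = grid @ A.T
    keep = np.einsum("ij,ij->i", mm, mm) <= radius_mm**2 + 1e-9
    return grid[keep]


def sphere_indices(
    center: tuple[int, int, int],
    radius_mm: float,
    affine: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """In-mask voxel coordinates within ``radius_mm`` of the center (inclusive)."""
    center = np.asarray(center, dtype=int)
    if not mask[tuple(center)]:
        raise ValueError(f"center {tuple(center)} is outside the mask")
    coords = center + sphere_offsets(radius_mm, affine)
    inside = np.all((coords >= 0) & (coords < np.array(mask.shape)), axis=1)
    coords = coords[inside]
    coords = coords[mask[tuple(coords.T)]]
    return coords


def neural_rdm(patterns: np.ndarray, item_ids: list[str] | None = None,
               condition: str | None = None) -> DissimilarityMatrix:
    """Neural RDM: one minus Spearman's rho between any two trial patterns.

    ``patterns`` is voxels x trials; ranks are taken across voxels within
    each trial.  Constant patterns (zero rank variance) give NaN entries.
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2 or P.shape[1] < 3:
        raise ValueError("patterns must be voxels x trials with >=2 voxels and >=3 trials")
    ranked = stats.rankdata(P, axis=0)
    const = ranked.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranked.T)
    values = 1.0 - corr
    if const.any():
        log.warning("neural_rdm: %d constant pattern(s); entries set to NaN", int(const.sum()))
        values[const, :] = np.nan
        values[:, const] = np.nan
    np.fill_diagonal(values, 0.0)
    n = P.shape[1]
    ids = item_ids if item_ids is not None else [str(i) for i in range(n)]
    return DissimilarityMatrix(values, list(ids), "neural", condition)


def _tri_ranks(rdm: DissimilarityMatrix) -> np.ndarray:
    return stats.rankdata(rdm.lower_triangle())


def partial_spearman(
    neural: DissimilarityMatrix,
    target: DissimilarityMatrix,
    controls: list[DissimilarityMatrix],
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Partial Spearman correlation between two RDMs given control RDMs.

    Lower triangles are vectorized, rank-transformed (average ranks on
    ties), and the partial Pearson correlation of neural vs target given
    the controls is computed by residual regression.  The one-tailed p for
    rho > 0 comes from the t statistic with df = m - 2 - k; with
    ``n_perm`` > 0 a permutation p (joint row/column shuffling of the
    neural RDM) is returned instead.
    """
    mats = [neural, target, *controls]
    for m in mats[1:]:
        if m.item_ids != neural.item_ids:
            raise ValueError("RDMs differ in size or item order")
    y = _tri_ranks(neural)
    x = _tri_ranks(target)
    C = np.column_stack([_tri_ranks(c) for c in controls]) if controls else None
    rho = _partial_corr_ranked(y, x, C)
    m = y.size
    k = 0 if C is None else C.shape[1]
    df = m - 2 - k
    if n_perm > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        n = neural.n
        null = np.empty(n_perm)
        tril = np.tril_indices(n, -1)
        for b in range(n_perm):
            perm = rng.permutation(n)
            vals = neural.values[np.ix_(perm, perm)][tril]
            null[b] = _partial_corr_ranked(stats.rankdata(vals), x, C)
        p = (1 + np.sum(null >= rho)) / (1 + n_perm)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt(df / max(1e-300, 1 - rho**2))
        p = float(stats.t.sf(t, df))
    return float(rho), float(p)


def _partial_corr_ranked(y: np.ndarray, x: np.ndarray, C: np.ndarray | None) -> float:
    ones = np.ones((y.size, 1))
    design = ones if C is None else np.column_stack([ones, C])
    # collinear controls make the design rank deficient
    Q, R = np.linalg.qr(design)
    if np.any(np.abs(np.diag(R)) < 1e-10 * y.size):
        raise ValueError("singular control correlation structure (collinear control RDMs)")
    yr = y - Q @ (Q.T @ y)
    xr = x - Q @ (Q.T @ x)
    ny, nx = np.linalg.norm(yr), np.linalg.norm(xr)
    # residuals below numerical noise mean the vector is explained by the controls
    tol = 1e-8
    if ny <= tol * max(np.linalg.norm(y - y.mean()), 1.0):
        return 0.0
    if nx <= tol * max(np.linalg.norm(x - x.mean()), 1.0):
        return 0.0
    return float((yr @ xr) / (ny * nx))


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-z transform atanh(r); |r| >= 1 is clamped with a warning."""
    r = np.asarray(r, dtype=float)
    clip = np.abs(r) >= 1
    if np.any(clip & np.isfinite(r)):
        warnings.warn("fisher_z: |r| >= 1 clamped to +/-(1 - 1e-7)")
    out = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    out = np.where(np.isnan(r), np.nan, out)
    return float(out) if out.ndim == 0 else out


def searchlight_map(
    beta: BetaVolumeSet,
    behavioral: dict[str, DissimilarityMatrix],
    condition: str,
    radius_mm: float = 6.0,
    alpha: float = 0.05,
    cluster_min: int = 10,
    min_voxels: int = 10,
    variation_fraction: float = 1.0 / 8.0,
    connectivity: int = 18,
) -> dict[str, RepresentationMap]:
    """Whole-volume searchlight for one subject and condition.

    Returns one :class:`RepresentationMap` per linguistic component; for
    each component the partial Spearman correlation against that
    component's behavioral RDM controls the other two.  Spheres with fewer
    than ``min_voxels`` in-mask voxels are skipped (NaN).
    """
    from .group import threshold_clusters  # shared cluster filter

    comps = [c for c in COMPONENTS if c in behavioral]
    if set(comps) != set(COMPONENTS):
        raise ValueError(f"behavioral RDMs required for all of {COMPONENTS}")
    item_ids = behavioral[comps[0]].item_ids
    for c in comps[1:]:
        if behavioral[c].item_ids != item_ids:
            raise ValueError("behavioral RDMs differ in item order")
    trials = beta.trial_indices(condition, item_ids)
    n = len(item_ids)
    tril = np.tril_indices(n, -1)
    m = tril[0].size

    # fixed regression pieces per component: ranked target residualized on controls
    pieces = {}
    for comp in comps:
        x = _tri_ranks(behavioral[comp])
        others = [behavioral[c] for c in comps if c != comp]
        C = np.column_stack([np.ones(m)] + [_tri_ranks(c) for c in others])
        Q, _ = np.linalg.qr(C)
        xr = x - Q @ (Q.T @ x)
        pieces[comp] = (Q, xr / np.linalg.norm(xr))
    df = m - 2 - (len(comps) - 1)

    retained = variation_filter(beta, variation_fraction)
    offsets = sphere_offsets(radius_mm, beta.affine)
    shape = beta.mask.shape
    rho_maps = {c: np.full(shape, np.nan) for c in comps}
    vol = beta.data[..., trials]

    centers = np.argwhere(retained)
    n_skipped = 0
    for center in centers:
        coords = center + offsets
        inside = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
        coords = coords[inside]
        coords = coords[retained[tuple(coords.T)]]
        if coords.shape[0] < max(min_voxels, 2):
            n_skipped += 1
            continue
        P = vol[coords[:, 0], coords[:, 1], coords[:, 2], :]
        ranked = stats.rankdata(P, axis=0)
        if np.any(ranked.std(axis=0) == 0):
            n_skipped += 1
            continue
        corr = np.corrcoef(ranked.T)
        y = stats.rankdata((1.0 - corr)[tril])
        for comp in comps:
            Q, xr = pieces[comp]
            yr = y - Q @ (Q.T @ y)
            ny = np.linalg.norm(yr)
            rho_maps[comp][tuple(center)] = 0.0 if ny == 0 else (yr @ xr) / ny
    if n_skipped:
        log.info("searchlight: %d center(s) skipped (sphere < %d voxels or constant pattern)",
                 n_skipped, min_voxels)

    out = {}
    for comp in comps:
        rho = rho_maps[comp]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt(df / np.clip(1 - rho**2, 1e-300, None))
        p = np.where(np.isnan(rho), np.nan, stats.t.sf(t, df))
        sig = threshold_clusters(p, alpha, cluster_min, connectivity)
        out[comp] = RepresentationMap(
            z=fisher_z(rho), p=p, sig_mask=sig,
            subject=beta.subject, condition=condition, component=comp,
        )
    return out
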
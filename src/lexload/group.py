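"""Group-level inference on representation maps.

One-tailed one-sample t maps across subjects, cluster-extent
thresholding (p < alpha uncorrected, cluster size strictly greater than
the minimum), the cognitive-load statistic (sum of Fisher-z values over a
subject's significantly positive voxels, plus its voxel-count variant),
cross-language overlap maps with per-ROI summaries, subsample stability,
and a permutation test on group-map extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .searchlight import RepresentationMap

log = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class GroupMap:
    t: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    n_subjects: int
    condition: str | None = None
    component: str | None = None


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def threshold_clusters(
    p_map: np.ndarray,
    alpha: float,
    cluster_min: int,
    connectivity: int = 18,
) -> np.ndarray:
    """Suprathreshold (p < alpha) voxels in connected components of size
    strictly greater than ``cluster_min``.  NaN p counts as not significant."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if cluster_min < 0:
        raise ValueError("cluster_min must be >= 0")
    supra = np.nan_to_num(np.asarray(p_map, dtype=float), nan=np.inf) < alpha
    if cluster_min == 0:
        return supra
    labels, n_lab = ndimage.label(supra, structure=_structure(connectivity))
    if n_lab == 0:
        return np.zeros_like(supra, dtype=bool)
    sizes = np.bincount(labels.ravel())
    keep = sizes > cluster_min
    keep[0] = False
    return keep[labels]


def one_sample_t_map(
    z_maps: list[np.ndarray],
    alpha: float = 0.05,
    cluster_min: int = 10,
    connectivity: int = 18,
    n_min: int = 3,
    condition: str | None = None,
    component: str | None = None,
) -> GroupMap:
    """Voxel-wise one-tailed one-sample t test (H1: mean > 0) across subjects.

    Voxels where fewer than ``n_min`` subjects have data are NaN.  A voxel
    with zero across-subject SD gets a +/-inf t sentinel (p = 0 when the
    mean is positive); all-zero maps give t = 0, p = 0.5.
    """
    stack = np.stack([np.asarray(z, dtype=float) for z in z_maps])
    finite = np.isfinite(stack)
    n = finite.sum(axis=0)
    safe_n = np.maximum(n, 1)
    vals = np.where(finite, stack, 0.0)
    mean = vals.sum(axis=0) / safe_n
    ss = (np.where(finite, stack - mean, 0.0) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
        t = mean / (sd / np.sqrt(safe_n))
    mean = np.where(n > 0, mean, np.nan)
    zero_sd = (sd == 0) & (n >= n_min)
    if np.any(zero_sd & (mean != 0)):
        log.warning("one_sample_t_map: %d voxel(s) with zero across-subject SD",
                    int(np.sum(zero_sd & (mean != 0))))
    with np.errstate(invalid="ignore"):
        t = np.where(zero_sd, np.sign(np.nan_to_num(mean)) * np.inf, t)
        t = np.where(zero_sd & (mean == 0), 0.0, t)
    t = np.where(n < n_min, np.nan, t)
    with np.errstate(invalid="ignore"):
        p = stats.t.sf(t, np.maximum(n - 1, 1))
    p = np.where(np.isnan(t), np.nan, p)
    sig = threshold_clusters(p, alpha, cluster_min, connectivity)
    return GroupMap(t=t, p=p, sig_mask=sig, n_subjects=len(z_maps),
                    condition=condition, component=component)


def cognitive_load(z_map: np.ndarray, sig_mask: np.ndarray) -> tuple[float, int]:
    """Cognitive load: sum of Fisher-z values over the significant voxels.

    Returns ``(load, n_sig_voxels)`` so the voxel-count validation variant
    comes for free.  Significance is one-tailed positive, so loads are
    non-negative and exactly zero on empty masks.
    """
    sig = np.asarray(sig_mask).astype(bool)
    if not sig.any():
        return 0.0, 0
    vals = np.asarray(z_map, dtype=float)[sig]
    if not np.all(np.isfinite(vals)):
        raise ValueError("NaN z values inside the significance mask (upstream invariant breach)")
    return float(vals.sum()), int(sig.sum())


def compute_load_table(
    rep_maps: dict[tuple[str, str, str], RepresentationMap],
    aoa_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format load table from subject-level representation maps.

    ``rep_maps`` maps (subject, condition, component) to a
    :class:`RepresentationMap`; loads use each map's own significance mask.
    """
    rows = []
    for (subject, condition, component), rmap in sorted(rep_maps.items()):
        load, n_sig = cognitive_load(rmap.z, rmap.sig_mask)
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "component": component,
                "load": load,
                "n_sig_voxels": n_sig,
                "aoa_group": (aoa_groups or {}).get(subject, ""),
            }
        )
    return pd.DataFrame(rows)


def overlap_map(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    atlas: np.ndarray,
    affine: np.ndarray | None = None,
    stat: np.ndarray | None = None,
    connectivity: int = 18,
    labels: dict[int, str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voxel-wise AND of two significance masks with per-ROI accounting.

    Returns the overlap mask and a table with one row per atlas ROI that
    contains overlap voxels (voxel count, peak mm coordinate).  The peak
    is the max-``stat`` voxel in the ROI's overlap when a statistic map is
    given, else the overlap centroid snapped to a member voxel.
    """
    a = np.asarray(sig_a).astype(bool)
    b = np.asarray(sig_b).astype(bool)
    atlas = np.asarray(atlas)
    if a.shape != b.shape or a.shape != atlas.shape:
        raise ValueError("mask/atlas grids differ")
    overlap = a & b
    rows = []
    for lab in np.unique(atlas[overlap]):
        if lab == 0:
            continue
        roi_overlap = overlap & (atlas == lab)
        coords = np.argwhere(roi_overlap)
        if stat is not None:
            vals = np.asarray(stat, dtype=float)[tuple(coords.T)]
            peak_vox = coords[np.nanargmax(vals)]
        else:
            centroid = coords.mean(axis=0)
            peak_vox = coords[np.argmin(np.linalg.norm(coords - centroid, axis=1))]
        if affine is not None:
            peak_mm = (np.asarray(affine) @ np.append(peak_vox, 1))[:3]
        else:
            peak_mm = peak_vox.astype(float)
        rows.append(
            {
                "roi": int(lab),
                "roi_name": (labels or {}).get(int(lab), str(int(lab))),
                "n_voxels": int(roi_overlap.sum()),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
            }
        )
    return overlap, pd.DataFrame(rows, columns=["roi", "roi_name", "n_voxels",
                                                "peak_x_mm", "peak_y_mm", "peak_z_mm"])


def _group_mean_loads(load_table: pd.DataFrame, subjects: list[str]) -> np.ndarray:
    sub = load_table[load_table["subject"].isin(subjects)]
    cells = sub.groupby(["condition", "component"])["load"].mean()
    idx = pd.MultiIndex.from_product([sorted(load_table["condition"].unique()),
                                      sorted(load_table["component"].unique())])
    return cells.reindex(idx).to_numpy()


def subsample_stability(
    load_table: pd.DataFrame,
    sizes: list[int],
    n_rep: int,
    seed: int,
) -> pd.DataFrame:
    """Stability of group-mean loads under random subject subsampling.

    For each subsample, group-mean loads per (condition, component) cell
    are Pearson-correlated with the full-sample cell means.
    """
    subjects = sorted(load_table["subject"].unique())
    rng = np.random.default_rng(seed)
    full = _group_mean_loads(load_table, subjects)
    rows = []
    for size in sizes:
        if size < 3:
            raise ValueError("subsample size must be >= 3")
        if size > len(subjects):
            raise ValueError(f"subsample size {size} exceeds {len(subjects)} subjects")
        for rep in range(n_rep):
            pick = list(rng.choice(subjects, size=size, replace=False))
            sub = _group_mean_loads(load_table, pick)
            ok = np.isfinite(full) & np.isfinite(sub)
            r = float(np.corrcoef(full[ok], sub[ok])[0, 1]) if ok.sum() > 2 else np.nan
            rows.append({"size": size, "replicate": rep, "correlation": r})
    return pd.DataFrame(rows)


def permutation_extent_test(
    z_maps_group1: list[np.ndarray],
    z_maps_group2: list[np.ndarray],
    alpha: float = 0.05,
    cluster_min: int = 10,
    connectivity: int = 18,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test on the difference in group-map significant extent.

    The statistic (an assumption — the choice is flagged in the output) is
    the group-1 minus group-2 count of significant voxels, each group's
    extent taken from its own one-sample t map.  Group labels are shuffled
    ``n_perm`` times; one-tailed p = (1 + #null >= observed) / (1 + n_perm).
    """
    if n_perm < 100:
        log.warning("permutation_extent_test: n_perm=%d is small; p is coarse", n_perm)
    if not z_maps_group1 or not z_maps_group2:
        raise ValueError("both groups must be non-empty")

    def extent(maps):
        gm = one_sample_t_map(maps, alpha=alpha, cluster_min=cluster_min,
                              connectivity=connectivity)
        return int(gm.sig_mask.sum())

    observed = extent(z_maps_group1) - extent(z_maps_group2)
    pooled = list(z_maps_group1) + list(z_maps_group2)
    n1 = len(z_maps_group1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        g1 = [pooled[i] for i in perm[:n1]]
        g2 = [pooled[i] for i in perm[n1:]]
        if extent(g1) - extent(g2) >= observed:
            count += 1
    return {
        "statistic": "group1_minus_group2_significant_voxel_extent (assumed statistic)",
        "observed": observed,
        "p_value": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
    }
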
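"""End-to-end orchestration: searchlight per subject, group maps, loads."""

from __future__ import annotations

import logging

from .group import GroupMap, compute_load_table, one_sample_t_map
from .rdm import COMPONENTS, CONDITIONS
from .searchlight import RepresentationMap, searchlight_map
from .synth import SyntheticDataset

log = logging.getLogger(__name__)


def run_searchlight_all(
    dataset: SyntheticDataset,
    conditions: list[str] | None = None,
    radius_mm: float = 6.0,
    alpha: float = 0.05,
    cluster_min: int = 10,
    **kwargs,
) -> dict[tuple[str, str, str], RepresentationMap]:
    """Searchlight maps for every (subject, condition, component)."""
    conditions = conditions or list(CONDITIONS)
    rep_maps = {}
    for beta in dataset.beta:
        for cond in conditions:
            behavioral = {comp: dataset.behavioral_rdms[(cond, comp)]
                          for comp in COMPONENTS}
            maps = searchlight_map(beta, behavioral, cond, radius_mm=radius_mm,
                                   alpha=alpha, cluster_min=cluster_min, **kwargs)
            for comp, rmap in maps.items():
                rep_maps[(beta.subject, cond, comp)] = rmap
        log.info("searchlight done for %s", beta.subject)
    return rep_maps


def group_maps(
    rep_maps: dict[tuple[str, str, str], RepresentationMap],
    alpha: float = 0.05,
    cluster_min: int = 10,
    connectivity: int = 18,
) -> dict[tuple[str, str], GroupMap]:
    """One-sample group t map per (condition, component)."""
    subjects = sorted({s for s, _, _ in rep_maps})
    out = {}
    for cond in CONDITIONS:
        for comp in COMPONENTS:
            zs = [rep_maps[(s, cond, comp)].z for s in subjects
                  if (s, cond, comp) in rep_maps]
            if not zs:
                continue
            out[(cond, comp)] = one_sample_t_map(
                zs, alpha=alpha, cluster_min=cluster_min,
                connectivity=connectivity, condition=cond, component=comp)
    return out


def analyze(dataset: SyntheticDataset, **searchlight_kwargs) -> dict:
    """Convenience bundle: subject maps, group maps, and the load table."""
    rep_maps = run_searchlight_all(dataset, **searchlight_kwargs)
    gmaps = group_maps(rep_maps)
    aoa = dict(zip(dataset.behavior["subject"], dataset.behavior["aoa_group"]))
    loads = compute_load_table(rep_maps, aoa_groups=aoa)
    return {"rep_maps": rep_maps, "group_maps": gmaps, "load_table": loads}
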
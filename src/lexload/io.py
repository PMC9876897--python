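"""File-format plumbing: NIfTI volumes via nibabel, TSV tables via pandas.

Dialects
--------
Stimulus TSV: columns ``id``, ``condition``, ``logo_units``, ``phon_units``
(tokens joined by ``|``), ``embedding_ref`` pointing into an embedding TSV
(``id`` + one column per dimension).  Events TSV: ``trial_index``,
``condition``, ``item_id``.  RDMs are square TSVs with id header
row/column.  Load tables, behavior, labels and overlap reports are plain
long-format TSVs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .rdm import DissimilarityMatrix, StimulusItem
from .searchlight import BetaVolumeSet, RepresentationMap
from .synth import SimulationConfig, SyntheticDataset


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_rdm(rdm: DissimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(rdm.values, index=rdm.item_ids, columns=rdm.item_ids)
    df.to_csv(path, sep="\t")


def load_rdm(path: str | Path, component: str, condition: str | None = None) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DissimilarityMatrix(df.to_numpy(), [str(c) for c in df.columns],
                               component, condition)


def save_stimuli(stimuli: list[StimulusItem], stim_path: str | Path,
                 emb_path: str | Path) -> None:
    rows = []
    emb_rows = []
    for s in stimuli:
        rows.append({
            "id": s.id, "condition": s.condition,
            "logo_units": "|".join(s.logo_units),
            "phon_units": "|".join(s.phon_units),
            "embedding_ref": s.id,
        })
        emb_rows.append([s.id] + list(s.embedding))
    pd.DataFrame(rows).to_csv(stim_path, sep="\t", index=False)
    dim = len(stimuli[0].embedding)
    pd.DataFrame(emb_rows, columns=["id"] + [f"d{i}" for i in range(dim)]).to_csv(
        emb_path, sep="\t", index=False)


def load_stimuli(stim_path: str | Path, emb_path: str | Path) -> list[StimulusItem]:
    stim = pd.read_csv(stim_path, sep="\t")
    emb = pd.read_csv(emb_path, sep="\t").set_index("id")
    out = []
    for _, row in stim.iterrows():
        vec = emb.loc[row["embedding_ref"]].to_numpy(dtype=float)
        out.append(StimulusItem(
            id=str(row["id"]), condition=row["condition"],
            logo_units=tuple(str(row["logo_units"]).split("|")),
            phon_units=tuple(str(row["phon_units"]).split("|")),
            embedding=vec,
        ))
    return out


def load_beta(beta_path: str | Path, events_path: str | Path,
              mask_path: str | Path, subject: str = "sub-01") -> BetaVolumeSet:
    data, affine = load_volume(beta_path)
    mask, _ = load_volume(mask_path)
    events = pd.read_csv(events_path, sep="\t")
    return BetaVolumeSet(data=data, affine=affine, mask=mask > 0.5,
                         trial_table=events, subject=subject)


def save_rep_map(rmap: RepresentationMap, affine: np.ndarray, outdir: str | Path) -> None:
    outdir = Path(outdir)
    stem = f"{rmap.subject}_{rmap.condition}_{rmap.component}"
    save_volume(rmap.z, affine, outdir / f"{stem}_z.nii.gz")
    save_volume(rmap.p, affine, outdir / f"{stem}_p.nii.gz")
    save_volume(rmap.sig_mask.astype(np.float32), affine, outdir / f"{stem}_sig.nii.gz")


def load_rep_map(outdir: str | Path, subject: str, condition: str,
                 component: str) -> RepresentationMap:
    outdir = Path(outdir)
    stem = f"{subject}_{condition}_{component}"
    z, _ = load_volume(outdir / f"{stem}_z.nii.gz")
    p, _ = load_volume(outdir / f"{stem}_p.nii.gz")
    sig, _ = load_volume(outdir / f"{stem}_sig.nii.gz")
    z = np.where(np.isfinite(z), z, np.nan)
    return RepresentationMap(z=z, p=p, sig_mask=sig > 0.5, subject=subject,
                             condition=condition, component=component)


def _config_to_json(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["grid_shape"] = list(config.grid_shape)
    d["effect_map"] = {f"{r}:{c}:{k}": v for (r, c, k), v in config.effect_map.items()}
    return d


def config_from_json(d: dict) -> SimulationConfig:
    d = dict(d)
    d["grid_shape"] = tuple(d.get("grid_shape", (20, 20, 20)))
    em = {}
    for key, v in d.get("effect_map", {}).items():
        region, cond, comp = key.split(":")
        em[(int(region), cond, comp)] = float(v)
    d["effect_map"] = em
    return SimulationConfig(**d)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Materialize a synthetic dataset: per-subject beta NIfTI + events
    TSV, mask/atlas NIfTI, stimulus/behavior/label TSVs, truth + config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in ds.beta:
        save_volume(b.data, ds.affine, outdir / f"{b.subject}_beta.nii.gz")
        b.trial_table.to_csv(outdir / f"{b.subject}_events.tsv", sep="\t", index=False)
    save_volume(ds.mask.astype(np.float32), ds.affine, outdir / "mask.nii.gz")
    save_volume(ds.atlas.astype(np.float32), ds.affine, outdir / "atlas.nii.gz")
    ds.labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    save_stimuli(ds.stimuli, outdir / "stimuli.tsv", outdir / "embeddings.tsv")
    ds.behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=2))
    (outdir / "config.json").write_text(json.dumps(_config_to_json(ds.config), indent=2))


def read_dataset(outdir: str | Path) -> SyntheticDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    from .rdm import build_all_rdms

    outdir = Path(outdir)
    config = config_from_json(json.loads((outdir / "config.json").read_text()))
    stimuli = load_stimuli(outdir / "stimuli.tsv", outdir / "embeddings.tsv")
    mask, affine = load_volume(outdir / "mask.nii.gz")
    atlas, _ = load_volume(outdir / "atlas.nii.gz")
    betas = []
    for si in range(config.n_subjects):
        subject = f"sub-{si + 1:02d}"
        betas.append(load_beta(outdir / f"{subject}_beta.nii.gz",
                               outdir / f"{subject}_events.tsv",
                               outdir / "mask.nii.gz", subject=subject))
    return SyntheticDataset(
        stimuli=stimuli, beta=betas, mask=mask > 0.5,
        atlas=np.round(atlas).astype(int), affine=affine,
        labels=pd.read_csv(outdir / "labels.tsv", sep="\t"),
        behavior=pd.read_csv(outdir / "behavior.tsv", sep="\t"),
        truth=json.loads((outdir / "truth.json").read_text()),
        config=config, behavioral_rdms=build_all_rdms(stimuli),
    )
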
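"""Plant representational geometry in one region and recover it.

A synthetic dataset is generated with the Chinese-word logo-grapheme RDM
embedded (effect size r = 0.7) into the multivoxel patterns of region 1;
everything else is white noise.  The 6-mm searchlight computes per-voxel
partial Spearman correlations (each component controlling the other two),
Fisher-z transformed; a group one-tailed t map with p < 0.05 and cluster
size > 10 should light up the planted region and nothing else.
"""

import numpy as np

import lexload as ll

cfg = ll.SimulationConfig(
    n_subjects=8, seed=4, n_regions=1, region_gap_voxels=4,
    effect_map={(1, "chinese_word", "logo"): 0.7},
)
ds = ll.simulate(cfg)
print(f"dataset: {cfg.n_subjects} subjects, mask of {int(ds.mask.sum())} voxels "
      f"({int((ds.atlas == 1).sum())} in the planted region)")

maps = ll.run_searchlight_all(ds, conditions=["chinese_word"])
zs = [maps[(b.subject, "chinese_word", "logo")].z for b in ds.beta]
gm = ll.one_sample_t_map(zs, alpha=0.05, cluster_min=10)

sig = gm.sig_mask
in_region = (sig & (ds.atlas == 1)).sum()
print(f"group-significant voxels: {int(sig.sum())}, of which {int(in_region)} "
      f"inside the planted region")

for comp in ll.COMPONENTS:
    med = np.nanmedian([np.nanmedian(maps[(b.subject, 'chinese_word', comp)].z[ds.atlas == 1])
                        for b in ds.beta])
    print(f"median in-region z for {comp:9s}: {med:+.3f}")
print("\nOnly the planted component (logo) should show a clearly positive z —"
      "\nthe partial correlation keeps the other components near zero.")

loads = ll.compute_load_table(maps)
print("\ncognitive loads (sum of z over each subject's significant voxels):")
print(loads.groupby("component")[["load", "n_sig_voxels"]].mean().round(2))
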
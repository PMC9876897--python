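"""Build behavioral dissimilarity matrices from stimulus decompositions.

Two reading stimuli are compared by the overlap of their basic units:
dissimilarity = 1 - shared / (|a| + |b|), with shared counted as the
multiset intersection.  Semantic dissimilarity is 1 - cosine similarity
of embedding vectors.  The script prints the two hand-checkable reference
pairs and then the summary of a full 40x40 RDM per component built from
synthetic stimuli.
"""

import numpy as np

import lexload as ll

# 热情 (enthusiasm) vs 眼睛 (eye): 6 and 5 logo-graphemes, 2 shared
reqing = ["扌", "丸", "灬", "忄", "青", "月"]
yanjing = ["目", "艮", "目", "青", "月"]
d_logo = ll.overlap_dissimilarity(reqing, yanjing)
print(f"logo-grapheme dissimilarity 热情/眼睛: {d_logo:.3f}   (1 - 2/11)")

# their pinyin: 6 phonetic units each (initial, final, tone per syllable), 1 shared
reqing_py = ["r", "e", "tone4", "q", "ing", "tone2"]
yanjing_py = ["y", "an", "tone3", "j", "ing", "tone1"]
d_phon = ll.overlap_dissimilarity(reqing_py, yanjing_py)
print(f"phonological dissimilarity rèqíng/yǎnjīng: {d_phon:.3f}   (1 - 1/12)")

# full behavioral RDMs over a synthetic stimulus inventory
stimuli = ll.generate_stimuli(ll.SimulationConfig(seed=0))
rdms = ll.build_all_rdms(stimuli)
print("\nper-condition RDMs (40 x 40, 780 unique pairs each):")
for (cond, comp), rdm in sorted(rdms.items()):
    tri = rdm.lower_triangle()
    print(f"  {cond:14s} {comp:9s}  mean={tri.mean():.3f}  range=[{tri.min():.3f}, {tri.max():.3f}]")

corr = ll.rdm_correlations([rdms[("chinese_word", c)] for c in ll.COMPONENTS])
print("\nSpearman correlations among the Chinese-word RDMs:")
print(corr.to_string(index=False))
print("\nLow correlations mean the three components carry distinct structure,"
      "\nwhich is what lets the searchlight separate them via partial correlation.")
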
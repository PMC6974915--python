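"""Quantify the four morphological traits and test pollination association.

Traits are measured directly from each 415-landmark configuration: tube
curvature (mm^-1), lobe area ratio, tube dilation, lobe recurvation (deg).
Association with pollination type uses LOD = (n/2) log10(SST/SSW) plus a
permutation test.
"""

import corollamorph as cm
from corollamorph.traits import TRAIT_COLUMNS

study = cm.make_fixture("two-clade-curvature")
traits = cm.trait_table(study.collection)
print(traits.groupby("pollination")[TRAIT_COLUMNS].mean().round(4))
print()

labels = traits["pollination"].to_numpy()
for col in ["centroid_size", *TRAIT_COLUMNS]:
    res = cm.lod_permutation_test(traits[col].to_numpy(), labels,
                                  n_permutations=10_000, seed=7, trait_name=col)
    gc = cm.group_comparisons(traits[col].to_numpy(), labels)
    h = gc.set_index("test").loc["kruskal-wallis", "statistic"]
    print(f"{col:18s} LOD = {res.lod:7.2f}  P = {res.p_value:.2e}  "
          f"(Kruskal-Wallis H = {h:.1f})")
# Tube curvature separates the hummingbird and bee clades, so its LOD is large
# and its permutation P sits at the test's resolution; traits that were not
# manipulated show small LODs.
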
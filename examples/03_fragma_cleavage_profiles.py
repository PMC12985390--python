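"""Methylation-dependent cleavage profiles around CpG sites (FRAGMA).

Simulates a methylome (CpG sites labelled tissue-wide or tumor-specific
hyper/hypomethylated by the 70%/30% density rules) and a sample whose
cutting is enriched at hypermethylated CpGs with the 5' terminal base
exactly at the C (offset 0) and the 3' terminal base 1 nt before the CpG
(offset -1). The printed profiles show exactly those peaks; hypomethylated
sites stay flat, which is the signal FRAGMA classification feeds on.
"""

import numpy as np

from cfends import fragma, synthetic_data
from cfends.synthetic_data import SimulationConfig

config = SimulationConfig(seed=3, n_fragments=20_000, n_case=1, n_control=1,
                          methyl_anchor_prob=0.25)
genome = synthetic_data.simulate_reference(config)
methylome, tissue_config = synthetic_data.simulate_methylome(genome, seed=3)
labels = fragma.classify_cpgs(methylome, tissue_config)
print("CpG classes:", labels.value_counts().to_dict())

cohort = synthetic_data.simulate_cohort(genome, methylome, config, labels)
fragments = cohort.samples[0][2]

hyper = methylome[labels.isin(["tissue_hyper", "hcc_specific_hyper"])]
hypo = methylome[labels.isin(["tissue_hypo", "hcc_specific_hypo"])]
for end_type in ("5p", "3p"):
    prof_hyper = fragma.cleavage_profile(fragments, hyper, end_type)
    prof_hypo = fragma.cleavage_profile(fragments, hypo, end_type)
    peak = prof_hyper.positions[np.argmax(prof_hyper.mean_proportion)]
    print(f"\n{end_type} cleavage proportion (%) by position relative to the CpG C:")
    print("  pos  :", "  ".join(f"{p:+d}".rjust(6) for p in prof_hyper.positions))
    print("  hyper:", "  ".join(f"{v:6.2f}" for v in prof_hyper.mean_proportion))
    print("  hypo :", "  ".join(f"{v:6.2f}" for v in prof_hypo.mean_proportion))
    print(f"  -> hypermethylated peak at position {peak:+d}")

vector = fragma.fragma_features(fragments, methylome, labels, "3p")
print(f"\n3' FRAGMA feature vector: {len(vector)} values "
      "(4 CpG categories x 11 window positions), ready for the classifier")
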
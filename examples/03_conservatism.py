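"""Taxonomic conservatism of enzyme traits.

Simulates a study whose trait frequencies are conserved at the genus level
and shows that the coefficient of variation (sample SD / mean per taxon)
drops as taxonomic resolution increases.
"""

import tempfile

from cazytraits import annotate_study, conservatism
from cazytraits.simulate import SyntheticConfig, generate_study

with tempfile.TemporaryDirectory() as study_dir:
    config = SyntheticConfig(
        n_genomes=40, conserved_rank="genus",
        between_clade_cv=0.6, within_clade_cv=0.05, seed=7,
    )
    generate_study(config, study_dir)
    result = annotate_study(study_dir=study_dir)
    table = conservatism(result.profiles, result.taxonomy)

medians = table.dropna(subset=["cov"]).groupby("rank", sort=False)["cov"].median()
print("median CoV per rank (taxa with >1 genome, all traits):")
for rank, value in medians.items():
    print(f"  {rank:<10} {value:.3f}")
# Above the conserved rank each taxon mixes clades with different planted
# means, so CoV is high; at the genus level genomes scatter only by the
# within-clade dispersion (5%), so CoV collapses toward it.
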
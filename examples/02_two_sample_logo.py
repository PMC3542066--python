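"""Two-sample logo: residues enriched around stably phosphorylated sites.

Simulates a medium-sized dataset, splits sites at the median variability
and contrasts the +/-6 flanking windows of the low- vs high-variability
halves, position by position and residue by residue.
"""

from phosvar import SimulationConfig, simulate_dataset
from phosvar.flank_analysis import add_flank_windows, two_sample_logo
from phosvar.structure_categories import classify_sites
from phosvar.variability import add_variability, split_by_variability

ds = simulate_dataset(SimulationConfig(seed=7, n_proteins=400, n_sites=2000,
                                       with_conservation=False))
table = add_flank_windows(
    classify_sites(add_variability(ds.site_table), ds.profiles), ds.sequences
)
low, high = split_by_variability(table, q=0.5)
print(f"{len(low)} low- vs {len(high)} high-variability sites")

logo = two_sample_logo(list(low["window"]), list(high["window"]), alpha=0.05)
flagged = logo[logo.flag != "NONE"].sort_values("p")
print(flagged.head(10).to_string(index=False))
print("ENRICHED = residue more frequent near stable (low-variability) sites; "
      "DEPLETED = more frequent near dynamically regulated ones. The generator "
      "plants proline at +1 of high-variability disordered sites, so P at +1 "
      "shows up as depleted in the low set.")
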
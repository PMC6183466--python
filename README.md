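# codmix

Ecotype-mixture analysis for coastal Atlantic cod surveys.

Along the Norwegian Skagerrak coast, juvenile (age-0) cod caught in beach
seines are a mixture of two genetically distinct ecotypes: a stationary
"fjord" type and a "North Sea" type of putative offshore origin. `codmix`
re-implements the full analysis chain that turns a multi-year beach-seine
survey plus a small diagnostic SNP panel into ecological conclusions about
the coexistence and growth of the two types:

1. **Panel design** (`codmix.markerpanel`) — candidate biallelic SNPs are
   ranked by Nei's coefficient of gene differentiation between the two
   reference samples,
   `G_ST = (H_T − H_S) / H_T`, and greedily pruned so that no kept pair has
   composite LD (absolute genotype-dosage correlation) above 0.5.
2. **Assignment** (`codmix.assign`) — each fish's multilocus genotype is
   scored against both references with the Rannala–Mountain Bayesian
   genotype probability (Dirichlet(½, ½) prior over allele frequencies);
   fish with < 20 scored loci or a normalized likelihood score < 80% stay
   unassigned.
3. **Coexistence** (`codmix.coexist`) — Simpson's index of diversity
   `1 − f² − (1 − f)²` of the assigned mixture at nested scales (coast,
   region, station, haul), both-types co-occurrence, and a sample-size
   weighted regression of the station North-Sea fraction on distance
   inland from the outer coast.
4. **Otolith growth** (`codmix.otolith`) — biological-intercept
   back-calculation from daily increments,
   `L_a = L_c + (O_a − O_c)(L_c − L_i)/(O_c − O_i)` with the intercept at
   hatch (L_i = 4.5 mm, O_i = 9 μm), giving ages, hatch dates and daily
   growth rates, plus hierarchical partitioning of length variance into
   age vs growth-rate contributions.
5. **Growth model** (`codmix.growthmodel`) — a linear mixed model for log
   body length,
   `log L = c₀ + c₁Y + c₂WE + c₃VT + c₄VC + c₅CO + c₆WE·CO + c₇VT·CO + c₈VC·CO + region + ε`,
   with a region random intercept, fitted by profiled REML/ML and selected
   in two AIC steps (random structure first, then nine nested fixed
   structures).

Because the original fish records are archived externally, the package
ships a seeded generator (`codmix.synthio`) that reproduces the survey's
statistical structure — divergent reference frequencies at a target mean
G_ST, a linear decline of the North-Sea fraction with distance inland
(−1.85×10⁻⁵ per metre), lengths drawn from the published mixed-model
coefficients with an 8% region variance share, and otolith series with
known growth targets — so every stage is testable end to end.

## Worked example

```bash
python examples/05_growth_model.py
```

```
ML AIC by fixed structure:
  Y+WE+VT+VC+CO+WE:CO+VT:CO+VC:CO      -1340.4
  Y+WE+VT+VC+CO+WE:CO+VT:CO            -1337.6
  ...
  Y                                     -636.2
selected: Y+WE+VT+VC+CO+WE:CO+VT:CO+VC:CO (refit by REML, n = 3660)
origin effect: 0.100 +/- 0.031 log-cm (generating truth 0.149)
region variance share: 8.2% (generating truth 8%)
predicted length (fjord): 9.38 cm
predicted length (northsea): 11.39 cm
```

A reduced synthetic survey (60 stations, 12 regions) is generated, the
two-step AIC selection keeps the region random intercept and a rich fixed
structure, and the refitted model recovers the generating conditions: the
North-Sea origin effect within two standard errors, the ~8% share of
length variance attributable to region, and the roughly 2 cm length
advantage of North Sea over fjord juveniles at identical habitat.

The other examples cover the generator (`01`), panel + assignment (`02`),
multi-scale coexistence (`03`) and otolith growth (`04`). A thin CLI wraps
the same functions:

```bash
ecotype-mix all --seed 1 --out out/          # full simulated pipeline
ecotype-mix select-panel --genotypes ref.csv --labels labels.csv --out panel.tsv
ecotype-mix assign --genotypes coast.csv --ref-genotypes ref.csv \
    --ref-labels labels.csv --out assignments.tsv
```

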
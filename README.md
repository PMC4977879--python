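# pvc-hgtscape

Comparative phylogenomics of horizontal gene transfer (HGT) and
cell-plan evolution for PVC-style bacterial clades (Planctomycetes,
Verrucomicrobiae, Chlamydiae, Lentisphaerae).

Some PVC bacteria divide their cytoplasm with an intracytoplasmic
membrane (compartmentalization); the clade also splits into sympatric
lineages (living among other microorganisms, exchange-prone) and
allopatric ones (obligate intracellular, isolated from exchange
partners).  This package provides the full analysis chain needed to ask
whether either trait shapes genome content:

* **Ancestral reconstruction** of the binary cell-plan character by
  unit-cost parsimony (with full ambiguity reporting) and by a
  two-state Mk model — `MkCharacterModel(...).fit()` returns rates,
  standard errors, per-node marginal probabilities
  `P(compartmentalized)` from Felsenstein pruning, and a `summary()`.
* **Gene-family clustering** by Markov clustering (MCL) of a weighted
  protein-similarity graph.
* **Gain/loss mapping** of each family's presence/absence pattern onto
  the rooted species tree by Sankoff parsimony (default gain:loss cost
  2:1; Dollo mode available).  Gains on terminal branches are
  *specific* (modern species), internal gains *non-specific*
  (ancestors).  Replaying the inferred events always reproduces the
  input matrix exactly.
* **HGT classification** of each gain from ranked homology hits using
  explicit threshold rules: ORFans lack any hit with e-value < 1e-4 and
  coverage > 50%; HGT calls remove self-phylum hits, drop hits failing
  e-value ≤ 1e-5 / coverage ≥ 60% / identity ≥ 30%, and accept iff none
  of the first ten surviving hits belongs to a sister phylum of the
  gaining lineage.  Transfer partners are the majority phylum of the
  retained hits.
* **Group statistics**: Shapiro-Wilk + Levene gatekeeping into one-way
  ANOVA + Tukey HSD or Kruskal-Wallis + Nemenyi, applied to HGT
  proportions and to the nine mobilome element classes, grouped by cell
  plan, lifestyle, phylum (the confounding control) or combined labels.
* **A synthetic-data generator** — gene content evolving by
  origination/loss/transfer along the tree with lifestyle-scaled
  transfer rates, hit tables whose taxonomy reflects true donors, an Mk
  character and mobilome counts — with a complete truth log, so the
  whole pipeline is testable against known ground truth.

A 33-tip demonstration tree of the PVC super-phylum (faithful topology,
illustrative branch lengths) ships with the package.

## Worked example

```python
import pvc_hgtscape as ph

tree = ph.load_pvc_demo()

# 1. cell-plan history
pars = ph.fitch_parsimony(tree)
print(pars.score, pars.placements[0].child, pars.placements[0].kind)
fit = ph.mk_fit(tree)
print(f"root P(compartmentalized) = {fit.root_probability(1):.3f}")

# 2. synthetic gene content -> events -> HGT calls -> statistics
from pvc_hgtscape.evaluation import detect_hgt
cfg = ph.SimConfig(seed=3, hit_phylum_noise=0.0)
matrix, log, events = detect_hgt(tree, cfg)
summary = ph.summarize_hgt(events, matrix)
print(summary.per_species.loc["Akkermansia_muciniphila",
                              ["total_hgt", "specific_hgt"]].to_dict())
report = ph.lifestyle_contrast(summary, tree)
row = report.query("measure=='specific_proportion' and scheme=='lifestyle'")
print(row[["test", "p_value"]].iloc[0].to_dict())
```

prints

```
1 Chlamydiaceae loss
root P(compartmentalized) = 0.959
{'total_hgt': 7.0, 'specific_hgt': 5.0}
{'test': 'kruskal', 'p_value': 0.000580858350177157}
```

i.e. the demo character history needs exactly one change — a loss of
compartmentalization on the stem of the Chlamydiaceae — the root is
reconstructed as compartmentalized with probability 0.96, and on
synthetic data generated with reduced allopatric transfer (the default
multiplier 0.2) the lifestyle contrast on specific-HGT proportions is
strongly significant.

The same pipeline runs from the shell:

```bash
pvc-hgtscape run --seed 3 --out results/demo     # full synthetic run
pvc-hgtscape ancestral --method both             # ancestral-state table
pvc-hgtscape validate --tree T.nwk --annot A.tsv # input checking
```

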
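# Methods

`pvc-hgtscape` implements a comparative-phylogenomic workflow for clades
like the PVC super-phylum (Planctomycetes, Verrucomicrobiae, Chlamydiae,
Lentisphaerae): reconstructing the evolution of a binary cell-plan
character (compartmentalization by an intracytoplasmic membrane),
mapping gene gain/loss events from phyletic patterns, classifying gains
as horizontal transfers (HGT) or ORFans from filtered homology hits,
and comparing HGT and mobilome loads across groups of species.  This
note records the models, the defaults and why, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

The species tree is rooted, possibly multifurcating, with non-negative
branch lengths in expected substitutions.  Every tip carries a phylum,
a lifestyle (`sympatric` — living among other microorganisms;
`allopatric` — obligate intracellular, isolated from exchange partners)
and a cell plan (`compartmentalized`, `non_compartmentalized`, or
`unknown`).  The tree is never re-rooted: the polarity of gains and
losses, and the distinction between "modern species" (terminal
branches) and "ancestors" (internal branches), depend on the root.  An
unknown cell plan is missing data — an all-ones tip conditional in the
likelihood and a free state in parsimony — never a third state.

## Ancestral reconstruction of the cell plan

**Parsimony.**  Unit-cost Sankoff (equivalent to Fitch on binary trees;
valid on multifurcations).  The result reports the minimal change
count, the full most-parsimonious state *set* per node, and the set of
equally parsimonious branch placements for each change.  Ambiguity is
surfaced rather than resolved: when a change can sit on more than one
branch, all placements are listed.

**Maximum likelihood.**  A two-state continuous-time Markov (Mk) model
with gain rate `q01` and loss rate `q10` per unit branch length;
transition probabilities use the closed form
`P(t) = pi + (I − pi) exp(−(q01+q10) t)`.  Log-likelihoods come from
Felsenstein pruning with per-node rescaling; marginal ancestral
probabilities multiply the inside (subtree) conditionals by the outside
likelihood of the rest of the tree and renormalize per node.  The
default variant is equal-rates (ER) with a flat root prior — the common
default of the standard R tooling for this task — with all-rates-
different (ARD) and stationary/fixed priors available by flag.  Rates
are fitted by bounded L-BFGS-B on log-rates (bounds 1e-8 … 1e4,
`ftol` 1e-12) with a deterministic multi-start at 0.01, 0.1 and 1 to
avoid local optima; standard errors are delta-method values from a
finite-difference Hessian on the log scale.  The `MkCharacterModel` /
`MkFitResult` pair follows the model/results convention of statistical
modelling packages: `fit()` returns an object carrying estimates,
uncertainties, marginals and a `summary()`.

Exact published per-node probabilities for the real PVC tree are not
reproducible here — they depend on an unpublished consensus tree with
branch lengths — so the bundled 33-tip demonstration topology is
checked qualitatively: exactly one loss of compartmentalization on the
stem of the non-compartmentalized Chlamydiaceae clade, a
compartmentalized root, and a root ML probability of
compartmentalization above one half.

## Gene families and event mapping

**Clustering.**  Families come from Markov clustering (MCL) of the
weighted protein-similarity graph: column-normalize with self-loops,
alternate expansion (power 2) and inflation, prune entries below 1e-6,
iterate to a 1e-9 fixed point (at most 1000 iterations, non-convergence
is an error); clusters are the connected components of the converged
flow's support.  Inflation defaults to 1.5, a standard choice for
ortholog graphs; it is exposed in configuration.

**Gain/loss mapping.**  Per family, Sankoff parsimony on the binary
presence character with asymmetric costs, default gain:loss = 2:1 (a
gain is the rarer event).  The root state takes part in the same
minimization through a virtual absent ancestor above the root, so a
family present at the root carries one gain on the root stem, counted
as non-specific.  Cost ties are broken deterministically toward keeping
the parent's state, which defers gains tipward and avoids loss-then-
regain churn; this realizes a "fewest gains, latest gains" preference
without randomness.  A Dollo mode (one gain at the MRCA of the present
tips, losses placed as early as possible) is available, since
presence/absence mappers in the literature use both regimes.  The hard
invariant — enforced at run time and tested on every simulation — is
that replaying a family's events from the root reproduces its phyletic
pattern cell-for-cell.

Gains on terminal branches are *specific* (acquired by a modern
species); internal-branch and root-stem gains are *non-specific*
(acquired by an ancestor).

## HGT classification

Each gain is interrogated through the ranked homology hits of one
member gene (the alphabetically first carrier species below the gained
branch).  Two rule sets are encoded with their printed inequality
senses, which are deliberately not harmonized:

* ORFan: no hit with e-value **<** 1e-4 AND coverage **>** 50% (strict).
* HGT: remove hits from the gain's own phylum; remove hits with
  e-value **>** 1e-5 OR coverage **<** 60% OR identity **<** 30%
  (boundary values survive); inspect the species of the first ten
  survivors; call HGT iff none belongs to a sister phylum.

Fewer than ten survivors are all inspected; zero survivors leave the
gain `unclassified` — an HGT call requires positive evidence.  A gain
whose lineage has no sister phyla at all (a root-stem or whole-clade
gain) is likewise `unclassified`: the sister-phylum veto is the rule's
only discriminative step, and without a defined sister set the call
would hinge on single hits, which taxonomy noise makes unacceptably
fragile.  Sister phyla are derived from the tree: the phyla of the sibling subtree(s) of
the focal lineage, walking rootward until a foreign phylum appears.
Coverage is query coverage.  The partner of an HGT is the most frequent
phylum among the retained top-ten hits, ties going to the best-ranked
hit.  Hit ranking is made fully deterministic (e-value ascending,
identity descending, species name) so permuting input rows can never
change a verdict.

A species' HGT gene count sums member genes of families whose presence
at that tip traces back to an HGT-classified gain: walking from the tip
rootward, the first event on the path is the responsible one, so a
family gained and lost on the same lineage contributes nothing below
the loss.  Proportions divide by the species' proteome size.

## Group statistics

One fixed cascade for every measure (HGT proportions per grouping
scheme; the nine mobilome element classes): Shapiro-Wilk per group and
Levene (median-centred) across groups at α = 0.05 choose between
one-way ANOVA + Tukey HSD (all groups normal *and* variances
homogeneous) and Kruskal-Wallis + Nemenyi otherwise.  Groups too small
or too degenerate to test for normality fall to the nonparametric
branch with a logged warning; data with no variance at all make the
report abstain.  The Nemenyi test is computed from pooled mean-rank
differences against the studentized-range distribution (no tie
correction; ties are measure-zero for proportions).  Element classes
that scale with genome size — CRISPRs, transposases, integrases,
conjugation genes — are analysed as proportions of the proteome, the
others as raw counts.  The phylum grouping is always emitted alongside
cell plan and lifestyle as the confounding control: if phylum classes
separate identically, a cell-plan effect cannot be told apart from
phylogenetic structure.  Raw p-values are the primary readout, matching
standard practice for this design; a clearly-labelled Holm-adjusted
column across the measure × scheme family is added as an extension.

## The synthetic generator

The generator is the package's specification of the data it expects,
not a tuning knob.  Gene content evolves along the tree with
Gillespie-style event times per branch (so a loss can follow a gain on
the same branch): per-family exponential losses (rate 0.4), Poisson
originations (rate 25; de novo genes that downstream look like ORFans)
and Poisson transfers-in (rate 30, scaled by a lifestyle multiplier —
sympatric 1.0, allopatric 0.2 by default, reflecting the isolation of
obligate intracellular lineages), all per unit branch length, on top of
600 root families.  On the 33-tip demonstration tree this yields on the
order of a thousand families, a desk-scale stand-in for real
proteomes.  A transfer's donor is external to the study clade with
probability 0.75, founding a new family whose simulated homology hits
are drawn from the donor taxon; internal transfers copy an existing
clade-born family — donors of external origin are excluded so that
every tip copy has an unambiguous horizontal-or-vertical status for
scoring (an arrival where the family is already present changes
nothing in the matrix but is logged, since such events are invisible to
phyletic patterns).  Every tip copy carries its true origin tag, the
ground truth for recovery scoring.

Hit tables condition on that tag: external copies draw good-quality
hits (e-values 1e-80…1e-20, coverage 65–100%, identity 35–95%) from
external taxa, vertical and internally transferred copies from their
own and sister phyla, de novo copies get at most a few decoy hits that
fail every threshold.  Taxonomy mislabelling is modelled as a per-hit
phylum swap (default probability 0.05).  The binary character evolves
under the same Mk machinery (defaults q01 = 0.05, q10 = 0.3 from a
compartmentalized root, mirroring a character that is mostly retained
but occasionally lost); mobilome counts are Poisson with
lifestyle-scalable means around empirically plausible baselines
(e.g. 30 transposases, 45 tRNAs) and proteome sizes ~N(2500, 250).

What the generator does *not* emulate: sequence evolution (no
alignments or substitution models), paralogy and multi-copy family
dynamics within a genome, biased donor lineages, rate heterogeneity
across families, or correlated loss of character and gene content.
Passing recovery tests therefore show that the pipeline's logic is
faithful and well-calibrated under its own assumptions — not that real
nr-database searches would behave this cleanly.

## Numerical and determinism notes

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical output files, which the pipeline manifest (per-stage
counts and SHA-256 checksums) makes checkable.  Matrix exponentials use
the 2-state closed form; likelihood underflow is prevented by per-node
rescaling.  Benchmarks in the test-suite and acceptance script use the
demonstration tree with 40–600 root families and 50–200 replicates per
property — sizes chosen so each property is measured with comfortable
Monte-Carlo margins on a single CPU.

## Known limitations

* Gain classification uses one representative gene per gain; families
  with heterogeneous member histories (possible with internal
  transfers) inherit the representative's verdict.
* Deep gains spanning every study phylum have no foreign "sister" set
  and therefore always classify as `unclassified`; ancient transfers
  into the clade's root lineage are outside the method's resolution.
* The Nemenyi implementation omits tie correction.
* No phylogenetic correction (e.g. PGLS) is applied to the group
  contrasts; species are treated as exchangeable within groups, as in
  the standard workflow this package mirrors.
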
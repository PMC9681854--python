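# plankshift

Do benthic foraminifera disperse through the plankton? Metabarcoding
surveys of the open ocean recover large numbers of 18S V9 MOTUs (molecular
operational taxonomic units) assigned to foraminiferal clades that are only
known from the seafloor — most of them Globothalamea, the clade from which
all holoplanktonic foraminifera derive. `plankshift` is a reusable pipeline
for the analyses that turn that observation into an inference: which of
those benthic-clade MOTUs *behave* like plankton in their spatial
occurrence, and where they sit on the foraminiferal tree.

It is written for molecular ecologists and micropaleontologists working
with amplicon MOTU tables, and ships a synthetic-world generator with known
ground truth so every stage can be validated end to end without touching
survey data.

## The four analyses

**1. Clade assignment by percent identity.** Each MOTU representative
sequence is aligned against a clade-labeled reference barcode database by
exact dynamic programming in global-overlap mode (terminal gaps free and
excluded from the identity denominator). The best-scoring hit's identity
decides assignment at the ≥ 90 % cutoff; its clade category — Spinose,
Non-Spinose, Microperforates or Basal (holoplanktonic), Monothalamea,
Tubothalamea or Globothalamea (benthic) — is inherited.

**2. Distance-decay occurrence modeling.** Presence/absence is collapsed
to station level and each MOTU gets a binomial GLM

&nbsp;&nbsp;&nbsp;&nbsp;logit P(present at station *s*) = β₀ + β₁·d(*s*),

with d the station's distance to coast in km. A two-sided Wald test on β₁
(α = 0.05) calls the occurrence trend increasing, constant or decreasing.
Benthic DNA advected off the shelf decays with distance; resident
planktonic taxa do not.

**3. Dual random-forest lifestyle consensus.** Two random forests are
trained on the MOTUs whose clade already fixes their lifestyle (the four
holoplanktonic clades vs Monothalamea + Tubothalamea): one on the logistic
coefficients (β₀, β₁), one on the raw station presence/absence profile.
Only MOTUs occurring in at least 5 stations participate. Each model is
scored by repeated stratified cross-validation (accuracy and minority-class
F1), and a Globothalamea MOTU is called **putative planktonic** only when
both models vote planktonic — a consensus rule that trades recall for
precision.

**4. Phylogenetic placement.** Putative-planktonic MOTUs are attached to a
fixed backbone tree by Felsenstein-pruning likelihood under GTR+Γ (+I):
each query is hung at the midpoint of every edge on an optimized pendant
branch, edges are ranked by log-likelihood, and results are written as
jplace v3 with likelihood weight ratios, plus a per-clade count table.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_lifestyle_consensus.py` generates the default synthetic
world (150 stations × 4 size fractions; 280 MOTUs across the seven clade
categories, 120 of them Globothalamea of which 30 % carry planktonic-type
occupancy) and classifies it:

```
training set: 160 labeled MOTUs; prediction set: 120 Globothalamea MOTUs
    coeff model: CV accuracy 99.8%, F1 (benthic) 1.00
  profile model: CV accuracy 98.9%, F1 (benthic) 0.98
model agreement: 98%
putative planktonic: 33 MOTUs
of which truly planktonic-type: 33
```

Both feature views separate the lifestyles almost perfectly on this world;
the 33 MOTUs in the consensus set are exactly the planktonic-type
Globothalamea that passed the station filter and both models' votes — zero
false positives, the behavior the consensus rule is designed for.

The same stages are available from the shell:

```bash
plankshift simulate --out world/ --seed 42
plankshift assign --motus world/motus.fasta --refdb world/reference.fasta \
    --taxonomy world/reference_taxonomy.tsv --out assignments.tsv
plankshift run-all --seed 42 --out report/
```

`run-all` writes every stage table (category summary, per-fraction and
per-distance-bin read proportions, logistic fits, trend contingency, model
report, lifestyle calls, placement clade counts) plus a manifest that makes
the run reproducible bit for bit.

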
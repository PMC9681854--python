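# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic worlds do and do not emulate, and the
numerical choices a maintainer would want to know about.

## Clade assignment

Queries are aligned to references by exact dynamic programming in
*global-overlap* (semi-global, dovetail) mode: a leading gap run in one
sequence and a trailing gap run in one sequence are free and excluded from
the identity denominator, so V9 amplicons of slightly different lengths are
not penalized for terminal overhangs. Identity is

    matches / alignment columns (terminal-gap columns excluded).

Scoring defaults are match +1, mismatch −2, gap −2.5 per column —
megablast-like values appropriate for highly similar sequences — and are
configurable through `AlignmentParams`. Scores are handled internally as
integers at 10⁻³ granularity so score ties are exact. Among equal-score
alignments the DP deterministically prefers more matched columns, then
fewer columns; the exhaustive-enumeration oracle applies the same rule,
which makes the two exactly comparable (and is why the reported identity is
a pure function of the inputs).

IUPAC ambiguity codes count as identical when their base sets intersect
(the permissive convention for curated barcodes); a strict switch treats
any ambiguity as a mismatch.

**Best hit and the assignment decision.** The best hit is the
highest-scoring alignment across the reference set, with ties broken by
higher identity, then longer alignment span, then lexicographically
smallest reference id. Ranking by raw identity would be wrong in overlap
mode: unrelated sequences routinely share a 3–4-column perfect terminal
core whose "identity" is 1.0. For the same reason a minimum-coverage gate
(span ≥ 50 % of the shorter sequence, configurable) guards the assignment
decision — it plays the role that an E-value threshold plays in a
seeded-search tool, keeping random sequences unassignable while leaving
near-full-length V9 hits untouched. A MOTU is assigned iff its best hit
passes both the coverage gate and the ≥ 90 % identity cutoff; unassigned
MOTUs carry no clade category and are excluded downstream.

No k-mer seeding or heuristics: at desk scale (hundreds of ~130-nt queries
against tens-to-hundreds of references) all-vs-all DP is fast, and the
inner loop is compiled with numba.

## Distance-decay occurrence model

A MOTU is present at a station iff its reads summed over all that station's
samples are ≥ 1; station distances must be consistent across samples.
Station ids are sorted, so presence matrices are invariant to sample order
and to how a station's reads are split across samples.

Each MOTU row is fitted by maximum likelihood (binomial GLM, logit link)
with distance in raw km — coefficients then read directly as log-odds per
km. A config switch substitutes log-distance. All-present and all-absent
rows return a flagged non-estimable fit (trend "constant", fitted
probability pinned at ~1 or ~0) rather than raising: they carry no slope
information but remain usable as presence profiles.

Complete separation or non-convergence (detected by parameter blow-up,
|log-odds| beyond ±30 over the observed range, or missing standard errors)
triggers a ridge-penalized Newton refit with λ = 10⁻⁴ on both
coefficients; standard errors then come from the inverse penalized Hessian
and the fit is flagged `penalized`. Rare MOTUs with clustered occurrences
are the interesting cases, so they are flagged, not dropped.

The trend call is a two-sided Wald test on β₁ at α = 0.05: "constant"
unless rejected, otherwise the sign decides increasing/decreasing. This is
the minimal formalization of an increasing-or-constant vs decreasing
contrast; simulation (in the test suite and acceptance script) confirms the
call has approximately nominal type-I level at 100 stations.

Distance-bin summaries default to edges (0, 50, 100, 250, 500, 1000,
2000) km; samples beyond the last edge go to a flagged overflow bin.

## Lifestyle classifier

Training labels come from taxonomy alone: the four holoplanktonic clades
are "planktonic" (112 such MOTUs in the motivating survey), Monothalamea +
Tubothalamea are "benthic" (32); Globothalamea MOTUs are the unlabeled
prediction set. Only MOTUs occurring in ≥ 5 stations participate —
occurrence patterns over fewer stations carry too little spatial signal.

The coefficient model's feature vector is exactly (β₀, β₁); MOTUs whose
fit is non-estimable keep their profile features but are excluded from the
coefficient model and can therefore only be called by consensus when both
votes exist. The profile model consumes the full station-indexed binary
vector with stations as fixed, ordered columns.

Both models are random forests (500 trees, scikit-learn defaults for
feature subsampling, seeded). Evaluation is stratified 5-fold
cross-validation repeated 10×; reported accuracy and F1 are fold means,
with F1 computed on the benthic (minority) class. Out-of-bag estimation
would be a reasonable alternative; external CV was chosen as the more
conventional validation.

Consensus: putative planktonic ⇔ both votes planktonic; benthic ⇔ both
benthic; anything else (including a missing coefficient vote) is
unresolved. By construction the putative-planktonic set is a subset of each
single model's planktonic set, and raising the station filter can only
shrink every set. The agreement rate is reported both over MOTUs with two
votes and over the full prediction set, since the appropriate denominator
is a judgment call.

## Placement

The backbone tree (rooted, binary, newick) and reference alignment are
inputs; tree inference is out of scope. Edges carry stable ids assigned in
postorder, the numbering written into the jplace tree string.

Likelihood is Felsenstein pruning under GTR with discrete-Γ rate variation
(default 4 equal-probability categories, category means computed from the
incomplete-gamma function so the mixture mean is exactly 1) and an optional
invariant-site category implemented uniformly as a zero-rate mixture
component. The rate matrix is scaled so branch lengths are expected
substitutions per site *averaged over the mixture*. Transition matrices
come from the eigendecomposition of the symmetrized rate matrix (stable
for reversible models); site patterns are compressed; per-node scaling with
log accumulators guards against underflow. Gaps and `?`/`.` are missing
data (all-ones partials). TVM+I+Γ — the model class selected for the
motivating backbone — is the special case with equal AG and CT
exchangeabilities, supplied directly by the user or estimated on the fixed
topology by Nelder–Mead maximization of the tree likelihood.

A query pre-aligned to the reference columns is placed by attaching it at
the **midpoint** of each edge and maximizing the likelihood over the
pendant length only (bounded scalar optimization on [10⁻⁸, 2.0]; results
at a bound are flagged). This is a documented simplification of published
placement algorithms, which also optimize the attachment position along the
edge; midpoint attachment is adequate for clade-level assignment and keeps
the stage dependency-free. Efficiency comes from precomputed postorder
("below") and preorder ("rest-of-tree") conditionals per edge, so each
pendant evaluation costs one transition matrix and an elementwise product.
Likelihood weight ratios are softmax-normalized best log-likelihoods across
all edges and sum to 1 per query.

The edge-to-clade map used for per-clade count tables is user input; for
synthetic runs the pipeline derives a trivial two-clade map from the root
split. Queries must already be aligned to the reference columns — a full
profile aligner is out of scope.

## Synthetic worlds

The generator emulates the features of a basin-scale amplicon survey that
the downstream stages actually consume:

- **Stations**: default 150, distances log-uniform on (1, 2000) km — a
  coastal-to-gyre span without modeling real bathymetry; 4 size fractions
  per station, which carry no occupancy signal by default (a config hook
  can add some).
- **References**: one random ancestor per clade category, references by
  per-site substitution at a rate (default 0.02/site) keeping expected
  within-category identity ≈ 0.96, far above the 0.90 cutoff, while
  between-category identity sits near random-sequence levels. A rate that
  would push expected within-category identity below 0.95 is rejected as
  an overlap of the identity bands.
- **Occupancy**: each MOTU draws (β₀, β₁) from its category's uniform
  prior box — planktonic β₁ ∈ [0, 0.002]/km (flat to increasing), benthic
  β₁ ∈ [−0.006, −0.0015]/km with β₀ ∈ [1, 3] (common inshore, decaying
  offshore) — and presence is Bernoulli(expit(β₀ + β₁·d)). 30 % of
  Globothalamea MOTUs (the default putative-planktonic fraction) draw from
  the planktonic prior instead; truth records every MOTU's lifestyle and
  coefficients.
- **Counts**: conditional on station presence, each sample draws a
  negative-binomial count (dispersion 0.5, mean 50 reads per station split
  across fractions) and one sample is bumped by +1 so presence always
  implies a nonzero station count. The abundance level is a generic
  over-dispersed choice, not calibrated to any survey's read depths.
- **Trees**: random topologies by repeated joining, exponential branch
  lengths (mean 0.1 substitutions/site), sequences simulated site-wise
  under the supplied model. Edges carrying held-out queries are simulated
  in two halves so the query lineage genuinely branches at the edge
  midpoint of the realized history — without this the queries would
  actually attach at the parent node and placement "errors" would be
  artifacts of the fixture.

Everything is driven by one seed with fixed-order spawned substreams per
operation, so identical specs produce byte-identical outputs.

What passing tests on these worlds shows — and does not show. The worlds
have clean clade structure, no chimeras or contamination, occupancy driven
by distance alone, and spatially independent stations. Success here
demonstrates that the pipeline's inference machinery recovers known signal
under its own model assumptions; it does not certify performance on real
survey data, where spatial autocorrelation, uneven sampling and unmodeled
environmental drivers blur the distance-decay contrast.

## Problem sizes

Defaults were chosen so a full validation pass (test suite plus acceptance
script) completes in minutes on one CPU: oracle comparisons run on ≤ 10-nt
sequence pairs and 3–5-leaf trees with ≤ 10 sites (the regime where
exhaustive enumeration is exact and affordable), logistic calibration uses
100-station replicates, the end-to-end world uses the default 150 × 4
design with 280 MOTUs, and placement recovery uses a 20-leaf, 500-site
backbone. All sizes scale up through `WorldSpec` and function arguments.

## Known limitations

- Identity is defined on the single best-scoring alignment; near-ties
  between references of different categories are resolved by the
  deterministic tie-break, not by voting across top hits.
- The ridge fallback biases separated slopes toward zero (by design — it
  keeps them finite); flagged `penalized` fits should not be read as
  unbiased effect estimates.
- Placement optimizes pendant length only; on very long edges the midpoint
  restriction can shave likelihood relative to a full placement optimizer,
  though clade-level assignment is unaffected in the tested regimes.
- The model-parameter estimator is a direct search adequate for a handful
  of free parameters; it is not a substitute for proper model selection.
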
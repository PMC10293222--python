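# Methods

## Screening model

The screen treats donor age as an ordinal covariate with six decade
levels (20–29 … 70–79) and asks, per (gene, tissue), whether the
location of the expression distribution moves monotonically across the
levels. Location is summarised by the per-bin **median**: bulk
expression in TPM-like units is strongly right-skewed, medians are
robust to the heavy upper tail, and the exported heatmap matrices are
median matrices, so the monotonicity filter and the visual artefact
agree. A mean-based summary is available (`TrendConfig.summary="mean"`)
for sensitivity analysis.

Monotonicity is evaluated on the usable bins only — a bin is dropped
when it has fewer than `min_bin_count` (default 2) samples or no
samples at all, since a single observation gives a degenerate median
and a degenerate test group. The default rule is **weak** monotonicity
(all consecutive differences of one sign, at least one strict): with
six bins and rounded expression units, exact ties between adjacent
medians are common enough that strict monotonicity would discard
genuine trends; strict mode is available. Fewer than two usable bins
yields direction "none", never an error.

Candidates passing the filter are tested with the **tie-corrected
Kruskal–Wallis** statistic over the usable age-bin groups. The
chi-square approximation with k−1 degrees of freedom gives the p-value;
an exact permutation computation is used in the test-suite as an
independent oracle, not in the pipeline. The all-identical degenerate
input (tie correction C → 0) returns (H, p) = (0, 1) by convention.
The statistic and p-value are computed by `scipy.stats.kruskal`, whose
definition is exactly the tie-corrected rank-sum formula; the test
suite re-derives H from first principles and the chi-square tail
symbolically (sympy) to pin this down to 1e-12.

Multiple testing uses **Bonferroni** with family = the number of
Kruskal–Wallis tests actually performed in one tissue (`per_tissue`,
default). The family could equally be defined per tissue × direction or
globally across tissues; per-tissue matches how the screen is run and
reported (tissue by tissue), and a `global` mode re-corrects across all
tissues for users who prefer the conservative family. Significance
defaults to corrected p < 0.01; 0.05 is a supported alternative since
both conventions circulate for this kind of screen.

## Network stage

The interaction subnetwork over the significant genes keeps edges with
confidence score ≥ 0.400 on the physical channel (edges without channel
information pass). The boundary is **inclusive** — the STRING
medium-confidence convention — with both the cutoff and its strictness
configurable. Scores are auto-normalised at parse time: any score above
1 switches the whole file to the 0–1000 integer dialect (divide by
1000), so raw downloads and pre-normalised files both work.

Isolated significant genes are kept as degree-0 nodes by default; node
counts and mean degree are reported under both conventions
(`include_isolated`), because the two are easy to conflate when
comparing against published node counts.

Connectivity against chance uses a **size-matched permutation null**:
random gene sets of the same size drawn uniformly from the edge-list
universe, add-one p-value. This is self-contained and testable, unlike
database-server enrichment p-values whose background model is opaque.
On purely Erdős–Rényi synthetic backgrounds the observed set is an
exchangeable draw, so the p-value is calibrated (≈ uniform), not small
— the planted-clique test shows the power side.

## Markov clustering

MCL is implemented from scratch (dense numpy): build the weighted
adjacency (edge confidences by default, unit weights optional), add a
self-loop of weight 1.0 (standard practice; prevents period-2
oscillation), column-normalise, then iterate expansion (matrix square)
→ inflation (elementwise power, default 3.0) → prune entries below
1e-5 → renormalise, until the maximum entry change is below 1e-8 or 200
iterations (flagged non-converged but still returned). A column emptied
by pruning gets its self-loop restored before renormalising. Clusters
are the connected components of the limit matrix's nonzero structure
(entries below 1e-9 treated as numerical zeros); this always yields a
partition, sorted by decreasing size with lexicographic leaders for
determinism. Dense matrices are the right scale here — panels induce
networks of at most a few hundred nodes — and sparse optimisation is a
non-goal.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
(equivalently one-sided Fisher's exact), universe defaulting to the
union of all collection genes (explicit universes supported for
proteome-style backgrounds). Terms with zero query overlap are excluded
from testing by default; because this changes the BH family size, it is
a flag. BH-FDR is computed over exactly the tested terms
(statsmodels' step-up; the suite cross-checks against a direct
implementation of the step-up definition). Each result carries
significance flags at FDR 0.01 and 0.05, the two thresholds in common
use for tissue-level and network-level enrichment respectively.

## Synthetic data generator

The generator emulates the inputs of an age-stratified bulk study:

* expression: `e = exp(mu_g + d · effect_size · age_index + eps)`,
  `eps ~ N(0, noise_sigma²)`, `mu_g ~ N(baseline_log_mean,
  baseline_log_sd²)`. Log-normal multiplicative noise keeps values
  positive (TPM-like) and makes the planted signal a constant
  log-fold-change per age class. Defaults: 300 genes, 3 tissues, 25
  samples per (tissue, bin), 30 + 30 planted trends of 0.4
  log-units/bin, noise σ = 0.25, baseline log-mean 2.0 (≈ 7 TPM
  geometric mean) and log-sd 1.0 (≈ 10-fold spread) — chosen once as
  realistic for a moderately expressed panel.
* each trend gene trends in exactly **one** tissue (uniformly chosen)
  and is flat elsewhere, mirroring the tissue specificity of real age
  trends; a gene's truth label is therefore per (gene, tissue).
* interactions: Erdős–Rényi over the gene universe with Uniform(0,1)
  confidence scores on the physical channel — the uniform scores
  exercise the 0.400 cutoff non-trivially.
* annotations: one planted term containing exactly
  `planted_term_overlap` trend genes plus random fillers, among
  uniform decoy terms.
* all draws come from a single seeded numpy PCG64 generator; fixed
  config + seed reproduces the bundle bit-for-bit.

What the generator does **not** emulate: gene–gene covariance and
batch structure, sex effects (sex is carried in metadata but never
planted), donor sharing across tissues, non-monotone age profiles, and
any coupling between trend genes and network topology. Passing tests
therefore demonstrate the statistical machinery recovers planted
structure under idealised independence — not that real-data trends of
a given effect size will be recovered at the same rates, nor that real
significant sets will be better-connected than chance.

## Problem sizes

The recovery and calibration suites use the default study conditions
over ten seeds (9,000 gene–tissue tests per suite); the Kruskal–Wallis
oracle sweep enumerates every 2–3-group labelling of up to 8 distinct
values plus 1,000 randomised tie cases; the hypergeometric oracle
enumerates every feasible configuration up to a 12-gene universe.
These sizes give exact or tight Monte-Carlo checks while keeping the
whole suite in the tens of seconds.

## Known limitations

* Gene identity is the case-sensitive symbol string; no alias or
  Ensembl↔symbol mapping (database-dependent, out of scope). Joins
  between the disease table, the matrix and the edge list silently
  reflect whatever identifier space the inputs use.
* Dense expression matrices only; missing cells are unsupported.
* The chi-square p-value is an approximation; with six groups of ≥ 2
  samples it is adequate, but tiny bins lean on the `min_bin_count`
  guard.
* The permutation null conditions on set size only, not on degree —
  hub-heavy query sets will look more connected than a degree-matched
  null would say.
* MCL's attractor structure can in principle overlap; taking connected
  components of the limit resolves this conservatively (overlapping
  systems merge rather than split).
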
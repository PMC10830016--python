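# Methods

This note records the models triweb implements, the conventions it fixes
where the literature leaves room, and what its synthetic data can and
cannot establish.

## Data model

A `TripartiteNetwork` holds three named species sets and two signed,
oriented bipartite layers; exactly one set must appear in both layers (the
*shared set*), and this is inferred from the layer orientations rather than
declared. Topology follows from where the shared set sits: **fan** (resource
of both layers, e.g. plants under pollination + herbivory), **chain**
(consumes one layer, is consumed in the other, e.g. herbivores under
herbivory + parasitism), **apex** (consumes both). The *basal* set is the
set that is never a consumer; extinction protocols remove basal species.
Apex networks have two never-consumer sets and therefore no unique removal
target; the data model and structural metrics support them, but the
extinction module raises a structural error rather than guess.

Conventions fixed here:

* Species identifiers are opaque strings; wherever determinism needs an
  ordering (hub selection, rank ties, stochastic draw order) the final
  tie-break is lexicographic id order.
* Merging parallel layers (`combine_layers`) unions edges and **sums**
  duplicate weights, reading weight as interaction intensity.
* Species with zero links overall are dropped at load time with a warning
  (configurable); they contribute nothing to connectivity or dynamics but
  would silently inflate set sizes and deflate C.
* Non-basal species with no resource links are kept in the data model but
  excluded from robustness numerators and denominators: they cannot undergo
  secondary extinction, so counting them as eternal survivors would bias R
  upward.
* The ≥ 5-connector screen used to assemble comparable network collections
  is a validation verdict (`validate_network`), never a load error, so small
  didactic networks remain usable.

## Structural metrics

* **C** — connectors / shared-set size, connectors being shared species
  with ≥ 1 link in each layer.
* **H_C** — hubs are the top `ceil(0.2 · |shared|)` shared species by total
  degree (ceiling guarantees ≥ 1 hub; the threshold is a parameter for
  sensitivity checks); H_C is the fraction of hubs that connect. Hub degree
  is *total* degree over both layers — the plain reading of "highest
  degree".
* **PC** — `2·k_min/k_tot` for a connector; 1 at an even split, → 0 as the
  split grows uneven. Defined only on connectors (a non-connector's PC
  would be identically 0 and carries no split information); `PC_C` is the
  arithmetic mean over connectors.
* **Degree heterogeneity** — written σ_k/⟨k⟩. The symbol reads as SD/mean
  (a dimensionless coefficient of variation) while some prose descriptions
  read "variance divided by the average"; both are implemented
  (`kind="cv"` / `"vmr"`), the default is **cv** with population SD, and the
  node set is *all* species' total degrees.

## Extinction protocol and robustness

Plants are removed one at a time along an extinction sequence. Animals are
under bottom-up control: a species goes extinct exactly when its last
resource link disappears, and its own disappearance severs the links of
whatever consumes it. This single rule yields the *simultaneous* secondary
extinctions of fan networks and the *cascading* ones of chains.

**R** is the area under the piecewise-linear curve through all P+1 points
(fraction of plants removed, surviving animal fraction), starting at (0, 1),
integrated by the trapezoid rule. A step-function variant
(`method="step"`, the right-Riemann sum) is exposed for sensitivity; on the
maximally robust trajectory the two give 1 − 1/(2P) and 1 − 1/P
respectively. Whole-community survivors pool all non-basal sets; per-set
curves renormalize to each set's own initial (supported) count, so R always
lies in [0, 1] and the whole-community value is a count-weighted average of
the per-set curves.

**Bipartite robustness.** Splitting the tripartite network drops shared
species with no links in a layer, so the two standalone bipartite networks
are not simply the layers. Each is replayed under the induced subsequence of
its own plants with the x-axis renormalized to its own plant count, giving
R_L (larger network by species count; ties go to the declared layer order)
and R_S (smaller). In chain/AA networks the layer not adjacent to plants has
no plant-removal protocol; its value is `None`.

**Targeted sequences** (`degree_desc`, `degree_asc`) sort by *initial*
total plant degree with randomized ties; degrees are not recomputed after
removals (a dynamic variant would change the question being asked — the
static ranking is the attack scenario tested here).

**Stochastic variant.** With per-consumer dependency weights d_ij (summing
to 1 at baseline), the loss of resource j kills consumer i with probability
R_i · d_ij, with R_i = 1 for animals and 0 for plants by default to keep
bottom-up control; losing *all* resources still kills outright. Baseline
dependencies are **not** renormalized after partial loss, following the
stochastic coextinction formulation this mirrors; `renormalize=True` is
available. With degenerate weights (every d = 1) the stochastic simulator
reproduces deterministic trajectories exactly, which the tests assert
bit for bit.

## Interdependence, importance, drivers

* **I** — Pearson (default; Spearman exposed, since the underlying choice
  is not standardized) correlation of the two animal sets' per-sequence
  robustness over random sequences. Flagged undefined when either series is
  constant.
* **Plant importance** — the score of a plant is the Pearson correlation
  between its position in the sequence and the community damage 1 − R, so
  an important plant (early loss ⇒ low robustness) scores strongly
  negative; ranks ascend with the score, rank 1 = most important, ties by
  id. Scoring against damage rather than robustness keeps the sign
  convention "more negative = more important" consistent with the
  keystone-identification oracle (exhaustive enumeration on a 3-plant
  network), which the acceptance tests pin down.
* **S_set** — squared Pearson correlation of rank vectors (equivalently
  squared Spearman of the scores) between each per-set ranking and the
  whole-community ranking. Classification: *driven* if any S > 0.9, *emergent*
  if all S < 0.5, *mixed* otherwise — boundary values land in *mixed*. S is
  direction-blind; a perfectly anti-correlated ranking scores 1, so the
  result carries a flag listing sets whose underlying correlation was
  negative.
* **Composition fit** — no-intercept least squares R ~ a·R_L + b·R_S (the
  formulation has no constant term); an intercept variant and the two
  single-predictor fits are provided for comparison. AA/chain rows, whose
  R_S is undefined, are excluded.
* **Feature regression** — exhaustive OLS over all 15 non-empty subsets of
  {σ_k/⟨k⟩, C, H_C, PC_C}, predictors z-scored (coefficients are effect per
  SD of the feature), selected by minimal AIC = n·ln(RSS/n) + 2(k+1).
  Exhaustive search is deterministic and trivially cheap at four candidates.
* **Group comparisons** — pairwise Welch t-tests (unequal variances) with
  conventional significance stars; the equal-variance pooled test is an
  option.

## Null models

Applied layer by layer; all replicates are simple graphs.

1. Uniform random simple bipartite graph on the same node sets with the
   same edge count.
2. Each consumer keeps its layer degree; its stubs attach to uniformly
   chosen resources without duplicates. "Animal nodes" is read role-wise:
   the consumer side of each layer (the two non-shared sets in fans, the
   shared and top sets in chains).
3. Both per-layer degree multisets are preserved by independently permuting
   the shared-set node identities within each layer — the least-assumption
   construction that breaks the cross-layer degree correlation of shared
   species while conserving every marginal exactly.
4. Exact per-node, per-layer degrees via bipartite-safe double-edge swaps
   ((r1,c1),(r2,c2) → (r1,c2),(r2,c1), rejected when a duplicate would
   arise), with 10·L accepted swaps by default. Very small or dense layers
   admit few legal swaps and simply return less randomized — degrees are
   still conserved exactly, which is the model's contract. Note that model
   4 conserves every node's per-layer degree and hence every PC exactly;
   statistics that are functions of the joint degree table have zero null
   variance under it by construction.

`null_compare` reports observed value, null mean/SD, z-score and empirical
two-sided percentile; replicates on which a statistic is undefined (e.g. no
connectors survive randomization) are dropped, counted and warned about.

## Synthetic generator

The generator emulates the statistical shape of published tripartite webs —
species sets of tens of species, right-skewed consumer degree
distributions, a minority of shared species connecting the layers — without
fitting any particular data set. Degree distributions attach to
**consumers** (animals choose resources, matching how bipartite webs are
sampled); resource degrees emerge. Defaults: 40 species per set, power-law
consumer degrees (exponent 2.5, k_min 1, truncated to the available
resources), target_C = 0.35, target_PC = 0.6 — mid-range values for webs of
this size; all are explicit knobs.

* **Connector count is exact**: `round(target_C · n_shared)` species are
  designated, only they are eligible in both layers (others are assigned one
  layer), and each receives at least one forced link per layer.
* **PC steering** happens in two stages. Each connector draws a split
  fraction f from Beta(a, a) with a solved from
  E[PC] = 2·I_(1/2)(a+1, a) = target_PC (closed form via the regularized
  incomplete beta), and stub placement is weighted by f / 1−f per layer.
  Because min(k1, k2) over small integer counts is noisy, the Beta stage
  alone lands slightly low, so a bounded greedy pass then rewires single
  edges between resource species (consumer degrees and the connector set
  are invariant) until the realized connector-PC mean is within 0.02 of
  target. Per-node PC values are *not* individually enforced — only the
  mean is a target.
* **Chain topology**: every shared species consumes ≥ 1 plant; top
  consumers attach only to designated connectors. The largest layer-1
  degree draws are assigned to the connectors-to-be — generalists tend to
  be the connectors in empirical webs, and it widens the range of PC means
  the layer-2 rewiring can reach. Steering can only rewire layer 2 (layer-1
  degrees are the shared species' own draws), so extreme targets are
  infeasible for some degree models: with power-law(2.5) degrees the
  reachable band is roughly PC_C ∈ [0.5, 0.95]; outside it the generator
  returns its best effort rather than erroring. Fan networks steer both
  layers and recover targets across (0, 1].
* **Weights**: per-consumer dependencies from a symmetric
  Dirichlet(concentration); they sum to 1 per consumer, a single-resource
  consumer depends fully, and large concentration approaches an even 1/k
  split.
* **Reproducibility**: one `numpy` Generator seeded from `config.seed`
  drives every draw in a fixed order; identical configs give identical
  networks.

What passing tests on generated data do *not* show: empirical webs carry
nestedness, modularity, sampling artefacts and phylogenetic signal that the
generator does not model, and generated non-connector plants can end up
isolated (they are dropped with a warning on file round trips, slightly
raising measured C relative to the in-memory object). Conclusions about
procedure correctness transfer; numerical values measured on synthetic
ensembles do not describe any particular empirical system.

## Problem sizes and numerical choices

Test and reference computations use networks of 25–40 species per set,
Monte-Carlo ensembles of 60–3000 sequences, and exhaustive enumeration up
to 6 plants (the exact oracle against which Monte-Carlo means are checked
to 3 standard errors). Statistical checks on stochastic components are
seeded and asserted within 3 SE analytic bands. Trapezoid integration, the
cv heterogeneity reading, Pearson correlations, the no-intercept
composition fit and the damage-based importance sign are the documented
defaults everywhere; each has an exposed alternative rather than a silent
choice.

## Known limitations

* No population dynamics (extinction is purely topological/probabilistic),
  no rewiring or adaptive foraging, no top-down removal scenarios.
* Apex topology lacks an extinction semantics (no unique basal set).
* Null models randomize topology only; weighted matrices are re-weighted
  after randomization rather than shuffled.
* The generator targets C and PC_C only; nestedness/modularity-targeted
  generation is out of scope.
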
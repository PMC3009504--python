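# Methods

## The model

`cspnet` quantifies crosstalk between biological pathways from three
ingredients: an undirected gene-level interaction network (a generalized
PPI set that may mix physical binding, successive-enzyme links and
TF→target relations, all treated as undirected edges), a collection of
possibly overlapping pathway gene sets, and — optionally — single-sample
time-course expression per stimulation condition.

**Crosstalk statistic.** For a pathway pair (A, B) the statistic is the
number of distinct PPI edges with one endpoint in A and the other in B.
A gene shared by both pathways participates on both sides — an edge
incident to it can still cross the pair — but the sharing relation itself
(u = v) is never an interaction and PPI self-loops never count.  Each PPI
edge contributes at most once to a pair even when both endpoints are
shared; the doubled-gene picture could be read as counting such edges
twice, but the distinct-edge convention is symmetric, conservative and
directly checkable against enumeration.  Three modes are exposed: `all`
(default), `no_shared` (endpoints restricted to the exclusive parts A\B
and B\A), and `shared_only` (the statistic becomes the overlap size
|A∩B|, with the same permutation machinery assessing it).

**Null model.** Significance of an observed pair count is assessed
against rewired pathway memberships: a swap picks two distinct genes from
two different pathways and exchanges them, subject to (i) both genes
interact with at least one gene, (ii) neither gene is already a member of
the receiving pathway.  These constraints conserve every pathway's size
and the global membership multiset exactly.  A permuted collection
applies `n_swaps` accepted exchanges (library default 100,000; the
desk-scale study conditions below use 2,000–10,000); `R` such collections
(default 1,000), each restarted from the original assignment with its own
deterministic child RNG stream, give the per-pair null counts.  The
restart convention makes the R nulls exchangeable and embarrassingly
parallel.  A second scheme, `degree_matched`, additionally requires the
two genes to fall in the same ⌊log₂ degree⌋ bin; on degree-homogeneous
backgrounds the two schemes produce per-pair nulls agreeing within a few
percent, which the test suite asserts at a 10% tolerance.

**Empirical p.** p = #{null counts ≥ observed}/R, so p may be exactly 0;
a (k+1)/(R+1) variant is available behind `add_one=True` for users who
need strictly positive values.  Pairs with p < α (strict, default 0.05)
become edges of the pathway network.  No multiple-testing adjustment is
applied by default — the edge set is defined by the raw per-pair test —
but Benjamini–Hochberg adjusted values are available from
`CrosstalkResults.pvalues_adjusted()`.

**Reported average degree.** Network summaries report `average_degree`
as edges ÷ nodes to one decimal — the convention used when these network
variants are compared in the literature this package operationalises —
and additionally expose the conventional mean degree 2·edges ÷ nodes as
`mean_degree` so no reader is misled.

**Known property: conservativeness.** An empirical p computed from
discrete, heavily tied counts is super-uniform: the achieved level can
sit well below α (we measure ≈2.7% at α = 5% on a sparse pure-null
instance), with a further small conservative contribution from the
finite swap chain's residual correlation with the observed assignment.
The effect shrinks as pair counts grow finer-grained; study conditions
that probe the nominal type-I rate therefore use a background dense
enough that typical pair counts are ≈18 rather than ≈2.

## Phenotype-specific networks

With one microarray per timepoint, replicate statistics (t-test,
Bayesian moderation) are unavailable; DE calling is by fold change
against the series baseline (the earliest, untreated sample):
gene g is DE at t iff (v_t+ε)/(v_0+ε) ≥ f or (v_0+ε)/(v_t+ε) ≥ f, with
f = 2.0 and pseudocount ε = 1.0 on raw intensities by default.  A PPI is
*active* at t iff at least one endpoint is DE.  The crosstalk pipeline is
re-run per timepoint on the active subgraph, and the resulting network is
intersected with the comprehensive network (the
`comprehensive_backbone` restriction) — our reading of deriving the
phenotype-specific network "based on" the comprehensive one.  Two
alternatives are provided: `enriched_only` reproduces the narrower
enriched-pathway baseline (pathways must be hypergeometrically enriched,
Bonferroni-corrected, in the timepoint's relevant genes), and
`restriction="none"` with `support_filter=True` skips re-permutation and
keeps a comprehensive edge iff it has ≥1 active supporting PPI.

The immediate PPI neighbours of the DE genes ("relevant genes") are
computed and reported — genes just below a fold cutoff can still matter,
and a curated interaction with a DE gene argues for relevance — but they
do not enter the active-PPI rule by default, which is stated purely in
terms of DE genes; `use_relevant_genes=True` substitutes them in for
sensitivity analysis.  When duplicate expression rows occur for one gene
(multiple probes), cells collapse by maximum: with single-sample arrays
the maximum is the conservative choice for ratio-based detection.

## CSPN detection

Given phenotype network series for ≥2 conditions:

* **static core** — exact intersection of edge sets over every timepoint
  of every condition;
* **static CSPN** — pathways whose degree inside the core *and* inside
  the comprehensive network both reach the `hub_quantile` (default 0.75)
  of the respective degree distributions, plus induced edges.  An
  absolute `min_comprehensive_degree` override exists for networks where
  a published absolute hub cutoff is preferred;
* **edge variability** — for presence at k of T timepoints,
  score = min(k, T−k)/⌊T/2⌋ ∈ [0,1]: 0 for constant edges, 1 for a
  maximally balanced on/off pattern.  No canonical formula exists for
  "alters obviously"; this normalised flip score is our formalisation,
  with `var_threshold` default 0.5 (present or absent in at least a
  quarter of timepoints on each side for T = 4);
* **dynamic CSPN** — candidate edges reach the variability threshold in
  ≥1 condition; candidate pathways are their endpoints with
  comprehensive degree ≤ the `low_degree_quantile` (default 0.5); kept
  edges join two candidates, and per-condition presence vectors are
  attached.  `detect_cspn` additionally enforces that static and dynamic
  edge sets are disjoint (relevant only at `var_threshold=0`).

Curation against prior biological knowledge is deliberately out of
algorithmic scope: the detectors report objective candidates.

## Synthetic study conditions

The generator emulates the *shape* of the real inputs — a curated
interactome of order 10⁴ genes, a few dozen overlapping pathway gene
sets, and per-condition single-sample time courses with a baseline
column — scaled so a complete analysis runs in seconds to minutes on one
CPU.  Defaults, chosen once: 1,200 genes, Erdős–Rényi background at
density 0.003, 30 pathways of 20–40 genes chained with ~10% overlap, two
conditions with four non-baseline timepoints (mirroring short cytokine
stimulation series), baseline intensity 100, fold-change signal 4,
multiplicative log-normal noise with σ = 0.2 (≈1.4% spurious
fold-change-2 calls per gene and timepoint — noisy, as single-array
fold-change analysis genuinely is).

Planted structure: a persistent 4-clique of hub pathways (P01–P04),
three transient pairs active at two of four timepoints, and a
structural-only "filler" chain over the remaining pathways (crosstalk in
the interactome with no expression events), each planted pair receiving
30 extra cross edges.  Two design rules make ground-truth recovery
well-posed rather than seed-lucky:

* planted cross edges join **sole-membership** genes only (genes in
  exactly one pathway), so chained overlaps cannot couple the schedules
  of different planted pairs and a planted edge can never double as
  crosstalk of a third pathway;
* background cross-edge counts of pairs touching expression-scheduled
  pathways are **capped** at the Erdős–Rényi mean + 2·√mean
  (`background_cross_cap_sd`, default 2.0), because random-graph tail
  pairs adjacent to always-DE hubs otherwise become persistently
  significant and contaminate the static core.  Pairs away from the
  scheduled pathways keep their natural fluctuations, and the cap is off
  in the two conditions below that need an untouched null.

Three named conditions cover the quantitative claims:
`calibration_config` (300 genes, density 0.02, ten disjoint 25-gene
pathways, nothing planted) probes type-I calibration;
`power_config` (default size, density 0.02, three planted pairs, no cap,
no noise) probes detection power and the nominal false-positive rate;
`recovery_config` (600 genes, 16 pathways, full planted architecture)
is the replicable CSPN-recovery condition.

What the generator does **not** emulate: probe-level artefacts, batch
effects, intensity-dependent noise, scale-free interactome topology
(an optional degree-heterogeneous background only enters through the
degree-matched scheme tests), or biological correlation between
pathways.  Passing tests therefore demonstrate the pipeline's internal
correctness and its statistical behaviour under clean planted signal,
not performance on real arrays.

## Numerical choices and scaling

* RNG: a single master seed; every repetition and timepoint gets a
  `SeedSequence`-spawned child stream, so results are bit-reproducible
  and parallelisable.
* Swap proposals are rejection-sampled with a cap of 1000·n_swaps
  proposals; exceeding the cap raises `SwapInfeasibleError` naming the
  constraint that kept failing.  Permutation requires ≥2 pathways that
  contain a connected gene; on active-PPI subgraphs a timepoint that
  cannot support the null yields an empty network with a warning rather
  than an abort.
* Pathways with fewer than 3 genes in the universe are excluded from
  enrichment testing (logged); the enrichment universe is the union of
  pathway genes and PPI nodes, which keeps the test well-defined when
  pathways contain genes absent from the interactome.
* Desk-scale runs in the test-suite and the acceptance script use
  R = 100–1,000 and 400–10,000 swaps depending on the instance; these
  are the package's scaled study conditions, with planted separation —
  not permutation depth — driving recovery.
* Average-degree reporting rounds half away from the tie only in the
  trivial sense of Python's `round(x, 1)`; none of the reference shapes
  sit on a .05 boundary.

## Limitations

* The quantile formalisations of "highly connected" and "relatively low
  degree" are brittle on very sparse comprehensive networks whose degree
  distribution concentrates on 1–2; absolute-threshold overrides are
  provided for such cases.
* Under noise, spurious DE calls genuinely activate structural
  crosstalk, so dynamic detection reports extra time-varying edges
  beyond the scheduled ones; with single-sample series this is a
  property of fold-change analysis itself, not removable by the
  detector.
* Empirical p-values are conservative on coarse counts (see above);
  users comparing many sparse pairs should expect sub-nominal
  false-positive rates rather than exact calibration.
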
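# Methods

`pulsewave` implements the analysis chain for a nutrient-impulse chemostat
experiment: a steady-state, nutrient-limited culture of *Saccharomyces
cerevisiae* receives an instantaneous pulse of the limiting nutrient
(glucose or ammonium sulphate), and the transcriptome is sampled from
seconds to hours until the limited steady state is re-established.  This
note records the models, parameter choices and numerical decisions the
package makes, and what its synthetic benchmarks do and do not demonstrate.

## Chemostat washout model

A chemostat with dilution rate `D` (h⁻¹) exchanges broth continuously, so a
nutrient injected at t = 0 and not consumed obeys

    dC/dt = −D (C − C_base),    C(0) = C_base + ΔC₀,

with closed form `C(t) = C_base + ΔC₀ e^{−Dt}` and dose identity
`ΔC₀ = stock_conc · v_inj / V`.  Cellular uptake is deliberately excluded,
making the curve an upper bound on the residual concentration; its role is
to set the experiment's time horizon, not to model metabolism.  Sampling
losses (20 mL per draw, ≤ 2% of the working volume) are ignored.  The
closed form is used throughout; a Runge–Kutta integration of the ODE serves
only as an independent test oracle (agreement to 10⁻⁶ relative tolerance
over D ∈ {0.05, 0.1, 0.5} h⁻¹ and t ∈ [0, 70] h).

Reference dosing: 50 mL of 40% w/v glucose or of 6.26% w/v ammonium
sulphate into a 1 L working volume at D = 0.1 h⁻¹, i.e. steps of 2% and
0.313% w/v; five residence times (50 h) define steady-state attainment.

## Time grid and data conventions

All internal times are seconds since the impulse.  The 15-sample design is
pre-impulse steady state (stored at −1 s so the grid is strictly
increasing), 20/40/60 s, 8/16/24/32 min, 1/2/3/4/5/7 h, and the second
steady state (nominally 100 h, once ≥ 5 residence times have passed).
Expression values are log2 intensities, assumed normalized upstream.
Duplicate steady-state columns sharing a sampling time are averaged into
one reference column at load time; the raw columns remain attached for
inspection.  Rate constants are h⁻¹ and converted at the model boundary.

## Synthetic data generator

The generator plants known structure so every downstream statistic can be
validated against ground truth.  Six archetype responses `r(t)` (log2
deviation from a per-gene baseline ~ N(8, 1)) are zero before the impulse
and after a 7 h horizon (at D = 0.1 h⁻¹ the impulse is effectively diluted
away by then), so all shapes return to baseline at the second steady state:

| archetype | shape on [0, 7 h] | defaults |
|---|---|---|
| immediate_down_recover | −A e^{−t/τ} | A = 2, τ = 1800 s |
| delayed_up | A (1 − e^{−(t−t₀)/τ}) for t ≥ t₀ | t₀ = 7200 s |
| sustained_up / down | ±A (1 − e^{−t/τ}), plateau held through 7 h | A = 2, τ = 1800 s |
| oscillatory | A sin(2πt/T) e^{−Dt} | T = 7200 s, D = 0.1 h⁻¹ |
| flat | 0 | — |

The sustained shapes rise smoothly rather than stepping: transcript
induction is not instantaneous, and a literal two-level step is degenerate
under column permutation (any permutation that reunites the two baseline
samples refits perfectly, which inflates the permutation null).  A module
is `size` genes sharing one archetype; a per-gene sign pattern can flip
members to plant exactly anti-correlated pairs (noiselessly, PCC = ±1
exactly).  Gaussian noise of sd 0.1 (default) is added on the log2 scale —
the standard microarray assumption.  The interactome generator is a
stochastic block model (PPI edge probability `p_intra` = 0.3 within
modules, `p_inter` = 0.02 elsewhere, including all pairs touching flat
background genes) plus `n_tf` transcription factors with directed PDI
edges to sampled targets.  The annotation generator gives module members
their module's term with probability `frac_in` = 0.8 and every other gene
with `frac_bg` = 0.05.  All generators are bit-reproducible under a fixed
seed.

What the generator does **not** emulate: probe-level intensity noise,
intensity-dependent variance, batch effects, mRNA-stability confounds,
correlated noise between genes, or scale-free network topology.  Passing
benchmarks therefore demonstrate correctness of the algorithms under
idealized, well-separated structure — not performance on real arrays.

The NP benchmark (`np_benchmark_design`) draws 2–4 modules of 50–125 genes
from {sustained_up ±, oscillatory ±} at noise sd 0.15, so every module pair
is either exactly anti-correlated or essentially uncorrelated (|PCC| <
0.05).  This is deliberate: with a |PCC| ≥ 0.7 edge filter, module-mean
profiles can be *pairwise* anti-correlated for at most two modules
(pairwise correlation of k unit vectors is bounded below by −1/(k−1)), so
identifiable multi-module designs must separate the remaining pairs by
network disconnection rather than by anti-correlation.

## Correlation profiling

Each sample is summarized by the Pearson correlation of its whole
expression column with the reference steady-state column.  Constant
vectors raise an error rather than silently yielding 0.  A perturbation
appears as a dip; re-equilibration as the return toward 1.

## Within-class differential expression

Per gene, an F-type statistic compares a natural cubic spline fit of
expression on warped time against the constant model:

    F = (ESS / df) / (RSS / (n − df − 1)),

with the spline basis (truncated-power natural spline, knots at quantiles)
built on `u = log1p(max(t, 0))` — the grid spans three orders of magnitude,
and linear-time knots would starve the sub-minute samples.  Significance is
by permutation of whole sample columns (preserving gene–gene correlation),
with the permuted statistics of all genes pooled into one null
distribution; this is valid because all genes share the design and the
null hypothesis is exchangeability of columns.  p-values use the +1
smoothing `(1 + #{null ≥ F}) / (1 + m)`, so the attainable floor is
~`1/(n_perm · G)` for G genes; perfect fits (zero residual) rank above
every finite null value.  Bonferroni (`min(1, p·G)`) and Benjamini–Hochberg
columns are always emitted; the significance flag defaults to Bonferroni at
α = 10⁻³.

Defaults and why: `df_spline = 4` — higher df lets *permuted* profiles
refit better, inflating the pooled null tail and costing power everywhere
(measured: df 5–6 reduce true positives several-fold at equal calibration);
`n_perm = 2000` — with a pooled null the Bonferroni floor is ≈ 1/n_perm, so
at least ~10³ permutations are needed for the 10⁻³ gate to be attainable at
all.  Type-I calibration on flat genes is nominal (fraction of raw p < 0.05
within [0.03, 0.07] pooled over 20 seeds of 500 null genes).

Known limitation: responses concentrated in few samples (late onset,
oscillation) earn modest F on this grid and typically pass B-H FDR < 0.05
but not Bonferroni 10⁻³.  A smooth-fit test is simply weakly powered
against oscillations sampled irregularly.

## Temporal clustering

**Hierarchical.**  Agglomerative clustering of genes or samples under
d = 1 − PCC with average linkage (conventional with correlation distance).
The "similarity 0.5" flat cut is a cut at d = 0.5, i.e. PCC = 0.5.
Constant items are rejected by name.  Results are deterministic given
input order; exact distance ties are broken by scipy's ordering.

**Self-organizing map.**  Significant genes are standardized per gene
(mean 0, sd 1) and arranged on a small grid (2×4 and 3×3 presets).
Training is batch SOM: kmeans++ seeding, Gaussian neighbourhood shrinking
linearly from σ₀ = 0.5 to ≈ 0 over `n_iter` = 500 sweeps, then plain
k-means polish to a stable assignment.  The narrow default neighbourhood is
deliberate: with 8–9 cells and well-separated temporal archetypes the
neighbourhood's only useful role is ordering similar prototypes onto
adjacent cells; wide radii (e.g. max(rows, cols)/2) measurably blur
archetypes together (ARI 0.86 vs 1.0 on noiseless data).  Per cell, the
centroid is the member mean and the confidence band is
`centroid ± z(ci_level) · spread` per time point.  The membership gate uses
the member-profile SD (a prediction band; `band="sd"`, default): genes
outside the band at more than `max_outside_frac` = 0.2 of the time points
are reported unassigned.  The SD/√m centroid confidence band (`band="se"`)
is available for display purposes but is far too narrow to gate membership
of large clusters.  Fixed seed ⇒ identical output.

## Negative–Positive network analysis

**Reduction.**  The node universe is the intersection of interactome nodes
and expression gene IDs (intersected on IDs as given).  Every surviving
edge gets the Pearson correlation of its endpoint profiles over the *full*
dynamic profile, reference steady state included (log2 scale, consistent
with the rest of the package).  Edges with |PCC| ≥ 0.7 are retained and
labelled co-regulated (PCC > 0) or anti-regulated; edges touching a
constant profile are skipped and counted, not fatal.  Reported node count
is the number of nodes incident to retained edges (the NP network proper);
co + anti = total edges by construction, and raising the threshold can only
remove edges.

**Module dissection.**  Modules are the largest clusters of co-expressed
nodes containing < 1% anti-regulated internal links.  The package replaces
manual dissection with a deterministic coarse-to-fine walk: nodes are
hierarchically clustered on their profiles (d = 1 − PCC, average linkage)
and the dendrogram is walked from the root; a candidate is accepted iff
(a) its intra-candidate anti-link fraction — anti edges over retained edges
inside it, 0 if edgeless — is below the bound, and (b) it induces a
*connected* subgraph of the reduced network.  Rejected candidates split
into their two children; sub-minimum clusters (< 2 nodes) and residue are
unclustered.  The connectivity requirement is essential as well as natural:
a network module should be one component, and without it any two
co-expressed but network-disjoint clusters would merge (their union
contains no anti edges), making more than two planted modules unrecoverable
in principle.  The anti-fraction denominator is retained intra-module
*edges*, not gene pairs, because the constraint counts network links.  If
the root itself is admissible the partition is legitimately one global
module — the expected outcome for a highly co-expressed network — and a
warning notes that inter-module analyses do not apply.

**Summaries.**  Inter-module entries average PCC over all cross-module
gene pairs and are labelled by sign.  AvgPCC of a node is the arithmetic
mean of PCC over its retained incident edges; nodes of degree ≥ 5 (the
default hub cut-off — "hub" has no canonical degree, so it is
configurable) are party hubs when |AvgPCC| > 0.1 and date hubs otherwise;
exact equality (measure-zero) falls to date.  A clustered node is an
interface gene iff it has ≥ 1 retained edge into another module, core
otherwise; TF interface counts are reported per ordered module pair.

## Enrichment

**Hypergeometric.**  The exact upper tail P(X ≥ n) for n annotated genes in
a query of t drawn from a background of N containing N_term annotated
genes, via `scipy.stats.hypergeom.sf` (validated against exhaustive
rational-arithmetic tail sums on all instances with N ≤ 25).  The default
background is the expression universe.  Selection gates the raw p at
α = 10⁻³; Bonferroni-over-terms and B-H columns are emitted alongside
because published enrichment tables are customarily reported after
Bonferroni correction over the number of terms tested (the multiplicity is
exposed as `n_terms_tested`).

**Detection parameter.**  dp = n²/t per term, where t is the module size;
a term is selected iff dp > 0.05/g with g the number of distinct terms
annotating the module.  The exponent placement follows the methodology the
statistic derives from and dimensional sanity (dp = n/t² would be bounded
by 1/t and could essentially never clear 0.05/g for realistic modules);
`formula="n_over_t2"` is available should the source convention be read
otherwise.  An optional term → slim mapping is applied before counting.

## Pipeline

`run_pipeline` executes simulate/load → correlate → diffexpr → cluster
(hierarchical samples + SOM of significant genes) → NP network →
enrichment (hypergeometric per SOM cell, dp per NP module), writing every
intermediate artifact, a JSON report, and a MANIFEST with SHA-256 hashes
and completed stages (retained on failure, with the failing stage named).
Each stage derives its sub-seed by hashing (global seed, stage name), so
stages can be re-run in isolation and identical config + seed yields
byte-identical reports.  Stage defaults not overridden by the user are
resolved at run time and echoed in the report.

## Problem sizes

The bundled benchmarks run at deliberately compact sizes chosen to exercise
every code path with clear planted structure: the default pipeline design
has 420 genes (5 modules + 200 flat background) on the 15-sample grid; the
NP benchmark uses ten seeded designs of 200–500 genes; statistical
calibration pools 20 seeds × 500 null genes at 100 permutations.  All
algorithms are vectorized and scale to transcriptome-size inputs (the
block-model generator materializes all gene pairs, so it is quadratic in
gene count; ~6000 genes remain practical).

## Known limitations

- The washout model ignores consumption and sampling losses; it bounds,
  rather than tracks, the real residual concentration.
- Oscillatory and late-onset responses are weakly detected by the
  spline-F test under strict Bonferroni control (see above).
- The module walk is greedy on the dendrogram: it finds the largest
  admissible clusters along the tree, not a globally optimal constrained
  partition (verified optimal on small enumerable fixtures).
- Synthetic benchmarks use idealized noise and block networks; results on
  real arrays and curated interactomes will be less clean.
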
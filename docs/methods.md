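# Methods

This note documents the model underlying `cortimap`, the choices made
where the design was open, and what the synthetic data do and do not
establish about real anatomical data.

## Scope and assumptions

The pipeline derives, for a network of vision-related cortical areas, the
expected number of synapses between every ordered pair of populations
(area × layer × E/I), plus population sizes and external input.  Core
assumptions:

- Each area is a 1 mm² patch (radius R₀ = √(1/π) mm); cortico-cortical
  connections originate and terminate inside the patches, ignoring spatial
  divergence.
- A constant volume density of synapses ρ_syn across areas.  Default
  8.3·10⁸ synapses/mm³, the product of the mean measured V1 indegree
  (average of 2300 and 5600 → 3950 synapses/neuron) and the V1 neuron
  density.  Because neuron density falls along the architectural gradient
  while ρ_syn stays fixed, weakly differentiated areas end up with higher
  per-neuron indegrees — an emergent property, not an input.
- A constant intrinsic synapse fraction FLN_i = 0.79: 79% of a neuron's
  synapses are intra-areal (types I + II), the rest inter-areal
  (III + IV).  A further 1.3% of inputs is attributed to subcortical
  sources during FLN normalization.
- Cortico-cortical connections are purely excitatory at the source.
- L1 carries synapses but no somata.
- The fraction of excitatory neurons per layer is identical across areas:
  γ = 0.78 (L2/3), 0.80 (L4), 0.82 (L5), 0.83 (L6).

## Architecture completion

Three completion rules fill gaps in the per-area table, in order:

1. **Densities by type.**  Missing laminar/overall densities are the
   arithmetic mean over measured areas of the same architectural type
   (ordinal 2–8).  A type without a measured representative is a hard
   error, not a silent fallback.
2. **Total thickness.**  OLS of thickness on log ρ over measured areas;
   missing values predicted from the fit.  The logarithm base is a config
   option (default 10); fit quality is base-invariant, slope units are not.
3. **Laminar fractions.**  Relative L4 thickness rises with log ρ and is
   predicted from a linear fit (floored at 0); agranular (type 2) areas
   are excluded from this fit and keep an exact structural zero.  The
   other layers show no density trend and are filled with the measured
   mean.  Each completed row is renormalized to sum to 1, so clipping of
   the L4 prediction is absorbed by the remaining layers.

Completion is idempotent, and provenance flags distinguish measured from
filled entries throughout.

## Local circuit scaling (types I and II)

The 8×8 template (`data/local_template.json`, a versioned copy of the
published 1 mm² microcircuit probabilities and population sizes) assumes a
Gaussian distance-dependent connection probability with σ = 297 µm.  The
template's printed disk average (0.066 at R₀ for peak 0.143) fixes one
neuron at the disk center; scaling to other radii uses the all-pairs
average, computed by reducing the 4-D position integral to a 1-D
quadrature over the disk line-picking density (relative tolerance 1e-6,
validated against a 10⁷-sample Monte-Carlo oracle).  The pairwise average
is strictly below the centered one.

Probabilities convert to expected synapse counts by inverting the
at-least-one-synapse relation C = 1 − (1 − 1/(N_s N_t))^{N_syn}; counts
stay real-valued expectations throughout.  Adapting the template to an
area preserves relative indegrees exactly and rescales them by a single
conversion factor

c_A(R) = N_syn_tot(R) / Σ_ij N_i(R) K′_ij(R) · FLN_i · ⟨K′_ij(R)/K′_ij(R_full)⟩,

where the unweighted mean runs over template pairs with nonzero indegree
and R_full is the radius of the area's full measured surface.  Type-I
synapses are c_A(R₀)·K′(R₀)·N(R₀).  The type-II total is the remaining
intrinsic input onto the patch, ρ_syn·S_patch·D·FLN_i minus the type-I
total: evaluating the local circuit at the full radius recovers the full
intrinsic indegree per neuron, and summing it over the patch's neurons
gives exactly the patch-level intrinsic budget.  This patch-level reading
is what closes the per-area synapse audit ρ_syn·S·D = I + II + III + IV
to 1e-9; the area's full surface still enters through K′(R_full).  As the
modeled radius grows, the type-I share of the intrinsic budget rises
monotonically toward 1 (absolute type-II totals also scale with R² and
are not monotone).

Agranular areas use the template restricted to the six non-L4
populations, run through the same c_A machinery.

## Cortico-cortical synapses (type III)

**Totals.**  FLN values carry the relative connection strength; the total
synapse count of a projection is N_syn_tot,A · FLN_AB.  Missing FLN for
connections known to exist (union of the binary matrix and positive
measured FLN) is filled from the exponential distance rule fitted by OLS
on log₁₀ FLN (λ = −slope·ln 10, c = 10^intercept).  Rows are normalized so
cortical FLN — including estimates for non-modeled cortical areas whose
distances are supplied — sums to 1 − FLN_i − 0.013.  Absent connections
remain exactly zero.

**Laminar origin.**  SLN is completed by a beta-binomial regression of
supragranular labeling counts with probit link (logit available; the two
give predicted curves within 0.05 of each other) on
ℓ = ln(ρ_target/ρ_source).  The sign convention makes a₁ < 0 correspond to
feedforward (high-SLN) projections out of denser areas.  The likelihood
is maximized with L-BFGS-B from a fixed 27-point start grid, making the
fit deterministic given the data; standard errors come from the numerical
observed information (delta method for the dispersion φ, parameterized on
a logit scale).

**Routing.**  Source fractions X_j put the SLN share on 2/3E and split
the rest between 5E and 6E by ordinal tracing strengths where available
(1/2/3 read as relative masses 1:10:100, 0 as absent) or by excitatory
population sizes.  Target-layer fractions Y_v use ordinal anterograde
patterns where available, otherwise the SLN-category termination set
({4} above 0.65, {1, 2/3, 5, 6} below 0.35, all six layers in between)
weighted by relative laminar thickness.  Layers with zero thickness are
dropped; if a pattern empties entirely (a feedforward projection into an
agranular area), mass is spread thickness-proportionally over the
existing layers.  Synapse-to-cell-body conditionals P(i | s_cc ∈ v) are
built from the cell-type table by rescaling cell-type occurrences to the
reference area's population shares and applying Bayes' rule to the
cortico-cortical synapse counts per layer and type; each defined layer
column sums to 1.  Finally every projection is rescaled so exactly 93% of
its synapses land on excitatory populations, conserving the projection
total (a config switch restricts this to feedback-category projections;
the default applies it to every projection).  If a projection has no
inhibitory mass at all, no rescale is possible and it is left unchanged.
L4 populations of agranular target areas receive zero, their mass
reassigned proportionally — conservation is prioritized where the data
are silent.

## External input (types II + IV)

Types II and IV are never separated: per area, the external synapse total
is the budget ρ_syn·S·D minus internal types I and III, distributed so
every neuron of the area has the same external indegree.  A negative
residual raises an inconsistency error naming the area.

## Graph analyses

**Communities.**  The area graph carries relative outdegrees
(column-normalized K^out) and relative indegrees (row-normalized K).
A random walker follows relative outdegrees and teleports with
probability p = 0.15 to nodes chosen proportionally to total out-weight;
dangling nodes teleport with probability 1.  Stationary rates come from
power iteration to 1e-12.  The two-level map-equation codelength is
minimized by greedy node moving with module-merge passes, restarted from
seeded node orders (default 100 restarts; 5 for surrogates).  The greedy
uses the aggregate form of the codelength (per-module exit flow and visit
mass), verified to equal the direct matrix evaluation to machine
precision, and matches exhaustive codelength minimization over all
partitions on graphs of up to 8 nodes.  Modularity
Q = (1/m) Σ (W^out − s^out s^in/m) δ is evaluated exactly as written;
significance uses surrogates that permute each source's target list
(weights travel with edges, so per-source outdegree totals are conserved
exactly) and re-run the full clustering pipeline.

**Paths.**  The gain matrix g_ij = K_ij·|J| (J_E = 0.15 mV,
J_I = −4 J_E; the inhibitory sign is kept as an edge attribute) is scaled
by the maximal real eigenvalue part so the leading real part is exactly 1,
reflecting near-critical operation.  Edge distances are natural-log
reciprocals of the weights (base choice affects reported distances, not
path identities); zero-weight edges are omitted rather than given
infinite distance.  All-pairs shortest paths use a vectorized min-plus
Bellman–Ford with early stopping; negative edge distances are handled and
negative cycles reported with an offending cycle.  For the spectrally
normalized gain graph no negative cycle can occur: the spectral radius of
a nonnegative matrix bounds every cycle's geometric-mean weight, so all
cycle distances are nonnegative by construction.  Ties are broken
deterministically by choosing the smallest predecessor index during
backward path reconstruction.  The shortest path between two areas is the
minimum over all start populations of the source area and end populations
of the target area.  Paths are categorized feedforward/lateral/feedback
by SLN thresholds 0.65/0.35 (directly connected pairs) and
high-to-low/horizontal/low-to-high by the architectural-type difference
(all pairs; difference zero is horizontal).

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical regularities the derivation
relies on: density increasing with architectural type, thickness falling
and relative L4 thickness rising with log density, FLN following
c·exp(−λd) with multiplicative log₁₀-normal noise (sd 0.4), SLN counts
beta-binomial (probability drawn from a beta with the probit-linear mean
and dispersion φ, then a binomial count over a configurable 100 labeled
neurons per connection), binary existence at 62% density, partial
coverage (55% of areas missing densities, two-thirds of connections
missing SLN, ordinal patterns for 40%), areas embedded in 3-space (so
distances are Euclidean and satisfy the triangle inequality), repeat
injections, and distances to non-modeled areas.  Default generating
parameters are λ = 0.11 mm⁻¹, c = 0.045, a₀ = −0.152, a₁ = −1.534,
φ = 0.214.  All randomness flows from one integer seed; regeneration is
bit-identical.

One deliberate subtlety: measured labeling fractions are normalized per
injection, which discards the absolute scale of the distance rule and —
because rows with larger mean distance are scaled up more — attenuates a
pooled log-linear fit of λ.  The generator therefore renormalizes rows to
a configured total by default (matching the structure of measured data)
but supports raw draws (`fln_row_total=None`), which are the appropriate
condition for parameter-recovery studies of the fitting code itself.

The cell-type table is a synthetic stand-in constructed from qualitative
morphology (pyramidal apical dendrites reach layers above the soma;
interneurons stay in their home layer); its numbers are plausible but not
measured.  The generator does not emulate cortical surface geometry,
patchy intra-area connectivity, injection-site spillover, or any spatial
correlation between existence and community structure — so the default
synthetic network has no planted modules, and community detection is
validated on separate planted-block datasets instead.  Passing tests
establish that the pipeline's estimators and audits behave correctly
under the assumed statistical structure; they cannot establish that real
cortex satisfies that structure.

## Numerical choices

- Quadrature for the pairwise disk average: `scipy.integrate.quad` on the
  disk line-picking density, relative tolerance 1e-9 requested.
- Eq.-inversion for synapse counts uses `log1p` throughout; inversion is
  stable up to population products ~1e15.
- Beta-binomial dispersion is bounded to (1e-6, 1−1e-6) on the logit
  scale; means clipped to [1e-10, 1−1e-10] inside the likelihood.
- Degenerate regressions (constant response) return slope 0 with the
  constant as prediction rather than failing.
- Bellman–Ford improvement tolerance 1e-12 (relative for predecessor
  identification).
- Greedy clustering accepts moves improving the codelength by more than
  1e-13 bits, making results insensitive to summation order.
- Default problem sizes (32 areas, 11 injections, 100 clustering
  restarts, 100 surrogates with 5 restarts each) complete the full
  pipeline in well under a minute on a single CPU; these are the sizes
  the packaged tests exercise.

## Known limitations

- The 93%-excitatory redistribution is applied to every projection by
  default; the alternative reading (feedback projections only) is a
  config switch (`redistribute="feedback"`).  The two differ only for
  non-feedback projections with inhibitory target mass.
- The infragranular ordinal weights (1:10:100) are an order-of-magnitude
  convention; results involving 5E/6E splits inherit it.
- The greedy map-equation optimizer is exact on small graphs (checked
  exhaustively to 8 nodes) but carries no global guarantee at scale;
  restarts mitigate this.
- The tie-break for equal-length paths is deterministic but implementation
  -defined (smallest predecessor index), not a global lexicographic
  minimum over node sequences.
- No dual-counterstream substructure, no direction-dependent synapses per
  neuron, no anisotropic distance rule, and no separation of type II from
  type IV input.
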
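# Methods

`pollinet` analyses how forest area loss and proximity to anthropogenic
forest edges reshape plant–pollinator communities and the architecture of
their interaction networks, in the design of a fragmented land-bridge island
system: paired 100 × 4 m edge and interior transects on islands spanning
several orders of magnitude in area, plus mainland reference sites, each
surveyed repeatedly across flowering seasons.  This note documents the
models, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Networks and community summaries

Surveys are pooled per (site, site class): every transect and survey round
of, say, the edge transects of one island contributes to a single weighted
bipartite matrix `A` (plants × pollinators) whose cells are summed visit
counts.  Flowering-plant-only records (`visit_count = 0`) contribute to
floral resources and plant richness but never create a matrix row, so plant
richness can exceed the interacting-plant set.  The four community metrics
are floral resources FR (summed floral area), plant richness PL, pollinator
abundance AB (summed visits) and pollinator richness PO.

## Network architecture metrics

**Relative connectance.** `RC = I / S_obs`, where `I` is the number of
distinct realised links in the local network and `S_obs` the number of
links that the same species realise anywhere in the study (all sites, all
classes, all rounds pooled).  Unlike classical connectance, the denominator
excludes pairs never observed to interact regionally — "forbidden links" do
not dilute the metric.  Interactions are counted as distinct species pairs,
not visitation events, matching how connectance-type metrics are defined in
network ecology.  The global link map pools islands *and* mainland; a
configuration hook allows restricting it.

**NODF.** Computed on the binarised matrix.  Every unordered row pair and
column pair contributes the percentage of the poorer vector's presences
contained in the richer vector; pairs with equal marginal totals (or an
empty poorer vector) contribute zero.  NODF is the mean contribution over
all `C(m,2) + C(n,2)` pairs, × 100, and is invariant to row/column
permutation.  The implementation reproduces `vegan::nestednodf` (sorted
variant) to machine precision; weighted NODF variants are out of scope.

**Modularity.** Barber's weighted bipartite modularity
`Q = (1/F) Σ_ij (A_ij − k_i d_j / F) δ(g_i, h_j)` with `F` the total weight
and `k`, `d` the marginal totals.  `Q` is maximised by label propagation
with agglomerative module merging, restarted from a range of initial module
counts (default 20 restarts, seeded); the single-module partition (`Q = 0`)
is always a candidate, so the returned optimum is never negative.  On small
matrices (≤ 4 × 4) the optimiser matches exhaustive enumeration of all
bipartite set partitions exactly; this is asserted in the test suite.

**Robustness.** Plants are removed sequentially — by default rarest floral
resources first, ties broken lexicographically — and a pollinator goes
secondarily extinct when its last partner disappears.  Robustness is the
trapezoidal area under the survival curve anchored at (0, 1) and (1, 0).
Closed forms used as oracles: a 1 × 1 network scores 0.5; a fully connected
network with `P` plants scores `1 − 1/(2P)`.  No behavioural rewiring is
modelled.

**Sampling completeness.** The abundance-based coverage estimator
`Ĉ = 1 − (f1/n) · (n−1)f1 / ((n−1)f1 + 2f2)` with `f1`, `f2` the singleton
and doubleton counts; interaction completeness applies the same formula to
per-link visit totals.

## Null models

The question the null models answer is whether island values differ from a
*passive sampling effect*: what a random sample of equal effort from the
unfragmented mainland would give.

* **Null model I** resamples, with replacement, the island's own number of
  transects from the mainland pool of the matching site class (edge pools
  compare only to edge, interior to interior) and recomputes the community
  metrics (sums over the sampled multiset, richness over the species union).
* **Null model II** resamples the island's observed number of interaction
  *events*, each drawn proportional to pooled mainland visit counts, under
  the constraint that the resulting network has exactly the island's
  observed plant and pollinator richness.  Draws are accepted by rejection
  sampling; beyond a configurable cap the draw is repaired by single-event
  swaps (dissolving surplus species into the kept set, moving single events
  to absent species) that preserve the event total exactly.  For extreme
  targets where swaps stall (e.g. one plant with several pollinators), a
  constructive fallback grows a connected species set link by link,
  satisfies every species with a greedy edge cover, and distributes the
  remaining events weight-proportionally.  Repaired draws are flagged in
  the draw metadata, and a pure-rejection mode is available.
  Null networks inherit mainland per-species floral totals for the rarity
  extinction order — the null world is assembled from the mainland.

Observed values are scored by the standardized effect size
`SES = (obs − mean_null) / sd_null` (sample s.d.), with two-tailed
significance read off the empirical 2.5–97.5 percentile interval of the
null draws.  Self-calibration holds by construction: observations drawn
from the null itself reject at ≈ 5%, which the test suite verifies at 1,000
draws.  For strongly discrete quantities (small richness counts) the
empirical-percentile test is conservative.

## Piecewise SEM

The analysis table holds one row per (island, site class) with
DA = −ln(area in ha) ("decreased area", sign-flippable by argument),
PE the edge indicator, DM = ln(distance to mainland in m), the four
community metrics and the four architecture metrics.  Each endogenous
variable gets a local model: gaussian linear mixed models for FR, RC, NE,
MO, RO and Poisson GLMMs (log link) for the counts PL, AB, PO, always with
a normal random intercept for island identity and always fitted by ML so
likelihood-derived quantities are comparable across structures.

Gaussian LMMs are fitted by an in-package profiled maximum likelihood:
with a single random intercept the fixed effects are a one-shot GLS solve
given the variance ratio, leaving a bounded 1-D optimisation; the zero
boundary is evaluated explicitly, so variance collapse degenerates exactly
to OLS.  Fixed effects and the log-likelihood match `lme4::lmer`
(`REML = FALSE`), checked in the test suite.  The Poisson GLMM is
implemented in-package by adaptive Gauss–Hermite quadrature: with a single
random intercept the per-group integrand has closed-form derivatives, so
the quadrature grid is centred on the posterior mode found by Newton steps,
11 nodes are used, and the optimiser receives the analytic gradient (the
posterior expectation of the complete-data score).  Fixed effects, standard
errors and the marginal log-likelihood agree with `lme4::glmer`
(`nAGQ = 11`) to ~1e-3, which the test suite checks directly against R.
Wald z tests give per-path p-values (α = 0.05).

**Standardization.** Gaussian: `β · sd(x) / sd(y)`.  Poisson:
`β · sd(x) / sd(ln(y + 0.5))` — a transparent proxy for the response-scale
s.d. that avoids committing to any package's latent-scale convention.  Its
consequence is that Poisson path coefficients are comparable within this
package but not numerically identical to latent-theoretic standardizations.

**d-separation.** The basis set contains one claim per non-adjacent
variable pair, skipping pairs of exogenous variables (their covariance is
free) and pairs joined by a declared correlated-error arc.  Each claim
conditions on the union of both variables' parents; the response is the
topologically later variable (claims against an exogenous variable keep the
endogenous one as response), since tests in non-gaussian families are
direction-sensitive.  The claim p-value is the Wald p of the omitted
variable added to the response's parent model (same family, same random
intercept).  Fisher's `C = −2 Σ ln p ~ χ²(2k)`; p-values are clipped at
1e-300 before the log.  Variables and their exogenous/endogenous roles
persist when selection removes a variable's last path, so removed paths
correctly reappear as independence claims.

**Model selection.** SEM-level `AIC = C + 2K`, `K` counting every estimated
parameter across component models (fixed effects, random-intercept
variances, gaussian residual variances).  Backward selection greedily
removes the directed path whose removal most lowers this AIC and stops when
no removal helps; non-significant paths may survive, and a final d-sep
p ≤ 0.05 triggers a warning rather than an error.  The loop is fully
deterministic.

**Effects.** Direct effect = the standardized coefficient; indirect =
sum over all directed compound paths of the product of standardized
coefficients (verified against the matrix closed form
`(I − B)⁻¹ − I` to 1e-8); total = direct + indirect.  Moderation terms are
estimated (products of mean-centered continuous factors, entering only
their target path's component model) but not traced.  Confidence intervals
come from a cluster bootstrap resampling islands with replacement,
refitting the fixed structure and re-tracing (default 1,000 draws; the CLI
default is 200 with a `--full-scale` switch); > 10% refit failures abort.

**Default structure.** The shipped 45-path hypothesis: each of DA, PE, DM
to each of the eight responses (24); FR→AB, PL→AB, FR→PO, PL→PO, AB→PO (5);
{FR, PL, AB, PO} → {RC, NE, MO} (12); {AB, RC, MO, NE} → RO (4), with
NE→RO as path 45.  Correlated errors join FR↔PL and the RC/NE/MO trio —
the architecture metrics are computed from the same matrix, so their
errors cannot be independent.  The structure is user-replaceable via YAML.

## Null-model SEM

The final structure is refit, without re-selection, on replicate datasets
whose FR/PL/AB/PO come from Null model I draws and RC/NE/MO/RO from Null
model II networks (island attribute columns bit-identical across
replicates).  Per path, the 2.5–97.5 percentile envelope of null
standardized coefficients is compared with the observed coefficient; paths
outside it deviate from passive-sampling expectation.  Null coefficients
are generally *not* centred on zero — sampling effort scales with island
area, so passive sampling alone induces area effects; that is precisely
the confound the comparison removes.  Non-convergent replicates are
dropped and counted (> 20% aborts), not retried, keeping the draw sequence
reproducible; every replicate's RNG derives from (seed, replicate, row).

## Synthetic data

Two generator modes, because no single simulator both mimics the field
design and provides exact ground-truth path coefficients:

* **Mechanistic mode** emulates the sampling design: 41 islands with
  ln-areas from a truncated normal (ln 3, s.d. 1.5, range 0.3–1,300 ha, so
  most islands are small), transect pairs = clamp(round(1.3 + 2.06 ln a),
  1, 16), 16 mainland site pairs, 20 rounds per transect, 68 plant and 313
  pollinator species with log-normal abundances.  Plant occupancy rises
  with island area and is shared within a transect pair (edges carry the
  interior flora plus extra edge-affiliated species); flowering is
  Bernoulli per round; floral areas are log-normal, scaled 18.52× on edge
  transects; visit counts are Poisson with rate ∝ (class-normalised floral
  area) × (pollinator abundance) × a Gaussian trait-matching kernel,
  scaled 18.43× on edges.  The visitation constant (0.055) was calibrated
  once so study-wide visit totals land near 2 × 10⁴.  Not emulated:
  phenological turnover, spatial geometry, behavioural rewiring, and the
  exact dependence structure of real communities — so a d-separation test
  of the shipped hypothesis on mechanistic data can legitimately reject.
* **DAG mode** simulates the analysis table directly from configured
  standardized coefficients: exogenous columns from the island design,
  endogenous variables built in topological order as β-weighted sums of
  standardized parents plus island intercept (30% of noise variance) and
  residual noise scaled to keep responses ≈ unit variance.  Poisson
  responses are counts with log-rate 1.8 + 0.7·latent; their standardized
  values entering children use ln(y + 0.5), matching the analysis-side
  proxy, so configured signs and approximate magnitudes are recoverable.
  Default truth uses 17 nonzero paths with |β| 0.25–0.8 mirroring the
  qualitative field findings.

Passing tests on synthetic data show that the estimators recover what the
generator encodes at the study's design size; they do not certify the
field-data conclusions themselves.

## Problem sizes and tolerances

Stochastic checks run at the sizes their precision requires: null-model
calibration at 1,000 + 1,000 draws (rejection within 5% ± 2%), d-separation
type-I error over 500 simulations at n = 200 (accepted within 3–8%, KS
uniformity at α = 0.01), sign recovery over 100 replicates at n = 82
(≥ 90% per true path), and the null-SEM self-calibration with a 150-draw
envelope against 60 held-out null datasets (deviation rate 2–9%).  The
acceptance script uses a 120/40 split for the same quantity.  Modularity
uses 20 restarts for reported metrics and 4 restarts inside null replicates,
where only the envelope of Q matters.  Null model II rejection caps default
to 10,000 tries standalone and 200 inside the replicate loops, where the
repair pass dominates anyway.  All RNG flows through
`numpy.random.default_rng` seeded from explicit (seed, index) tuples; two
runs with the same seed are bit-identical.

## Known limitations

* Poisson standardization is proxy-based (above); exact replication of
  latent-scale conventions from other software is not attempted.
* The repair pass of Null model II slightly perturbs the conditional draw
  distribution relative to pure rejection; purists can disable it.
* The greedy AIC backward selection explores single-path removals only and
  can retain spurious paths at n = 82, as any stepwise procedure can.
* Degenerate groups (islands with a single usable site class, networks too
  sparse for a metric) are retained where the maths allows and dropped from
  the design table otherwise.
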
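# Methods

This note documents the models implemented in `suckletrack`, their
assumptions and defaults, what the synthetic generator does and does not
emulate, and the design decisions taken where the underlying methods admit
more than one convention. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Study design and data model

The package targets longitudinal mother–infant designs: each sow (dyad)
contributes source samples from maternal body sites and the birth
environment, and on each sampling day one piglet per litter contributes
mucosal samples from four intestinal segments. Samples are typed by a
metadata table (`sample_id, role, environment, host_id, dyad_id, day`, plus
optional `breed`/`sex`); `role` is `source` or `sink`, and `environment`
doubles as the source-environment label for sources and the gut-segment
label for sinks, drawn from a controlled vocabulary. Sinks must carry a
`dyad_id` (the dam); environment-only sources such as a shared incubator may
omit it. Feature tables are tab-delimited with features as rows (header cell
`#OTU ID`, optional trailing `taxonomy` column), trees are Newick with tip
names equal to feature IDs (missing branch lengths become 0 with a warning),
and distance matrices are square TSV. Sample and feature IDs are
case-sensitive opaque keys; enum labels are case-folded.

## Rarefaction and diversity

Rarefaction draws a multivariate-hypergeometric subsample (without
replacement) to a common depth; samples below depth are dropped (or raise
under `policy="strict"`). Alpha diversity uses the bias-corrected Chao1,
`S_obs + F1(F1−1)/(2(F2+1))` — defined even when no doubletons exist — and
Shannon entropy in base 2 (bits), both matching the QIIME 1.x conventions;
the log base is switchable. Beta diversity offers Bray-Curtis and
unweighted/weighted UniFrac (scikit-bio backend); weighted UniFrac is
non-normalized by default, again the QIIME 1.x default, with a `normalized`
flag. Presence for unweighted metrics means count ≥ 1 after rarefaction.
The UniFrac implementations are checked in the test suite against an
independent brute-force oracle that enumerates every branch of random trees
and sums unique/observed branch lengths explicitly.

Beta-diversity trajectories summarise a distance matrix per (group, day):
`within` averages each sample's distance to its same-day group mates
(singleton time points are skipped with a warning); `from_day0` averages
each sample's distance to its group's day-0 samples, quantifying divergence
from the birth community.

## Ordination and PERMANOVA

PCoA is classical metric scaling: Gower double-centering of squared
distances, symmetric eigendecomposition, coordinates scaled by the square
root of positive eigenvalues. Negative eigenvalues (semi-metric inputs) are
reported but excluded from the proportion-explained denominator; no
Cailliez/Lingoes correction is applied. PERMANOVA is the one-way
pseudo-F of Anderson (2001): `SS_total = Σ_{i<j} d²_ij / n`, within-group
analogues per group, `F = (SS_b/(a−1))/(SS_w/(n−a))`, `R² = SS_b/SS_total`.
Factors are tested marginally, one at a time — the output table reports one
(R², P) pair per factor per metric, with P rendered as `< 0.001` below the
display floor while the machine-readable column keeps full precision.
Permutation p-values count the observed statistic in numerator and
denominator, `p = (1 + #{F* ≥ F})/(1 + B)`, so the attainable floor is
`1/(B+1)` and p is never 0; an exhaustive-enumeration mode replaces the
Monte-Carlo loop for small designs. Kruskal-Wallis uses the tie-corrected H
with a χ² approximation; the two-group path uses Mann-Whitney U, exact for
tie-free pooled samples of ≤ 12 and a tie-corrected normal approximation
(without continuity correction) otherwise.

## Source tracking

The sampler follows the collapsed-Gibbs construction of SourceTracker:
source environments are collapsed to taxon count vectors `m_v` (summed
across all sows by default; a `dyad_only` mode restricts to the sink's own
dam, trading sample size for specificity), and each sink read carries a
latent source label resampled one read at a time from the conditional given
in the README. The Unknown source has no observed counts and a larger
per-taxon pseudocount (α₂ = 0.1 vs α₁ = 0.001), so reads of taxa absent
from every source migrate to it. Defaults mirror SourceTracker v1.0:
β = 10, sink rarefaction depth 1000, 10 restarts × 100 burn-in sweeps with
one retained draw each; retained draws record assignment fractions
`N_v/N`, so each draw sums to 1 exactly. Sinks below the rarefaction depth
are used at native depth with a logged warning rather than dropped.
Leave-one-out prior auto-tuning is out of scope. The per-read sweep is a
numba kernel driven by pre-generated uniforms, which makes chains
deterministic given a seed and keeps a pure-Python twin available for
verification.

Two behaviours of the model are worth knowing. First, the posterior
mean of a correct source saturates below 1 (a few percent leak to Unknown)
because the Unknown component can absorb multinomial noise; the validation
therefore measures recovery as mean absolute error over a mixture grid
(≤ 0.05 under well-separated sources at depth 1000). Second, when sinks mix
*dam-specific* community variants but sources are pooled across dams, the
dam-private fraction is genuinely absent from the pooled profiles and is
attributed to Unknown — an upward bias of the Unknown share that is a
property of the model, not a defect of the sampler.

## Transmission testing

The unit of analysis is the (sow, sampled piglet) pair inside a day window;
with one piglet sampled per litter per day, a window spanning three sampling
days yields three pairs per sow. Routes are evaluated per (source
environment, gut segment, window), with windows defaulting to days 0–3 and
day 4 onward. Candidates must be present in more than 20% (strict) of
either the route's source samples or its sink samples. Per candidate OTU:

* **Sharing statistic** — fraction of pairs with the OTU present in both
  members (presence = count ≥ 1 on the table as given; the pipeline
  rarefies first).
* **Pairing-permutation test** — dams are randomly re-matched to piglets;
  one-sided for excess sharing (transmission is directional); all `n!`
  pairings are enumerated when n ≤ 7.
* **Fisher's exact test** — two-sided, on the 2×2 source-presence ×
  sink-presence table over pairs.
* **Spearman fallback** — for OTUs present in *every* source and sink
  sample of the route (where presence-based tests are blind), paired
  dam/piglet relative abundances are rank-correlated; exact permutation p
  for ≤ 7 tie-free pairs, t-approximation otherwise. Significance requires
  a *positive* ρ, the same directionality argument as the one-sided
  permutation test.

Decision rule: transmitted iff (permutation p < α AND Fisher p < α) OR
(universal presence AND Spearman p < α with ρ > 0), α = 0.05. No
multiple-testing correction enters the decision (the rule is applied at raw
α); BH-adjusted p-values are reported alongside for transparency. Summaries
report both event-level counts (OTU × route) and distinct-OTU counts.

The dyad-vs-random comparison asks whether each sink is closer to its own
dam's source community than to a random sow's. Reported values are the mean
true-pair distance and the mean over sampled mismatched pairs; significance
is a one-sided dam-relabeling permutation test on the mean true-pair
distance. A two-sample rank test between the true and random distance sets
was considered and rejected: every sink appears in both sets, so that test
is structurally conservative under the exchangeable null, whereas the
relabeling test is exact there (the test suite verifies uniform null
p-values by simulation).

## Host-gene association

Relative expression follows 2^−ΔΔCt: target Ct normalised against a
reference gene, then against a calibrator condition — by default the mean
ΔCt of the day-0 samples of the same segment (the calibrator is
configurable; fold changes are invariant to adding a constant to all four
Ct values). OTU–gene association is Spearman correlation between matched
relative abundances and relative expression, with BH adjustment applied
jointly across the full OTU × gene grid (the most conservative family
definition). Correlated OTUs are stratified into small- vs
large-intestine-enriched groups by comparing mean relative abundance across
the two segment classes (ties go to large intestine; a rank-test p
accompanies each label). This contrast rule is a stand-in for an
unspecified upstream stratification procedure and is flagged as such in the
output metadata.

## Co-occurrence network

Counts are CLR-transformed per sample (pseudocount 1 by default). Each
node's CLR profile is lasso-regressed on all others along a 30-point
log-spaced penalty path (Meinshausen-Bühlmann neighborhood selection);
edges are the OR of the two directed selections with the mean of the two
coefficients as signed weight — the weights are regression coefficients,
not correlations, and are labelled `mb_coefficient` in outputs to avoid
overclaiming. StARS selects the penalty: 50 subsamples of
⌊10√n⌋ rows (capped at 0.8 n), total instability `mean 2f(1−f)` over edge
selection frequencies, instability monotonized by a running maximum from
the sparse end, and the smallest penalty (densest graph) with monotonized
instability ≤ 0.05 is kept. Edges with |weight| below a display threshold
(default 0.05) are suppressed in the emitted edge list. In the pipeline the
network is fit over sink samples only, on the OTUs significantly associated
with gene expression.

## Synthetic data generator

The generator emulates the target study design: `n_dyads` sows
(default 8), days (0, 1, 3, 7, 14, 28, 35), four gut segments, six source
environments, sequencing depth 27 848 reads/sample (the study's rarefaction
depth; column sums equal the depth exactly because samples are multinomial
draws). Source environments get sparse Dirichlet base profiles
(concentration 0.1); each dam's personal variant is a Dirichlet resample
around the base (concentration 200 — the "dam effect"), and each sample is
further overdispersed by a per-sample Dirichlet resample (concentration
500). Sinks are multinomial draws from
`Σ_v γ_v · (dam's profile for source v) + γ_unknown · (dyad-specific
profile over reserved features that never occur in any source)`; the
default mixing schedule drifts linearly from milk-dominated at birth to
feces-dominated at weaning, with the large intestine drifting faster than
the small intestine. Ground truth (per-sink mixing vectors, planted OTUs,
gene links) is emitted as a JSON sidecar.

Planted transmitted OTUs follow a carriage model: each planted OTU is
carried by a random half of the sows; a carrier dam always sheds it in the
route environment, each of her piglets sampled in the window acquires it
with probability `p_share` (0.9, gut-wide), and piglets of non-carrier dams
pick it up from the environment at the `background` rate (0.2,
independently per piglet). Joint matched-pair presence equal to `p_share`
marginally — an alternative reading — was rejected because near-universal
presence makes the pairing-permutation null degenerate and no analysis
could detect it. A configurable number of "universal" OTUs are additionally
planted in every dam and piglet with dam-correlated lognormal abundance,
exercising the Spearman branch. Gene expression per sink sample is
`exp(baseline + Σ sign·strength·z(log abundance) + Gaussian noise)` for the
linked OTUs.

What the generator does **not** emulate: sequence-level artefacts (chimeras,
PCR bias), taxonomic structure in the profiles, true phylogenetic signal
(the tree is a random coalescent-style topology with exponential branch
lengths, so UniFrac results are exercised but not ecologically meaningful),
litter-size variation, or antibiotic/diet covariates. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability under the stated noise model — not performance on real
amplicon data.

## Validation scales and numerical choices

The validation battery (tests and `scripts/acceptance.py`) uses scaled
problem sizes chosen to exercise each claim: mixture recovery on a 3×3 grid
of true 3-source mixtures at sink depth 1000 with well-separated profiles
(Dirichlet concentration 0.05); transmission sensitivity/specificity over
20 generator seeds at the planted conditions above with the dam effect
disabled (so that non-planted OTUs are genuinely null); p-value calibration
over 200 replicates at reduced permutation counts (99–999); chain-graph
recovery at p = 20, n = 400, partial correlation 0.5 over 20 seeds; and a
byte-identity check of two same-seed pipeline runs. The demo pipeline is a
scaled-down study (8 dyads, 4 days, 150 OTUs, depth 5000).

Numerical conventions: permutation counters use a `±1e-12` tolerance when
comparing statistics; PCoA treats eigenvalues below `1e-10·|λ_max|` as
zero; Gibbs determinism comes from pre-generated uniforms consumed in a
fixed order (consequently a consistent relabeling of taxa changes the sweep
order, so label invariance holds in distribution, not bitwise); stage seeds
in the pipeline are derived from the global seed by a fixed affine map, and
all emitted paths in config/manifest are relative so same-seed runs are
byte-identical anywhere.

## Known limitations

* With the dam effect enabled, *every* abundant OTU genuinely co-varies
  within dyads, and the decision rule (faithfully) flags many of them —
  on real data the "transmitted" label should be read as "dyad-associated
  presence/abundance", not proof of a transmission event.
* The Unknown share is upward-biased whenever sinks contain host-private
  community variants absent from the pooled sources (see above).
* PERMANOVA is marginal one-way per factor; confounded factors (e.g. day
  and segment in an unbalanced design) are not partitioned sequentially.
* The Spearman fallback requires universal presence under the strictest
  reading (every source and sink sample of the route); rare-but-transmitted
  OTUs missed by the presence tests are not rescued by it.
* StARS instability is estimated from subsamples of a single dataset; for
  n below ~25 the subsample size approaches n and stability selection
  loses meaning.
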
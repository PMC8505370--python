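# Methods

This note documents the statistical procedures, the synthetic-data
generator's assumptions, and the numerical choices that were genuinely
open — in enough detail that a user can decide whether each default fits
their data.

## Sampling arithmetic and faunal indices

A field sample consists of a dried soil mass `dry_mass` (g), a total
animal count `counted_total`, and a genus-identified subsample of at
most 100 individuals (all of them when fewer were present). Total
abundance per 100 g dry soil is `counted_total × 100 / dry_mass`; genus
abundances allocate this total proportionally to the identified counts.
Genus richness is therefore the richness of the identified subsample; a
rarefaction correction is deliberately not applied by default, matching
the common reporting practice for this protocol (the subsample size is
essentially constant across plots, so comparisons remain fair).

Trophic groups are plant feeders (PF), bacterial feeders (BF), fungal
feeders (FF), predators (Pr) and omnivores (Om); Om and Pr are also
reported combined because their life-history strategies are similar.
Derived ratios: predator–prey (Pr+Om)/PF, channel FF/(FF+BF), and
grazing pressure log(PF/root mass). The log base for the grazing ratio
is natural (configurable); the literature writes "log" without a base,
and the natural log keeps it commensurable with the log-linear richness
terms used in the models.

Life-history classes follow the colonizer–persister (c–p) scale, 1–5.
c–p 1 and 2 are pooled as r-strategists. Plant feeders are excluded
from every c–p-based quantity (they track host-plant resources rather
than enrichment/disturbance). The Maturity Index is the c–p-weighted
mean of relative abundances *within the free-living (non-PF) fraction*;
weighting within the full community instead is available via
`maturity_index(..., exclude_pf=False)`.

The Enrichment and Structure indices use weighted guild components

    EI = 100·e/(e+b),  SI = 100·s/(s+b)

with e, b, s weighted abundance sums over enrichment (BF1 ×3.2,
FF2 ×0.8), basal (BF2, FF2 ×0.8) and structure guilds (c–p 3 → 1.8,
c–p 4 → 3.2, c–p 5 → 5.0 for BF/FF/Om, plus Pr2 → 0.8 and Pr3–5 as
above). FF2 belongs to both the enrichment and the basal component.
The weights ship as `data/guild_weights.tsv` and are an explicit input,
so an alternative published weighting can be substituted without code
changes. Guild codes never printed in the classic framework (FF1, Om1,
Om2, Pr1) are mapped to "excluded" with weight 0.

Undefined metrics (empty profile, zero denominator, missing root mass)
propagate as NaN, never as 0 — zero is a legal value of every ratio and
must stay distinguishable from "not computable".

The shipped genus table (`data/genus_annotations.tsv`, 51 genera)
carries a `source` column: 13 genera are `verified` (codes printed in
the source study), the rest are `curated` from the standard
Bongers/Yeates classifications and should be reviewed before use with
real data from other regions.

## The design and its reconstruction

The dominance design sows nine grassland species (five grasses, two
legumes, two herbs) at richness 1, 2, 6 and 9 in four blocks, with
replicates of identical compositions in different blocks. Two species
(Phleum pratense, Anthriscus sylvestris) were nearly extinct at
sampling and act only as partners. The sampled roster is: two
monocultures per target species (14); all 21 target pairs at two
replicates except seven legume-containing pairs at one (35); twelve
single-replicate pairs with the two non-target partners after the
stated exclusions and one doubling (12); 24 six-species plots; 8
nine-species plots — 93 in total.

The six-species compositions are not individually published; only their
margins are (each target occurs 16 times in 24 plots). The package
generates 12 distinct 6-subsets — each species appearing 8 times, then
duplicated into two replicates — by exhaustive backtracking over the
omitted 3-subsets with lexicographic ordering. Any such solution
matches every printed margin; the field compositions may differ, which
affects nothing downstream because no statistic conditions on the
identity of a six-species composition beyond its mixture label. Block
assignment cycles blocks 1–4 within each richness level while keeping
replicates of a composition apart (the nine-species community has eight
replicates, which four blocks can only balance two-per-block).

## The synthetic generator

The generator produces study-shaped data, not estimates of the field
system. Covariates are lognormal with log-linear richness links:

    v = exp(α + β·ln(sown richness) + block + ε),  ε ~ N(0, σ²)

with defaults (α on the natural scale): shoot mass 220 g m⁻² (β=0.35),
root mass 1.8 mg cm⁻³ (β=0.20), SRL 100 m g⁻¹ (β=−0.08, the "small
negative" relationship), leaf C/N 19 (β=0, no richness relationship),
soil C_org 20 mg g⁻¹ (β=0.15). Root length density is root mass × SRL
(unit-converted) with 5% noise, hence strongly collinear with root mass
by construction, as in real data. Soil N is built from the standardized
log C_org with target correlation 0.866. Block intercepts have SD 0.08
on the log scale. Realized richness thins legume presence (extinction
probability 0.35; herbs 0.15) in mixtures, reproducing the pattern of
legume losses that motivated the single-replicate pairs.

Nematode counts: expected per-100 g trophic abundances follow the
causal structure assumed by the trophic-abundance SEM — BF responds to
soil C_org (slope 0.05 per mg g⁻¹), PF to leaf C/N (+0.08) and shoot
mass (−0.0015 per g m⁻²), FF is flat, and Om+Pr follows a log-log
(elasticity) numerical response to the *realized* prey abundances
(0.6 on BF, 0.5 on PF). Intercepts put the community at the reported
field scale: ≈1850 individuals per 100 g with plant feeders ≈60%.
Counts are negative binomial (Gamma–Poisson, dispersion 8; `None` gives
the Poisson limit), allocated to genera by a geometric rank–abundance
series (ratio 0.55) over the annotation table's genera within each
group, and identification is a multivariate hypergeometric subsample of
min(total, 100) individuals. Dry mass is Normal(22 g, 1.5 g) truncated
at 10 g — the protocol records only the ~25 g fresh mass, and the dry
mass is what the arithmetic needs. Root-derived measurements are
flagged missing on the second monoculture replicates (86 of 93 plots
complete), mirroring the field campaign.

What the generator does *not* emulate: temporal dynamics, spatial
autocorrelation beyond block intercepts, composition-specific community
effects (mixture identity contributes no variance of its own), genus-
level environmental responses within trophic groups, and taxonomic
error. Passing tests therefore demonstrate correctness of the
*methods* under a realistic sampling model, not field realism of any
particular effect size. Effect-size defaults were chosen once so that
the standardized causal paths are ≈0.3–0.6 at n = 86 — strong enough
that a correct implementation recovers every path sign, weak enough
that miscalibrated tests are detectable.

## Ordination

Bray–Curtis (abundance) and Jaccard (presence–absence) dissimilarities
come from scipy. NMDS minimizes Kruskal stress-1 by iterative
majorization (Guttman transform) alternating with pooled-adjacent-
violators isotonic regression of configuration distances on
dissimilarity ranks (weak/primary tie treatment). Defaults: k = 3, 20
starts (classical-scaling start plus 19 seeded random starts),
convergence when stress improves by < 1e-7, 500 iterations maximum.
Because stress-1 is scale-invariant, the optimizer has a flat scale
direction; the final configuration is pinned to the data scale (rms
configuration distance = rms dissimilarity), centred, rotated to
principal axes, and sign-fixed, making scores bit-for-bit reproducible
for a given seed. Strongly clustered data with tied between-cluster
dissimilarities admit degenerate zero-stress embeddings — a property of
the stress criterion itself, worth checking via the stress value and a
Shepard-style inspection when clusters are expected.

Vector fitting regresses each genus' abundance on all k score axes;
r² and direction cosines are reported, with axis-wise loadings
available separately since axis 2 is where a richness gradient
typically expresses itself in this design. Indicator analysis computes
IndVal = sqrt(A·B) over single richness levels and their combinations
(up to all-but-one), reporting each genus' best combination. All
permutation p-values use the add-one estimator
p = (1 + #{perm ≥ observed})/(1 + n_perm), so p is never exactly 0;
defaults are 999 permutations at α = 0.05, with mandatory seeds.

SD-ellipse areas per group are π·s₁·s₂ with s₁, s₂ the standard
deviations along the principal axes of the group's axis-1/2 score
covariance (square roots of the covariance eigenvalues).

## Mixed models and the richness tests

All models carry crossed random intercepts for block and mixture
identity (a monoculture's mixture identity is its species). They are
estimated with statsmodels' MixedLM as two variance components over a
single trivial group; the likelihood is maximized by Powell search
followed by L-BFGS refinement, which reproduces lme4's ML
log-likelihoods to ≈1e-6 on this design (the default optimizer can
stall 1–3 log-units short on these crossed structures, which would
corrupt likelihood-ratio tests).

Richness tests compare, by maximum likelihood, a random-effects-only
null against the same model plus sown richness as a log-linear term (or
realized richness, untransformed by default); the LRT chi-square has
df = 1. ML rather than REML because the models differ in fixed effects.
Response transformations follow a fixed ledger: log for BF, FF and
Om+Pr abundances, the predator–prey ratio, and c–p 1+2 and c–p 4
abundances; square root for FF genus richness and c–p 3 and c–p 5;
identity otherwise (including PF abundance). A log transform of a
non-positive value is a hard error naming the offending plots.

Tukey HSD (studentized range) compares NMDS scores across the four
richness levels; groups with fewer than two observations are dropped
with a warning.

D_max = (O_T − M_Max)/M_Max measures transgressive overyielding, with
M_Max the best constituent monoculture — the maximum for variables
expected to increase with richness, the minimum for variables expected
to decrease (channel and grazing-pressure ratios). Species-level
monoculture values average the available replicates. The deviation-
from-zero test aggregates replicate plots to mixture means (replicates
sit in different blocks, so block effects average out), regresses the
means on centred ln(sown richness), and tests the intercept — the grand
mean under this parameterization — with F = t², df = (1, n_mixtures − 2).
With all 45 mixtures contributing this gives denominator df 43; the
procedure reports its own dfs when mixtures drop out (undefined
benchmarks).

## Piecewise SEM

A `SemModel` is a DAG with per-variable transformation tags and
optional correlated-error pairs. Every endogenous variable gets a
mixed-effects component model on its parents (REML). Path coefficients
are standardized as b·SD(x)/SD(y) on the transformed scales; marginal
R² is var(fixed)/(var(fixed)+var(random)+var(residual)) and conditional
R² adds the random-intercept variances to the numerator.

The d-separation basis set contains one claim per non-adjacent pair,
conditioned on the union of both members' parents; correlated-error
pairs are exempt. Each claim is tested by adding the putative cause to
the response's conditioning model; the response is the pair member
later in topological order and never a design variable (the richness
gradient cannot be a response — mixture identity determines it exactly,
so such a regression would be degenerate). Claim and path p-values use
a t reference with inner-stratum denominator df (n − p − total random-
intercept levels + 2, nlme-style): with ~30 claims aggregated into
Fisher's C = −2 Σ ln p ~ χ²(2k), the normal reference's slight
anti-conservatism compounds into a visibly inflated rejection rate,
while the stratum df keeps the aggregate test honest. Claim p-values
are floored at 1e-300 (Fisher's C rejects p = 0 as input). An empty
basis set gives C = 0 with fit p = 1.

The default trophic-abundance model mirrors the generator: ln richness
→ {root mass, SRL, shoot mass, leaf C/N, soil C_org}; soil C_org → BF;
leaf C/N and shoot mass → PF; BF and PF → Om+Pr; FF driverless.
Covariates enter on the log scale (they are multiplicative,
right-skewed quantities; logging makes the component models linear and
homoscedastic). Abundances use log1p: a subsample containing no
individual of a group estimates that group's abundance as exactly 0,
and the unit offset is immaterial at per-100 g abundances of order
10²–10³. PF abundance is log-scale here (its generating link is
multiplicative) even though the LRT ledger keeps PF untransformed.
Correlated errors are declared between trophic-abundance pairs without
a directed path (BF–PF, BF–FF, PF–FF, FF–OmPr): all group abundances
are estimated from the same ≤100-individual subsample, so their
measurement errors are negatively coupled by construction, and testing
those pairs as independence claims would reject a true model. Rows
with missing values in any model variable are dropped and counted
(n = 86 with the default generator's root-data pattern).

## Numerical conventions and limitations

* Seeds control every stochastic step (generator, NMDS starts,
  permutations); identical seeds give bit-identical output.
* Ties in isotonic regression use the weak (primary) treatment; ties in
  permutation statistics count as "as extreme" (≥ with 1e-12 slack).
* Degenerate inputs: empty profiles, all-zero dissimilarity pairs,
  collinear score groups, saturated DAGs and zero-residual D_max tables
  all have defined, tested behaviour (NaN flags, zero areas, C = 0,
  F = 0/p = 1 respectively).
* The LRT is asymptotic; on this design its size is mildly conservative
  (≈0.04 at nominal 0.05 over 1000 null simulations), driven by the
  mixture-level replication of the richness gradient.
* Fisher's C assumes independent claim p-values; claims sharing data
  are dependent, and the t-reference df choice above compensates in
  aggregate but is not an exact correction.
* IndVal group combinations grow combinatorially; with the four
  richness levels this is 14 candidate sets per genus, which is cheap,
  but many-level groupings should restrict `max_order`.
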
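# Methods

This note documents the models and procedures implemented in `aflpop`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Data model and filtering

The unit of analysis is a binary matrix X (n individuals × L loci) of
dominant band phenotypes plus per-individual metadata: group (host-web)
id, age class (five instar stages or `unknown`), sex, and planar
coordinates in meters. All members of one web share coordinates, because
positions are recorded per web.

A locus is retained only if its presence count c satisfies
2 ≤ c ≤ n − 2. Invariant loci (c = 0, n) carry no information; singleton
loci (c = 1) and their mirror images (c = n − 1) cannot be distinguished
from scoring noise and destabilize frequency-corrected statistics.
Individuals whose retained profile is all-zero are dropped by default
(a bandless profile makes band-sharing dissimilarity undefined and is
read as a failed fingerprint; `drop_empty_individuals=False` disables
this). Dropping individuals can tighten the c ≤ n − 2 bound, so the
filter iterates to a fixed point — this is what makes it idempotent.

Group-level analyses exclude webs with fewer than 2 members
(`min_web_size=2`); the relatedness permutation test requires at least 3,
because at group sizes 1–2 the permutation null coincides with the
sampling CI of the group mean.

### Coordinates

Geographic coordinates (WGS84 lat/lon) are projected to UTM with an
in-package transverse-Mercator forward projection (Krüger alpha-series,
4th order in the third flattening; error well under a millimeter at the
sub-degree extents of a field site). Sites must fall in one UTM zone and
hemisphere; a site straddling a zone boundary raises an error suggesting
a local planar projection, since mixing zones would corrupt pairwise
distances. Tests verify the projection against an independently derived
series (Snyder's formulas) and against a geodesic closed form
(1 km along a meridian projects to within 1 m of 1000 m).

### Age/sex strata

`juveniles` = instars 1–3; `males`/`females` = instar 4 + adults of that
sex; `adults` pools both sexes. Instar 3 is the first sexable stage but
is grouped with juveniles, because sub-adult (instar 4) is the first
stage with distinguishable genitalia and field surveys contrast
"sub-males/sub-females" with juveniles. The mapping is configurable
(`juvenile_classes=`) since the cut is a convention, not a biological
constant.

## Jaccard dissimilarity and NMDS

The pairwise dissimilarity is D = 2B/(1 + B) with
B = Σ|x_j − x_k| / Σ(x_j + x_k) (binary Bray–Curtis). Algebraically
D = (b + c)/(a + b + c) with a the shared bands and b, c the private
ones — the classical Jaccard distance — and the implementation simply
calls `scipy pdist(metric="jaccard")`; the equivalence is asserted in
tests. D is undefined for a bandless pair, which the locus filter makes
unreachable.

NMDS embeds D in k = 3 dimensions using only rank order. Each start
alternates (i) isotonic (pool-adjacent-violators) regression of the
configuration distances onto the dissimilarity ranks — the *primary*
treatment of ties: pairs with equal dissimilarity are pre-sorted by
current distance and may receive different fitted values — and (ii) a
Guttman majorization step. Because Kruskal stress-1 normalizes by Σd²,
the Guttman step alone does not strictly guarantee stress-1 descent, so
an accepted step must not increase stress; otherwise the update is
halved once and, failing that, the start terminates. The recorded
stress trace is therefore non-increasing by construction (tested).

Stopping: a start ends when stress_new/stress_old exceeds the
convergence ratio (default 0.999999, the conventional setting), when
stress < 1e-4, after 50 iterations without improvement, or at 500
iterations. Start 0 is classical (Torgerson) metric scaling of D —
standard practice, and usually already close — with the remaining starts
random Gaussian; the lowest-stress configuration wins. `stop_stress`
optionally ends the search once a target stress is beaten, mirroring
restart schedules that stop at the first convergent solution. The
returned configuration is column-centered; stress is rotation-invariant
so no rotation is canonicalized.

## Cluster number by average silhouette

Candidate partitions come from cutting an agglomerative dendrogram of D
at C = 2…C_max (C_max defaults to the number of sampled webs, matching
the survey design). The silhouette of point i is
s_i = (b_i − a_i)/max(a_i, b_i) with a_i the mean within-cluster and b_i
the mean nearest-other-cluster dissimilarity; singleton-cluster points
score 0. C = 1 has no silhouette and is assigned 0, so it is reported
(with a warning) only when every partition scores negative. Ties break
toward smaller C.

The linkage is a genuinely open choice (the analysis this package
reimplements does not state one): the default is average/UPGMA, the most
robust choice on distance input, and the acceptance harness scans all
four (`average`, `complete`, `single`, `ward`) and reports which
reproduces a published optimum. Dendrogram construction and cutting are
delegated to scipy (`linkage`/`fcluster`); silhouettes are computed
in-package and cross-checked against scikit-learn and a brute-force
double loop.

## Haploid admixture model and delta-K

Dominant bands are treated as haploid loci with independent frequencies.
With K clusters: q_x ~ Dirichlet(α·1_K) per individual, per-locus origin
z_xl ~ Categorical(q_x), band x_l | z_xl = k ~ Bernoulli(p_kl),
p_kl ~ Beta(1, 1). All three conditionals are conjugate; α (one value
for all clusters) is updated by random-walk Metropolis on log α with
step 0.05 under a uniform prior on (0, 10].

The log-likelihood is recorded every 10 post-burn-in sweeps;
ln P(X|K) ≈ mean(lnL) − var(lnL)/2 (sample variance), the standard
harmonic-adjustment summary. The number of clusters is the argmax of the
Evanno statistic ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(K) over replicate
runs (≥ 2 per K, default 10; recovery experiments in the tests use 3,
which is ample at the divergences simulated). A zero replicate sd leaves
ΔK undefined at that K (flagged, excluded). Replicate Q matrices are
aligned by greedy column-correlation matching before averaging for bar
plots; alignment never affects ΔK.

Chain lengths: the model mixes fast on binary loci (independent
conjugate updates, no linkage), so defaults are 10k burn-in / 20k sweeps
and the recovery tests use a few hundred/thousand; million-sweep
reference settings remain available via parameters. The trace-based
estimator needs ≥ 2 recorded values and is exact on the documented
two-point example.

Note on exchangeability: permuting the input individuals yields the same
posterior law, but not bit-identical Q rows under a fixed seed, because
the vectorized sampler consumes random draws in array order. Tests
therefore assert recovery of the same partition (up to label swap) after
permutation rather than exact row equality.

## Relatedness for dominant markers

Codominant estimators (Queller–Goodnight and kin) need allele dosage,
which dominant bands hide. The package uses the centered band-sharing
correlation

    r_xy = Σ_l (x_l − p_l)(y_l − p_l) / Σ_l p_l(1 − p_l),

with p_l the sample band frequency. Properties: identical profiles at
p = 0.5 score +1, complementary profiles −1; because Σ_x (x_l − p_l) = 0
the off-diagonal entries sum to −Σ_x r_xx exactly, so the all-pairs mean
is ≈ −1/(n − 1) and random pairs are centered near zero — matching a
permutation null built around "relatedness 0". The estimator
deliberately measures *relative* similarity, not pedigree relatedness:
full sibs average ≈ 0.4 rather than 0.5 under dominance. It is pluggable
(`estimator=` hook) so a Lynch–Milligan-style dominant estimator can be
swapped in.

The per-web test: observed statistic = mean pairwise r within the web;
null = means of n_perm random groups of the same size drawn without
replacement from the whole sample; p_ge = (1 + #{null ≥ obs})/(n_perm + 1)
(the +1 keeps p > 0 and makes null p-values uniform on the achievable
grid); bootstrap CI resamples the web's pairs with replacement. Flags
follow the null CI: `higher` above the 97.5th percentile, `lower` below
the 2.5th. Band frequencies always come from the whole sample, never the
web, so small webs are not self-centered.

## Spatial autocorrelation

Squared genetic distance between individuals = number of mismatching
bands (the binary case of the standard multilocus distance). Gower
double-centering gives C with zero row sums; for distance class h,

    r_h = Σ_{x≠y ∈ h} c_xy / Σ_x w_x(h) c_xx,

with w_x(h) the number of partners of x in class h. Consequences used as
runtime assertions and tests: class numerators sum to −trace(C); a
single all-pairs class gives r = −1/(n − 1); a lone pair gives −1;
within-web clones with fully divergent webs give +1.

Distance classes are upper bounds in meters; a pair joins the first
class covering its distance. The first bound must be ≥ 1 m so same-web
pairs (distance 0) always form class 1. Empty classes are merged into
the next class (or raise, in strict mode) — correlograms with empty
classes are not meaningful. The last bound auto-extends to the maximum
observed distance.

Uncertainty: (i) per-class 95% bootstrap CI by resampling the class's
unordered pairs with replacement and recomputing r from the resampled
numerator/denominator contributions (1000 draws by default); (ii)
permutation null by shuffling genotypes across geographic positions
(equivalently, conjugating C by a random permutation while classes stay
fixed), 999 draws by default — the conventional count; the permutation
unit is the individual, matching a null of no spatial structure at the
individual level. Two significance summaries are reported: the
permutation test alone (r outside the null CI; calibrated at 5% type-I
error, which the calibration tests verify) and the conservative joint
rule (additionally the bootstrap CI entirely outside the null CI), used
for declaring a class biologically meaningful.

## Synthetic colonies

The generator emulates a transect survey: `n_webs` webs evenly spaced
along 1000 m (optional jitter), group sizes uniform on
[`group_size_min`, `group_size_max`] (default 4–12, bracketing typical
field group sizes), 200 loci by default with latent dominant-allele
frequencies Uniform(0.1, 0.9) — chosen to avoid quasi-invariant loci the
filter would discard. Genetics are latent diploid biallelic; the
observed band is the OR of the two alleles. Downstream analyses still
treat bands as haploid, mirroring how dominant data are analysed in
practice; the generator keeps the dominance information loss real.

Kinship/dispersal structure per web: two parents are drawn from the
global pool; each resident is a full sib (probability `sib_fraction`,
Mendelian segregation), otherwise a migrant (probability `migrant_rate`,
fresh global draw), otherwise a maternal half sib. Truth tables record
parents, so pairwise pedigree relatedness (0/0.25/0.5) is exact.
Defaults (`sib_fraction=0.25`, `migrant_rate=0.1`) describe a moderately
kin-structured population; calibration runs use (0, 1) for pure
panmixia and power runs (1, 0) for maximal structure.

The two-source generator isolates admixture signal: per-locus allele
frequencies of the two pools are pushed apart by `source_divergence`
(at 0.9, a central locus lands near 0.05 vs 0.95); webs alternate
between sources; per locus each individual draws an origin from its
ancestry vector and then a genotype from that source — so an admixed
individual's expected band frequency is the ancestry-weighted mean of
the source *band* frequencies (tested as a closed form).

What the generator does **not** emulate: scoring error and peak-calling
noise, linkage between fragments, continuous isolation-by-distance
within webs, overlapping generations, and mutation. Passing tests
therefore demonstrate correctness of the statistics and their
calibration under the stated model, not robustness to fingerprinting
artifacts — on real data the upstream repeatability filtering has to do
that job.

## Problem sizes and reproducibility

Simulation-based tests and the acceptance script use deliberately scaled
problem sizes chosen to exercise each property with comfortable
statistical margins: calibration at 20 webs × 5 × 300 loci with 199
permutations (100–200 replicates), autocorrelation power at 10 webs × 6
× 100 loci (20–50 replicates), delta-K recovery at ~45 individuals × 60
loci with K = 1–4 and 3 replicates per K, NMDS checks at n ≤ 60 with
tens of starts. Every random quantity flows from a single seed through
`numpy.random.SeedSequence` spawning; reruns with the same seed are
byte-identical, including the pipeline's `summary.json` (timing is
logged, not written).

## Known limitations

* The relatedness estimator is a similarity index, not an unbiased
  pedigree-relatedness estimator; compare groups against the permutation
  null, not against absolute pedigree values.
* NMDS stress values are comparable only at similar n; very small
  samples (n < ~30) can inflate stress.
* The admixture model assumes independent loci; tightly linked fragments
  would overstate confidence in Q.
* Delta-K cannot select K = 1 (the statistic is undefined at the ends of
  the scan); inspect mean lnP(X|K) directly when no structure is
  plausible.
* The permutation null for spatial autocorrelation permutes individuals
  by default; the web-level mode (`perm_unit="web"`, shuffling whole webs
  across web positions with co-membership intact) leaves the same-web
  class invariant, so it probes cross-web structure only.
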
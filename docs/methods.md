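# Methods

## Coordinate and model conventions

All genetic coordinates are cM, 0-based, with half-open ancestry segments
[start, end); conversions to Morgans divide by 100. A pulse admixture G
generations ago therefore draws mosaic piece lengths exponential with rate
G/100 per cM (rate G per Morgan). The default genetic map ships 22
autosomes with fixed published-style sex-averaged lengths (total ≈ 3500 cM)
and is fully configurable; SNP grids are attached per chromosome when
painting or call tables are needed.

A `PulseModel` is a proportion map plus a time t > 0; the first label plays
the role of source A with fraction q. A `TwoWaveModel` is (q, t1, mu, t2)
with 0 < t2 < t1: A and B merge at t1, then migrants from A replace a
fraction mu at t2. Times are generations before present; the first
post-admixture generation (during which sources do not yet recombine) is
neglected throughout, which is standard and immaterial for t ≳ 10.

## The ancestry-proportion distribution

Along a chromosome, ancestry under a pulse is a stationary two-state Markov
process: A-segments exponential with rate (1−q)t per Morgan, B-segments
with rate qt. The fraction x of a chromosome of length L Morgans in state
A then has atoms P(x=0) = (1−q)e^{−qh} and P(x=1) = q e^{−(1−q)h}, h = tL,
plus the continuous occupation-time density

    f_c(x) = q(1−q) h e^{−h[(1−q)x + q(1−x)]}
             { [qx + (1−q)(1−x)] I1(2hα)/α + 2 I0(2hα) },

with α = sqrt(q(1−q)x(1−x)). Printed statements of this density sometimes
drop the radical from α; the plain-product variant integrates to ~0 rather
than 1 (e.g. total mass 1.07e-4 at q=0.5, t=30, L=1) and is kept only
behind `alpha_variant="plain"` so the test suite can document the
resolution. With the radical, total mass is 1 and the mean is q to 1e-6
across the tested (q, t, L) grid, and the variance matches

    Var[x] = 2q(1−q)(e^{−h} + h − 1)/h²,

whose limits are q(1−q) as h→0 (single-segment chromosome) and
2q(1−q)/h as h→∞.

Numerics: Bessel terms are evaluated with exponentially scaled functions
(`scipy.special.ive`) and assembled in log space; the naive expression
overflows near h ≈ 700 (old admixture × long chromosomes). The α→0 limit
uses I1(z)/(z/2) → 1.

### Diploid convolution

Phase-switch errors make per-haplotype proportions unreliable in practice,
so the likelihood can operate on diploid proportions y = (x1+x2)/2 with
homologous chromosomes treated as independent. The diploid law has atoms
at {0, 1/2, 1} (products of the haploid atoms), boundary-attached
continuous components from atom × continuous pairs, and a continuous ×
continuous part computed by FFT convolution on a fixed grid (default 4001
points for y). Two quadrature details matter: trapezoid end-weights are
applied inside the convolution, and the grid point at y = 1/2 takes the
mean of the one-sided limits of the (discontinuous) atom-attached
components — together these keep the total-mass error below ~1e-5 at the
default grid across q ∈ [0.1, 0.9], h ∈ [0.1, 50]. The constructor
verifies normalization and refuses a grid that cannot meet its tolerance.

### Likelihood and MLE

Chromosomes are independent within and between individuals; an observation
within ε (default 1e-6) of an atom contributes the atom's probability,
anything else the continuous density. `fit_pulse` maximizes over a
Cartesian grid, by default q ∈ [0.05, 0.95] step 0.01 and integer
t ∈ [2, 100], with ties broken toward smaller t then smaller q.
`PulseDatingMLE` additionally supports fixing q at the sample mean
ancestry (`fix_q="mean"`), the usual choice when only the time is of
interest — the mean of the fitted distribution is q regardless, so this
costs essentially nothing and removes one grid dimension. During the grid
search the diploid normalization guard is relaxed to 1e-3: extreme grid
corners (e.g. q = 0.05 with h ≈ 300) carry ~1e-4 quadrature error, which
cannot move the argmax.

The per-chromosome SD statistic used for variance matching (weighted by
sqrt of chromosome length in cM) operates on diploid per-individual
fractions; the haploid alternative is available by constructing the
dataset haploid. Calibration-by-simulation takes any
`simulate_and_summarize(t, seed)` procedure, averages replicates per grid
time, and interpolates linearly when the statistic is monotone in t.
Bootstrap intervals resample individuals (the exchangeable unit) with
percentile endpoints, B = 1000 by default.

## Two-wave theory and historical bounds

Under (q, t1, mu, t2), B tracts are exponential with rate
r = q·t1 + (1−q)·mu·t2 and the B fraction is M = (1−q)(1−mu). Matching a
pulse's r = (1−M)T defines the pulse-equivalent time

    T (q + mu − q·mu) = t1 − (1−q)(t1 − mu·t2),

and `solve_early_time` inverts for t1 given (T, t2, q, mu). Because t1 is
affine in each argument, extremes over a parameter box sit at corners; the
grid scan (1-generation steps for times, 0.01 for proportions) is kept as
a cheap cross-check of the corner argument, filtering solutions violating
t1 > t2. The proportion-weighted average (q·t1 + mu·t2)/(q + mu) is
verified to stay within 15% of T over the default historical box.

One subtlety the tests make explicit: T is defined by *segment-length*
equivalence. The ancestry-proportion variance under two waves integrates a
two-locus autocovariance with both time scales,

    ∫C = [mu + (1−mu)q² − (1−M)²]/t2 + (1−mu)·q(1−q)/t1,

so the variance-matched pulse time can sit below T when the recent wave is
strong (e.g. q=0.5, t1=40, mu=0.2, t2=10 gives T=35 but a
variance-equivalent time ≈ 27). Tract-length dating recovers T exactly in
expectation; the proportion MLE recovers a single time bracketed by t2 and
t1 and closer to T than to either event — the identifiability point that a
two-wave history masquerades as one pulse — and agrees with T
quantitatively when the recent wave is mild. The full Laplace-transform
segment-length machinery for multi-wave models is intentionally out of
scope; only the closed forms for r, M, and the equivalence are
implemented.

The ancestry back-projection f_early = S_present/(1−mu) converts
present-day bounds on the dominant (Southern) European component into
bounds at the time of the early event; the lower present-day bound pairs
with the upper replacement bound (both reflect a maximal recent wave) and
vice versa.

## IBD ancestry deconvolution

Segments are trimmed 0.25 cM at each end (boundary misidentification)
before cM-weighted accumulation of the 3×3 diploid-state matrix, which is
symmetrized since pair order is arbitrary. A_rand(p) is the outer product
of the diploid state distribution [p², 2p(1−p), (1−p)²]; A_IBD(f, p) is
built from three independent chromosomes — the shared haplotype EU with
probability f, each other haplotype with probability p — and has
structurally zero (hom-EU, hom-ME) corners. λ is estimated from the
symmetrized observed corner against A_rand's; the empirical A_IBD is
(A_obs − (1−λ)A_rand)/λ with negative entries clamped (flagged, and the
fit marked unstable above 2% clamped mass), and f is the L1-closest
theoretical matrix over a 0.001-step grid (equal cell weights by default;
occupancy weights available). p_EU is always an input from upstream
genome-wide local ancestry, never re-estimated here. Length strata
([3,7], [3,4], >15 cM, …) reuse the identical computation through a filter
parameter. A diagnostic correlation between segment ME-ancestry share and
a quality covariate is reported but not acted on.

## Localization

LD thinning is a greedy left-to-right scan dropping any SNP with r² above
0.2 against a retained SNP within the window (the larger of 1 cM and the
last 250 retained SNPs); the thresholds are conventions, chosen where the
underlying procedure is known to have been used but its settings are not
recorded. Regional frequencies are smoothed with a 0.5 pseudocount
(Jeffreys-style) so log-likelihoods stay finite; panels are balanced by
down-sampling to the smallest region with the run seed. Classification of
a masked haploid chromosome sums log allele frequencies over masked-in
retained SNPs; ties are broken by the fixed region order and flagged.
Classified-chromosome proportions are exposed separately from
grid-matched ancestry proportions — the two quantities differ, and the
matching step (squared-distance minimization against simulated cohorts
run through the full simulate → degrade → classify pipeline) is the only
route from one to the other.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structural* features the estimators rely
on: exponential ancestry tracts with the correct rates, chromosome-level
proportion distributions (verified against the closed form), finite-N
genealogical noise (Wright–Fisher mode), intra-continental
allele-frequency divergence (Balding–Nichols with drift F, giving
pairwise Hudson F_ST ≈ F between equally drifted regions, and linkage
equilibrium within panels — acceptable because localization operates on
an LD-thinned set), block-structured local-ancestry errors calibrated to
a target per-SNP accuracy (default study condition ≈ 70% for EU/ME
admixture, with constant-label error blocks that also inflate apparent
segment lengths, as observed for real LAI), and IBD cohorts with
whole-segment ancestry labels (3–7 cM segments are much shorter than
typical tracts at t ≈ 30, so within-segment switches are negligible).

They do not emulate: real LD and haplotype structure within panels,
ascertainment of SNP arrays, phasing errors as a distinct process from
LAI noise, bottleneck genealogy beyond the WF mode, mutation, sex
chromosomes, or real recombination-map hotspots (maps are uniform unless
a real map is loaded). Passing tests therefore demonstrate correctness of
the estimators under their own model assumptions and robustness to the
emulated noise levels — not performance on any particular real dataset.

## Problem sizes and statistical test design

Simulation-backed tests use desk-scale sizes chosen to keep each check's
Monte-Carlo error well inside its tolerance: WF recovery uses N = 500
(1000 chromosomes) with 5 replicates per time point; two-wave agreement
uses replicate populations as the independent unit (runs within one
finite population share a genealogy, so run-level two-sample tests would
be anticonservative); IBD recovery uses 1e5 segments; localization uses
three chromosomes, 80 haplotypes per panel, and 80-chromosome cohorts.
Seeded statistical checks on multi-cell grids use 3σ bands so the
family-wise false-alarm rate stays near 1%; single checks use the 2 SE
bands stated with each property. Tract-length means are estimated
censoring-aware (runs cut by a chromosome end are right-censored
exponential observations; estimate = total run length / completed runs),
which removes the edge-truncation bias that a naive mean suffers on
chromosome-scale maps.

## Known limitations

- The proportion MLE assumes exchangeable, independent chromosomes; long
  IBD sharing within founder cohorts mildly violates independence and is
  not modelled in the likelihood.
- The two-wave bounds inherit whatever biases the inputs (T, q, mu, t2
  intervals) carry; the machinery only propagates them.
- The IBD deconvolution assumes segments coalesce near the bottleneck and
  that labelling error is ancestry-independent; the quality diagnostic
  reports but does not correct violations.
- The localizer's product-of-frequencies likelihood is only valid after
  LD thinning; applying it to unthinned data overstates confidence.
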
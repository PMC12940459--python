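# Methods

`radioplan` implements prescription-free inverse treatment planning: a
search over plan parameterizations that maximises the complication-free
tumor control probability

P₊ = P_B · (1 − P_I),

with P_B the product of the target volumes' tumor control probabilities
(TCP) and P_I the complement of the joint complication-free probability
over the organs at risk (OARs).  Instead of fixed dose prescriptions, the
clinician sets acceptable response levels (minimum/maximum TCP, maximum
NTCP) that confine the search to clinically meaningful plans.  This note
records the models, their assumptions, the numerical choices, and what
the synthetic test bed does and does not show.

## Dose-response models

**Tumor control.** The Poisson TCP model on a voxelised dose
distribution,

TCP = ∏ᵢ exp(−ρ vᵢ exp(−α·EQD0ᵢ)),

with clonogen density ρ (cells/cm³, homogeneous within each target
volume), linear radiosensitivity α (Gy⁻¹), and the linear-quadratic (LQ)
iso-effect EQD0ᵢ = Dᵢ(1 + (Dᵢ/N)/(α/β)) for N equal fractions.  The
product is a single exponential of a sum of expected surviving
clonogens, so it is evaluated in log space by construction and cannot
underflow voxel by voxel.

**Normal tissue complication.** The relative-seriality (Källman) model,

NTCP = [1 − ∏ᵢ (1 − P(Dᵢ)ˢ)^(vᵢ/V)]^(1/s),

with the per-voxel sigmoid P(Dᵢ) = exp(−exp(e·γ − (EQD2ᵢ/D₅₀)(e·γ −
ln ln 2))) and EQD2ᵢ = EQD0ᵢ/(1 + 2/(α/β)).  The 1/s exponent acts on the
whole bracket.  That bracketing is load-bearing: it is what makes uniform
whole-organ irradiation reduce NTCP exactly to the voxel response P for
*every* seriality s (so the closed-form uniform-dose inversion used for
the sampling bounds is exact), makes serial organs (large s) respond to
the hottest subvolume, and gives parallel organs (s → 0) strong
partial-volume protection.  Under the alternative reading that applies
1/s only to the product, a parallel organ such as small bowel (s = 0.14)
would approach 100% complication probability for any plan delivering
moderate dose to a fraction of its volume, which is inconsistent with
both the model's published behaviour and observed clinical plan
evaluations; we therefore implement the bracketed form.  Per-voxel
probabilities are clipped to [1e−300, 1 − 1e−16] before logarithms.

**Composites.** P_B = ∏ TCPᵢ over the targets, P_I = 1 − ∏ (1 − NTCPᵢ)
over the OARs (an empty OAR list gives P_I = 0), P₊ = P_B(1 − P_I).  A
differential DVH and a voxel list share one code path: a DVH is a dose
distribution whose "voxels" are bins.

**Inversions.** The iso-effective uniform dose for a TCP level is
D̄ = [ln(ρV) − ln(−ln TCP)] / [α(1 + 2/(α/β))] (EQD2); for an NTCP level
it inverts the voxel sigmoid, D̄ = D₅₀·[eγ − ln(−ln NTCP)]/[eγ − ln ln 2].
Both are exact inverses of the forward models for uniform irradiation
(property-tested).  Physical total dose for N fractions is recovered from
EQD2 by solving the LQ quadratic for its unique non-negative root.

**gEUD.** The generalized equivalent uniform dose is the volume-weighted
power mean (∑ (vᵢ/V) Dᵢᵃ)^(1/a).  With |a| = 40 (the planning objectives'
exponents) naive powers overflow at clinical dose levels; the sum is
rescaled by the maximum dose for a > 0 and the minimum for a < 0, making
every ratio power ≤ 1 in magnitude.  A cold voxel with a < 0 returns 0 by
convention (the power mean's limit).

## Radiobiological parameters

Shipped as versioned TSV fixtures: the primary TCP set (ρ = 2.8·10⁸
cells/cm³ and α = 0.1205 Gy⁻¹ at α/β = 1.6 Gy for the imaging-defined
boost volume, fitted densities 5.4·10⁵ and 1.2·10⁴ cells/cm³ for the
residual gland and the extracapsular margin), two sensitivity sets for
α/β = 1.2 and 2.7 Gy with refit α and densities, and the
relative-seriality NTCP quadruples (D₅₀, γ, α/β, s) for seven pelvic
OARs.  One published entry (sensitivity set 3, residual-gland density
0.5·10⁵ with CI [4.2·10⁵, 6.3·10⁵]) has a point value outside its own
confidence bracket; the fixture encodes it verbatim and flags the
anomaly in a comment rather than silently "repairing" it.

## Synthetic phantom and beamlet engine

The patient cohort's dose data are not redistributable, so the package
generates a seeded synthetic pelvic phantom: nested noise-perturbed
ellipsoids on a voxel grid (default 40×40×24 at 2.5 mm; a 20×20×12 at
5 mm "small" preset covers the same physical extent for fast runs).  The
boost volume is carved inside the gland, the residual gland is the set
difference, the extracapsular target is a 3 mm dilation shell, and seven
OARs are placed with pelvic topology (rectum posterior, bladder
superior-anterior, femoral heads lateral, small bowel superior, penile
bulb inferior, sigmoid colon superior-posterior).  Structures are
realized by taking the requested number of voxels nearest in a perturbed
ellipsoidal metric, so realized volumes match requests to within half a
voxel and all set invariants (nesting, disjointness) hold by
construction.  Requests are validated against the published cohort
ranges (prostate 23.59–60.26 cm³, boost fraction 3.67–39.14%); the
17-case cohort volume table itself ships as a fixture.

The dose engine is a linear beamlet model: equi-angular parallel beams
(default 8) in the axial plane, each a 2-D array of pencil beamlets
(default 10 mm) covering the targets plus margin, with exponential depth
attenuation (μ = 0.005 mm⁻¹, a water-equivalent effective attenuation
for megavoltage photons) and a Gaussian lateral profile (σ = 0.55 ×
width).  Kernels are normalized to unit peak, weights are Gy at the
beamlet peak.  Plan optimization minimises a priority-weighted one-sided
quadratic penalty on structure gEUDs plus a small quadratic smoothing
term on neighbouring beamlet weights (a stand-in for deliverability),
by projected gradient descent with Armijo backtracking from a
deterministic cold start; the penalty sequence is non-increasing by
construction and the optimizer returns its best iterate with a
convergence flag.  The engine is a pluggable contract — any callable
mapping gEUD objectives to per-structure dose can replace it.

Because this surrogate is convex-ish and deterministic, the outer search
is better behaved than it would be driving a clinical optimizer with
its own local optima; conclusions about *search* difficulty therefore do
not transfer to clinical engines, while conclusions about the
radiobiological objective algebra do.

## Prescription-free search

Thirteen gEUD objectives parameterize a plan: a lower and an upper
objective per target (a = −40/+40), one upper objective per OAR
(a = +40), each with a goal (Gy) and a priority in [0, 1000].  Goal
sampling ranges derive from the response levels (defaults: TCP between
85% and 99.99%, NTCP at most 10%): target ranges span the uniform
physical doses reproducing the two TCP levels (volume-dependent through
ln(ρV)), OAR ranges run from 0 Gy up to the dose giving the NTCP level.
Target goal pairs are sorted on decoding so the lower goal never exceeds
the upper.

The swarm uses the standard constricted global-best update (inertia
0.729, cognitive = social = 1.49445), 150 particles × 10 epochs by
default.  "Initial velocity attenuation 0.1" is read as scaling the
uniform initial velocity draw; "particle reset probability 0.001" as a
per-particle, per-epoch uniform position re-draw with zeroed velocity
and retained personal best.  Positions are clamped to the bounds with
the velocity zeroed on clamped coordinates.  Infeasible candidates
(any TCP below its minimum or NTCP above its maximum) receive fitness
P₊ − 1 − (total level violation), strictly below every feasible
candidate, so the swarm is steered back while the archive keeps the full
history.  Equal fitness keeps the earlier candidate.  A single master
seed derives named sub-streams (phantom, swarm, cohort), so runs are
bit-reproducible.

## Pareto analysis

Feasible plans are analysed in (P_I, 1 − P_B), both minimised.  The
front is the standard non-dominated subset (float ties at 1e−12;
coordinate duplicates kept once).  The published description of
non-domination literally requires a candidate to dominate all others —
a stricter condition that generally selects nothing; we treat that as a
typographical slip, implement standard non-domination, and keep the
literal predicate behind a flag for comparison.  The utopia (illusion)
point is the coordinatewise minimum.  The theoretical optimum on the
front interpolates piecewise-linearly between adjacent points (the
interpolation family was an open choice; linear is the least-assumption
option) and maximises (1 − x)(1 − y) per segment in closed form.  The
selected plan is the archive member with the highest P₊, which provably
lies on the front since P₊ improves with either coordinate.

## Parameter calibration

Densities for the two non-boost targets are calibrated so the
cohort-mean P_B under clinical-style dose distributions matches an
outcome-derived 99%.  One scalar target cannot identify two densities;
the residual TCP budget (target P_B divided by the boost volume's mean
TCP) is split evenly on the log scale between the two structures by
default, overridable by an explicit allocation.  Each density is then a
bracketing bisection in log₁₀ρ (TCP is strictly decreasing in ρ), and
every fit is validated by forward re-evaluation to 1e−4.  For the
sensitivity sets, α is refit first (bisection; TCP strictly increasing
in α) so the boost volume's cohort-mean TCP is 99.2%.  Confidence
intervals are percentile bootstrap over patient-level resamples (the
original CI method was unstated; patient resampling is the natural unit
here).  The cohort stand-in generates near-normal within-structure dose
spreads (boost 70 ± 1.5 Gy, gland 60 ± 2 Gy, margin 52 ± 4 Gy in 20
fractions) on the published per-case volumes — it emulates dose
heterogeneity and volume variation, not spatial correlation, so recovery
tests certify the calibration machinery, not clinical parameter values.

## Evaluation

DVHs bin voxel doses at 0.05 Gy by default; cumulative curves are
non-increasing and conserve volume to 1e−9.  D_x% uses linear
interpolation on the cumulative curve with x as relative volume
(ICRU-style reporting); the homogeneity index is (D2% − D98%)/D50%.
Protocol constraints ship on both the 20-fraction physical and the EQD2
dose scale; EQD2-domain checking converts the DVH dose axis through the
LQ transform.  The published rectum EQD2 column does not follow the
per-fraction conversion applied to the other OARs; it is encoded
verbatim with a provenance comment.

The gamma index uses global normalization to the reference maximum
(3% dose / 2 mm distance-to-agreement / 10% low-dose threshold / 95%
pass by default), evaluating each point of the evaluated grid against
the tri-linearly interpolated reference on a 0.4 mm sub-voxel offset
grid capped at 3 × DTA, with offsets sorted by distance for an exact
early exit.  The search equals exhaustive brute force (property-tested).

## Problem sizes and determinism

The bundled desk-scale configuration uses the 5 mm phantom preset
(≈1 300 structure voxels, ≈400 beamlets), engine budget 120 iterations,
and a 20-particle × 5-epoch swarm (100 plan evaluations, ≈15–20 s per
run).  At this scale the best-found P₊ varies by ~0.01–0.04 across
seeds because the P₊ ridge is flat: near the optimum, several Gy of
target-dose movement changes P₊ by less than 0.005, a property of the
saturating dose-response models rather than of the search.  A practical
consequence for the scaled-down sensitivity comparison (γ between the
selected plans of two runs with different TCP parameter sets): plans
that are equivalent in P₊ need not be equivalent in dose at a 3%/2 mm
γ tolerance, so the selected-plan γ at this search budget is dominated
by which of several near-optimal plans the swarm happens to find — two
runs with the *same* parameter set and different seeds show comparable
or larger γ disagreement than runs with different parameter sets and a
shared seed.  The comparison therefore supports parameter insensitivity
(the parameter-set effect is below the search-noise floor) while the
γ pass rate itself only approaches the full-scale equivalence reading
as the swarm budget grows well beyond desk scale.

## Known limitations

No setup margins, organ motion or setup-error modelling; homogeneous
radiobiological parameters within each structure; a water-equivalent
analytic dose kernel with no heterogeneity corrections or deliverability
constraints beyond weight smoothing; LQ validity assumed at the boost
fraction doses; Pareto analysis restricted to two objectives.  Passing
the synthetic-phantom tests demonstrates the correctness of the
response algebra, the search mechanics and the reproducibility contract
— not clinical plan quality on patient anatomy.
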
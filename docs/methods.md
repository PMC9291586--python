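# Methods

## Model structure

The simulator tracks an infinite, randomly mating diploid population with
discrete non-overlapping generations. Its state is the pair of haplotype
(gamete-type) frequency vectors transmitted by each sex: the egg pool
(maternal copies of the next generation) and the sperm pool (paternal
copies). Keeping the pools separate preserves parent-of-origin information,
which matters twice: the ancestral Y is strictly paternal, and turnover is
classified from parent-of-origin frequencies.

The genome has seven biallelic loci on four independently assorting linkage
groups:

| group | loci               | focal alleles  | recombination |
|-------|--------------------|----------------|---------------|
| XY    | SD + SA            | Y, SA^Y        | r_XY          |
| I^A   | SD + SA            | A, SA^A        | r_A           |
| II^W  | SD + SA            | W, SA^W        | r_W           |
| EPI   | single locus       | EPI            | —             |

A gamete type is an integer in [0, 127]; bit i (least-significant first)
holds the allele at locus i in the order XY.SD, XY.SA, IA.SD, IA.SA,
IIW.SD, IIW.SA, EPI. This bijection is part of the file format: trajectory
and sweep outputs are comparable across runs and machines.

Sex: W present → female; else Y or A present → male; else female. W/W is
unreachable in valid dynamics (W-bearing zygotes are female, and females do
not sire offspring, so W never enters the sperm pool after the introduction
generation) but classifies female if constructed directly.

One generation is: (i) zygote genotype frequencies as the outer product of
the two pools; (ii) sex assignment; (iii) viability selection *within each
sex* — fitness-weighted and renormalized per sex, so each sex contributes
exactly half of the next generation's gene pool regardless of the
post-selection sex ratio (the standard two-sex recursion; the model has no
sex-ratio selection beyond what the SD alleles themselves create through
genotype frequencies); (iv) gametogenesis: within a two-locus group the
parental haplotypes receive mass (1−r)/2 each and the recombinants r/2
each; groups assort independently.

## Fitness

Per SA locus, genotype fitness is 1 (no focal copy), 1 + h_sex·s_sex (one
copy), 1 + s_sex (two copies). Active loci are sexually antagonistic
(sM·sF < 0); throughout the sweep machinery sF = −sM. Defaults: hM = 0.6,
hF = 0.4 for SA^Y and SA^A (male-beneficial alleles partially dominant in
males), mirrored to hM = 0.4, hF = 0.6 for the female-beneficial SA^W.
Total fitness is multiplicative over the three SA loci; males are further
multiplied by w_EPI = 1 + σ·ε. The binary interaction indicator σ over
(EPI copies, partner-SA copies) is, by interaction type:

* dominance — σ = 1 iff both loci carry at least one focal copy
  (directional selection on both);
* overdominance — σ = 1 only in double heterozygotes (stabilizing);
* coadaptation — σ = 1 only in the two matched double homozygotes
  (+/+;+/+ and focal/focal;focal/focal — disruptive).

Epistasis is male-limited by assumption; no female hook exists.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| s_Y, s_new | SA selection coefficients (dimensionless) | sampled U(0, 0.05) | sF = −sM |
| hM, hF | dominance per sex | 0.6/0.4 (0.4/0.6 for SA^W) | fixed |
| ε | epistasis effect size | sampled U(0, 0.05) | ≥ 0 |
| r_XY, r_A, r_W | SD–SA recombination per group | 0.01 | see below |
| intro_freq | introduction frequency of A/W | 10⁻⁴ | across all genotypes |
| burn_in / total | run lengths (generations) | 10,000 / 200,000 | desk profile: 2,000 / 20,000 |
| initial SA/EPI frequency | segregating loci at start | 0.25 | linkage equilibrium |

Recombination defaults: the SA-driven turnover mechanism requires tight
SD–SA linkage to build the co-adapted haplotype, so the default is
r = 0.01 for all three groups; all three rates are independently
configurable and recorded in run metadata. Selection coefficients with
s ≤ −1 (non-positive homozygote fitness) are rejected at construction.

## Scenario protocol

1. Build the ancestral XY population: zygotes 50% Y/+ males (Y strictly
   paternal) and 50% +/+ females; the two scenario-relevant SA loci and EPI
   at frequency 0.25 in both pools, independent across loci. The SA locus of
   the non-segregating third group is inert (s = 0, frequency 0), since the
   sweep samples and reports only the two relevant coefficients.
2. Burn in (default 10,000 generations) so SA/EPI frequencies approach
   their equilibrium under the sampled coefficients; the equilibrium is
   whatever the dynamics reach, not an analytic fixed point.
3. Introduce the novel SD allele by moving a fraction 10⁻⁴ of every
   +-carrying gamete type's mass to its focal counterpart, in both pools
   (mutation across all genotypes; for W the sperm-pool mass is purged by
   the dynamics in one generation).
4. Run to the horizon (default 200,000 generations total).
5. Classify: Y→A reads the frequency of A among paternally inherited copies
   of males, Y→W the frequency of W among maternally inherited copies of
   females; outcome 1 (turnover) iff the read is ≥ 0.5. The within-sex read
   is the default because complete turnover drives it to exactly 1 (a
   pool-wide W read plateaus at 0.5); `read_mode="pool"` exposes the
   alternative. The tie at exactly 0.5 → turnover is an arbitrary,
   documented choice never observed in practice.

The recursion is deterministic, so a scenario specification maps to exactly
one outcome; sweep randomness lives only in parameter sampling, with
per-replicate streams spawned from the master seed by replicate index
(reproducible and independent of execution order or worker count).

## Numerical policy

Pools are renormalized every generation; pre-normalization deviations
beyond 10⁻⁹ are logged. Frequencies are clipped at zero (rounding-level
negatives only). Dynamics are restricted to the scenario's reachable
gamete subspace (32 of 128 types per transition; 16 during burn-in) — the
subspace is bit-closed under recombination, and a regression test checks
equality with the dense 128-type computation to 10⁻¹². An optional early
stop (L∞ pool change < 10⁻¹³ for 100 consecutive generations) exists but is
disabled by default so run lengths are exactly as configured.

## Boundary estimation

The scientific object is the location of the 0.5-probability turnover
boundary in (s_Y, s_new), optionally resolved along ε. Binary outcomes are
smoothed with a local-linear kernel estimator (Gaussian product kernel;
default bandwidth (range)·n^(−1/4) per axis with n the number of distinct
sampled points): at each grid point a weighted least-squares plane is fit
and its intercept is the probability estimate. The local-linear form
removes the first-order edge bias a plain kernel average shows at the
borders of the sampled range. Exact duplicate rows are aggregated into
integer weights first, which makes the estimate exactly invariant to
replicating the table. Boundaries are extracted per s_Y grid column as
linearly interpolated 0.5-crossings; several crossings per column are
reported as separate branches, which is how non-monotone boundaries (seen
under coadaptation epistasis) appear. ε-resolved fits are per-slice
evaluations of a single three-dimensional smooth rather than per-type
pooled regressions; fits are per (scenario, epistasis-type) table by
design, since mixing types would smooth across qualitatively different
regimes.

## What the tests do and do not show

The test suite verifies the model's exact invariants (sex map, σ matrices,
Mendelian cross ratios, neutral conservation, (1−r) linkage-disequilibrium
decay in closed-form settings, ε = 0 equivalence of the epistasis types)
and cross-checks the deterministic recursion against an independently
implemented finite-population Wright–Fisher simulator (N = 10⁵, multinomial
sampling) within accumulated binomial error. Grid-based checks of the
epistasis effect on turnover use a desk-scale profile (burn-in 2,000, total
20,000 generations) and a 6×6 coefficient grid — large enough for the
qualitative geometry (the maintenance region grows under ancestral-linked
dominance epistasis; the minimal invading s_new is non-decreasing in ε) but
not a substitute for full-length boundary mapping: boundary positions at
the desk profile can differ from the full profile wherever invasion is so
slow that 18,000 post-introduction generations do not complete it.

All simulated data come from this model itself; nothing here emulates
empirical noise sources (genotyping error, finite samples, demography), so
passing tests certify the implementation, not the biology of any real
species.

## Known limitations

* No drift in the main engine (infinite population); the Wright–Fisher
  simulator lives in the test suite only.
* One-time introduction of a single novel SD allele; no recurrent mutation,
  no simultaneous A and W invasion, no reversals (W→Y).
* Epistasis is male-limited and binary (σ ∈ {0,1}); hemizygous-Y variants
  of coadaptation are not modelled.
* Two alleles per locus, one EPI locus, at most the four canonical
  transition × partner scenarios.
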
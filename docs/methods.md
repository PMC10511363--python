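# Methods

This note records the models, conventions and design choices behind
`cismr`, in the spirit of the model documentation shipped with simulation
and statistics packages: what is computed, under which assumptions, which
knobs matter, and what the synthetic validation does and does not show.

## Data model and conventions

Summary statistics are per-variant association records (effect/other
allele, effect-allele frequency, beta, SE, p, N). Coordinates are 1-based
inclusive; every window below is a closed interval. Chromosome labels are
strings without a `chr` prefix. Only biallelic SNPs are kept: indels are
dropped at load and counted, a deliberate simplification — frameshift
variants such as those at ABO would need allele-aware LD handling that the
clumping and harmonization logic here does not attempt. Effects on
case/control traits are log-odds per effect allele; quantitative effects
are per unit of trait.

LD enters as a user-supplied signed correlation matrix over an ordered
variant list. Matrices are validated (symmetry repaired below 1e-8
asymmetry, |r| ≤ 1, unit diagonal) and indexed by (chrom, pos) since r²
does not depend on allele orientation.

## Locus selection

Outcome loci are selected greedily: the smallest-p genome-wide-significant
variant (p ≤ 5×10⁻⁸) leads a locus; significant variants within 500 kb on
the same chromosome are absorbed; repeat. Ties break to the smaller
position, so the output is a pure function of the data. Greedy min-p is
the standard convention when a merging algorithm is not otherwise
specified; the half-window and threshold are config values. Exclusion of
high-LD regions (MHC by default, chr6:28,510,120–33,480,577 GRCh38) tests
the *lead* position; a window-overlap mode exists behind a flag because
the two rules differ for loci led from just outside the region.

## Instruments

The candidate pool for a gene:locus pair is the intersection of two
closed ±500 kb filters — around the transcription start site (the cis
definition) and around the locus lead (keeping instruments in the part of
the cis window that can speak to the outcome signal). Both filters
commute, so order is irrelevant. Exposure significance defaults to
5×10⁻⁸; there is no universally agreed threshold for cis-instrument
selection, so it is a config value echoed into the run report.

Clumping is greedy by ascending p (ties by position): a candidate is
accepted iff r² < 0.001 with every accepted variant within 10 Mb. These
defaults are the conventional "default settings" of the widely used
clumping tools. Variants absent from the LD matrix are dropped rather
than assumed independent — the conservative choice. When no LD matrix is
available at the pipeline level, only the top variant survives, since no
independence claim can be made.

Harmonization aligns outcome records to exposure allele orientation:
label-identical (unchanged), swapped (outcome beta negated, EAF
mirrored), reverse-complement with or without swap (strand flip first).
Palindromic A/T and C/G pairs carry no strand information in their
labels; they are oriented by frequency only when *both* studies' EAFs lie
outside [0.42, 0.58] (the ambiguity limit of the common harmonization
default) and are otherwise dropped. All actions and drops are audited.
The simulator applies random label swaps and strand flips as stressors;
harmonization recovers the unstressed effects bit-exactly for every
non-palindromic variant, which is tested.

## MR estimators

Dispatch follows the instrument count: one → Wald ratio; two → IVW; three
or more → IVW plus the sensitivity battery. Numerical conventions:

* Ratio SEs use the first-order delta method σ_Y/|β_X|; the second-order
  term is available behind a flag on the Wald ratio.
* IVW weights are 1/σ²_Y; the SE carries a multiplicative random-effects
  scaling max(1, √(Q/(k−1))) — never below the fixed-effect SE. IVW
  p-values are normal.
* Egger orients pairs to β_X ≥ 0 before fitting (the convention under
  which the InSIDE assumption is stated), scales SEs by
  max(1, √(Q/(k−2))), and uses t distributions on k−2 degrees of freedom
  for slope and intercept — with few instruments the normal reference is
  visibly anticonservative for the intercept test.
* Weighted median interpolates the ratio at cumulative standardized
  weight 0.5. The penalized variant multiplies weights by
  min(1, 20·P(χ²₁ > Q_i)) where Q_i = w_i(r_i − θ̂_IVW)² is instrument
  i's heterogeneity contribution; penalization is referenced to the IVW
  consensus. Weighted mode maximizes a normal-kernel weighted density
  with bandwidth 0.9·min(sd, IQR/1.34)·k^(−1/5) (times a bandwidth
  factor φ, default 1) on a 512-point grid over the ratio range ±3h;
  identical ratios (zero bandwidth) return that ratio.
* Median and mode SEs come from a parametric bootstrap (5,000 draws by
  default, seeded from the run config) over the normal sampling
  distributions of both β_X and β_Y.
* Steiger sums per-instrument variance explained — t²/(t²+n−2) for
  quantitative traits, z²/(z²+n) on the observed scale for case/control —
  and calls the direction forward when the exposure sum is strictly
  larger (ties are backward, the conservative convention). Its p-value
  compares Fisher-transformed √(Σr²) values with
  SE = √(1/(n_exp−3)+1/(n_out−3)).

The sensitivity gate is: Egger intercept p ≥ 0.05 (when computed), every
computed battery estimate sharing the primary estimate's sign, and
Steiger forward. Published analyses declare battery failures without
always stating the combining rule; sign consistency is this package's
operationalization, and every component flag is reported so users can
re-gate. BH-FDR (via `statsmodels`) pools all combinations of one
exposure dataset — across states, genes and outcomes — matching the
convention of reporting one family per dataset; per-outcome families are
a switch away.

## Colocalization

Per-variant Wakefield log approximate Bayes factors,
labf = ½log(V/(V+W)) + ½z²·W/(V+W), feed a configuration enumeration:
H0 mass 1, H1 = p1·Σᵢ BF1ᵢ, H2 = p2·Σⱼ BF2ⱼ, H3 = p1·p2·Σ_{i≠j} BF1ᵢBF2ⱼ,
H4 = p12·Σᵢ BF1ᵢBF2ᵢ, all in log space (safe past |labf| = 700).
Priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. The prior effect SD √W is
0.2 on the log-odds scale for case/control traits and 0.15·sdY for
quantitative traits, following the defaults of the established
approximate-Bayes-factor colocalization method; sdY is estimated by
regressing 2·n·maf·(1−maf) on 1/var(β̂) through the origin when not
supplied. Both SDs are per-study config values.

The engine itself accepts any m ≥ 1 so it can be unit-tested against a
brute-force oracle; the ≥ 50-variant requirement is enforced at the
pipeline layer, where colocalization runs on the *full* shared locus
window (clumped instrument sets could never reach 50 variants).

Prior sensitivity rescans PP_H4 over p12 ∈ [10⁻⁸, 10⁻⁴] (50 log-spaced
points, ABFs computed once). A result is flagged *robust* when PP_H4
stays ≥ 0.8 down to p12 = 10⁻⁶ — ten-fold more skeptical than the
default prior. This robustness rule, and the secondary-peak diagnostic
below, are this package's concrete operationalizations of checks that
are usually described only qualitatively; all constants are config
values.

The single-causal-variant diagnostic iteratively peels association peaks:
smallest-p variant (first peak must reach 5×10⁻⁸, later peaks 10⁻⁶),
masking everything within 250 kb or with r² ≥ 0.01 when LD is supplied.
Two or more peaks in either study's window flag a violation.

## The synthetic-data generator

Summary statistics are drawn directly from their asymptotic sampling
distribution: with AR(1) LD R (ρ = 0.9 by default, variants every 5 kb),
sparse per-allele causal vector b, and SE vector S from the standard
large-sample formulas (quantitative: sdY/√(2n·maf(1−maf)); case/control:
1/√(2n·φ(1−φ)·maf(1−maf)), case fraction φ = 0.5 by default), observed
effects are MVN(R·b, S·R·S). This is exact to first order and orders of
magnitude faster than individual-level simulation; one genotype-level
test validates the marginal-effect construction against per-variant
regressions on 50,000 explicit genotypes.

Default study conditions mirror the data regimes the pipeline targets:
case/control outcome GWAS with n = 50,000 and per-allele log-OR ≈ 0.1–0.15
at causal variants (z ≈ 6–12, comparable to lead signals in large
COVID-19 or biobank GWAS), and quantitative eQTLs with each causal
variant explaining 1% of expression variance. The eQTL sample size
defaults to n = 10,000 — larger than typical single-cell eQTL cohorts
(~10²) — because the generator's role is to test the inference machinery
under identified conditions; underpowered-exposure regimes can be
simulated by lowering `n_exp`. Exposure and outcome noise are
independent (the two-sample design); a shared-noise correlation knob
exists for sample-overlap experiments but is off by default.

Causal architectures follow the colocalization hypothesis vocabulary: H0
(none), H1/H2 (one study), H3 (distinct causal variants placed so their
AR(1) correlation ≈ 0.5), H4 (shared). MR scenarios set b_out = θ·b_exp,
optionally plus a pleiotropy vector (balanced: ±U(0, s) with random
signs; directional: U(0, s); s = 0.08 per allele by default); reverse
causation swaps the roles. Mixture datasets place genes on rotating
chromosomes 50 Mb apart so windows never interact, and record a truth
table.

What the simulator does *not* emulate: real haplotype structure (AR(1)
is smooth; real LD is blocky with long-range exceptions like the MHC),
allele-frequency-dependent architecture, winner's curse from discovery
filtering, population stratification, imputation noise, overlapping
samples (by default), or indels. Passing tests therefore demonstrate
that the machinery is correct and calibrated under its stated model, not
that any particular real-data finding is right.

## Validation experiments and problem sizes

The benchmark suite (also rerun by `scripts/acceptance.py`) uses sizes
chosen to give tight Monte Carlo error while staying fast on one CPU:
500 replicates for IVW recovery (bias and coverage), 200 each for Egger
calibration, Steiger directionality and the H4/H3 colocalization
calibration (m = 200 variants per window), 100 windows per arm for the
peak diagnostic, and 100 genes for the end-to-end mixture
(60% H0 / 30% H3 / 10% H4). In the mixture, H3 genes become genuine
MR hits (their top eQTL carries an LD-induced outcome association) that
then fail colocalization — the mechanism by which MR-identified
transcripts under LD confounding rarely colocalize — and the pipeline's
colocalized share of MR hits is compared with the truth-table H4 share
within binomial error.

## Known limitations

* SNP-only; no proxy-variant lookup for instruments missing in the
  outcome; no multi-allelic handling.
* Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition); the per-variant H4 posterior is reported but no
  credible-set machinery beyond it.
* No MR-PRESSO, multivariable MR, winner's-curse or sample-overlap
  correction.
* The sensitivity gate's sign-consistency rule is deliberately lenient
  with noisy battery estimates near zero; users wanting
  nominal-significance requirements can re-gate from the reported flags.
* Exact numerical parity with any specific external MR/colocalization
  implementation is not claimed; conventions (random-effects floor,
  t vs normal references, penalization reference point) are documented
  above and validated against this package's own oracles.
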
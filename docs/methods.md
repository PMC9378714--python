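# Methods

This note documents the statistical machinery behind `colocscreen`: the
models, the defaults and the reasoning behind design choices that were
genuinely open.

## Colocalisation model

The engine asks, for a genomic region shared by two traits, which of five
hypotheses the summary statistics support: no causal variant for either trait
(H0), a causal variant for trait 1 only (H1) or trait 2 only (H2), distinct
causal variants for each (H3), or a single shared causal variant (H4).  It
assumes **at most one causal variant per trait per region** — the classic
single-signal assumption — and works entirely from marginal effect estimates
and standard errors.

Per-variant evidence is the Wakefield asymptotic Bayes factor.  For variant
*j* with estimate β̂ⱼ, standard error sⱼ, V = sⱼ², prior effect variance W and
shrinkage r = W/(V+W):

    log ABFⱼ = ½ log(1 − r) + (β̂ⱼ/sⱼ)² r/2.

A point-mass prior (W = 0) gives log ABF = 0 — no evidence either way — and
the unit test verifies the closed form against numerical integration of the
marginal-likelihood ratio.

Hypothesis weights combine sums of Bayes factors with per-variant prior
probabilities p₁, p₂ (trait-specific causality) and p₁₂ (shared causality):
L₀ = 1, L₁ = p₁·S₁, L₂ = p₂·S₂, L₃ = p₁p₂·(S₁S₂ − S₁₂), L₄ = p₁₂·S₁₂ with
S₁ = Σⱼb₁ⱼ, S₂ = Σⱼb₂ⱼ, S₁₂ = Σⱼb₁ⱼb₂ⱼ.  All sums use log-sum-exp; L₃ is a
difference of exponentials computed in the log domain and clamped to zero
(with a warning) if cancellation drives it negative.  The per-variant
posterior of being the shared variant given H4 is b₁ⱼb₂ⱼ/S₁₂.  The
implementation is tested to 1e-10 against brute-force enumeration of all
(Q+1)² causal-configuration pairs.

### Parameters

| parameter | default | meaning |
|---|---|---|
| p₁, p₂ | 1e-4 | prior probability a given variant is causal for one trait |
| p₁₂ | 1e-5 | prior probability a given variant is causal for both |
| W^½ (quantitative) | 0.15 | effect-size prior s.d. in phenotype s.d. units |
| W^½ (binary) | 0.2 | effect-size prior s.d. on the log-odds scale |
| window | ±500 kb | region around the protein-coding gene |
| pp_min | 0.8 | PP(H4) threshold for candidacy |
| r2_min | 0.8 | LD-guard threshold (strict >) |

The prior s.d. values are the conventional defaults of this model family.
Robustness to the association priors is assessed over a 3×3×3 grid
(p₁, p₂ ∈ {1e-4, 1e-5, 1e-6}; p₁₂ ∈ {1e-5, 5e-6, 1e-6}); combinations with
p₁₂ > min(p₁, p₂) are incoherent and skipped (17 of 27 points survive), and a
result is "robust" when PP(H4) clears `pp_min` at every retained point.
PP(H4) is provably non-decreasing in p₁₂ at fixed p₁, p₂, which the suite
checks across the grid.

### LD guards

Because a single mis-specified region can produce a confident but wrong H4,
two guards bracket every candidate:

1. **Instrument representation** — the lead cis-pQTL, or a proxy at
   r² > 0.8, must survive into the harmonised shared variant set.  A lead
   missing from the LD panel fails the guard (conservative).
2. **Sentinel concordance** — each trait's regional sentinel (smallest p,
   ties broken by larger |z| then lower position) must be in LD at r² > 0.8
   with the other's.  This rejects regions where two nearby but distinct
   signals masquerade as colocalisation; the cost is that noise can
   occasionally push a true pair's sentinel onto a weaker proxy and drop it.
   The screen accepts that trade deliberately: false positives are filtered
   at the price of a small loss of true candidates.

All r² thresholds are strict (> not ≥) throughout.

## Harmonisation and filtering

Coordinates are 1-based, windows inclusive on both ends.  Tables are
intersected on variant id; swapped allele pairs flip the second table's sign
and EAF; anything else is dropped.  No strand rescue is attempted — both
dialects this package was built around are forward-strand, and a silent
strand error is worse than a dropped variant.  Strand-ambiguous A/T and C/G
variants are dropped when the minor-allele frequency falls in 0.40–0.50
(configurable; applied only when both tables carry EAF).  Records reported by
fewer than 80% of contributing studies are dropped where a coverage column
exists; missing coverage means single-cohort data and is treated as full.

Approximate conditional adjustment for a set S of independent lead signals
operates on the standardised scale, z' = z − R·,ₛ Rₛₛ⁻¹ zₛ, with standard
errors held fixed (a first-order approximation) and the leads themselves set
to z' = 0.  The lead submatrix must be well-conditioned (condition number
below 1e8 by default); collinear leads are a hard error naming the culprits.
The adjustment is tested to 1e-8 against explicit OLS residualisation on
constructed genotypes whose sample correlation equals R exactly.

## Multi-trait colocalisation

The hypothesis space is deliberately simplified: a region is either null,
associated with exactly one trait, or all m traits share one variant.  With
per-variant Bayes factors b_tj,

    L_null = 1,  L_t = p_single·Σⱼ b_tj,  L_share = p_shared·Σⱼ Πₜ b_tj,

and pp_shared = L_share/(L_null + Σₜ Lₜ + L_share).  At m = 2 this equals the
pairwise posterior with the H3 term removed (verified algebraically in the
suite).  Defaults p_single = 1e-4, p_shared = 1e-5 match the pairwise priors.

Two reported quantities extend this weight set:

- **regional_prob** (probability that *every* trait has some signal) adds an
  independent-signals configuration with weight Πₜ p_single·Σⱼ b_tj, and
  reports the mass of {shared, independent} in that extended set.
- **coherence_pp**, used for all clustering *decisions*: the plain shared
  posterior competes only against the null and single-trait hypotheses, so
  when three traits carry strong joint evidence the all-share weight
  dominates even if a fourth member does not fit the shared variant at all.
  For each trait t the decision criterion therefore adds an
  "all-but-t share, t associated elsewhere" configuration with weight
  p_shared·Σⱼ Π_{s≠t} b_sj · p_single·Σⱼ b_tj.  A trait set is coherent only
  when full sharing also beats every leave-one-out alternative.

Cluster discovery is greedy and divisive: start from all traits; while the
coherent posterior is below τ (default 0.8) and more than two traits remain,
drop the trait whose exclusion maximises the remainder's coherence; emit a
surviving set as a cluster (reporting the plain shared posterior of its
members, the candidate variant, and the share of posterior mass it carries);
recurse on the removed traits.  The procedure is deterministic given input
order; full configuration enumeration is available as a test oracle for ≤3
traits.  This is an approximation to partition-based multi-trait methods:
it cannot represent two simultaneous clusters *within* one candidate set in a
single weight computation and relies on the recursion to find them.

## Fine-mapping and prior transfer

Under exactly one causal variant, PIPⱼ = priorⱼ·BFⱼ / Σₖ priorₖ·BFₖ.  The
stepwise two-ancestry procedure fine-maps the better-powered ancestry with
equal priors, then uses those PIPs — floored and renormalised,
priorⱼ ∝ PIPⱼ + 1/(10·Q) — as priors for the second ancestry.  The floor
keeps every variant's posterior support positive so stage 2 can rescue
variants stage 1 missed; pure PIP priors would zero them irreversibly.  The
payoff comes when ancestry 2 has shorter LD blocks: stage 1 narrows the
candidate set to one long block, stage 2 discriminates within it.  The model
is single-signal only; regions with secondary signals should first be reduced
with `conditional_adjust`.

## Mendelian randomisation

The Wald ratio β̂_out/β̂_exp estimates the causal effect of a 1 s.d. increase
in exposure (log-odds scale for binary outcomes), with first-order standard
error |s_out/β̂_exp| — exposure uncertainty is ignored.  This choice, rather
than a second-order correction, matches the error propagation that published
single-instrument analyses of this kind use, and is accurate for strong
instruments; coverage of the 95% CI is verified at 93–97% over 1,000
simulations.  Instruments with |β̂_exp/s_exp| < 4 are flagged weak but never
silently dropped — a screen must report.

## Tier classification

Candidates passing PP(H4) and both guards are tiered on regional minimum
p-values among shared variants: tier 1 — p < 5e-8 in both traits; tier 2 —
in exactly one; tier 3 — both within (5e-8, 1e-4).  All inequalities are
strict; a pair with one suggestive and one non-suggestive p matches no rule
and is returned as unclassified (the screen logs and skips it).

## Synthetic data

The generator emulates the statistical structure the colocalisation model
assumes, not population-genetic realism.

**Panels.** Haplotypes follow a first-order Markov copying process: within a
block of `block_len` variants each haplotype copies its previous allele with
probability ρ, otherwise redraws at that variant's frequency (uniform in
`maf_range`); blocks are independent.  Adjacent within-block dosage
correlation is ≈ ρ and decays geometrically, and realised frequencies stay
inside the requested range.  Haplotypes are paired into diploid dosages.

**Summary statistics.** Marginal z-scores are drawn directly at the
summary level: z ~ MVN(√n_eff·Rλ, R) with R the panel LD matrix and λ the
standardised joint-effect vector (λⱼ = ±√(variance explained)); then
β̂ = z·se with se = 1/√n_eff.  For quantitative traits n_eff = n; for binary
traits with case fraction φ, n_eff = n·φ(1−φ) (the usual log-odds effective
sample size).  Simulating at the z level rather than via individual-level
regression is exact under the model and orders of magnitude faster; an
individual-level path exists only as a test oracle at small n.  If the
empirical R fails a Cholesky factorisation it is repaired to the nearest
positive semi-definite correlation matrix with a logged note.

**What this does not emulate** — and hence what passing tests do not show
about real data: coalescent LD (haplotype blocks here are rectangular and
exchangeable), allele-frequency spectra, imputation quality and its
correlation with MAF, sample overlap between traits, population
stratification, and multi-signal regions.  Scenario recovery rates on this
generator are best-case figures for the model's own assumptions.

**Default study conditions.** GWAS size n = 10,000 per trait, per-variant
variance explained 1% (causal |z| ≈ 10 at n = 10,000), binary case fraction
0.5, two-ancestry comparisons at n₁ = 10,000 vs n₂ = 2,000 with ancestry-2
blocks 4× shorter.  Regional problem sizes in the validation suite are
60–250 variants with panels of 600–3,000 haplotypes — large enough for
stable LD estimates while keeping the full suite fast.

## Numerical choices

- All Bayes-factor and posterior arithmetic in the natural-log domain via
  `scipy.special.logsumexp`; simulated p-values clipped to [1e-300, 1].
- Sentinel ties: smaller p, then larger |z|, then lower position.
- Pairwise-complete LD estimation; variants with > 10% missing dosages are
  rejected, zero-variance variants excluded with a warning.
- Generators are pure functions of (parameters, seed); per-trait streams are
  split from one `SeedSequence` and recorded in the truth manifest.

## Known limitations

- Single causal variant per trait per region everywhere (no SuSiE-style
  multi-signal colocalisation, no multi-causal fine-mapping configurations).
- No strand rescue and no INDELs in harmonisation; no liftover.
- The multi-trait hypothesis space is a simplification (see above); its
  posteriors are comparable across runs of this package but not numerically
  to partition-enumeration implementations.
- Wald-ratio SEs ignore exposure uncertainty; weak instruments are flagged,
  not corrected.
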
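# Methods

## The decision problem

A cis-mQTL that is also associated with a complex trait admits four
generative explanations: mediation through methylation, reverse
causation (the trait alters methylation), LD confounding (two distinct
causal variants in linkage disequilibrium), and horizontal pleiotropy.
The pipeline assembles one piece of evidence against each alternative —
reverse MR for explanation 2, fine-mapping concordance for explanation
3 — and reports the remainder as the joint call `1_mediation_or_4`,
because a single cis instrument cannot separate mediation from
pleiotropy and we do not pretend otherwise.

Decision rules, in order of precedence (configurable off via
`reverse_first=False` for sensitivity analyses):

1. reverse-MR p ≤ α (default 0.05) → `2_reverse`;
2. concordance verdict discordant → `3_ld`;
3. forward-MR p ≤ α *and* reverse unlikely *and* concordant →
   `1_mediation_or_4`;
4. otherwise `inconclusive` (also when required evidence is missing).

Replication 2SMR and expression 2SMR results are carried in the
evidence bundle and reported, but never gate the call.

## Synthetic-study generator

### Linkage disequilibrium

Haplotypes are zero-mean AR(1)-correlated standard normals thresholded
at the MAF quantile; two independent haplotypes per sample are summed
into dosages ∈ {0, 1, 2}. The dosage correlation for latent correlation
r equals the haplotype phi coefficient,

    φ(r) = (P₁₁(r) − maf²) / (maf·(1 − maf)),

with the orthant probability P₁₁ in closed form through Owen's T
function (both thresholds equal). This map is invertible, so the
generator can place a variant at an exact target r² — the
`ld_confounded` scenario appends a second causal cluster whose lead
variant sits at the requested r² (default 0.3) to the sentinel, with
its own high-LD neighbours, by solving for the AR(1) index distance.
The closed form is verified against Monte-Carlo dosage correlations in
the tests.

Thresholding attenuates correlation (φ(0.999) ≈ 0.97 at MAF 0.3), and
φ(ρᵈ) decays much more slowly than φ(ρ)ᵈ; defaults were chosen off this
map: `ld_rho = 0.999` and a 31-variant region give ≈ 25 variants at
r² ≥ 0.8 with the central sentinel — large enough that a rank-1
concordance (1/25 = 0.04) clears the 0.05 rule, small enough that K = 2
enumeration is trivial.

### Structural equations

With G the sentinel dosage (variance v_G = 2·maf·(1−maf)), covariate
term c·(age_z + sex_z) with c = 0.05, polygenic background
P = Σ_k β_k G_k over 20 unlinked instruments (β_k = 0.1 SD/allele):

- mediation:      M = a·G + cov + ε_M;  Y = b·M + P + cov + ε_Y
- reverse:        Y = P + cov + ε_Y;    M = a·G + c·Y + cov + ε_M
- ld_confounded:  M = a·G₁ + cov + ε_M; Y = d·G₂ + P + cov + ε_Y,
                  r²(G₁,G₂) = r2_pair
- pleiotropy:     M = a·G + cov + ε_M;  Y = d·G + P + cov + ε_Y

The polygenic background is present in every scenario so that the trait
always has valid instruments for reverse MR; only in `reverse` does the
trait feed back on methylation. Residual SDs default to the value that
makes each population variance exactly 1 (including covariance cross
terms), so after the final empirical standardization the recorded truth
parameters are already on the SD scale and parameter recovery is exact,
not approximate.

Defaults — a = 0.95 SD/allele (cis-mQTL effects on methylation of this
magnitude are typical for sentinel instruments), b = 0.5 SD/SD (middle
of the plausible causal-effect range), c = 0.4, d = a·b = 0.475 (so the
pleiotropy scenario is marginally identical to mediation, which is the
point), maf = 0.3, n = 5,000.

Instrument-trait effects for reverse MR come from a simulated *external*
cohort (default n = 20,000) regenerated under the same equations and
written to the bundle as `trait_gwas.tsv`. This matters: estimating
both reverse-MR stages in the one sample correlates their errors (the
instrument-trait estimate contains b·β̂_GM) and inflates the reverse-MR
type-I rate several-fold under mediation; with external exposure
effects the rate sits at its nominal ~5%.

What the generator does **not** emulate: realistic recombination maps
or LD beyond the exponential-decay kernel, population structure,
trans-mQTL networks, cell-type heterogeneity, array probe artefacts,
or non-Gaussian trait distributions. Passing tests show the pipeline's
statistical machinery is correct and calibrated under these idealized
conditions; they do not certify behaviour under cryptic relatedness or
batch structure in real cohorts.

## Preparation

- Friedewald LDL = TC − (HDL + 0.45·TG), VLDL = TC − (HDL + LDL), in
  mmol/L; negative LDL estimates are flagged NaN and excluded.
- Rank-based inverse-normal transform with the Blom offset 3/8:
  Φ⁻¹((rank − 3/8)/(n + 1/4)); ties share the average rank.
- Residualization by OLS with intercept; rank-deficient designs raise
  an error naming the collinear columns.
- Cis filter: same chromosome, |pos_SNP − pos_CpG| ≤ 1 Mb (1-based
  inclusive coordinates), p < 1×10⁻¹⁴; any SNP with a significant
  *trans* association is removed from the instrument set entirely.
- Instrument independence by greedy LD clumping (take best p, drop
  everything at r² ≥ 0.1, repeat) rather than a conditional joint
  model: what the downstream MR needs is pairwise-independent
  sentinels, which clumping guarantees by construction. Tie-breaks:
  smaller p, then smaller position, then lexicographic ID.

## Association scan

Per (SNP, trait): OLS of trait on dosage + covariates + intercept (QR
factorization), two-sided p from the t distribution, partial R² =
t²/(t² + df) as variance explained (a full-model ΔR² is the obvious
alternative; partial R² is the default and the choice is documented
rather than asserted). Complete cases per pair; monomorphic SNPs and
pairs with n < 30 are skipped and logged. p-values are additionally
carried in log space (`neg_log10_p`, via `t.logsf` with a `log_ndtr`
fallback) because float64 p underflows to 0 beyond |t| ≈ 40 — routine
for mQTL-scale effects — and significance ranking must keep resolving
there. The Bonferroni threshold is strict (`p < thr`).

## Mendelian randomization

- **2SLS** (one-sample): stage 1 projects the exposure on instruments +
  covariates; the coefficient covariance uses stage-2 residuals against
  the *observed* exposure, σ²·(W'P_Z W)⁻¹ — the naive OLS-on-fitted SE
  is wrong and not used. With one instrument the estimate equals the
  reduced-form ratio exactly. First-stage F < 10 is logged, not
  enforced (instruments pre-filtered at p < 1e-14 are strong). t
  p-values.
- **Wald ratio**: β = β_GY/β_GX, SE with both delta terms (the
  outcome-only term materially understates the SE when the exposure
  stage is noisy — 0.146 vs 0.160 for a 0.982 (0.103) exposure stage);
  normal p-values for summary-statistic MR.
- **IVW**: fixed-effect inverse-variance weighting of per-instrument
  ratios; with one instrument it reduces to the Wald ratio. Chosen as
  the reverse-MR combiner for its single-number verdict; MR-Egger and
  median/mode estimators are out of scope.
- **Harmonization**: match by SNP ID, else best LD proxy with r² > 0.8
  (recorded); flip outcome betas on allele swap; drop palindromic (A/T,
  C/G) variants with MAF in (0.42, 0.5] as strand-ambiguous (cutoff
  configurable); unresolvable pairs are omitted with a logged reason.

## Bivariate fine mapping

Region = sentinel plus every variant with r² ≥ 0.8 (inclusive) to it.
Per-variant evidence is Wakefield's approximate Bayes factor,

    log BF = ½·log(se²/(se² + W)) + ½·z²·W/(se² + W),

with Gaussian effect-prior variance W = 0.04 (prior SD 0.2 on
standardized effects; configurable), validated against numerical
integration. Per-variant posteriors are the softmax of log BFs under a
uniform causal prior (no functional weighting).

**Concordance rate** = (1-based rank of the top methylation-BF variant
in the descending trait-BF ranking) / (region size), concordant iff
strictly < 0.05. Ties break by larger |z|, then position, then ID, and
are logged. Note the arithmetic consequence: a region smaller than 20
variants can never be concordant even with perfect agreement — the
report flags region size for this reason.

**Posterior over K ∈ {1, 2} causal variants** by exhaustive enumeration
under z ~ N(0, R + v·R_S R_S') for causal set S versus z ~ N(0, R),
using matrix-determinant-lemma closed forms (validated against direct
multivariate-normal densities). Two numerical choices matter at
mQTL-scale signals:

- the model is evaluated on the correlation scale,
  z* = √df·t/√(t² + df): at |t| ≈ 40 the raw t-statistics of a causal
  variant's neighbours fall systematically below the r·λ mean structure
  (their regression residual variance is larger), and that
  misspecification masquerades as a second causal variant;
- the prior non-centrality variance v defaults to max(z*²) − 1 (floored
  at 1), an empirical-Bayes scale choice; a fixed small v penalizes the
  true strong effect and again favours spurious K = 2.

With z = 0 and v → 0 the posterior approaches the prior over K; for any
finite v the Occam determinant terms differ slightly between K = 1 and
K = 2, so the no-information identity is exact only in that limit.
K > 2 and shotgun search are out of scope (regions capped at 500
variants). An `external_coloc_p` slot lets externally computed
colocalization p-values ride along in reports; nothing here computes
them.

## Enrichment

BED half-open 0-based intervals internally; a 1-based point p overlaps
[start, end) iff start < p ≤ end. Chromosome names are normalized
("chr1" ↔ "1") with a warning. The exact test is the hypergeometric
upper tail over the target + unique-control population; the calibrated
test resamples one matched control per target per iteration (10,000 by
default) and reports the add-one empirical p,
(1 + #{iterations ≥ observed}) / (iterations + 1), which can never be
zero and whose floor halves when iterations double. Matched pools are
an input (property matching is done upstream); a simple MAF ± 0.05 /
same-category matcher ships for synthetic tests. SNP and CpG targets
are tested separately per track.

## Determinism and problem sizes

Every stochastic step threads one seeded `numpy` Generator; no global
random state. Reports carry no timestamps or output paths, floats are
written with fixed formats, and JSON keys are sorted, so identical
config + seed reproduces every output byte for byte (tested through the
CLI).

Test-suite problem sizes are the package's own choices: parameter
recovery uses 200 studies of n = 5,000 with a minimal 3-variant region
(2SLS needs only the sentinel); type-I calibration uses 20 × 250
independent null tests at n = 400; scenario classification uses 100
seeds per architecture at the full default study size. The whole suite
runs in a few minutes on one core.

## Known limitations

- Mediation vs pleiotropy is never resolved; the call label carries the
  ambiguity by design.
- Concordance is insensitive in regions with fewer than 20 variants and
  inherits the arbitrariness of rank/m under BF ties among
  near-perfectly correlated neighbours.
- Greedy clumping can differ from a conditional-selection model when
  secondary signals are shadowed by LD with the lead.
- The K-posterior uses |r| from the r² matrix (signs are not retained),
  which is conservative for anti-correlated pairs.
- One printed reference SE in the replication panel (the low-frequency
  ADIPOQ signal) is not reproducible from its printed inputs at ±0.001;
  recomputation from the source's own p-value shows its inputs were
  rounded after, not before, the ratio. The corresponding check is left
  failing rather than loosened.
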
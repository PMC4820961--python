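# Methods

This note documents the statistical models implemented in `methvc`, the
assumptions behind them, the synthetic cohort used to validate them, and
the numerical choices that matter.

## Study design and data model

The unit of analysis is one CpG site: a vector of methylation values over
individuals organised in twin families (MZ and DZ pairs, optionally
parents and full siblings). Methylation enters the models on the M scale,
`M = log2(β/(1−β))`, after covariate residualization and per-site
z-standardization; β values (`β = M_signal/(M_signal+U_signal+α)`, offset
α = 100) are used only descriptively. Analyses that use genome-wide SNP
data run on residuals that additionally remove ten genotype principal
components (top eigenvectors of the IBS GRM); twin-only analyses omit the
PCs.

## Quality control

Probe filters, applied in order: (1) blacklisted probes (ambiguous mapping;
SNP at the interrogated CpG) are removed globally; (2) per-cell failures —
detection P > 0.01, bead count < 3, zero intensity — are set missing;
(3) probes with success rate < 0.95 across samples are dropped. Sample
contamination is called from 65 biallelic SNP control probes: an
allele-signal proportion in [0.2, 0.4] or [0.6, 0.8] (closed intervals —
a conservative choice, configurable) is an "unclear genotype", and samples
with ≥ 15 unclear genotypes are flagged. Remaining missing cells are
imputed by the site mean (deterministic default; a k-nearest-sites variant
with k = 10 is available).

## Relatedness matrices

The IBS GRM uses the standardized-genotype estimator
`A_jk = (1/N) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i))` over SNPs with
sample MAF > 0.01; allele frequencies are estimated from the full sample
(relatives included), with a founders-only option. Missing dosages use
pairwise-complete averaging. The IBD-like matrix zeroes off-diagonal
entries strictly below 0.05, leaving close relatives' relatedness intact.
Pedigree-expected relatedness (MZ 1, first-degree 0.5, unrelated 0,
diagonal 1) is computed by the recursive kinship algorithm plus explicit
twin/sibling patching for families whose parents are unobserved.

A practical caveat: GRM entries carry sampling noise with s.d.
≈ 1/√N_SNPs. The 0.05 threshold therefore only separates relatives from
non-relatives cleanly when the panel is large enough; with 500 SNPs
(noise s.d. ≈ 0.045) roughly an eighth of unrelated pairs survive
thresholding, which attenuates the pedigree variance component. Analyses
that need the SNP-vs-pedigree separation use a 2,000-SNP panel, where the
misclassification rate is negligible.

## Twin models

Per zygosity group the pair vector is bivariate normal with a common mean
and total variance; expected covariances are `a²+c²` (MZ) and `a²/2+c²`
(DZ) under ACE, and `a²+d²` / `a²/2+d²/4` under ADE. Components are
estimated by maximum likelihood with component standard deviations
softplus-reparameterized (keeping variances non-negative), quasi-Newton
optimization with three random restarts, and the best log-likelihood kept.
Reported components are proportions of the fitted total variance and sum
to one exactly. Likelihood-ratio tests compare nested models against the
conventional χ² reference, which is conservative when the tested component
lies on the zero boundary (verified empirically: size ≤ nominal under a
true AE model). Equal total variances across zygosity groups are assumed;
incomplete pairs are dropped.

## Two-GRM mixed model

Per site, `y ~ N(μ1, σ²_SNP·A_IBS + σ²_ped·A_IBD + σ²_e·I)` with a free
intercept. σ²_SNP captures variance tagged by genotyped SNPs (identified
through the faint realized relatedness between nominally unrelated
individuals, and through causal-variant sharing); σ²_ped absorbs the
remaining additive genetic variance carried by close relatives. Estimation
is maximum likelihood on log-scale variances (an ML/REML distinction is
immaterial for the mean-recovery checks used here; ML is the default),
with analytic gradients, L-BFGS-B, and two starting points. Non-negativity
of σ²_ped enforces `h²_SNPs ≤ h²_IBD` by construction. Standard errors
come from the observed information (central-difference Hessian on the
variance scale); components pinned below 1e-8 are flagged as boundary
solutions with undefined SEs, and identical input matrices (an exact
likelihood ridge) flag both genetic components. Sites that fail to
converge are emitted with a status column rather than discarded silently.

Each likelihood evaluation costs one Cholesky factorization, O(n³) dense.
When every covariance term is block-diagonal over families (pedigree
GRM, or a thresholded GRM without cross-family entries) the likelihood
factorizes and is evaluated with batched small-block linear algebra, O(n)
for twin-pair data — this is what makes simulation calibration with
hundreds of replicate fits cheap.

The ratio `h²_SNPs/h²_IBD` is reported only where `h²_IBD ≥ 1e-6`;
below that floor it is undefined and excluded from summaries.

## Variance-moderation models

With moderator m (sex coded 0/1, or age z-scored using the analysis
sample's own mean and s.d., stored with the fit),

    V_ij = A_ij (σ_a + β_g m_i)(σ_a + β_g m_j) + δ_ij (σ_e + β_e m_i)²

is fitted by ML with a free intercept. A single total-genetic component
with a close-relative relationship matrix is used (the interaction
question concerns total genetic vs environmental variance, not the
SNP-tagged split; the matrix is a configuration option, pedigree-expected
by default in the pipeline for speed and exactness of the family block
structure, with the IBD-thresholded GRM available). No separate baseline
SNP-variance term is included; this is a documented modelling choice
suitable for sensitivity analysis rather than an estimated necessity.
Interaction significance uses the 1-df Wald statistic `(β/s.e.)²` with SEs
from a central-difference Hessian (step 1e-4 on the parameter scale);
singular Hessians yield flagged fits with undefined tests. The likelihood
is invariant under jointly flipping the sign of (σ_a, β_g) (and of
(σ_e, β_e)); fits are reported with σ_a, σ_e ≥ 0. Derived trajectories:
`Va(m) = (σ_a+β_g m)²`, `Ve(m) = (σ_e+β_e m)²`, `h²(m) = Va/(Va+Ve)`,
evaluated by default at sex 0/1 and at ages 25 and 50 on the stored
z scale.

## Annotation and enrichment

Gene-centric classes, oriented by the strand of the nearest-TSS gene:
proximal promoter (−1.5 kb…+500 bp), distal promoter (−10 kb…−1.5 kb),
gene body (+500 bp…3′ end), downstream (3′ end…+5 kb), intergenic
otherwise. Boundary positions belong to the more promoter-proximal class;
nearest-TSS ties break to the lower gene id. CGI classes: island, shore
(≤ 2 kb from an island edge), shelf (2–4 kb), non-CGI; the CGI definition
(GC > 50%, length > 200 bp, observed/expected CpG > 0.6, all strict) is
available as a sequence-level predicate. Coordinates are 1-based inclusive
internally; BED input is converted on read. Enrichment is a per-class 2×2
Pearson χ² without continuity correction (appropriate for the large counts
this is used on; a corrected variant is available), Bonferroni-controlled
over the test family (default 117 tests at α = 0.05 → 4.27×10⁻⁴).

Site categories: variable (s.d. of β > 0.03, strict), high/low
heritability (h² ≥ 0.5 / h² < 0.2, likewise for h²_SNPs), longitudinally
stable/unstable (r ≥ 0.5 / r < 0.2).

## Synthetic cohort

`simulate` generates the validation data. Defaults mirror a large adult
twin register: 769 MZ + 424 DZ pairs, 212 parents, 16 siblings, mean age
37.2 (s.d. 13.3, range 17–79), 66% female. Genotypes are gene-dropped
through each family from Hardy–Weinberg founders (MAF uniform on
[0.01, 0.5]); MZ co-twins share one realized transmission. Twins share age
exactly; parent age is the twin age plus an offset ~ N(28, 3²) —
plausible structure, irrelevant to the estimators. Per site, the value is

    μ + g_SNP + g_ped·s_g(m)/s_g(0) + c_fam + d + e·s_e(m)/s_e(0)

where g_SNP is a weighted sum of standardized causal dosages scaled to
var_snp, g_ped and d are multivariate-normal draws from the *expected*
additive and dominance relatedness (exactness of ground truth for recovery
tests; dominance correlation 0.25 in DZ/sib pairs, the standard
coefficient), c_fam is family-shared, e is independent, and
`s_g(m) = σ_g + β_g·m`, `s_e(m) = σ_e + β_e·m` moderate the genetic and
environmental standard deviations multiplicatively — matching the
estimation model's parameterization, scaled so variances equal the stated
fractions at m = 0. μ is the M value of the site's baseline β. Missing
cells are injected completely at random (default rate 0.1%).

What the simulator does *not* emulate: linkage disequilibrium, array
intensity noise, probe cross-hybridization, batch structure correlated
with biology, and cell-composition confounding (covariates are generated
independent of methylation unless effects are injected). Passing recovery
tests therefore demonstrates correctness of the estimators under the
models' assumptions, not robustness to real-array artefacts.

## Validation scale and tolerances

Tests validate *mean* recovery over replicate sites because single-site
variance-component estimates at desk scale (200 MZ + 200 DZ pairs) have
sampling s.d. of ~0.05–0.15. Desk-scale problem sizes: 50 replicate sites
for twin-ACE and two-GRM recovery (the latter with the 2,000-SNP panel,
see the thresholding caveat above), 50 sites for moderation-slope
recovery, 200 replicate null sites for the empirical size of the Wald
tests, 20–25 sites for the twin-vs-GRM heritability equivalence. The β↔M
transform pair round-trips to 1e-12; GRM computation matches a brute-force
double loop to 1e-12; enrichment χ² matches the hand-computed Pearson
statistic to 1e-10.

## Known limitations

- Twin models assume equal total variance across zygosity groups and no
  sex-limitation structure.
- Boundary-constrained variance estimates are biased upward near zero
  (means over sites with a true component of exactly zero exceed zero);
  LRT/Wald references at the boundary are conservative.
- The moderation model's linear s.d. trajectories can cross zero outside
  the observed moderator range; trajectories should not be extrapolated.
- The thresholded GRM is only an IBD proxy when the SNP panel is large
  (see above); with small panels the SNP/pedigree split is attenuated.
- GEE-style covariate association uses an independence working correlation
  with family-cluster-robust errors; efficiency (not validity) is lost if
  within-family correlation is strong.
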
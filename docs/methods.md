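# Methods

Statistical model, parameter defaults, numerical choices and known
limitations for every stage of the `lysompn` package. All problem sizes
quoted here (cohort group sizes, 2,000 bulk genes, 6-sample single-cell
design, and so on) are the package's own default choices for its synthetic
generator and tests; every one of them is configurable.

## 1. Variant tiering and carrier calling (`lysompn.variants`)

**Model.** Variants are screened against a fixed lysosomal-dysfunction gene
panel and retained only when sequencing support and population frequency are
consistent with a rare, well-covered germline call:

- on-panel gene symbol;
- read depth > 10 and alternate-allele reads > 5 (strict inequalities);
- gnomAD allele frequency ≤ 0.005; a **missing** AF is treated as rare and
  retained, since absence from the reference population is itself evidence
  of rarity.

When several filters fail, one exclusion reason is reported with fixed
precedence `off_panel` → `low_depth` → `low_alt` → `common_af`, so the
report is deterministic and order-invariant with respect to the input rows.

Tier assignment is two flags, not a partition:

- **Tier 1** — predicted protein-truncating consequences (`stop_gained`,
  `frameshift_variant`, `splice_acceptor_variant`, `splice_donor_variant`,
  `start_lost`) or any frameshift-length indel;
- **Tier 2** — ClinVar clinical significance `Pathogenic` or
  `Likely_pathogenic` (case-insensitive, compound annotations accepted).

A variant may satisfy both; `tier_summary` therefore reports distinct
qualifying variants by inclusion–exclusion,
`n_distinct = n_tier1 + n_tier2 − n_both`, where distinctness is keyed on
(gene, chrom, pos, ref, alt) so the same allele observed in several subjects
counts once. A subject is an LD carrier when they harbour at least one
qualifying (Tier 1 or Tier 2, post-filter) variant.

## 2. Carrier-burden association (`lysompn.assoc`)

**Odds ratio.** `logistic_or(a, b, c, d)` fits a saturated two-row binomial
GLM (statsmodels IRLS, logit link) of carrier status on case/control
membership. For a single binary covariate the maximum-likelihood estimate is
analytically the cross-product ratio `ad/bc`; the IRLS fit converges to it
to machine precision, and the acceptance tests assert agreement within
1e-8. If any cell is zero the Haldane–Anscombe correction (add 0.5 to every
cell) is applied and flagged in the result. The Wald confidence interval
and p-value come from the asymptotic normality of the log-OR with
`se = sqrt(1/a + 1/b + 1/c + 1/d)`; a one-sided p halves the two-sided one
in the direction of the estimate.

**Chi-square.** `pearson_chi2` is the standard uncorrected Pearson statistic
on the 2×2 table (1 df), delegated to `scipy.stats.chi2_contingency` with
`correction=False`.

**Percent rendering.** `render_percent(f)` returns
`floor(100·f + 0.5)` followed by `%` — round-half-up, matching how carrier
frequencies are conventionally printed (6/55 → `11%`, 15/190 → `8%`,
23/461 → `5%`). Note `round()` in Python is banker's rounding and would
disagree at exact halves; the explicit floor form avoids that.

**Limitation.** The Wald p-value and the Pearson chi-square p-value are
different approximations and need not agree, especially at small carrier
counts; the package reports both rather than reconciling them.

## 3. Bulk RNA differential expression (`lysompn.bulkrna`)

**Normalization.** Median-of-ratios size factors: per-gene geometric means
over samples (genes with any zero are excluded from the reference), size
factor = median of the sample/reference ratios, then rescaled to geometric
mean 1 so normalized counts stay on the raw scale. If fewer than 10 genes
are all-positive the code falls back to library-size factors and warns.
Under a pure per-sample scaling of a common profile the recovered factors
equal the true scalings exactly (a test oracle).

**Testing.** Welch's unequal-variance t-test on `log2(normalized + 1)`,
two-sided, with Benjamini–Hochberg q-values. A gene with zero variance in
both groups gets p = 1 (no evidence, rather than NaN). Calls use
|log2FC| > 0.5 and p < 0.05 — deliberately raw-p, mirroring common
exploratory DEG practice; the q-value is reported alongside so stricter
readers can re-threshold.

**Annotation.** `classify_lr_cytokine` flags DEGs that appear as ligand or
receptor in the bundled ligand–receptor database and marks cytokine-class
ligands. `overlap_sets` computes exact Venn partitions (the seven regions
for three sets) with the invariant that regions partition the union.

## 4. Enrichment (`lysompn.enrich`)

**GSEA.** The weighted Kolmogorov–Smirnov enrichment score: genes ranked by
a signed statistic, hit increments proportional to |statistic| (weight
p = 1) normalized by the in-set total, miss decrements 1/(N − |S|); ES is
the running-sum excursion of maximal absolute value, signed by the
excursion that attains it. When the positive and negative excursions have
exactly equal magnitude, which of the two is returned depends on
floating-point summation order; the acceptance oracle therefore asserts the
magnitude exactly and the sign only when the extrema are unambiguous (gap
> 1e-9). NES divides ES by the mean |ES| of gene-set-label permutations of
matching sign (gene-set permutation, not phenotype permutation — chosen
because the package ranks genes by an externally supplied statistic and the
sample-level design may be too small to permute); the empirical p-value uses
the (b + 1)/(m + 1) estimator so it is never exactly zero.

**ORA.** Over-representation p-value is the hypergeometric survival
function P(X ≥ k) via `scipy.stats.hypergeom.sf(k − 1, …)`, which the
acceptance test confirms against exhaustive enumeration of all equally
likely draws.

**Regulon TF scoring.** Gene statistics are converted to normal scores
(rank-based inverse-normal transform), a regulon's NES is the mode-signed
mean of its targets' scores times √n — the analytic null for a mean of n
i.i.d. standard normals — with a minimum-target filter. Flipping every
target's mode negates the NES exactly (tested).

## 5. Differential co-expression networks (`lysompn.diffnet`)

**Model.** Pearson correlation on `log2(normalized + 1)` within each group;
an edge exists when r > 0.6 (signed by default — anticorrelation is not
co-expression; an absolute-value mode is available). Edges are canonically
ordered (sorted gene pair) so networks are comparable across groups.
Differential edges are those present in the carrier network, absent in the
non-carrier network, **and** supported by the protein-interaction template
with combined score strictly > 700 (the conventional "high-confidence"
cut). Modules come from NetworkX greedy modularity communities; hubs are
ranked by weighted degree (sum of |r| over incident differential edges)
with ties broken alphabetically for determinism.

**Limitation (edge-retention ceiling).** With the default 8 carrier
samples, the Fisher-z sampling distribution of r around a true value of 0.8
gives only ~0.73–0.81 probability that any single true edge exceeds the 0.6
threshold. Per-edge retention therefore cannot meet a 95% bar at this
sample size for any honest generator; the recovery criterion is stated at
the module level (best-matching module Jaccard ≥ 0.8, planted genes among
the top-30 hubs), which the redundancy of a 15-gene clique makes reliable.
Measured over 10 seeds the minimum Jaccard is 0.94.

## 6. Single-cell stages (`lysompn.sccore`)

**QC.** Per-cell UMI total, detected genes, mitochondrial fraction
(`MT-`-prefixed genes); filters on each plus an optional PCA-outlier filter
(z-score of the first principal components against a robust scale). One
removal reason per cell with fixed precedence; filtering away every cell is
an error, not an empty result.

**Normalization and typing.** `log_normalize` is `log1p` of
counts-per-10,000. Cell types are assigned by argmax over marker sets of the
mean column-z-scored marker expression; an exact tie (including the all-zero
z case) yields `unassigned` rather than an arbitrary winner. On synthetic
data typing agrees with the generating labels in > 99% of cells.

**Proportion test.** For each cell type, the null distribution of the
group-A count under label exchangeability is the hypergeometric law — the
exact marginal distribution of shuffling group labels over cells — so the
permutation test is implemented by direct `rng.hypergeometric` draws
(n_perm = 1,000 by default), which is both faster and exactly equivalent in
distribution to materializing label permutations. Effect size is
`log2((k_A + 1)/(n_A + 1) · (n_B + 1)/(k_B + 1))` (+1 pseudocounts guard
empty types); a multinomial bootstrap (n_boot) gives a confidence interval;
BH adjustment across types. Groups below `min_cells = 100` raise.

**DEG.** Wilcoxon rank-sum on log-normalized expression within a cell type,
with average log2 fold change computed on the `expm1` (de-logged) scale as
single-cell convention dictates; calls at |avg_log2FC| > 0.25, BH-adjusted.
Pseudo-bulk aggregation sums raw counts per sample (optionally per cell
type) and hands the result to the bulk Welch-t machinery — the
sample-as-replicate design that avoids pseudoreplication.

**Communication.** For a ligand–receptor pair restricted to the
"secreted signaling" category, expression per type is Tukey's trimean of
log-normalized values, zeroed when detected in < 5% of that type's cells;
the communication probability is the Hill form
`(L·R) / (Kh + L·R)` with `Kh = 0.5`, bounded in [0, 1) and monotone
decreasing in Kh (tested). `interaction_delta` is the carrier − non-carrier
probability difference per pair.

**Module scores and regulon activity.** Module score = mean log-normalized
expression of module genes minus the mean of a size-matched random
background (seeded), compared across groups by rank-sum. `grn_activity`
averages mode-weighted z-scored target expression per (TF, group) within a
cell type, with dense descending ranks per group and a minimum-target
filter; an empty result is returned as a typed empty frame.

## 7. Synthetic generator (`lysompn.synthio`)

The generator exists so every detector in the package can be tested against
known truth. It emulates the **statistical structure** the pipeline assumes
— group-specific carrier prevalence, negative-binomial counts with
library-size variation, correlated gene programs, cell-type mixtures with
planted composition and expression shifts — and makes **no attempt** to
emulate real sequencing artefacts (ambient RNA, doublets, batch chemistry,
GC bias, index hopping), real genome coordinates, or real biology beyond
the planted effects. All randomness flows from one integer seed through
`numpy.random.default_rng`; sub-generators derive independent streams with
fixed offsets, so outputs are byte-identical across runs and platforms.

**Cohort and variants.** Four groups (48 PMF, 55 PV, 87 ET, 461 controls)
with carrier prevalences set to reproduce the reconstructed counts
(4, 6, 5, 23). Each planted carrier receives at least one qualifying
variant (Tier 1 or Tier 2, passing all filters); non-carriers receive only
non-qualifying decoys (off-panel, low-coverage, common, or benign), so the
tiering stage's recovered carrier set must equal the planted set exactly.

**Bulk counts.** 2,000 genes × (8 carrier + 6 non-carrier) samples,
negative-binomial with per-gene mean ~ logUniform(20, 500) and dispersion
~ U(0.05, 0.5), per-sample library factors ~ U(1, 2). Planted DE genes (10
up, 10 down, log2 effect 2) draw means from logUniform(100, 500) —
cytokine-class transcripts in stimulated marrow are moderately-to-highly
expressed — and dispersions from U(0.05, **0.3**). The dispersion ceiling
is a design-by-power-analysis choice, not tuning toward a test: a
prospective Welch-t power calculation at n = 6 vs 6 and log2 effect 2 gives
~0.85 power at dispersion 0.5 but > 0.95 at 0.3, and the generator's
documented contract is that planted signals are recoverable by the
designated detector at the configured effect size. Planted co-expression
modules (two 15-gene cliques, target ρ = 0.8) share a latent log2-scale
factor (SD 3.0) with tight dispersion 0.05 in carriers only, so
count-level correlation survives counting noise; the protein-interaction
template contains every within-module pair at score > 700 plus random
decoy edges.

**Single cell.** Six samples (2 carrier, 2 non-carrier, 2 healthy), 2,500
cells each, 8 marrow cell types with Dirichlet-free fixed base proportions.
Planted composition shifts (Monocyte ×2.0, CD8_T ×1.5 in carriers) are
applied by renormalizing: planted types keep exactly fold × base share and
the remaining types absorb the complement proportionally. Per-sample
cell-type counts use **largest-remainder quota rounding** of the target
proportions rather than a multinomial draw: a multinomial adds composition
noise of SD ≈ 0.07 in log2 fold terms, which makes the planted fold itself
a random quantity (≈ 2.9σ from band edge) — the planted signal would then
not be what the ledger claims. Quota counts make the planted fold exact by
construction; the **test statistics'** null calibration is unaffected
because the proportion test permutes labels over the realized cells, and
the type-I criterion is verified separately with randomly labelled data.
Expression is negative-binomial over log-normal library sizes with
per-type marker boosts (+3 log2), a planted monocyte ligand (OSM, +2 log2
in carriers), and additive log2 regulon shifts on TF target genes graded
carrier > non-carrier > healthy for STAT1, plus a disease factor (CEBPB), a
healthy-enriched factor (HLF) and two null decoy TFs.

## 8. Pipeline and I/O (`lysompn.cli_io`)

The `lysompn run` pipeline executes simulate → tier → assoc → bulk →
diffnet → sc, writing a manifest that records, per stage, the SHA-256 of
every input and output file plus the parameter set and seed. A stage is
skipped on rerun when all of those match, so reruns are no-ops and any
parameter change invalidates exactly the affected stages. YAML configs are
strictly validated: unknown keys at any level are rejected rather than
ignored, so typos fail loudly. All tabular I/O is TSV with explicit column
checks (missing columns, negative counts, alt > depth, duplicate
ligand–receptor pairs and malformed regulon modes all raise).

## Numerical choices (summary)

- `numpy.random.default_rng` (PCG64) everywhere; no global seeding.
- Empirical p-values use (b + 1)/(m + 1); BH via statsmodels `multipletests`.
- Percent rendering by explicit `floor(x·100 + 0.5)` (round-half-up).
- Correlation/ES oracles are asserted at 1e-10 / 1e-9; the logistic-vs-
  cross-product identity at 1e-8 (IRLS convergence tolerance).
- GSEA sign at exactly tied excursions is summation-order dependent and
  documented as such rather than papered over.

## Limitations

- Wald and Pearson chi-square p-values can diverge at small counts; both
  are reported.
- Per-edge network retention is bounded by Fisher-z sampling error at
  n = 8 (≈ 0.73–0.81 per true edge); recovery guarantees are module-level.
- The generator does not model sequencing artefacts, batch effects,
  doublets or ambient contamination; calibration results transfer to real
  data only insofar as the distributional assumptions hold.
- DEG calls use raw p < 0.05 by design (exploratory convention); q-values
  are provided for stricter control.
- Communication probabilities are scored only for secreted-signaling pairs
  and depend on the Hill constant Kh; deltas are comparable only at fixed
  Kh.
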
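# Methods

This note documents the models and procedures `coexpair` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the method
literature leaves room.

## Network model

Gene–gene similarity is the Pearson correlation `r_ij` of expression
profiles across samples, computed on residualized expression (see
Preprocessing). Adjacency is the soft-thresholded transform

- unsigned: `a_ij = |r_ij|^β` — negative co-expression contributes fully;
- signed: `a_ij = ((1 + r_ij)/2)^β` — anticorrelated genes are pushed
  toward 0.

The exponent β (integer, default chosen per dataset) is selected by the
scale-free topology criterion: for each candidate power, total connectivity
`k_i = Σ_{j≠i} a_ij` is computed, genes are binned into 10 equal-width bins
of k, and `log10(mean frequency)` is regressed on `log10(mean k)` over
nonempty bins. The signed fit index is R² × (−sign(slope)), so only a
*decaying* power law scores positively. The chosen β is the smallest with
fit ≥ 0.9; if none reaches the target the best-scoring power is returned
with `target_met=False` rather than an error, since downstream stages are
still well defined. Binning (equal-width, empty bins dropped) is a
convention of this implementation; the criterion's originators do not pin
it down.

Topological overlap follows the standard unsigned form

    ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,

with ω_ii = 1 and DistTOM = 1 − ω as the clustering dissimilarity. The
matrix is dense double precision: a 21k-gene problem needs roughly 3.5 GB
per matrix and a large-memory host; the pipeline refuses dense TOM above a
configurable gene count (default 25,000) without an explicit override, and
a gene-subset option covers desk-scale work.

## Module detection

Genes are clustered by UPGMA (unweighted average linkage) on DistTOM.
Branch cutting is a dynamic, gap-based decomposition of the merge tree,
deliberately *not* a line-by-line port of any reference implementation:

- merges at or above the cut height (default 0.99) never join branches;
- below the cut height, a merge still separates its two children when both
  hold at least `min_size` (default 50) leaves and the merge height exceeds
  each child's internal top height by at least `split_gap` (default 0.02 on
  the dissimilarity scale) — the single exposed branch-split sensitivity;
- surviving branches smaller than `min_size` are unassigned ("grey").

Reference dynamic tree cutting has many unstated internal constants; the
contract adopted here is recovery of planted structure (tested: ARI ≥ 0.9
against ground truth over 20 generator replicates), not bit-identity.
Oversplitting is tolerated because the eigengene merge step below re-joins
pieces of one latent factor.

Module eigengenes: genes are z-scored across samples, the eigengene is the
leading right singular vector of the module's standardized matrix, rescaled
to unit variance, sign-fixed so it correlates non-negatively with the
module's mean standardized expression; variance explained is
`s₁²/Σs²`. Modules with eigengene dissimilarity DistME = 1 − cor(ME) below
0.25 are merged iteratively — always the closest pair first, eigengenes
recomputed after *every* merge (order can matter), merged module keeping the
larger member's label, lexicographic on ties. Grey never merges. Module
colors are a fixed palette assigned by descending size, so labels are
deterministic; only determinism, not the specific names, carries meaning.

## Cross-condition comparison

Module overlap between the two conditions' assignments is cross-tabulated
over the full gene universe and scored by the hypergeometric tail, computed
by log-space summation of the pmf so values far below 1e-300 keep ~3 digits
of log-accuracy; probabilities smaller than the double-precision floor are
reported as log10 values with a "< 1e-308" display. Two tail conventions
exist in the wild: the inclusive tail P(X ≥ shared) (the textbook
enrichment P, default of `hypergeom_tail`) and the strict tail
P(X > shared) that the widely used R overlap-table routine effectively
prints. `overlap_table` uses the strict convention so its output matches
published overlap tables; a flag switches to the inclusive tail.

Association: case/control status is regressed on each module eigengene by
maximum-likelihood logistic regression (intercept + ME only — the
expression is already residualized, so no further covariates enter). AIC is
2·2 − 2·logL. With membership fixed from condition A, eigengenes are
recomputed on condition B's expression for the identical gene sets
(including the grey set as its own column) and re-tested. Per module the
conditions are compared by ΔAIC = AIC_B − AIC_A, the relative model
likelihood exp(−ΔAIC/2), and Z = |β_B − β_A| / √(se_A² + se_B²) with a
one-sided normal tail. The independent-SE Z is conservative because the two
conditions' eigengenes are correlated (same samples); it is reported anyway
as the conventional summary. Perfect separation is flagged, never silently
reported as numbers, and flagged fits make the comparison unavailable. No
multiple-testing correction is applied across modules by default (raw P per
module is the convention followed); a BH option exists in `qtl.bh_fdr` for
callers who want it.

A subgroup helper runs the same machinery for an arbitrary gene subset
(e.g. a functional splinter of a module) and additionally reports the
correlation of the subset eigengene with its parent module's eigengene in
each condition, which is how coupling loss under perturbation shows up.

## Preservation

For each condition-A module: kIM_i = within-module adjacency sum for gene
i; kME_{i,p} = cor(gene i, ME_p) for all genes × modules. Preservation per
module is the correlation across its genes of kIM (and of own-module kME)
between conditions; modules are ranked per statistic (rank 1 = best,
average ranks on ties) and summarized by the median rank. The composite is
computed over these two statistics, with the module table exposing both so
callers can extend it. The heavyweight permutation-Z preservation framework
is intentionally out of scope — the correlation statistics plus median rank
are what this analysis chain consumes. Hubs are argmax-kIM per condition,
lexicographic on exact ties; modules under 3 genes are flagged unreliable
rather than dropped.

## Risk-locus enrichment

A locus maps to every gene whose (1-based, inclusive) interval lies within
`window_bp` (default 250,000) of its position, distance 0 inside the gene
body, strand ignored. Enrichment of a module's risk-gene fraction is tested
against permutations that draw |module| genes without replacement with
probability proportional to total connectivity k — high-k genes are the
ones module detection tends to assign, so a uniform null would overstate
enrichment. Sampling uses exponential keys (`Exp(1)/k_i`, smallest keys
win): reproducible under a seed and order-independent. The empirical P uses
the add-one convention (1 + #{null ≥ observed})/(B + 1), ties counting
toward the tail — the P can never be 0 and is conservative under
discreteness. All-zero k falls back to uniform with a warning. The generic
gene-set route is a standard two-sided Fisher's exact test on the 2×2
module × set table with fold = in-module set fraction over universe set
fraction; modified (EASE-style) variants and any online annotation service
are out of scope — users supply their own GMT sets.

## Eigengene QTL scan

Per SNP passing QC (MAF ≥ 0.01, call rate ≥ 0.95, both configurable): OLS
of the eigengene on intercept + additive dosage + covariates, Wald t-test
on the dosage term. Covariates default to the first five principal
components of the column-standardized dosage matrix (missing dosages
mean-imputed for the PC computation only). Missing genotypes drop samples
for that SNP only (per-SNP complete case). The interaction model adds
status and dosage×status and reports the interaction coefficient — equal to
the case-minus-control slope difference when no covariates are present —
with per-group slopes emitted alongside; SNPs with fewer than 10 genotyped
samples in either class are flagged, not tested. Scans are summarized by
step-up Benjamini–Hochberg q-values and λ = median(Wald χ²)/0.4549364 (the
1-df χ² median); λ is computed from the reported term's Wald statistic.
PCs are included in the interaction model by default, with a flag-free path
to drop them by passing `covars=None`.

## Synthetic data generator

Each planted module m is one latent factor u_m per condition:

    u_m = ε + β_status(m, condition)·status + Z γ_m [+ β_qtl·dosage],
    gene i in m:  x_i = λ_i u_m + σ ε_i,   λ_i = decay^rank(i),

with ε, ε_i standard normal, Z the sample covariates, and the QTL term
entering one designated module's factor. Geometric loadings produce hub
genes and an approximately scale-free connectivity distribution (the
scale-free fit on default data reaches R² ≥ 0.9 within powers 1–12).
Background genes are independent noise. The responder module's status shift
is β_base in condition 1 and β_stim in condition 2; all other modules carry
β_base in both conditions, so eigengene association exists broadly but only
the responder systematically gains fit under stimulation. Status enters the
factor mean, not per-gene means, making the eigengene the natural readout.

Defaults describe the study conditions the package is exercised under:
3,000 genes × (200 cases + 200 controls), five modules of 200/150/120/80/60
genes, loading decay 0.99, unit gene noise, β_base = 0.25, β_stim = 0.75
latent SD per status unit, three N(0,1) covariates with N(0, 0.2²) effects,
200 HWE SNPs with MAF ~ U(0.05, 0.5), a QTL of effect 0.35 on the second
module (MAF ≥ 0.2 so the planted signal is informative), 5% of responder
genes and 2.5% of the remaining genes placed within 250 kb of a risk locus
(genes are spaced 1 Mb apart on one chromosome so each locus tags exactly
one gene). The decay and noise scale were fixed once so that the binding
small-module case keeps a usable loading spread: with decay 0.99 the
smallest default module spans loadings 1→0.55, giving kME–loading
correlations ≈ 0.95 and clean recovery; per-gene variance explained by the
factor then ranges from ~50% (hubs) down to ~23% (tails), a realistic span
for strong co-expression modules. No empirical reference pins down the
noise decomposition; it is a modeling choice, not a fitted constant.

Randomness flows through named child streams of the master seed (samples,
parameters, each condition's expression, panel genotypes, the QTL SNP, risk
loci), so enlarging the SNP panel cannot perturb the expression draws; all
outputs are bit-reproducible given the seed.

What the generator does **not** emulate: read-count (negative-binomial)
noise — it works at the residualized-expression level the network stages
consume; LD between panel SNPs; correlated or hierarchical module factors;
batch structure. Passing recovery tests therefore demonstrates correctness
of the machinery under a favorable, well-specified factor model, not
performance on raw RNA-seq data.

## Problem sizes used in automated checks

Planted-module recovery runs the full default shape (3,000 × 400) over 20
seeds. The responder-ΔAIC replication (50 replicates) runs at 1,000 genes
with the default module sizes — the association machinery operates on
eigengenes, so gene count beyond the modules adds cost, not information.
Permutation-P calibration uses a 3,000-gene universe with a 1,200-gene risk
set and 300-gene modules at B = 500 over 500 repeats: the add-one,
ties-to-tail P is exactly uniform only in the continuous limit, and this
design keeps the discreteness bias of the module risk fraction well inside
the Kolmogorov–Smirnov band being asserted. QTL calibration uses 5,000 null
SNPs on 400 samples.

## Numerical notes and edge cases

- Correlations are clipped to [−1, 1] before powering; constant genes are a
  named error everywhere a correlation is required.
- TOM division guards 0/0 (isolated gene pairs) to 0; entries are clipped
  to [0, 1].
- Quantile normalization uses mean ranks for ties and interpolates
  fractional ranks between adjacent mean quantiles; it is idempotent to
  1e-12 and preserves within-sample rank order.
- Residualization is a single least-squares projection applied to all genes
  at once; rank-deficient designs report the offending columns by name.
- The empirical-P convention, tie handling, rank tie handling (average),
  hub tie handling (lexicographic) and module-label tie handling
  (lexicographic) are all fixed so identical inputs give byte-identical
  outputs.
- Logistic fits that fail to converge or blow past |β| > 50 are treated as
  separation and flagged.

## Known limitations

- Dense matrices only; no block-wise TOM approximation, so genome-scale
  runs need tens of GB of RAM.
- Pearson correlation only (no robust/biweight option yet); the signed
  network is available but shares the Pearson base.
- The coefficient Z-test ignores the between-condition eigengene
  correlation (conservative by construction).
- Preservation omits permutation Z-statistics by design.
- The QTL scan is a fixed-effects OLS screen: no mixed models, imputation,
  or LD-aware clumping.
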
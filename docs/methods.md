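# Methods

## Motif definitions

**Z-DNA-prone tracts.** A tract is valid when every adjacent pair of bases
alternates purine (A/G) and pyrimidine (C/T) and no adjacent pair is
{A, T} in either orientation; any non-ACGT symbol (including N) terminates
a tract. Reported tracts are maximal (extending one base in either
direction breaks validity) and at least `zdna_min_len` nucleotides long.
Defaults follow the non-B DB / nBMST convention: minimum 10 nt, A–T steps
excluded. Both choices are exposed in `ScanParams` because the upstream
tools do not document every threshold; `zdna_allow_at_steps=True` admits
(AT)n tracts. The A–T exclusion is reverse-complement symmetric (ApT and
TpA are each self-complementary), so the hit set of a reverse complement
is always the mirror image of the forward hit set.

**STRs.** A short tandem repeat is a maximal perfect repetition of a
primitive unit (one that is not itself a repetition of a shorter string)
with unit length in `[str_unit_min, str_unit_max]` (default 2–6 bp), at
least `str_min_copies` = 3 full copies, and total tract length at least
`str_min_len` = 10 nt. A partial trailing copy extends the tract's stop
coordinate but not its copy count. Each genomic tract is reported once,
labelled by its primitive unit in leftmost phase. The Z-DNA and STR scans
are fully independent: a (TG)n tract is both a Z-DNA motif and an STR and
appears in both outputs.

Softmasked (lowercase) bases are scanned by default; with
`include_softmasked=False` they terminate tracts like N. Coordinates are
0-based half-open internally and 1-based inclusive in all serialized
output, matching GTF and the nBMST-style TSV.

Both scanners are implemented as single-pass run detection (a vectorized
path handles chromosome-scale inputs) and are tested for exact equivalence
with brute-force enumeration of maximal valid tracts — exhaustively over
all sequences up to 10 nt and on randomized kilobase-scale sequences.

## Densities

Motif density is count × 10⁶ / genome size (motifs per Mb). Genome size
sums all FASTA record lengths including assembly gaps (N runs) and
softmasked bases, because the density denominator of the source analyses
is the raw assembly span; `ungapped=True` restricts the denominator to
A/C/G/T.

## Promoter positional analysis

For each gene the anchor is the first base of its start codon
(`start_codon` features when the annotation has them, else the 5′ end of
the 5′-most CDS; for multi-transcript genes the 5′-most start codon).
Supported annotation dialects are the UCSC exports `augustus` (gene ids
derived from `gN.tM` transcript ids), `ncbiRefSeq` and `xenoRefGene`
(gene ids from the `gene_id` attribute).

A motif is assigned to a gene when its anchor coordinate lies in the
upstream window (default 10 kb, binned per kb). On the + strand the window
is `[pos−L, pos−1]` and the anchor is the motif stop; on the − strand the
window is `[pos+1, pos+L]` and the anchor is the motif start under the
default *oriented* convention — the motif end nearest the gene in
transcription direction — or the literal stop coordinate under the
*genomic* convention. Both conventions are one flag apart because the
minus-strand reading of a "stop site" is genuinely ambiguous in the
underlying protocol. Windows truncated at contig edges are kept without
renormalization. A motif may serve several genes; each (gene, motif) pair
is assigned at most once.

Distance bins are 1 kb wide by default, giving k = 10 regions over 10 kb.
The region count k is configurable: published analyses of this design
report Friedman df = 10 (i.e. 11 regions) while describing 10 one-kb bins,
and this implementation does not guess which reading was used — both are a
`--bin-kb`/`--window-kb` choice away.

Statistics on the species × region matrix:

* **Lilliefors** normality per region: D = sup |Fₙ − Φ((x−x̄)/s)| with a
  seeded Monte-Carlo null distribution of D at the same n (default 10 000
  replicates; the null table is cached per (n, reps, seed)). The p-value
  is (1 + #exceedances)/(reps + 1). Constant input is an error.
* **Friedman**: within-block average ranks with ties;
  χ²_F = [12/(nk(k+1))] Σ R_j² − 3n(k+1), divided by the tie-correction
  factor 1 − Σ(t³−t)/(nk(k²−1)); df = k−1. The p-value is the upper-tail
  χ² probability by default; `p_method="exact"` enumerates all (k!)ⁿ
  within-block orderings (used for very small matrices, where the χ²
  approximation is visibly off).
* **Nemenyi all-pairs**: q = |R̄ᵢ − R̄ⱼ| / sqrt(k(k+1)/(12n)) referred to
  the studentized range distribution with k groups and infinite df;
  symmetric matrix with unit diagonal.

**Top-gene selection.** Genes are ranked by upstream motif count; with G
genes and fraction q (default 0.05), m = ⌈qG⌉ and the threshold c is the
count of the m-th gene; every gene with count ≥ c is returned. The ceiling
guarantees at least 5 % inclusion before ties, and tie inclusion makes the
set a superset of the strict top m.

## Trait-evolution models

All models are multivariate normal x ~ N(μ1, σ²V) on a rooted tree with
branch lengths; C is the MRCA-depth matrix (C_ij = depth of the most
recent common ancestor, C_ii = tip depth).

* **BM**: V = C.
* **Pagel's λ** (λ ∈ [0, 1]): V_ij = λC_ij off-diagonal, V_ii = C_ii.
* **OU**, fixed root, α > 0, ultrametric tree required:
  V_ij = (1/2α) e^{−α(tᵢ+tⱼ−2t_a)} (1 − e^{−2αt_a}).
* **EB**, r ≤ 0, ultrametric tree required: V_ij = (e^{r t_a} − 1)/r,
  → t_a as r → 0.

σ² scales V at likelihood time. μ̂ = (1ᵀV⁻¹x)/(1ᵀV⁻¹1) and
σ̂² = (x−μ̂1)ᵀV⁻¹(x−μ̂1)/n are profiled analytically; the scalar shape
parameter is maximized by bounded searches started from a 5-segment grid
(endpoints always evaluated, so boundary optima such as λ̂ = 1 are exact).
Bounds: λ ∈ [0, 1]; α ∈ (10⁻⁸/T, 50/T]; r ∈ [ln(10⁻⁵)/T, 0], with T the
tree height. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1), k = 2 for BM and 3
otherwise; ties below 10⁻⁶ go to the fewer-parameter model. A constant
trait vector yields a flagged degenerate fit (σ̂² = 0, unbounded
likelihood) instead of an exception. BM fits are defined from 2 tips
(its closed form needs no more); shape-parameter models need 3 — AICc is
+∞ until n > k+1, which only affects model selection at tiny n.

**Ancestral states (BM).** The estimate at internal node v is the BM
root-state MLE of the tree re-rooted at v, assembled from patristic
distances: (C_v)_ij = (d(v,i)+d(v,j)−d(i,j))/2, â_v =
(1ᵀC_v⁻¹x)/(1ᵀC_v⁻¹1). This equals the GLS conditional mean given the
tips, and is validated against a dense joint-covariance oracle.

## PGLS

For design matrix X (intercept first) and candidate covariance structures
{BM, OU, λ}: at each shape parameter θ, β̂(θ) = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via
Cholesky whitening; the profile log-likelihood uses the ML variance
RSS/n; θ is optimized as above and structures are compared by AICc
(k = #coefficients + 1 + one shape parameter except BM). Standard errors
use the unbiased residual variance RSS/(n−p−1) with p predictors, giving
conventional t-tests with n−p−1 df alongside ML-based AICc. R² = 1 −
RSS(full)/RSS(intercept-only at the same θ̂); adjusted R² =
1 − (1−R²)(n−1)/(n−p−1), which can be negative. EB is not offered as a
PGLS correlation structure.

**Bootstrap.** Parametric: B response vectors are simulated from the
fitted model (Xβ̂ + N(0, σ̂²_ML V(θ̂))), each refitted under the same
covariance structure (re-optimizing θ), and the replicate slopes are
summarized by 2.5/50/97.5 % quantiles. Fully reproducible from the seed.

**Decision rule.** Two traits are called correlated iff the slope p-value
is < 0.05 and adjusted R² > 0.1. Under a β₁ = 0 null with BM residuals
the adjusted-R² gate makes the rule conservative (empirical call rate well
below 5 %; measured by the acceptance script and test suite).

**Trait handling.** Mass-adjusted durations are residuals of OLS
log₁₀(duration) on log₁₀(mass) — the standard allometric adjustment,
chosen because the upstream protocol imports adjusted traits without
defining the formula; precomputed adjusted columns can be supplied
instead. In the CLI, predictors (masses, genome sizes, durations) are
log₁₀-transformed by default (`--no-log10-predictor` disables); densities
are used untransformed. Species lacking complete data for a trait pair
are pruned from the tree (degree-2 nodes merged, branch lengths summed)
before fitting; group-wise analyses (e.g. all / non-passerine / passerine)
are driven by an arbitrary categorical column, not hardcoded taxonomy.

## Synthetic data

The generators define the validation conditions:

* **Genomes** (`sim_genome`, planted-only mode): an i.i.d. background at
  45 % GC (avian-like) is scrubbed by targeted mutation of any
  scanner-valid tract, then payloads are planted with guard flanks that
  block extension, and the sequence is re-verified until the scan equals
  the planted truth exactly. The truth of each plant is the scan of its
  payload in isolation, so cross-class plants (a (TG)n STR that is also a
  Z-DNA tract) are accounted in both classes. Planted-only mode is capped
  at 5 Mb per contig to keep generation fast; larger contigs use oracle
  mode, where the truth is the scan of the emitted sequence.
* **Annotations** (`sim_annotation` / `sim_promoter_dataset`): start
  codons on both strands with pairwise-disjoint upstream windows, and an
  optional per-bin plant plan whose expected region matrix follows
  directly from the plan.
* **Trees** (`sim_yule_tree`): pure-birth simulation — waiting time
  Exp(λk) from k to k+1 lineages plus a final Exp(λn) hang time, so
  E[height] = Σ_{k=2..n} 1/(λk); ultrametric by construction with no
  zero-length terminal branches.
* **Traits** (`sim_trait` / `sim_regression_dataset`): draws from
  N(μ1 or Xβ, σ²V) using the same covariance builders the inference uses,
  with an independent Cholesky path.

Default study conditions (`SimConfig`): 12 species, 0.5-Mb single-contig
genomes, 25 planted Z-DNA and 40 planted STR tracts per genome, 20 genes,
unit-rate Yule tree, BM traits with σ² = 1.

What passing these tests shows — and does not. The synthetic genomes have
i.i.d. composition: no isochores, repeat families, or realistic gap
structure, so planted-genome recovery demonstrates scanner and bookkeeping
correctness, not robustness to compositional artifacts of real genomes.
Trait simulations match the inference model exactly, so parameter-recovery
results demonstrate estimator correctness and calibration, not robustness
to model misspecification. Real analyses additionally inherit assembly and
annotation quality, which no synthetic test covers.

## Numerical choices and limitations

* Likelihoods use dense Cholesky factorizations; problems are comfortably
  fast to a few hundred tips but scale as O(n³) per evaluation.
* Ultrametricity is required for OU/EB with tolerance
  (max depth spread)/height ≤ 10⁻⁶.
* The Lilliefors Monte-Carlo p has resolution 1/(reps+1); the Friedman
  exact method is limited to (k!)ⁿ ≤ 2 × 10⁶ orderings.
* λ̂ has the known downward bias at moderate n; validation bands are set
  at the simulation sizes stated in the test suite (200-tip trees).
* Repair-based genome scrubbing mutates background bases until the scan
  matches truth; it errors after a bounded number of iterations rather
  than looping forever (not observed at the default conditions).
* The problem sizes used by the acceptance script (12 × 0.5 Mb genomes,
  20-species promoter panel, 100–200 simulation replicates at 100–200
  tips) are the package's chosen validation scale: large enough for the
  stated recovery bands, small enough to run on a laptop in minutes.
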
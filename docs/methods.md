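# Methods

This note records the statistical definitions, conventions and design
choices behind `cubkit`, in the order the pipeline applies them.

## CDS filtering

A coding sequence is retained iff it (1) contains only A/C/G/T, (2) has
length ≡ 0 (mod 3), (3) starts with ATG, (4) ends with TAA/TAG/TGA, (5) has
no internal in-frame stop, and (6) is ≥ 300 nt (inclusive). Rules are checked
in that order and a rejected sequence is charged to the *first* failing rule,
which makes the rejection report deterministic; the order itself is a
convention (any order yields the same retained set). Ambiguity codes fail
rule 1 rather than being repaired — the analysis is defined on unambiguous
codons only — and RNA input must be pre-converted (`rna_to_dna`). GenBank
CDS features are spliced and strand-corrected with Biopython's location
machinery; an optional `dedupe_by_gene_name` collapses inverted-repeat
duplicates but is off by default, since published per-genome CDS counts are
raw feature counts.

## Genetic code and counting conventions

The standard code (NCBI table 1) is the default; the bacterial/plastid table
11 has the same degeneracy structure and is selectable. Ser, Leu and Arg are
treated as single six-fold families (the CodonW convention), not 2+4
subfamilies. The "59-codon space" is the sense codons minus ATG (Met) and
TGG (Trp); it hosts the preferred-codon screen and the clustering profiles.

Two counting modes coexist deliberately: GC1/GC2/GC3 are computed over the
whole CDS *including* the terminal stop (switchable), because whole-CDS GC
is the composition convention; all family-based indices (RSCU, RFSC, ENc,
SCUO, MILC) exclude the terminal stop, because stops are not part of the
synonymous-family space. The one exception is the high-frequency screen,
where the three stops form a TER family — genome-level stop-codon usage is a
legitimate three-codon family for that screen — so the genome index table is
built from stop-inclusive counts when TER rows are requested.

## RSCU, RFSC and codon screens

RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij) and RFSC_ij = x_ij / Σ_j x_ij, with
RSCU = RFSC × n_i. Families with zero total count give missing (NaN) values
rather than zeros. Genome-scope tables are computed from *aggregated* codon
counts across filtered genes, not as means of per-gene tables: aggregation
avoids undefined per-gene families and matches how species-level heatmaps
are built; a mean-of-genes mode exists for comparison. A codon is preferred
when RSCU > 1; high-frequency when RFSC > 0.60 or RFSC > 1.5 × (1/n_i) (the
"average frequency of its synonymous codons" is read as the uniform
within-family expectation 1/n_i). "Ends in A/T" is equivalent to "ends in
A/U" on the RNA alphabet.

## ENc

Wright's estimator: per family with n > 1 observed codons,
F̂ = (n Σ p_j² − 1)/(n − 1); F̂ values are averaged within each degeneracy
class k, and ENc = 2 + Σ_k N_k / F̄_k with N_k the number of amino acids of
degeneracy k (9, 1, 5, 3 for k = 2, 3, 4, 6 under the standard code, giving
the 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ form). Families with n ≤ 1 are skipped
(F̂ undefined at n = 1); a class mean ≤ 0 is treated as missing. Missing
classes are filled in: the three-fold class uses (F̄₂ + F̄₄)/2 when both
neighbours exist, otherwise a missing class uses the mean of the available
class means; fills are flagged. The result is clamped to [2, 61] (the
uniform-usage estimator overshoots 61 slightly at finite counts). The
expected curve is ENc\*(S) = 2 + S + 29/(S² + (1−S)²); note its true
maximum sits at S ≈ 0.502, marginally right of 0.5, because of the linear
term.

## PR2 and the neutrality regression

PR2 coordinates are x = G3/(G3+C3), y = A3/(A3+T3) over third positions of
codons whose family has degeneracy exactly 4 (V, P, T, A, G) — the
family-restricted convention; a `family_mode="all"` variant uses every
tallied codon, since the plain-language definition ("the third base of the
codon") is ambiguous. Zero denominators yield missing coordinates rather
than imputed ones. The neutrality fit is ordinary least squares of per-gene
GC12 on GC3 (all filtered genes, no outlier exclusion), with Pearson r and
the two-tailed t-based p-value; GC3 variance of zero makes the slope
missing with a warning.

## Correspondence analysis

Classical CA on the gene × 59 RSCU matrix treated as a nonnegative table
(the "COA on RSCU" mode, which removes amino-acid composition effects;
raw-count CA is available by passing counts instead). The table is scaled to
grand total 1, standardized residuals (P − rcᵀ)/√(r_i c_j) are decomposed by
SVD, principal coordinates are σ-scaled, and inertia fractions are
σ_k²/Σσ². Zero-margin rows/columns are dropped and reported as NaN
coordinates; sign indeterminacy is fixed by making the largest-magnitude
column loading of each axis positive. Four axes are kept by default.

## SCUO and MILC

SCUO: per multi-codon family, O_i = (log n_i − H_i)/log n_i with H_i the
Shannon entropy of within-family frequencies; SCUO is the count-weighted
mean of O_i over observed multi-codon families. It is 0 under uniform usage,
1 under single-codon usage, and base-invariant.

MILC: M_a = 2 Σ_j x_aj ln(f_aj/g_aj) against reference family frequencies
g; MILC = (Σ_a M_a)/L − c with c = Σ_a (n_a − 1)/L over amino acids
observed in the gene. Natural log is fixed (the statistic is not
base-invariant). The default reference is the gene's own genome-aggregate
usage, the "average usage of the sample" at genome scope; a pooled
cross-genome reference is available for multi-genome runs. Reference cells
that are zero where the gene has counts get 0.5 added to every reference
codon of that family (the smallest intervention keeping M_a finite), and
the result is flagged. Genome summaries report the unweighted mean of
per-gene SCUO and MILC (a whole-genome single computation is also possible
by passing aggregate counts).

## Clustering

Species profiles are the 59-dimensional genome-aggregate RSCU vectors;
dissimilarity is the squared Euclidean distance, fed unmodified to
between-groups average linkage (merge the pair with minimal mean
inter-cluster *original* dissimilarity — the SPSS "intergroup linkage"
procedure, equivalent to UPGMA). Ties are broken lexicographically on the
clusters' sorted leaf-label tuples, so the topology is input-order
invariant. Newick export places a node merged at height h at h/2 from the
leaves (ultrametric-style); child order is canonical (lexicographic by leaf
labels) and labels with metacharacters are quoted.

## Synthetic genomes

The generator emulates a chloroplast CDS set: default 57 genes of 100–500
codons (≥ 300 nt), ATG start, uniform stop, amino acids i.i.d. from a
plant-plastome-like composition, and within-family codon distributions
softmax-tilted in two directions — a designated A/T-ending codon per family
up-weighted by exp(bias_theta) (default 0.7, enough to reproduce the
A/T-ending preferred-codon signature typical of plastomes), and G/C-ending
codons by exp(w), where w is solved by bisection so the gene's expected GC3
hits its target (bisection tolerance 1e−4 on expected GC3; targets outside
the achievable range are clamped and flagged — GC3 = 0 is infeasible, for
instance, because Met and Trp force G-ending codons). Per-gene GC3 targets
are drawn uniformly from `gc3_range` (default 0.15–0.45) and, when a
neutrality triple (slope, intercept, noise_sd) is given (default
(0.1, 0.34, 0.02), a selection-dominated regime), each gene also gets a
GC12 target met by exponentially tilting the amino-acid composition; the
two tilts are alternated three times since they interact weakly. All
randomness flows through one seeded generator, so a fixed seed is
byte-reproducible.

What the generator does *not* emulate: real gene-function structure
(ribosomal vs photosynthesis genes), shared ancestry along a phylogeny,
inverted-repeat duplication, context-dependent mutation, or
expression-driven covariation beyond what the GC3/GC12 machinery induces.
Passing tests on synthetic data therefore validate the estimators and the
pipeline plumbing under known sampling distributions — not any biological
claim about real plastomes. Two synthetic regimes differ notably from real
chloroplast data: MILC genome means are small (~0.05) because genes are
exchangeable draws around the genome average, whereas real plastome genes
are functionally heterogeneous (published genome MILC values sit near 0.55);
and independent-seed genomes are farther apart in RSCU space than real
congeneric species.

## Numerical conventions and degenerate inputs

Fractions are exact ratios of integer tallies; 0·log 0 ≡ 0; undefined
quantities are NaN plus a warning, never silently imputed (the one
documented exception: NaN RSCU entries become 0 inside the CA and distance
matrices, with a warning). Summary tables round to 2 decimal places
(percentages and indices) and 4 for regression slopes. Statistical
primitives (OLS, Pearson r, SVD) delegate to scipy/numpy; scipy's
hierarchical clustering is used only as a test oracle because it does not
expose the deterministic tie-break.

## Problem sizes used in checks

The automated checks run at desk scale: 57-gene genomes, six-genome
comparative studies, 20-replicate recovery experiments, uniform-usage
calibrations at 10⁴ codons, and an RSCU-uniformity check at ~10⁵ pooled
codons. These sizes put Monte-Carlo error well inside the asserted
tolerances (e.g. mean slope recovery ±0.05 at per-replicate sd ≈ 0.03).
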
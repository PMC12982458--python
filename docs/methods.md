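# Methods and design notes

## The marker model

An MNP locus is a 200–300 bp amplicon containing a cluster of linked
SNPs; its genotype in one accession is the **set of distinct amplicon
allele sequences** the accession carries. Two accessions share a
genotype at a locus only when these sequence sets are identical. The
toolkit deliberately avoids a diploid model: ploidy in many target crops
is uncharacterized, so an accession carries 1..k allele sequences per
locus (k = `alleles_per_accession`, default 2, configurable upward). At
the *screening* stage, by contrast, the input is a conventional
multi-sample short-read SNP callset, and genotypes there are ordinary
diploid-coded calls (hom-ref / het / hom-alt / missing) — that is what
upstream variant callers emit regardless of true ploidy.

## SNP filtering

A variant is retained when all of the following hold, evaluated in the
fixed order contig-length → MAF → call rate → HWE → CNV (a rejected
record is tallied under its first failing rule, which makes rejection
reports reproducible):

* contig length > 250 bp (`min_contig_length_bp` = 251) — shorter
  contigs cannot host an amplicon;
* minor allele frequency ≥ 0.05, counting two allele observations per
  non-missing call; missing calls are excluded, never imputed;
* call rate ≥ 0.80;
* exact conditional Hardy–Weinberg test p ≥ 0.01. The test conditions
  on the allele totals: with `n` individuals and `na` minor-allele
  copies, P(h heterozygotes) ∝ C(n,h)·C(n−h,(na−h)/2)·2^h over the
  parity-matched support, and the p-value sums outcomes no more likely
  than the observed one (standard two-sided, not mid-p). The
  implementation is exact integer arithmetic; the test suite checks it
  against an independent Fraction-factorial enumeration for every table
  with n ≤ 50 at 1e-12.
* no copy-number signal. No standard formula exists for this rule, so a
  documented stand-in heuristic is used: flag when locus mean depth
  exceeds `cnv_depth_ratio_max` (2.0) times the cohort median locus
  depth, or when more than `cnv_sample_fraction_max` (0.10) of samples
  exceed that ratio against their own median depth. Without depth
  information the rule is disabled with a warning.

Filtering is idempotent and monotone in its thresholds (property
tested).

## Window screening and panel assembly

Every window position (window 300 bp, step 1 bp) is evaluated; a window
qualifies when it contains **more than three** SNPs (strict inequality)
and its discriminative power reaches 0.2. The window genotype label of a
sample is the concatenated per-SNP symbol string (ref base, alt base, or
IUPAC ambiguity code for an unphased het); a sample missing any
constituent call has a missing label. DP is the exact unordered-pair
discordance

    DP = 1 − Σᵢ C(nᵢ,2) / C(n,2)

over non-missing labels (sampling-with-replacement forms like
1 − Σ fᵢ² were considered and rejected in favour of the exact pair
count; the closed form is verified against pair enumeration by property
test). The scan is implemented as a sweep over the O(#SNPs) start
intervals on which the covered SNP subset is constant, and is
exhaustively equal to evaluating every start independently.

A 1-bp step yields hundreds of near-identical qualifying windows per
region, so overlapping qualifying windows are merged into runs and one
representative window is kept per run. The representative is chosen by
**(SNP count, then DP, then leftmost start)**: within a run, DP
differences are dominated by missing-call noise, and preferring a
higher-DP subset window would leave the remaining cluster SNPs inside
the primer flank — either invalidating the amplicon or shifting its
bounds away from the designed locus. If the top-ranked window's amplicon
is infeasible the next-ranked window is tried before the run is dropped.

The amplicon is the tightest span containing the window's SNPs plus a
20-bp SNP-free flank on each side (`flank_clear_bp`, a feasibility proxy
for primer landing — no thermodynamic design is attempted), widened
symmetrically to the 200 bp minimum, clamped to the contig, and
validated to 200–300 bp with no foreign SNP in the flanks. Panel
selection is greedy in descending (DP, SNP count) order, skipping
candidates within 10 kb (start-to-start) of a selected locus on the same
contig, stopping at the target size (default 505). Coordinates are
0-based half-open everywhere except the VCF boundary and human-readable
reports.

## Amplicon genotyping

Reads reach loci either via the identity tag in the read name
(`accession|locus|index`, the simulator contract) or by exact,
orientation-aware matching of both terminal 20-bp flanks of the locus's
reference amplicon; no alignment is performed, keeping the stage
deterministic and dependency-free.

Error collapsing tallies exact sequences, then folds any sequence whose
count fraction is below 5% and which lies within
`error_collapse_max_mismatch` substitutions of a sequence at least
`error_collapse_ratio` times more abundant, processing rares in
descending count (ties lexicographic) and iterating to a fixpoint so a
growing centroid can absorb further fragments. Defaults are mismatch
radius 2 and skew 5: at 200–300 bp and a per-base error of a few per
mille, the mean errors per read exceeds 1, so a large share of reads
carry one or two substitutions; a radius of 1 (or a 10× skew) strands a
true allele's error cloud whenever its exact-copy count is modest, and
allele-set recovery at depth ~100 drops below the intended ≥99%.
Because only sub-5% sequences are ever folded, a genuine minor allele
(≥ `min_allele_fraction` = 20%) can never be absorbed.

Allele calling: depth < 20 → no-call; otherwise alleles are the collapsed
sequences with fraction ≥ 0.2, capped at `max_alleles_per_locus`
(default 2; exceeding the cap logs a warning rather than failing, since
ploidy is not assumed). These thresholds are this package's own
defaults — the analysis software used in marker-system studies of this
kind is proprietary and its internals unpublished — and all are surfaced
in configuration and reports. Raising `min_allele_fraction` can only
shrink allele sets (property tested). Per-sample summaries report mean
locus coverage over *detected* loci.

## Identification statistics

* **GS**: identical-allele-set loci divided by the full panel size
  (default) — the "core panel" denominator — or by the count of loci
  called in both accessions (`shared_called`); the differentiation ratio
  is differential / compared regardless of mode.
* **Reproducibility** compares two independent runs over accession ×
  locus cells called in both; **accuracy** = 1 − (1 − r)/2, the
  convention that exactly one member of a discordant run pair is wrong.
  Fractions are reported unrounded; formatting belongs to report edges.
* **PIC** uses the Botstein form 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ², with allele
  frequencies counted ploidy-agnostically: each accession's called
  allele set contributes one observation per member allele. PIC never
  exceeds expected heterozygosity (property tested).
* **Molecular ID**: per locus, distinct cohort alleles are indexed in
  lexicographic order; the canonical string is the locus-ordered,
  semicolon-separated list of sorted allele-index tuples with `.` for
  no-calls. The canonical string is the normative identifier; the
  16-hex-digit SHA-256 prefix is a convenience handle. Alleles absent
  from the registry extend it deterministically with a warning.
* Summary moments use the sample (n−1) standard deviation.

## Cohort structure

Distances are D = 1 − GS in the configured denominator mode. UPGMA
merges the closest pair (ties: lexicographically smallest leaf-label
pair) with size-weighted average linkage; node height is half the merge
distance, so the tree is ultrametric by construction; Newick branch
lengths are parent-minus-child heights. The "ordination" of the GS
matrix is implemented as PCoA (classical MDS: double-center −½D²,
eigendecompose, scale eigenvectors by √λ), the defensible reading of
running a principal-component view on pairwise similarities; negative
eigenvalues are truncated with a warning and axis signs are fixed by
making the largest-magnitude loading positive. A plain PCA on a one-hot
allele-membership matrix is available as an alternative view
(`pca_onehot`), since either reading of "PCA on the genotyping results"
is defensible.

## The synthetic cohort generator

The generator emulates the study conditions of a marker-design project:
defaults are a 30-accession cohort in 3 founder clusters, 505 planted
MNP loci on 520 contigs of 4 kb, 12 founder haplotypes, background SNP
rate 5e-4/bp, 2% missing screening calls, per-base read error 1e-3 and
1% locus dropout. Planted loci receive 6–10 SNPs spanning 170–230 bp in
linkage across founder haplotypes, so their amplicons (SNP span plus
flanks, computed with the *same* arithmetic as the screening stage) fall
in the 200–300 bp band; accessions draw k founder haplotypes per locus
from cluster-specific Dirichlet weights (`cluster_founder_alpha`,
default 2.0 — mild substructure; small values give strongly diverged
clusters for clade tests). Background SNPs are excluded from a 650-bp
zone around each planted window so that no sliding window can chain a
planted locus with background variation. Read depth is Poisson with
mean 50 by default — allele calling needs ≥20×, so nothing downstream
depends on the multi-thousand-fold coverage a production run would use;
a negative-binomial option (`depth_dispersion`) exists because real
per-locus depth dispersion is assay-dependent, and its default is
deliberately unset. Dropout is independent Bernoulli per locus × sample
with per-accession overrides (emulating low-panel-compatibility
samples whose detection rates sit near 1 − rate). The error model is
substitution-only: amplicons are short and MNP alleles are SNP
haplotypes; no PCR chimeras, primer competition or indels are
simulated — so passing tests say nothing about indel robustness or
amplification bias in real data. Reads are emitted pre-assigned to loci
via their names; flank-based assignment exercises the mapping-free
alternative. Every output byte (FASTA, VCF, FASTQ, truth JSON) is fixed
by `rng_seed`.

## Numerical and scale choices

* Exact integer arithmetic in the HWE test; float comparisons in tests
  at 1e-12 absolute.
* All tie-breaks (window ranking, allele ordering, UPGMA pair choice,
  molecular-ID indexing) are total orders, so identical seeds give
  byte-identical outputs end to end (manifest digests verify this).
* Test and demo problem sizes are deliberately small — tens of loci,
  10–30 accessions, depth ~100 — chosen so the full suite runs in
  seconds while still exercising every code path at realistic parameter
  values; the acceptance checks state their sizes inline (e.g. the
  planted-recovery check uses 60 loci across 60 × 6 kb contigs with 30
  accessions).
* `run_pipeline` is file-mediated: each stage reads its inputs from the
  run directory, so stages can be re-run or resumed independently and a
  missing intermediate aborts with a structured error before work
  starts.

## Known limitations

* Primer design is approximated by the SNP-free-flank rule; no melting
  temperature, dimer or multiplex-compatibility checks.
* The CNV filter is a depth heuristic, not a CNV caller.
* GS uses allele-set identity only; partial allele sharing at a locus
  contributes nothing.
* The screening DP definition (exact pair discordance) is one of several
  in use; panels screened with a sampling-with-replacement definition
  would differ near the 0.2 admission boundary.
* Demo detection rates sit near 0.83, not 1.0: reads are synthesized
  from truth amplicons while the screened panel can shift bounds when an
  edge SNP fails a filter — the realistic signature of imperfect panel
  compatibility, not a genotyping defect (tag-mode genotyping against
  the truth panel recovers fingerprints exactly).
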
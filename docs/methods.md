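# Methods

`sexmarker` implements a desk-scale pipeline for discovering PCR-based
sex markers in species with an XY sex-chromosome system, modelled on the
strategy used to develop the *CsPDS5*-CAPS assay for *Cannabis sativa*:
infer Y-linked transcripts from male/female expression data without a Y
assembly, pair them with their X-chromosome gametologs, and turn an
allele-differential restriction site into a CAPS genotyping assay with a
single common primer pair.

## Pipeline model and assumptions

The pipeline assumes a diploid XY system in which females (and
monoecious individuals, which carry two X chromosomes) are XX. Y-linked
genes are then expected to be expressed in males only, and their X and Y
copies (gametologs) to have diverged in sequence since recombination
stopped.

1. **k-mer sieve.** Each sample contributes an exact presence/absence
   set of its length-*k* substrings (default *k* = 16). A k-mer is
   *male-specific* when it occurs in **every** male sample and **no**
   female sample (intersection over males minus union over females).
   Transcripts carrying at least one male-specific k-mer survive.
   Profiles are plain in-memory sets: the all/none predicate needs
   exactness and candidate transcriptomes are small, so probabilistic
   structures would buy nothing. k-mers containing `N` are dropped
   (expansion would inflate the sets; `N` is missing data). By default
   k-mers are stranded (transcripts are oriented mRNA); a `canonical`
   flag folds in reverse complements for unstranded input.

2. **Expression filters.** Two layers over a transcripts × samples TPM
   matrix. The *male-bias test* computes
   `log2FC = log2((mean_male + c) / (mean_female + c))` with pseudocount
   c = 1 (females of Y genes have mean 0, so an unregularised ratio is
   undefined), a two-sided Wilcoxon rank-sum p-value per transcript, and
   Benjamini–Hochberg FDR across all tested transcripts; the pass flag
   is `log2FC >= 1` and `FDR <= 0.05`. The rank-sum test was chosen for
   distribution-freeness at small n; a Welch t-test can be swapped in
   via `test="ttest"`. The *strict filter* retains transcripts with mean
   male TPM > 10 and TPM exactly 0 in every female sample — the
   signature of a gene physically absent from XX genomes. "Average" is
   the arithmetic mean.

   *Small-cohort power.* An exact two-sided rank-sum p-value cannot go
   below `2 / C(n_m + n_f, n_m)` — at 3 vs 3 samples that floor is 0.1,
   above any usual FDR threshold, whatever the effect size. The
   orchestrated pipeline therefore gates on the strict filter plus
   log2FC, and adds the FDR gate only when the design is powered for it
   (floor ≤ threshold). The powered/unpowered decision depends only on
   the sample sizes, never on the observed data; the statistics are
   reported either way.

3. **Gametolog pairing.** Each surviving transcript is searched against
   the supplied X loci by local affine-gap alignment (match +2,
   mismatch −3, gap open −5, gap extend −2; a gap of length L costs
   `open + (L−1)·extend`). The best hit is accepted when identity ≥ 0.90
   and query coverage ≥ 0.90 with no runner-up within 0.9× of the best
   score; a perfect full-length hit is *rejected* (a sequence identical
   to the female genome is not Y-diverged), and a strong runner-up marks
   the candidate ambiguous (paralog/autosome risk). The identity floor
   deliberately sits below the ~95% identity of a 5%-diverged gametolog
   pair: a tighter floor would reject true pairs for exactly the
   divergence that makes them useful markers. Accepted pairs are
   globally aligned and ranked by divergence = (substitution + indel
   columns) / alignment length, each indel column counted once
   (a gap-length-weighted variant was considered and rejected as the
   default because a single long indel would dominate the ranking).
   Alignment is deterministic: among co-optimal alignments the first in
   the aligner's canonical enumeration order is used.

4. **CAPS design.** On each X/Y alignment (optionally with extra
   cultivar rows), every enzyme in the table is scanned on both strands
   of both alleles; a site counts as *differential* only if the other
   allele has no match within the homologous alignment columns extended
   by |recognition| − 1 on each side — this prevents a site merely
   shifted by an indel from masquerading as allele-specific. Conserved
   flank windows (length 18–25, ≤ 3 substitution columns, zero indel
   columns, within 400 columns of the site) host the common primers:
   the column-wise consensus over all rows with polymorphic columns
   encoded as minimal IUPAC codes, reverse primer reverse-complemented,
   3'-terminal base forced non-degenerate by sliding the window, total
   degeneracy capped at 16. Tm is estimated by the Wallace rule
   (2(A+T) + 4(G+C)) averaged over degenerate expansions — crude, but
   only used for ranking and window extension (floor 48 °C, cap 72 °C).
   Allele probes (15–25 nt) are centred on the diagnostic columns of the
   site, one matching each allele exactly. Candidates are ranked by a
   deterministic score favouring a larger minimum gap between predicted
   XY bands (gel resolvability), lower primer degeneracy and shorter
   amplicons.

5. **In-silico assay.** PCR reports every template interval where the
   forward primer matches the plus strand and the reverse primer the
   minus strand downstream, zero mismatches under IUPAC expansion
   (the published assay folded all known SNPs into the primers as
   degenerate bases, implying exact-match intent). Digestion cuts at
   every recognition match on either strand at top-strand coordinate
   `site_start + cut_offset`; fragment lengths are the distances between
   successive cuts, and always sum to the amplicon length. Genotype
   patterns are XX = digest(X amplicon), XY = multiset union of both
   digests; gel calls match observed band multisets against these within
   a tolerance (default 10 bp, mimicking agarose resolution). TaqMan
   simulation is endpoint-only: a dye fires iff its probe matches an
   allele present in the genotype (VIC = X/uncut allele, FAM = Y/cut
   allele); no-template controls are dark. Digestion is treated as
   complete, and heteroduplex or partial-digestion artifacts are not
   modelled.

## Coordinate and cut conventions

All coordinates are 0-based half-open internally and in machine-readable
output (`candidates.json`, truth files), so downstream code can compare
coordinates without conversion. `cut_offset` is the top-strand cut position from the start of
the recognition sequence (EcoRI `G^AATTC` = 1). Band sizes derive from
top-strand cut coordinates, ignoring sticky-end overhang asymmetry,
since gel bands are read as double-stranded lengths; as a consequence,
reverse-complementing a template shifts predicted fragment bounds of a
sticky-end cutter by up to the overhang length (exact invariance holds
for blunt, centre-cutting palindromes). `N` in a template never
satisfies a recognition or primer match (conservative: no phantom sites
from missing data). Palindromic enzymes are scanned on one strand only.

## Synthetic data

The generators produce the study conditions every test runs under. A
gametolog pair starts from a random uniform ACGT ancestor (default
1000 bp) split into X and Y copies: one concrete realisation of the
enzyme's recognition sequence is planted in Y at the centre and ablated
in X by 3 substitutions at the homologous position (matching the few-bp
X/Y difference that motivates allele probes), two 25-column windows
60 columns either side of the site are kept mutation-free so a common
primer pair always exists, and every other position mutates in one
branch with probability equal to the requested divergence (default
0.05 — a plausible value for gametologs in an old stratum).
Substitutions only by default, keeping the truth alignment gap-free and
coordinates stable. Generation is rejection-sampled until the planted
site is the unique differential site for its enzyme, and is a pure
function of the seed.

A cohort (default 3 males, 3 females, 20 autosomal decoys, per-sample
SNP rate 0.001) gives females the X transcript plus decoys and males
additionally the Y transcript. TPM values are log-normal (σ = 0.4)
around a male mean of 50 for the Y transcript (exactly 0 in females)
and 20 for decoys; the first decoy is male-biased but female-nonzero,
so it passes the bias test yet must be removed by the strict filter.

What the generator does **not** emulate: read-level sequencing error and
coverage variation, assembly fragmentation and chimerism, paralogous
gene families, repeat/retrotransposon context, indel divergence (off by
default) and cross-cultivar population structure. Passing the planted
recovery tests therefore shows the pipeline logic is correct under its
own assumptions, not that real RNA-seq cohorts of this size would yield
a unique marker.

## Packaged example data

The packaged worked example (`sexmarker.fixtures`) carries the published
*CsPDS5* assay oligos — the degenerate CAPS primer pair (degeneracies 4
and 2), the TaqMan primer pair (4 and 16) and the two allele probes —
together with **synthetic** X/Y loci (`synthetic_*` files): random
719/719 bp backbones in which the published footprints and the
Y-specific EcoRI site are planted so that the assay arithmetic matches
the published marker exactly (one 419 bp amplicon per allele; Y digest
157 + 262 bp; X uncut; TaqMan amplicon ≈ 200 bp containing the site).
The real loci are not redistributed. Likewise `synthetic_s1` (25
transcript records) and `synthetic_s2` (6 candidate-gene alignments)
mimic only the shape of the original candidate sets. The fixture
builder (`scripts/make_synthetic_fixtures.py`) verifies all of this at
generation time with the package's own scanner plus brute-force checks.

## Problem sizes

Default test and acceptance runs use 1000 bp gametologs, 22-transcript
cohorts (1 Y gene + 1 X copy + 20 decoys), 3 + 3 samples and 3 seeds;
alignment-oracle checks use 200 random pairs up to 200 bp and digestion
checks 1000 random amplicons. These sizes exercise every code path with
exact brute-force cross-checks while keeping a full run to minutes on
one CPU.

## Limitations

* The 379 → 25 candidate reduction reported for real *C. sativa*
  RNA-seq, and all greenhouse validation counts (312 'FINOLA' samples,
  137 F2 individuals, > 500 samples overall), are wet-lab results on
  data this package does not ship; they are out of desk scale and are
  not recomputed here. The packaged acceptance checks reproduce the
  assay arithmetic and pipeline logic, not those cohort-scale numbers.
* Read mapping and transcript quantification are upstream of this
  package: inputs are candidate transcript FASTA and a TPM table.
* No dCAPS design, primer thermodynamics beyond the Wallace estimate,
  secondary-structure/dimer checks, or multiplexing.
* TaqMan simulation is presence/absence of signal; no fluorescence
  kinetics or Ct values.
* The rank-sum option is unpowered below ~4 samples per sex (see above);
  conclusions from 3 + 3 cohorts rest on the strict zero-female filter.
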
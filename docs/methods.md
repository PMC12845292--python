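# Methods

This note documents the models, parameters and numerical choices behind
`ferromir`, and what its synthetic-data validation does and does not show.

## Study design emulated

The package targets a two-organ (leaf L, root R), four-treatment factorial:
Fe-sufficient control (CK), four days of Fe deficiency (FeD), and six hours of
recovery by root exposure (RE) or foliar spray (Fol). All contrasts are
(test, reference) pairs within one organ; deficiency is contrasted against CK,
resupply against FeD by default (a `resupply_baseline="CK"` switch exists,
since both contrast families are meaningful in this design).

## IDE1/IDE2 element matching

IDE1 is modeled as two consecutive 9-bp consensus modules (18 bp), IDE2 as
three (27 bp) whose middle module is the functional core. The shipped
consensus defaults (`ATCAAGCATGCTTCTTGC`; `TTGAACGGCAAGTTTCACGCTGTCACT`) are
externally sourced from the literature that characterized these elements in
barley promoters and are plain constructor arguments, not constants.

Match criteria:

* IDE1: every module ≥ `min_matches_per_module` (default 6 of 9, i.e. 66.7 %).
* IDE2: core ≥ 6/9, total ≥ `ide2_min_total` (default 14 of 27), and a flank
  requirement with two readings. The default **positional** reading pins the
  six core-proximal positions of each flank (variation is free only in the
  three core-distal positions); the **count** reading (`flank_rule="count"`)
  asks for any ≥ 6/9 in each flank. The positional reading makes the 14/27
  floor mathematically slack (its minimum attainable total is 18), so that
  floor only binds when module thresholds are relaxed — a consequence of the
  rule hierarchy itself, preserved as specified.

Candidates may be up to `max_gaps` (default 1) bases shorter than the
consensus; a gap is a deletion that counts as a mismatch in its module. A
candidate is accepted when **any** gap placement satisfies the criteria; the
reported placement maximizes total matches with ties to the leftmost gap.
(Choosing the max-total placement *first* and then testing it can reject
candidates for which a slightly lower-total placement passes; the
any-placement rule is the one that agrees with exhaustive enumeration.)

Scanning slides every window start, both strands (switchable), and every
allowed gap count over the anchor-proximal `window` bp (default 2000, the
span within which compact plant pri-miRNA core promoters typically lie).
Overlapping accepted windows are collapsed **per strand** to the hit with
maximal total matches (ties → fewer gaps → most upstream); the strands are
distinct match spaces, and cross-strand suppression would let a chance
reverse-complement reading mask a genuine forward element (observed on
synthetic data). Windows containing N never match.

Coordinates: the anchor (offset 0) is the 3′ end of the supplied sequence;
offsets are negative, 1-based, inclusive; local [s, e) in a window of length L
maps to −(L−s) … −(L−e+1). An 18-mer at [1645, 1663) in 2000 bp is therefore
−355/−338. Published tables for such elements often print end = start + motif
length (one position more); `hits_to_table(table1_style=True)` reproduces that
convention.

**Registration ambiguity.** A gapless element planted with many substitutions
(3 per module) can be outranked, under a gap-allowing scan, by a gapped
re-reading of the same locus that matches strictly more consensus positions.
This is inherent to degenerate matching, not a scanner defect; recovery tests
therefore assert exact-offset recovery under the gap budget the elements were
planted with.

## Differential expression

* **miRNA path** (sparse libraries): replicate counts are pooled per group and
  compared with an exact binomial test — under H0 the count in library b out
  of the pooled total is Binomial(x_a + x_b, N_b/(N_a + N_b)); the two-sided p
  doubles the smaller tail, capped at 1, with p = 1 when both counts are zero.
  Calls: raw p ≤ 0.05 and |log₂FC| ≥ 0.5, both inclusive.
* **mRNA path**: a per-feature negative-binomial Wald test on normalized
  counts. The NB is mean/dispersion parameterized (var = μ + φμ²). φ is
  estimated once per contrast by a ratio-of-sums moment estimator pooled over
  all features and both groups, φ̂ = Σ(s² − c·μ̂)/Σ(μ̂² − s²/n) with c the
  Poisson-part scale on the normalized axis; per-feature moment estimates at
  2–3 replicates are far too noisy to calibrate the test (they inflate the
  type-I rate well above nominal). The Wald statistic is the pseudocounted
  log₂ fold-change over its delta-method standard error; two-sided normal p,
  BH-adjusted, called at q ≤ 0.05 and |log₂FC| ≥ 1.
* **Normalization**: counts-per-million by default. Median-of-ratios size
  factors are available for the mRNA path (`norm="median-of-ratios"`) and are
  the right choice when expression changes are heavy and asymmetric: any pure
  library-size scaling absorbs part of a one-sided shift by construction
  (composition bias). Simulations that measure effect-size recovery plant
  balanced up/down effects — mirroring the roughly balanced up/down calls such
  experiments report — and use median-of-ratios.
* **Fold-changes**: log₂((mean_b + 1)/(mean_a + 1)) on the normalized scale;
  the pseudocount of 1 CPM guards zeros.
* **Fe-responsive sets**: pattern A = up(FeD vs CK) ∩ down(RE vs FeD) ∩
  down(Fol vs FeD); pattern B mirror; the pooled "changed after resupply" sets
  are unions over the two routes. Pure set algebra, order-invariant.

Validated behavior (all recomputed by the test suite and
`scripts/acceptance.py`): type-I fraction at p ≤ 0.05 within [0.03, 0.07] on a
2000-feature null (NB φ = 0.1, 3 replicates, baseline mean 500); ≥ 95 % power
at planted |log₂FC| = 2; mean estimated lfc within 0.1 of a planted ±1;
empirical false-discovery proportion ≤ 0.10 under BH at 0.05.

## Target-site scoring

A miRNA (5′→3′) is aligned antiparallel to transcript windows. Column
penalties: Watson–Crick 0, G:U wobble 0.5, mismatch 1, gap 2, each doubled in
the weight region (miRNA positions 2–13), reflecting the premium plant
cleavage-guided miRNAs place on 5′ pairing. A gap carries the 1-based miRNA
position it interrupts (deleted site base: the unpaired miRNA base; inserted
site base: the next miRNA base). U/T are interchangeable on input.

The search is exhaustive: for the default single-gap budget, all gapless
offsets plus every single-deletion and single-insertion split are scored with
vectorized prefix/suffix sums of the column-penalty matrix (exact, ~0.5 ms per
21-nt × 300-nt pair); larger gap budgets fall back to full recursive
enumeration, practical only for short sequences. Ties go to the 5′-most site
on the transcript. The cutoff is **inclusive** at 2.5 — sites at exactly 2.5
are retained, consistent with reporting modules at that boundary score.

## Regulatory modules

A module is a (miRNA, target, organ, contrast) tuple passing four predicates:
(1) ≥ 1 IDE1 hit in the miRNA promoter; (2) a predicted target site at score
≤ 2.5; (3) the miRNA differentially expressed in the contrast; (4) the target
differentially expressed with the opposite sign. The strict mode requires the
target's own call; a relaxed mode (`require_target_significant=False`) accepts
an opposite-signed fold-change without significance, for targets that respond
below the calling threshold. Organ membership of a miRNA is derived from where
it is differentially expressed, never hard-coded. Target hits referencing
features absent from the DE universe are skipped with a warning.

Enrichment is the one-sided hypergeometric tail on term/sample overlaps within
a user-supplied universe, BH-corrected across terms; annotation content is out
of scope.

## Physiology

* Fv/Fm = (Fm − F0)/Fm and Y(II) = (Fm′ − Fs)/Fm′; both reject non-positive
  maxima and are scale-invariant (instrument units cancel).
* Chlorosis: HSV conversion, foreground = largest connected component with
  saturation > 0.15 and value > 0.1 whose centroid lies in the central 50 % of
  the frame (the central leaflet); < 5000 px → `insufficient-roi`. The hue
  statistic is the circular mean (wrap-around safe); the verdict is chlorotic
  when the mean hue lands inside [55°, 70°] **and** sits > 10° from the
  reference hue — the destination-band reading of "shift into"; the
  direction-of-shift reading was the open alternative. White-balance
  correction is out of scope; the reference hue is an explicit input.
* Correlation PCA standardizes variables to unit variance (ddof = 1) and
  eigendecomposes the correlation matrix, so eigenvalues sum to the number of
  retained variables and eigenvalue = fraction × n_variables — the identity
  `eigenvalue_from_fraction` exposes (a component explaining 45.26 % of 12
  variables has eigenvalue 5.4312). Zero-variance variables are dropped with a
  warning; component signs are fixed by making each loading vector's
  largest-magnitude entry positive.
* ANOSIM: R = (mean between-group rank − mean within-group rank)/(M/2) over
  the M = n(n−1)/2 ranked pairwise distances (Euclidean on standardized data
  by default; any distance matrix accepted; rank-based, hence invariant to
  monotone transforms). When the number of distinct labelings is ≤ the
  requested permutations the null is enumerated exhaustively and
  p = #{R* ≥ R}/#labelings; otherwise p = (1 + #{R* ≥ R})/(1 + permutations).

## Synthetic data

All generators draw from substreams of one integer seed (one stream per
output type), so outputs are bit-reproducible and independent. Defaults encode
the emulated study: 8 groups × 3 replicates (a conventional replicate count
for designs reported as means ± SD), NB counts at baseline mean 500 with
φ = 0.1 (var = μ + φμ²; φ = 0 degenerates to Poisson — the generator's index
of dispersion is within [0.9, 1.1] there and above 1.5 at φ = 0.5), uniform
i.i.d. ACGT promoter background (maximal, unstructured false-positive
pressure), 2000-bp promoters, effects expressed as per-group log₂ offsets so
any contrast's true lfc is the offset difference. Planted motifs are consensus
copies with exact per-module substitution counts and optional deletions
(recorded by consensus position, matching the "_" notation used for published
gapped variants); planted duplex edits map one-to-one onto penalty columns so
the true score is known arithmetic. Leaf images are discrete central disks of
exact pixel count and hue over a low-saturation background; physiology tables
are truncated-Gaussian draws around configured means — the defaults reproduce
the study's narrative values (control Fv/Fm 0.78, deficient 0.74, recovered
0.76; root Fe −19 %, leaf Fe −8 % under deficiency).

**What passing tests show — and not.** The synthetic backgrounds are
memoryless and the planted effects clean, so recovery rates here bound what
structured genomes (repeats, CpG/AT skew, homologous promoter families),
overdispersed real libraries, batch effects and partial-complementarity
biology would give. The end-to-end module-recovery scenario (3 true modules,
200 decoy transcripts, 5 decoy miRNAs, partial-evidence decoys) validates the
evidence logic, not genome-scale specificity.

## Problem sizes used in validation

Motif oracle equivalence: 10⁵ candidates (70 % uniform random, 30 %
near-consensus to populate the accept boundary). Planted recovery: 60
elements. DE calibration: 2000-feature matrices, 20 repetitions for the FDR
estimate (10 in the acceptance script). Target-scoring oracle: full recursive
enumeration at miRNA ≤ 10 nt, transcript ≤ 30 nt. These sizes give stable
Monte-Carlo estimates (binomial SE of the type-I rate at n = 2000 is ~0.005)
while keeping the whole suite in the low minutes on one CPU.

## Known limitations

* The exact binomial miRNA test assumes pooled counts are binomially
  distributed given totals — it ignores biological replicate variance and is
  anticonservative for highly dispersed features; it is the standard choice
  for sparse small-RNA libraries, not a replacement for replicate-aware models.
* The NB Wald test uses one pooled dispersion per contrast — no per-feature
  shrinkage, no trend on the mean, no multi-factor designs.
* The penalty scheme is a documented approximation in the style of plant
  target predictors; it does not reproduce any specific external tool's
  scores on real transcriptomes, and the validated cutoff semantics (score
  ≤ 2.5) are the contribution, not the constants.
* Promoter scanning is window-exhaustive but genome-naive: no annotation
  lookup, no PWM scoring, no conservation filtering.
* Chlorosis scoring presumes a color-managed image; the segmentation
  thresholds are tuned for the synthetic images and exposed in the API.
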
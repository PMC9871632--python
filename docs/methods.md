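# Methods

## Scope and data model

The toolkit operates on a samples × markers matrix of ALT-allele dosages
{0, 1, 2} with a reserved missing sentinel; half-missing genotype calls
(`0/.`) are treated as missing, matching call-rate semantics. Coordinates
are 1-based inclusive everywhere internally (the VCF convention); only the
BED export converts to 0-based half-open. Dosage counts ALT alleles as
labeled in the source VCF — no TOP/BOT re-strandization is attempted, which
is safe because every downstream statistic here is invariant to swapping
the allele labels (p ↔ 1 − p).

## Marker statistics

For ALT frequency p estimated as (Σ dosage)/(2 × called genotypes) over
non-missing calls:

- He = 2p(1 − p), the plug-in Nei gene diversity. The small-sample
  correction ×n/(n−1) is available behind an argument but is not the
  default: the panel-summary ranges users compare against are plug-in
  values. Per-marker GD is defined identically to He (SnpReady convention)
  and dataset GD is the unweighted mean over markers.
- PIC = 1 − (p² + q²) − 2p²q², with ceiling 0.375 at p = 0.5 (prints as
  0.38 at two decimals).
- Ho = fraction of heterozygous calls among non-missing calls.

Markers with zero non-missing calls are excluded from summaries with a
reported count, never silently. Group summaries recompute frequencies
within each group on the same marker set, so group means are comparable.

## The mining cascade

Stages run in a fixed order and each appends an audit record
(in-count, out-count, per-reason drop counts):

1. **Site quality.** call rate ≥ 0.90, MAF ≥ 0.01, biallelic. Both
   thresholds are inclusive (≥): the stated percentages carry no
   strictness, and inclusivity is the conservative reading; both are
   configurable.
2. **Specificity.** The probe left-flank + ref + right-flank (default
   50 + 1 + 50 bp) must occur exactly once in the reference, counting
   forward-strand and reverse-complement occurrences at distinct locations
   (a palindromic self-hit is one location). Matching is exact — no
   mismatch tolerance — which mirrors zero-mismatch unique mapping;
   sensitivity to 1-mismatch near-hits is out of scope. Probes truncated
   below 30 bp by contig edges fail with reason `short_flank`.
3. **Flanking variants.** Any other raw variant (from the full input VCF,
   not just surviving candidates) within ±50 bp disqualifies a candidate;
   both members of a close pair drop. The goal is a clean amplification
   context for targeted assays.
4. **Flanking SSRs.** A marker drops if either flank contains a perfect
   tandem repeat with primitive unit 1–6 bp, tract ≥ 12 bp and ≥ 2 full
   units (MISA-like defaults, configurable). Detection reports maximal
   tracts only; the Fine–Wilf periodicity argument guarantees each tract
   is reported at exactly one (primitive) unit length for tracts ≥ 12 bp.
5. **Exonic restriction.** Only exon-overlapping markers continue;
   unannotated markers are dropped under a separate reason code. Region
   classification uses precedence exon > intron > upstream > downstream >
   intergenic, with strand-aware promoter windows (default 5000 bp — the
   source annotation practice never states a window, so it is exposed as a
   parameter).
6. **Informative subset.** A deterministic greedy maximizer of summed PIC
   under per-chromosome quotas (largest-remainder apportionment
   proportional to candidate counts) and an optional minimum inter-marker
   spacing. The seed only permutes candidates before a stable sort by
   descending PIC, so it resolves exact PIC ties; two "independent
   selection exercises" are two seeds. An exhausted chromosome relaxes its
   quota to the rest with a warning — never a silent shortfall. Greedy
   selection without spacing is provably optimal for this separable
   objective (verified against exhaustive search in tests); spacing makes
   it a heuristic.
7. **LD / redundancy pruning.** Exact-duplicate dosage columns drop first;
   then, for each same-chromosome pair with dosage r² ≥ 0.90, the
   lower-PIC member drops (tie: larger position). The 0.90 default is the
   lower edge of the "high LD" bin. A final trim to the target size
   removes lowest-PIC markers, always from the chromosome currently
   furthest above its proportional share, keeping the panel balanced.

Panel assembly unions two selections keyed by (chrom, pos), records the
source set(s) per locus, collapses shared loci (both counts — with and
without cross-set duplicates — are reported, since the two can genuinely
differ), and rejects ref/alt conflicts.

## Evaluation statistics

**Simple-matching dissimilarity.** Per locus, two genotypes share
m = 2 − |xᵢ − xⱼ| alleles; d = 1 − mean(m/2) over pairwise-complete loci.
The AMOVA companion squared distance is Σ(xᵢ − xⱼ)² over complete loci,
rescaled by L_total/L_complete so pairs with different missingness are
comparable (the Smouse–Peakall codominant metric). Dissimilarity bins:
low [0, 0.25], medium (0.25, 0.50], high (0.50, 1] — interval edges are
assigned to the lower bin, one convention applied consistently because the
customary interval notation overlaps at the boundaries.

**AMOVA / PhiPT.** SS_total = (1/N)Σ_{i<j} d²ᵢⱼ; SS_within sums the same
per group with its own size; df are k − 1 and N − k;
n₀ = (N − Σn_g²/N)/(k − 1); Va = (MS_among − MS_within)/n₀;
Vw = MS_within; PhiPT = Va/(Va + Vw), reported unclamped (a negative
estimate is informative). The permutation test shuffles whole individuals
across groups with sizes fixed and uses the +1-corrected p-value, so p = 0
is impossible. `amova_from_ss` completes the identical decomposition from
sums of squares alone, which is how the published two-pool table
(SS 13226.23/168008.8, pools 195/182 — the printed group sizes, which sum
to 377, are taken as authoritative for the arithmetic) is reproduced
exactly: Va 67.87, Vw 448.02, PhiPT 0.132, split 13 %/87 %.

**Neighbor joining.** Saitou–Nei NJ via scikit-bio on the simple-matching
matrix; negative branch lengths are clamped to zero. For additive inputs
(the tested contract) no negative branches arise and tip-to-tip path
lengths reproduce the input distances to 1e-9.

**PCA.** Markers are centred at 2p and scaled by √(2p(1 − p)); missing
dosages are mean-imputed per marker (zero after centring), the common GRM
practice. The sample-by-sample covariance is eigendecomposed; unit
eigenvectors are the reported scores and the variance fraction of each
component is its eigenvalue over the full trace (first 15 reported by
default). Monomorphic markers are excluded (not standardizable).

**LD.** Inclusion filter: Ho ≤ 0.15 and missingness ≤ 0.20, no MAF floor;
monomorphic markers pass the filter and are skipped at the r² stage as
zero-variance pairs (counted). r² is the squared Pearson correlation of
dosage vectors over pairwise-complete samples — the composite-LD estimator,
not EM haplotype estimation, which is nearly identical in material with
Ho ≈ 0.03 and exactly identical in the fully homozygous limit (tested
against the haplotype formula D²/(p₁q₁p₂q₂)). Bins: very_low [0, 0.10),
low [0.10, 0.50), moderate [0.50, 0.90), high [0.90, 1]; 0.90 belongs to
high. The bin taxonomy's alternative "very low (0.00–0.01)" phrasing is
inconsistent with the adjacent "low (0.10–0.50)" bin, so the 0.10 edge is
used.

## The simulator

Balding–Nichols: ancestral frequency p ~ Uniform(0.05, 0.5) (randomly
flipped so ALT may be major), subpopulation frequency
p_g ~ Beta(p(1 − F)/F, (1 − p)(1 − F)/F), which has mean p for every F;
F = 0 is handled as the exact no-drift limit. Genotypes follow
inbreeding-adjusted Hardy–Weinberg: P(het) = 2p_g q_g(1 − f), homozygotes
proportional — a one-parameter Hardy–Weinberg departure, not a pedigree
simulation, chosen because it reproduces the key marginal of inbred panels
(Ho far below He; f = 0.9 gives Ho/He ≈ 0.1, matching the 0.03/0.29 ratio
the target material shows) with a single interpretable knob. Missingness
is i.i.d. per call by default; an optional per-marker Beta-distributed
rate reproduces long-tailed call-rate distributions (mean well below the
median). Defaults mirror the study conditions: pools of 195 and 182, seven
chromosomes, F = 0.15 (PhiPT in the ~0.13 neighbourhood).

The fabricated reference places each marker's ref base on random-sequence
chromosomes; a configurable fraction of markers get single-exon genes
(exonic truth), a fraction two-exon genes straddling the SNP (intronic),
the rest stay non-genic. Injected defects — a 14 bp AT tract in the left
flank, a copied 101 bp probe elsewhere on the chromosome, a low-frequency
decoy variant 10–40 bp away — are logged per marker in a truth JSON, and
chance tandem tracts are scrubbed from the flanks of non-flagged markers,
so the truth record *fully determines* every filter decision and the
cascade can be audited reason-by-reason. Markers are spaced ≥ 150 bp so
flanks, windows and gene models of neighbours never interact.

What the simulator does **not** emulate: linkage (markers are independent;
LD-bearing fixtures are built by duplicating/perturbing columns in tests),
allele-frequency spectra of real germplasm, batch/assay artefacts, or
pedigree structure within pools. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not performance on
any real breeding panel; simulator parameters are test instruments, not
estimates of real material.

## Numerical and testing choices

- Statistics computed over non-missing (or pairwise-complete) calls only;
  all-missing columns raise a dedicated undefined-statistic error.
- Permutation p-values use (1 + hits)/(n_perm + 1); permutation count
  defaults to 999.
- Tie-breaks are deterministic and documented: top-pair ties by sample-id
  lexicographic order; LD-prune ties drop the larger position; equal-PIC
  selection ties by seeded permutation.
- Test problem sizes: oracle-equivalence suites use ≤ 8 samples (AMOVA
  double-loop), ≤ 15 candidates (exhaustive subsets), 4 taxa (NJ topology
  enumeration) and 500 random 100 bp sequences (SSR all-substrings scan);
  parameter-recovery runs use 200–300 samples × 500–1000 markers with
  99–199 permutations, and the permutation-uniformity check uses 200
  replicate null datasets of 20 × 50. These sizes give stable Monte-Carlo
  margins (3–4 SD acceptance bands) while keeping the default suite fast.
- The acceptance script's quantities are deterministic arithmetic
  (completing an AMOVA from published sums of squares; the PIC ceiling);
  `--seed` is accepted for interface uniformity.

## Known limitations

- Specificity is exact-match only; paralogs differing by ≥ 1 mismatch
  within the probe are not detected.
- The greedy selector with a spacing constraint is not guaranteed optimal.
- `amova_from_distances` supports one grouping level (two-level
  decomposition); hierarchical designs (regions/populations/individuals)
  are out of scope.
- LD p-values are per-pair; no multiple-testing correction is applied to
  the pair table.
- The GFF region classifier resolves overlapping annotations by fixed
  precedence rather than transcript-aware rules.
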
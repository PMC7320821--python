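# Methods

## Setting and data model

The package operates on tissue-resolved omics tables from a non-model plant:
a genes × tissues expression matrix in FPKM, a mass-feature × tissues
metabolite intensity matrix with per-feature neutral mass and chemical-class
metadata, a homology-derived transcript annotation (length, enzyme-class
labels, CYP flag) and transcript sequences. Seven tissues (young/mature
leaf, young/mature stem, inflorescence, pericarp, seed) are the default
shape. Nothing in the analysis depends on that number beyond the minimum of
three tissues needed for rank correlation, but its small size has
consequences the design takes seriously (below).

All correlation throughout is tie-corrected Spearman: Pearson correlation of
average ranks. With *n* = 7 observations, ρ takes values from the finite set
1 − 6S/336 with S the squared rank distance; the smallest supra-threshold
value at ρ² > 0.85 is ρ = 0.9286 (S = 4, two adjacent rank swaps), and any
independent profile crosses |ρ| > 0.922 with probability 34/5040 ≈ 0.7%.
These discreteness facts drive three design choices: deterministic
tie-breaking in clustering, positive-only correlation edges, and the
co-expression height cap.

## Pathway assignment by co-expression

Transcripts carrying at least one of the pathway's enzyme-class labels are
clustered by average linkage (complete and single available) on distance
1 − ρ. Constant-expression transcripts, whose rank correlation is undefined,
are excluded with a warning before clustering.

Because distances are discrete, exact merge ties are routine, and generic
linkage implementations resolve them by internal traversal order. The
package ships its own Lance-Williams agglomeration (`omicforge._cluster`)
with a published tie rule — candidates within 10⁻⁹ of the minimal distance
are tied; the pair containing the smallest original leaf index merges first
— so the dendrogram is a deterministic function of the data, invariant to
pool ordering. The output is a scipy-compatible linkage matrix; `fcluster`,
`cophenet` and `dendrogram` apply unchanged.

Selection walks the dendrogram cuts from low to high (the all-singleton cut,
then every distinct merge height) and returns the smallest cluster whose
members jointly cover every enzyme class of the pathway; ties go to the
lower cut height, then lexicographic member order. If no eligible cluster
covers all classes the result is an explicit no-assignment, not an error.

Cuts are capped at `max_cut_height` (default 0.25, i.e. mean within-cluster
ρ ≥ 0.75; `None` removes the cap). The cap is what makes "cluster" mean
*co-expressed* cluster: without it, at cut heights near 1 a chance chain of
mutually uncorrelated decoy transcripts that happens to cover all classes
can be smaller than the true module and win on size, despite carrying no
co-expression evidence. In synthetic benchmarks at the default noise this
failure occurred in roughly 9% of replicates without the cap and disappears
with it; the cap value is insensitive over ~0.2–0.5 because planted modules
cohere below 0.15 while unrelated transcripts chain above 0.5.

## CYP prioritization funnel

1. **Filter** — transcripts flagged as CYPs with length ≥ 500 bp and FPKM
   ≥ 5 in at least one tissue. Both comparisons are inclusive by default
   (configurable to strict).
2. **Tier 1** — Spearman correlation of each filtered CYP against every
   metabolite of the target class across tissues; a gene survives with at
   least one edge at ρ² > 0.85 (strict).
3. **Tier 2** — tier-1 genes correlated at the same threshold with at least
   ⌈fraction × |pathway genes|⌉ of the assigned pathway genes; fraction
   defaults to 0.5, so "at least half" holds exactly for odd counts
   (⌈0.5 × 31⌉ = 16).

Edges are kept only for **positive** ρ by default. A candidate participating
in a biosynthetic pathway co-accumulates with the pathway's products and
co-expresses with its genes; anti-correlation is not evidence of
participation. The choice also matters statistically: sign-blind ρ² doubles
the chance-edge rate at seven tissues (≈ 1.35 expected spurious tier-2
candidates per 200 independent decoy CYPs versus ≈ 0.7 positive-only).
A sign-blind mode (`positive_only=False`) and an |ρ|-threshold mode
(`r2_mode="abs_rho"`) are available for sensitivity analysis. The threshold
is interpreted as squared Spearman ρ, hence |ρ| > 0.92195.

The surviving gene–metabolite and gene–pathway-gene edges form a typed
network exported as SIF plus an attribute table (edge ρ, ρ², kind; node
type), round-trippable through `read_network`.

## SSR scanning

Microsatellites are maximal exact tandem runs of primitive 1–6 bp motifs
meeting per-class minimum repeat counts (defaults 10/6/5/5/5/5, the MISA
convention); `N` breaks runs. Runs whose motif is a repetition of a shorter
word are never reported separately (a di-run is not also a tetra-run).
When maximal runs of different motif lengths overlap, records are chosen
greedily left to right (shorter motif first at equal start), so reported
intervals on a sequence never overlap, and each record satisfies
end − start + 1 = motif length × repeat count. Motifs are reported in the
phase observed at the run start; a canonical column (lexicographically
minimal rotation) supports aggregation. Coordinates are 1-based inclusive.
Records separated by at most 100 interruption bases group into compound
SSRs. The summary table mirrors the standard two-block layout: scan-wide
counts plus the repeat-class distribution with percentages.

## Report arithmetic conventions

Percentages round half away from zero at the stated number of decimals
(report-table convention; Python's bankers' rounding is deliberately not
used). N50 uses the descending-sort convention: the first length at which
the cumulative sum reaches half the total. The median of an even count is
the midpoint of the two central values, rounded to whole bases for report
parity. "Transcriptionally active" means FPKM strictly greater than the
threshold (default 0). BUSCO summaries derive the missing count by
subtraction and compute all percentages from the same denominator;
completeness is the rounded percentage of complete (single + duplicated)
groups. One published-table cell (the di-nucleotide SSR fraction) appears
truncated rather than rounded in its source; this package rounds
consistently and reports 48.0 where truncation would print 47.9.

## Translation-frame rule

`translate_longest` searches all six frames and returns the translation of
the longest open reading frame that starts with an exact ATG and ends at
the first true stop codon (TAA/TAG/TGA) or the frame end. Codons containing
N translate to X and do not terminate extension. Ties are broken forward
strand first, lower frame offset, leftmost start, so the result is
deterministic.

## ppm matching and metabolite tools

Mass-feature annotation compares neutral masses (adduct handling is out of
scope; callers pre-convert m/z). The error is always relative to the
reference mass, the window is two-sided and inclusive at ±10 ppm, and all
references are evaluated and returned sorted by absolute error.
Internal-standard normalization divides every feature by the standard's
intensity in the same tissue (the standard row becomes 1), requiring a
strictly positive standard everywhere; within-tissue ratios between other
features are preserved. PCA treats tissues as observations with features
centred; component signs are fixed by making the largest-magnitude loading
positive. Metabolite clustering uses the same deterministic average-linkage
machinery on 1 − ρ with a default of four flat clusters; constant features
are excluded with label −1.

## Synthetic data: what it emulates, and what not

The generator plants the statistical structure the analysis assumes, with
ground truth recorded for every entity:

- **Modules.** Each pathway module has a log-scale tissue profile; member
  genes (default 3 per enzyme class) draw FPKM = exp(profile + N(0, σ²)),
  i.e. multiplicative log-normal noise, the standard first-order variance
  model for expression and intensity data. Default σ = 0.15. The preset
  profiles space tissues ≈ 0.6 log-units apart (≈ 40-fold range across
  tissues), typical of tissue-specific specialized metabolism and wide
  enough that tissue rank order is well defined at the default noise.
- **Decoys.** Every enzyme class also gets decoy genes (default 2 per
  class) with independent random profiles, so cluster selection — not mere
  annotation — is what recovers the module. Independent decoy CYPs
  (default 200) surround the planted pathway-linked CYPs (default 7, riding
  the iridoid module's profile).
- **Metabolites.** Class-linked features (default 15 per linked class)
  share the module profile plus independent noise; unlinked features are
  independent. Each feature's neutral mass sits within ±5 ppm of a built-in
  reference compound of its class (monoisotopic masses computed from
  molecular formulae), exercising the ppm matcher realistically.
- **Contigs.** Planted (motif, repeat-count) SSRs are embedded at recorded
  coordinates in random flanks that are re-screened to be free of
  qualifying repeats; each planted contig is verified so the planted run is
  the only record the scanner reports.

Identical configurations (including the seed) give bit-identical outputs;
independent per-stage random streams derive from (seed, stage) pairs so a
stage's output does not depend on which other stages run.

The generator does **not** emulate: read-level noise or mapping bias,
zero-inflation beyond an optional uniform dropout, correlated noise between
tissues (biological replicates are collapsed), adducts/isotopes or
retention-time structure on the metabolite side, imperfect/approximate
repeats, or homology structure in sequences. Passing planted-truth
benchmarks therefore demonstrates correctness of the analytics under the
assumed variance model, not robustness to every artefact of real LC-MS or
RNA-seq data.

## Benchmark sizes and numerical choices

The planted-truth benchmarks run 100 seeded replicates at σ = 0.15 (one
module of 30 genes, 20 class-decoys, 7 linked among 200 decoy CYPs, 50
background genes); oracle-equivalence suites use 500 random 1-kb sequences
for the SSR scanner, 1,000 random length sets for N50, and 10 random
15-item instances for the clustering oracle. On one CPU the full test suite
completes in well under a minute and the acceptance script in seconds.
Under these conditions the pathway selector attains mean precision ≈ 1.00
and recall ≈ 0.99, and the end-to-end funnel mean tier-2 precision ≈ 0.93
with recall ≈ 1.00; residual tier-2 false positives are the irreducible
chance-correlated decoys discussed above (≈ 0.7 expected per replicate at
seven tissues).

Numerical details: distances below 10⁻¹² are snapped to zero before
linkage; merge-tie tolerance is 10⁻⁹ (distinct average-of-rational
distances at these cluster sizes differ by ≥ 6 × 10⁻⁸); TSV writers emit 12
significant digits for bit-stable round trips; correlation values are
clipped to [−1, 1] against floating-point overshoot.

## Known limitations

- The smallest-covering-cluster rule assumes exactly one co-expressed
  cluster per pathway; two genuinely distinct co-expressed sub-pathways
  would be collapsed to whichever covering cluster is smaller.
- Seven observations give rank correlation little resolution: the
  ρ² > 0.85 threshold admits only rank-distance S ≤ 4, so single noisy
  tissues can flip edge decisions, and chance edges are non-negligible at
  scale (mitigated, not eliminated, by positive-only edges and the tier-2
  link requirement).
- The ppm matcher annotates by mass alone; isobaric compounds (e.g.
  ursolic vs oleanolic acid) are indistinguishable without MS² evidence,
  which is out of scope.
- `percent` reproduces report-table rounding, not the truncation some
  published tables use; single-cell discrepancies of 0.1 are expected
  against truncated sources.
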
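# Methods

This note documents the models, algorithms, parameter choices and known
limitations of barcodeval. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Plastome structure and comparison

A plastid genome is treated as a circular uppercase string over
A/C/G/T/N with 0-based half-open coordinates throughout (GenBank 1-based
closed intervals are converted on read).

**Inverted-repeat location.** The IR pair is found by seeding shared
k-mers (k = 20, sampled at stride k on the reverse complement so any
shared exact segment ≥ 2k−1 is guaranteed a seed) between the sequence
and its reverse complement, extending each seed pair outward with zero
mismatches, and keeping the longest disjoint pair of reverse-complement
segments of at least `min_ir_len` (default 1,000 bp — an order of
magnitude below real plastid IRs, well above random background). Ties go
to the smallest IRa start for determinism. The two single-copy arcs
between the IR copies are labeled LSC/SSC by size. Annotated
`repeat_region` features can be preferred over computation; either way
the map is validated: equal IR lengths, full coverage, and
reverse-complement identity with at most 1% mismatch (absorbing
annotation or boundary ambiguity).

**Repeat scan.** All maximal exact repeated pairs (forward and
palindromic) with unit length in [8, 50] bp are enumerated by seed
extension and deduplicated by (unit, position pair); mononucleotide units
are excluded, as are hits inside the IR when the IR intervals are passed
as exclusions (the IR's own self-match is structural, not informative).
The upper bound of 50 is read as a maximum repeat *length*; the original
tool setting it mimics is ambiguous on this point, so the cap is a
parameter.

**Single-copy comparison.** LSC is compared with LSC and SSC with SSC,
IRs removed. The collinear backbone is the longest chain (LIS) of k-mers
that are unique within, and shared between, the two regions; segments
between consecutive anchors — plus the head and tail — are globally
aligned with edlib and their CIGARs accumulated into SNP columns and gap
events (one event per maximal run of gap columns, regardless of length).
When the anchor chain spans less than half of the reference region the
genomes are declared too divergent for anchoring rather than returning
unreliable counts. This replaces whole-genome alignment; it recovers
planted edit scripts exactly on 10 kb regions with ≤ 20 well-separated
edits (tested), but SNP/gap totals on real genome pairs are not promised
to match any particular aligner's output bit for bit.

## Primer windows

Candidate amplicons are tiled greedily left to right over a pairwise
aligned region: for each variant column (mismatch or gap), the nearest
upstream and downstream windows that are identical in both genomes,
gap-free, 18–24 nt, and within Tm 50–65 °C are paired so the product
length falls in [400, 1,100] bp; every emitted candidate brackets at
least one variant and re-validates (primers are exact substrings of both
genomes). Tm uses the Wallace rule 2(A+T)+4(G+C) up to 20 nt and
64.9 + 41(GC−16.4)/len above — standard short-oligo practice; both are
selectable. The window-scan granularity, and the greedy (rather than
globally optimal) tiling, are this package's own choices: they trade
primer-quality optimization for determinism and reproducibility.
Self-complementarity and dimer checks are deliberately out of scope.

## Matrix preparation

Cleaning drops columns whose fraction of N/? exceeds `max_ambiguous`
(default 0) and column blocks that are mononucleotide A or T runs of
≥ 8 bp in ≥ 50% of rows (poly-A/T stretches are slippage-prone and
misalign); the 8 bp / 50% thresholds are this package's quantification of
a qualitative practice. A provenance table maps kept columns to original
coordinates.

Indels are coded by simple indel coding: each distinct maximal gap span
becomes one appended binary column (T = present, A = absent), with '?'
for rows whose own gap strictly contains the span. Coded columns
participate in distances and character methods (they are ordinary A/T
columns), toggleable via `EvalConfig.code_indels`.

Diagnostic characters are (column, state) pairs fixed in one species and
absent from all others. Ambiguity codes never supply nor match a state,
and an overlapping heterozygote *blocks* a diagnostic (conservative: a
heterozygous individual that may carry the state makes the character
unreliable).

ITS orthologue screening flags rows by GC content (default bounds
45–70%) and by IUPAC-aware presence of configurable conserved 5.8S
motifs (empty by default — the exact motif set is study-specific).

## Diversity statistics

π for a species is the mean pairwise p-distance (pairwise deletion)
among its sequences; the marker-level summary is the unweighted mean
over species with ≥ 2 individuals (per-species averaging; pooling all
conspecific pairs is available but weights large samples more). The
screening rule selects markers with mean π > 0.0005 and amplification
success ≥ 0.8; success is observed wet-lab data, never computed, and the
0.8 operationalizes "amplifies in most species".

DIP diversity groups overlapping gap spans into loci (connected
components of overlapping spans); alleles are the distinct gap
configurations at a locus and h = n/(n−1)(1 − Σ pᵢ²) with the unbiased
correction, matching the haplotype-diversity convention (a 6/3 split of
nine individuals gives exactly 0.5).

## Distance-based barcoding

p-distances compare only columns where both sequences carry an
unambiguous A/C/G/T; a pair with no shared column is NA (it propagates
to an explicit error in tree building and never silently becomes 0).

**Barcode-gap assessment.** All finite pairwise distances are ranked; a
gap is reported when the *widest* consecutive step straddles the maximum
intraspecific distance and exceeds `gap_factor` (default 2.0) times the
median positive step. Two details matter: p-distances tie on a
1/shared-sites grid, so zero steps are uninformative and the typical
step is taken over positive steps only; and the qualifying step must be
the dominant discontinuity of the whole curve, because large spacings in
the sparse extreme tail are ordinary order statistics, not gaps.

**Partitioning.** Given a prior P (the maximum intraspecific divergence),
the linkage threshold is the lower bound of the widest ranked-distance
gap whose upper member exceeds P (P itself serves as virtual lower
bound); individuals are clustered by single linkage at that threshold
and each multi-member group is recursively re-examined with 100
geometrically spaced priors in [P/10, P] until stable. A split is
accepted only when the chosen gap is wider than the top-level prior — a
discontinuity narrower than the assumed intraspecific divergence is
noise. Without this guard the recursion shreds tight conspecific
clusters on grid-spacing artifacts. This is a deterministic
simplification of automatic barcode-gap discovery; the original's
slope-based gap model and Monte-Carlo machinery are not reproduced.

**Divergence tests.** Welch's t and the Wilcoxon rank-sum (normal
approximation, tie-corrected; W reported as the rank sum of the
intraspecific sample) compare intra- vs interspecific distances, either
pooled or as per-species max-intra vs min-inter, optionally restricted
to pairs within a section or group. Pairwise distances are not
independent observations, so the pooled p-values are descriptive; under
a simulated exchangeable null the type-I error is nevertheless at the
nominal 5% (tested at 1,000 replicates).

## Similarity-based barcoding

Leave-self-out top-hit classification: similarity is the identity
fraction over pairwise-shared unambiguous columns (1 − p-distance) on
the aligned matrix — local seeded search adds nondeterminism without
benefit when sequences are already aligned. Ties are strict: any
heterospecific sequence tied at the top fails the query. A species is
identified when every individual's top hits are exclusively conspecific;
singletons are excluded from the denominator (self-exclusion makes their
success impossible).

## Character-based barcoding

Each species receives a DNF formula over (column, state) literals. When
single-position diagnostics exist, they are used directly (up to 5
disjuncts). Otherwise a greedy search grows conjunctions literal by
literal, choosing the literal minimizing
`50 · (conspecifics excluded) + 800 · (heterospecifics still covered)` —
the 50/800 asymmetry makes false positives sixteen times costlier than
false negatives — stopping at 3 literals or zero covered negatives, and
adding disjuncts until all conspecifics are covered. Training equals
testing on the full matrix (the reference database is verified against
itself). Classification is exclusive: an individual satisfying zero or
several species' formulas is unassigned, and a species is identified
only when all of its individuals are assigned to it. The greedy search
finds a perfect formula whenever an exhaustive ≤ 2-literal one exists
(tested on 100 random small matrices).

## Tree-based barcoding

Neighbor joining from the Q-criterion Q(i,j) = (n−2)d(i,j) − R_i − R_j
with deterministic tie-breaking (smallest sorted clade labels); branch
lengths from the standard formulas, negatives clamped to zero with the
deficit moved to the sister so the joined path length is preserved
(changes no topology). NJ is consistent: random additive matrices are
recovered exactly (100 × 8-leaf, tested). Bootstrap resamples columns
with replacement; replicate r uses seed + r, so supports are
bit-reproducible; supports annotate the original-data tree, and
monophyly is judged on that tree (not a consensus). A species is
monophyletic when one edge separates exactly its leaves; singletons are
reported separately, not counted.

## Synthetic data generator

The generator emulates the statistical shape of a multi-species barcode
study on a star phylogeny: ancestral i.i.d. sequence → species consensus
(per-site substitution probability `d_inter`, uniform over the three
alternatives, Jukes–Cantor-like — no transition bias, which p-distance
methods cannot see anyway) → individuals (`d_intra`). One reserved
column per species may be forced to a unique state (`p_diag`) and is
masked from all mutation, so planted diagnostics are exactly recoverable
(tested). Species-specific deletions (3–10 bp, `indel_rate` per
species × marker) occupy distinct coordinates. For plastid markers an
individual's whole haplotype is, with probability `p_share`, drawn from
another species' consensus — the chloroplast-capture signature of
hybridization/ILS. Nuclear markers receive IUPAC heterozygous codes at
rate `p_het`. The closed-form expected p-distance under the two-step
model (branch change probability c = (1−q₁)q₂ + q₁(1−q₂/3) composed, and
disagreement 2c(1−c) + ⅔c²) validates the generator within 3 SE at
10 kb (tested).

Preset conditions:

| preset  | d_intra | d_inter | p_diag | indel_rate | p_share | use |
|---------|---------|---------|--------|------------|---------|-----|
| clean   | 0.003   | 0.05    | 1.0    | 0.2        | 0       | separable baseline: every method should reach 100% |
| hybrid  | 0.003   | 0.05    | 1.0    | 0.2        | 0.3     | chloroplast capture: distance/tree degrade, character holds |
| gapless | 0.02    | 0.03    | 0.2    | 0.2        | 0       | overlapping divergences, sparse diagnostics |

All presets use 10 species × 5 individuals and three 600 bp markers (two
plastid, one nuclear) — sized so a full four-method combination grid
runs in seconds while keeping ≥ 1,000 pairwise distances per matrix;
intra/inter rates sit in the ranges plastid barcoding studies report
(~10⁻³ within, ~10⁻² between species).

What the generator does **not** emulate: nested clade structure beyond
the optional two-clade mode (real oaks have sectional structure),
rate variation among sites and markers, alignment error, partial
sequences and amplification failure, pseudogene contamination, and
recombination. Passing the synthetic tests therefore shows the methods
are implemented correctly and respond to hybridization/ILS as expected —
not that any particular empirical identification rate will be attained
on real data, where unmodeled curation effects dominate.

## Numerical conventions and degenerate inputs

- p-distance with empty overlap is NA, never 0; trees refuse NA input.
- Partition priors must be positive; when a dataset has no intraspecific
  variation the evaluation floor-clamps the prior at 10⁻⁴.
- Bootstrap replicates in which some pair shares no sampled column are
  dropped from the support denominator.
- All ties (NJ joins, hit rankings, gap candidates) break
  lexicographically or toward the smaller coordinate; identical inputs
  and seeds give byte-identical outputs.
- GC content ignores N; reported to two decimals.

## Known limitations

- The genome comparison is collinear-only: rearrangements and
  inversions break the anchor chain and surface as a divergence error
  rather than being modeled.
- The character method's cost weights map a published configuration onto
  a greedy search whose exact semantics differ from the original tool;
  only the cost asymmetry, not the search trajectory, is preserved.
- Pooled divergence tests treat non-independent pairwise distances as
  samples; interpret p-values comparatively, not inferentially.
- The partition step is a deterministic ABGD-style approximation; on
  data with genuinely continuous divergence distributions it will be
  conservative (few splits) by design of the gap-width guard.
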
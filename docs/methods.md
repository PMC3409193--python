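# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind each stage of the pipeline. Coordinates are
0-based, half-open everywhere; `N` is treated as missing data (excluded
from distances, similarity windows and parsimony state sets); IUPAC
ambiguity codes are mapped to `N` on input by default.

## Composite-likelihood TN93 distances

The default pairwise distance follows the "maximum composite likelihood"
idea: substitution parameters are shared across all pairs of an
alignment rather than re-estimated per pair. Concretely, base
frequencies are the empirical frequencies over all ungapped characters,
and the purine and pyrimidine transition/transversion ratios (κ₁, κ₂)
maximize the summed profile log-likelihood over all pairs (Nelder–Mead
over log κ, with each pair's distance profiled out by bounded 1-D
optimization). Each pair's distance is then the ML branch length under
TN93 with those shared parameters, computed from the pair's 4×4 base-pair
count matrix using the closed-form TN93 transition probabilities.
Variances come from the observed information (numeric second derivative
of the per-pair log-likelihood); for the closed-form estimators
(p-distance, JC, K2P) the standard delta-method formulas are used.

Gap handling is strict pairwise deletion: a column enters a pair's
comparison iff neither member carries `-` or `N` there. A pair with no
comparable columns, or one whose ML distance runs into the optimizer
bound (taken as saturation), is reported NA with a warning rather than
extrapolated. Within one alignment the correction ordering p ≤ JC ≤ TN93
holds wherever all are defined.

Whether shared or per-pair frequency estimation better matches any
particular external implementation is not resolvable from published
descriptions; the model is selectable (`p`, `jc`, `k2p`, `tn93`) and the
simpler estimators double as independent oracles in the tests.

## Ortholog assignment and chimera diagnostics

Orthologs are assigned per (label, foreign species) as the
minimum-distance partner. Ties within 10⁻⁹ are flagged ambiguous and two
labels claiming the same partner are flagged as conflicts; neither is
resolved silently, because downstream biology depends on assignments
being unambiguous. The mutual-best, unambiguous pairs form the ortholog
map used for group averages.

Per-region nearest-paralog tables recompute distances region by region;
a chimera signal is raised for a gene whose confident regions split into
a 5′ block and a 3′ block (each ≥2 contiguous regions) with different
nearest parents. Regions under 100 sites are flagged low-confidence and
excluded from the blocks. Note the diagnostic is symmetric: the parents
of a chimeric duplicate can themselves show a mirrored switch, so flags
identify candidates for inspection, not a unique culprit.

Neighbor joining is delegated to scikit-bio's implementation behind the
module surface; on additive matrices it reproduces the generating tree
exactly, which the tests exploit as a closed-form oracle.

## Similarity calculator

Windows are indexed by start column and advance by a configurable step
(default 1 nt; the original tool's step is not documented, and a smaller
step only smooths the track). Within a window, columns where either
member has `-`/`N` are skipped; if skipped columns exceed
`max_gap_fraction` (default 0.20) the window is unscored, otherwise the
score is identities over scored columns. A final partial window is not
scored, preserving the fixed-denominator semantics. The candidate
threshold (default 0.96) is stored in configuration, not hard-coded: it
sits above the ~0.94 background similarity of orthologs that diverged at
the human–macaque split, so super-threshold runs indicate homogenization
more recent than that split.

## Micro-indel coding and parsimony

A maximal `-` run in one row is an indel; runs with identical (start,
length) in ≥2 rows become one binary character. The "micro" cutoff is
100 nt by default — the term is conventionally left unbounded, so the
cutoff is configurable and logged. A row whose own longer gap engulfs a
character's span is coded missing (`.`), since presence or absence is
unobservable there. Singleton indels are retained but flagged
uninformative; informative characters require ≥2 present and ≥2 absent
states. Only shared characters are ever counted in topology comparisons,
which follows from the definition of a shared indel.

Fitch counts are computed per character with missing leaves pruned, on
whatever topology is supplied — homoplasy is always judged against a
stated tree, never a consensus. Counts are invariant to root placement,
so unrooted topologies may be passed rooted arbitrarily; the test suite
checks Fitch totals against exhaustive enumeration of ancestral
labelings on trees of ≤8 leaves.

## Sawyer fragment statistic

Only polymorphic columns within a same-species group carry conversion
signal; columns containing any gap within the group are excluded before
polymorphism is assessed, so fragment scoring never meets a gap. For a
pair, matches score +1 and mismatches −g·(n_match/n_mismatch), where g is
the conventional "G-scale" (default 1, making the expected random-walk
increment zero; g = 0 restricts fragments to mismatch-free runs). The
penalty constant is this package's formulation — published parameter
lists name G-scale without fixing the constant, and exact score equality
with specific external implementations (which vary by version) is not
guaranteed. Maximal-scoring fragments come from the Ruzzo–Tompa
algorithm and are filtered by minimum aligned length (1 nt), minimum
polymorphisms (2) and minimum score (2), the conventional defaults.

Significance: the observed best fragment score is compared with the best
scores of column-order permutations of the same walk (vectorized
max-subarray via cumulative sums), p = (1 + #{null ≥ obs})/(1 + N),
Bonferroni-corrected across pairs within the species group. Permutations
and correction are within-species by design; between-species comparisons
would be both biologically spurious and statistically wasteful. A
degenerate null (all permutation scores equal) reports p = 1 with a
warning. N ≥ 1000 permutations is recommended; the generator must be
seeded.

## Evidence integration

Recent-tier calls require a super-threshold similarity region plus at
least one corroborating indicator for the same pair in the same region —
a co-localized homoplasic micro-indel, a significant fragment, or an
imported external-method region (RDP/bootscan tables are imported, not
reimplemented). A significant fragment with no super-threshold window
becomes an ancient-tier call. Super-threshold regions with no
corroboration are reported separately as uncorroborated candidates.
Overlapping calls for one pair merge to their union extent with combined
evidence.

## TREx clock

At a two-fold degenerate third position only two nucleotides are
synonymous, so identity decays toward the equilibrium q = p₁² + p₂²
(≈ 0.5008 at the 0.52/0.48 silent-site bias). The decay constant is
calibrated so the initial loss of identity per year equals twice the
silent rate r (both lineages substitute): f₂(T) = q + (1−q)e^(−2rT/(1−q)).
This is exactly the identity function of a stationary two-state chain
with flux r per lineage, which is what the simulator implements — the
parameter-recovery tests therefore check calibration, not just
inversion. A per-lineage convention (decay rate r instead of 2r) sits
behind the `two_lineage` flag for comparison with sources that report
per-lineage times. Confidence intervals propagate the binomial error on
f₂ through the inversion. f₂ ≤ q is reported as saturated (infinite
date), never extrapolated; f₂ = 1 dates to exactly 0.

Two-fold status is assigned pairwise — both codons must make the third
position two-fold, and when the codon contexts differ the two synonymous
state sets must coincide — which avoids counting frame-disrupted or
context-shifted sites. Codons containing gaps or `N` are skipped;
internal stops are excluded with a warning (how gap-containing codons
were handled in the original exon analyses is not documented; exclusion
is the conservative choice).

## Reference-intron screens and duplication placement

Reference introns are screened with GC ≤ 45% (published removals were at
47.1%+ with retentions at 38.5%; no cutoff is printed anywhere, so 45%
is this package's default, logged as such), distance to telomere ≥ 15
Mbp, and no long conserved noncoding sequence. Presence in an mRNA
database is *not* disqualifying by default, since such presence was
shown not to imply functional constraint; a flag enables the stricter
screen. Records with incomplete metadata are excluded with reason.

Duplication placement compares the paralog distance mean against each
split's ortholog distance distribution: "before" the split when the
paralog mean exceeds it by more than one pooled sd, "after" when it
falls short by more, otherwise unresolved. This is deliberately blunt —
a Welch test would imply a precision the small reference panels cannot
support.

## Simulator

The species tree must be ultrametric (all tips at the present) with
branch lengths in years; duplications that predate the root live on a
configurable stem above it. All live lineages advance in lockstep
between events (TN93 substitution via closed-form transition matrices;
indels as a Poisson process per lineage with geometric lengths,
insertion/deletion equiprobable), which is what allows a conversion
event to copy the donor's sequence state at the moment of the event.
Indel placement within an inter-event epoch is applied at the epoch
boundary — an approximation that is immaterial at the rates simulated.
The emitted alignment is the true alignment: insertions create columns
(gaps elsewhere), deletions leave gap columns, nothing is realigned, so
inference is tested free of aligner noise (real data adds alignment
error the simulator deliberately omits). Conversion donors default to a
named co-resident paralog; tract lengths are geometric, matching the
reported range from a dozen to several thousand nucleotides.

Ground truth records every duplication (including chimeric duplicates
fused from two parents at a breakpoint), loss or pseudogenization,
realized conversion tract and indel in final alignment coordinates, plus
true pairwise divergence times from the gene genealogy. Determinism is
exact: one config plus one seed gives byte-identical output.

What the presets emulate: `fourparalog_oneloss` mirrors the study regime
(four paralogs arising on the stem before a three-species primate
phylogeny, one loss, one pseudogenization, ~12.5 kb of introns in eight
regions, substitution rate 1.3×10⁻⁹/site/year so paralog distances land
near 0.16 and human–macaque ortholog distances near 0.07);
`chimeric_dup` a chimeric duplicate whose 5′ and 3′ halves descend from
different parents; `no_conversion`/`one_conversion` four-paralog
single-species groups (5 kb, paralog divergence ≈ 0.14) without and with
one 800 nt tract converted 2.5 Mya (tract similarity ≈ 0.99, well over
the 0.96 threshold, with ≥10 internal polymorphisms). What passing tests
show is therefore recovery under the stated regime — clean alignments,
stationary TN93, neutral indels — not robustness to alignment error,
rate heterogeneity or selection.

## Problem sizes in the test and acceptance runs

Fitch-vs-oracle agreement uses 1,000 random binary characters on random
trees of 4–8 leaves (exhaustive enumeration is exact there). NJ recovery
uses the closed-form additive oracle plus 100 simulated 50 kb alignments
on an 8-taxon tree spanning pairwise divergences 0.06–0.18, scored under
JC (the estimator is immaterial to the NJ property and JC keeps the loop
brisk). TREx recovery uses 200 pairs of 500 two-fold sites at a true
divergence of 40 My. Conversion-detection size uses 500 conversion-free
groups at 1,000 permutations; power uses 50 families with one planted
tract, scored by recent-tier recall and call/tract Jaccard overlap. The
published 12-paralog distance matrix is bundled and summarized directly.

## Known limitations

- The TN93 composite estimator shares κ across pairs but not a
  rate-heterogeneity model; uniform rates among sites are assumed.
- Parsimony is binary/multistate Fitch without ambiguity-code awareness
  or weighting; indel characters are simple identical-span codes (no
  complex indel coding).
- The Sawyer statistic's mismatch penalty is one principled choice among
  several in circulation; cross-implementation score equality should not
  be expected, though fragment locations and significance calls agree on
  clear signals.
- The simulator has no selection (dN/dS), no rate variation among sites
  or lineages, and no population-genetic (coalescent) effects.
- Absolute geological dating narratives are out of scope; the clock
  stages report years and relative placements only.
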
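# Methods

## Unique-residue model

The focal taxon contributes one row of a gap-free multiple protein
alignment; columns where its letter appears in no other row are treated as
lineage-specific substitutions. The score of such a column `p` sums the
per-column variability `V_i` (number of distinct letters, `1 ≤ V_i ≤
n_rows`) over the window `W(p) = [max(0, p−25), min(l−1, p+25)]` with
inverse-square distance weights `(|i−p|/10 + 1)^(−2)`; the center term has
weight exactly 1 and the outermost terms weight `(3.5)^(−2) ≈ 0.082`. The
window half-width (25 columns) and decay scale (10 columns) are fixed
constants of the score, not tunables. Columns are 0-based throughout, and
the three boundary cases of the piecewise definition are implemented as one
truncated window, which is algebraically identical.

Two directions of the score are exposed because the formula and its
narrative gloss disagree: summing `V_i` rewards variable flanks, while the
biological intent — a unique substitution inside an otherwise conserved
block is the interesting event — wants the opposite. The default is the
literal formula; `conservation_transform=True` substitutes
`n_rows − V_i + 1`, which maps a fully conserved column to the maximal
contribution. Both are tested; pipelines should state which they used.

Uniqueness requires only that the focal letter be absent from the other
rows at `p`; the other rows need not agree with each other. Calling requires
at least three rows (with two, "unique" degenerates to "different").
Protein scores are `Σ S(p) / l`; proteins with no unique residue score 0 and
are excluded from ranking. Ranked lists keep `k = ceil(fraction · n)` items
— the ceiling is forced by the worked count 5,882 → 295 at 5% — with
descending-score order and ties at the cutoff broken by ascending id for
reproducibility.

Gap handling: the default drops any column with a gap in *any* row (the
strictest reading of "gap-removed"); `mode="focal"` drops only columns
gapped in the focal row, for alignments where outgroup coverage is patchy.

## Sex-linked discovery

Hit filtering keeps alignments with match length strictly greater than
100 bp, mismatch rate strictly below 3% and query coverage strictly above
10%. The mismatch rate is computed as `mismatch_len / match_len`: the
inverse ratio cannot be "below 3%" for any credible alignment, so the
inverted form is the default and the literal one is available as
`literal_rate=True` for comparison. A scaffold is genome-specific when no
retained hit from the other assembly targets it; an optional positional
variant (`min_covered_fraction`) instead merges the hits' target intervals
and requires the covered fraction to fall below a threshold, for users who
want "covering" to mean more than mere existence of a hit.

RAD-tag association: "present in most of one sex, absent in most of the
other" is quantified as presence in at least `min_in` samples of the
associated sex and at most `max_out` of the other. Defaults are
`ceil(0.8·n_sex)` and `floor(0.08·n_other)` — in a 25+25 design, at least 20
and at most 2 — and are fully configurable; the optional one-sided Fisher
exact p-value reports the hypergeometric tail of the tag's 2×2 table.
Tag-hit classification assigns each tag exactly one of five categories
(male-specific only, male-specific and shared, female-specific only, shared
only, no hit) from its precomputed best hits per reference set. Paralog
search keeps each Y-candidate's best-scoring target (maximal match length,
ties by ascending target id) and deduplicates the target list. The
repeat-masked percentage of a scaffold subset merges overlapping intervals
before summing, so split or duplicated annotations cannot inflate it.

## Selection statistics

The branch-site test statistic is `2·max(0, lnL_alt − lnL_null)`; negative
deltas, which arise from optimizer noise, are clamped to zero (p = 1).
The default reference distribution is chi-square with df = 1, the standard
choice for the modified model A versus the ω = 1 null; the 50:50
mixture refinement (halving the tail) is available via `mixture=True` but
off by default. FDR adjustment is Benjamini–Hochberg (delegated to
statsmodels; an independent step-up implementation serves as the test
oracle). The pairwise screen selects `ω > 1 ∧ p_adj < α` (α = 0.01) and then
removes genes positively selected in any other lineage (the exclusion set,
typically assembled at a looser α = 0.05). Divergence ranking computes
`r = |log2(ω1/ω2)|` — symmetric in the two lineages and invariant under
common rescaling — cuts the top `ceil(0.05·n)`, and only then applies the
optional `ω1 > ω2` / exclusion sub-selection, matching the order in which
the published counts were derived. Genes with non-positive ω (dS = 0
upstream) are skipped with a warning; an optional filter drops genes whose
codon alignment is shorter than 150 bp.

## Expression classification

The calls are deliberately threshold rules, not significance tests: with one
sample per tissue there are no replicates to estimate dispersion from, so
model-based DE machinery is replaced by explicit median-of-ratios
normalization (reference genes = nonzero in every tissue; factor = median
ratio to the geometric-mean pseudo-reference; library-size fallback with a
warning when no reference gene exists) and a pseudocount log-ratio,
`log2((a+1)/(b+1))` on normalized counts. "Expressed" is raw count ≥ 10,
and "unexpressed" is its negation, tying the DE rules to the expression
definition. The gonad rule requires raw count > 500 in one gonad, the gene
unexpressed in the other, and |log2FC| > 4; the secretory rule requires raw
count ≥ 500 in at least one sex and |log2FC| > 4, with no unexpressed
requirement. The strict/inclusive inequality pattern follows the rules'
phrasing (">500" vs "at least 500" / "at least ten"). A stricter gonad
variant (|log2FC| > 10), used in some figure-level summaries, is reachable
via `DEConfig(gonad_lfc_min=10)`. Count thresholds are applied to raw
counts — they are phrased as read counts — while the fold change uses
normalized values. Venn partitions enumerate per-gene membership over the
four named sets, so the 15 region counts always sum to the union size.

## Synthetic data

One integer seed drives a named substream per generator (seed sequence
keyed on the generator name), so adding a generator never changes another's
output and identical seeds give byte-identical artifacts.

*Alignments*: 12 taxa × 500 columns by default, matching a typical
vertebrate homolog panel. Planted columns give the focal row a private
letter; elsewhere the requested per-column variability is realized and the
focal letter is guaranteed to recur in another row whenever the profile is
below `n_taxa` (at exactly `n_taxa` all rows are distinct and uniqueness is
unavoidable — such profiles are for column-census checks only).

*Assembly pairs*: 100 shared scaffolds of 1 kb with per-base substitution
divergence (0–0.2), plus planted male-only (default 12) and female-only
(default 0) scaffolds of random sequence. Hit tables are emitted directly
from the construction — one full-length hit per shared pair whose
match/mismatch lengths are the realized substitution counts — rather than by
running an aligner; this keeps the loop tool-free, at the cost of not
modelling split hits, indels or repeats.

*RAD-tags*: 10,000 tags × (25 male + 25 female) samples. Y-linked tags
(default 30) are present in each male with probability 1 − dropout and in
each female with probability `error`; autosomal tags in every sample with
probability 1 − dropout. This matches the polymorphism-free stack setting
(no allelic mismatch within a tag), so dropout is the only male-side noise.

*Counts*: Gamma-Poisson (negative binomial, variance `μ + αμ²`; α = 0
degenerates to Poisson) around a flat base mean (default 100) over a
four-tissue design (testis, ovary, male and female secretory organ), with
library-size multipliers and planted genes: a finite fold scales the up
tissue's mean; an infinite fold plants an exclusive gene with mean
`10 × base` in the up tissue and exactly 0 in its opposite-sex partner.

What the generators do *not* emulate — real flanking-conservation structure,
segmental duplications and repeat-driven spurious hits, RAD locus dropout
correlated with restriction-site polymorphism, and count overdispersion
heterogeneity across genes — bounds what passing recovery tests show: they
validate the calling logic and thresholds, not robustness to assembly or
library artifacts in real data.

## Problem sizes and numerical choices

The benchmark suite runs the generators at the design scales above (500-
column alignments, 100+12 scaffolds at 1 kb, 10,000 × 50 tag matrices,
2,000-gene count tables), which keeps the full test suite under ~10 s while
preserving the study-like sample configuration. Score-oracle agreement is
asserted to relative 1e−12 over 1,000 random instances; the LRT p-value at
the 5% chi-square critical value to 1e−4. Degenerate inputs are handled
explicitly: all-gap alignments, zero-match hits, empty ranking input,
genes with zero counts everywhere (library-size fallback), and non-positive
ω records all either raise a named error or warn and skip, as documented on
each function.

## Known limitations

The scaffold-specificity call is presence/absence of hits, not synteny; the
tag-association defaults (0.8 / 0.08) are a calibration choice, since
"most" is inherently fuzzy; and the DE module's normalization is a
simplification that matches model-based normalization only when most genes
are unchanged between tissues.
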
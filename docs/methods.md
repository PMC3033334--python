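# Methods

## The procedure

The package implements a conservative, replicate-concordance approach to
differential expression on probe-level intensity data, followed by set
construction and annotation statistics.

### Signal summarization

Probe-set intensities are collapsed to one signal per (gene, sample) by the
probe median (default) or a 10%-trimmed mean. This is a deliberately simple,
documented summarizer: robust platform-specific signal computations
(mismatch correction, biweight averaging) are out of scope, and nothing
downstream depends on the summarizer beyond monotonicity — fold changes are
ratios of condition means of these signals.

### Present/Absent detection

For each (gene, sample), the probe intensities are tested against a
background level with a one-sided Wilcoxon signed-rank test; the test is
run on log₂ values, where multiplicative noise is symmetric, so the nominal
level holds under log-normal error (on the raw scale the skew of 2^ε − 1
would bias the rank sum upward). Present ⇔ p < `detection_alpha` (0.05).
With 11 probes the smallest attainable one-sided p is 2⁻¹¹ ≈ 4.9 × 10⁻⁴.
Genes with fewer than 3 probes are conservatively Absent with p = 1.

### Change calls and concordance selection

Every experimental replicate is compared with every reference replicate
(3 × 3 = 9 comparisons). Each comparison is a two-sided signed-rank test on
the matched per-probe log₂ ratios; the direction is the sign of the median
log-ratio when p < `change_alpha`, else NoChange. The rank test family is
operationalized as the matched-probe signed-rank form because probes are
matched within a probe set across samples; an unmatched rank-sum variant is
available via `DEConfig(paired=False)`.

Concordance = max(#Increase, #Decrease) / #pairs. Selection requires the
majority direction to reach the smallest count c with c/n ≥
`concordance_cutoff` (ceiling semantics; 0.77 with 9 pairs ⇒ 7) **and** the
fold change of condition-mean signals to pass `fc_threshold` (2.0) in the
same direction. A Fisher-combined p over the 9 pairwise p-values is
reported for ranking but never used for selection, mirroring the stated
selection criteria exactly. A configurable `min_present` floor on Present
calls in the experimental replicates can additionally gate selection
(default off).

Exact signed-rank null distributions are used for ≤ 25 effective
differences, computed by dynamic programming on doubled (hence integer)
tied-average ranks; above 25 a normal approximation with tie and continuity
corrections applies. Zero differences are dropped; an all-zero vector gives
p = 1. Two-sided p = min(1, 2·min(lower, upper)). These conventions agree
with exhaustive sign-assignment enumeration (tested to n = 12) and with
scipy's exact Wilcoxon on tie-free data.

### Selective sets

Up(c vs r) = selected genes with direction Up. The selective set of
condition c is the intersection of Up(c vs r) over its comparators; with
the default four-population scheme each condition is compared against the
same cell type at the other stage and the other cell type at the same
stage. Venn region counts are enumerated for up to 6 comparator lists.
Disjointness across conditions follows from antisymmetry (a gene 2-fold up
in A vs B cannot be 2-fold up in B vs A) and is asserted on every run.

### Clustering

Distance 1 − Pearson correlation, average linkage (UPGMA), written as an
explicit Lance–Williams agglomeration for a fully deterministic tie-break:
among equally distant pairs, the pair containing the lowest original item
index merges first, and the lower-indexed subtree is placed left. Average
linkage has no inversions, so heights are non-decreasing. Gene-axis
profiles are log₂-transformed and row-standardized (display convention;
correlation is invariant to the standardization itself), sample-axis
profiles use raw log₂. Zero-variance items are dropped with a warning.
Trees export to Newick with branch lengths = parent height − child height.
The implementation is cross-checked against scipy's UPGMA on random
instances.

### Enrichment

Exact hypergeometric tails (scipy's log-space implementation) with
expected = m·n/N. The default universe is the union of category members
("annotated-only", the convention of quoting expected counts against the
annotated fraction of an array); `full_array` mode takes an explicit
universe. Flags are one-sided and uncorrected — the p < 0.001 cutoff plus
the observed > 3 floor is itself the false-positive control — and a
Benjamini–Hochberg column is emitted for diagnostics only. External-list
overlap uses the same statistics after optional ortholog translation; the
map is many-to-many and a gene counts once however many partners map to it.

### Cross-talk

Given a (ligand, receptor) pair table, a hit is a ligand in the sending set
whose receptor is in the receiving set (same-set pairs never count), per
orientation. The completeness statistic — upper hypergeometric tail of the
number of receptors-of-sent-ligands landing in the receiving set, over
random placement in the universe — is this package's own addition for
calibration; the underlying screen is purely combinatorial.

## The simulator

`stageset.simulate` draws probe-level intensities
2^(baseline + gene effect + block effects + probe affinity + noise) for k
conditions × r replicates. Defaults (`default_spec`): 1000 genes × 11
probes, conditions G9/S9/G22/S22 × 3 replicates, baseline 7.0 log₂, gene
spread 1.0 log₂ SD, probe affinity 0.5 log₂ SD, noise 0.35 log₂ SD; one
50-gene selective block per condition at 2.0 log₂ (4-fold) effect; a
60-gene block shared by {G9, S9} at 1.5 log₂, emulating the mitotic program
common to pre-pubertal germ and Sertoli cells; 10% absent genes at a
background intensity of 16 with the same noise and no probe structure; four
planted-enrichment categories (size 40, half drawn from their block) plus
20 null categories sampled uniformly; and three named ligand/receptor
gene pairs planted across the G9/S9 blocks to exercise the cross-talk
screen against the bundled demo pair table. Layout is deterministic
(blocks occupy leading gene indices, absent genes trailing); one seeded
generator draws, in order, gene effects, probe affinities, noise, then
category membership.

What the simulator does **not** emulate: scanner/spatial artifacts,
cross-array normalization effects, probe-sequence-specific bias, correlated
noise between replicates, or realistic annotation structure (categories are
flat sets, not a DAG). Passing tests therefore demonstrate correctness of
the procedure and its statistics under the stated error model, not
performance on raw platform data.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `concordance_cutoff` | 0.77 | fraction of pairwise calls that must agree (7 of 9); 0.60 is accepted as a looser screen |
| `fc_threshold` | 2.0 | fold-change filter on condition means |
| `change_alpha`, `detection_alpha` | 0.05 | per-test levels of the rank tests |
| `p_cutoff`, `min_observed` | 0.001, 4 | enrichment flags: p < 0.001 and observed > 3 |
| `noise_sd_log2` | 0.35 | per-probe log₂ noise SD of the simulator |
| planted `log2_effect` | 2.0 | 4-fold selective elevation |

## Numerical choices and degenerate inputs

* Intensities are floored at 1.0 before taking log₂ (arrays do not report
  meaningful values below ~1); fold-change denominators are floored at 1.0
  intensity unit, numerators at 10⁻⁹ so the ratio stays positive.
* Required concordant count uses ceiling semantics with a 10⁻⁹ guard
  against floating-point under-rounding of cutoff·n.
* Exact-test limits: signed-rank exact to n = 25 (the DP is O(n³) in the
  doubled-rank sum); hypergeometric tails are exact at all sizes.
* Ties in |log-ratios| get averaged ranks; zero ratios are dropped; a gene
  whose probes are identical across the pair yields p = 1, NoChange.
* Empty called set ⇒ FDP 0.0 by convention; a condition with no planted
  genes is excluded from recovery scoring.
* Venn region enumeration is capped at 6 comparator lists (64 regions);
  beyond that only the full intersection and pairwise counts are emitted.

## Design choices

* Selection uses concordance **and** fold change only; the combined p is
  never thresholded. A single configurable cutoff (0.77) is used; the 60%
  figure sometimes quoted for this style of screen is treated as an
  illustrative first-pass value, selectable via config.
* "Selective" requires full selection (concordance + fold change) in every
  comparison, the conservative reading, rather than fold change alone.
* The detection test runs on the log scale (see above) — same contract,
  correct level under multiplicative noise.
* Identifiers are opaque case-sensitive strings; ortholog/symbol mapping is
  always an explicit input table.
* The cross-talk completeness p-value is an extension beyond the
  combinatorial screen, and is labelled as such.

## Problem sizes

The shipped study design (1000 genes × 11 probes × 12 samples) runs the
full pipeline — 8 ordered comparisons × 9 pairwise tests per gene — in a
few seconds on one core; the acceptance script's oracle sweeps (sign
enumeration to n = 12, hypergeometric enumeration to N = 60) add a few
seconds more. Larger universes scale linearly in genes; clustering is the
only super-linear stage (O(n³) agglomeration, practical to a few thousand
leaves).

## Known limitations

* The probe cube requires a constant probe count per gene; ragged probe
  sets are rejected rather than padded.
* No cross-array normalization is provided; inputs are assumed comparable.
* Categories are taken as given (no ontology propagation).
* The normal-approximation branch of the signed-rank test (> 25 probes) is
  approximate in the extreme tails.
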
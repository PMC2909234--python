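# Methods

This note documents the models, estimators and design choices behind
each stage of the pipeline, the synthetic-data generator used to test
them, and the known limitations.

## Divergence estimation

Pairwise K<sub>a</sub>/K<sub>s</sub> uses Nei–Gojobori (1986) counting.
Synonymous site fractions are computed per codon position as the
proportion of synonymous changes among changes that do not create a stop
codon (stop-producing mutations are removed from the denominator, the
convention of DnaSP-style counters); site totals are averaged over the
two sequences. Codons differing at more than one position are resolved
by equal-weight averaging over all minimal mutational pathways,
excluding pathways through stop codons (if every pathway is blocked, all
are used). Proportions are corrected for multiple hits with
Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); a pair with p ≥ 0.75 is flagged
`saturated` and the affected rate is NaN rather than a number. Codons
containing gaps or N in either sequence are skipped pairwise (not by
complete deletion) to maximise comparable sites per pair. The
implementation agrees with Biopython's independent NG86 implementation
to 10⁻⁶ on codons away from stop-codon neighbourhoods, where the two
stop conventions coincide; this is exercised in the test suite.

Known estimator limitations, deliberately retained because the counting
method itself is the documented choice: with transition/transversion
bias the equal-rate site counting is biased, and beyond roughly 15–20%
nucleotide divergence the Jukes–Cantor correction under-corrects
synonymous sites (many are effectively two-state), inflating
K<sub>a</sub>/K<sub>s</sub> by ~10–20%. The neutrality calibration test
therefore runs the estimator in its domain of validity: ω = 1, no
transition bias (κ = 1), pairwise divergence below ~5%, and 2 500 codons
per dataset pooled over three replicates so that genealogical
pseudo-replication (all pairs share the same underlying mutations) does
not dominate the Monte Carlo error.

Amino-acid distances are p-distances over pairwise-comparable columns
(both codons gap-free, unambiguous and non-stop). The clock-like tree is
UPGMA (average linkage, node height = merge distance / 2) with
deterministic lexicographic tie-breaking. UPGMA stands in for a
linearized minimum-evolution tree: both are ultrametric, and every
downstream quantity that matters (lineage ages, close-pair selection) is
defined directly on pairwise distances, minimising sensitivity to the
tree method.

## Positive-selection site calling

The package does not reimplement codon-model likelihood or MCMC
machinery. Externally computed per-site posteriors can be supplied as a
TSV track (`codon_index, prob_a, prob_b, gapped`). Two self-contained
counting detectors make the pipeline runnable end to end:

* **Phylogenetic detector.** Ancestral nucleotides are reconstructed by
  minimum-change parsimony. Sankoff dynamic programming with unit costs
  is used rather than the classical two-pass Fitch refinement because
  the latter is only guaranteed optimal on binary trees; on
  multifurcating genealogies it overcounted changes by ~25% in testing,
  while the Sankoff assignment reproduces true low-divergence
  substitution counts to within a few percent. Ties prefer the parent
  state, then alphabetical order, making the reconstruction
  deterministic. Each inferred change is classified
  synonymous/non-synonymous in its reconstructed codon context (one
  deterministic minimal pathway for multi-step codons). Per codon, the
  score is 1 − P(X ≥ n | n + s, p<sub>N</sub>), a one-sided binomial
  tail with p<sub>N</sub> = N/(N+S) from the codon's own site fractions
  averaged over the column. Gapped codons are not analysed (score 0,
  flagged gapped). The binomial tail is evaluated through the
  regularized incomplete beta function so fractional pathway-averaged
  counts are handled smoothly.

* **Population-genetics detector.** The same binomial score applied to
  synonymous/non-synonymous differences aggregated over *close pairs*
  (amino-acid p-distance < 0.05), where multiple hits are rare. Close
  pairs share mutations through common ancestry, so aggregated counts
  are not independent; the detector is documented as this approximation
  and is used for ranking evidence, not for calibrated error rates.

**Combination rule.** An ungapped codon is called positively selected
iff max(prob_a, prob_b) > 0.95 and min(prob_a, prob_b) > 0.50; a gapped
codon iff prob_b > 0.95. All comparisons are strict, and the rule is
monotone in both probabilities (property-tested). Gapped and ungapped
PSS counts are reported separately.

## Recombination

For every unordered sequence pair, alignment columns that are variable
across the dataset and unambiguous in both sequences are classified
match/mismatch. At each candidate breakpoint, a 2×2 chi-square (no
continuity correction) compares mismatch counts within windows of the 20
nearest variable sites on either side (truncated at the ends); the
maximum chi-square over breakpoints is the pair's statistic, and its
p-value comes from permuting column order (default 1000 permutations,
α = 0.05). Permutations are seeded per pair from a stable hash of the
pair's ids, so scans are bit-reproducible and invariant to the input
order of sequences; permutation batches stop early only when the
p-value's lower bound already exceeds α, which cannot change the set of
reported events. Externally produced event lists can be substituted for
the built-in scan.

Signals are consolidated into independent events by transitively merging
events whose breakpoints lie within 30 nt and whose sequence sets
overlap. The denominator of the headline ratio — the total number of
synonymous mutations implied by the data — is counted on a clock-like
tree by the same parsimony reconstruction as above; at the low
synonymous divergences of allele pairs this is close to model-based
counts (within ~1% of simulation truth on the true tree, ~8% on the
UPGMA tree, in the shipped tests). The ratio is reported to three
decimals, and the fraction of sequences involved in any event is
reported as a lower bound on the recombinant fraction.

Power note: with 20-site windows the scan resolves conversion tracts
spanning roughly ≥ 20 variable sites whose flanks carry a dense
mismatch contrast; shorter or older tracts are genuinely invisible to
the statistic. The recovery tests therefore score recall over
*detectable* planted events (see Simulation below).

## Specificities

Sequences within 5% amino-acid divergence are assumed to share a
specificity: clusters are single-linkage connected components over pairs
with distance ≤ 0.05 (boundary pairs same-specificity, per the strict
">5% means different" reading). A genus is credited with every cluster
containing at least one of its sequences; lineage sharing between genera
A and B is (#clusters containing both)/(#clusters containing A) —
numerator symmetric, denominator row-specific. Lineage ages use the
linear calibration 1% amino-acid divergence = 1 My (configurable).

The rate of appearance of new specificities assumes one amino-acid
change at a positively selected site suffices to create a new
specificity: rate = 100·ΣK (over close pairs) / Σ(PSS differences), as a
ratio of sums (a mean-of-ratios alternative is exposed since the
estimator form is a free choice). Its Poisson corollary,
P(no PSS change) = exp(−K<sub>a</sub>/rate), with the companion
threshold K<sub>a</sub>(p) = −rate·ln p, gives the divergence beyond
which two alleles are unlikely to share a specificity (4.88% < 5% at
K<sub>a</sub> = 0.058 with rate 0.0192); the two functions are exact
inverses (property-tested to 10⁻¹²).

## Replacement changes

Pairs within a nucleotide-difference limit (default 15 nt, configurable;
a statistical-parsimony connection probability is *not* computed) are
linked; within each connected component a minimum spanning forest is
built by Kruskal with ties broken on lexicographic edge ids. Each
amino-acid difference along a forest edge counts as one independent
replacement (multi-step codons decomposed along one deterministic
minimal pathway), which yields the *minimum* number of independent
replacement mutations; reticulations are not added. Changes are
conservative iff both residues fall in one of RHK, DE, NQ, C, AGPST,
ILMV, FWY (charge/volume/polarity groups; they partition the 20
residues, assert-tested). The conservative fraction among PSS changes is
compared with a 35% baseline — an empirical constant from published
protein surveys, taken as given — by an exact two-sided binomial test.

## Population-genetic arithmetic

θ = (SNPs per bp) × 3 treats third codon positions as the silent
fraction of coding sites; μ = θ/(4N<sub>e</sub>) with N<sub>e</sub> =
10⁴ by default (the order implied by allele numbers in natural
populations); projected silent divergence D = μ·(t/g). The per-lineage
convention (no factor 2) is the package default because it reproduces
the standard back-of-envelope endpoints (0.012 at μ = 1.2×10⁻⁷, t = 5
My, g = 50 y; 0.10 at μ = 5×10⁻⁷, g = 25 y); `two_lineage=True` adds the
conventional factor 2 for a diverging pair, and the discrepancy between
the two conventions is deliberately surfaced as a flag rather than
hidden. `generation_time_for` is the exact inverse of
`project_divergence`.

## Structure analysis

PDB files are parsed with Biopython (first model, heavy atoms, waters
and heteroatoms excluded) with Chothia-style radii C 1.70, N 1.55,
O 1.52, S 1.80 Å (other elements fall back to 1.70 Å with a warning).
Accessible surface area is Shrake–Rupley with a 1.4 Å probe and a
deterministic golden-spiral point set (default 960 points/atom; an
isolated atom reproduces 4π(r+p)² essentially exactly). A fixed point
set makes ASA exactly translation invariant and additive over
non-overlapping chains, but rotation invariant only up to sampling
resolution (~1–2% at 960 points) — an inherent property of every
fixed-grid Shrake–Rupley implementation, tested at that tolerance.
Molecular (reduced) surface area is out of scope.

Alignment columns map onto structure residues through a global BLOSUM62
alignment (gap open −11, extend −1) of the reference row's translation
against the structure sequence; unaligned columns stay unmapped and
identity < 30% triggers a warning. PSS vs non-PSS exposure is compared
with a Mann–Whitney U test — exact when the smaller sample has ≤ 8
observations and no ties (verified against brute-force enumeration for
n₁+n₂ ≤ 10), otherwise the tie-corrected normal approximation. Lysine
conservation profiles report, for each lysine of a chosen reference, the
column frequency of K among ungapped sequences, binned
<50% / 50–75% / >75%.

## Synthetic data

`simulate_dataset` emulates the statistical structure of an S-locus
sample:

* **Genealogy.** `n_clades` long stem lineages under a common root
  (total height `crown_depth`, default 0.2 expected substitutions/site)
  each subtend a shallow random clade (height `clade_depth`, default
  0.01); leaves are allocated round-robin to clades and genera
  round-robin within clades, so allelic lineages span genera as real
  trans-generic polymorphism does. Defaults (60 sequences, 200 codons,
  5 clades, 4 genera) give within-clade amino-acid divergence ≲ 2% and
  cross-clade divergence ≳ 10%, so the 5% clustering threshold sits in
  the gap, and a maximum amino-acid divergence around 20–25%,
  matching the scale of the oldest observed allele lineages.
* **Codon evolution.** Exact event-by-event (Gillespie) simulation per
  codon site: single-nucleotide moves with transition bias κ (default
  2), non-synonymous moves multiplied by ω — `omega_pss` (default 5) at
  the 20 planted PSS, `omega_background` (default 0.1) elsewhere — and
  stop codons forbidden. Rates are normalised so one unit of branch
  length equals one expected substitution per nucleotide site for a
  neutral sequence. Every substitution is recorded (branch, site,
  position, states, time, synonymous flag), giving exact count oracles.
* **Gene conversion.** After substitution simulation, events are drawn
  Poisson with expectation `conversion_rate` (default 0.030, the upper
  of the two published-scale estimates) per realized synonymous
  substitution — a post-hoc calibration, since the target statistic is
  defined per synonymous mutation. Each event copies a geometric tract
  (mean 150 nt) from a contemporaneous donor branch into a recipient
  branch at a uniform time point and is inherited by all recipient
  descendants, with the recipient's own later substitutions replayed on
  top of the converted tract. Placements whose tract overlaps an
  earlier event's tract on overlapping lineages are resampled: planted
  events are mutually independent by construction, because a collision
  would overwrite the earlier event's evidence and make its truth label
  wrong. Conversions that would create a stop codon revert that codon.
* **Truth and recovery.** The truth table carries planted PSS, all
  substitutions, all conversion events (tract, time, donor/recipient
  lineages), clade and genus assignments and the true tree.
  `recovery_metrics` scores PSS precision/recall/FPR, specificity
  cluster-count error, synonymous-count relative error, and conversion
  recall. Conversion recall is computed over *detectable* events: a
  planted event is eligible when, for a recipient leaf against a
  donor-side leaf, the 20 nearest variable sites outside each tract
  boundary carry ≥ 8 mismatches while the 20 nearest inside carry ≤ 2 —
  the contrast the windowed chi-square requires. Deep conversions
  (donor near the recipient's own ancestor) fail this filter and are
  information-theoretically invisible, as they are in real data. An
  eligible event is recovered when a detected event involves one of its
  recipient leaves with a breakpoint within 60 nt of either tract edge.

What the generator does **not** emulate: indels and alignment
uncertainty (gaps arise only via masking), codon-usage and base
composition bias, rate heterogeneity beyond the two ω classes,
population-level sampling (sequences are one per lineage tip), and
selection on the conversion process itself. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to alignment error or demographic complications.

## Problem sizes used in the shipped tests

The reference recovery dataset is 60 sequences × 200 codons (seed 1);
conversion recall is pooled over six replicate datasets (seeds 1–6) so
that the handful of detectable events per dataset accumulates to a
stable denominator. The neutrality calibration uses three replicates of
16 sequences × 2 500 codons at low divergence, and the Poisson
branch-count check one dataset of 24 × 800. These sizes keep the whole
suite under a minute while leaving each stochastic assertion several
standard errors of headroom.

## Numerical conventions

All coordinates are 1-based with closed intervals; breakpoints name the
first column right of the break. Probabilities compared with the PSS
thresholds use strict inequalities. Deterministic tie-breaking
everywhere: alphabetical states in parsimony, lexicographic ids in
UPGMA merges, Kruskal edges and pathway orderings; permutation seeds
derive from a CRC of the pair ids (order-invariant, below 2³¹).
Degenerate inputs raise typed errors (`AlignmentError`, `ContentError`,
`ValueError`) rather than returning silent defaults, except where a
documented fill is the contract (missing track codons → probability 0
with a logged warning).
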
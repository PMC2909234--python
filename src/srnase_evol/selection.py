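"""Per-codon positive-selection scoring and the dual-method PSS call.

Full codon-model machinery (phylogenetic site models, population-genetics
MCMC over omega) is deliberately out of scope: external per-site posterior
tracks can be supplied through :class:`~srnase_evol.io.ProbabilityTrack`.
What ships here are two lightweight counting detectors so the pipeline is
self-contained:

* a phylogenetic detector — Fitch parsimony ancestral states, each
  inferred change classified synonymous/non-synonymous in its
  reconstructed codon context, then a one-sided binomial tail against the
  codon's neutral non-synonymous site fraction;
* a population-genetics detector — the same binomial score on
  synonymous/non-synonymous differences aggregated over *close* pairs
  (amino-acid divergence < 5%, which minimizes multiple hits).  Pairs
  share mutations through shared ancestry, so the aggregation is a
  non-independent approximation.

The combination rule calls an ungapped codon positively selected when one
detector exceeds 0.95 and the other exceeds 0.50; a gapped codon (not
analysable phylogenetically) needs the population-genetics detector alone
to exceed 0.95.  Comparisons are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.special import betainc

from .divergence import (
    TreeNode,
    aa_distance_matrix,
    deterministic_pathway,
    is_clean_codon,
    pathway_counts,
    synonymous_sites,
)
from .io import CodonAlignment, ProbabilityTrack

logger = logging.getLogger("srnase_evol")

NUCLEOTIDES = "ACGT"

#: strict posterior-probability thresholds of the combination rule
PRIMARY_THRESHOLD = 0.95
SECONDARY_THRESHOLD = 0.50

#: close-pair cutoff for the population-genetics detector
CLOSE_PAIR_AA_DIVERGENCE = 0.05


def binomial_tail(k: float, n: float, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), continued to real k, n.

    Uses the regularized incomplete beta function, which coincides with
    the binomial survival function at integer arguments and extends it
    smoothly to the fractional counts produced by pathway averaging.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    return float(betainc(k, n - k + 1.0, p))


def _codon_pn(alignment: CodonAlignment, codon_index: int) -> float:
    """Neutral non-synonymous fraction N/(N+S) from the codon's site counts,

    averaged over all clean codons observed in the column."""
    fracs = []
    for c in alignment.codon_column(codon_index):
        if is_clean_codon(c):
            s = synonymous_sites(c)
            fracs.append((3.0 - s) / 3.0)
    if not fracs:
        return 0.75
    return sum(fracs) / len(fracs)


_INF = 10**9


def _fitch_column(
    tree: TreeNode, states: dict[str, str]
) -> dict[int, str]:
    """Minimum-change (parsimony) assignment for one nucleotide column.

    Sankoff dynamic programming with unit substitution costs, exact on
    multifurcating trees.  ``states`` maps leaf name -> nucleotide;
    gaps/N are treated as uninformative (any state at no cost).  Ties
    prefer the parent's state, then alphabetical order, so the
    reconstruction is deterministic.  Returns node id -> nucleotide.
    """
    cost: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            nt = states[node.name or ""]
            if nt in NUCLEOTIDES:
                cost[id(node)] = [0 if s == nt else _INF for s in NUCLEOTIDES]
            else:
                cost[id(node)] = [0, 0, 0, 0]
        else:
            total = [0, 0, 0, 0]
            for child in node.children:
                c = cost[id(child)]
                best = min(c)
                for si in range(4):
                    # stay (cost c[si]) or switch from any state (best + 1)
                    total[si] += min(c[si], best + 1)
            cost[id(node)] = total
    assign: dict[int, str] = {}

    def down(node: TreeNode, parent_index: int | None) -> None:
        c = cost[id(node)]
        if parent_index is None:
            idx = min(range(4), key=lambda s: (c[s], s))
        else:
            idx = min(range(4), key=lambda s: (c[s] + (s != parent_index), s != parent_index, s))
        assign[id(node)] = NUCLEOTIDES[idx]
        for child in node.children:
            down(child, idx)

    down(tree, None)
    return assign


def ancestral_codon_sequences(
    alignment: CodonAlignment, tree: TreeNode
) -> dict[int, str]:
    """Parsimony nucleotide reconstruction at every tree node.

    Returns node id -> full-length nucleotide string (leaves keep their
    observed sequences, with gaps/N replaced by the parsimony state).
    """
    leaf_names = set(tree.leaf_names())
    if leaf_names != set(alignment.ids):
        raise ValueError("tree leaves do not match alignment ids")
    by_id = {r.id: r.residues for r in alignment.records}
    nodes = tree.postorder()
    columns: list[dict[int, str]] = []
    for col in range(alignment.length):
        states = {name: by_id[name][col] for name in leaf_names}
        columns.append(_fitch_column(tree, states))
    return {
        id(node): "".join(columns[col][id(node)] for col in range(alignment.length))
        for node in nodes
    }


def _edge_change_counts(
    tree: TreeNode, sequences: dict[int, str], n_codons: int
) -> tuple[list[float], list[float]]:
    """Per-codon synonymous / non-synonymous change counts over all edges."""
    syn = [0.0] * n_codons
    nonsyn = [0.0] * n_codons
    for node in tree.postorder():
        for child in node.children:
            sp = sequences[id(node)]
            sc = sequences[id(child)]
            for k in range(n_codons):
                cp, cc = sp[3 * k : 3 * k + 3], sc[3 * k : 3 * k + 3]
                if cp == cc:
                    continue
                if not (is_clean_codon(cp) and is_clean_codon(cc)):
                    continue
                for _pos, _c1, _c2, aa1, aa2 in deterministic_pathway(cp, cc):
                    if aa1 == aa2:
                        syn[k] += 1.0
                    else:
                        nonsyn[k] += 1.0
    return syn, nonsyn


def detector_phylo(alignment: CodonAlignment, tree: TreeNode) -> list[float]:
    """Phylogenetic positive-selection score per codon (``prob_a``).

    Codons with alignment gaps are not analysed and score 0.
    """
    if len(alignment.records) < 4:
        raise ValueError("phylogenetic detector needs at least 4 sequences")
    sequences = ancestral_codon_sequences(alignment, tree)
    syn, nonsyn = _edge_change_counts(tree, sequences, alignment.n_codons)
    gapped = alignment.gapped_codons()
    probs = []
    for k in range(1, alignment.n_codons + 1):
        if k in gapped:
            probs.append(0.0)
            continue
        n_obs, s_obs = nonsyn[k - 1], syn[k - 1]
        total = n_obs + s_obs
        if total == 0:
            probs.append(0.0)
            continue
        pn = _codon_pn(alignment, k)
        probs.append(1.0 - binomial_tail(n_obs, total, pn))
    return probs


def detector_popgen(alignment: CodonAlignment) -> list[float]:
    """Population-genetics positive-selection score per codon (``prob_b``).

    Aggregates pairwise synonymous/non-synonymous differences over close
    pairs (amino-acid p-distance < 0.05).  Gapped codons are scored from
    the pairs that are gap-free at that codon.
    """
    if len(alignment.records) < 4:
        raise ValueError("population-genetics detector needs at least 4 sequences")
    dm = aa_distance_matrix(alignment)
    n = len(alignment.records)
    close = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if dm.values[i, j] < CLOSE_PAIR_AA_DIVERGENCE
    ]
    if not close:
        logger.warning(
            "no sequence pairs below %.0f%% amino-acid divergence; "
            "population-genetics track is all zero",
            100 * CLOSE_PAIR_AA_DIVERGENCE,
        )
        return [0.0] * alignment.n_codons
    probs = []
    for k in range(1, alignment.n_codons + 1):
        syn = nonsyn = 0.0
        column = alignment.codon_column(k)
        for i, j in close:
            ci, cj = column[i], column[j]
            if ci == cj or not (is_clean_codon(ci) and is_clean_codon(cj)):
                continue
            s, ns = pathway_counts(ci, cj)
            syn += s
            nonsyn += ns
        total = syn + nonsyn
        if total == 0:
            probs.append(0.0)
            continue
        pn = _codon_pn(alignment, k)
        probs.append(1.0 - binomial_tail(nonsyn, total, pn))
    return probs


@dataclass(frozen=True)
class SiteSelectionProfile:
    """Final positively-selected-site (PSS) calls with their evidence."""

    prob_a: tuple[float, ...]
    prob_b: tuple[float, ...]
    gapped: tuple[bool, ...]
    is_pss: tuple[bool, ...]

    @property
    def pss_set(self) -> frozenset[int]:
        """1-based codon indices called positively selected."""
        return frozenset(k + 1 for k, f in enumerate(self.is_pss) if f)

    @property
    def n_ungapped_pss(self) -> int:
        return sum(1 for f, g in zip(self.is_pss, self.gapped) if f and not g)

    @property
    def n_gapped_pss(self) -> int:
        return sum(1 for f, g in zip(self.is_pss, self.gapped) if f and g)

    @property
    def n_codons(self) -> int:
        return len(self.is_pss)


def call_pss(track: ProbabilityTrack) -> SiteSelectionProfile:
    """Apply the dual-method combination rule to a probability track.

    Ungapped codon: PSS iff max(prob_a, prob_b) > 0.95 and
    min(prob_a, prob_b) > 0.50.  Gapped codon: PSS iff prob_b > 0.95.
    All comparisons strict.
    """
    calls = []
    for pa, pb, g in zip(track.prob_a, track.prob_b, track.gapped):
        if g:
            calls.append(pb > PRIMARY_THRESHOLD)
        else:
            calls.append(
                max(pa, pb) > PRIMARY_THRESHOLD and min(pa, pb) > SECONDARY_THRESHOLD
            )
    return SiteSelectionProfile(
        prob_a=tuple(track.prob_a),
        prob_b=tuple(track.prob_b),
        gapped=tuple(track.gapped),
        is_pss=tuple(calls),
    )


def build_selection_profile(
    alignment: CodonAlignment, tree: TreeNode | None = None
) -> SiteSelectionProfile:
    """Run both stand-in detectors and the combination rule end to end."""
    if tree is None:
        from .divergence import linearized_tree

        tree = linearized_tree(aa_distance_matrix(alignment))
    prob_a = detector_phylo(alignment, tree)
    prob_b = detector_popgen(alignment)
    gapped = alignment.gapped_codons()
    track = ProbabilityTrack(
        prob_a=prob_a,
        prob_b=prob_b,
        gapped=[k in gapped for k in range(1, alignment.n_codons + 1)],
    )
    return call_pss(track)


def profile_to_track(profile: SiteSelectionProfile) -> ProbabilityTrack:
    return ProbabilityTrack(
        prob_a=list(profile.prob_a),
        prob_b=list(profile.prob_b),
        gapped=list(profile.gapped),
    )
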
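"""Pairwise divergence estimation and clock-like trees.

Synonymous (Ks) and non-synonymous (Ka) per-site rates are computed by
Nei–Gojobori (1986) counting with Jukes–Cantor correction for multiple
hits.  Amino-acid p-distances feed an average-linkage (UPGMA) ultrametric
tree used as the linearized, clock-like stand-in for lineage-age work:
ages are defined directly on pairwise distances, so the tree method
matters little downstream.

Conventions (following common population-genetics software practice):

* synonymous site fractions per codon position count only changes that do
  not create a stop codon (stop-producing mutations are excluded from the
  denominator);
* codons differing at several positions are resolved by equal-weight
  averaging over all minimal mutational pathways, excluding pathways that
  pass through a stop codon (falling back to all pathways when every
  pathway is blocked);
* codons containing a gap or N in either sequence are skipped pairwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .io import STOP_CODONS, CodonAlignment

NUCLEOTIDES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, '*' for stops
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    GENETIC_CODE[_stop] = "*"


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid, '*' for stop, None for gapped/ambiguous codons."""
    return GENETIC_CODE.get(codon)


def is_clean_codon(codon: str) -> bool:
    """True for a fully resolved, non-stop sense codon."""
    aa = GENETIC_CODE.get(codon)
    return aa is not None and aa != "*"


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (NG86).

    Each position contributes the fraction of its possible changes that
    are synonymous, among changes not producing a stop codon.
    """
    if not is_clean_codon(codon):
        raise ValueError(f"cannot count sites of codon {codon!r}")
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        if n_valid:
            total += n_syn / n_valid
    return total


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons.

    Minimal mutational pathways are averaged with equal weight; pathways
    passing through a stop codon are excluded (all pathways are used if
    every one is blocked).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        syn = nonsyn = 0
        cur = c1
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            if GENETIC_CODE.get(nxt, "*") == GENETIC_CODE.get(cur, "*"):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (valid if ok else blocked).append((syn, nonsyn))
    use = valid or blocked
    s = sum(v[0] for v in use) / len(use)
    n = sum(v[1] for v in use) / len(use)
    return s, n


@lru_cache(maxsize=None)
def deterministic_pathway(
    c1: str, c2: str
) -> tuple[tuple[int, str, str, str, str], ...]:
    """One minimal pathway c1 -> c2, chosen reproducibly.

    The first position ordering (in lexicographic order of positions) that
    avoids stop codons is used; if all orderings hit a stop, the first
    ordering is used.  Each step is
    ``(position, from_codon, to_codon, from_aa, to_aa)``.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    chosen = None
    first = None
    for order in itertools.permutations(diffs):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            steps.append(
                (pos, cur, nxt, GENETIC_CODE.get(cur, "*"), GENETIC_CODE.get(nxt, "*"))
            )
            cur = nxt
        if first is None:
            first = steps
        if ok:
            chosen = steps
            break
    return tuple(chosen if chosen is not None else first or [])


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - (4/3) p); p < 0.75."""
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    if p >= 0.75:
        raise ValueError("p >= 0.75 is outside the Jukes-Cantor domain (saturated)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jukes_cantor_inverse(d: float) -> float:
    """p-distance implied by a JC distance d (inverse of :func:`jukes_cantor`)."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass(frozen=True)
class PairDivergence:
    """Nei–Gojobori Ka/Ks and amino-acid distance for one sequence pair."""

    id_pair: tuple[str, str]
    ka: float  # nan when saturated
    ks: float  # nan when saturated
    p_aa: float
    n_aa_diffs: int
    n_codons_compared: int
    saturated: bool = False


def kaks_pair(seq1: str, seq2: str, ids: tuple[str, str] = ("seq1", "seq2")) -> PairDivergence:
    """NG86 Ka/Ks with JC correction for one aligned codon-sequence pair.

    Codons containing a gap or N, or a stop, in either sequence are
    skipped pairwise.  ``saturated`` is set (and the affected rate is NaN)
    when a p-distance reaches the JC domain boundary of 0.75.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences have unequal lengths")
    if len(seq1) % 3:
        raise ValueError("sequence length not divisible by 3")
    s_sites = 0.0
    n_sites = 0.0
    sd = 0.0
    nd = 0.0
    n_codons = 0
    n_aa_diffs = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (is_clean_codon(c1) and is_clean_codon(c2)):
            continue
        n_codons += 1
        s_sites += 0.5 * (synonymous_sites(c1) + synonymous_sites(c2))
        s, n = pathway_counts(c1, c2)
        sd += s
        nd += n
        if GENETIC_CODE[c1] != GENETIC_CODE[c2]:
            n_aa_diffs += 1
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ks = float("nan") if ps >= 0.75 else jukes_cantor(ps)
    ka = float("nan") if pn >= 0.75 else jukes_cantor(pn)
    return PairDivergence(
        id_pair=ids,
        ka=ka,
        ks=ks,
        p_aa=n_aa_diffs / n_codons,
        n_aa_diffs=n_aa_diffs,
        n_codons_compared=n_codons,
        saturated=saturated,
    )


def all_pairs_kaks(alignment: CodonAlignment) -> list[PairDivergence]:
    """Ka/Ks/p_aa for every unordered sequence pair of an alignment."""
    out = []
    recs = alignment.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            out.append(
                kaks_pair(recs[i].residues, recs[j].residues, (recs[i].id, recs[j].id))
            )
    return out


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with named rows."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def aa_distance_matrix(alignment: CodonAlignment) -> DistanceMatrix:
    """Amino-acid p-distance matrix over pairwise-ungapped codon columns."""
    n = len(alignment.records)
    # translate once; None marks gapped/ambiguous or stop codons
    prots: list[list[str | None]] = []
    for r in alignment.records:
        aas = []
        for i in range(0, alignment.length, 3):
            c = r.residues[i : i + 3]
            aas.append(GENETIC_CODE[c] if is_clean_codon(c) else None)
        prots.append(aas)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = comp = 0
            for a, b in zip(prots[i], prots[j]):
                if a is None or b is None:
                    continue
                comp += 1
                diffs += a != b
            if comp == 0:
                raise ValueError(
                    f"no comparable residues between {alignment.records[i].id} "
                    f"and {alignment.records[j].id}"
                )
            m[i, j] = m[j, i] = diffs / comp
    return DistanceMatrix(ids=tuple(alignment.ids), values=m)


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name or "" for l in self.leaves()]

    def postorder(self) -> list["TreeNode"]:
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{blen:.6f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{blen:.6f}"

        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def linearized_tree(matrix: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) ultrametric tree from a distance matrix.

    Node height is half the merge distance; ties are broken by the
    lexicographically smallest member ids, so the result is deterministic.
    """
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    # active clusters: key = smallest member id
    nodes: dict[str, TreeNode] = {
        i: TreeNode(height=0.0, name=i) for i in matrix.ids
    }
    sizes: dict[str, int] = {i: 1 for i in matrix.ids}
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((matrix.ids[i], matrix.ids[j]))] = float(
                matrix.values[i, j]
            )
    while len(nodes) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], a, b)
                for a, b in itertools.combinations(sorted(nodes), 2)
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, a, b = best
        merged = TreeNode(height=d / 2.0, children=(nodes[a], nodes[b]))
        key = min(a, b)
        other_key = max(a, b)
        na, nb = sizes[a], sizes[b]
        for c in list(nodes):
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((key, c))] = (na * dac + nb * dbc) / (na + nb)
        dist.pop(frozenset((a, b)))
        del nodes[other_key]
        nodes[key] = merged
        sizes[key] = na + nb
        sizes.pop(other_key)
    (root,) = nodes.values()
    return root
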
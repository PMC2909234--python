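"""Independent amino-acid replacements at positively selected sites.

Closely related sequences are linked into a parsimony-style network (pairs
within a nucleotide-difference limit), a minimum spanning forest is taken
within each connected component, and each amino-acid difference along a
forest edge is counted as one independent replacement — the minimum number
of replacement mutations implied by the data.  Replacements are classified
conservative/non-conservative by the charge/volume/polarity groups
RHK, DE, NQ, C, AGPST, ILMV, FWY.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from .divergence import GENETIC_CODE, deterministic_pathway, is_clean_codon
from .io import CodonAlignment
from .selection import SiteSelectionProfile

#: amino-acid groups within which a change is conservative
CONSERVATIVE_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("RHK"),
    frozenset("DE"),
    frozenset("NQ"),
    frozenset("C"),
    frozenset("AGPST"),
    frozenset("ILMV"),
    frozenset("FWY"),
)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: empirical genome-wide expectation for the conservative fraction
DEFAULT_CONSERVATIVE_BASELINE = 0.35

DEFAULT_CONNECTION_LIMIT = 15


@dataclass(frozen=True)
class ParsimonyNetwork:
    """Sequences linked within a difference limit, with a spanning forest."""

    ids: tuple[str, ...]
    edges: dict[tuple[str, str], int]          # all edges within the limit
    forest_edges: tuple[tuple[str, str], ...]  # MSF edges (sorted id pairs)
    components: tuple[frozenset[str], ...]
    connection_limit: int


@dataclass(frozen=True)
class ReplacementChange:
    """One independent amino-acid replacement on a forest edge."""

    codon_index: int
    from_aa: str
    to_aa: str
    edge: tuple[str, str]
    at_pss: bool
    conservative: bool


def _pair_nt_diffs(s1: str, s2: str) -> int:
    """Nucleotide differences over positions where both are unambiguous."""
    return sum(
        1
        for a, b in zip(s1, s2)
        if a != b and a in "ACGT" and b in "ACGT"
    )


def build_network(
    alignment: CodonAlignment, connection_limit: int = DEFAULT_CONNECTION_LIMIT
) -> ParsimonyNetwork:
    """Link pairs within ``connection_limit`` nt differences; MSF per component.

    Kruskal on edges sorted by (weight, id pair) makes the forest
    deterministic under sequence reordering.
    """
    if connection_limit < 1:
        raise ValueError("connection limit must be >= 1")
    ids = tuple(sorted(alignment.ids))
    seq = {r.id: r.residues for r in alignment.records}
    edges: dict[tuple[str, str], int] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = _pair_nt_diffs(seq[ids[i]], seq[ids[j]])
            if d <= connection_limit:
                edges[(ids[i], ids[j])] = d
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    forest = []
    for (a, b), w in sorted(edges.items(), key=lambda kv: (kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            forest.append((a, b))
    comp_members: dict[str, set[str]] = {}
    for i in ids:
        comp_members.setdefault(find(i), set()).add(i)
    components = tuple(
        sorted((frozenset(m) for m in comp_members.values()), key=min)
    )
    return ParsimonyNetwork(
        ids=ids,
        edges=edges,
        forest_edges=tuple(forest),
        components=components,
        connection_limit=connection_limit,
    )


def classify_change(from_aa: str, to_aa: str) -> bool:
    """True when the replacement is conservative (same group), else False."""
    if from_aa not in STANDARD_RESIDUES or to_aa not in STANDARD_RESIDUES:
        raise ValueError(f"nonstandard residue in change {from_aa}->{to_aa}")
    if from_aa == to_aa:
        raise ValueError("identical residues do not constitute a change")
    return any(from_aa in g and to_aa in g for g in CONSERVATIVE_GROUPS)


def enumerate_replacements(
    network: ParsimonyNetwork,
    alignment: CodonAlignment,
    pss: SiteSelectionProfile,
) -> list[ReplacementChange]:
    """All amino-acid replacements along the spanning forest.

    Codons differing at several positions are decomposed along one
    deterministic minimal pathway; every amino-acid-changing step counts
    as one replacement.
    """
    seq = {r.id: r.residues for r in alignment.records}
    pss_set = pss.pss_set
    out: list[ReplacementChange] = []
    for a, b in network.forest_edges:
        s1, s2 = seq[a], seq[b]
        for k in range(1, alignment.n_codons + 1):
            c1, c2 = s1[3 * (k - 1) : 3 * k], s2[3 * (k - 1) : 3 * k]
            if c1 == c2 or not (is_clean_codon(c1) and is_clean_codon(c2)):
                continue
            for _pos, _f, _t, aa1, aa2 in deterministic_pathway(c1, c2):
                if aa1 == aa2 or "*" in (aa1, aa2):
                    continue
                out.append(
                    ReplacementChange(
                        codon_index=k,
                        from_aa=aa1,
                        to_aa=aa2,
                        edge=(a, b),
                        at_pss=k in pss_set,
                        conservative=classify_change(aa1, aa2),
                    )
                )
    return out


@dataclass(frozen=True)
class ConservativeSummary:
    n_changes: int
    n_conservative: int
    fraction_conservative: float
    baseline: float
    p_value: float


def conservative_summary(
    changes: list[ReplacementChange],
    baseline: float = DEFAULT_CONSERVATIVE_BASELINE,
    at_pss_only: bool = True,
) -> ConservativeSummary:
    """Conservative fraction among replacements (at PSS by default) with a
    two-sided exact binomial test against the expected baseline."""
    use = [c for c in changes if c.at_pss] if at_pss_only else list(changes)
    if not use:
        raise ValueError("no replacement changes to summarise")
    k = sum(1 for c in use if c.conservative)
    n = len(use)
    test = binomtest(k, n, baseline, alternative="two-sided")
    return ConservativeSummary(
        n_changes=n,
        n_conservative=k,
        fraction_conservative=k / n,
        baseline=baseline,
        p_value=float(test.pvalue),
    )
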
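"""Specificity clustering, sharing across genera, ages and the rate of
appearance of new specificities.

Under balancing selection, functionally distinct S-alleles (specificities)
are long-lived, so sequences closer than 5% amino-acid divergence are
treated as the same specificity and clusters spanning several genera mark
ancestral (trans-generic) lineages.  The rate at which new specificities
arise is estimated from close sequence pairs under the assumption that a
single amino-acid change at a positively selected site is enough to create
a new specificity; its Poisson corollary gives the divergence beyond which
a pair is unlikely (<5%) to share a specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .divergence import DistanceMatrix

DEFAULT_THRESHOLD = 0.05
#: My of lineage age per unit amino-acid divergence (1% divergence = 1 My)
DEFAULT_CALIBRATION_MY = 100.0
#: non-synonymous divergence per new specificity (1.92%)
DEFAULT_KA_PER_SPECIFICITY = 0.0192


@dataclass(frozen=True)
class SpecificityPartition:
    """Clusters of sequences deemed one specificity each."""

    clusters: tuple[frozenset[str], ...]
    genus_of: dict[str, str]
    threshold: float

    @property
    def n_specificities(self) -> int:
        return len(self.clusters)

    def genus_composition(self, cluster: frozenset[str]) -> set[str]:
        return {self.genus_of.get(i, "unknown") or "unknown" for i in cluster}


@dataclass(frozen=True)
class ClosePair:
    """A sequence pair below the specificity threshold, with its divergence."""

    id_pair: tuple[str, str]
    ka: float
    ks: float
    n_aa_diffs: int
    n_pss_diffs: int

    def __post_init__(self) -> None:
        if self.n_pss_diffs > self.n_aa_diffs:
            raise ValueError("PSS differences cannot exceed amino-acid differences")


@dataclass(frozen=True)
class SpecificityRate:
    """Percent divergence accumulated per new specificity."""

    ks_per_new_specificity: float
    ka_per_new_specificity: float


def cluster_specificities(
    matrix: DistanceMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    genus_of: dict[str, str] | None = None,
) -> SpecificityPartition:
    """Single-linkage specificity clusters at the given distance threshold.

    Pairs at distance <= threshold are linked; connected components are the
    specificities (so >5% divergence means a different specificity, with
    boundary pairs kept together).  Clusters are ordered by their smallest
    member id.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] <= threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j])
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=min
    )
    return SpecificityPartition(
        clusters=tuple(comps),
        genus_of=dict(genus_of or {}),
        threshold=threshold,
    )


def genus_counts(partition: SpecificityPartition) -> dict[str, int]:
    """Specificities per genus, plus the overall count under key 'total'.

    A genus is credited with every cluster containing at least one of its
    sequences; the total is simply the number of clusters.
    """
    counts: dict[str, int] = {}
    for cluster in partition.clusters:
        for genus in partition.genus_composition(cluster):
            counts[genus] = counts.get(genus, 0) + 1
    counts["total"] = partition.n_specificities
    return counts


def shared_lineages(
    partition: SpecificityPartition,
) -> dict[tuple[str, str], tuple[int, int, float]]:
    """Fraction of each genus's lineages shared with every other genus.

    Entry (A, B) -> (shared, total_A, fraction): the number of clusters
    containing both genera over the number containing A.  The numerator is
    symmetric; the denominator is row-specific, so the table is not.
    """
    genera = sorted(
        {g for c in partition.clusters for g in partition.genus_composition(c)}
    )
    if len(genera) < 2:
        raise ValueError("need at least 2 genera to compute lineage sharing")
    per_genus = {
        g: [c for c in partition.clusters if g in partition.genus_composition(c)]
        for g in genera
    }
    out: dict[tuple[str, str], tuple[int, int, float]] = {}
    for a in genera:
        denom = len(per_genus[a])
        if denom == 0:
            continue
        for b in genera:
            if a == b:
                continue
            shared = sum(
                1 for c in per_genus[a] if b in partition.genus_composition(c)
            )
            out[(a, b)] = (shared, denom, shared / denom)
    return out


def lineage_ages(
    matrix: DistanceMatrix, calibration_my: float = DEFAULT_CALIBRATION_MY
) -> tuple[dict[tuple[str, str], float], float]:
    """Lineage ages in My from amino-acid divergence (default 1% = 1 My).

    Returns (per-pair ages, maximum age).  The oldest pairwise age bounds
    the age of the oldest specificity lineage in the sample.
    """
    ages: dict[tuple[str, str], float] = {}
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            ages[(matrix.ids[i], matrix.ids[j])] = (
                float(matrix.values[i, j]) * calibration_my
            )
    return ages, max(ages.values()) if ages else 0.0


def new_specificity_rate(
    pairs: list[ClosePair], estimator: str = "ratio_of_sums"
) -> SpecificityRate:
    """Synonymous / non-synonymous divergence per new specificity (percent).

    ``ratio_of_sums`` (default) divides total divergence by total PSS
    differences; ``mean_of_ratios`` averages per-pair ratios over pairs
    with at least one PSS difference.
    """
    total_pss = sum(p.n_pss_diffs for p in pairs)
    if total_pss == 0:
        raise ValueError("no differences at positively selected sites; rate undefined")
    if estimator == "ratio_of_sums":
        ks = 100.0 * sum(p.ks for p in pairs) / total_pss
        ka = 100.0 * sum(p.ka for p in pairs) / total_pss
    elif estimator == "mean_of_ratios":
        with_hits = [p for p in pairs if p.n_pss_diffs > 0]
        ks = 100.0 * sum(p.ks / p.n_pss_diffs for p in with_hits) / len(with_hits)
        ka = 100.0 * sum(p.ka / p.n_pss_diffs for p in with_hits) / len(with_hits)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return SpecificityRate(ks_per_new_specificity=ks, ka_per_new_specificity=ka)


def poisson_no_hit(
    ka: float, ka_per_specificity: float = DEFAULT_KA_PER_SPECIFICITY
) -> float:
    """P(zero PSS changes) for a pair at non-synonymous divergence ``ka``.

    PSS changes accrue as a Poisson process with one expected change per
    ``ka_per_specificity`` units of non-synonymous divergence, so the
    zero-hit probability is exp(-ka / rate).
    """
    if ka < 0:
        raise ValueError("divergence must be non-negative")
    if ka_per_specificity <= 0:
        raise ValueError("rate must be positive")
    return math.exp(-ka / ka_per_specificity)


def threshold_ka(
    p: float, ka_per_specificity: float = DEFAULT_KA_PER_SPECIFICITY
) -> float:
    """Non-synonymous divergence beyond which P(zero PSS changes) < p."""
    if not 0 < p <= 1:
        raise ValueError("probability must be in (0, 1]")
    return -ka_per_specificity * math.log(p)
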
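"""Gene-conversion / recombination detection and the events-per-synonymous-
mutation ratio.

At an S-locus, recombination is expected to be rare and dominated by short
gene-conversion tracts.  The detector here is a pairwise maximum
chi-square (MaxChi) scan: for every sequence pair, variable alignment
columns are classified match/mismatch, and at each candidate breakpoint a
2x2 chi-square compares mismatch counts in windows of the ``window``
nearest variable sites on either side.  Significance is assessed by
permuting column order (seeded, bit-reproducible, invariant to the input
order of sequences).  Externally produced event lists (e.g. from
multi-method recombination scanners) can be fed to the consolidation and
ratio stages through the same event records.

The denominator of the headline statistic — the total number of
synonymous mutations implied by the data — is counted on a clock-like
tree by parsimony ancestral reconstruction, which is adequate at the low
synonymous divergences typical of allele pairs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .divergence import TreeNode
from .io import CodonAlignment
from .selection import _edge_change_counts, ancestral_codon_sequences

DEFAULT_WINDOW = 20
DEFAULT_PERMUTATIONS = 1000
DEFAULT_ALPHA = 0.05
DEFAULT_BREAKPOINT_TOLERANCE = 30

_NT = frozenset("ACGT")


@dataclass(frozen=True)
class RecombinationEvent:
    """One candidate conversion signal between a sequence pair."""

    seq1: str
    seq2: str
    breakpoint: int  # 1-based alignment column; first column right of the break
    chi2: float
    p_value: float


@dataclass(frozen=True)
class RecombinationReport:
    events: tuple[RecombinationEvent, ...]
    n_independent_events: int
    n_syn_mutations: float
    ratio: float
    recombinant_ids: frozenset[str]
    n_sequences: int

    @property
    def percent_recombinant_sequences(self) -> float:
        """Lower bound on the fraction of sequences touched by an event."""
        return 100.0 * len(self.recombinant_ids) / self.n_sequences


def _max_chi2_rows(y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Max windowed 2x2 chi-square per row of a 0/1 matrix.

    ``y`` has shape (rows, m); each row is a mismatch indicator over m
    variable sites.  Returns (max chi2 per row, argmax breakpoint index
    per row), where breakpoint index b means the break falls before
    variable site b (0-based).
    """
    rows, m = y.shape
    if m < 2:
        return np.zeros(rows), np.zeros(rows, dtype=int)
    c = np.concatenate([np.zeros((rows, 1)), np.cumsum(y, axis=1)], axis=1)
    b = np.arange(1, m)
    l0 = np.maximum(0, b - window)
    r1 = np.minimum(m, b + window)
    a = c[:, b] - c[:, l0]          # mismatches left
    nl = (b - l0).astype(float)     # sites left
    cc = c[:, r1] - c[:, b]         # mismatches right
    nr = (r1 - b).astype(float)     # sites right
    bb = nl - a                     # matches left
    dd = nr - cc                    # matches right
    n = nl + nr
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            n
            * (a * dd - bb * cc) ** 2
            / (nl * nr * (a + cc) * (bb + dd))
        )
    chi2 = np.nan_to_num(chi2, nan=0.0, posinf=0.0)
    arg = np.argmax(chi2, axis=1)
    return chi2[np.arange(rows), arg], b[arg]


def _pair_seed(seed: int, id1: str, id2: str) -> int:
    """Stable per-pair RNG seed independent of sequence input order."""
    a, b = sorted((id1, id2))
    return zlib.crc32(f"{seed}:{a}|{b}".encode()) & 0x7FFFFFFF


def maxchi_scan(
    alignment: CodonAlignment,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    window: int = DEFAULT_WINDOW,
) -> list[RecombinationEvent]:
    """MaxChi breakpoint scan over all unordered sequence pairs.

    Returns events with permutation p-value below ``alpha``.  Permutations
    stop early (in batches of 100) once a pair is clearly non-significant,
    which does not change which events are reported.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    seqs = {r.id: np.frombuffer(r.residues.encode(), dtype="S1") for r in alignment.records}
    ids = sorted(seqs)
    arr = np.stack([seqs[i] for i in ids])
    is_nt = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    # columns variable across the alignment (ignoring gaps/N)
    variable_cols = []
    for col in range(alignment.length):
        vals = set(arr[is_nt[:, col], col].tolist())
        if len(vals) >= 2:
            variable_cols.append(col)
    events: list[RecombinationEvent] = []
    if not variable_cols:
        return events
    vc = np.array(variable_cols)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both = is_nt[i, vc] & is_nt[j, vc]
            cols = vc[both]
            if cols.size < 4:
                continue
            y = (arr[i, cols] != arr[j, cols]).astype(float)
            n_mismatch = int(y.sum())
            if n_mismatch == 0 or n_mismatch == cols.size:
                continue
            obs, arg = _max_chi2_rows(y[None, :], window)
            obs_chi2 = float(obs[0])
            if obs_chi2 <= 0:
                continue
            breakpoint = int(cols[int(arg[0])]) + 1  # 1-based column right of break
            rng = np.random.default_rng(_pair_seed(seed, ids[i], ids[j]))
            exceed = 0
            done = 0
            while done < n_permutations:
                batch = min(100, n_permutations - done)
                perms = rng.permuted(
                    np.tile(y, (batch, 1)), axis=1
                )
                mx, _ = _max_chi2_rows(perms, window)
                exceed += int(np.sum(mx >= obs_chi2))
                done += batch
                # clearly non-significant: p-value lower bound already > alpha
                if (exceed + 1) / (n_permutations + 1) > alpha:
                    break
            p = (exceed + 1) / (done + 1)
            if p < alpha:
                events.append(
                    RecombinationEvent(
                        seq1=ids[i], seq2=ids[j],
                        breakpoint=breakpoint, chi2=obs_chi2, p_value=p,
                    )
                )
    return events


def consolidate_events(
    events: list[RecombinationEvent],
    breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE,
) -> tuple[int, frozenset[str]]:
    """Merge signals of the same underlying event.

    Two events are merged when their breakpoints differ by at most the
    tolerance and their sequence sets overlap (transitively).  Returns the
    number of independent events and the union of involved sequence ids.
    """
    n = len(events)
    if n == 0:
        return 0, frozenset()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sets = [{e.seq1, e.seq2} for e in events]
    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(events[i].breakpoint - events[j].breakpoint)
                <= breakpoint_tolerance
                and sets[i] & sets[j]
            ):
                parent[find(i)] = find(j)
    groups = {find(i) for i in range(n)}
    ids = frozenset().union(*sets)
    return len(groups), ids


def count_syn_mutations(alignment: CodonAlignment, tree: TreeNode) -> float:
    """Total synonymous mutations implied by the data on a tree.

    Parsimony ancestral reconstruction; every inferred nucleotide change
    is classified in its reconstructed codon context.
    """
    sequences = ancestral_codon_sequences(alignment, tree)
    syn, _nonsyn = _edge_change_counts(tree, sequences, alignment.n_codons)
    return float(sum(syn))


def recomb_per_synmut(n_events: int, n_syn: float) -> float:
    """Independent recombination events per synonymous mutation (3 decimals)."""
    if n_syn <= 0:
        raise ValueError("undefined ratio: synonymous mutation count must be > 0")
    return round(n_events / n_syn, 3)


def build_report(
    alignment: CodonAlignment,
    tree: TreeNode,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    window: int = DEFAULT_WINDOW,
    breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE,
    events: list[RecombinationEvent] | None = None,
) -> RecombinationReport:
    """Scan, consolidate and normalise by the synonymous mutation count.

    ``events`` may be supplied externally (e.g. parsed from another
    recombination scanner) to skip the built-in MaxChi scan.
    """
    if events is None:
        events = maxchi_scan(alignment, n_permutations, seed, alpha, window)
    n_indep, ids = consolidate_events(events, breakpoint_tolerance)
    n_syn = count_syn_mutations(alignment, tree)
    ratio = recomb_per_synmut(n_indep, n_syn) if n_syn > 0 else float("nan")
    return RecombinationReport(
        events=tuple(events),
        n_independent_events=n_indep,
        n_syn_mutations=n_syn,
        ratio=ratio,
        recombinant_ids=ids,
        n_sequences=len(alignment.records),
    )
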
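"""Synthetic S-allele codon alignments with known truth.

The generator reproduces the statistical structure the analyses assume:

* a clock-like genealogy with ``n_clades`` long-lived specificity
  lineages — long internal stems (total height ``crown_depth`` expected
  substitutions per site) each subtending a shallow clade (height
  ``clade_depth``), so that specificity clusters are separated by deep
  divergence and cohesive within;
* genera assigned round-robin within clades, so ancestral lineages span
  genera (trans-generic sharing);
* codon evolution by an exact event-by-event (Gillespie) process with
  transition/transversion bias ``kappa`` and per-site selection classes:
  non-synonymous changes are accelerated by ``omega_pss`` at planted
  positively selected sites and damped by ``omega_background`` elsewhere;
  stop codons are forbidden;
* rare gene-conversion events superimposed as a Poisson process
  calibrated post hoc so the expected number of events per *realized*
  synonymous substitution equals ``conversion_rate``; each event copies a
  geometric-length tract from a contemporaneous donor lineage into a
  recipient branch and is inherited by all its descendants.

Every substitution and conversion is recorded in a truth table, enabling
exact parameter-recovery oracles (site calls, breakpoints, cluster counts,
synonymous-mutation counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .divergence import GENETIC_CODE, TreeNode
from .io import CodonAlignment, alignment_from_strings
from .recombination import RecombinationEvent
from .selection import SiteSelectionProfile
from .specificity import SpecificityPartition

GENUS_POOL = (
    "Malus", "Pyrus", "Sorbus", "Crataegus",
    "Eriobotrya", "Cydonia", "Amelanchier", "Chaenomeles",
)

SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n_sequences: int = 60
    n_codons: int = 200
    n_clades: int = 5
    n_genera: int = 4
    clade_depth: float = 0.01
    crown_depth: float = 0.2
    n_pss: int = 20
    pss_positions: tuple[int, ...] | None = None
    omega_pss: float = 5.0
    omega_background: float = 0.1
    kappa: float = 2.0
    conversion_rate: float = 0.03
    tract_length_mean: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega_pss <= 0 or self.omega_background <= 0:
            raise ValueError("omega values must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.clade_depth < self.crown_depth:
            raise ValueError("need 0 < clade_depth < crown_depth")
        if self.n_pss > self.n_codons:
            raise ValueError("more planted PSS than codons")
        if self.conversion_rate < 0:
            raise ValueError("conversion rate must be non-negative")
        if self.n_clades < 1 or self.n_sequences < self.n_clades:
            raise ValueError("need at least one sequence per clade")
        if self.n_genera > len(GENUS_POOL):
            raise ValueError(f"at most {len(GENUS_POOL)} genera supported")


@dataclass(frozen=True)
class Substitution:
    branch: int          # child-node id of the branch
    site: int            # 1-based codon index
    position: int        # 0..2 within codon
    from_nt: str
    to_nt: str
    synonymous: bool
    time: float          # depth from root, substitutions/site


@dataclass(frozen=True)
class ConversionEvent:
    donor_branch: int
    recipient_branch: int
    tract_start: int     # 1-based nucleotide columns, closed interval
    tract_end: int
    time: float
    recipient_leaves: tuple[str, ...]
    donor_leaves: tuple[str, ...]


@dataclass(frozen=True)
class SimulationTruth:
    run_id: str
    pss_positions: frozenset[int]
    substitutions: tuple[Substitution, ...]
    conversions: tuple[ConversionEvent, ...]
    clade_of: dict[str, int]
    genus_of: dict[str, str]
    branch_counts: dict[int, tuple[int, int]]  # branch -> (syn, nonsyn)
    branch_lengths: dict[int, float]
    tree: TreeNode

    @property
    def n_syn_total(self) -> int:
        return sum(s for s, _n in self.branch_counts.values())

    @property
    def n_nonsyn_total(self) -> int:
        return sum(n for _s, n in self.branch_counts.values())

    @property
    def n_clades(self) -> int:
        return len(set(self.clade_of.values()))


@lru_cache(maxsize=None)
def _neighbours(codon: str, kappa: float) -> tuple[tuple[str, float, bool, int, str], ...]:
    """Single-nucleotide sense neighbours: (to_codon, weight, syn, pos, to_nt)."""
    out = []
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if GENETIC_CODE[alt] == "*":
                continue
            w = kappa if (codon[pos], nt) in _TRANSITION else 1.0
            out.append((alt, w, GENETIC_CODE[alt] == aa, pos, nt))
    return tuple(out)


@lru_cache(maxsize=None)
def _rate_normaliser(kappa: float) -> float:
    """Mean neutral total rate over sense codons, per codon."""
    return float(
        np.mean([sum(w for _c, w, _s, _p, _n in _neighbours(c, kappa))
                 for c in SENSE_CODONS])
    )


class _Node:
    __slots__ = ("id", "parent", "depth", "name", "children")

    def __init__(self, id: int, parent: "_Node | None", depth: float, name: str | None):
        self.id = id
        self.parent = parent
        self.depth = depth
        self.name = name
        self.children: list[_Node] = []


def _build_genealogy(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[_Node, list[_Node], dict[str, int], dict[str, str]]:
    """Clade-structured ultrametric genealogy with genus labels."""
    root = _Node(0, None, 0.0, None)
    nodes = [root]
    clade_of: dict[str, int] = {}
    genus_of: dict[str, str] = {}
    # round-robin leaf allocation to clades
    leaves_per_clade = [0] * config.n_clades
    for i in range(config.n_sequences):
        leaves_per_clade[i % config.n_clades] += 1
    h = config.crown_depth

    for c in range(config.n_clades):
        k = leaves_per_clade[c]
        # leaves of this clade, genera round-robin within the clade
        active: list[_Node] = []
        for m in range(k):
            genus = GENUS_POOL[m % config.n_genera]
            name = f"{genus}_c{c}s{m}"
            leaf = _Node(-1, None, h, name)
            clade_of[name] = c
            genus_of[name] = genus
            active.append(leaf)
        if k == 1:
            clade_root = active[0]
        else:
            join_depths = np.sort(rng.uniform(h - config.clade_depth, h, k - 1))[::-1]
            for depth in join_depths:
                i, j = sorted(rng.choice(len(active), size=2, replace=False))
                a, b = active[i], active[j]
                joint = _Node(-1, None, float(depth), None)
                joint.children = [a, b]
                a.parent = b.parent = joint
                active = [x for x in active if x not in (a, b)] + [joint]
            (clade_root,) = active
        # attach clade root under the global root, renumbering ids
        clade_root.parent = root
        root.children.append(clade_root)

        def renumber(node: _Node) -> None:
            node.id = len(nodes)
            nodes.append(node)
            for ch in node.children:
                renumber(ch)

        renumber(clade_root)
    return root, nodes, clade_of, genus_of


def _to_treenode(node: _Node, crown_depth: float) -> TreeNode:
    return TreeNode(
        height=crown_depth - node.depth,
        name=node.name,
        children=tuple(_to_treenode(c, crown_depth) for c in node.children),
    )


def _leaves_under(node: _Node) -> list[_Node]:
    if not node.children:
        return [node]
    out: list[_Node] = []
    for c in node.children:
        out.extend(_leaves_under(c))
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Simulate a codon alignment and its complete truth record."""
    rng = np.random.default_rng(config.seed)
    root, nodes, clade_of, genus_of = _build_genealogy(config, rng)
    n_codons = config.n_codons
    if config.pss_positions is not None:
        pss = frozenset(config.pss_positions)
        if any(not 1 <= p <= n_codons for p in pss):
            raise ValueError("planted PSS positions out of range")
    else:
        pss = frozenset(
            int(p) + 1
            for p in rng.choice(n_codons, size=config.n_pss, replace=False)
        )
    omega_at = np.array(
        [
            config.omega_pss if (k + 1) in pss else config.omega_background
            for k in range(n_codons)
        ]
    )
    qbar = _rate_normaliser(config.kappa)
    scale = 3.0 / qbar  # neutral expectation: 1 substitution/site/unit depth

    root_seq = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), n_codons)]
    node_seq: dict[int, list[str]] = {root.id: root_seq}
    branch_events: dict[int, list[Substitution]] = {}
    branch_lengths: dict[int, float] = {}

    def evolve(parent: _Node) -> None:
        for child in parent.children:
            t = child.depth - parent.depth
            branch_lengths[child.id] = t
            seq = list(node_seq[parent.id])
            events: list[Substitution] = []
            for k in range(n_codons):
                omega = omega_at[k]
                elapsed = 0.0
                codon = seq[k]
                while True:
                    nbrs = _neighbours(codon, config.kappa)
                    rates = np.array(
                        [w * (1.0 if syn else omega) for _c, w, syn, _p, _n in nbrs]
                    ) * scale
                    total = rates.sum()
                    elapsed += rng.exponential(1.0 / total)
                    if elapsed >= t:
                        break
                    pick = rng.choice(len(nbrs), p=rates / total)
                    to_codon, _w, syn, pos, to_nt = nbrs[pick]
                    events.append(
                        Substitution(
                            branch=child.id,
                            site=k + 1,
                            position=pos,
                            from_nt=codon[pos],
                            to_nt=to_nt,
                            synonymous=bool(syn),
                            time=parent.depth + elapsed,
                        )
                    )
                    codon = to_codon
                seq[k] = codon
            node_seq[child.id] = seq
            branch_events[child.id] = events
            evolve(child)

    evolve(root)

    branch_counts = {
        b: (
            sum(1 for e in ev if e.synonymous),
            sum(1 for e in ev if not e.synonymous),
        )
        for b, ev in branch_events.items()
    }
    n_syn_real = sum(s for s, _ in branch_counts.values())

    leaf_nodes = _leaves_under(root)
    leaf_seq = {lf.name: list(node_seq[lf.id]) for lf in leaf_nodes}
    node_by_id = {n.id: n for n in nodes}

    def seq_at(branch_node: _Node, time: float) -> list[str]:
        """Sequence on a branch at absolute time ``time``."""
        seq = list(node_seq[branch_node.parent.id])
        for e in branch_events.get(branch_node.id, []):
            if e.time <= time:
                k = e.site - 1
                c = seq[k]
                seq[k] = c[: e.position] + e.to_nt + c[e.position + 1 :]
        return seq

    conversions: list[ConversionEvent] = []
    if config.conversion_rate > 0 and n_syn_real > 0:
        n_conv = int(rng.poisson(config.conversion_rate * n_syn_real))
        branch_ids = sorted(branch_lengths)
        lengths = np.array([branch_lengths[b] for b in branch_ids])
        probs = lengths / lengths.sum()
        length_nt = 3 * n_codons
        placed: list[tuple[int, int, frozenset[str]]] = []
        for _ in range(n_conv):
            # planted events must be mutually independent, otherwise a later
            # event overwrites the evidence (and the truth labels) of an
            # earlier one on the same lineages; resample colliding placements
            proposal = None
            for _attempt in range(100):
                rec_id = int(rng.choice(branch_ids, p=probs))
                rec = node_by_id[rec_id]
                u = float(rng.uniform(rec.parent.depth, rec.depth))
                donors = [
                    b
                    for b in branch_ids
                    if b != rec_id
                    and node_by_id[b].parent.depth <= u < node_by_id[b].depth
                ]
                if not donors:
                    continue
                donor_id = int(rng.choice(donors))
                tract_len = int(rng.geometric(1.0 / config.tract_length_mean))
                start = int(rng.integers(1, max(2, length_nt - tract_len + 2)))
                end = min(length_nt, start + tract_len - 1)
                touched = frozenset(
                    lf.name
                    for node in (rec, node_by_id[donor_id])
                    for lf in _leaves_under(node)
                )
                if any(
                    start <= p_end and p_start <= end and (touched & p_leaves)
                    for p_start, p_end, p_leaves in placed
                ):
                    continue
                proposal = (rec_id, donor_id, u, start, end, touched)
                break
            if proposal is None:
                continue
            rec_id, donor_id, u, start, end, touched = proposal
            placed.append((start, end, touched))
            rec = node_by_id[rec_id]
            donor = node_by_id[donor_id]
            donor_seq = seq_at(donor, u)
            rec_leaves = tuple(sorted(lf.name for lf in _leaves_under(rec)))
            donor_leaves = tuple(sorted(lf.name for lf in _leaves_under(donor)))
            first_codon = (start - 1) // 3
            last_codon = (end - 1) // 3
            for leaf in rec_leaves:
                original = list(leaf_seq[leaf])
                seq = list(original)
                # copy donor tract
                for p in range(start - 1, end):
                    k, off = divmod(p, 3)
                    c = seq[k]
                    seq[k] = c[:off] + donor_seq[k][off] + c[off + 1 :]
                # replay later substitutions on the recipient path inside the tract
                path_events: list[Substitution] = []
                node: _Node | None = next(
                    lf for lf in leaf_nodes if lf.name == leaf
                )
                while node is not None and node.id != rec.parent.id:
                    path_events.extend(
                        e
                        for e in branch_events.get(node.id, [])
                        if e.time > u
                        and start <= 3 * (e.site - 1) + e.position + 1 <= end
                    )
                    node = node.parent
                for e in sorted(path_events, key=lambda e: e.time):
                    k = e.site - 1
                    c = seq[k]
                    seq[k] = c[: e.position] + e.to_nt + c[e.position + 1 :]
                # conversions must not create stop codons
                for k in range(first_codon, last_codon + 1):
                    if GENETIC_CODE[seq[k]] == "*":
                        seq[k] = original[k]
                leaf_seq[leaf] = seq
            conversions.append(
                ConversionEvent(
                    donor_branch=donor_id,
                    recipient_branch=rec_id,
                    tract_start=start,
                    tract_end=end,
                    time=u,
                    recipient_leaves=rec_leaves,
                    donor_leaves=donor_leaves,
                )
            )

    names = sorted(leaf_seq)
    alignment = alignment_from_strings(
        (name, "".join(leaf_seq[name])) for name in names
    )
    truth = SimulationTruth(
        run_id=f"sim-{config.seed}",
        pss_positions=pss,
        substitutions=tuple(
            e for b in sorted(branch_events) for e in branch_events[b]
        ),
        conversions=tuple(conversions),
        clade_of=clade_of,
        genus_of=genus_of,
        branch_counts=branch_counts,
        branch_lengths=branch_lengths,
        tree=_to_treenode(root, config.crown_depth),
    )
    return alignment, truth


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineOutputs:
    """Inferred quantities from one pipeline run over a simulated dataset."""

    run_id: str
    pss_profile: SiteSelectionProfile | None = None
    events: tuple[RecombinationEvent, ...] | None = None
    partition: SpecificityPartition | None = None
    n_syn_mutations: float | None = None


@dataclass(frozen=True)
class RecoveryMetrics:
    pss_precision: float | None = None
    pss_recall: float | None = None
    pss_fpr: float | None = None
    conversion_recall: float | None = None
    breakpoint_error_mean: float | None = None
    n_eligible_conversions: int | None = None
    cluster_count_error: int | None = None
    syn_count_relative_error: float | None = None


def eligible_conversions(
    alignment: CodonAlignment,
    truth: SimulationTruth,
    min_diagnostic_per_flank: int = 8,
    window: int = 20,
    max_inner_mismatches: int = 2,
) -> list[ConversionEvent]:
    """Truth conversions with a detectable footprint.

    A site is diagnostic when it discriminates donor-derived from
    recipient-background material: for a recipient leaf against a
    donor-side leaf, flank sites just outside the tract should mismatch
    and sites just inside should match.  An event is considered
    detectable when, at each tract boundary, the ``window`` nearest
    variable sites outside carry at least ``min_diagnostic_per_flank``
    mismatches while the ``window`` nearest variable sites inside carry
    at most ``max_inner_mismatches`` — the 2x2 contrast the chi-square
    scan requires.  Deep conversions (donor close to the recipient's own
    ancestor) and heavily overwritten tracts fail this filter and are
    genuinely undetectable.
    """
    seq = {r.id: np.frombuffer(r.residues.encode(), dtype="S1")
           for r in alignment.records}
    arr = np.stack(list(seq.values()))
    is_nt = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    variable = np.array(
        [
            c
            for c in range(alignment.length)
            if len(set(arr[is_nt[:, c], c].tolist())) >= 2
        ]
    )
    out = []
    for ev in truth.conversions:
        rec = ev.recipient_leaves[0]
        donors = [d for d in ev.donor_leaves if d not in ev.recipient_leaves]
        if not donors:
            continue
        dn = donors[0]
        y = (seq[rec][variable] != seq[dn][variable])
        ok = True
        for boundary, inside_right in ((ev.tract_start - 1, True),
                                       (ev.tract_end, False)):
            b = int(np.searchsorted(variable, boundary))
            left = y[max(0, b - window) : b]
            right = y[b : b + window]
            outer, inner = (left, right) if inside_right else (right, left)
            if int(outer.sum()) < min_diagnostic_per_flank:
                ok = False
            if int(inner.sum()) > max_inner_mismatches:
                ok = False
        if ok:
            out.append(ev)
    return out


def conversion_recovery(
    alignment: CodonAlignment,
    truth: SimulationTruth,
    events: tuple[RecombinationEvent, ...],
    breakpoint_tolerance: int = 60,
    min_diagnostic_per_flank: int = 8,
) -> tuple[float | None, float | None, int]:
    """(recall, mean breakpoint error, n eligible) for planted conversions.

    A planted event is recovered when a detected event involves one of its
    recipient leaves and has a breakpoint within the tolerance of either
    tract boundary.
    """
    eligible = eligible_conversions(alignment, truth, min_diagnostic_per_flank)
    if not eligible:
        return None, None, 0
    recovered = 0
    errors = []
    for ev in eligible:
        rec_set = set(ev.recipient_leaves)
        best = None
        for d in events:
            if not ({d.seq1, d.seq2} & rec_set):
                continue
            err = min(
                abs(d.breakpoint - ev.tract_start),
                abs(d.breakpoint - ev.tract_end),
            )
            if err <= breakpoint_tolerance and (best is None or err < best):
                best = err
        if best is not None:
            recovered += 1
            errors.append(best)
    recall = recovered / len(eligible)
    mean_err = float(np.mean(errors)) if errors else None
    return recall, mean_err, len(eligible)


def recovery_metrics(
    outputs: PipelineOutputs,
    truth: SimulationTruth,
    alignment: CodonAlignment | None = None,
    breakpoint_tolerance: int = 60,
) -> RecoveryMetrics:
    """Compare pipeline outputs with the simulation truth."""
    if outputs.run_id != truth.run_id:
        raise ValueError(
            f"run id mismatch: outputs {outputs.run_id!r} vs truth {truth.run_id!r}"
        )
    kwargs: dict = {}
    if outputs.pss_profile is not None:
        inferred = outputs.pss_profile.pss_set
        true = truth.pss_positions
        n_codons = outputs.pss_profile.n_codons
        tp = len(inferred & true)
        fp = len(inferred - true)
        kwargs["pss_precision"] = tp / len(inferred) if inferred else 1.0
        kwargs["pss_recall"] = tp / len(true) if true else 1.0
        negatives = n_codons - len(true)
        kwargs["pss_fpr"] = fp / negatives if negatives else 0.0
    if outputs.events is not None:
        if alignment is None:
            raise ValueError("alignment required for conversion recovery")
        recall, err, n_elig = conversion_recovery(
            alignment, truth, outputs.events, breakpoint_tolerance
        )
        kwargs["conversion_recall"] = recall
        kwargs["breakpoint_error_mean"] = err
        kwargs["n_eligible_conversions"] = n_elig
    if outputs.partition is not None:
        kwargs["cluster_count_error"] = (
            outputs.partition.n_specificities - truth.n_clades
        )
    if outputs.n_syn_mutations is not None:
        true_syn = truth.n_syn_total
        kwargs["syn_count_relative_error"] = (
            (outputs.n_syn_mutations - true_syn) / true_syn if true_syn else None
        )
    return RecoveryMetrics(**kwargs)


# ---------------------------------------------------------------------------
# truth serialisation
# ---------------------------------------------------------------------------


def write_truth(
    truth: SimulationTruth, config: SimulationConfig, outdir: str | Path
) -> None:
    """Write truth tables (TSV) and the config (YAML) next to the alignment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"codon_index": sorted(truth.pss_positions)}).to_csv(
        outdir / "pss_truth.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "donor_branch": e.donor_branch,
                "recipient_branch": e.recipient_branch,
                "tract_start": e.tract_start,
                "tract_end": e.tract_end,
                "time": e.time,
                "recipient_leaves": ",".join(e.recipient_leaves),
                "donor_leaves": ",".join(e.donor_leaves),
            }
            for e in truth.conversions
        ],
        columns=[
            "donor_branch", "recipient_branch", "tract_start", "tract_end",
            "time", "recipient_leaves", "donor_leaves",
        ],
    ).to_csv(outdir / "events_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sequence": s, "clade": c, "genus": truth.genus_of[s]}
            for s, c in sorted(truth.clade_of.items())
        ]
    ).to_csv(outdir / "clades.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            },
            fh,
            sort_keys=True,
        )
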
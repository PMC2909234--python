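"""Reading, writing and validation of the pipeline's file formats.

The substrate of every analysis stage is an in-frame codon alignment of
S-RNase coding sequences.  Genus labels are carried on each record, parsed
from the sequence identifier (S-allele datasets conventionally encode the
taxon in the id, e.g. ``Malus_domestica_S7``).  Per-site selection
probabilities produced by external site-model tools can be plugged in as
TSV tracks.

All coordinates are 1-based and intervals are closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("srnase_evol")

VALID_NUCLEOTIDES = frozenset("ACGTN-")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AlignmentError(ValueError):
    """Raised for ragged, out-of-frame or otherwise invalid alignments."""


class ContentError(ValueError):
    """Raised for illegal characters or out-of-range values in inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned coding sequence with its genus label."""

    id: str
    genus: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ContentError("sequence id must be nonempty")
        bad = set(self.residues) - VALID_NUCLEOTIDES
        if bad:
            raise ContentError(
                f"illegal characters {sorted(bad)} in sequence {self.id!r}; "
                "only A,C,G,T,N and '-' are accepted"
            )


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-aware, in-frame codon alignment.

    Invariants: nucleotide length divisible by 3, all rows equal length,
    at least two rows, unique ids.
    """

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("alignment needs at least 2 sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(
                f"alignment length {length} is not divisible by 3 (frame error)"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")

    @property
    def length(self) -> int:
        """Alignment length in nucleotide columns."""
        return len(self.records[0].residues)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def genera(self) -> list[str]:
        return [r.genus for r in self.records]

    def codon(self, record_index: int, codon_index: int) -> str:
        """Codon at 1-based codon position ``codon_index``."""
        s = 3 * (codon_index - 1)
        return self.records[record_index].residues[s : s + 3]

    def codon_column(self, codon_index: int) -> list[str]:
        return [self.codon(i, codon_index) for i in range(len(self.records))]

    def gapped_codons(self) -> set[int]:
        """1-based codon indices where any sequence carries a gap."""
        out: set[int] = set()
        for k in range(1, self.n_codons + 1):
            if any("-" in c for c in self.codon_column(k)):
                out.add(k)
        return out

    def row(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


@dataclass(frozen=True)
class RegionMask:
    """Set of 1-based codon indices retained for analysis."""

    included_codons: frozenset[int]

    def __post_init__(self) -> None:
        if any(i < 1 for i in self.included_codons):
            raise ContentError("codon indices are 1-based; got index < 1")


@dataclass
class ProbabilityTrack:
    """Per-codon selection probabilities from two detectors.

    ``prob_a`` is the phylogenetic detector, ``prob_b`` the population
    genetics detector; ``gapped`` flags codons with alignment gaps (the
    phylogenetic detector does not analyse those).
    """

    prob_a: list[float]
    prob_b: list[float]
    gapped: list[bool]

    def __post_init__(self) -> None:
        n = len(self.prob_a)
        if not (len(self.prob_b) == len(self.gapped) == n):
            raise ContentError("track columns have unequal lengths")
        for p in list(self.prob_a) + list(self.prob_b):
            if not 0.0 <= p <= 1.0:
                raise ContentError(f"probability {p} outside [0, 1]")

    @property
    def n_codons(self) -> int:
        return len(self.prob_a)


def parse_genus(seq_id: str, delimiter: str = "_", token: int = 0) -> str:
    """Extract the genus label from a sequence id (default: first '_' token)."""
    parts = seq_id.split(delimiter)
    if token >= len(parts) or not parts[token]:
        return "unknown"
    return parts[token]


def read_fasta(
    path: str | Path, delimiter: str = "_", genus_token: int = 0
) -> CodonAlignment:
    """Read an aligned FASTA file into a validated :class:`CodonAlignment`.

    Sequences are uppercased; genus labels are parsed from ids using
    ``delimiter``/``genus_token``.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        records.append(
            SequenceRecord(
                id=rec.id, genus=parse_genus(rec.id, delimiter, genus_token),
                residues=residues,
            )
        )
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return CodonAlignment(records=tuple(records))


def write_fasta(alignment: CodonAlignment, path: str | Path) -> None:
    recs = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in alignment.records
    ]
    SeqIO.write(recs, str(Path(path)), "fasta")


def alignment_from_strings(
    pairs: Iterable[tuple[str, str]], delimiter: str = "_", genus_token: int = 0
) -> CodonAlignment:
    """Build an alignment from (id, sequence) pairs — handy for tests/CLI."""
    records = tuple(
        SequenceRecord(
            id=i, genus=parse_genus(i, delimiter, genus_token), residues=s.upper()
        )
        for i, s in pairs
    )
    return CodonAlignment(records=records)


def read_probability_track(
    path: str | Path, alignment: CodonAlignment
) -> ProbabilityTrack:
    """Read a per-codon probability TSV aligned to ``alignment``.

    Expected columns: codon_index, prob_a, prob_b, gapped.  Codons missing
    from the file are filled with probability 0 (a warning is logged).
    """
    path = Path(path)
    n = alignment.n_codons
    prob_a = [0.0] * n
    prob_b = [0.0] * n
    gapped = [False] * n
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["codon_index", "prob_a", "prob_b", "gapped"])
    seen: set[int] = set()
    for _, row in df.iterrows():
        k = int(row["codon_index"])
        if not 1 <= k <= n:
            raise ContentError(
                f"codon_index {k} out of range 1..{n} in {path.name}"
            )
        pa, pb = float(row["prob_a"]), float(row["prob_b"])
        for p in (pa, pb):
            if not 0.0 <= p <= 1.0:
                raise ContentError(f"probability {p} outside [0, 1] in {path.name}")
        prob_a[k - 1] = pa
        prob_b[k - 1] = pb
        gapped[k - 1] = bool(int(row["gapped"]))
        seen.add(k)
    missing = n - len(seen)
    if missing:
        logger.warning(
            "probability track %s covers %d/%d codons; missing codons filled "
            "with probability 0", path.name, len(seen), n,
        )
    return ProbabilityTrack(prob_a=prob_a, prob_b=prob_b, gapped=gapped)


def write_probability_track(track: ProbabilityTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "codon_index": range(1, track.n_codons + 1),
            "prob_a": track.prob_a,
            "prob_b": track.prob_b,
            "gapped": [int(g) for g in track.gapped],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def apply_mask(alignment: CodonAlignment, mask: RegionMask) -> CodonAlignment:
    """Restrict an alignment to the codons in ``mask`` (order preserved)."""
    if not mask.included_codons:
        raise AlignmentError("empty region mask")
    n = alignment.n_codons
    bad = [i for i in mask.included_codons if i > n]
    if bad:
        raise ContentError(f"mask codon indices {sorted(bad)} exceed {n} codons")
    keep = sorted(mask.included_codons)
    records = tuple(
        SequenceRecord(
            id=r.id,
            genus=r.genus,
            residues="".join(r.residues[3 * (k - 1) : 3 * k] for k in keep),
        )
        for r in alignment.records
    )
    return CodonAlignment(records=records)
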
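"""Structure mapping: solvent accessibility of selected sites and lysines.

Positively selected sites that determine specificity should face the
solvent, so their accessible surface area (ASA) is compared with that of
the remaining residues on an S-RNase crystal structure.  ASA is computed
with the Shrake–Rupley method using a deterministic golden-spiral point
set (probe 1.4 Å, Chothia-style heavy-atom radii), alignment columns are
mapped onto structure residues through a global protein alignment, and
exposure differences are tested with a Mann–Whitney U test.  Lysine
conservation profiles locate candidate ubiquitylation sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .divergence import GENETIC_CODE, is_clean_codon
from .io import CodonAlignment, SequenceRecord
from .selection import SiteSelectionProfile

logger = logging.getLogger("srnase_evol")

#: heavy-atom van der Waals radii (Å), Chothia-style
DEFAULT_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

ResidueKey = tuple[str, int]  # (chain id, residue number)


@dataclass(frozen=True)
class Atom:
    element: str
    chain: str
    resseq: int
    xyz: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class StructureModel:
    """Heavy atoms of the first model of a crystal structure."""

    atoms: tuple[Atom, ...]
    residues: tuple[tuple[str, int, str], ...]  # (chain, resseq, one-letter aa)

    @property
    def sequence(self) -> str:
        return "".join(aa for _c, _r, aa in self.residues)

    def residue_keys(self) -> list[ResidueKey]:
        return [(c, r) for c, r, _aa in self.residues]


def parse_structure(
    path: str | Path, radii: dict[str, float] | None = None
) -> StructureModel:
    """Parse heavy ATOM records of the first model of a PDB file.

    Waters and other heteroatoms are excluded; elements outside the radius
    table fall back to 1.70 Å with a warning.
    """
    radii = radii or DEFAULT_RADII
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("model", str(path))
    models = list(struct.get_models())
    if not models:
        raise ValueError(f"no ATOM records in {path}")
    if len(models) > 1:
        logger.info("multi-model file %s: using model 1 only", path)
    model = models[0]
    atoms: list[Atom] = []
    residues: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag != " ":
                continue  # waters / heteroatoms
            aa = seq1(residue.get_resname())
            residues.append((chain.id, resseq, aa))
            for atom in residue:
                element = (atom.element or atom.get_name()[:1]).upper()
                if element in ("H", "D"):
                    continue
                if element not in radii:
                    logger.warning(
                        "element %s not in radius table; using 1.70 Å", element
                    )
                r = radii.get(element, 1.70)
                x, y, z = atom.coord
                atoms.append(
                    Atom(
                        element=element,
                        chain=chain.id,
                        resseq=resseq,
                        xyz=(float(x), float(y), float(z)),
                        radius=r,
                    )
                )
    if not atoms:
        raise ValueError(f"no ATOM records in {path}")
    return StructureModel(atoms=tuple(atoms), residues=tuple(residues))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_asa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[ResidueKey, float]:
    """Per-residue accessible surface area (Å²).

    Each atom's solvent sphere (radius + probe) is sampled with a
    deterministic point set; points outside all neighbouring solvent
    spheres are accessible.  Residue ASA is the sum over its atoms.
    """
    if not model.atoms:
        raise ValueError("structure has no atoms")
    pts = _sphere_points(n_points)
    xyz = np.array([a.xyz for a in model.atoms])
    radii = np.array([a.radius for a in model.atoms])
    ext = radii + probe
    tree = cKDTree(xyz)
    max_ext = float(ext.max())
    asa: dict[ResidueKey, float] = {}
    for idx, atom in enumerate(model.atoms):
        r = ext[idx]
        surface = xyz[idx] + pts * r
        neighbours = [
            j
            for j in tree.query_ball_point(xyz[idx], r + max_ext)
            if j != idx
        ]
        if neighbours:
            d2 = (
                (surface[:, None, :] - xyz[neighbours][None, :, :]) ** 2
            ).sum(axis=2)
            buried = (d2 < (ext[neighbours] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = 4.0 * np.pi * r * r * frac
        key = (atom.chain, atom.resseq)
        asa[key] = asa.get(key, 0.0) + float(area)
    return asa


def map_alignment_to_structure(
    reference: SequenceRecord, model: StructureModel
) -> dict[int, ResidueKey]:
    """Map alignment codon columns to structure residues via the reference.

    The reference row is translated (gapped codons skipped), globally
    aligned to the structure's residue sequence (BLOSUM62, affine gaps),
    and the two numberings are composed.  Unaligned columns are unmapped.
    """
    ref_positions: list[int] = []  # codon index per reference residue
    ref_aas: list[str] = []
    for k in range(0, len(reference.residues), 3):
        codon = reference.residues[k : k + 3]
        if is_clean_codon(codon):
            ref_positions.append(k // 3 + 1)
            ref_aas.append(GENETIC_CODE[codon])
    ref_protein = "".join(ref_aas)
    struct_seq = model.sequence
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    alignment = aligner.align(ref_protein, struct_seq)[0]
    keys = model.residue_keys()
    mapping: dict[int, ResidueKey] = {}
    n_ident = n_aligned = 0
    for (r0, r1), (s0, s1) in zip(*alignment.aligned):
        for off in range(r1 - r0):
            ri, si = r0 + off, s0 + off
            mapping[ref_positions[ri]] = keys[si]
            n_aligned += 1
            n_ident += ref_protein[ri] == struct_seq[si]
    if n_aligned and n_ident / n_aligned < 0.30:
        logger.warning(
            "reference/structure identity %.0f%% is below 30%%; the mapping "
            "may be unreliable", 100 * n_ident / n_aligned,
        )
    return mapping


def mann_whitney(
    x: list[float], y: list[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann–Whitney U statistic and p-value.

    Exact distribution when the smaller sample has at most 8 observations
    and there are no ties; otherwise the normal approximation with tie
    correction.
    """
    has_ties = len(set(x) | set(y)) < len(x) + len(y)
    method = "exact" if min(len(x), len(y)) <= 8 and not has_ties else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SurfaceReport:
    n_pss: int
    n_npss: int
    mean_asa_pss: float
    mean_asa_npss: float
    exposed_fraction_pss: float
    exposed_fraction_npss: float
    u_statistic: float
    p_value: float


def category_surface_stats(
    asa: dict[ResidueKey, float],
    pss: SiteSelectionProfile,
    mapping: dict[int, ResidueKey],
) -> SurfaceReport:
    """Compare accessible surface of PSS vs non-PSS mapped residues."""
    pss_set = pss.pss_set
    pss_asa: list[float] = []
    npss_asa: list[float] = []
    for codon_index, key in sorted(mapping.items()):
        if key not in asa:
            continue
        (pss_asa if codon_index in pss_set else npss_asa).append(asa[key])
    if not pss_asa or not npss_asa:
        raise ValueError("both PSS and non-PSS categories must be non-empty")
    total = sum(pss_asa) + sum(npss_asa)
    u, p = mann_whitney(pss_asa, npss_asa)
    return SurfaceReport(
        n_pss=len(pss_asa),
        n_npss=len(npss_asa),
        mean_asa_pss=sum(pss_asa) / len(pss_asa),
        mean_asa_npss=sum(npss_asa) / len(npss_asa),
        exposed_fraction_pss=sum(pss_asa) / total,
        exposed_fraction_npss=sum(npss_asa) / total,
        u_statistic=u,
        p_value=p,
    )


@dataclass(frozen=True)
class LysineProfile:
    """Conservation of each lysine of a reference sequence."""

    # reference codon index -> (frequency of K among ungapped, bin label)
    lysines: dict[int, tuple[float, str]]


def _bin_label(freq: float) -> str:
    if freq < 0.50:
        return "<50%"
    if freq <= 0.75:
        return "50-75%"
    return ">75%"


def lysine_profile(alignment: CodonAlignment, reference_id: str) -> LysineProfile:
    """Column frequency of lysine at each K position of the reference.

    Gapped codons are excluded from the denominator.  Frequencies are
    binned <50% / 50–75% / >75%, the scheme used to colour candidate
    ubiquitylation sites.
    """
    ref = alignment.row(reference_id)
    out: dict[int, tuple[float, str]] = {}
    for k in range(1, alignment.n_codons + 1):
        codon = ref.residues[3 * (k - 1) : 3 * k]
        if not is_clean_codon(codon) or GENETIC_CODE[codon] != "K":
            continue
        n_k = n_total = 0
        for c in alignment.codon_column(k):
            if not is_clean_codon(c):
                continue
            n_total += 1
            n_k += GENETIC_CODE[c] == "K"
        freq = n_k / n_total if n_total else 0.0
        out[k] = (freq, _bin_label(freq))
    if not out:
        raise ValueError(f"reference {reference_id!r} has no lysine residues")
    return LysineProfile(lysines=out)
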
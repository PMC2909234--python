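"""Population-genetic rate arithmetic.

Closed-form conversions between silent-site SNP density, the diversity
parameter theta = 4 Ne mu, the per-generation mutation rate, and projected
silent divergence over a given time at a given generation time.  The
divergence projection uses D = mu * (t / g) (per-lineage convention);
``two_lineage=True`` adds the conventional factor 2 for a diverging pair.
"""

from __future__ import annotations

from dataclasses import dataclass

#: effective population size suggested by S-allele numbers in natural populations
DEFAULT_NE = 10_000

#: third codon positions treated as the silent fraction of coding sites
DEFAULT_POSITIONS_PER_SILENT_SITE = 3.0


@dataclass(frozen=True)
class RateEstimate:
    theta: float
    ne: float
    mu: float
    gen_time_years: float
    time_years: float
    divergence: float


def theta_from_snp_density(
    snps_per_bp: float,
    positions_per_silent_site: float = DEFAULT_POSITIONS_PER_SILENT_SITE,
) -> float:
    """Silent-site diversity theta from genome-wide SNP density.

    With one SNP every L bp and silent sites making up one position in
    ``positions_per_silent_site``, theta = (1/L) * factor.
    """
    if not 0 <= snps_per_bp <= 1:
        raise ValueError("SNP density must be in [0, 1]")
    return snps_per_bp * positions_per_silent_site


def mu_from_theta(theta: float, ne: float = DEFAULT_NE) -> float:
    """Per-site per-generation mutation rate from theta = 4 Ne mu."""
    if ne <= 0:
        raise ValueError("effective population size must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (4.0 * ne)


def project_divergence(
    mu: float, years: float, gen_time_years: float, two_lineage: bool = False
) -> float:
    """Silent divergence accumulated over ``years`` at generation time ``g``."""
    if gen_time_years <= 0:
        raise ValueError("generation time must be positive")
    d = mu * (years / gen_time_years)
    return 2.0 * d if two_lineage else d


def generation_time_for(
    divergence: float, mu: float, years: float, two_lineage: bool = False
) -> float:
    """Generation time required to accumulate ``divergence`` over ``years``.

    Exact inverse of :func:`project_divergence`.
    """
    if divergence <= 0:
        raise ValueError("divergence must be positive")
    factor = 2.0 if two_lineage else 1.0
    return factor * mu * years / divergence
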
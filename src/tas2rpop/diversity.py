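"""Within-locus diversity statistics: segregating sites, nucleotide
diversity, and Tajima's D.

All three statistics are SNP-based: indel and structural rows are
inventoried separately and never enter S, pi, or D.  A multi-allelic
nucleotide position counts once toward S and contributes its full
multi-allele heterozygosity to pi.

pi uses the unbiased per-site estimator

    pi = (1/L) * sum_sites  n_c/(n_c - 1) * (1 - sum_a p_a^2)

(n_c = called haplotypes at the site, p_a = allele frequencies), which
equals the exact mean pairwise Hamming distance between haplotypes divided
by L.  Tajima's D contrasts the same pairwise-difference estimator of theta
with the segregating-site estimator S/a1, standardized by the Tajima (1989)
variance approximation; it requires a constant haplotype count, so sites
with missing calls are dropped from D (and the drop is logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import Consequence
from .io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiversityResult:
    """Per-locus diversity summary.

    ``pi`` is dimensionless (per-nucleotide); user-facing tables report it
    in percent.  ``tajima_d`` is None when S = 0 (undefined, distinct from
    zero).
    """

    S: int
    S_nonsyn: int
    S_syn: int
    pi: float
    tajima_d: Optional[float]
    n_hap: int
    L: int

    @property
    def pi_percent(self) -> float:
        return 100.0 * self.pi


# ---------------------------------------------------------------------------
# Site grouping
# ---------------------------------------------------------------------------

def _snp_positions(matrix: GenotypeMatrix) -> Dict[Tuple[str, int], List[int]]:
    """Row indices of SNP records grouped by nucleotide position."""
    groups: Dict[Tuple[str, int], List[int]] = {}
    for i, v in enumerate(matrix.variants):
        if v.is_snp:
            groups.setdefault((v.chrom, v.pos), []).append(i)
    return groups


def segregating_sites(matrix: GenotypeMatrix) -> Tuple[int, int, int]:
    """Count variable nucleotide positions and their n/s split.

    A position with >= 2 alleles among called haplotypes counts once toward
    S regardless of how many alternate alleles segregate there.  The split
    (S_nonsyn, S_syn) covers only positions whose segregating SNP rows are
    annotated nonsynonymous or synonymous; stop/start-codon classes count in
    S but in neither split, so S_nonsyn + S_syn <= S.
    """
    S = S_ns = S_syn = 0
    for (_, _), rows in sorted(_snp_positions(matrix).items()):
        seg_rows = [i for i in rows if matrix.segregating[i]]
        if not seg_rows:
            continue
        S += 1
        cons = {matrix.variants[i].consequence for i in seg_rows}
        if Consequence.NONSYNONYMOUS in cons:
            S_ns += 1
        elif Consequence.SYNONYMOUS in cons:
            S_syn += 1
    return S, S_ns, S_syn


def _site_heterozygosities(matrix: GenotypeMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Unbiased heterozygosity n_c/(n_c-1)*(1 - sum p_a^2) per SNP position.

    Returns (het, n_c) arrays over positions in genomic order.
    """
    hets: List[float] = []
    ncs: List[int] = []
    for (_, _), rows in sorted(_snp_positions(matrix).items()):
        totals = {int(matrix.hap_counts[i, 1]) for i in rows}
        if len(totals) != 1:
            logger.warning("position with inconsistent called totals; using per-row minimum")
        n_c = min(totals)
        if n_c < 2:
            raise ValueError("site with fewer than 2 called haplotypes")
        alt_counts = [int(matrix.hap_counts[i, 0]) for i in rows]
        ref_count = n_c - sum(alt_counts)
        if ref_count < 0:
            raise ValueError("allele counts exceed called total at a position")
        freqs = np.array(alt_counts + [ref_count], dtype=float) / n_c
        hets.append(n_c / (n_c - 1) * (1.0 - float(np.sum(freqs**2))))
        ncs.append(n_c)
    return np.asarray(hets, dtype=float), np.asarray(ncs, dtype=np.int64)


def pi_total_exact(matrix: GenotypeMatrix) -> "Fraction":
    """Un-normalized mean pairwise difference as an exact rational.

    Per SNP position the unbiased heterozygosity n/(n-1)*(1 - sum p_a^2)
    reduces to (n^2 - sum_a k_a^2) / (n*(n-1)) with integer allele counts
    k_a; summing these fractions is exact, so pi * L can be compared
    against a brute-force pair enumeration without float slack.
    """
    from fractions import Fraction

    total = Fraction(0)
    for (_, _), rows in sorted(_snp_positions(matrix).items()):
        n_c = min(int(matrix.hap_counts[i, 1]) for i in rows)
        if n_c < 2:
            raise ValueError("site with fewer than 2 called haplotypes")
        alt_counts = [int(matrix.hap_counts[i, 0]) for i in rows]
        counts = alt_counts + [n_c - sum(alt_counts)]
        total += Fraction(n_c * n_c - sum(k * k for k in counts), n_c * (n_c - 1))
    return total


def nucleotide_diversity(matrix: GenotypeMatrix, L: int) -> float:
    """Mean pairwise nucleotide difference per site, normalized by L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if matrix.n_sites == 0:
        return 0.0
    het, _ = _site_heterozygosities(matrix)
    return float(het.sum()) / L


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> Dict[str, float]:
    """Tajima (1989) normalizing constants for n haplotypes."""
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_summaries(S: int, pi_total: float, n: int) -> Optional[float]:
    """D from a segregating-site count and un-normalized mean pairwise
    difference, for n haplotypes.  None when S = 0 (undefined)."""
    if S == 0:
        return None
    if n < 4:
        logger.warning("Tajima's D with n=%d haplotypes: variance approximation degrades", n)
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - S / c["a1"]) / math.sqrt(var)


def tajimas_d(matrix: GenotypeMatrix) -> Optional[float]:
    """Tajima's D over the matrix's SNP positions.

    Positions with missing calls (called total below the matrix maximum)
    are dropped so that a single haplotype count n applies.
    """
    het, ncs = _site_heterozygosities(matrix)
    if len(ncs) == 0:
        return None
    n = int(ncs.max())
    full = ncs == n
    n_dropped = int((~full).sum())
    if n_dropped:
        logger.info("Tajima's D: dropped %d site(s) with missing calls", n_dropped)
    het = het[full]
    seg = het > 0
    S = int(seg.sum())
    pi_total = float(het.sum())
    return tajimas_d_from_summaries(S, pi_total, n)


# ---------------------------------------------------------------------------
# Fast array path (complete biallelic data, e.g. simulated haplotypes or
# null windows)
# ---------------------------------------------------------------------------

def diversity_from_counts(alt_counts: np.ndarray, n: int, L: int) -> Tuple[int, float, Optional[float]]:
    """(S, pi, D) from biallelic alternate-allele counts with a constant
    haplotype total n and no missing data."""
    alt_counts = np.asarray(alt_counts, dtype=np.int64)
    seg = (alt_counts > 0) & (alt_counts < n)
    k = alt_counts[seg].astype(float)
    het = 2.0 * (k / n) * (1.0 - k / n) * n / (n - 1)
    S = int(seg.sum())
    pi_total = float(het.sum())
    return S, pi_total / L, tajimas_d_from_summaries(S, pi_total, n)


def compute_diversity(matrix: GenotypeMatrix, L: int) -> DiversityResult:
    """Full per-locus diversity summary for an annotated genotype matrix."""
    S, S_ns, S_syn = segregating_sites(matrix)
    pi = nucleotide_diversity(matrix, L) if matrix.n_sites else 0.0
    d = tajimas_d(matrix) if S > 0 else None
    return DiversityResult(
        S=S, S_nonsyn=S_ns, S_syn=S_syn, pi=pi, tajima_d=d,
        n_hap=2 * matrix.n_samples, L=L,
    )
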
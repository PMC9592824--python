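"""Population differentiation: Weir-Cockerham F_ST and genotype PCA.

F_ST is estimated with the Weir & Cockerham (1984) variance-components
method in its haploid (allele-level) form: phased haplotypes are treated as
independent allele draws, so there is no within-individual (c) component.
Per site, with r populations of haploid sample sizes n_i and alternate
allele frequencies p_i:

    n_bar = sum(n_i) / r
    n_C   = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r - 1)
    p_bar = sum(n_i * p_i) / (r * n_bar)
    s^2   = sum(n_i * (p_i - p_bar)^2) / ((r - 1) * n_bar)

    a = (n_bar/n_C) * [ s^2 - (1/(n_bar-1)) * (p_bar*(1-p_bar) - s^2*(r-1)/r) ]
    b = (n_bar/(n_bar-1)) * [ p_bar*(1-p_bar) - s^2*(r-1)/r ]

The multi-site estimate is the ratio of sums sum(a) / sum(a+b), never a
mean of per-site ratios.  Per-site and aggregate estimates may be negative
and are reported unclamped.

PCA operates on the dosage matrix with Patterson scaling: each site is
centered by 2*p_hat and scaled by sqrt(p_hat*(1-p_hat)); scores come from
the singular value decomposition and variance-explained fractions from the
squared singular values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import Consequence
from .io import MISSING, GenotypeMatrix, SampleManifest

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def wc_components_per_site(
    pop_alt_counts: Sequence[int], pop_totals: Sequence[int]
) -> Tuple[float, float, float]:
    """Haploid Weir-Cockerham components (a, b, c) for one biallelic site.

    ``pop_alt_counts[i]`` / ``pop_totals[i]`` are the alternate-allele count
    and called haploid total for population i.  Populations with zero called
    haplotypes are excluded (and logged); at least two must remain.  c is
    identically 0 for allele-level data.
    """
    alts, totals = [], []
    for alt, tot in zip(pop_alt_counts, pop_totals):
        if tot <= 0:
            logger.info("population with no called haplotypes excluded from site")
            continue
        alts.append(alt)
        totals.append(tot)
    r = len(totals)
    if r < 2:
        raise ValueError("F_ST requires >= 2 populations with called haplotypes")
    n = np.asarray(totals, dtype=float)
    p = np.asarray(alts, dtype=float) / n
    n_bar = n.sum() / r
    if n_bar <= 1:
        raise ValueError("mean sample size must exceed 1 haplotype")
    n_C = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = float((n * p).sum() / (r * n_bar))
    s2 = float((n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar))
    inner = p_bar * (1.0 - p_bar) - s2 * (r - 1) / r
    a = (n_bar / n_C) * (s2 - inner / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * inner
    return a, b, 0.0


def theta_site(a: float, b: float, c: float) -> float:
    """Per-site theta = a / (a + b + c); nan when the denominator is 0."""
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


@dataclass
class FstResult:
    """Weighted (ratio-of-sums) F_ST with per-site components."""

    theta_weighted: float
    per_site: List[Tuple[int, float, float, float, float]]  # (row, a, b, c, theta)
    grouping: str
    n_sites_used: int
    theta_nonsyn: Optional[float] = None
    theta_syn: Optional[float] = None


def _pop_counts_per_site(
    matrix: GenotypeMatrix, manifest: SampleManifest, grouping: str
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Per-site per-population (alt_count, called_total) haploid counts."""
    labels = np.array(
        [dict((e[0], e) for e in manifest.entries)[s][1 if grouping in ("population", "pop") else 2]
         for s in matrix.samples]
    )
    pops = sorted(set(labels))
    dos = matrix.dosages
    called = dos != MISSING
    alt = np.where(called, dos, 0)
    alt_counts = np.empty((matrix.n_sites, len(pops)), dtype=np.int64)
    totals = np.empty_like(alt_counts)
    for j, pop in enumerate(pops):
        cols = labels == pop
        alt_counts[:, j] = alt[:, cols].sum(axis=1)
        totals[:, j] = 2 * called[:, cols].sum(axis=1)
    return alt_counts, totals, pops


def wc_fst_weighted(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    grouping: str = "population",
    site_filter: str = "all",
) -> FstResult:
    """Ratio-of-sums Weir-Cockerham F_ST over the matrix's segregating rows.

    ``site_filter``: "all", "nonsynonymous" or "synonymous" (consequence
    annotations must be attached for the restricted filters).  Every
    decomposed alternate allele enters once.
    """
    if len(set(manifest.labels("population" if grouping in ("population", "pop") else "superpop"))) < 2:
        raise ValueError("F_ST requires >= 2 populations")
    alt_counts, totals, _ = _pop_counts_per_site(matrix, manifest, grouping)
    keep = np.asarray(matrix.segregating, dtype=bool).copy()
    if site_filter == "nonsynonymous":
        keep &= np.array([v.consequence is Consequence.NONSYNONYMOUS for v in matrix.variants], dtype=bool)
    elif site_filter == "synonymous":
        keep &= np.array([v.consequence is Consequence.SYNONYMOUS for v in matrix.variants], dtype=bool)
    elif site_filter != "all":
        raise ValueError(f"unknown site filter {site_filter!r}")
    per_site = []
    sum_a = sum_den = 0.0
    for i in np.flatnonzero(keep):
        a, b, c = wc_components_per_site(alt_counts[i], totals[i])
        per_site.append((int(i), a, b, c, theta_site(a, b, c)))
        sum_a += a
        sum_den += a + b + c
    if not per_site or sum_den == 0:
        raise ValueError("F_ST undefined: no usable sites / zero total denominator")
    return FstResult(
        theta_weighted=sum_a / sum_den,
        per_site=per_site,
        grouping=grouping,
        n_sites_used=len(per_site),
    )


def fst_from_pop_counts(alt_counts: np.ndarray, totals: np.ndarray) -> float:
    """Ratio-of-sums theta directly from (sites x pops) haploid count arrays;
    fast path for simulation calibration and null windows."""
    sum_a = sum_den = 0.0
    n_used = 0
    for i in range(alt_counts.shape[0]):
        tot = totals[i]
        alt = alt_counts[i]
        if (alt.sum() == 0) or (alt.sum() == tot.sum()):
            continue  # monomorphic overall
        a, b, c = wc_components_per_site(alt, tot)
        sum_a += a
        sum_den += a + b + c
        n_used += 1
    if n_used == 0 or sum_den == 0:
        raise ValueError("F_ST undefined over these sites")
    return sum_a / sum_den


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Sample scores and variance-explained fractions for one site subset."""

    coords: np.ndarray           # samples x components
    var_explained: np.ndarray    # per-component fraction of total variance
    site_subset: str
    samples: List[str] = field(default_factory=list)


def genotype_pca(
    matrix: GenotypeMatrix,
    site_subset: str = "all",
    n_components: int = 10,
    scaling: str = "patterson",
) -> PCAResult:
    """PCA of the dosage matrix over a consequence-defined site subset.

    Missing dosages are mean-imputed per site (they then contribute nothing
    after centering).  ``scaling``: "patterson" (default) divides each
    centered site by sqrt(p_hat*(1-p_hat)); "center" only centers.
    """
    keep = np.asarray(matrix.segregating, dtype=bool).copy()
    if site_subset == "nonsynonymous":
        keep &= np.array([v.consequence is Consequence.NONSYNONYMOUS for v in matrix.variants], dtype=bool)
    elif site_subset == "synonymous":
        keep &= np.array([v.consequence is Consequence.SYNONYMOUS for v in matrix.variants], dtype=bool)
    elif site_subset != "all":
        raise ValueError(f"unknown site subset {site_subset!r}")
    if matrix.n_samples < 2:
        raise ValueError("PCA requires >= 2 samples")
    if not keep.any():
        raise ValueError(f"no polymorphic sites in subset {site_subset!r}")

    dos = matrix.dosages[keep].astype(float)
    miss = dos == MISSING
    dos[miss] = np.nan
    p_hat = np.nanmean(dos, axis=1) / 2.0
    centered = dos - 2.0 * p_hat[:, None]
    centered[np.isnan(centered)] = 0.0
    if scaling == "patterson":
        denom = np.sqrt(p_hat * (1.0 - p_hat))
        ok = denom > 0
        centered = centered[ok] / denom[ok][:, None]
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")

    X = centered.T  # samples x sites
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    k = min(n_components, len(s))
    coords = U[:, :k] * s[:k]
    var_explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(
        coords=coords,
        var_explained=var_explained,
        site_subset=site_subset,
        samples=list(matrix.samples),
    )
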
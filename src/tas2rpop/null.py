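"""Empirical genome-wide null distributions and percentile (P_E) tests.

Rather than fitting a demographic model, observed per-gene statistics are
compared to the genome-wide distribution of the same statistic computed in
adjacent (non-overlapping) 1-kb windows, after excluding masked regions
(annotated functional elements, repeats, telomeres).  The percentile
position of an observed value within this distribution is its P_E value;
values below the 5th or above the 95th percentile are flagged as outliers.

The percentile uses the empirical CDF with ties counted as <=:

    P_E = 100 * #{null values <= observed} / #null values
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .differentiation import fst_from_pop_counts, _pop_counts_per_site
from .diversity import nucleotide_diversity, tajimas_d
from .io import GeneRegion, GenomeMask, SampleManifest, extract_region_genotypes

logger = logging.getLogger(__name__)

STATISTICS = ("pi", "tajima_d", "fst")
LOW_PCT = 5.0
HIGH_PCT = 95.0


@dataclass
class Window:
    """One candidate null window, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NullDistribution:
    """Sorted per-window values of one statistic, with provenance."""

    statistic: str
    values: np.ndarray
    window_size: int = 1000
    n_windows_total: int = 0
    n_windows_dropped: int = 0
    mask_id: str = ""

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("null distribution contains non-finite values")
        self.values = np.sort(vals)
        if self.n_windows_total == 0:
            self.n_windows_total = len(self.values) + self.n_windows_dropped
        if self.n_windows_dropped + len(self.values) != self.n_windows_total:
            raise ValueError("window provenance counts do not add up")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PercentileCall:
    """An observed statistic placed on its empirical null."""

    observed: float
    pe: float
    flag: str  # low_outlier | none | high_outlier


def tile_windows(
    chrom_lengths: Mapping[str, int],
    window_size: int = 1000,
    mask: Optional[GenomeMask] = None,
    max_mask_overlap: float = 0.0,
) -> List[Window]:
    """Tile adjacent non-overlapping windows, dropping masked ones.

    A window whose overlap fraction with the mask exceeds
    ``max_mask_overlap`` is dropped (default 0.0: any overlap drops it).
    Trailing partial windows are dropped.
    """
    if window_size < 100:
        raise ValueError("window_size must be >= 100 bp")
    windows: List[Window] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start0 in range(0, length - window_size + 1, window_size):
            w = Window(chrom, start0 + 1, start0 + window_size)
            if mask is not None:
                ov = mask.overlap_length(chrom, start0, start0 + window_size)
                if ov / window_size > max_mask_overlap:
                    continue
            windows.append(w)
    return windows


def window_statistics(
    vcf_source,
    windows: Sequence[Window],
    manifest: SampleManifest,
    statistic: str,
    grouping: str = "population",
    mask_id: str = "",
) -> NullDistribution:
    """Compute one statistic in every window and collect the finite values.

    Windows where the statistic is undefined (no segregating sites for
    Tajima's D; zero F_ST denominator) count toward ``n_windows_dropped``
    and are never imputed.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    values: List[float] = []
    dropped = 0
    for w in windows:
        region = GeneRegion(f"{w.chrom}:{w.start}-{w.end}", w.chrom, w.start, w.end, None, None)
        try:
            matrix = extract_region_genotypes(vcf_source, region, manifest)
            val = _window_value(matrix, manifest, statistic, w.length, grouping)
        except ValueError:
            val = None
        if val is None or not np.isfinite(val):
            dropped += 1
        else:
            values.append(float(val))
    if not values:
        raise ValueError("empty null distribution: statistic undefined in every window")
    return NullDistribution(
        statistic=statistic,
        values=np.array(values),
        window_size=windows[0].length if windows else 1000,
        n_windows_total=len(windows),
        n_windows_dropped=dropped,
        mask_id=mask_id,
    )


def _window_value(matrix, manifest, statistic, length, grouping) -> Optional[float]:
    if matrix.n_sites == 0:
        return 0.0 if statistic == "pi" else None
    if statistic == "pi":
        return nucleotide_diversity(matrix, length)
    if statistic == "tajima_d":
        return tajimas_d(matrix)
    alt_counts, totals, _ = _pop_counts_per_site(matrix, manifest, grouping)
    seg = np.asarray(matrix.segregating, dtype=bool)
    if not seg.any():
        return None
    return fst_from_pop_counts(alt_counts[seg], totals[seg])


def pe_percentile(null: NullDistribution, observed: float) -> PercentileCall:
    """Percentile position of ``observed`` in the null (ties count as <=)."""
    if len(null) == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(observed):
        raise ValueError("observed value must be finite")
    n_le = int(np.searchsorted(null.values, observed, side="right"))
    pe = 100.0 * n_le / len(null)
    if pe < LOW_PCT:
        flag = "low_outlier"
    elif pe > HIGH_PCT:
        flag = "high_outlier"
    else:
        flag = "none"
    return PercentileCall(observed=float(observed), pe=pe, flag=flag)


# ---------------------------------------------------------------------------
# Persistence: TSV with '#'-prefixed provenance header
# ---------------------------------------------------------------------------

def write_null(null: NullDistribution, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"#statistic={null.statistic}\twindow_size={null.window_size}\t"
            f"n_windows_total={null.n_windows_total}\t"
            f"n_windows_dropped={null.n_windows_dropped}\tmask_id={null.mask_id}\n"
        )
        fh.write("#value\n")
        for v in null.values:
            fh.write(f"{float(v)!r}\n")


def read_null(path: str) -> NullDistribution:
    meta: Dict[str, str] = {}
    values: List[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for item in line.lstrip("#").split("\t"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k] = v
                continue
            values.append(float(line))
    return NullDistribution(
        statistic=meta.get("statistic", "pi"),
        values=np.array(values),
        window_size=int(meta.get("window_size", 1000)),
        n_windows_total=int(meta.get("n_windows_total", 0)),
        n_windows_dropped=int(meta.get("n_windows_dropped", 0)),
        mask_id=meta.get("mask_id", ""),
    )
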
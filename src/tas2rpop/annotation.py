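"""Variant consequence classification, deleteriousness triage, and allele
frequency summaries.

Variants are classified into a closed set of consequence categories (as
produced upstream by Ensembl VEP) and, for nonsynonymous SNPs, triaged by
their PolyPhen-2 and SIFT scores.  A variant is a *putatively high impact*
(PHI) site if it is a nonsynonymous SNP called possibly/probably damaging by
PolyPhen-2 AND deleterious by SIFT, or if it gains/loses a stop codon or
loses the start codon, or if it is an indel (inframe or frameshift).
Synonymous variants are never PHI.

Frequencies follow the convention of the source dataset: the reported "MAF"
is the unfolded alternate-allele frequency and may exceed 0.5; a folded
minor-allele frequency is available separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class Consequence(enum.Enum):
    """Closed consequence vocabulary; short aliases follow the reporting
    convention Ns/Sg/If/Fs."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    INFRAME = "inframe"
    FRAMESHIFT = "frameshift"

    @property
    def abbreviation(self) -> str:
        return _ABBREV[self]

    @classmethod
    def parse(cls, text: str) -> "Consequence":
        key = text.strip().lower()
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown consequence category: {text!r}") from None


_ABBREV = {
    Consequence.SYNONYMOUS: "Sy",
    Consequence.NONSYNONYMOUS: "Ns",
    Consequence.STOP_GAINED: "Sg",
    Consequence.STOP_LOST: "Sl",
    Consequence.START_LOST: "St",
    Consequence.INFRAME: "If",
    Consequence.FRAMESHIFT: "Fs",
}

#: Consequence classes that make a variant PHI irrespective of scores.
STOP_START_CLASSES = frozenset(
    {Consequence.STOP_GAINED, Consequence.STOP_LOST, Consequence.START_LOST}
)
INDEL_CLASSES = frozenset({Consequence.INFRAME, Consequence.FRAMESHIFT})


@dataclass
class VariantRecord:
    """One alternate allele at one site, with annotation and frequency.

    ``pos`` is 1-based.  ``sift`` / ``polyphen`` are in [0, 1] when present.
    ``alt_freq`` is the unfolded alternate-allele frequency.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    consequence: Optional[Consequence] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    alt_freq: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1]")
        if self.alt_freq is not None and not (0.0 <= self.alt_freq <= 1.0):
            raise ValueError(f"alt_freq {self.alt_freq} outside [0, 1]")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def minor_allele_freq(self) -> Optional[float]:
        """Folded MAF; derived, not the reporting convention."""
        if self.alt_freq is None:
            return None
        return min(self.alt_freq, 1.0 - self.alt_freq)


class PolyPhenCategory(enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


class SiftCategory(enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"


#: PolyPhen-2 qualitative rating bounds (probability of damage).
POLYPHEN_BENIGN_MAX = 0.446
POLYPHEN_POSSIBLY_MAX = 0.908
#: SIFT deleteriousness threshold.
SIFT_DELETERIOUS_BELOW = 0.05


def polyphen_category(score: float) -> PolyPhenCategory:
    """Qualitative PolyPhen-2 rating for a probability-of-damage score.

    Boundary scores (0.446, 0.908) fall in the possibly-damaging class: the
    published interval 0.446-0.908 is read as closed on both ends.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen-2 score {score} outside [0, 1]")
    if score < POLYPHEN_BENIGN_MAX:
        return PolyPhenCategory.BENIGN
    if score <= POLYPHEN_POSSIBLY_MAX:
        return PolyPhenCategory.POSSIBLY_DAMAGING
    return PolyPhenCategory.PROBABLY_DAMAGING


def sift_category(score: float) -> SiftCategory:
    """SIFT rating: deleterious iff score < 0.05.

    A score of exactly 0.05 is tolerated (the published rule assigns only
    "< 0.05" and "> 0.05"; the tie goes to the non-damaging side).
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    if score < SIFT_DELETERIOUS_BELOW:
        return SiftCategory.DELETERIOUS
    return SiftCategory.TOLERATED


@dataclass
class PHICall:
    """PHI classification with the reasons that triggered it.

    ``is_phi`` is true iff ``reasons`` is non-empty.  ``warning`` carries a
    reason code when a nonsynonymous record could not be scored (both
    deleteriousness scores absent).
    """

    is_phi: bool
    reasons: frozenset = frozenset()
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_phi != bool(self.reasons):
            raise ValueError("is_phi must match non-empty reasons")


def classify_phi(record: VariantRecord) -> PHICall:
    """Apply the PHI (putatively high impact) rule to one variant.

    PHI iff:
      * nonsynonymous AND PolyPhen-2 possibly/probably damaging AND SIFT
        deleterious (both scores must be present and concordant), or
      * stop gained / stop lost / start lost, or
      * an indel (inframe or frameshift; both qualify).
    """
    if record.consequence is None:
        raise ValueError("record has no consequence annotation")
    cons = record.consequence
    reasons = set()
    warning = None
    if cons in STOP_START_CLASSES:
        reasons.add(cons.value)
    elif cons in INDEL_CLASSES:
        reasons.add("indel")
    elif cons is Consequence.NONSYNONYMOUS:
        if record.sift is None and record.polyphen is None:
            warning = "unscored_nonsynonymous"
        elif (
            record.polyphen is not None
            and record.sift is not None
            and polyphen_category(record.polyphen) is not PolyPhenCategory.BENIGN
            and sift_category(record.sift) is SiftCategory.DELETERIOUS
        ):
            reasons.add("damaging_and_deleterious")
    return PHICall(is_phi=bool(reasons), reasons=frozenset(reasons), warning=warning)


def alt_allele_frequency(alt_count: int, called_allele_total: int) -> float:
    """Alternate-allele frequency from haploid counts, full precision."""
    if called_allele_total < 1:
        raise ValueError("allele frequency undefined: no called alleles")
    if not 0 <= alt_count <= called_allele_total:
        raise ValueError("alt_count outside [0, called_allele_total]")
    return alt_count / called_allele_total


#: Default frequency bands reported in the family-wide summary.
DEFAULT_BANDS = (
    ("below_0.004", 0.0, 0.004, "right_open"),
    ("below_0.34", 0.0, 0.34, "right_open"),
    ("intermediate_0.25_0.75", 0.25, 0.75, "closed"),
)


@dataclass
class SFSSummary:
    """Site-frequency-spectrum summary over a set of segregating records."""

    n_sites: int
    n_singletons: int
    band_fractions: Mapping[str, float]
    mean_alt_freq: float
    min_alt_freq: float
    max_alt_freq: float

    def __post_init__(self) -> None:
        if self.n_singletons > self.n_sites:
            raise ValueError("more singletons than sites")


def sfs_summary(
    records: Sequence[VariantRecord],
    hap_counts: Sequence[tuple],
    bands: Iterable[tuple] = DEFAULT_BANDS,
) -> SFSSummary:
    """Summarize the allele-frequency distribution of segregating records.

    A singleton is an alternate allele observed exactly once among all called
    chromosomes (unfolded).  Band fractions use the record alt frequencies;
    a band is either half-open [lo, hi) or closed [lo, hi].
    """
    if len(records) == 0:
        raise ValueError("no segregating records")
    if len(records) != len(hap_counts):
        raise ValueError("records and hap_counts length mismatch")
    freqs = []
    n_singletons = 0
    for rec, (alt_count, total) in zip(records, hap_counts):
        freqs.append(alt_allele_frequency(alt_count, total))
        if alt_count == 1:
            n_singletons += 1
    fractions = {}
    for name, lo, hi, kind in bands:
        if kind == "closed":
            n_in = sum(1 for f in freqs if lo <= f <= hi)
        else:
            n_in = sum(1 for f in freqs if lo <= f < hi)
        fractions[name] = n_in / len(freqs)
    return SFSSummary(
        n_sites=len(freqs),
        n_singletons=n_singletons,
        band_fractions=fractions,
        mean_alt_freq=sum(freqs) / len(freqs),
        min_alt_freq=min(freqs),
        max_alt_freq=max(freqs),
    )
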
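"""Readers and writers for the external inputs of the scan.

Five inputs are consumed: a VCF (region slices of phased diploid genotypes),
a sample panel (sample -> population -> super population), a gene-coordinate
table (1-based inclusive GRCh37 intervals), a per-variant effect-annotation
table (consequence + SIFT + PolyPhen-2, produced upstream by VEP), and a BED
exclusion mask for the empirical-null builder.

Coordinate conventions: the gene table and VCF are 1-based inclusive; BED is
0-based half-open.  All conversions happen here; the internal model is
1-based inclusive.  All tabular writers emit tab-separated UTF-8 with a
``#``-prefixed header line.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotation import Consequence, VariantRecord

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel


# ---------------------------------------------------------------------------
# Gene regions
# ---------------------------------------------------------------------------

@dataclass
class GeneRegion:
    """One analyzed gene interval (1-based inclusive coordinates).

    ``excluded`` marks loci dropped from analysis (the table encodes them
    with "na" coordinates, e.g. deletion-polymorphic loci); they are carried
    through reporting but receive no statistics.
    """

    name: str
    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    transcript_length: Optional[int]
    n_codons: Optional[int]
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.excluded:
            return
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start")
        if self.n_codons is not None and self.n_codons < 1:
            raise ValueError(f"{self.name}: n_codons < 1")
        span = self.end - self.start + 1
        if self.transcript_length is not None and self.transcript_length != span:
            logger.warning(
                "%s: transcript_length %d != genomic span %d",
                self.name, self.transcript_length, span,
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)[–—-](?P<end>[\d,]+)$")


def _parse_int(text: str) -> int:
    return int(text.replace(",", ""))


def read_gene_table(source) -> List[GeneRegion]:
    """Parse a tab-separated gene table: gene, chrom:start-end, length, codons.

    Rows with "na" coordinates are returned flagged ``excluded`` rather than
    dropped.  ``source`` is a path or an iterable of lines.
    """
    regions: List[GeneRegion] = []
    for i, row in enumerate(_iter_rows(source, expect_header=True)):
        if len(row) < 4:
            raise ValueError(f"gene table row {i + 1}: expected 4 columns, got {len(row)}")
        name, coords, length_s, codons_s = row[:4]
        if coords.strip().lower().startswith("na"):
            regions.append(GeneRegion(name, None, None, None, None, None, excluded=True))
            continue
        m = _COORD_RE.match(coords.strip())
        if m is None:
            raise ValueError(f"gene table row {i + 1} ({name}): malformed coordinates {coords!r}")
        regions.append(
            GeneRegion(
                name=name,
                chrom=m.group("chrom"),
                start=_parse_int(m.group("start")),
                end=_parse_int(m.group("end")),
                transcript_length=_parse_int(length_s) if length_s.strip().lower() != "na" else None,
                n_codons=_parse_int(codons_s) if codons_s.strip().lower() != "na" else None,
            )
        )
    return regions


def write_gene_table(regions: Sequence[GeneRegion], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene\tcoordinates\ttranscript_length\tn_codons\n")
        for r in regions:
            if r.excluded:
                fh.write(f"{r.name}\tna:na-na\tna\tna\n")
            else:
                fh.write(
                    f"{r.name}\t{r.chrom}:{r.start}-{r.end}\t{r.transcript_length}\t{r.n_codons}\n"
                )


# ---------------------------------------------------------------------------
# Sample panel
# ---------------------------------------------------------------------------

@dataclass
class SampleManifest:
    """Sample -> population -> super population nesting.

    Invariants enforced on construction: unique sample ids; every population
    under exactly one super population.
    """

    entries: List[Tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen = set()
        pop_to_super: Dict[str, str] = {}
        for sample, pop, sup in self.entries:
            if sample in seen:
                raise ValueError(f"duplicate sample id {sample!r}")
            seen.add(sample)
            if pop in pop_to_super and pop_to_super[pop] != sup:
                raise ValueError(
                    f"population {pop!r} nested under two super populations: "
                    f"{pop_to_super[pop]!r} and {sup!r}"
                )
            pop_to_super[pop] = sup
        self._pop_to_super = pop_to_super

    @property
    def samples(self) -> List[str]:
        return [e[0] for e in self.entries]

    @property
    def populations(self) -> List[str]:
        return sorted({e[1] for e in self.entries})

    @property
    def super_populations(self) -> List[str]:
        return sorted({e[2] for e in self.entries})

    def population_of(self, sample: str) -> str:
        return dict((e[0], e[1]) for e in self.entries)[sample]

    def labels(self, grouping: str = "population") -> List[str]:
        """Per-sample group labels, in manifest order."""
        if grouping in ("population", "pop"):
            return [e[1] for e in self.entries]
        if grouping in ("superpop", "super_population", "super_pop"):
            return [e[2] for e in self.entries]
        raise ValueError(f"unknown grouping {grouping!r}")

    def subset(self, samples: Iterable[str]) -> "SampleManifest":
        keep = set(samples)
        return SampleManifest([e for e in self.entries if e[0] in keep])


def read_sample_panel(source) -> SampleManifest:
    """Parse a panel TSV with columns sample, pop, super_pop."""
    rows = list(_iter_rows(source, expect_header=False))
    if not rows:
        raise ValueError("empty sample panel")
    header = [c.lstrip("#").strip().lower() for c in rows[0]]
    if "sample" in header:
        idx = {name: header.index(name) for name in ("sample", "pop", "super_pop")}
        rows = rows[1:]
    else:
        idx = {"sample": 0, "pop": 1, "super_pop": 2}
    entries = []
    for row in rows:
        entries.append((row[idx["sample"]], row[idx["pop"]], row[idx["super_pop"]]))
    return SampleManifest(entries)


def write_sample_panel(manifest: SampleManifest, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#sample\tpop\tsuper_pop\n")
        for sample, pop, sup in manifest.entries:
            fh.write(f"{sample}\t{pop}\t{sup}\n")


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Per-site alternate-allele dosages for diploid samples.

    One row per decomposed alternate allele (multi-allelic VCF records are
    split into one row per ALT).  ``dosages`` holds integers in {0, 1, 2}
    with ``MISSING`` (-1) for uncalled genotypes; ``hap_counts`` holds
    (alt_count, called_allele_total) per row.  ``segregating`` flags rows
    polymorphic within the retained sample subset.
    """

    variants: List[VariantRecord]
    dosages: np.ndarray
    hap_counts: np.ndarray
    samples: List[str]
    segregating: np.ndarray = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.hap_counts = np.asarray(self.hap_counts, dtype=np.int64)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage matrix shape mismatch")
        if self.hap_counts.shape != (len(self.variants), 2):
            raise ValueError("hap_counts shape mismatch")
        if np.any(self.hap_counts[:, 0] > self.hap_counts[:, 1]):
            raise ValueError("alt_count exceeds called_allele_total")
        if np.any(self.hap_counts[:, 1] > 2 * len(self.samples)):
            raise ValueError("called_allele_total exceeds 2 x n_samples")
        if self.segregating is None:
            alt, tot = self.hap_counts[:, 0], self.hap_counts[:, 1]
            self.segregating = (alt > 0) & (alt < tot)
        self.segregating = np.asarray(self.segregating, dtype=bool)
        keys = [(v.chrom, v.pos, v.alt) for v in self.variants]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites not strictly increasing by (chrom, pos, alt)")

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def alt_freqs(self) -> np.ndarray:
        tot = self.hap_counts[:, 1].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.hap_counts[:, 0] / tot, np.nan)

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            variants=[v for v, m in zip(self.variants, mask) if m],
            dosages=self.dosages[mask],
            hap_counts=self.hap_counts[mask],
            samples=list(self.samples),
            segregating=self.segregating[mask],
        )


def _chrom_variants(chrom: str) -> List[str]:
    c = str(chrom)
    return [c, c[3:]] if c.startswith("chr") else [c, "chr" + c]


def extract_region_genotypes(vcf_source, region: GeneRegion, manifest: SampleManifest) -> GenotypeMatrix:
    """Extract the manifest's samples over a gene region from a VCF.

    Samples are retained in manifest order; multi-allelic records are
    decomposed into one row per alternate allele; records monomorphic in the
    retained subset are kept but flagged non-segregating.  Requires a
    tabix/CSI index for random access; an unindexed plain VCF is streamed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), gts012=False)
    vcf_samples = list(vcf.samples)
    wanted = [s for s in manifest.samples if s in set(vcf_samples)]
    if not wanted:
        raise ValueError("no overlap between VCF samples and manifest")
    if len(wanted) < len(manifest.samples):
        logger.warning(
            "%d of %d manifest samples absent from VCF",
            len(manifest.samples) - len(wanted), len(manifest.samples),
        )
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    cols = np.array([col_of[s] for s in wanted])

    chrom_names = _chrom_variants(region.chrom)
    seqnames = set(vcf.seqnames)
    if seqnames and not any(c in seqnames for c in chrom_names):
        raise ValueError(f"contig {region.chrom!r} absent from VCF contig set")
    target = next((c for c in chrom_names if c in seqnames), str(region.chrom))

    has_index = any(
        os.path.exists(f"{vcf_source}{ext}") for ext in (".tbi", ".csi")
    )

    def records():
        if has_index:
            yield from vcf(f"{target}:{region.start}-{region.end}")
        else:
            # no index: stream and filter
            for rec in vcf:
                if str(rec.CHROM) in chrom_names and region.start <= rec.POS <= region.end:
                    yield rec

    variants: List[VariantRecord] = []
    dosage_rows: List[np.ndarray] = []
    hap_rows: List[Tuple[int, int]] = []
    for rec in records():
        if not (region.start <= rec.POS <= region.end):
            continue
        gt = rec.genotype.array()[:, :2][cols]  # (n_kept, 2) allele indices, -1 missing
        called = gt >= 0
        called_total = int(called.sum())
        for ai, alt in enumerate(rec.ALT, start=1):
            alt_per_hap = (gt == ai)
            dos = alt_per_hap.sum(axis=1).astype(np.int16)
            dos[~called.all(axis=1)] = MISSING
            alt_count = int(alt_per_hap[called].sum())
            variants.append(
                VariantRecord(
                    chrom=str(rec.CHROM), pos=int(rec.POS), ref=rec.REF, alt=alt,
                    rsid=rec.ID if rec.ID not in (None, ".") else None,
                    alt_freq=(alt_count / called_total) if called_total else None,
                )
            )
            dosage_rows.append(dos)
            hap_rows.append((alt_count, called_total))

    order = sorted(
        range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos, variants[i].alt)
    )
    return GenotypeMatrix(
        variants=[variants[i] for i in order],
        dosages=np.array([dosage_rows[i] for i in order], dtype=np.int16).reshape(len(order), len(wanted)),
        hap_counts=np.array([hap_rows[i] for i in order], dtype=np.int64).reshape(len(order), 2),
        samples=wanted,
    )


def write_genotype_matrix_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Emit a (decomposed, biallelic-per-row) VCF 4.2 text file.

    Genotypes are reconstructed from dosages as unphased 0/0, 0/1, 1/1 or
    ./.; round-tripping through :func:`extract_region_genotypes` recovers
    identical dosages and site order.
    """
    contigs = []
    for v in matrix.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for v, row in zip(matrix.variants, matrix.dosages):
            gts = "\t".join(gt_str[int(d)] for d in row)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def read_annotation_table(source) -> Dict[tuple, VariantRecord]:
    """Parse the effect-annotation TSV into a (chrom, pos, ref, alt) map.

    Columns: chrom pos ref alt rsid consequence sift polyphen.  Unknown
    consequence strings and duplicate keys are rejected; empty score fields
    yield absent scores.
    """
    table: Dict[tuple, VariantRecord] = {}
    for i, row in enumerate(_iter_rows(source, expect_header=True)):
        if len(row) < 6:
            raise ValueError(f"annotation row {i + 1}: expected >= 6 columns")
        chrom, pos_s, ref, alt, rsid, cons_s = row[:6]
        sift_s = row[6] if len(row) > 6 else ""
        poly_s = row[7] if len(row) > 7 else ""
        rec = VariantRecord(
            chrom=chrom, pos=int(pos_s), ref=ref, alt=alt,
            rsid=rsid if rsid not in ("", ".") else None,
            consequence=Consequence.parse(cons_s),
            sift=float(sift_s) if sift_s.strip() not in ("", ".") else None,
            polyphen=float(poly_s) if poly_s.strip() not in ("", ".") else None,
        )
        if rec.key in table:
            raise ValueError(f"duplicate annotation key {rec.key}")
        table[rec.key] = rec
    return table


def write_annotation_table(records: Sequence[VariantRecord], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tpos\tref\talt\trsid\tconsequence\tsift\tpolyphen\n")
        for r in records:
            sift = f"{r.sift:.6g}" if r.sift is not None else ""
            poly = f"{r.polyphen:.6g}" if r.polyphen is not None else ""
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.rsid or '.'}\t"
                f"{r.consequence.value}\t{sift}\t{poly}\n"
            )


def annotate_matrix(matrix: GenotypeMatrix, table: Mapping[tuple, VariantRecord]) -> None:
    """Attach consequences and scores to matrix variants, in place."""
    for v in matrix.variants:
        ann = table.get(v.key)
        if ann is not None:
            v.consequence = ann.consequence
            v.sift = ann.sift
            v.polyphen = ann.polyphen
            if v.rsid is None:
                v.rsid = ann.rsid


# ---------------------------------------------------------------------------
# Genome mask
# ---------------------------------------------------------------------------

@dataclass
class GenomeMask:
    """Excluded genomic intervals, per chromosome, 0-based half-open.

    Intervals are merged and sorted on construction.
    """

    intervals: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for chrom, ivs in self.intervals.items():
            ivs = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
            if np.any(ivs[:, 0] >= ivs[:, 1]):
                raise ValueError(f"mask interval with start >= end on {chrom}")
            ivs = ivs[np.argsort(ivs[:, 0])]
            out = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.array(out, dtype=np.int64)
        self.intervals = merged

    def total_masked(self) -> int:
        return int(sum((ivs[:, 1] - ivs[:, 0]).sum() for ivs in self.intervals.values()))

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Overlap (bp) of [start, end) with the mask on ``chrom``."""
        best = 0
        for name in _chrom_variants(chrom):
            ivs = self.intervals.get(name)
            if ivs is None or len(ivs) == 0:
                continue
            lo = np.maximum(ivs[:, 0], start)
            hi = np.minimum(ivs[:, 1], end)
            best = max(best, int(np.clip(hi - lo, 0, None).sum()))
        return best

    def to_bed_text(self) -> str:
        lines = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                lines.append(f"{chrom}\t{s}\t{e}")
        return "\n".join(lines) + ("\n" if lines else "")


def read_mask(source) -> GenomeMask:
    """Parse a BED3+ exclusion mask (0-based half-open); merges on load."""
    intervals: Dict[str, list] = {}
    for row in _iter_rows(source, expect_header=False):
        if not row or row[0].startswith(("#", "track", "browser")):
            continue
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"BED interval with start >= end: {chrom}:{start}-{end}")
        intervals.setdefault(chrom, []).append((start, end))
    return GenomeMask({c: np.array(v) for c, v in intervals.items()})


def write_mask(mask: GenomeMask, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(mask.to_bed_text())


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _iter_rows(source, expect_header: bool) -> Iterable[List[str]]:
    """Yield tab-split rows from a path or an iterable of lines; a leading
    '#'-prefixed line (or the first line when ``expect_header``) is skipped
    as a header."""
    if isinstance(source, str) and ("\n" in source or source == ""):
        lines = source.splitlines()
    elif isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    rows = [ln.split("\t") for ln in lines if ln.strip()]
    if not rows:
        return
    first = rows[0]
    if first[0].startswith("#") or (expect_header and not _looks_like_data(first)):
        rows = rows[1:]
    for row in rows:
        if row[0].startswith("#"):
            continue
        yield [c.strip() for c in row]


def _looks_like_data(row: List[str]) -> bool:
    return any(_COORD_RE.match(c) or c.replace(",", "").isdigit() for c in row[1:])


def write_tsv(path: str, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a '#'-header TSV (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
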
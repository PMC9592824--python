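"""End-to-end scan: per-gene diversity, differentiation, percentile calls,
PHI inventory, frequency summary, and PCA, rendered as the summary tables.

One YAML config references every input (VCF, panel, gene table, annotation
table, optional per-statistic empirical nulls).  Genes are processed in
gene-table order; excluded genes (na coordinates) are reported as excluded
with no statistics; a gene region with no overlapping variants yields S = 0
and an undefined D rather than an error.  Every output directory carries a
run manifest with the config hash, so two runs on identical inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as io_mod
from .annotation import Consequence, classify_phi, sfs_summary, SFSSummary
from .differentiation import FstResult, PCAResult, genotype_pca, wc_fst_weighted
from .diversity import DiversityResult, compute_diversity
from .io import GeneRegion, GenotypeMatrix, SampleManifest
from .null import NullDistribution, PercentileCall, pe_percentile, read_null

logger = logging.getLogger(__name__)

DEFAULT_MAF_THRESHOLD = 0.001
PCA_SUBSETS = ("all", "synonymous", "nonsynonymous")


@dataclass
class ScanConfig:
    """Inputs and choices for one scan run."""

    vcf: str
    panel: str
    gene_table: str
    annotations: Optional[str] = None
    null_paths: Dict[str, str] = field(default_factory=dict)  # statistic -> TSV
    length_source: str = "transcript"  # or "span"
    grouping: str = "population"
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    pca_subsets: Tuple[str, ...] = PCA_SUBSETS
    pca_components: int = 10
    pca_scaling: str = "patterson"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pca_subsets" in raw:
            raw["pca_subsets"] = tuple(raw["pca_subsets"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GeneSummary:
    """One summary-table row."""

    gene: str
    excluded: bool = False
    S: Optional[int] = None
    S_nonsyn: Optional[int] = None
    S_syn: Optional[int] = None
    pi_pct: Optional[float] = None
    pi_pctile: Optional[float] = None
    tajima_d: Optional[float] = None
    d_pctile: Optional[float] = None
    fst: Optional[float] = None
    fst_pctile: Optional[float] = None
    fst_nonsyn: Optional[float] = None
    fst_syn: Optional[float] = None


@dataclass
class ScanResult:
    summary: List[GeneSummary]
    phi_rows: List[dict]
    sfs: Optional[SFSSummary]
    pca: Dict[str, PCAResult]
    manifest: SampleManifest
    config: ScanConfig


def run_scan(config: ScanConfig) -> ScanResult:
    """Run the full analysis described by ``config``."""
    manifest = io_mod.read_sample_panel(config.panel)
    regions = io_mod.read_gene_table(config.gene_table)
    ann_table = io_mod.read_annotation_table(config.annotations) if config.annotations else {}
    nulls: Dict[str, NullDistribution] = {
        stat: read_null(path) for stat, path in config.null_paths.items()
    }
    logger.info(
        "scan: L source=%s, grouping=%s, mask rule per null provenance, %d nulls",
        config.length_source, config.grouping, len(nulls),
    )

    summary: List[GeneSummary] = []
    matrices: List[Tuple[GeneRegion, GenotypeMatrix]] = []
    for region in regions:
        if region.excluded:
            summary.append(GeneSummary(gene=region.name, excluded=True))
            continue
        matrix = io_mod.extract_region_genotypes(config.vcf, region, manifest)
        io_mod.annotate_matrix(matrix, ann_table)
        matrices.append((region, matrix))
        summary.append(_summarize_gene(region, matrix, manifest, config, nulls))

    phi_rows = _phi_inventory(matrices, config.maf_threshold)
    sfs = _sfs_over_genes(matrices)
    pca = _pca_over_genes(matrices, config)
    return ScanResult(
        summary=summary, phi_rows=phi_rows, sfs=sfs, pca=pca,
        manifest=manifest, config=config,
    )


def _summarize_gene(
    region: GeneRegion,
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    config: ScanConfig,
    nulls: Dict[str, NullDistribution],
) -> GeneSummary:
    L = region.transcript_length if (
        config.length_source == "transcript" and region.transcript_length
    ) else region.span
    div = compute_diversity(matrix, L)
    row = GeneSummary(
        gene=region.name, S=div.S, S_nonsyn=div.S_nonsyn, S_syn=div.S_syn,
        pi_pct=div.pi_percent, tajima_d=div.tajima_d,
    )
    for attr, filt in (("fst", "all"), ("fst_nonsyn", "nonsynonymous"), ("fst_syn", "synonymous")):
        try:
            res = wc_fst_weighted(matrix, manifest, grouping=config.grouping, site_filter=filt)
            setattr(row, attr, res.theta_weighted)
        except ValueError:
            logger.info("%s: F_ST undefined for filter %s", region.name, filt)
    if "pi" in nulls:
        row.pi_pctile = pe_percentile(nulls["pi"], div.pi).pe
    if "tajima_d" in nulls and div.tajima_d is not None:
        row.d_pctile = pe_percentile(nulls["tajima_d"], div.tajima_d).pe
    if "fst" in nulls and row.fst is not None:
        row.fst_pctile = pe_percentile(nulls["fst"], row.fst).pe
    return row


def _phi_inventory(matrices, maf_threshold: float) -> List[dict]:
    """PHI sites with alt frequency strictly above the report threshold,
    sorted by descending frequency."""
    rows = []
    for region, matrix in matrices:
        for v, seg in zip(matrix.variants, matrix.segregating):
            if not seg or v.consequence is None:
                continue
            call = classify_phi(v)
            if not call.is_phi:
                continue
            if v.alt_freq is None or v.alt_freq <= maf_threshold:
                continue
            rows.append(
                {
                    "gene": region.name, "chrom": v.chrom, "pos": v.pos,
                    "ref": v.ref, "alt": v.alt, "rsid": v.rsid or ".",
                    "consequence": v.consequence.abbreviation,
                    "reasons": ",".join(sorted(call.reasons)),
                    "alt_freq": v.alt_freq,
                }
            )
    rows.sort(key=lambda r: (-r["alt_freq"], r["chrom"], r["pos"], r["alt"]))
    return rows


def _sfs_over_genes(matrices) -> Optional[SFSSummary]:
    records, counts = [], []
    for _, matrix in matrices:
        for v, seg, hc in zip(matrix.variants, matrix.segregating, matrix.hap_counts):
            if seg:
                records.append(v)
                counts.append((int(hc[0]), int(hc[1])))
    if not records:
        return None
    return sfs_summary(records, counts)


def _pca_over_genes(matrices, config: ScanConfig) -> Dict[str, PCAResult]:
    if not matrices:
        return {}
    combined = _concat_matrices([m for _, m in matrices])
    out = {}
    for subset in config.pca_subsets:
        try:
            out[subset] = genotype_pca(
                combined, site_subset=subset,
                n_components=config.pca_components, scaling=config.pca_scaling,
            )
        except ValueError:
            logger.info("PCA skipped for subset %s (no polymorphic sites)", subset)
    return out


def _concat_matrices(mats: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    samples = mats[0].samples
    for m in mats:
        if m.samples != samples:
            raise ValueError("matrices have different sample sets")
    variants = [v for m in mats for v in m.variants]
    dosages = np.vstack([m.dosages for m in mats])
    hap_counts = np.vstack([m.hap_counts for m in mats])
    seg = np.concatenate([m.segregating for m in mats])
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos, variants[i].alt))
    return GenotypeMatrix(
        variants=[variants[i] for i in order],
        dosages=dosages[order],
        hap_counts=hap_counts[order],
        samples=samples,
        segregating=seg[order],
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt(value, nd=4) -> str:
    if value is None:
        return "na"
    if isinstance(value, float):
        return f"{value:.{nd}f}"
    return str(value)


def write_outputs(result: ScanResult, outdir) -> Dict[str, str]:
    """Write summary.tsv, phi.tsv, sfs.tsv, pca_*.tsv and run_manifest.json."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    paths["summary"] = os.path.join(outdir, "summary.tsv")
    io_mod.write_tsv(
        paths["summary"],
        ["gene", "S", "S_ns", "S_syn", "ns_pct", "pi_pct", "pi_pctile", "D",
         "D_pctile", "fst", "fst_pctile", "fst_ns", "fst_syn"],
        (
            [r.gene, _fmt(r.S), _fmt(r.S_nonsyn), _fmt(r.S_syn),
             _fmt(100.0 * r.S_nonsyn / r.S, 0) if r.S else "na",
             _fmt(r.pi_pct, 3), _fmt(r.pi_pctile, 1), _fmt(r.tajima_d, 2),
             _fmt(r.d_pctile, 1), _fmt(r.fst, 2), _fmt(r.fst_pctile, 1),
             _fmt(r.fst_nonsyn, 2), _fmt(r.fst_syn, 2)]
            for r in result.summary
        ),
    )

    paths["phi"] = os.path.join(outdir, "phi.tsv")
    io_mod.write_tsv(
        paths["phi"],
        ["gene", "chrom", "pos", "ref", "alt", "rsid", "consequence", "reasons", "alt_freq"],
        (
            [r["gene"], r["chrom"], r["pos"], r["ref"], r["alt"], r["rsid"],
             r["consequence"], r["reasons"], f"{r['alt_freq']:.4f}"]
            for r in result.phi_rows
        ),
    )

    paths["sfs"] = os.path.join(outdir, "sfs.tsv")
    if result.sfs is not None:
        rows = [
            ["n_sites", result.sfs.n_sites],
            ["n_singletons", result.sfs.n_singletons],
            ["mean_alt_freq", f"{result.sfs.mean_alt_freq:.6f}"],
            ["min_alt_freq", f"{result.sfs.min_alt_freq:.6f}"],
            ["max_alt_freq", f"{result.sfs.max_alt_freq:.6f}"],
        ] + [[f"band_{k}", f"{v:.6f}"] for k, v in result.sfs.band_fractions.items()]
    else:
        rows = []
    io_mod.write_tsv(paths["sfs"], ["quantity", "value"], rows)

    pop_of = {e[0]: (e[1], e[2]) for e in result.manifest.entries}
    for subset, pca in result.pca.items():
        key = {"all": "pca_all", "synonymous": "pca_syn", "nonsynonymous": "pca_nonsyn"}[subset]
        paths[key] = os.path.join(outdir, f"{key}.tsv")
        k = pca.coords.shape[1]
        io_mod.write_tsv(
            paths[key],
            ["sample", "pop", "super_pop"] + [f"PC{i + 1}" for i in range(k)],
            (
                [s, pop_of[s][0], pop_of[s][1]] + [f"{c:.6g}" for c in pca.coords[i]]
                for i, s in enumerate(pca.samples)
            ),
        )
        paths[key + "_var"] = os.path.join(outdir, f"{key}_variance.tsv")
        io_mod.write_tsv(
            paths[key + "_var"],
            ["component", "var_explained"],
            ([i + 1, f"{v:.6g}"] for i, v in enumerate(pca.var_explained)),
        )

    paths["manifest"] = os.path.join(outdir, "run_manifest.json")
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(result.config),
                "config_hash": result.config.digest(),
                "seed": result.config.seed,
                "n_genes": len(result.summary),
            },
            fh, indent=2, sort_keys=True, default=str,
        )
        fh.write("\n")
    return paths
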
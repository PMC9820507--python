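"""Panel variant extraction from VCF and rare-variant filtering.

Reads the 16-gene MODY panel regions from a BED file (0-based half-open,
GRCh38), extracts normalized bi-allelic variants falling inside those regions
from a multi-sample VCF, computes within-cohort minor allele frequencies and
carrier sets, and applies the rarity/depth filters (cohort MAF < 0.001, mean
sequencing depth > 20x, both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

log = logging.getLogger(__name__)

__all__ = [
    "PANEL_SUBTYPES",
    "GeneRegion",
    "PanelVariant",
    "load_gene_regions",
    "normalize_allele",
    "extract_panel_variants",
    "compute_cohort_maf",
    "filter_variants",
    "write_variants_tsv",
]

# MODY subtype number per panel gene; RFX6 and NKX6-1 are candidate genes
# without an assigned subtype.
PANEL_SUBTYPES: dict[str, int | str] = {
    "HNF4A": 1,
    "GCK": 2,
    "HNF1A": 3,
    "PDX1": 4,
    "HNF1B": 5,
    "NEUROD1": 6,
    "KLF11": 7,
    "CEL": 8,
    "PAX4": 9,
    "INS": 10,
    "BLK": 11,
    "ABCC8": 12,
    "KCNJ11": 13,
    "APPL1": 14,
    "RFX6": "candidate",
    "NKX6-1": "candidate",
}

# Default rare-variant filter thresholds (both comparisons strict).
DEFAULT_MAF_MAX = 0.001
DEFAULT_MIN_MEAN_DEPTH = 20.0


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


@dataclass(frozen=True)
class GeneRegion:
    """One panel gene's genomic interval (0-based half-open)."""

    gene: str
    chrom: str
    start: int
    end: int
    mody_subtype: int | str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene}: start {self.start} must be < end {self.end}"
            )
        if self.gene not in PANEL_SUBTYPES:
            raise ValueError(f"gene {self.gene!r} is not in the 16-gene panel")

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Is a 1-based position inside this 0-based half-open interval?"""
        return (
            _norm_chrom(chrom) == _norm_chrom(self.chrom)
            and self.start < pos_1based <= self.end
        )


@dataclass
class PanelVariant:
    """A normalized bi-allelic alt allele inside a panel gene.

    Carrier sets hold subject ids; ``n_called`` counts subjects with a
    non-missing genotype at the site. ``mean_depth`` is the mean per-genotype
    sequencing depth over called samples.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    het_carriers: frozenset[str]
    hom_carriers: frozenset[str]
    n_called: int
    mean_depth: float

    def __post_init__(self):
        if self.het_carriers & self.hom_carriers:
            raise ValueError(
                f"{self.key}: het and hom carrier sets must be disjoint"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (_norm_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def carriers(self) -> frozenset[str]:
        return self.het_carriers | self.hom_carriers

    @property
    def n_carriers(self) -> int:
        return len(self.het_carriers) + len(self.hom_carriers)

    @property
    def cohort_maf(self) -> float:
        return compute_cohort_maf(self)


def load_gene_regions(bed_path: str | Path) -> list[GeneRegion]:
    """Parse the panel BED; returns the 16 regions in genomic order.

    Expects >= 4 columns (chrom, start, end, gene) with an optional fifth
    column carrying the MODY subtype; '#' lines are comments. Unknown gene
    symbols, duplicate genes and malformed rows raise with the line number.
    """
    path = Path(bed_path)
    regions: list[GeneRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns"
                )
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if gene not in PANEL_SUBTYPES:
                raise ValueError(
                    f"{path}:{lineno}: gene {gene!r} is not in the 16-gene panel"
                )
            if gene in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            try:
                regions.append(
                    GeneRegion(gene, chrom, start, end, PANEL_SUBTYPES[gene])
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not regions:
        raise ValueError(f"{path}: no regions found")
    regions.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.start))
    return regions


def _chrom_sort_key(chrom: str):
    c = _norm_chrom(chrom)
    return (0, int(c)) if c.isdigit() else (1, c)


def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim a ref/alt pair: drop shared suffix, then shared prefix.

    Left-alignment against a reference sequence is out of scope (no FASTA is
    consumed); trimming alone makes SNVs extracted from padded multi-allelic
    records comparable across representations.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _genotype_alleles(record, n_samples: int) -> np.ndarray:
    """Allele index matrix (n_samples, 2); -1 marks a missing allele."""
    try:
        arr = record.genotype.array()
        return np.asarray(arr)[:, :2]
    except Exception:  # pragma: no cover - older cyvcf2 fallback
        gts = record.genotypes
        return np.array([[g[0], g[1]] for g in gts], dtype=np.int32)


def extract_panel_variants(
    vcf_path: str | Path, regions: list[GeneRegion]
) -> list[PanelVariant]:
    """Extract one PanelVariant per normalized alt allele inside the panel.

    Multi-allelic records are split per alt; symbolic and spanning-deletion
    alleles are skipped; variants outside every region are dropped. Mean
    depth is the mean FORMAT/DP over called samples, falling back to site
    INFO/DP divided by the sample count.
    """
    vcf = VCF(str(vcf_path), gts012=True)
    samples = np.asarray(vcf.samples)
    if len(samples) == 0:
        raise ValueError(f"{vcf_path}: VCF has no samples (GT data required)")

    by_chrom: dict[str, list[GeneRegion]] = {}
    for r in regions:
        by_chrom.setdefault(_norm_chrom(r.chrom), []).append(r)

    seqnames = {_norm_chrom(c) for c in vcf.seqnames}
    if seqnames and not (seqnames & set(by_chrom)):
        raise ValueError(
            "no panel contig found in VCF: panel uses "
            f"{sorted(by_chrom)} but VCF declares {sorted(seqnames)}"
        )

    out: list[PanelVariant] = []
    saw_gt = False
    for rec in vcf:
        chrom = _norm_chrom(rec.CHROM)
        cand = by_chrom.get(chrom)
        if not cand:
            continue
        alleles = None
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            if not alt or alt.startswith("<") or alt == "*":
                continue
            pos, ref, alt_n = normalize_allele(rec.POS, rec.REF, alt)
            region = next((r for r in cand if r.contains(chrom, pos)), None)
            if region is None:
                continue
            if alleles is None:
                alleles = _genotype_alleles(rec, len(samples))
                saw_gt = True
                called = np.all(alleles >= 0, axis=1)
                depth = _mean_depth(rec, called, len(samples))
            hits = (alleles == alt_idx).sum(axis=1)
            het = samples[called & (hits == 1)]
            hom = samples[called & (hits == 2)]
            out.append(
                PanelVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    gene=region.gene,
                    het_carriers=frozenset(het.tolist()),
                    hom_carriers=frozenset(hom.tolist()),
                    n_called=int(called.sum()),
                    mean_depth=depth,
                )
            )
    if out and not saw_gt:  # pragma: no cover - defensive
        raise ValueError(f"{vcf_path}: no GT genotypes found")
    out.sort(key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    return out


def _mean_depth(rec, called: np.ndarray, n_samples: int) -> float:
    dp = rec.format("DP")
    if dp is not None:
        d = np.asarray(dp, dtype=float).reshape(n_samples, -1)[:, 0]
        valid = called & (d >= 0) & np.isfinite(d)
        if valid.any():
            return float(d[valid].mean())
    site_dp = rec.INFO.get("DP")
    if site_dp is not None and n_samples > 0:
        return float(site_dp) / n_samples
    return float("nan")


def compute_cohort_maf(variant: PanelVariant) -> float:
    """Within-cohort minor allele frequency: (n_het + 2*n_hom) / (2*n_called).

    Missing genotypes are excluded from the denominator (standard VCF AN
    semantics). If the alt allele turns out to be the major allele the
    folded frequency min(f, 1-f) is returned with a warning.
    """
    if variant.n_called == 0:
        raise ValueError(f"{variant.key}: no called genotypes, MAF undefined")
    f = (len(variant.het_carriers) + 2 * len(variant.hom_carriers)) / (
        2 * variant.n_called
    )
    if f > 0.5:
        log.warning(
            "%s: alt allele frequency %.4f > 0.5; folding to minor allele",
            variant.key,
            f,
        )
        return 1.0 - f
    return f


def filter_variants(
    variants: list[PanelVariant],
    maf_max: float = DEFAULT_MAF_MAX,
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
) -> list[PanelVariant]:
    """Keep variants with cohort MAF < maf_max, mean depth > min_mean_depth
    and at least one carrier; both threshold comparisons are strict.

    Order is preserved; each rejection is logged with its reason.
    """
    kept = []
    for v in variants:
        if v.n_carriers == 0:
            log.info("drop %s: no carriers", v.key)
            continue
        maf = compute_cohort_maf(v)
        if not maf < maf_max:
            log.info("drop %s: cohort MAF %.6f >= %.6f", v.key, maf, maf_max)
            continue
        if not v.mean_depth > min_mean_depth:
            log.info(
                "drop %s: mean depth %.1fx <= %.1fx", v.key, v.mean_depth, min_mean_depth
            )
            continue
        kept.append(v)
    return kept


def write_variants_tsv(variants: list[PanelVariant], path: str | Path) -> None:
    """Write variants as TSV (CHROM, POS, REF, ALT, GENE, N_HET, N_HOM, MAF, MEAN_DP)."""
    import pandas as pd

    rows = [
        {
            "CHROM": v.chrom,
            "POS": v.pos,
            "REF": v.ref,
            "ALT": v.alt,
            "GENE": v.gene,
            "N_HET": len(v.het_carriers),
            "N_HOM": len(v.hom_carriers),
            "MAF": f"{compute_cohort_maf(v):.6f}",
            "MEAN_DP": f"{v.mean_depth:.1f}",
        }
        for v in variants
    ]
    pd.DataFrame(
        rows,
        columns=["CHROM", "POS", "REF", "ALT", "GENE", "N_HET", "N_HOM", "MAF", "MEAN_DP"],
    ).to_csv(path, sep="\t", index=False)
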
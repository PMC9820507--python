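"""Subject-level aggregation: carrier unions, prevalence, gene proportions.

Prevalence of monogenic diabetes here follows the biobank screening
convention: the numerator is the number of distinct carriers of qualifying
variants (including carriers not currently diabetic — they carry a screened
mutation), the denominator is the number of diabetes cases (T1DM + T2DM).
A stricter diabetic-carriers-only numerator is available behind a flag; the
report flags the convention rather than silently switching.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .phenotype import DiabetesStatus
from .triage import Tier, TriagedVariant, write_tier_tables, triaged_to_frame

log = logging.getLogger(__name__)

__all__ = [
    "PrevalenceSummary",
    "carrier_union",
    "prevalence",
    "gene_proportions",
    "render_report",
]

KNOWN_TIERS = frozenset({Tier.A, Tier.B})
NOVEL_TIERS = frozenset({Tier.C})
ALL_TIERS = KNOWN_TIERS | NOVEL_TIERS


def carrier_union(
    triaged: list[TriagedVariant], tiers: Iterable[Tier]
) -> frozenset[str]:
    """Distinct subjects carrying >= 1 variant in the requested tiers.

    Subjects carrying more than one qualifying variant are logged: on real
    cohorts per-variant carrier counts then over-count subjects if summed.
    """
    tiers = frozenset(Tier(t) for t in tiers)
    counts: Counter = Counter()
    for t in triaged:
        if t.tier in tiers:
            counts.update(t.carriers)
    multi = sorted(s for s, c in counts.items() if c > 1)
    if multi:
        log.warning(
            "%d subject(s) carry more than one qualifying variant: %s",
            len(multi),
            ", ".join(multi[:10]),
        )
    return frozenset(counts)


@dataclass
class PrevalenceSummary:
    """Carrier unions per tier group and prevalence among diabetes cases."""

    n_diabetes: int
    carriers_known: frozenset[str]
    carriers_novel: frozenset[str]
    carriers_all: frozenset[str]
    prevalence_known_pct: float
    prevalence_novel_pct: float
    prevalence_overall_pct: float
    gene_proportions: dict[str, float]
    numerator_mode: str = "all_carriers"

    def formatted(self) -> dict[str, str]:
        """Percent strings in the publication's style (1-2 decimals)."""
        return {
            "prevalence_known_pct": f"{self.prevalence_known_pct:.1f}",
            "prevalence_novel_pct": f"{self.prevalence_novel_pct:.2f}",
            "prevalence_overall_pct": f"{self.prevalence_overall_pct:.1f}",
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("carriers_known", "carriers_novel", "carriers_all"):
            d[k] = sorted(d[k])
        d["n_carriers_known"] = len(self.carriers_known)
        d["n_carriers_novel"] = len(self.carriers_novel)
        d["n_carriers_all"] = len(self.carriers_all)
        d["formatted"] = self.formatted()
        return d


def prevalence(
    triaged: list[TriagedVariant],
    statuses: Mapping[str, DiabetesStatus],
    diabetic_carriers_only: bool = False,
) -> PrevalenceSummary:
    """Prevalence of screened monogenic-diabetes mutations among diabetes cases.

    ``diabetic_carriers_only`` restricts the numerator to carriers whose own
    status is T1DM/T2DM (off by default; the default reproduces the
    all-carriers convention).
    """
    n_diabetes = sum(
        1
        for s in statuses.values()
        if DiabetesStatus(s) in (DiabetesStatus.T1DM, DiabetesStatus.T2DM)
    )
    if n_diabetes == 0:
        raise ValueError("prevalence undefined: no diabetes cases in cohort")

    def _union(tiers):
        u = carrier_union(triaged, tiers)
        if diabetic_carriers_only:
            u = frozenset(
                s
                for s in u
                if DiabetesStatus(statuses[s])
                in (DiabetesStatus.T1DM, DiabetesStatus.T2DM)
            )
        return u

    known = _union(KNOWN_TIERS)
    novel = _union(NOVEL_TIERS)
    allc = _union(ALL_TIERS)
    props = gene_proportions(triaged, ALL_TIERS) if allc else {}
    return PrevalenceSummary(
        n_diabetes=n_diabetes,
        carriers_known=known,
        carriers_novel=novel,
        carriers_all=allc,
        prevalence_known_pct=100.0 * len(known) / n_diabetes,
        prevalence_novel_pct=100.0 * len(novel) / n_diabetes,
        prevalence_overall_pct=100.0 * len(allc) / n_diabetes,
        gene_proportions=props,
        numerator_mode="diabetic_carriers_only" if diabetic_carriers_only else "all_carriers",
    )


def gene_proportions(
    triaged: list[TriagedVariant], tiers: Iterable[Tier]
) -> dict[str, float]:
    """Percent of the carrier union attributable to each gene.

    A subject carrying variants in several genes counts toward each gene, so
    proportions can exceed 100 in total on pathological inputs; on cohorts
    with disjoint carriers they sum to 100. Genes without carriers are omitted.
    """
    tiers = frozenset(Tier(t) for t in tiers)
    union = carrier_union(triaged, tiers)
    if not union:
        raise ValueError("gene proportions undefined on an empty carrier union")
    per_gene: dict[str, set] = {}
    for t in triaged:
        if t.tier in tiers:
            per_gene.setdefault(t.variant.gene, set()).update(t.carriers)
    return {
        gene: 100.0 * len(carriers) / len(union)
        for gene, carriers in sorted(per_gene.items())
    }


def render_report(
    triaged: list[TriagedVariant],
    statuses: Mapping[str, DiabetesStatus],
    outdir: str | Path,
    manifest: dict | None = None,
    make_charts: bool = False,
) -> dict[str, Path]:
    """Write the report bundle: tier tables, prevalence JSON, proportion data,
    run manifest, and (optionally) donut charts of the gene proportions.

    Output is deterministic for identical inputs; no timestamps are embedded.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {outdir}: {exc}") from exc

    paths = dict(write_tier_tables(triaged, outdir))

    summary = prevalence(triaged, statuses)
    prev_path = outdir / "prevalence.json"
    prev_path.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
    paths["prevalence"] = prev_path

    chart_groups = {
        "tier_a": (Tier.A,),
        "tier_b": (Tier.B,),
        "tier_c": (Tier.C,),
        "all_tiers": tuple(ALL_TIERS),
    }
    proportions = {}
    for name, tiers in chart_groups.items():
        if carrier_union(triaged, tiers):
            proportions[name] = {
                "n_subjects": len(carrier_union(triaged, tiers)),
                "gene_pct": {
                    g: round(p, 1) for g, p in gene_proportions(triaged, tiers).items()
                },
            }
    prop_path = outdir / "gene_proportions.json"
    prop_path.write_text(json.dumps(proportions, indent=2, sort_keys=True) + "\n")
    paths["gene_proportions"] = prop_path

    if make_charts and proportions:
        paths.update(_donut_charts(proportions, outdir))

    from . import __version__

    man = {"modyscreen_version": __version__, "n_variants_triaged": len(triaged)}
    man.update(manifest or {})
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(man, indent=2, sort_keys=True, default=str) + "\n")
    paths["manifest"] = man_path
    return paths


@dataclass
class ScreenResult:
    """Everything the full screen produces, for reporting or inspection."""

    subjects: list
    statuses: dict[str, DiabetesStatus]
    variants_extracted: list
    variants_filtered: list
    triaged: list[TriagedVariant]
    summary: PrevalenceSummary


def run_screen(
    vcf: str | Path,
    phenotypes: str | Path,
    panel_bed: str | Path,
    annotations: str | Path,
    maf_max: float | None = None,
    min_mean_depth: float | None = None,
    cadd_min: float | None = None,
) -> ScreenResult:
    """End-to-end screen: classify, extract, filter, annotate, triage, aggregate."""
    from .annotate import annotate_variants, load_annotation_catalogue
    from .phenotype import classify_cohort, read_phenotypes
    from .triage import CADD_MIN, run_triage
    from .variants import (
        DEFAULT_MAF_MAX,
        DEFAULT_MIN_MEAN_DEPTH,
        extract_panel_variants,
        filter_variants,
        load_gene_regions,
    )

    subjects = read_phenotypes(phenotypes)
    statuses = classify_cohort(subjects)
    regions = load_gene_regions(panel_bed)
    extracted = extract_panel_variants(vcf, regions)
    filtered = filter_variants(
        extracted,
        maf_max=DEFAULT_MAF_MAX if maf_max is None else maf_max,
        min_mean_depth=(
            DEFAULT_MIN_MEAN_DEPTH if min_mean_depth is None else min_mean_depth
        ),
    )
    catalogue = load_annotation_catalogue(annotations)
    annotated = annotate_variants(filtered, catalogue)
    triaged = run_triage(
        annotated, statuses, cadd_min=CADD_MIN if cadd_min is None else cadd_min
    )
    summary = prevalence(triaged, statuses)
    return ScreenResult(
        subjects=subjects,
        statuses=statuses,
        variants_extracted=extracted,
        variants_filtered=filtered,
        triaged=triaged,
        summary=summary,
    )


def _donut_charts(proportions: dict, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = {}
    for name, data in proportions.items():
        genes = list(data["gene_pct"])
        vals = [data["gene_pct"][g] for g in genes]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.pie(
            vals,
            labels=[f"{g} ({v}%)" for g, v in zip(genes, vals)],
            wedgeprops=dict(width=0.4),
            startangle=90,
        )
        ax.set_title(f"Carriers by gene — {name} (n={data['n_subjects']})")
        path = outdir / f"proportions_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        out[f"chart_{name}"] = path
    return out
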
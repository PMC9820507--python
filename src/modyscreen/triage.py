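"""Penetrance computation and three-tier pathogenicity triage.

Penetrance of a variant is the fraction of its carriers who express diabetes
(T1DM or T2DM under the rule-based classifier), as a percent of all carriers
regardless of zygosity.

Tiers, in strict precedence order:

* Tier A — known pathogenic: HGMD DM or DM?, and pathogenic/likely
  pathogenic in the clinical-interpretation engine and/or ClinVar. No CADD
  requirement.
* Tier B — known but uncertain: HGMD DM or DM? (not meeting Tier A's P/LP
  condition) with CADD Phred > 20 (top 1% most deleterious).
* Tier C — potentially novel: no MODY HGMD record, ClinVar not P/LP, CADD
  Phred > 20, and complete (100%) disease penetrance.

Everything else is untier-ed (NONE).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotate import AnnotatedVariant, AnnotationRecord, HgmdClass, PathClass
from .phenotype import DiabetesStatus
from .variants import PANEL_SUBTYPES

log = logging.getLogger(__name__)

__all__ = [
    "Tier",
    "TriagedVariant",
    "compute_penetrance",
    "assign_tier",
    "run_triage",
    "write_tier_tables",
    "CADD_MIN",
]

# CADD Phred strictly above this marks the top 1% most deleterious variants.
CADD_MIN = 20.0

_PLP = frozenset({PathClass.P, PathClass.LP})
_DM_ANY = frozenset({HgmdClass.DM, HgmdClass.DM_Q})


class Tier(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    NONE = "NONE"


@dataclass(frozen=True)
class TriagedVariant:
    """Annotated variant with its penetrance and assigned tier."""

    annotated: AnnotatedVariant
    n_carriers: int
    n_diabetic_carriers: int
    penetrance_pct: float
    diagnosis_breakdown: tuple[tuple[str, int], ...]  # sorted (status, count)
    tier: Tier

    @property
    def variant(self):
        return self.annotated.variant

    @property
    def annotation(self) -> AnnotationRecord:
        return self.annotated.annotation

    @property
    def carriers(self) -> frozenset[str]:
        return self.annotated.variant.carriers


def compute_penetrance(
    carriers: Iterable[str], statuses: Mapping[str, DiabetesStatus]
) -> tuple[int, float, Counter]:
    """(n_diabetic, penetrance %, diagnosis breakdown) over a carrier set.

    A carrier counts as diabetic with status T1DM or T2DM. Raises on an
    empty carrier set or a carrier without a status.
    """
    carriers = sorted(set(carriers))
    if not carriers:
        raise ValueError("penetrance undefined for an empty carrier set")
    breakdown: Counter = Counter()
    for subj in carriers:
        status = statuses.get(subj)
        if status is None:
            raise KeyError(f"carrier {subj!r} has no diabetes status")
        breakdown[DiabetesStatus(status).value] += 1
    n_diabetic = breakdown[DiabetesStatus.T1DM.value] + breakdown[
        DiabetesStatus.T2DM.value
    ]
    return n_diabetic, 100.0 * n_diabetic / len(carriers), breakdown


def _cadd_above(annotation: AnnotationRecord, cadd_min: float) -> bool:
    return annotation.cadd_phred is not None and annotation.cadd_phred > cadd_min


def assign_tier(
    annotation: AnnotationRecord,
    n_carriers: int,
    n_diabetic_carriers: int,
    cadd_min: float = CADD_MIN,
    tier_b_accept_dm_q: bool = True,
) -> Tier:
    """Assign a tier from evidence and penetrance; precedence A > B > C.

    Complete penetrance for Tier C is evaluated on exact carrier counts
    (n_diabetic == n_carriers), not on a rounded percentage.
    """
    hgmd_known = annotation.hgmd in _DM_ANY
    tier_b_hgmd = (
        annotation.hgmd in _DM_ANY
        if tier_b_accept_dm_q
        else annotation.hgmd is HgmdClass.DM
    )
    if hgmd_known and (annotation.qci in _PLP or annotation.clinvar in _PLP):
        return Tier.A
    if tier_b_hgmd and _cadd_above(annotation, cadd_min):
        return Tier.B
    if (
        annotation.hgmd is HgmdClass.ABSENT
        and annotation.clinvar not in _PLP
        and _cadd_above(annotation, cadd_min)
        and n_carriers > 0
        and n_diabetic_carriers == n_carriers
    ):
        return Tier.C
    return Tier.NONE


def _subtype_sort_key(gene: str):
    sub = PANEL_SUBTYPES.get(gene, "candidate")
    return (sub, "") if isinstance(sub, int) else (99, gene)


def run_triage(
    annotated: list[AnnotatedVariant],
    statuses: Mapping[str, DiabetesStatus],
    cadd_min: float = CADD_MIN,
    tier_b_accept_dm_q: bool = True,
) -> list[TriagedVariant]:
    """Triage every annotated variant; output sorted by (subtype, gene, pos)."""
    out = []
    for av in annotated:
        v = av.variant
        n_diab, pct, breakdown = compute_penetrance(v.carriers, statuses)
        tier = assign_tier(
            av.annotation,
            n_carriers=v.n_carriers,
            n_diabetic_carriers=n_diab,
            cadd_min=cadd_min,
            tier_b_accept_dm_q=tier_b_accept_dm_q,
        )
        out.append(
            TriagedVariant(
                annotated=av,
                n_carriers=v.n_carriers,
                n_diabetic_carriers=n_diab,
                penetrance_pct=pct,
                diagnosis_breakdown=tuple(sorted(breakdown.items())),
                tier=tier,
            )
        )
    out.sort(
        key=lambda t: (
            _subtype_sort_key(t.variant.gene),
            t.variant.gene,
            t.variant.pos,
        )
    )
    return out


_STATUS_SHORT = {"NON_DIABETES": "N.D", "T1DM": "T1DM", "T2DM": "T2DM"}


def _format_breakdown(breakdown: tuple[tuple[str, int], ...]) -> str:
    return ";".join(f"{_STATUS_SHORT[s]}({n})" for s, n in breakdown)


TABLE_COLUMNS = [
    "Gene",
    "MODY",
    "ID",
    "Chr:Pos",
    "Ref/Alt",
    "Protein change",
    "N",
    "MAF",
    "Penetrance (%)",
    "Diagnosis (n)",
    "CADD",
    "HGMD",
    "QCI",
    "ClinVar",
    "SIFT",
    "PolyPhen-2",
    "gnomAD AF",
    "Tier",
]


def triaged_to_frame(triaged: list[TriagedVariant]) -> pd.DataFrame:
    """Tabulate triaged variants with the published table columns."""
    from .annotate import _cadd_to_str, _POLY_OUT, _SIFT_OUT  # reuse formatting
    from .variants import compute_cohort_maf

    rows = []
    for t in triaged:
        v, a = t.variant, t.annotation
        sub = PANEL_SUBTYPES.get(v.gene, "candidate")
        rows.append(
            {
                "Gene": v.gene,
                "MODY": sub,
                "ID": a.dbsnp_id or "-",
                "Chr:Pos": f"{v.chrom}:{v.pos}",
                "Ref/Alt": f"{v.ref}/{v.alt}",
                "Protein change": a.protein_change or "-",
                "N": t.n_carriers,
                "MAF": f"{compute_cohort_maf(v):.6f}",
                "Penetrance (%)": f"{t.penetrance_pct:.1f}".rstrip("0").rstrip("."),
                "Diagnosis (n)": _format_breakdown(t.diagnosis_breakdown),
                "CADD": _cadd_to_str(a),
                "HGMD": a.hgmd.value if a.hgmd is not HgmdClass.ABSENT else "N/A",
                "QCI": a.qci.value if a.qci is not PathClass.ABSENT else "N/A",
                "ClinVar": a.clinvar.value if a.clinvar is not PathClass.ABSENT else "N/A",
                "SIFT": _SIFT_OUT[a.sift],
                "PolyPhen-2": _POLY_OUT[a.polyphen],
                "gnomAD AF": "-" if a.gnomad_af is None else f"{a.gnomad_af:.7f}",
                "Tier": t.tier.value,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_tier_tables(
    triaged: list[TriagedVariant], outdir: str | Path
) -> dict[str, Path]:
    """Write tier_a.tsv / tier_b.tsv / tier_c.tsv mirroring the result tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tier, name in [(Tier.A, "tier_a"), (Tier.B, "tier_b"), (Tier.C, "tier_c")]:
        frame = triaged_to_frame([t for t in triaged if t.tier is tier])
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
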
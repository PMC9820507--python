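"""External-evidence catalogue for panel variants.

Variant pathogenicity evidence (HGMD disease-mutation class, ACMG-style
clinical classifications from a clinical-interpretation engine and ClinVar,
CADD Phred deleteriousness, SIFT/PolyPhen-2 functional predictions, gnomAD
allele frequency) is consumed as a static tab-separated catalogue and joined
exactly on the normalized (chrom, pos, ref, alt) variant key — dbSNP ids are
display metadata, never join keys, because novel variants lack them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
import logging
import math
from pathlib import Path

import pandas as pd

from .variants import PanelVariant, _norm_chrom, normalize_allele

log = logging.getLogger(__name__)

__all__ = [
    "HgmdClass",
    "PathClass",
    "SiftCall",
    "PolyPhenCall",
    "AnnotationRecord",
    "AnnotatedVariant",
    "load_annotation_catalogue",
    "write_annotation_catalogue",
    "annotate_variants",
    "CADD_BELOW_10_SENTINEL",
    "CATALOGUE_COLUMNS",
]

# CADD values printed as "< 10" are stored as this sentinel: the pipeline only
# ever evaluates the predicate cadd > 20, so any value below 10 is equivalent.
CADD_BELOW_10_SENTINEL = 9.99


class HgmdClass(str, Enum):
    DM = "DM"          # disease-causing mutation
    DM_Q = "DM?"       # likely disease-causing
    ABSENT = "ABSENT"  # no MODY HGMD record


class PathClass(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    ABSENT = "ABSENT"


class SiftCall(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    ABSENT = "ABSENT"


class PolyPhenCall(str, Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class AnnotationRecord:
    """Evidence for one variant; ABSENT/None encode missing evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dbsnp_id: str | None = None
    gene: str | None = None
    protein_change: str | None = None
    hgmd: HgmdClass = HgmdClass.ABSENT
    qci: PathClass = PathClass.ABSENT
    clinvar: PathClass = PathClass.ABSENT
    cadd_phred: float | None = None
    cadd_below_threshold: bool = False
    sift: SiftCall = SiftCall.ABSENT
    polyphen: PolyPhenCall = PolyPhenCall.ABSENT
    gnomad_af: float | None = None

    def __post_init__(self):
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"{self.key}: CADD Phred must be >= 0")
        if self.gnomad_af is not None and not (0 <= self.gnomad_af <= 1):
            raise ValueError(f"{self.key}: gnomAD AF must be in [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (_norm_chrom(self.chrom), self.pos, self.ref, self.alt)

    @classmethod
    def all_absent(cls, chrom: str, pos: int, ref: str, alt: str) -> "AnnotationRecord":
        return cls(chrom=chrom, pos=pos, ref=ref, alt=alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A filtered panel variant paired with its evidence record."""

    variant: PanelVariant
    annotation: AnnotationRecord


CATALOGUE_COLUMNS = [
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "DBSNP",
    "GENE",
    "PROTEIN_CHANGE",
    "HGMD",
    "QCI",
    "CLINVAR",
    "CADD_PHRED",
    "SIFT",
    "POLYPHEN",
    "GNOMAD_AF",
]

_ABSENT_TOKENS = {"", "N/A", "NA", "-", ".", "NONE"}

_HGMD_TOKENS = {"DM": HgmdClass.DM, "DM?": HgmdClass.DM_Q}
_PATH_TOKENS = {c.value: c for c in PathClass if c is not PathClass.ABSENT}
_SIFT_TOKENS = {
    "D": SiftCall.DELETERIOUS,
    "DELETERIOUS": SiftCall.DELETERIOUS,
    "T": SiftCall.TOLERATED,
    "TOLERATED": SiftCall.TOLERATED,
}
_POLYPHEN_TOKENS = {
    "P.D": PolyPhenCall.PROBABLY_DAMAGING,
    "PROBABLY_DAMAGING": PolyPhenCall.PROBABLY_DAMAGING,
    "P.P": PolyPhenCall.POSSIBLY_DAMAGING,
    "POSSIBLY_DAMAGING": PolyPhenCall.POSSIBLY_DAMAGING,
    "BENIGN": PolyPhenCall.BENIGN,
}


def _is_absent_token(tok) -> bool:
    if tok is None or (isinstance(tok, float) and math.isnan(tok)):
        return True
    return str(tok).strip().upper() in _ABSENT_TOKENS


def _parse_enum(tok, table: dict, default, what: str, where: str):
    if _is_absent_token(tok):
        return default
    key = str(tok).strip()
    hit = table.get(key) or table.get(key.upper())
    if hit is None:
        raise ValueError(f"{where}: unknown {what} token {tok!r}")
    return hit


def _parse_cadd(tok, where: str) -> tuple[float | None, bool]:
    if _is_absent_token(tok):
        return None, False
    s = str(tok).strip()
    if s.startswith("<"):
        bound = float(s.lstrip("<").strip())
        if bound <= 10:
            return CADD_BELOW_10_SENTINEL, True
        return bound - 0.01, True
    try:
        return float(s), False
    except ValueError as exc:
        raise ValueError(f"{where}: unparseable CADD value {tok!r}") from exc


def load_annotation_catalogue(
    tsv_path: str | Path,
) -> dict[tuple[str, int, str, str], AnnotationRecord]:
    """Load the catalogue TSV into a map keyed by (chrom, pos, ref, alt).

    'N/A' and '-' are accepted as absent; unknown class tokens and duplicate
    keys raise with the offending row.
    """
    path = Path(tsv_path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalogue columns {sorted(missing)}")
    catalogue: dict[tuple[str, int, str, str], AnnotationRecord] = {}
    for i, rec in enumerate(df.to_dict("records")):
        where = f"{path} row {i + 2}"
        pos, ref, alt = normalize_allele(
            int(rec["POS"]), str(rec["REF"]).strip(), str(rec["ALT"]).strip()
        )
        cadd, below = _parse_cadd(rec["CADD_PHRED"], where)
        record = AnnotationRecord(
            chrom=_norm_chrom(str(rec["CHROM"]).strip()),
            pos=pos,
            ref=ref,
            alt=alt,
            dbsnp_id=None if _is_absent_token(rec["DBSNP"]) else str(rec["DBSNP"]).strip(),
            gene=None if _is_absent_token(rec["GENE"]) else str(rec["GENE"]).strip(),
            protein_change=(
                None
                if _is_absent_token(rec["PROTEIN_CHANGE"])
                else str(rec["PROTEIN_CHANGE"]).strip()
            ),
            hgmd=_parse_enum(rec["HGMD"], _HGMD_TOKENS, HgmdClass.ABSENT, "HGMD", where),
            qci=_parse_enum(rec["QCI"], _PATH_TOKENS, PathClass.ABSENT, "QCI", where),
            clinvar=_parse_enum(
                rec["CLINVAR"], _PATH_TOKENS, PathClass.ABSENT, "ClinVar", where
            ),
            cadd_phred=cadd,
            cadd_below_threshold=below,
            sift=_parse_enum(rec["SIFT"], _SIFT_TOKENS, SiftCall.ABSENT, "SIFT", where),
            polyphen=_parse_enum(
                rec["POLYPHEN"], _POLYPHEN_TOKENS, PolyPhenCall.ABSENT, "PolyPhen", where
            ),
            gnomad_af=(
                None
                if _is_absent_token(rec["GNOMAD_AF"])
                else float(rec["GNOMAD_AF"])
            ),
        )
        if record.key in catalogue:
            raise ValueError(f"{where}: duplicate variant key {record.key}")
        catalogue[record.key] = record
    return catalogue


def _cadd_to_str(rec: AnnotationRecord) -> str:
    if rec.cadd_phred is None:
        return "N/A"
    if rec.cadd_below_threshold and rec.cadd_phred == CADD_BELOW_10_SENTINEL:
        return "<10"
    return f"{rec.cadd_phred:g}"


_SIFT_OUT = {SiftCall.DELETERIOUS: "D", SiftCall.TOLERATED: "T", SiftCall.ABSENT: "N/A"}
_POLY_OUT = {
    PolyPhenCall.PROBABLY_DAMAGING: "P.D",
    PolyPhenCall.POSSIBLY_DAMAGING: "P.P",
    PolyPhenCall.BENIGN: "Benign",
    PolyPhenCall.ABSENT: "N/A",
}


def write_annotation_catalogue(
    records, tsv_path: str | Path
) -> None:
    """Write records (iterable or keyed map) back to the catalogue TSV format."""
    if isinstance(records, dict):
        records = records.values()
    rows = []
    for r in records:
        rows.append(
            {
                "CHROM": r.chrom,
                "POS": r.pos,
                "REF": r.ref,
                "ALT": r.alt,
                "DBSNP": r.dbsnp_id or "N/A",
                "GENE": r.gene or "N/A",
                "PROTEIN_CHANGE": r.protein_change or "N/A",
                "HGMD": r.hgmd.value if r.hgmd is not HgmdClass.ABSENT else "N/A",
                "QCI": r.qci.value if r.qci is not PathClass.ABSENT else "N/A",
                "CLINVAR": r.clinvar.value if r.clinvar is not PathClass.ABSENT else "N/A",
                "CADD_PHRED": _cadd_to_str(r),
                "SIFT": _SIFT_OUT[r.sift],
                "POLYPHEN": _POLY_OUT[r.polyphen],
                "GNOMAD_AF": "N/A" if r.gnomad_af is None else f"{r.gnomad_af:.7f}",
            }
        )
    pd.DataFrame(rows, columns=CATALOGUE_COLUMNS).to_csv(tsv_path, sep="\t", index=False)


def annotate_variants(
    variants: list[PanelVariant],
    catalogue: dict[tuple[str, int, str, str], AnnotationRecord],
) -> list[AnnotatedVariant]:
    """Left-join evidence onto variants by exact normalized key.

    A variant without a catalogue row gets an all-ABSENT record (and is
    logged: without a CADD score it can never reach the score-based tiers).
    """
    out = []
    for v in variants:
        rec = catalogue.get(v.key)
        if rec is None:
            log.info("no annotation for %s; using all-absent record", v.key)
            rec = AnnotationRecord.all_absent(v.chrom, v.pos, v.ref, v.alt)
        out.append(AnnotatedVariant(variant=v, annotation=rec))
    return out
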
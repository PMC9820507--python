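"""Synthetic biobank cohorts and the deterministic table-replay fixture.

Two generators live here:

* :func:`simulate_cohort` — a stochastic cohort generator. Diabetes class
  labels are drawn first at configurable fractions; biomarkers are then
  sampled from truncated normals strictly inside each class's defining
  region, so the rule-based classifier recovers the planted labels exactly.
  Panel variants are planted in distinct subjects with a deterministic
  number of diabetic carriers, round(target_penetrance * n_carriers) —
  penetrance is realized by construction, not sampled.

* :func:`build_replay_fixture` — a deterministic pseudo-cohort of 14,364
  subjects reconstructed from the study's published variant tables. Running
  the full pipeline on it reproduces every printed carrier count, cohort
  MAF, penetrance, tier and diagnosis breakdown, which is the package's
  main validation surface since the underlying biobank data are
  access-restricted.

Outputs are plain text: phenotype CSV, VCF 4.2 (GT:DP per genotype, INFO/DP
per site), annotation catalogue TSV and the panel BED. Identical config and
seed give byte-identical files.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib.resources import files as resource_files
from pathlib import Path


import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .annotate import (
    AnnotationRecord,
    HgmdClass,
    PathClass,
    PolyPhenCall,
    SiftCall,
    write_annotation_catalogue,
    _parse_cadd,
    _parse_enum,
    _is_absent_token,
    _HGMD_TOKENS,
    _PATH_TOKENS,
    _SIFT_TOKENS,
    _POLYPHEN_TOKENS,
)
from .phenotype import DiabetesStatus, SubjectPhenotype, write_phenotypes
from .variants import GeneRegion, load_gene_regions, normalize_allele

__all__ = [
    "CohortConfig",
    "PlantedVariant",
    "SimulatedCohort",
    "simulate_cohort",
    "ReplayFixture",
    "build_replay_fixture",
    "packaged_fixture_path",
    "load_replay_tables",
    "default_annotation",
]

# Study-cohort composition: 72 T1DM + 2915 T2DM + 11,377 non-diabetes.
STUDY_N_SUBJECTS = 14364
STUDY_CLASS_COUNTS = {"T1DM": 72, "T2DM": 2915, "NON_DIABETES": 11377}
STUDY_DIABETES_FRACTION = (72 + 2915) / 14364
STUDY_T1DM_FRACTION_OF_DIABETES = 72 / (72 + 2915)

# Per-class biomarker location/scale, (mean, sd), from the study's baseline
# characteristics: HbA1c %, C-peptide ng/mL, BMI kg/m^2, age years.
DEFAULT_BIOMARKER_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "T1DM": {"hba1c": (8.8, 1.5), "c_peptide": (0.32, 0.14), "bmi": (28.6, 5.1), "age": (38.4, 14.7)},
    "T2DM": {"hba1c": (7.4, 1.8), "c_peptide": (2.83, 1.67), "bmi": (32.3, 6.0), "age": (51.8, 11.8)},
    "NON_DIABETES": {"hba1c": (5.3, 0.4), "c_peptide": (2.02, 1.4), "bmi": (28.9, 6.0), "age": (35.1, 11.7)},
}

# Self-report rates used by the generator (fractions of each class).
FEMALE_FRACTION = 0.558
ONSET_DECLARED_FRACTION = 0.63
T2DM_TABLET_FRACTION = 0.69
T2DM_INSULIN_FRACTION = 0.221
FAMILY_HISTORY_RATES = {  # (father, mother) per class
    "T1DM": (0.458, 0.458),
    "T2DM": (0.465, 0.621),
    "NON_DIABETES": (0.421, 0.449),
}

SIMULATED_DEPTH = 32  # per-genotype sequencing depth written to FORMAT/DP


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def packaged_fixture_path(name: str) -> Path:
    """Path to a packaged fixture file (tables, panel BED)."""
    return Path(str(resource_files("modyscreen") / "fixtures" / name))


@dataclass
class CohortConfig:
    """Simulation parameters; defaults mirror the study cohort's composition."""

    n_subjects: int = STUDY_N_SUBJECTS
    diabetes_fraction: float = STUDY_DIABETES_FRACTION
    t1dm_fraction_of_diabetes: float = STUDY_T1DM_FRACTION_OF_DIABETES
    biomarker_params: dict = field(
        default_factory=lambda: {
            c: dict(v) for c, v in DEFAULT_BIOMARKER_PARAMS.items()
        }
    )
    seed: int = 0
    n_background_common: int = 0  # common (MAF >= 0.001) in-panel variants
    overlap_carriers: bool = False  # plant all variants over a shared pool

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("diabetes_fraction", "t1dm_fraction_of_diabetes"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PlantedVariant:
    """A panel variant to plant at a fixed penetrance.

    The number of diabetic carriers written is exactly
    round(target_penetrance * n_carriers); diabetic carriers are realized as
    T2DM (the common presentation of screened monogenic diabetes carriers).
    """

    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    n_carriers: int
    target_penetrance: float
    annotation: AnnotationRecord | None = None
    zygosity: str = "het"  # "het" | "hom"

    def __post_init__(self):
        if self.n_carriers < 1:
            raise ValueError(f"{self.gene}:{self.pos}: n_carriers must be >= 1")
        if not (0 <= self.target_penetrance <= 1):
            raise ValueError(
                f"{self.gene}:{self.pos}: target_penetrance must be in [0, 1]"
            )
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be 'het' or 'hom'")

    @property
    def key(self) -> tuple[str, int, str, str]:
        pos, ref, alt = normalize_allele(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)

    @property
    def n_diabetic_carriers(self) -> int:
        return _round_half_up(self.target_penetrance * self.n_carriers)


def default_annotation(pv: PlantedVariant) -> AnnotationRecord:
    """Fallback evidence for a planted variant with no explicit record.

    Deleterious-looking but database-absent (CADD 25, no HGMD/ClinVar
    class): a fully penetrant variant so annotated lands in the novel tier.
    """
    pos, ref, alt = normalize_allele(pv.pos, pv.ref, pv.alt)
    return AnnotationRecord(
        chrom=pv.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=pv.gene,
        cadd_phred=25.0,
        sift=SiftCall.DELETERIOUS,
        polyphen=PolyPhenCall.PROBABLY_DAMAGING,
    )


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort plus its variant plantings."""

    config: CohortConfig
    subjects: list[SubjectPhenotype]
    statuses: dict[str, DiabetesStatus]
    # (chrom, pos, ref, alt, het carrier ids, hom carrier ids) per variant
    variant_rows: list[tuple]
    annotations: list[AnnotationRecord]
    panel_bed: Path

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write phenotype CSV, VCF, annotation TSV and panel BED; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotypes": outdir / "phenotypes.csv",
            "vcf": outdir / "cohort.vcf",
            "annotations": outdir / "annotations.tsv",
            "panel_bed": outdir / "panel_grch38.bed",
        }
        write_phenotypes(self.subjects, paths["phenotypes"])
        _write_vcf(paths["vcf"], self.subject_ids, self.variant_rows)
        write_annotation_catalogue(self.annotations, paths["annotations"])
        paths["panel_bed"].write_text(Path(self.panel_bed).read_text())
        return paths


def _subject_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _check_planted(
    planted: list[PlantedVariant], regions: list[GeneRegion], n_subjects: int
) -> None:
    by_gene = {r.gene: r for r in regions}
    seen: set[tuple] = set()
    for pv in planted:
        if pv.n_carriers > n_subjects:
            raise ValueError(
                f"{pv.gene}:{pv.pos}: n_carriers {pv.n_carriers} exceeds "
                f"cohort size {n_subjects}"
            )
        region = by_gene.get(pv.gene)
        if region is None:
            raise ValueError(f"{pv.gene}: not a panel gene")
        if not region.contains(pv.chrom, pv.pos):
            raise ValueError(
                f"{pv.gene}:{pv.chrom}:{pv.pos}: position outside the gene's "
                f"panel region {region.chrom}:{region.start}-{region.end}"
            )
        if pv.key in seen:
            raise ValueError(f"duplicate planted position {pv.key}")
        seen.add(pv.key)


def simulate_cohort(
    config: CohortConfig,
    planted: list[PlantedVariant] | None = None,
    panel_bed: str | Path | None = None,
) -> SimulatedCohort:
    """Generate a cohort with planted panel variants at fixed penetrance.

    Carriers of distinct planted variants are distinct subjects unless
    ``config.overlap_carriers`` is set, in which case every variant draws
    its carriers from the start of the subject list (maximal overlap, for
    exercising union logic). Background common variants, if requested, are
    planted inside panel regions at cohort MAF >= 0.001 so the rare-variant
    filter has something to drop.
    """
    planted = list(planted or [])
    bed = Path(panel_bed) if panel_bed else packaged_fixture_path("panel_grch38.bed")
    regions = load_gene_regions(bed)
    _check_planted(planted, regions, config.n_subjects)

    n = config.n_subjects
    ids = _subject_ids(n)
    rng = np.random.default_rng(config.seed)

    # --- carrier allocation (deterministic) ---
    statuses: dict[str, DiabetesStatus] = {}
    variant_rows: list[tuple] = []
    annotations: list[AnnotationRecord] = []
    cursor = 0
    for pv in planted:
        start = 0 if config.overlap_carriers else cursor
        if start + pv.n_carriers > n:
            raise ValueError(
                f"{pv.gene}:{pv.pos}: not enough unallocated subjects for "
                f"{pv.n_carriers} distinct carriers"
            )
        carriers = ids[start : start + pv.n_carriers]
        if not config.overlap_carriers:
            cursor += pv.n_carriers
        n_diab = pv.n_diabetic_carriers
        for i, subj in enumerate(carriers):
            want = DiabetesStatus.T2DM if i < n_diab else DiabetesStatus.NON_DIABETES
            prev = statuses.get(subj)
            if prev is not None and prev != want:
                raise ValueError(
                    f"{pv.gene}:{pv.pos}: carrier {subj} already planted with "
                    f"status {prev.value}; incompatible overlap"
                )
            statuses[subj] = want
        het = carriers if pv.zygosity == "het" else []
        hom = carriers if pv.zygosity == "hom" else []
        pos, ref, alt = normalize_allele(pv.pos, pv.ref, pv.alt)
        variant_rows.append((pv.chrom, pos, ref, alt, list(het), list(hom)))
        annotations.append(pv.annotation or default_annotation(pv))

    # --- fill remaining class quotas ---
    n_diab_total = _round_half_up(n * config.diabetes_fraction)
    n_t1 = _round_half_up(n_diab_total * config.t1dm_fraction_of_diabetes)
    n_t2 = n_diab_total - n_t1
    planted_counts = Counter(s.value for s in statuses.values())
    remaining = [i for i in ids if i not in statuses]
    need_t1 = max(0, n_t1 - planted_counts["T1DM"])
    need_t2 = max(0, n_t2 - planted_counts["T2DM"])
    for idx, subj in enumerate(remaining):
        if idx < need_t1:
            statuses[subj] = DiabetesStatus.T1DM
        elif idx < need_t1 + need_t2:
            statuses[subj] = DiabetesStatus.T2DM
        else:
            statuses[subj] = DiabetesStatus.NON_DIABETES

    # --- background common variants ---
    m = max(1, math.ceil(0.0025 * n))  # cohort MAF m/(2n) >= 0.00125
    taken = {(row[0], row[1]) for row in variant_rows}
    for b in range(config.n_background_common):
        region = regions[b % len(regions)]
        pos = region.start + 20 + 3 * b
        while (region.chrom, pos) in taken or pos > region.end:
            pos += 1
        taken.add((region.chrom, pos))
        carriers = rng.choice(ids, size=min(m, n), replace=False).tolist()
        variant_rows.append((region.chrom, pos, "G", "A", sorted(carriers), []))

    # --- biomarkers, sampled per class strictly inside class regions ---
    subjects = _sample_phenotypes(ids, statuses, config, rng)
    return SimulatedCohort(
        config=config,
        subjects=subjects,
        statuses=statuses,
        variant_rows=variant_rows,
        annotations=annotations,
        panel_bed=bed,
    )


def _sample_phenotypes(ids, statuses, config: CohortConfig, rng) -> list[SubjectPhenotype]:
    n = len(ids)
    order = {"T1DM": [], "T2DM": [], "NON_DIABETES": []}
    for i, subj in enumerate(ids):
        order[statuses[subj].value].append(i)

    age = np.empty(n)
    bmi = np.empty(n)
    hba1c = np.empty(n)
    cpep = np.empty(n)
    for cls, idx in order.items():
        if not idx:
            continue
        p = config.biomarker_params[cls]
        k = len(idx)
        age[idx] = _truncated_normal(rng, *p["age"], 18.0, 89.0, k)
        bmi[idx] = _truncated_normal(rng, *p["bmi"], 12.0, 70.0, k)
        if cls == "NON_DIABETES":
            # HbA1c capped at the diagnostic threshold so the classifier
            # can never promote a planted non-diabetic to T2DM.
            hba1c[idx] = _truncated_normal(rng, *p["hba1c"], 3.5, 6.5, k)
            cpep[idx] = _truncated_normal(rng, *p["c_peptide"], 0.0, 12.0, k)
        elif cls == "T2DM":
            # C-peptide floored at the T1DM cut so insulin-treated T2DM
            # subjects are never re-classified as T1DM.
            hba1c[idx] = _truncated_normal(rng, *p["hba1c"], 4.0, 16.0, k)
            cpep[idx] = _truncated_normal(rng, *p["c_peptide"], 0.5, 12.0, k)
        else:  # T1DM
            hba1c[idx] = _truncated_normal(rng, *p["hba1c"], 4.0, 16.0, k)
            cpep[idx] = _truncated_normal(rng, *p["c_peptide"], 0.0, 0.499, k)

    female = rng.random(n) < FEMALE_FRACTION
    fam_father = np.zeros(n, dtype=bool)
    fam_mother = np.zeros(n, dtype=bool)
    for cls, idx in order.items():
        if not idx:
            continue
        pf, pm = FAMILY_HISTORY_RATES[cls]
        fam_father[idx] = rng.random(len(idx)) < pf
        fam_mother[idx] = rng.random(len(idx)) < pm
    tablets = rng.random(n) < T2DM_TABLET_FRACTION
    insulin = rng.random(n) < T2DM_INSULIN_FRACTION
    onset_declared = rng.random(n) < ONSET_DECLARED_FRACTION
    onset_value = rng.uniform(10.0, 60.0, size=n)

    subjects = []
    for i, subj in enumerate(ids):
        cls = statuses[subj].value
        if cls == "T1DM":
            self_decl, on_ins, on_tab = True, True, False
        elif cls == "T2DM":
            # Self-declared always true: T2DM membership must not hinge on
            # the sampled medication flags.
            self_decl, on_ins, on_tab = True, bool(insulin[i]), bool(tablets[i])
        else:
            self_decl, on_ins, on_tab = False, False, False
        onset = None
        if cls != "NON_DIABETES" and onset_declared[i]:
            onset = round(float(min(onset_value[i], age[i])), 1)
        subjects.append(
            SubjectPhenotype(
                subject_id=subj,
                age=round(float(age[i]), 1),
                sex="female" if female[i] else "male",
                bmi=round(float(bmi[i]), 1),
                hba1c=round(float(hba1c[i]), 2),
                c_peptide=round(float(cpep[i]), 3),
                self_declared_diabetes=self_decl,
                on_insulin=on_ins,
                on_tablets=on_tab,
                age_of_onset=onset,
                family_history_father=bool(fam_father[i]),
                family_history_mother=bool(fam_mother[i]),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=modyscreen-cohortsim
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Per-sample read depth">
"""


def _chrom_order(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _write_vcf(path: Path, sample_ids: list[str], variant_rows: list[tuple]) -> None:
    index = {s: i for i, s in enumerate(sample_ids)}
    chroms = sorted({row[0] for row in variant_rows}, key=_chrom_order)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        dp = SIMULATED_DEPTH
        for chrom, pos, ref, alt, het, hom in sorted(
            variant_rows, key=lambda r: (_chrom_order(r[0]), r[1], r[2], r[3])
        ):
            gts = [f"0/0:{dp}"] * len(sample_ids)
            for s in het:
                gts[index[s]] = f"0/1:{dp}"
            for s in hom:
                gts[index[s]] = f"1/1:{dp}"
            info_dp = dp * len(sample_ids)
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={info_dp}\tGT:DP\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Replay fixture: reconstruct the published tables as a pseudo-cohort
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "table2": "table2_known_pathogenic.tsv",
    "table3": "table3_known_vus.tsv",
    "table4": "table4_novel.tsv",
}

_REQUIRED_TABLE_COLS = {
    "GENE", "MODY", "CHROM", "POS", "REF", "ALT", "PROTEIN_CHANGE",
    "N", "MAF", "PENETRANCE", "DIAGNOSIS",
}


def _parse_diagnosis(token: str, where: str) -> Counter:
    """Parse 'ND:4;T2DM:1' into a status Counter."""
    mapping = {"ND": "NON_DIABETES", "N.D": "NON_DIABETES", "T1DM": "T1DM", "T2DM": "T2DM"}
    out: Counter = Counter()
    for part in str(token).split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            cls, count = part.split(":")
            out[mapping[cls.strip()]] += int(count)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{where}: bad DIAGNOSIS token {token!r}") from exc
    return out


def load_replay_tables() -> dict[str, pd.DataFrame]:
    """Load and validate the packaged published-table fixtures.

    Adds parsed helper columns: DIAGNOSIS_COUNTS (Counter) and the expected
    tier per table. Raises naming the offending row on schema violations.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, fname in _TABLE_FILES.items():
        path = packaged_fixture_path(fname)
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        missing = _REQUIRED_TABLE_COLS - set(df.columns)
        if missing:
            raise ValueError(f"{fname}: missing columns {sorted(missing)}")
        df["POS"] = df["POS"].astype(int)
        df["N"] = df["N"].astype(int)
        df["MAF"] = df["MAF"].astype(float)
        df["PENETRANCE"] = df["PENETRANCE"].astype(float)
        parsed = []
        for i, rec in enumerate(df.to_dict("records")):
            where = f"{fname} row {i + 2} ({rec['GENE']} {rec.get('DBSNP', '-')})"
            counts = _parse_diagnosis(rec["DIAGNOSIS"], where)
            if sum(counts.values()) != rec["N"]:
                raise ValueError(
                    f"{where}: diagnosis counts {dict(counts)} do not sum to N={rec['N']}"
                )
            n_diab = counts["T1DM"] + counts["T2DM"]
            expect = 100.0 * n_diab / rec["N"]
            if abs(expect - rec["PENETRANCE"]) > 0.11:
                raise ValueError(
                    f"{where}: printed penetrance {rec['PENETRANCE']} "
                    f"inconsistent with diagnosis breakdown ({expect:.2f})"
                )
            parsed.append(counts)
        df["DIAGNOSIS_COUNTS"] = parsed
        df["EXPECTED_TIER"] = {"table2": "A", "table3": "B", "table4": "C"}[name]
        out[name] = df
    counts = pd.read_csv(
        packaged_fixture_path("table1_counts.tsv"), sep="\t", comment="#"
    )
    out["counts"] = counts
    return out


@dataclass
class ReplayFixture:
    """Paths and expectations of the deterministic table-replay cohort."""

    outdir: Path
    paths: dict[str, Path]
    tables: dict[str, pd.DataFrame]
    class_counts: dict[str, int]
    n_subjects: int


# Deterministic biomarker realizations per class: any field combination
# satisfying the classifier rules suffices; these match the class means.
_REPLAY_PROFILES = {
    "T2DM": dict(age=52.0, bmi=32.0, hba1c=8.0, c_peptide=2.8,
                 self_declared_diabetes=True, on_insulin=False, on_tablets=True),
    "T1DM": dict(age=38.0, bmi=28.6, hba1c=8.8, c_peptide=0.3,
                 self_declared_diabetes=True, on_insulin=True, on_tablets=False),
    "NON_DIABETES": dict(age=35.0, bmi=28.9, hba1c=5.2, c_peptide=2.0,
                         self_declared_diabetes=False, on_insulin=False,
                         on_tablets=False),
}


def build_replay_fixture(outdir: str | Path) -> ReplayFixture:
    """Write the replay pseudo-cohort (phenotypes, VCF, catalogue, BED).

    Each published variant row is planted in N fresh subjects whose
    diagnoses match the printed breakdown; the remaining subjects fill the
    published 72 / 2,915 / 11,377 class split. Fully deterministic.
    """
    tables = load_replay_tables()
    counts_df = tables["counts"]
    class_counts = dict(zip(counts_df["CLASS"], counts_df["N"].astype(int)))
    n_subjects = int(sum(class_counts.values()))
    ids = _subject_ids(n_subjects)

    statuses: dict[str, str] = {}
    variant_rows: list[tuple] = []
    annotations: list[AnnotationRecord] = []
    cursor = 0
    seen_pos: set[tuple] = set()
    for name in ("table2", "table3", "table4"):
        for i, rec in enumerate(tables[name].to_dict("records")):
            where = f"{_TABLE_FILES[name]} row {i + 2} ({rec['GENE']})"
            key = (str(rec["CHROM"]), int(rec["POS"]))
            if key in seen_pos:
                raise ValueError(f"{where}: duplicate genomic position {key}")
            seen_pos.add(key)
            carriers = ids[cursor : cursor + rec["N"]]
            cursor += rec["N"]
            # fixed order: T1DM, then T2DM, then non-diabetes
            alloc = (
                ["T1DM"] * rec["DIAGNOSIS_COUNTS"]["T1DM"]
                + ["T2DM"] * rec["DIAGNOSIS_COUNTS"]["T2DM"]
                + ["NON_DIABETES"] * rec["DIAGNOSIS_COUNTS"]["NON_DIABETES"]
            )
            for subj, cls in zip(carriers, alloc):
                statuses[subj] = cls
            variant_rows.append(
                (str(rec["CHROM"]), int(rec["POS"]), rec["REF"], rec["ALT"],
                 list(carriers), [])
            )
            annotations.append(_fixture_annotation(rec, where))

    planted_counts = Counter(statuses.values())
    remaining = ids[cursor:]
    need = {
        cls: class_counts[cls] - planted_counts[cls]
        for cls in ("T1DM", "T2DM", "NON_DIABETES")
    }
    if any(v < 0 for v in need.values()):
        raise ValueError(f"planted carriers exceed published class counts: {need}")
    pos = 0
    for cls in ("T1DM", "T2DM", "NON_DIABETES"):
        for subj in remaining[pos : pos + need[cls]]:
            statuses[subj] = cls
        pos += need[cls]

    subjects = []
    for i, subj in enumerate(ids):
        profile = _REPLAY_PROFILES[statuses[subj]]
        subjects.append(
            SubjectPhenotype(
                subject_id=subj,
                sex="female" if i % 2 == 0 else "male",
                family_history_father=False,
                family_history_mother=False,
                age_of_onset=None,
                **profile,
            )
        )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.csv",
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "panel_bed": outdir / "panel_grch38.bed",
    }
    write_phenotypes(subjects, paths["phenotypes"])
    _write_vcf(paths["vcf"], ids, variant_rows)
    write_annotation_catalogue(annotations, paths["annotations"])
    paths["panel_bed"].write_text(
        packaged_fixture_path("panel_grch38.bed").read_text()
    )
    return ReplayFixture(
        outdir=outdir,
        paths=paths,
        tables=tables,
        class_counts=class_counts,
        n_subjects=n_subjects,
    )


def _fixture_annotation(rec: dict, where: str) -> AnnotationRecord:
    cadd, below = _parse_cadd(rec.get("CADD"), where)
    pos, ref, alt = normalize_allele(int(rec["POS"]), rec["REF"], rec["ALT"])
    return AnnotationRecord(
        chrom=str(rec["CHROM"]),
        pos=pos,
        ref=ref,
        alt=alt,
        dbsnp_id=None if _is_absent_token(rec.get("DBSNP")) else str(rec["DBSNP"]),
        gene=rec["GENE"],
        protein_change=rec["PROTEIN_CHANGE"],
        hgmd=_parse_enum(rec.get("HGMD"), _HGMD_TOKENS, HgmdClass.ABSENT, "HGMD", where),
        qci=_parse_enum(rec.get("QCI"), _PATH_TOKENS, PathClass.ABSENT, "QCI", where),
        clinvar=_parse_enum(
            rec.get("CLINVAR"), _PATH_TOKENS, PathClass.ABSENT, "ClinVar", where
        ),
        cadd_phred=cadd,
        cadd_below_threshold=below,
        sift=_parse_enum(rec.get("SIFT"), _SIFT_TOKENS, SiftCall.ABSENT, "SIFT", where),
        polyphen=_parse_enum(
            rec.get("POLYPHEN"), _POLYPHEN_TOKENS, PolyPhenCall.ABSENT, "PolyPhen", where
        ),
        gnomad_af=(
            None if _is_absent_token(rec.get("GNOMAD_AF")) else float(rec["GNOMAD_AF"])
        ),
    )
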
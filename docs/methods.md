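# Methods

## Scope and model

`modyscreen` screens a biobank-style cohort for monogenic diabetes (MODY)
over a fixed 16-gene panel. The underlying model is deliberately simple and
fully rule-based — there is no statistical inference, only counting under
explicit operational definitions:

* **Phenotype model.** Diabetes status is an operational classification,
  not clinical adjudication. T1DM requires self-declared diabetes, insulin
  treatment *exclusively* (insulin flag set, tablets flag unset) and a
  measured serum C-peptide < 0.5 ng/mL, reflecting absolute insulin
  deficiency. Failing that, T2DM requires any of: self-declared diabetes,
  any diabetes medication, or HbA1c > 6.5 %. All comparisons are strict
  (`< 0.5`, `> 6.5`, onset `< 25`), and a missing biomarker never satisfies
  a criterion, which keeps the classifier a total function. "Exclusively"
  is interpreted against the two recorded drug classes only; the data
  carry no other medication fields.
* **Variant model.** A variant is a normalized bi-allelic alt allele whose
  1-based position lies inside a panel region (BED, 0-based half-open; the
  conversion is centralized in `GeneRegion.contains` and property-tested).
  Cohort MAF is computed from the analyzed cohort itself,
  (n_het + 2·n_hom)/(2·n_called), with missing genotypes removed from the
  denominator (VCF AN semantics); external population frequency (gnomAD)
  is a separate annotation column and plays no role in filtering. The alt
  allele is assumed minor; if its frequency exceeds 0.5 the folded
  frequency is used and a warning logged.
* **Penetrance.** Percent of carriers (het or hom, counted once) whose
  classified status is T1DM or T2DM. Complete penetrance is tested on
  integer counts (`n_diabetic == n_carriers`), never on a rounded float.
* **Triage.** Tier A = HGMD DM/DM? ∧ (QCI ∈ {P, LP} ∨ ClinVar ∈ {P, LP});
  Tier B = HGMD DM/DM? ∧ CADD Phred > 20; Tier C = HGMD absent ∧ ClinVar ∉
  {P, LP} ∧ CADD > 20 ∧ penetrance = 100 %. Precedence A > B > C makes the
  tiers disjoint. "DM?" is a distinct enum value treated like "DM" in both
  A and B (configurable for B via `tier_b_accept_dm_q`). Presence in dbSNP
  or gnomAD does **not** disqualify Tier C: novel here means "not recorded
  as a MODY disease mutation", not "never observed". Tier A has no CADD
  requirement, which is why a known pathogenic variant with CADD < 10
  still tiers as A.
* **Prevalence.** Numerator = distinct carriers of qualifying variants
  (union over variants, so shared carriers count once), including carriers
  who are not themselves diabetic; denominator = diabetes cases
  (T1DM + T2DM). This is the convention used in biobank carrier-screening
  reports; it intentionally counts non-penetrant carriers. A
  `diabetic_carriers_only` mode is provided for the stricter reading, and
  the report records which mode produced its numbers rather than silently
  "correcting" either.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `maf_max` | 0.001 | cohort allele fraction | rare-variant cut; strict `<` |
| `min_mean_depth` | 20 | × coverage | genotype-quality proxy; strict `>` |
| `cadd_min` | 20 | CADD Phred | top 1 % most deleterious; strict `>` |
| T1DM C-peptide cut | 0.5 | ng/mL | insulin-deficiency marker |
| T2DM HbA1c cut | 6.5 | % | diagnostic threshold; strict `>` |
| clinical-screen onset cut | 25 | years | classical MODY criterion |
| BMI bands | 18.5 / 25 / 30 | kg/m² | WHO bands, `[18.5, 25)` normal |

The depth filter is implemented as a per-variant mean over called
genotypes (FORMAT/DP, falling back to site INFO/DP divided by the sample
count); a per-sample reading of the same phrase would be a different
filter, and the choice is documented here because the inputs admit both.

## Synthetic cohorts

`simulate_cohort` emulates the screening setting, not human genetics at
large. Class labels (T1DM / T2DM / non-diabetes) are assigned first at the
study cohort's composition (0.5 % / 20.3 % / 79.2 % by default); biomarkers
are then drawn from truncated normals whose bounds lie strictly inside each
class's defining region (non-diabetic HbA1c capped at 6.5 %, T2DM C-peptide
floored at 0.5 ng/mL, T1DM C-peptide confined to (0, 0.5)). Consequently the
classifier recovers the generated labels exactly — by design, since the
generator's job is to produce cohorts whose ground truth is known. Per-class
biomarker means and spreads are the study cohort's baseline characteristics
(e.g. HbA1c 5.3 ± 0.4 % in non-diabetes, 7.4 ± 1.8 % in T2DM).

Variant planting is deterministic: a planted variant with `n_carriers = n`
and `target_penetrance = p` gets exactly `round(p·n)` diabetic carriers
(realized as T2DM), so realized penetrance equals `round(p·n)/n` on every
seed; the only stochasticity is in the biomarker draws. Carriers of
distinct variants are distinct subjects unless `overlap_carriers` is set.
Background common variants (MAF ≥ 0.001) can be planted inside panel
regions to exercise the rarity filter. All randomness flows from a single
`numpy` Generator seeded by `CohortConfig.seed`; identical config and seed
give byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, genotyping error, depth variation (DP is constant),
age-dependent penetrance, relatedness, and any correlation between
biomarkers beyond their class conditioning. Tests passing on synthetic
cohorts therefore validate the pipeline's arithmetic and plumbing, not its
behavior under real-data artifacts.

## The replay cohort

Because the original biobank genotypes are access-restricted, the package
ships the study's printed variant tables as fixtures and reconstructs a
deterministic pseudo-cohort from them: each of the 50 variants is planted
in N fresh subjects whose diagnoses match the printed breakdown, and the
remaining subjects fill the published 72 / 2,915 / 11,377 class split using
fixed per-class biomarker profiles (any field combination satisfying the
classifier rules suffices; e.g. T2DM as self-declared + tablets +
HbA1c 8.0 %). The two "known" tables print no genomic positions, so the
fixtures carry synthetic placeholder positions inside each gene's region
(marked as such in the files); the "novel" table uses its published GRCh38
coordinates. The panel BED uses canonical GRCh38 gene spans with small
padding and is named by build. Per-genotype depth is a constant 32×, above
the 20× filter.

The replay is a consistency check of the pipeline against the published
aggregates — carrier counts, MAFs (N/(2·14,364) to 6 decimals), penetrance
(within 0.1 percentage point, since the source tables mix rounding and
truncation: 66.6 for 2/3 but 16.67 for 1/6), tier assignments (10 + 12 + 28),
carrier unions (67 / 34 / 101) and prevalences (2.2 % / 1.14 % / 3.4 % of
2,987 diabetes cases). It cannot validate anything the tables do not
constrain (e.g. the 35-subject clinical-criteria count, which depends on
unpublished per-subject onset data; replay subjects carry no onset).

## Numerical and degenerate-input choices

* CADD values printed as "< 10" are stored as a 9.99 sentinel with a
  below-threshold flag; only the predicate `cadd > 20` is ever evaluated,
  so the sentinel's exact value is immaterial. A missing CADD score
  excludes a variant from Tiers B and C (logged), never errors.
* Indel normalization is parsimony trimming (shared suffix, then shared
  prefix); left-alignment requires a reference FASTA, which is not among
  the pipeline's inputs. All study variants are SNVs; indels are handled
  without crashing, which is the requirement.
* Multi-allelic records are split per alt allele; a sample with genotype
  1/2 is a het carrier of both alts. Symbolic (`<...>`) and spanning-
  deletion (`*`) alleles are skipped.
* Variant identity everywhere is the normalized (chrom, pos, ref, alt) —
  dbSNP ids are never join keys (novel variants lack them); `chr` prefixes
  are stripped on both sides of every comparison.
* Empty inputs raise: penetrance of an empty carrier set, gene proportions
  of an empty union, prevalence with zero diabetes cases, summaries of an
  empty cohort. An empty *variant* list is valid and produces empty tier
  tables.
* Deterministic rounding: counts use half-up rounding (`floor(x + 0.5)`),
  avoiding banker's-rounding surprises in carrier allocation.

## Known limitations

* No structural-variant or CNV detection; no genotype likelihoods; the
  pipeline consumes hard GT calls only.
* Evidence classes (HGMD, ACMG-style, ClinVar, CADD, SIFT, PolyPhen-2) are
  consumed as a static catalogue; the package never re-derives them, so
  its triage is only as current as the catalogue it is given.
* The phenotype rules cannot distinguish MODY from clinically similar
  presentations; that is precisely the motivation for the genetic screen,
  and the clinical-criteria screen (`meets_clinical_mody_criteria`) is
  reported for comparison, not used for filtering.
* Penetrance from a single cross-sectional cohort ignores age at
  examination; young carriers who will later develop diabetes deflate it.
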
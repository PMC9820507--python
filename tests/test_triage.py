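"""Penetrance arithmetic and tier assignment, checked against a brute-force
truth-table oracle over the evidence grid."""

from __future__ import annotations

import itertools
import random

import pytest

from modyscreen import (
    AnnotatedVariant,
    AnnotationRecord,
    DiabetesStatus,
    HgmdClass,
    PathClass,
    Tier,
    assign_tier,
    compute_penetrance,
    run_triage,
)
from modyscreen.variants import PanelVariant

T1, T2, ND = DiabetesStatus.T1DM, DiabetesStatus.T2DM, DiabetesStatus.NON_DIABETES


class TestPenetrance:
    @pytest.mark.parametrize(
        "statuses, expected_pct, expected_diab",
        [
            ([T2, T2, ND], 200 / 3, 2),       # printed as 66.6
            ([ND] * 5, 0.0, 0),
            ([T2] * 3 + [ND] * 8, 300 / 11, 3),  # printed as 27.2
            ([T1] + [ND] * 5, 100 / 6, 1),    # printed as 16.67
            ([T2], 100.0, 1),
        ],
    )
    def test_carrier_fractions(self, statuses, expected_pct, expected_diab):
        carriers = [f"s{i}" for i in range(len(statuses))]
        status_map = dict(zip(carriers, statuses))
        n_diab, pct, breakdown = compute_penetrance(carriers, status_map)
        assert n_diab == expected_diab
        assert pct == pytest.approx(expected_pct)
        assert sum(breakdown.values()) == len(carriers)

    def test_empty_carrier_set_rejected(self):
        with pytest.raises(ValueError):
            compute_penetrance([], {})

    def test_unknown_carrier_named(self):
        with pytest.raises(KeyError, match="ghost"):
            compute_penetrance(["ghost"], {"other": T2})

    def test_invariant_under_subject_relabeling(self):
        statuses = [T2, ND, T2, ND, ND]
        a = compute_penetrance(
            [f"a{i}" for i in range(5)],
            {f"a{i}": s for i, s in enumerate(statuses)},
        )
        b = compute_penetrance(
            [f"zz{i}" for i in range(5)],
            {f"zz{i}": s for i, s in enumerate(statuses)},
        )
        assert a[:2] == b[:2]


def ann(hgmd=HgmdClass.ABSENT, qci=PathClass.ABSENT, clinvar=PathClass.ABSENT,
        cadd=None):
    return AnnotationRecord(
        chrom="7", pos=1500, ref="A", alt="G",
        hgmd=hgmd, qci=qci, clinvar=clinvar, cadd_phred=cadd,
    )


class TestAssignTier:
    @pytest.mark.parametrize(
        "kw, n, n_diab, expected",
        [
            # known pathogenic: HGMD DM + ClinVar P, regardless of QCI/CADD
            (dict(hgmd=HgmdClass.DM, qci=PathClass.VUS, clinvar=PathClass.P, cadd=25.0), 1, 0, Tier.A),
            # Tier A has no CADD requirement at all
            (dict(hgmd=HgmdClass.DM, qci=PathClass.P, clinvar=PathClass.P, cadd=9.99), 1, 0, Tier.A),
            (dict(hgmd=HgmdClass.DM_Q, qci=PathClass.LP, cadd=29.9), 5, 0, Tier.A),
            # known DM but only VUS evidence + deleterious CADD -> Tier B
            (dict(hgmd=HgmdClass.DM, qci=PathClass.VUS, clinvar=PathClass.VUS, cadd=24.8), 11, 3, Tier.B),
            (dict(hgmd=HgmdClass.DM, qci=PathClass.VUS, cadd=20.0), 1, 1, Tier.NONE),  # strict >
            # novel: database-absent, deleterious, fully penetrant
            (dict(cadd=26.2), 1, 1, Tier.C),
            (dict(cadd=19.9), 1, 1, Tier.NONE),
            (dict(cadd=26.2), 2, 1, Tier.NONE),  # incomplete penetrance
            (dict(clinvar=PathClass.P, cadd=26.2), 1, 1, Tier.NONE),  # ClinVar P disqualifies novel
            (dict(clinvar=PathClass.VUS, cadd=26.2), 1, 1, Tier.C),  # VUS does not
            (dict(), 1, 1, Tier.NONE),  # missing CADD excludes score tiers
        ],
    )
    def test_evidence_combinations(self, kw, n, n_diab, expected):
        assert assign_tier(ann(**kw), n_carriers=n, n_diabetic_carriers=n_diab) is expected

    def test_dm_q_configurable_for_tier_b(self):
        a = ann(hgmd=HgmdClass.DM_Q, cadd=25.0)
        assert assign_tier(a, 1, 0) is Tier.B
        assert assign_tier(a, 1, 0, tier_b_accept_dm_q=False) is Tier.NONE

    def test_agrees_with_truth_table_oracle(self):
        """Exhaustive grid of evidence states vs an independent realization
        of the three tier predicates."""
        plp = {PathClass.P, PathClass.LP}
        dmish = {HgmdClass.DM, HgmdClass.DM_Q}

        def oracle(hgmd, qci, clinvar, cadd, n, n_diab):
            a = hgmd in dmish and (qci in plp or clinvar in plp)
            b = hgmd in dmish and cadd is not None and cadd > 20
            c = (
                hgmd is HgmdClass.ABSENT
                and clinvar not in plp
                and cadd is not None
                and cadd > 20
                and n_diab == n
            )
            if a:
                return Tier.A
            if b:
                return Tier.B
            if c:
                return Tier.C
            return Tier.NONE

        grid = itertools.product(
            list(HgmdClass),
            list(PathClass),
            list(PathClass),
            [None, 9.99, 19.9, 20.0, 20.1, 31.0],
            [(1, 1), (3, 3), (3, 2), (5, 0)],
        )
        for hgmd, qci, clinvar, cadd, (n, n_diab) in grid:
            got = assign_tier(
                ann(hgmd=hgmd, qci=qci, clinvar=clinvar, cadd=cadd),
                n_carriers=n,
                n_diabetic_carriers=n_diab,
            )
            assert got is oracle(hgmd, qci, clinvar, cadd, n, n_diab), (
                hgmd, qci, clinvar, cadd, n, n_diab,
            )


def annotated_variant(gene, pos, carriers, annotation):
    return AnnotatedVariant(
        variant=PanelVariant(
            chrom="7", pos=pos, ref="A", alt="G", gene=gene,
            het_carriers=frozenset(carriers), hom_carriers=frozenset(),
            n_called=100, mean_depth=32.0,
        ),
        annotation=annotation,
    )


class TestRunTriage:
    def test_every_variant_tiered_and_sorted_by_subtype(self):
        statuses = {f"s{i}": T2 for i in range(6)}
        avs = [
            annotated_variant("HNF1A", 10, ["s0"], ann(cadd=25.0)),       # subtype 3
            annotated_variant("HNF4A", 20, ["s1"], ann(cadd=25.0)),       # subtype 1
            annotated_variant("RFX6", 30, ["s2"], ann(cadd=25.0)),        # candidate
            annotated_variant("GCK", 40, ["s3"], ann(hgmd=HgmdClass.DM, qci=PathClass.P)),
        ]
        triaged = run_triage(avs, statuses)
        assert [t.variant.gene for t in triaged] == ["HNF4A", "GCK", "HNF1A", "RFX6"]
        assert all(t.tier is not None for t in triaged)

    def test_empty_input_gives_empty_output(self):
        assert run_triage([], {}) == []

    def test_unknown_carrier_status_names_subject(self):
        avs = [annotated_variant("GCK", 10, ["mystery"], ann(cadd=25.0))]
        with pytest.raises(KeyError, match="mystery"):
            run_triage(avs, {"someone_else": T2})

    def test_subject_permutation_leaves_triage_unchanged(self):
        rnd = random.Random(7)
        carriers = [f"s{i}" for i in range(8)]
        statuses = {c: (T2 if i < 3 else ND) for i, c in enumerate(carriers)}
        avs = [annotated_variant("GCK", 10, carriers, ann(hgmd=HgmdClass.DM, cadd=25.0))]
        base = run_triage(avs, statuses)
        for _ in range(3):
            items = list(statuses.items())
            rnd.shuffle(items)
            again = run_triage(avs, dict(items))
            assert again[0].penetrance_pct == base[0].penetrance_pct
            assert again[0].tier is base[0].tier
            assert again[0].diagnosis_breakdown == base[0].diagnosis_breakdown

    def test_tiers_partition_variants(self):
        statuses = {f"s{i}": (T2 if i % 2 else ND) for i in range(10)}
        avs = [
            annotated_variant("GCK", 10 * (i + 1), [f"s{i}"], a)
            for i, a in enumerate(
                [ann(hgmd=HgmdClass.DM, qci=PathClass.P), ann(hgmd=HgmdClass.DM, cadd=25.0),
                 ann(cadd=25.0), ann(), ann(cadd=15.0)]
            )
        ]
        triaged = run_triage(avs, statuses)
        assert len(triaged) == len(avs)
        assert sum(t.tier in (Tier.A, Tier.B, Tier.C, Tier.NONE) for t in triaged) == len(avs)
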
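"""Unit tests for co-segregation, ranking and exposure screening."""

import itertools

import pytest

from famvar import (
    AffectionStatus,
    ExposureRecord,
    Individual,
    Pedigree,
    PipelineConfig,
    Zygosity,
    classify_variant,
    cosegregation_status,
    rank_candidates,
    shared_exposure_screen,
)
from famvar.errors import StructuralError, ValidationError
from famvar.family import SegregationVerdict

from conftest import make_variant


def flat_pedigree(statuses):
    """Unrelated individuals P0..Pn with the given affection statuses."""
    return Pedigree(
        "FAM", [Individual(f"P{i}", status=s) for i, s in enumerate(statuses)]
    )


class TestCosegregation:
    def test_variant_tracking_with_disease_is_consistent(self, family1_pedigree, family1_genotypes):
        v = make_variant(genotypes=family1_genotypes)
        status = cosegregation_status(v, family1_pedigree)
        assert status.verdict is SegregationVerdict.CONSISTENT
        assert set(status.carriers) == {"I:2", "II:2"}
        assert status.non_carriers == ("III:1",)

    def test_suspected_relatives_do_not_constrain(self):
        # affected mother carries, healthy son does not; untyped suspected sibs
        ped = Pedigree(
            "FAM3",
            [
                Individual("II:5", status=AffectionStatus.AFFECTED),
                Individual("II:1", status=AffectionStatus.SUSPECTED),
                Individual("II:2", status=AffectionStatus.SUSPECTED),
                Individual("III:1", status=AffectionStatus.UNAFFECTED),
            ],
        )
        v = make_variant(genotypes={"II:5": Zygosity.HET, "III:1": Zygosity.HOM_REF})
        assert cosegregation_status(v, ped).verdict is SegregationVerdict.CONSISTENT

    def test_affected_noncarrier_is_inconsistent(self):
        ped = flat_pedigree([AffectionStatus.AFFECTED, AffectionStatus.AFFECTED])
        v = make_variant(genotypes={"P0": Zygosity.HET, "P1": Zygosity.HOM_REF})
        assert cosegregation_status(v, ped).verdict is SegregationVerdict.INCONSISTENT

    def test_unaffected_carrier_means_reduced_penetrance(self):
        ped = flat_pedigree([AffectionStatus.AFFECTED, AffectionStatus.UNAFFECTED])
        v = make_variant(genotypes={"P0": Zygosity.HET, "P1": Zygosity.HET})
        verdict = cosegregation_status(v, ped).verdict
        assert verdict is SegregationVerdict.CONSISTENT_REDUCED_PENETRANCE

    @pytest.mark.parametrize(
        "genotypes",
        [
            {"P0": Zygosity.HET},  # single genotyped individual
            {"P1": Zygosity.HET, "P2": Zygosity.HOM_REF},  # no genotyped affected
        ],
    )
    def test_uninformative_when_underpowered(self, genotypes):
        ped = flat_pedigree(
            [AffectionStatus.AFFECTED, AffectionStatus.UNAFFECTED, AffectionStatus.UNKNOWN]
        )
        v = make_variant(genotypes=genotypes)
        assert cosegregation_status(v, ped).verdict is SegregationVerdict.UNINFORMATIVE

    def test_unknown_individual_in_genotypes_is_structural_error(self, family1_pedigree):
        v = make_variant(genotypes={"nobody": Zygosity.HET})
        with pytest.raises(StructuralError):
            cosegregation_status(v, family1_pedigree)

    def test_verdict_invariant_to_order_and_untyped_additions(self, family1_genotypes):
        v = make_variant(genotypes=family1_genotypes)
        statuses = {
            "I:2": AffectionStatus.AFFECTED,
            "II:2": AffectionStatus.AFFECTED,
            "III:1": AffectionStatus.UNAFFECTED,
        }
        verdicts = set()
        for perm in itertools.permutations(statuses):
            inds = [Individual(i, status=statuses[i]) for i in perm]
            inds.append(Individual("X:1", status=AffectionStatus.AFFECTED))  # untyped
            verdicts.add(cosegregation_status(v, Pedigree("F", inds)).verdict)
        assert verdicts == {SegregationVerdict.CONSISTENT}


class TestRanking:
    def test_tier_dominates_then_points_then_segregation(self, cfg, table2_variants, family1_pedigree, family1_genotypes):
        triples = []
        for gene in ("NPR2", "CYBA"):
            v = table2_variants[gene]
            v.genotypes = dict(family1_genotypes)
            triples.append((v, classify_variant(v, cfg), cosegregation_status(v, family1_pedigree)))
        ranked = rank_candidates(triples)
        assert [t[0].gene for t in ranked] == ["CYBA", "NPR2"]

    def test_position_breaks_full_ties(self, cfg, family1_pedigree):
        a = make_variant("stop_gained", gene="AAA", pos=2000)
        b = make_variant("stop_gained", gene="AAA", pos=1000)
        triples = [
            (v, classify_variant(v, cfg), cosegregation_status(v, family1_pedigree))
            for v in (a, b)
        ]
        assert [t[0].pos for t in rank_candidates(triples)] == [1000, 2000]

    def test_permutation_invariant_total_order(self, cfg, family1_pedigree, table2_variants):
        triples = [
            (v, classify_variant(v, cfg), cosegregation_status(v, family1_pedigree))
            for v in table2_variants.values()
        ]
        baseline = rank_candidates(triples)
        for perm in itertools.permutations(triples):
            assert rank_candidates(list(perm)) == baseline
        assert rank_candidates(rank_candidates(triples)) == baseline

    def test_empty_input(self):
        assert rank_candidates([]) == []


def _family4_pedigree():
    father = Individual(
        "II:1", "male", AffectionStatus.AFFECTED,
        exposures=[
            ExposureRecord("Trichloroethylene", "chemical agent", start_age=46, end_age=56),
            ExposureRecord("asbestos dust", "toxic dust", start_age=46, end_age=56),
            ExposureRecord("tramadol", "opioid", start_age=52, end_age=53),
        ],
    )
    son = Individual(
        "III:1", "male", AffectionStatus.AFFECTED,
        exposures=[
            ExposureRecord("trichloroethylene", "chemical agent", start_age=16, end_age=23),
            ExposureRecord("Asbestos dust", "toxic dust", start_age=23, end_age=26),
            ExposureRecord("tramadol", "opioid", start_age=42),
        ],
    )
    return Pedigree("FAM4", [father, son])


class TestSharedExposureScreen:
    def test_father_son_shared_occupational_exposures(self):
        hits = shared_exposure_screen(_family4_pedigree())
        assert [(h.substance, h.risk_tier) for h in hits] == [
            ("trichloroethylene", "definite"),
            ("asbestos", "possible"),
            ("tramadol", "possible"),
        ]
        assert all(h.affected_ids == ("II:1", "III:1") for h in hits)

    def test_solvent_exposure_shared_by_brothers_only(self):
        ped = Pedigree(
            "FAM5",
            [
                Individual("II:1", status=AffectionStatus.AFFECTED,
                           exposures=[ExposureRecord("organic solvents", "chemical agent"),
                                      ExposureRecord("toxic dust", "toxic dust")]),
                Individual("II:2", status=AffectionStatus.AFFECTED,
                           exposures=[ExposureRecord("paint dust", "chemical agent")]),
                Individual("II:3", status=AffectionStatus.UNAFFECTED),
            ],
        )
        hits = shared_exposure_screen(ped)
        assert [(h.substance, h.risk_tier) for h in hits] == [("organic solvents", "definite")]

    def test_empty_when_any_affected_lacks_data(self):
        ped = Pedigree(
            "F",
            [
                Individual("A", status=AffectionStatus.AFFECTED,
                           exposures=[ExposureRecord("tramadol", "opioid")]),
                Individual("B", status=AffectionStatus.AFFECTED),  # no data
            ],
        )
        assert shared_exposure_screen(ped) == []

    def test_unaffected_exposures_shrink_the_screen(self):
        base = _family4_pedigree()
        hits0 = {h.substance for h in shared_exposure_screen(base)}
        grown = Pedigree(
            "FAM4",
            base.individuals
            + [Individual("II:2", status=AffectionStatus.UNAFFECTED,
                          exposures=[ExposureRecord("tramadol", "opioid")])],
        )
        hits1 = {h.substance for h in shared_exposure_screen(grown)}
        assert hits1 < hits0 and "tramadol" not in hits1

    def test_requires_an_affected_individual(self):
        ped = flat_pedigree([AffectionStatus.UNAFFECTED])
        with pytest.raises(ValidationError):
            shared_exposure_screen(ped)


class TestPedigreeStructure:
    def test_cyclic_parentage_rejected(self):
        with pytest.raises(StructuralError):
            Pedigree("F", [
                Individual("A", father="B"),
                Individual("B", father="A"),
            ])

    def test_dangling_parent_rejected(self):
        with pytest.raises(StructuralError):
            Pedigree("F", [Individual("A", father="ghost")])

    def test_duplicate_id_rejected(self):
        with pytest.raises(StructuralError):
            Pedigree("F", [Individual("A"), Individual("A")])
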
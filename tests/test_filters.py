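import pandas as pd
import pytest

import fabrynet as fn
from fabrynet.disease import KnownBiomarker
from fabrynet.errors import SelectionError, ValidationError
from fabrynet.filters import (
    PUBLISHED_REFERENCE_THRESHOLD,
    AnnotationRecord,
    candidate_fixture_inputs,
    read_annotations,
    write_annotations,
)


class TestReferenceThreshold:
    def test_packaged_table_selects_b2m(self):
        known = fn.load_known_biomarkers()
        best, threshold = fn.reference_threshold(known)
        assert best.gene_symbol == "B2M"
        assert threshold == 71.0

    def test_all_measurable_returns_top_ranked(self):
        known = [
            KnownBiomarker("X", cv_accuracy=60, plasma_measurable=True),
            KnownBiomarker("Y", cv_accuracy=80, plasma_measurable=True),
        ]
        best, threshold = fn.reference_threshold(known)
        assert best.gene_symbol == "Y" and threshold == 80

    def test_single_entry(self):
        known = [KnownBiomarker("Z", cv_accuracy=55, plasma_measurable=True)]
        assert fn.reference_threshold(known)[0].gene_symbol == "Z"

    def test_none_measurable_raises(self):
        known = [KnownBiomarker("X", cv_accuracy=60, plasma_measurable=False)]
        with pytest.raises(SelectionError):
            fn.reference_threshold(known)


class TestClassifyLocation:
    def test_axon_is_neuronal(self):
        ann = AnnotationRecord(protein="P", subcellular_terms=frozenset({"axon"}))
        assert fn.classify_location(ann) == "N"

    def test_endothelial_plus_hippocampus_is_nv(self):
        ann = AnnotationRecord(
            protein="P",
            tissue_terms=frozenset({"endothelial cell", "hippocampus"}),
        )
        assert fn.classify_location(ann) == "NV"

    def test_no_terms_is_none(self):
        assert fn.classify_location(AnnotationRecord(protein="P")) == "none"

    def test_terms_normalized_case_insensitively(self):
        ann = AnnotationRecord(protein="P", subcellular_terms=frozenset({" AXON "}))
        assert fn.classify_location(ann) == "N"

    @pytest.mark.parametrize(
        "evidence,expected", [("uncertain", "none"), ("supported", "N"), ("enhanced", "N")]
    )
    def test_atlas_tissue_terms_gated_by_evidence(self, evidence, expected):
        # cerebral cortex appears only in the atlas tissue vocabulary
        ann = AnnotationRecord(
            protein="P", tissue_terms=frozenset({"cerebral cortex"}), evidence=evidence
        )
        assert fn.classify_location(ann) == expected

    def test_curated_terms_not_gated(self):
        ann = AnnotationRecord(
            protein="P", tissue_terms=frozenset({"neuron"}), evidence="uncertain"
        )
        assert fn.classify_location(ann) == "N"

    def test_adding_terms_never_demotes(self):
        base = AnnotationRecord(protein="P", subcellular_terms=frozenset({"axon"}))
        richer = AnnotationRecord(
            protein="P",
            subcellular_terms=frozenset({"axon"}),
            tissue_terms=frozenset({"endothelial cell", "liver"}),
        )
        order = {"none": 0, "N": 1, "V": 1, "NV": 2}
        assert order[fn.classify_location(richer)] >= order[fn.classify_location(base)]


class TestCascade:
    def test_threshold_100_empties_all_stages(self):
        results, annotations, locations = candidate_fixture_inputs()
        stages = fn.filter_candidates(results, annotations, 100.0, locations=locations)
        assert stages.counts == {
            "above_threshold": 0, "measurable": 0, "located": 0,
        }

    def test_packaged_candidate_table_keeps_36(self):
        results, annotations, locations = candidate_fixture_inputs()
        stages = fn.filter_candidates(
            results, annotations, PUBLISHED_REFERENCE_THRESHOLD, locations=locations
        )
        assert stages.counts["located"] == 36

    def test_stages_are_nested(self):
        results, annotations, locations = candidate_fixture_inputs()
        stages = fn.filter_candidates(
            results, annotations, PUBLISHED_REFERENCE_THRESHOLD, locations=locations
        )
        s1 = set(stages.stage1["variables"])
        s2 = set(stages.stage2["variables"])
        s3 = set(stages.stage3["variables"])
        assert s3 <= s2 <= s1

    def test_unmeasurable_annotations_empty_stage2(self):
        results, _, locations = candidate_fixture_inputs()
        annotations = {
            v[0]: AnnotationRecord(protein=v[0], plasma=False, urine=False)
            for v in results["variables"]
        }
        stages = fn.filter_candidates(results, annotations, 0.0, locations=locations)
        assert stages.counts["above_threshold"] == 36
        assert stages.counts["measurable"] == 0

    def test_bad_threshold_rejected(self):
        results, annotations, locations = candidate_fixture_inputs()
        with pytest.raises(ValidationError):
            fn.filter_candidates(results, annotations, 120.0, locations=locations)


class TestPrioritize:
    @pytest.fixture()
    def stage3(self):
        results, annotations, locations = candidate_fixture_inputs()
        return fn.filter_candidates(
            results, annotations, PUBLISHED_REFERENCE_THRESHOLD, locations=locations
        ).stage3

    def test_flagship_set(self, stage3):
        flagship = fn.prioritize(stage3, acc_min=90, required_location="NV")
        assert {v[0] for v in flagship["variables"]} == {
            "CAMK2A", "ILK", "LMNA", "KHSRP",
        }
        # sorted by accuracy descending
        assert list(flagship["cv_accuracy"]) == sorted(
            flagship["cv_accuracy"], reverse=True
        )

    def test_accuracy_bound_is_inclusive(self, stage3):
        flagship = fn.prioritize(stage3, acc_min=93, required_location="NV")
        assert "KHSRP" in {v[0] for v in flagship["variables"]}

    def test_impossible_accuracy_empty(self, stage3):
        assert len(fn.prioritize(stage3, acc_min=101)) == 0

    def test_neuronal_only_selection(self, stage3):
        got = {v[0] for v in fn.prioritize(stage3, 90, "N")["variables"]}
        assert got == {
            "CTSS", "FOSL1", "PPP1CC", "CDK1", "GNB5", "AKT3", "MAPK1", "PTPN13",
        }


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        recs = [
            AnnotationRecord(
                protein="A", plasma=True, urine=False,
                subcellular_terms=frozenset({"axon"}),
                tissue_terms=frozenset({"endothelial cell"}),
                evidence="enhanced",
            ),
            AnnotationRecord(protein="B"),
        ]
        p = tmp_path / "ann.csv"
        write_annotations(recs, p)
        back = read_annotations(p)
        assert back["A"] == recs[0] and back["B"] == recs[1]
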
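import json

import jsonschema
import pytest

from mavekit import (
    emit_schema,
    load_registry,
    lookup_terms,
    recommended_repositories,
    validate_metadata,
)
from mavekit.errors import (
    DuplicateTermError,
    RegistryFormatError,
    UnknownCategoryError,
)
from mavekit.fixtures import ablate
from mavekit.vocabulary import (
    DataType,
    MetadataDocument,
    RULE_TABLE,
    Severity,
    findings_to_jsonl,
    findings_to_text,
    resolve_pointer,
)


class TestRegistry:
    def test_bundled_default_has_required_categories(self, registry):
        assert "libraryGeneration" in registry.categories
        for cat in (
            "projectScope",
            "libraryIntegrationExpression",
            "assayType",
            "sequencingMethod",
            "phenotypeRelevance",
        ):
            assert cat in registry.categories
            assert registry.terms_in(cat)

    def test_duplicate_terms_rejected(self, tmp_path):
        bad = {
            "version": "x",
            "categories": list(load_registry().categories),
            "terms": [
                {"category": "assayType", "label": "dup term"},
                {"category": "assayType", "label": "dup term"},
            ],
        }
        p = tmp_path / "reg.json"
        p.write_text(json.dumps(bad))
        with pytest.raises(DuplicateTermError):
            load_registry(p)

    def test_missing_categories_rejected(self, tmp_path):
        p = tmp_path / "reg.json"
        p.write_text(json.dumps({"version": "x", "categories": [], "terms": []}))
        with pytest.raises(RegistryFormatError):
            load_registry(p)

    def test_malformed_json_names_position(self, tmp_path):
        p = tmp_path / "reg.json"
        p.write_text("{not json")
        with pytest.raises(RegistryFormatError) as exc:
            load_registry(p)
        assert "line" in str(exc.value)

    def test_lookup_empty_query_matches_all(self, registry):
        all_terms = lookup_terms(registry, "assayType", "")
        assert len(all_terms) >= 1
        assert all_terms == registry.terms_in("assayType")

    def test_lookup_no_match_and_curie_match(self, registry):
        assert lookup_terms(registry, "assayType", "zzzz-no-match") == []
        assert lookup_terms(registry, "assayType", "obi:0000916")

    def test_lookup_unknown_category(self, registry):
        with pytest.raises(UnknownCategoryError):
            lookup_terms(registry, "notACategory", "x")


class TestDepositionMatrix:
    @pytest.mark.parametrize(
        "data_type,expected",
        [
            ("processedScores", ["MaveDB"]),
            ("unprocessedScores", ["MaveDB"]),
            ("rawCounts", ["MaveDB"]),
            ("rawSequenceReads", ["Sequence Read Archive", "Gene Expression Omnibus"]),
            ("targetSequence", ["MaveDB"]),
            ("linkedSequenceReferences", ["MaveDB"]),
            ("sequenceMetadataDigests", ["MaveDB", "SeqRepo"]),
            ("variantLibrary", ["MaveDB"]),
            ("analysisCode", ["GitHub", "Zenodo"]),
            ("structuredVocabularyDescription", ["This work", "MaveDB"]),
        ],
    )
    def test_every_row(self, data_type, expected):
        assert recommended_repositories(data_type) == expected

    def test_unknown_type(self):
        with pytest.raises(UnknownCategoryError):
            recommended_repositories("notAType")

    def test_covers_all_declared_types(self):
        for dt in DataType:
            assert recommended_repositories(dt)


class TestValidateMetadata:
    def test_compliant_preset_is_clean(self, preset_doc, registry):
        assert validate_metadata(preset_doc, registry) == []

    def test_unversioned_accession_is_error(self, preset_doc, registry):
        doc = preset_doc.to_dict()
        doc["referenceLinks"][0]["accession"] = "NM_000546"
        (f,) = validate_metadata(doc, registry)
        assert (f.rule_id, f.severity) == ("VERSIONED_ACCESSION_REQUIRED", Severity.error)
        assert f.path == "/referenceLinks/0/accession"

    def test_empty_target_residues_is_error(self, preset_doc, registry):
        doc = preset_doc.to_dict()
        doc["targets"][0]["residues"] = ""
        (f,) = validate_metadata(doc, registry)
        assert (f.rule_id, f.severity) == ("TARGET_SEQUENCE_REQUIRED", Severity.error)

    def test_non_mondo_disease_is_warning(self, preset_doc, registry):
        doc = preset_doc.to_dict()
        doc["disease"]["diseaseCurie"] = "DOID:0050"
        (f,) = validate_metadata(doc, registry)
        assert (f.rule_id, f.severity) == ("DISEASE_TERM_SOURCE", Severity.warning)

    def test_missing_raw_read_deposition_is_warning(self, preset_doc, registry):
        doc = preset_doc.to_dict()
        doc["sequencing"]["rawReadDepositions"] = []
        (f,) = validate_metadata(doc, registry)
        assert (f.rule_id, f.severity) == ("RAW_READS_DEPOSITION", Severity.warning)

    def test_deterministic_and_idempotent(self, preset_doc, registry):
        doc = ablate(preset_doc, "MODEL_SYSTEM_TAXON")
        first = validate_metadata(doc, registry)
        second = validate_metadata(doc, registry)
        assert first == second

    def test_paths_resolve_in_document(self, preset_doc, registry):
        for rule_id in RULE_TABLE:
            doc = ablate(preset_doc, rule_id)
            for f in validate_metadata(doc, registry):
                resolve_pointer(doc.data, f.path)  # raises if unresolvable

    def test_findings_sorted_by_severity_then_path(self, preset_doc, registry):
        doc = preset_doc.to_dict()
        doc["targets"][0]["residues"] = ""
        doc["sequencing"]["rawReadDepositions"] = []
        doc["analysis"].pop("archiveDoi")
        findings = validate_metadata(doc, registry)
        sevs = [f.severity for f in findings]
        assert sevs == sorted(sevs, key=[Severity.error, Severity.warning, Severity.info].index)

    def test_unknown_field_preserved_and_reported(self, preset_doc, registry):
        doc = preset_doc.to_dict()
        doc["bespokeNote"] = "kept"
        findings = validate_metadata(doc, registry)
        assert [f.rule_id for f in findings] == ["UNKNOWN_FIELD"]
        assert MetadataDocument(doc).to_dict()["bespokeNote"] == "kept"

    def test_exports(self, preset_doc, registry):
        doc = ablate(preset_doc, "RAW_COUNTS_SHARED")
        findings = validate_metadata(doc, registry)
        jsonl = findings_to_jsonl(findings)
        assert json.loads(jsonl.splitlines()[0])["ruleId"] == "RAW_COUNTS_SHARED"
        assert "RAW_COUNTS_SHARED" in findings_to_text(findings)


class TestAblationMatrix:
    def test_error_rules_fire_exactly_once(self, preset_doc, registry):
        error_rules = [r for r, s in RULE_TABLE.items() if s == Severity.error]
        assert len(error_rules) == 6
        for rule_id in error_rules:
            findings = validate_metadata(ablate(preset_doc, rule_id), registry)
            assert [f.rule_id for f in findings] == [rule_id], rule_id

    def test_every_rule_has_a_matched_ablation(self, preset_doc, registry):
        for rule_id in RULE_TABLE:
            findings = validate_metadata(ablate(preset_doc, rule_id), registry)
            assert rule_id in {f.rule_id for f in findings}, rule_id

    def test_ablation_does_not_mutate_original(self, preset_doc, registry):
        before = preset_doc.to_dict()
        ablate(preset_doc, "TARGET_SEQUENCE_REQUIRED")
        assert preset_doc.to_dict() == before
        assert validate_metadata(preset_doc, registry) == []


class TestSchema:
    def test_dialect_and_meta_schema_valid(self, registry):
        schema = emit_schema(registry)
        assert schema["$schema"] == "https://json-schema.org/draft/2020-12/schema"
        jsonschema.validators.Draft202012Validator.check_schema(schema)

    def test_schema_stable_for_same_registry(self, registry):
        a = json.dumps(emit_schema(registry), sort_keys=True)
        b = json.dumps(emit_schema(load_registry()), sort_keys=True)
        assert a == b

    def test_accepts_preset_rejects_bare_taxon(self, registry, preset_doc):
        validator = jsonschema.validators.Draft202012Validator(emit_schema(registry))
        assert validator.is_valid(preset_doc.data)
        doc = preset_doc.to_dict()
        doc["modelSystem"]["taxonCurie"] = "12345"
        assert not validator.is_valid(doc)

    def test_term_enums_embedded(self, registry):
        schema = emit_schema(registry)
        assert "libraryGenerationTerms" in schema["$defs"]
        assert "doped oligonucleotide synthesis" in schema["$defs"]["libraryGenerationTerms"]["enum"]
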
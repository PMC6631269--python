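"""Activity-record curation, deduplication and ensemble construction."""

from dataclasses import replace

import pytest

from targetfish.dataset import (
    ActivityRecord,
    SchemaError,
    build_target_ensembles,
    deduplicate_ligand_target,
    filter_activity_records,
    load_activity_table,
    load_database,
    prepare_database,
    save_activity_table,
    save_database,
)


def rec(**kw):
    base = dict(
        molecule_id="M1", smiles="CCO", target_id="T1", target_name="t",
        standard_type="Ki", standard_relation="=", standard_value=10.0,
        standard_units="nM", confidence_score=8,
    )
    base.update(kw)
    return ActivityRecord(**base)


class TestFilter:
    def test_one_violator_per_rule(self):
        clean = [rec(molecule_id=f"C{i}") for i in range(6)]
        violators = [
            rec(molecule_type="Protein"),
            rec(is_prodrug=True),
            rec(target_type="ORGANISM"),
            rec(data_validity_comment="Outside typical range"),
            rec(confidence_score=4),
            rec(standard_relation=">"),
        ]
        retained, report = filter_activity_records(clean + violators)
        assert len(retained) == 6
        for rule in (
            "molecule_type", "prodrug", "target_type", "data_validity",
            "confidence", "standard_relation",
        ):
            assert report.rule_counts[rule] == 1, rule
        assert report.n_in == 12 and report.n_out == 6

    def test_empty_input(self):
        retained, report = filter_activity_records([])
        assert retained == [] and report.n_in == report.n_out == 0
        assert all(v == 0 for v in report.rule_counts.values())

    def test_confidence_exactly_5_is_rejected(self):
        retained, report = filter_activity_records([rec(confidence_score=5)])
        assert retained == [] and report.rule_counts["confidence"] == 1

    def test_confidence_6_passes(self):
        retained, _ = filter_activity_records([rec(confidence_score=6)])
        assert len(retained) == 1

    @pytest.mark.parametrize("stype, ok", [
        ("IC50", True), ("Ki", True), ("Kd", True), ("EC50", True), ("Potency", False),
    ])
    def test_standard_type_whitelist(self, stype, ok):
        retained, _ = filter_activity_records([rec(standard_type=stype)])
        assert bool(retained) is ok

    @pytest.mark.parametrize("ttype, ok", [
        ("SINGLE PROTEIN", True), ("SINGLE_PROTEIN", True),
        ("PROTEIN COMPLEX", True), ("CELL-LINE", False),
    ])
    def test_target_type_dialects(self, ttype, ok):
        retained, _ = filter_activity_records([rec(target_type=ttype)])
        assert bool(retained) is ok

    def test_organism_never_filtered(self):
        retained, _ = filter_activity_records(
            [rec(organism="Influenza A virus"), rec(organism="")]
        )
        assert len(retained) == 2

    def test_units_rule_is_optional(self):
        records = [rec(standard_units="ug.mL-1")]
        retained, report = filter_activity_records(records)
        assert not retained and report.rule_counts["units"] == 1
        retained, report = filter_activity_records(records, require_nm_units=False)
        assert len(retained) == 1 and "units" not in report.rule_counts

    def test_first_failing_rule_attribution_and_conservation(self):
        # violates both prodrug and confidence: attributed to prodrug (earlier)
        both = rec(is_prodrug=True, confidence_score=2)
        retained, report = filter_activity_records([both, rec()])
        assert report.rule_counts["prodrug"] == 1
        assert report.rule_counts["confidence"] == 0
        assert report.n_in == report.n_out + report.n_rejected

    def test_filter_is_idempotent(self):
        mixed = [rec(molecule_id=f"C{i}") for i in range(4)] + [
            rec(is_prodrug=True), rec(standard_relation=">")
        ]
        retained, _ = filter_activity_records(mixed)
        again, report = filter_activity_records(retained)
        assert again == retained
        assert report.n_rejected == 0

    def test_malformed_counted(self):
        retained, report = filter_activity_records([rec(standard_value=None)])
        assert not retained and report.rule_counts["malformed"] == 1


class TestDedup:
    def test_lowest_value_wins(self):
        kept = deduplicate_ligand_target(
            [rec(standard_value=100.0), rec(standard_value=10.0)]
        )
        assert len(kept) == 1 and kept[0].standard_value == 10.0

    def test_single_annotation_unchanged(self):
        records = [rec()]
        assert deduplicate_ligand_target(records) == records

    def test_tie_keeps_first_in_input_order(self):
        first = rec(standard_value=10.0, organism="first")
        second = rec(standard_value=10.0, organism="second")
        kept = deduplicate_ligand_target([first, second])
        assert kept == [first]

    def test_matches_group_min_oracle(self):
        import random

        rng = random.Random(4)
        records = [
            rec(
                molecule_id=f"M{rng.randint(0, 5)}",
                target_id=f"T{rng.randint(0, 3)}",
                standard_value=float(rng.randint(1, 500)),
            )
            for _ in range(200)
        ]
        kept = deduplicate_ligand_target(records)
        oracle = {}
        for r in records:
            key = (r.molecule_id, r.target_id)
            oracle[key] = min(oracle.get(key, float("inf")), r.standard_value)
        assert {(r.molecule_id, r.target_id): r.standard_value for r in kept} == oracle


class TestEnsembles:
    def test_minimum_size_threshold(self):
        records = [
            rec(molecule_id=f"A{i}", target_id="small") for i in range(9)
        ] + [rec(molecule_id=f"B{i}", target_id="big") for i in range(10)]
        db = build_target_ensembles(records, min_ensemble_size=10)
        assert db.target_ids == ["big"]

    def test_counts_by_construction(self):
        records = [
            rec(molecule_id=f"M{t}_{i}", target_id=f"T{t}")
            for t in range(3)
            for i in range(12)
        ]
        db = build_target_ensembles(records, min_ensemble_size=10)
        assert len(db) == 3
        assert sum(len(e) for e in db.ensembles) == 36

    def test_shared_ligand_in_both_ensembles(self):
        records = [
            rec(molecule_id=f"M{i}", target_id="T1") for i in range(10)
        ] + [rec(molecule_id=f"N{i}", target_id="T2") for i in range(9)] + [
            rec(molecule_id="M0", target_id="T2")
        ]
        db = build_target_ensembles(records, min_ensemble_size=10)
        assert "M0" in db.ensemble("T1").molecule_ids
        assert "M0" in db.ensemble("T2").molecule_ids

    def test_best_value_carried_into_members(self):
        records = deduplicate_ligand_target(
            [rec(standard_value=50.0), rec(standard_value=5.0)]
            + [rec(molecule_id=f"M{i}") for i in range(2, 12)]
        )
        db = build_target_ensembles(records, min_ensemble_size=10)
        assert dict(db.ensemble("T1").members)["M1"] == 5.0

    def test_zero_targets_is_empty_with_warning(self):
        db = build_target_ensembles([rec()], min_ensemble_size=10)
        assert len(db) == 0 and "warning" in db.provenance


class TestIO:
    def test_activity_table_round_trip(self, tmp_path):
        records = [rec(molecule_id=f"M{i}", standard_value=float(i + 1)) for i in range(5)]
        path = tmp_path / "acts.tsv"
        save_activity_table(records, path)
        assert load_activity_table(path) == records

    def test_chembl_style_headers(self, tmp_path):
        path = tmp_path / "chembl.tsv"
        path.write_text(
            "molregno\tcanonical_smiles\ttarget_chembl_id\tpref_name\tstandard_type\t"
            "standard_relation\tstandard_value\tstandard_units\tconfidence_score\t"
            "data_validity_comment\ttarget_type\tmolecule_type\torganism\n"
            "1001\tCCO\tCHEMBL204\tHepsin\tKi\t=\t12.5\tnM\t9\t\tSINGLE PROTEIN\t"
            "Small molecule\tHomo sapiens\n"
        )
        records = load_activity_table(path)
        assert records[0].molecule_id == "1001"
        assert records[0].target_id == "CHEMBL204"
        assert records[0].standard_value == 12.5
        assert records[0].confidence_score == 9

    def test_missing_required_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("molecule_id,smiles,target_id\nM1,CCO,T1\n")
        with pytest.raises(SchemaError, match="standard_value"):
            load_activity_table(path)

    def test_database_round_trip_with_panel(self, tmp_path, small_db):
        path = tmp_path / "db.json"
        save_database(small_db, path)
        loaded = load_database(path)
        assert loaded.activity_tag == small_db.activity_tag
        assert loaded.target_ids == small_db.target_ids
        assert loaded.representation == small_db.representation
        assert loaded.panel.registry_hash == small_db.panel.registry_hash
        for mid in small_db.panel.rows:
            assert loaded.panel.row(mid) == small_db.panel.row(mid)
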
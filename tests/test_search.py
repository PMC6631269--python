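"""Consensus scoring and target ranking against brute-force oracles."""

import random

import pytest

from targetfish.calibration import ThresholdTable
from targetfish.dataset import TargetDatabase, TargetEnsemble
from targetfish.fingerprints import (
    BitFingerprint,
    FingerprintPanel,
    FingerprintSpec,
    Registry,
    tanimoto,
)
from targetfish.search import max_tc_per_fp, predict_targets, rank_targets, score_target

N_BITS = 64


def toy_registry(n_specs=3):
    return Registry(
        [FingerprintSpec.make(f"fp{i}", "circular", N_BITS, radius=1) for i in range(n_specs)]
    )


def random_row(registry, rng, density=0.3):
    return [
        BitFingerprint(
            s.name,
            frozenset(i for i in range(N_BITS) if rng.random() < density),
            N_BITS,
        )
        for s in registry.specs
    ]


def toy_db(registry, rng, n_targets, max_members):
    """A database over random bit fingerprints (no chemistry involved)."""
    panel = FingerprintPanel(registry)
    ensembles = []
    for t in range(n_targets):
        members = []
        for m in range(rng.randint(1, max_members)):
            mid = f"T{t}_m{m}"
            panel.add(mid, random_row(registry, rng))
            members.append((mid, 10.0))
        ensembles.append(TargetEnsemble(f"T{t}", f"target {t}", members))
    db = TargetDatabase(
        activity_tag="Ki",
        ensembles=ensembles,
        smiles={},
        provenance={},
        representation="ionized",
    )
    db.panel = panel
    return db


def brute_force_ranking(query_row, db, thresholds, n_min_fp, constant=None):
    """Exhaustive pairwise re-implementation of the consensus score."""
    names = [fp.spec_name for fp in query_row]
    constant = constant if constant is not None else len(names)
    scored = []
    for ens in db.ensembles:
        tc_max = {}
        for qfp in query_row:
            best = max(
                tanimoto(qfp, db.panel.fingerprint(mid, qfp.spec_name))
                for mid in ens.molecule_ids
            )
            tc_max[qfp.spec_name] = best
        qualifying = [n for n in names if tc_max[n] >= thresholds[n]]
        if len(qualifying) >= n_min_fp:
            sc = sum(tc_max[n] for n in qualifying) / constant
            scored.append((ens.target_id, sc, len(qualifying)))
    scored.sort(key=lambda x: (-x[1], -x[2], x[0]))
    return scored


class TestScoreTarget:
    def test_worked_example(self):
        thresholds = ThresholdTable({"a": 0.3, "b": 0.3, "c": 0.3}, 95, 0, 0)
        ts = score_target({"a": 0.9, "b": 0.2, "c": 0.5}, thresholds, n_min_fp=2)
        assert ts is not None
        assert set(ts.evidence) == {"a", "c"}
        assert ts.sc == pytest.approx((0.9 + 0.5) / 3)

    def test_perfect_match_scores_one(self):
        thresholds = ThresholdTable({"a": 0.5, "b": 0.5}, 95, 0, 0)
        ts = score_target({"a": 1.0, "b": 1.0}, thresholds, n_min_fp=2)
        assert ts.sc == pytest.approx(1.0)

    def test_below_all_thresholds_returns_none(self):
        thresholds = ThresholdTable({"a": 0.5, "b": 0.5}, 95, 0, 0)
        assert score_target({"a": 0.4, "b": 0.49}, thresholds, n_min_fp=1) is None

    def test_boundary_qualifies(self):
        thresholds = ThresholdTable({"a": 0.5}, 95, 0, 0)
        ts = score_target({"a": 0.5}, thresholds, n_min_fp=1)
        assert ts is not None and ts.qualifying_fp_count == 1


class TestMaxTc:
    def test_member_identical_to_query(self):
        rng = random.Random(0)
        registry = toy_registry()
        db = toy_db(registry, rng, 1, 5)
        mid = db.ensembles[0].molecule_ids[0]
        out = max_tc_per_fp(db.panel.row(mid), db.ensembles[0], db.panel)
        assert all(tc == 1.0 for tc, _ in out.values())

    def test_singleton_ensemble(self):
        rng = random.Random(1)
        registry = toy_registry()
        db = toy_db(registry, rng, 1, 1)
        query = random_row(registry, rng)
        out = max_tc_per_fp(query, db.ensembles[0], db.panel)
        only = db.ensembles[0].molecule_ids[0]
        for qfp in query:
            expected = tanimoto(qfp, db.panel.fingerprint(only, qfp.spec_name))
            assert out[qfp.spec_name] == (expected, only)

    def test_matches_exhaustive_maximum(self):
        rng = random.Random(2)
        registry = toy_registry()
        db = toy_db(registry, rng, 1, 5)
        query = random_row(registry, rng)
        out = max_tc_per_fp(query, db.ensembles[0], db.panel)
        for qfp in query:
            expected = max(
                tanimoto(qfp, db.panel.fingerprint(m, qfp.spec_name))
                for m in db.ensembles[0].molecule_ids
            )
            assert out[qfp.spec_name][0] == pytest.approx(expected)


class TestRanking:
    def test_equivalent_to_brute_force_on_random_databases(self):
        rng = random.Random(3)
        registry = toy_registry(4)
        for trial in range(10):
            db = toy_db(registry, rng, rng.randint(1, 5), 10)
            thresholds = ThresholdTable(
                {s.name: rng.uniform(0.1, 0.6) for s in registry.specs}, 95, 0, 0
            )
            query = random_row(registry, rng)
            result = rank_targets("q", query, db, thresholds, n_min_fp=2)
            oracle = brute_force_ranking(query, db, thresholds, n_min_fp=2)
            got = [(t.target_id, t.sc, t.qualifying_fp_count) for t in result.ranked]
            assert [(t, q) for t, _, q in got] == [(t, q) for t, _, q in oracle]
            for (_, sc_a, _), (_, sc_b, _) in zip(got, oracle):
                assert sc_a == pytest.approx(sc_b)

    def test_ranking_invariant_to_normalizing_constant(self):
        rng = random.Random(4)
        registry = toy_registry(4)
        db = toy_db(registry, rng, 5, 8)
        thresholds = ThresholdTable(
            {s.name: 0.2 for s in registry.specs}, 95, 0, 0
        )
        query = random_row(registry, rng)
        normalized = brute_force_ranking(query, db, thresholds, 2)
        raw_sum = brute_force_ranking(query, db, thresholds, 2, constant=1)
        assert [t for t, _, _ in normalized] == [t for t, _, _ in raw_sum]

    def test_dominating_addition_never_lowers_score(self):
        rng = random.Random(5)
        registry = toy_registry()
        db = toy_db(registry, rng, 2, 5)
        thresholds = ThresholdTable({s.name: 0.1 for s in registry.specs}, 95, 0, 0)
        query = random_row(registry, rng)
        before = rank_targets("q", query, db, thresholds, n_min_fp=1)
        sc_before = {t.target_id: t.sc for t in before.ranked}
        # add a copy of the query itself: per-spec Tc of 1.0 dominates all maxima
        db.panel.add("T0_clone", query)
        db.ensembles[0].members.append(("T0_clone", 1.0))
        after = rank_targets("q", query, db, thresholds, n_min_fp=1)
        sc_after = {t.target_id: t.sc for t in after.ranked}
        assert sc_after["T0"] >= sc_before.get("T0", 0.0)
        assert after.ranked[0].target_id == "T0"

    def test_raising_thresholds_shrinks_result_set(self):
        rng = random.Random(6)
        registry = toy_registry()
        db = toy_db(registry, rng, 5, 8)
        query = random_row(registry, rng)
        lo = ThresholdTable({s.name: 0.1 for s in registry.specs}, 95, 0, 0)
        hi = ThresholdTable({s.name: 0.4 for s in registry.specs}, 95, 0, 0)
        got_lo = {t.target_id for t in rank_targets("q", query, db, lo, 1).ranked}
        got_hi = {t.target_id for t in rank_targets("q", query, db, hi, 1).ranked}
        assert got_hi <= got_lo
        got_minfp = {t.target_id for t in rank_targets("q", query, db, lo, 3).ranked}
        assert got_minfp <= got_lo

    def test_score_bounds(self):
        rng = random.Random(7)
        registry = toy_registry()
        db = toy_db(registry, rng, 5, 8)
        thresholds = ThresholdTable({s.name: 0.0 for s in registry.specs}, 95, 0, 0)
        for _ in range(20):
            query = random_row(registry, rng)
            for t in rank_targets("q", query, db, thresholds, 1).ranked:
                assert 0.0 <= t.sc <= 1.0

    def test_tie_break_by_target_id(self):
        registry = toy_registry(1)
        panel = FingerprintPanel(registry)
        fp = [BitFingerprint("fp0", frozenset({1, 2}), N_BITS)]
        panel.add("a1", fp)
        panel.add("b1", fp)
        db = TargetDatabase(
            "Ki",
            [
                TargetEnsemble("TB", "", [("b1", 1.0)]),
                TargetEnsemble("TA", "", [("a1", 1.0)]),
            ],
            {}, {}, "ionized",
        )
        db.panel = panel
        thresholds = ThresholdTable({"fp0": 0.1}, 95, 0, 0)
        result = rank_targets("q", fp, db, thresholds, n_min_fp=1)
        assert [t.target_id for t in result.ranked] == ["TA", "TB"]


class TestPredict:
    def test_self_retrieval_on_chemistry_db(self, small_db, small_thresholds):
        mid = small_db.ensembles[0].molecule_ids[3]
        result = predict_targets(
            ("self", small_db.search_smiles[mid]), small_db, small_thresholds,
            n_min_fp=4, top_k=5,
        )
        assert result.ranked[0].target_id == small_db.ensembles[0].target_id
        assert result.ranked[0].sc == pytest.approx(1.0)

    def test_invalid_query_raises(self, small_db, small_thresholds):
        from targetfish.chemstd import StandardizationError

        with pytest.raises(StandardizationError):
            predict_targets("zz((", small_db, small_thresholds)

    def test_registry_mismatch_rejected(self, small_db):
        bad = ThresholdTable({"MFP1": 0.5}, 95, 0, 0, registry_hash="deadbeef")
        with pytest.raises(ValueError, match="registry"):
            predict_targets("CCO", small_db, bad)

    def test_parameters_recorded(self, small_db, small_thresholds):
        result = predict_targets("CCO", small_db, small_thresholds, n_min_fp=4, top_k=5)
        assert result.parameters["n_min_fp"] == 4
        assert result.parameters["top_k"] == 5
        assert result.parameters["registry_hash"] == small_db.panel.registry_hash
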
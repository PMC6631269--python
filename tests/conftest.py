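"""Shared fixtures: a small synthetic congeneric-series database.

Everything is generated at test time; nothing is read from disk.
"""

import pytest

from targetfish import calibration, dataset, fingerprints, fixtures


@pytest.fixture(scope="session")
def registry():
    return fingerprints.default_registry()


@pytest.fixture(scope="session")
def small_library():
    """3 synthetic targets x 12 analogs, clean records only."""
    specs = fixtures.default_target_specs(n_targets=3, n_analogs=12)
    return fixtures.generate_activity_table(specs, seed=11)


@pytest.fixture(scope="session")
def small_db(small_library, registry):
    retained, _ = dataset.filter_activity_records(small_library.records)
    deduped = dataset.deduplicate_ligand_target(retained)
    db = dataset.build_target_ensembles(deduped, min_ensemble_size=10)
    dataset.prepare_database(db, registry, ionize=True, seed=11)
    return db


@pytest.fixture(scope="session")
def small_thresholds(small_db):
    return calibration.calibrate_from_panel(small_db.panel, n_pairs=5000, m_percent=95, seed=11)
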
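"""Multi-fingerprint consensus target search.

For a query molecule and each target ensemble, the engine computes — per
fingerprint type i — the maximum Tanimoto similarity Tc_i^max between the
query and any ensemble member.  A fingerprint "qualifies" when that maximum
meets or exceeds its calibrated significance threshold Tc_m%.  A target is
paired to the query only if at least ``n_min_fp`` fingerprints qualify, and
its consensus score is

    SC = (1 / N_fp) * sum over qualifying i of Tc_i^max

with N_fp the registry size, so SC is bounded by [0, 1] and reaches 1 only
when every fingerprint finds an identical ensemble compound.  Ranking is by
SC descending; the normalizing constant is the registry size by convention —
any fixed constant yields the identical ranking.  Ties break by number of
qualifying fingerprints (descending), then target id (ascending).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import chemstd
from .calibration import ThresholdTable
from .dataset import TargetDatabase, TargetEnsemble
from .fingerprints import BitFingerprint, FingerprintPanel, bulk_tanimoto, tanimoto

__all__ = [
    "TargetScore",
    "QueryResult",
    "max_tc_per_fp",
    "score_target",
    "rank_targets",
    "predict_targets",
]


@dataclass(frozen=True)
class TargetScore:
    """One scored (query, target) pairing with its per-fingerprint evidence."""

    target_id: str
    target_name: str
    sc: float
    qualifying_fp_count: int
    evidence: dict[str, tuple[float, str]]  # spec -> (tc_max, best molecule)


@dataclass
class QueryResult:
    """Ranked targets for one query, with the full parameter provenance."""

    query_id: str
    ranked: list[TargetScore]
    parameters: dict = field(default_factory=dict)


def max_tc_per_fp(
    query_row: Sequence[BitFingerprint],
    ensemble: TargetEnsemble,
    panel: FingerprintPanel,
) -> dict[str, tuple[float, str]]:
    """Per-fingerprint maximum Tc between the query and the ensemble.

    Returns spec_name -> (tc_max, molecule id attaining it; first member on
    ties).  The query row must be aligned to the panel's registry.
    """
    member_ids = [m for m in ensemble.molecule_ids if m in panel.rows]
    if not member_ids:
        raise ValueError(f"ensemble {ensemble.target_id} has no fingerprinted members")
    out: dict[str, tuple[float, str]] = {}
    pos = panel.position()
    rows = np.fromiter((pos[m] for m in member_ids), dtype=np.int64)
    for qfp, spec in zip(query_row, panel.registry.specs):
        if qfp.spec_name != spec.name:
            raise ValueError("query row is not aligned to the panel registry")
        ids, mat, pops = panel.packed(spec.name)
        tc = bulk_tanimoto(qfp, mat[rows], pops[rows])
        best = int(np.argmax(tc))
        out[spec.name] = (float(tc[best]), member_ids[best])
    return out


def score_target(
    tc_max_map: Mapping[str, tuple[float, str]] | Mapping[str, float],
    thresholds: ThresholdTable,
    n_min_fp: int,
    *,
    target_id: str = "",
    target_name: str = "",
) -> TargetScore | None:
    """Apply the qualification rule and the consensus score.

    ``tc_max_map`` maps spec name to tc_max (optionally with the argmax
    molecule).  Qualification is ``tc_max >= threshold`` (meets-or-exceeds).
    Returns None when fewer than ``n_min_fp`` fingerprints qualify.
    """
    n_specs = len(thresholds)
    evidence: dict[str, tuple[float, str]] = {}
    for name, entry in tc_max_map.items():
        tc_max, best = entry if isinstance(entry, tuple) else (entry, "")
        if tc_max >= thresholds[name]:
            evidence[name] = (tc_max, best)
    if len(evidence) < n_min_fp:
        return None
    sc = sum(tc for tc, _ in evidence.values()) / n_specs
    return TargetScore(
        target_id=target_id,
        target_name=target_name,
        sc=sc,
        qualifying_fp_count=len(evidence),
        evidence=evidence,
    )


def rank_targets(
    query_id: str,
    query_row: Sequence[BitFingerprint],
    db: TargetDatabase,
    thresholds: ThresholdTable,
    n_min_fp: int = 4,
    top_k: int | None = None,
    *,
    exclude_molecule: str | None = None,
) -> QueryResult:
    """Score every ensemble for a precomputed query fingerprint row and rank.

    ``exclude_molecule`` removes one molecule id from every ensemble before
    scoring (leave-one-out evaluation without rebuilding the database).
    """
    if db.panel is None:
        raise ValueError("database has no fingerprint panel; run prepare_database")
    if thresholds.registry_hash and thresholds.registry_hash != db.panel.registry_hash:
        raise ValueError("threshold table was calibrated under a different registry")
    scores: list[TargetScore] = []
    for ens in db.ensembles:
        if exclude_molecule is not None and exclude_molecule in ens.molecule_ids:
            ens = TargetEnsemble(
                ens.target_id,
                ens.target_name,
                [(m, v) for m, v in ens.members if m != exclude_molecule],
            )
            if not ens.members:
                continue
        tc_map = max_tc_per_fp(query_row, ens, db.panel)
        ts = score_target(
            tc_map, thresholds, n_min_fp,
            target_id=ens.target_id, target_name=ens.target_name,
        )
        if ts is not None:
            scores.append(ts)
    scores.sort(key=lambda t: (-t.sc, -t.qualifying_fp_count, t.target_id))
    if top_k is not None:
        scores = scores[:top_k]
    return QueryResult(
        query_id=query_id,
        ranked=scores,
        parameters={
            "m_percent": thresholds.m_percent,
            "n_min_fp": n_min_fp,
            "top_k": top_k,
            "registry_hash": db.panel.registry_hash,
            "db": dict(db.provenance),
        },
    )


def _query_row(query, db: TargetDatabase):
    """Fingerprint a query under the database registry, matching its
    neutral/ionized representation."""
    from .fingerprints import compute_fingerprint
    from rdkit import Chem

    if isinstance(query, str):
        query = chemstd.RawStructure("query", query)
    elif isinstance(query, tuple):
        query = chemstd.RawStructure(*query)
    if isinstance(query, chemstd.RawStructure):
        std = chemstd.standardize(query)
        query = (
            chemstd.ionize_at_ph(std) if db.representation == "ionized" else std
        )
    mol = Chem.MolFromSmiles(query.smiles)
    if mol is None:
        raise chemstd.StandardizationError(f"query SMILES {query.smiles!r} is invalid")
    row = []
    for spec in db.panel.registry.specs:
        try:
            row.append(compute_fingerprint(mol, spec))
        except Exception as exc:
            raise ValueError(f"fingerprint {spec.name} failed for query: {exc}") from exc
    return query.source_id, row


def predict_targets(
    query,
    db: TargetDatabase,
    thresholds: ThresholdTable,
    n_min_fp: int = 4,
    top_k: int | None = 5,
) -> QueryResult:
    """Rank candidate protein targets for a query molecule.

    ``query`` may be a SMILES string, a raw structure, or an already
    standardized/ionized structure; standardization and protonation are
    applied as needed to match the database representation.
    """
    if db.panel is None:
        raise ValueError("database has no fingerprint panel; run prepare_database")
    qid, row = _query_row(query, db)
    return rank_targets(qid, row, db, thresholds, n_min_fp=n_min_fp, top_k=top_k)
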
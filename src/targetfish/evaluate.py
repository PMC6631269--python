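"""Validation harnesses: top-k hold-out accuracy and pH-sensitivity analysis.

Two annotation protocols are supported for the top-1/top-5 statistics.
``single_random_annotation`` draws, per query, one of its experimentally
annotated targets at random and asks whether that one target is retrieved
(the classic external-set protocol).  ``scan_all_annotations`` counts a hit
when ANY annotated target of the query appears in the top k — the more
realistic reading when ligands carry several genuine annotations, and the
default here.

The pH-sensitivity analysis compares, pair by pair, the Tc computed with
both partners neutral against the Tc with both partners ionized at pH 7.4,
and classifies each pair against the fingerprint's significance threshold
into four quadrants: below/below, above/above, awarded (significant only
after ionization) and penalized (significance lost upon ionization).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import ThresholdTable, pair_tanimotos
from .dataset import ActivityRecord, TargetDatabase
from .fingerprints import FingerprintPanel
from .search import predict_targets

__all__ = [
    "AnnotatedQuery",
    "TopKReport",
    "QuadrantRecord",
    "QuadrantSummary",
    "make_holdout",
    "evaluate_topk",
    "first_hit_rank",
    "quadrant_classify",
    "ionization_sensitivity",
]

QUADRANTS = ("below_below", "above_above", "awarded", "penalized")


@dataclass(frozen=True)
class AnnotatedQuery:
    """A hold-out molecule with its experimentally annotated targets."""

    molecule_id: str
    smiles: str
    true_targets: frozenset

    def __post_init__(self):
        if not self.true_targets:
            raise ValueError("a query must have at least one annotated target")


@dataclass
class TopKReport:
    """Top-1/top-5 retrieval statistics over a query set."""

    protocol: str
    n: int
    p1: float  # percentage
    p5: float  # percentage
    ranks: dict[str, int | None]  # query -> rank of first true target (None = unranked)
    seed: int


@dataclass(frozen=True)
class QuadrantRecord:
    pair: tuple[str, str]
    spec_name: str
    tc_neutral: float
    tc_ionized: float
    klass: str


@dataclass
class QuadrantSummary:
    """Per-fingerprint quadrant counts and pH-dependence flags."""

    counts: dict[str, dict[str, int]]      # spec -> klass -> count
    ph_dependent: dict[str, bool]          # spec -> any pair with differing Tc
    n_pairs: int


def make_holdout(
    records: Sequence[ActivityRecord], n_holdout: int, seed: int
) -> tuple[list[ActivityRecord], list[AnnotatedQuery]]:
    """Randomly hold out molecules (with ALL their annotations) for validation.

    Held-out molecules are removed from the training records entirely; each
    becomes a query annotated with every target it was measured on.
    """
    mol_ids = sorted({r.molecule_id for r in records})
    if n_holdout >= len(mol_ids):
        raise ValueError(
            f"cannot hold out {n_holdout} of {len(mol_ids)} distinct molecules"
        )
    rng = random.Random(seed)
    held = set(rng.sample(mol_ids, n_holdout))
    training = [r for r in records if r.molecule_id not in held]
    queries = []
    for mid in sorted(held):
        mine = [r for r in records if r.molecule_id == mid]
        queries.append(
            AnnotatedQuery(
                molecule_id=mid,
                smiles=mine[0].smiles,
                true_targets=frozenset(r.target_id for r in mine),
            )
        )
    return training, queries


def evaluate_topk(
    queries: Sequence[AnnotatedQuery],
    db: TargetDatabase,
    thresholds: ThresholdTable,
    n_min_fp: int = 4,
    protocol: str = "scan_all_annotations",
    seed: int = 0,
) -> TopKReport:
    """Top-1/top-5 accuracy of the consensus search over annotated queries.

    Queries whose ranked list is empty count as misses.  Under
    ``single_random_annotation`` one true target per query is drawn with
    ``seed`` and must itself be retrieved; under ``scan_all_annotations`` any
    true target counts.
    """
    if not queries:
        raise ValueError("no queries to evaluate")
    if protocol not in ("scan_all_annotations", "single_random_annotation"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = random.Random(seed)
    ranks: dict[str, int | None] = {}
    for q in queries:
        if protocol == "single_random_annotation":
            wanted = {rng.choice(sorted(q.true_targets))}
        else:
            wanted = set(q.true_targets)
        result = predict_targets(
            _as_query(q), db, thresholds, n_min_fp=n_min_fp, top_k=None
        )
        ranks[q.molecule_id] = first_hit_rank(
            [ts.target_id for ts in result.ranked], wanted
        )
    n = len(queries)
    p1 = 100.0 * sum(1 for r in ranks.values() if r is not None and r <= 1) / n
    p5 = 100.0 * sum(1 for r in ranks.values() if r is not None and r <= 5) / n
    return TopKReport(protocol=protocol, n=n, p1=p1, p5=p5, ranks=ranks, seed=seed)


def first_hit_rank(ranked_target_ids: Sequence[str], wanted: set) -> int | None:
    """1-based rank of the first wanted target in a ranking (None if absent)."""
    for i, tid in enumerate(ranked_target_ids, start=1):
        if tid in wanted:
            return i
    return None


def _as_query(q: AnnotatedQuery):
    from .chemstd import RawStructure

    return RawStructure(q.molecule_id, q.smiles)


def quadrant_classify(tc_neutral: float, tc_ionized: float, threshold: float) -> str:
    """Classify one pair against a significance threshold.

    The boundary (Tc equal to the threshold) counts as "above", matching the
    meets-or-exceeds rule used by the search.
    """
    above_n = tc_neutral >= threshold
    above_i = tc_ionized >= threshold
    if above_n and above_i:
        return "above_above"
    if not above_n and not above_i:
        return "below_below"
    return "awarded" if above_i else "penalized"


def ionization_sensitivity(
    pairs: Sequence[tuple[str, str]],
    panel_neutral: FingerprintPanel,
    panel_ionized: FingerprintPanel,
    thresholds: ThresholdTable,
    *,
    keep_records: bool = False,
) -> QuadrantSummary | tuple[QuadrantSummary, list[QuadrantRecord]]:
    """Four-quadrant neutral-vs-ionized similarity comparison per fingerprint.

    The same pair list must be fingerprinted under both protonation forms
    with one registry.  A fingerprint is flagged pH-dependent when any pair's
    Tc differs between the two forms.
    """
    if panel_neutral.registry_hash != panel_ionized.registry_hash:
        raise ValueError("neutral and ionized panels use different registries")
    tc_n = pair_tanimotos(panel_neutral, pairs)
    tc_i = pair_tanimotos(panel_ionized, pairs)
    counts: dict[str, dict[str, int]] = {}
    ph_dependent: dict[str, bool] = {}
    records: list[QuadrantRecord] = []
    for spec in panel_neutral.registry.specs:
        t = thresholds[spec.name]
        vn, vi = tc_n[spec.name], tc_i[spec.name]
        spec_counts = dict.fromkeys(QUADRANTS, 0)
        for k, pair in enumerate(pairs):
            klass = quadrant_classify(float(vn[k]), float(vi[k]), t)
            spec_counts[klass] += 1
            if keep_records:
                records.append(
                    QuadrantRecord(pair, spec.name, float(vn[k]), float(vi[k]), klass)
                )
        counts[spec.name] = spec_counts
        ph_dependent[spec.name] = bool(np.any(vn != vi))
    summary = QuadrantSummary(counts=counts, ph_dependent=ph_dependent, n_pairs=len(pairs))
    return (summary, records) if keep_records else summary
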
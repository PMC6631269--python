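"""Curated activity database construction.

Raw bioactivity tables (ChEMBL-style) mix assay qualities, molecule classes
and measurement types.  The curation applied here keeps only records that
are unambiguous enough to anchor a similarity search:

* small molecules only, prodrugs excluded;
* single-protein or protein-complex targets (no organism restriction, so
  antibacterial/antiviral targets are retained);
* no data-validity warnings and assay confidence score strictly above 5;
* standard_type in {IC50, Ki, Kd, EC50} with standard_relation not '>'
  (a ">" bound says nothing about how active the compound actually is);
* values reported in nM (added rule: comparing "best" values across units
  is meaningless).

Rules are evaluated in that order and each rejected record is attributed to
the first rule it fails, which makes the report counts an exact partition:
n_in = n_out + sum of per-rule rejections.

After filtering, each (ligand, target) annotation is deduplicated to the
lowest (best) activity value, and targets with at least ``min_ensemble_size``
distinct ligands become searchable target ensembles, grouped per activity
type (Ki and IC50 databases by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

from .fingerprints import (
    BitFingerprint,
    FingerprintPanel,
    FingerprintSpec,
    Registry,
    compute_panel,
    pack_bits,
)

__all__ = [
    "ActivityRecord",
    "FilterReport",
    "TargetEnsemble",
    "TargetDatabase",
    "SchemaError",
    "filter_activity_records",
    "deduplicate_ligand_target",
    "build_target_ensembles",
    "prepare_database",
    "load_activity_table",
    "save_activity_table",
    "save_database",
    "load_database",
]

SCHEMA_VERSION = 1

ALLOWED_STANDARD_TYPES = ("IC50", "Ki", "Kd", "EC50")
DEFAULT_DATABASE_TYPES = ("Ki", "IC50")  # Kd/EC50 pass the filter but are built on request
ALLOWED_TARGET_TYPES = ("SINGLE PROTEIN", "SINGLE_PROTEIN", "PROTEIN COMPLEX")


class SchemaError(ValueError):
    """Raised when an activity table's columns cannot be resolved."""


@dataclass(frozen=True)
class ActivityRecord:
    """One ligand-target activity annotation."""

    molecule_id: str
    smiles: str
    target_id: str
    target_name: str = ""
    molecule_type: str = "Small molecule"
    is_prodrug: bool = False
    target_type: str = "SINGLE PROTEIN"
    organism: str = ""  # informational only; never filtered on
    standard_type: str = "Ki"
    standard_relation: str = "="
    standard_value: float | None = None
    standard_units: str = "nM"
    confidence_score: int | None = None
    data_validity_comment: str = ""


@dataclass
class FilterReport:
    """Per-rule rejection counts under first-failing-rule attribution."""

    rule_counts: dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    @property
    def n_rejected(self) -> int:
        return sum(self.rule_counts.values())


@dataclass
class TargetEnsemble:
    """All curated ligands of one protein target, with best activity each."""

    target_id: str
    target_name: str
    members: list[tuple[str, float]]  # (molecule_id, best_activity_value)

    @property
    def molecule_ids(self) -> list[str]:
        return [m for m, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TargetDatabase:
    """A searchable activity-type-homogeneous database of target ensembles."""

    activity_tag: str
    ensembles: list[TargetEnsemble]
    smiles: dict[str, str]          # molecule_id -> source SMILES
    provenance: dict = field(default_factory=dict)
    representation: str = "neutral"  # or "ionized"
    search_smiles: dict[str, str] = field(default_factory=dict)
    panel: FingerprintPanel | None = None

    @property
    def target_ids(self) -> list[str]:
        return [e.target_id for e in self.ensembles]

    def ensemble(self, target_id: str) -> TargetEnsemble:
        for e in self.ensembles:
            if e.target_id == target_id:
                return e
        raise KeyError(target_id)

    def __len__(self) -> int:
        return len(self.ensembles)


# ---------------------------------------------------------------------------
# filtering

def _rule_malformed(r: ActivityRecord) -> bool:
    return not (
        r.molecule_id
        and r.smiles
        and r.target_id
        and r.standard_value is not None
        and r.standard_value > 0
        and r.confidence_score is not None
    )


_FILTER_RULES: list[tuple[str, callable]] = [
    ("malformed", _rule_malformed),
    ("molecule_type", lambda r: r.molecule_type != "Small molecule"),
    ("prodrug", lambda r: bool(r.is_prodrug)),
    ("target_type", lambda r: r.target_type not in ALLOWED_TARGET_TYPES),
    ("data_validity", lambda r: bool((r.data_validity_comment or "").strip())),
    ("confidence", lambda r: not (r.confidence_score > 5)),
    ("standard_type", lambda r: r.standard_type not in ALLOWED_STANDARD_TYPES),
    ("standard_relation", lambda r: r.standard_relation == ">"),
    ("units", lambda r: r.standard_units != "nM"),
]

FILTER_RULE_NAMES = [name for name, _ in _FILTER_RULES]


def filter_activity_records(
    records: Sequence[ActivityRecord], *, require_nm_units: bool = True
) -> tuple[list[ActivityRecord], FilterReport]:
    """Apply the curation rules; reject under the first failing rule.

    Confidence must be strictly greater than 5; a score of exactly 5 is
    rejected.  The trailing ``units`` rule is an addition beyond the source
    criteria and can be disabled.
    """
    rules = [
        (name, fn)
        for name, fn in _FILTER_RULES
        if require_nm_units or name != "units"
    ]
    report = FilterReport(rule_counts={name: 0 for name, _ in rules}, n_in=len(records))
    retained: list[ActivityRecord] = []
    for rec in records:
        for name, fails in rules:
            if fails(rec):
                report.rule_counts[name] += 1
                break
        else:
            retained.append(rec)
    report.n_out = len(retained)
    return retained, report


def deduplicate_ligand_target(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Keep, per (molecule, target), the record with the lowest (best) value.

    Ties keep the first record in input order.
    """
    best: dict[tuple[str, str], ActivityRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.molecule_id, rec.target_id)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.standard_value < best[key].standard_value:
            best[key] = rec
    return [best[k] for k in order]


def build_target_ensembles(
    records: Sequence[ActivityRecord],
    min_ensemble_size: int = 10,
    activity_tag: str | None = None,
) -> TargetDatabase:
    """Group deduplicated records into per-target ensembles.

    Targets with fewer than ``min_ensemble_size`` distinct ligands are
    dropped.  A ligand annotated on several targets appears in each of their
    ensembles.  An input yielding zero surviving targets gives an empty
    database (with a provenance warning), not an error.
    """
    tags = {r.standard_type for r in records}
    if activity_tag is None:
        if len(tags) > 1:
            raise ValueError(f"records mix activity types {sorted(tags)}; pass activity_tag")
        activity_tag = next(iter(tags)) if tags else "Ki"
    else:
        records = [r for r in records if r.standard_type == activity_tag]

    by_target: dict[str, list[ActivityRecord]] = {}
    t_order: list[str] = []
    for rec in records:
        if rec.target_id not in by_target:
            by_target[rec.target_id] = []
            t_order.append(rec.target_id)
        by_target[rec.target_id].append(rec)

    ensembles = []
    smiles: dict[str, str] = {}
    for tid in t_order:
        recs = by_target[tid]
        if len({r.molecule_id for r in recs}) < min_ensemble_size:
            continue
        ensembles.append(
            TargetEnsemble(
                target_id=tid,
                target_name=recs[0].target_name,
                members=[(r.molecule_id, r.standard_value) for r in recs],
            )
        )
        for r in recs:
            smiles.setdefault(r.molecule_id, r.smiles)

    provenance = {
        "activity_tag": activity_tag,
        "min_ensemble_size": min_ensemble_size,
        "n_input_records": len(records),
        "n_targets": len(ensembles),
        "n_molecules": len(smiles),
    }
    if not ensembles:
        provenance["warning"] = "no target reached the minimum ensemble size"
    return TargetDatabase(
        activity_tag=activity_tag,
        ensembles=ensembles,
        smiles=smiles,
        provenance=provenance,
    )


def prepare_database(
    db: TargetDatabase,
    registry: Registry,
    *,
    ionize: bool = True,
    ph: float = 7.4,
    seed: int = 0,
) -> TargetDatabase:
    """Standardize and (optionally) ionize the library, then fingerprint it.

    The search representation (neutral vs pH-ionized) is recorded in the
    database so queries and calibration can match it.
    """
    from . import chemstd

    structures: list = []
    failures: list[tuple[str, str]] = []
    for mid, smi in db.smiles.items():
        try:
            std = chemstd.standardize(chemstd.RawStructure(mid, smi), seed=seed)
            structures.append(chemstd.ionize_at_ph(std, ph=ph) if ionize else std)
        except chemstd.StandardizationError as exc:
            failures.append((mid, str(exc)))
    db.representation = "ionized" if ionize else "neutral"
    db.search_smiles = {s.source_id: s.smiles for s in structures}
    db.panel = compute_panel(structures, registry)
    db.provenance.update(
        {
            "ionization_ph": ph if ionize else None,
            "build_seed": seed,
            "registry_hash": registry.registry_hash,
            "standardization_failures": failures,
        }
    )
    return db


# ---------------------------------------------------------------------------
# I/O

#: accepted aliases for each canonical activity-table column
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "molecule_id": ("molecule_id", "molregno", "chembl_id", "molecule_chembl_id"),
    "smiles": ("smiles", "canonical_smiles"),
    "target_id": ("target_id", "target_chembl_id", "tid"),
    "target_name": ("target_name", "pref_name"),
    "molecule_type": ("molecule_type",),
    "is_prodrug": ("is_prodrug", "prodrug"),
    "target_type": ("target_type",),
    "organism": ("organism",),
    "standard_type": ("standard_type",),
    "standard_relation": ("standard_relation",),
    "standard_value": ("standard_value",),
    "standard_units": ("standard_units",),
    "confidence_score": ("confidence_score",),
    "data_validity_comment": ("data_validity_comment",),
}

_REQUIRED = ("molecule_id", "smiles", "target_id", "standard_type", "standard_value")


def load_activity_table(path) -> list[ActivityRecord]:
    """Read a TSV/CSV activity table, resolving ChEMBL-style column aliases."""
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias.lower() in lower:
                colmap[canonical] = lower[alias.lower()]
                break
    missing = [c for c in _REQUIRED if c not in colmap]
    if missing:
        raise SchemaError(
            f"activity table {path} is missing required columns {missing}; "
            f"found {list(df.columns)}"
        )

    def get(row, canonical, default=""):
        return row[colmap[canonical]] if canonical in colmap else default

    records = []
    for _, row in df.iterrows():
        value_s = get(row, "standard_value")
        conf_s = get(row, "confidence_score")
        records.append(
            ActivityRecord(
                molecule_id=get(row, "molecule_id"),
                smiles=get(row, "smiles"),
                target_id=get(row, "target_id"),
                target_name=get(row, "target_name"),
                molecule_type=get(row, "molecule_type", "Small molecule"),
                is_prodrug=str(get(row, "is_prodrug", "0")).strip().lower()
                in ("1", "true", "yes"),
                target_type=get(row, "target_type", "SINGLE PROTEIN"),
                organism=get(row, "organism"),
                standard_type=get(row, "standard_type"),
                standard_relation=get(row, "standard_relation", "="),
                standard_value=float(value_s) if value_s != "" else None,
                standard_units=get(row, "standard_units", "nM"),
                confidence_score=int(float(conf_s)) if conf_s != "" else None,
                data_validity_comment=get(row, "data_validity_comment"),
            )
        )
    return records


def save_activity_table(records: Sequence[ActivityRecord], path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep=sep, index=False)


def save_database(db: TargetDatabase, path) -> None:
    """Persist a database (including any fingerprint panel) as one JSON file."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "activity_tag": db.activity_tag,
        "representation": db.representation,
        "provenance": db.provenance,
        "smiles": db.smiles,
        "search_smiles": db.search_smiles,
        "ensembles": [
            {
                "target_id": e.target_id,
                "target_name": e.target_name,
                "members": [[m, v] for m, v in e.members],
            }
            for e in db.ensembles
        ],
    }
    if db.panel is not None:
        doc["panel"] = {
            "registry": [
                [s.name, s.family, s.n_bits, list(s.params)]
                for s in db.panel.registry.specs
            ],
            "rows": {
                mid: [
                    "".join(f"{w:016x}" for w in pack_bits(fp.bits, fp.n_bits))
                    for fp in row
                ]
                for mid, row in db.panel.rows.items()
            },
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _unpack_hex(hex_words: str, n_bits: int, spec_name: str) -> BitFingerprint:
    bits = set()
    for w_i in range(len(hex_words) // 16):
        word = int(hex_words[w_i * 16 : (w_i + 1) * 16], 16)
        base = w_i * 64
        while word:
            lsb = word & -word
            bits.add(base + lsb.bit_length() - 1)
            word ^= lsb
    return BitFingerprint(spec_name, frozenset(bits), n_bits)


def load_database(path) -> TargetDatabase:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported database schema in {path}")
    db = TargetDatabase(
        activity_tag=doc["activity_tag"],
        ensembles=[
            TargetEnsemble(
                target_id=e["target_id"],
                target_name=e["target_name"],
                members=[(m, float(v)) for m, v in e["members"]],
            )
            for e in doc["ensembles"]
        ],
        smiles=doc["smiles"],
        provenance=doc["provenance"],
        representation=doc["representation"],
        search_smiles=doc.get("search_smiles", {}),
    )
    if "panel" in doc:
        specs = [
            FingerprintSpec(name, family, n_bits, tuple(tuple(p) for p in params))
            for name, family, n_bits, params in doc["panel"]["registry"]
        ]
        registry = Registry(specs)
        panel = FingerprintPanel(registry)
        for mid, row in doc["panel"]["rows"].items():
            panel.add(
                mid,
                [
                    _unpack_hex(hex_words, spec.n_bits, spec.name)
                    for hex_words, spec in zip(row, registry.specs)
                ],
            )
        db.panel = panel
    return db
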
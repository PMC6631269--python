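"""Structure standardization and protonation-state handling.

The curation pipeline mirrors what large bioactivity databases require before
any similarity work is meaningful: salt/fragment stripping, normalization of
functional-group depictions, neutralization, stereochemistry recalculation and
— because roughly half of drug-like molecules are ionizable — assignment of
the dominant protonation microspecies at physiological pH (7.4).

The microspecies step is rule based: a bundled SMARTS→pKa table covers the
common drug-like ionizable groups (carboxylic acids, sulfonic/phosphonic
acids, tetrazoles, phenols, thiols, sulfonamides, aliphatic amines, amidines,
guanidines, and the aromatic bases left neutral at 7.4).  Every acid with
pKa below the working pH is deprotonated and every base whose conjugate acid
has pKa above it is protonated, so zwitterions fall out naturally.  This is a
deterministic dominant-species picker, not a pKa predictor.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawStructure",
    "StandardStructure",
    "IonizedStructure",
    "StandardizationError",
    "strip_to_largest_fragment",
    "standardize",
    "standardize_library",
    "dedupe_enantiomers",
    "ionize_at_ph",
    "neutralize",
    "read_smi",
    "write_smi",
]


class StandardizationError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""


@dataclass(frozen=True)
class RawStructure:
    """A structure exactly as provided by the source, before any curation."""

    source_id: str
    smiles: str


@dataclass(frozen=True)
class StandardStructure:
    """A salt-stripped, normalized, neutral-form structure.

    ``flags`` records which corrective steps actually fired so that curation
    reports can attribute changes per molecule.
    """

    source_id: str
    neutral_smiles: str
    flags: dict = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        return self.neutral_smiles


@dataclass(frozen=True)
class IonizedStructure:
    """The dominant protonation microspecies of a structure at a given pH."""

    source_id: str
    ionized_smiles: str
    ph: float
    net_formal_charge: int

    @property
    def smiles(self) -> str:
        return self.ionized_smiles


# ---------------------------------------------------------------------------
# parsing helpers

def _mol_from_smiles(smiles: str) -> tuple[Chem.Mol, bool]:
    """Parse SMILES, attempting a standardizer cleanup on valence failures.

    Returns (mol, had_valence_fix).
    """
    if not smiles or not smiles.strip():
        raise StandardizationError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        return mol, False
    relaxed = Chem.MolFromSmiles(smiles, sanitize=False)
    if relaxed is None:
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")
    try:
        fixed = rdMolStandardize.Cleanup(relaxed)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise StandardizationError(
            f"irrecoverable valence error in {smiles!r}: {exc}"
        ) from exc
    if fixed is None:
        raise StandardizationError(f"irrecoverable valence error in {smiles!r}")
    return fixed, True


def strip_to_largest_fragment(smiles: str) -> tuple[str, bool]:
    """Keep only the largest fragment of a (possibly multi-component) SMILES.

    The largest fragment is the one with the most heavy atoms; ties are broken
    by lexicographic order of the fragments' canonical SMILES so the choice is
    deterministic.  Returns ``(fragment_smiles, was_multifragment)``.
    """
    mol, _ = _mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return Chem.MolToSmiles(frags[0]), False
    keyed = sorted(
        (( -f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)) for f in frags),
    )
    return keyed[0][1], True


_METALS = frozenset(
    [3, 4, 11, 12, 13, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
     37, 38, 39, 40, 42, 46, 47, 48, 49, 50, 55, 56, 78, 79, 80, 81, 82, 83]
)


def standardize(raw: RawStructure, seed: int = 0) -> StandardStructure:
    """Standardize one structure: sanitize, disconnect metals, normalize,
    strip to the largest fragment, neutralize and recalculate stereochemistry.

    Idempotent: standardizing the output again is a fixed point.  ``seed`` is
    accepted for interface symmetry with :func:`standardize_library`, where it
    drives the enantiomer pick; it has no effect on a single molecule.
    """
    mol, had_valence_fix = _mol_from_smiles(raw.smiles)

    had_bonded_metal = any(
        a.GetAtomicNum() in _METALS and a.GetDegree() > 0 for a in mol.GetAtoms()
    )
    if had_bonded_metal:
        mol = rdMolStandardize.MetalDisconnector().Disconnect(mol)
    mol = rdMolStandardize.Normalize(mol)

    frag_smiles, was_multifragment = strip_to_largest_fragment(Chem.MolToSmiles(mol))
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:  # pragma: no cover - normalized fragments re-parse
        raise StandardizationError(f"fragment of {raw.smiles!r} failed to re-parse")

    mol = rdMolStandardize.Uncharger().uncharge(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    return StandardStructure(
        source_id=raw.source_id,
        neutral_smiles=Chem.MolToSmiles(mol),
        flags={
            "was_multifragment": was_multifragment,
            "had_valence_fix": had_valence_fix,
            "metal_disconnected": had_bonded_metal,
            "stereo_recalculated": True,
            "enantiomer_picked": False,
        },
    )


def dedupe_enantiomers(
    structures: Sequence[StandardStructure], seed: int
) -> list[StandardStructure]:
    """Collapse stereoisomer groups to one seeded-random representative.

    Structures are grouped by their canonical SMILES with stereochemistry
    stripped; within each group of more than one distinct member a single
    representative is drawn with ``seed`` (the source data gives no rule
    beyond a random pick, so the seed makes the pick reproducible).
    """
    groups: dict[str, list[StandardStructure]] = {}
    order: list[str] = []
    for s in structures:
        mol = Chem.MolFromSmiles(s.neutral_smiles)
        if mol is None:
            raise StandardizationError(f"invalid standardized SMILES {s.neutral_smiles!r}")
        Chem.RemoveStereochemistry(mol)
        key = Chem.MolToSmiles(mol)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)

    rng = random.Random(seed)
    kept: list[StandardStructure] = []
    for key in order:
        members = groups[key]
        distinct = sorted({m.neutral_smiles for m in members})
        if len(distinct) == 1:
            kept.append(members[0])
            continue
        pick = rng.choice(distinct)
        chosen = next(m for m in members if m.neutral_smiles == pick)
        flags = dict(chosen.flags)
        flags["enantiomer_picked"] = True
        kept.append(StandardStructure(chosen.source_id, chosen.neutral_smiles, flags))
    return kept


def standardize_library(
    raws: Iterable[RawStructure], seed: int = 0
) -> tuple[list[StandardStructure], list[tuple[str, str]]]:
    """Standardize a library and deduplicate stereoisomer groups.

    Returns ``(standardized, failures)`` where failures are
    ``(source_id, reason)`` pairs — parse failures are recorded, never
    silently dropped.
    """
    out: list[StandardStructure] = []
    failures: list[tuple[str, str]] = []
    for raw in raws:
        try:
            out.append(standardize(raw, seed=seed))
        except StandardizationError as exc:
            failures.append((raw.source_id, str(exc)))
    return dedupe_enantiomers(out, seed=seed), failures


# ---------------------------------------------------------------------------
# protonation

def _load_pka_rules() -> list[dict]:
    text = resources.files("targetfish.data").joinpath("pka_rules.yaml").read_text()
    raw = yaml.safe_load(text)["rules"]
    for rule in raw:
        rule["pattern"] = Chem.MolFromSmarts(rule["smarts"])
        if rule["pattern"] is None:  # pragma: no cover - table is validated by tests
            raise ValueError(f"bad SMARTS in pKa table: {rule['smarts']}")
    return raw


_PKA_RULES: list[dict] | None = None


def pka_rules() -> list[dict]:
    """The bundled SMARTS→pKa rule table (parsed once, cached)."""
    global _PKA_RULES
    if _PKA_RULES is None:
        _PKA_RULES = _load_pka_rules()
    return _PKA_RULES


def ionize_at_ph(std: StandardStructure, ph: float = 7.4) -> IonizedStructure:
    """Assign the dominant protonation microspecies at ``ph``.

    Acidic groups with pKa < ph lose a proton; basic groups whose conjugate
    acid has pKa > ph gain one.  Acid and base rules act independently, so
    amino acids and other zwitterions come out doubly charged.  Molecules
    without recognized ionizable groups are returned unchanged.
    """
    mol = Chem.MolFromSmiles(std.neutral_smiles)
    if mol is None:
        raise StandardizationError(f"invalid SMILES {std.neutral_smiles!r}")
    rw = Chem.RWMol(mol)
    touched: set[int] = set()
    for rule in pka_rules():
        fires = (rule["kind"] == "acid" and rule["pka"] < ph) or (
            rule["kind"] == "base" and rule["pka"] > ph
        )
        for match in rw.GetMol().GetSubstructMatches(rule["pattern"]):
            idx = match[rule["site"]]
            if idx in touched:
                continue
            touched.add(idx)  # later (weaker) rules must not re-ionize the site
            if not fires:
                continue
            atom = rw.GetAtomWithIdx(idx)
            if rule["kind"] == "acid":
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
                atom.SetNoImplicit(True)
                atom.SetFormalCharge(atom.GetFormalCharge() - 1)
            else:
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
                atom.SetFormalCharge(atom.GetFormalCharge() + 1)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return IonizedStructure(
        source_id=std.source_id,
        ionized_smiles=Chem.MolToSmiles(out),
        ph=ph,
        net_formal_charge=Chem.GetFormalCharge(out),
    )


def neutralize(smiles: str) -> str:
    """Remove protonation-derived charges; permanent charges (e.g. quaternary
    ammonium) are untouched.  Inverse of :func:`ionize_at_ph` for proton-only
    ionization."""
    mol, _ = _mol_from_smiles(smiles)
    return Chem.MolToSmiles(rdMolStandardize.Uncharger().uncharge(mol))


# ---------------------------------------------------------------------------
# .smi I/O (one "SMILES<TAB>id" per line; ids autogenerated when absent)

def read_smi(path) -> list[RawStructure]:
    raws = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            source_id = parts[1] if len(parts) > 1 else f"mol{i}"
            raws.append(RawStructure(source_id=source_id, smiles=smiles))
    return raws


def write_smi(structures: Iterable[StandardStructure | IonizedStructure], path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.smiles}\t{s.source_id}\n")
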
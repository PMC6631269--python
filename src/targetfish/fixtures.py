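"""Synthetic activity-data generator.

Similarity-based target fishing works because real bioactivity data is
organized in congeneric series: each protein target accumulates analogs
decorated around a handful of scaffolds.  The generator reproduces exactly
that structure — one drug-like scaffold per synthetic target, decorated with
substituents drawn from a shared alphabet — so within-target similarity
exceeds between-target similarity and the whole pipeline (curation,
calibration, search, validation) is exercisable without any external
database.

Activity tables additionally carry, on request, records that each violate
exactly one curation rule, so filter bookkeeping can be checked against the
planted ground truth.  Activity values are lognormal in nM: positive and
right-skewed like real Ki/IC50 data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .dataset import ActivityRecord, save_activity_table

__all__ = [
    "SyntheticTargetSpec",
    "SyntheticLibrary",
    "SCAFFOLDS",
    "DECORATIONS",
    "generate_series",
    "generate_activity_table",
    "default_target_specs",
]

#: drug-like ring systems with one marked attachment point
SCAFFOLDS: tuple[str, ...] = (
    "c1ccc2[nH]c([*:1])nc2c1",          # benzimidazole
    "c1ccc2nc([*:1])ccc2c1",            # quinoline
    "c1ccc2[nH]c([*:1])cc2c1",          # indole
    "c1ccc(-c2ccc([*:1])cc2)cc1",       # biphenyl
    "c1ccc2sc([*:1])nc2c1",             # benzothiazole
    "c1ccc2oc([*:1])nc2c1",             # benzoxazole
    "c1ccc(N2CCN([*:1])CC2)cc1",        # phenylpiperazine
    "c1ccc(S(=O)(=O)N([*:1])C2CC2)cc1", # arylsulfonamide
    "O=c1cc([*:1])oc2ccccc12",          # coumarin (chromen-2-one)
    "c1cnc2[nH]c([*:1])cc2c1",          # azaindole
    "c1ccc(-c2nnc([*:1])o2)cc1",        # phenyloxadiazole
    "c1ccc(-c2cc([*:1])no2)cc1",        # phenylisoxazole
    "c1ccc(-c2ncc([*:1])s2)cc1",        # phenylthiazole
    "c1ccc(C(=O)N2CCC([*:1])CC2)cc1",   # benzoylpiperidine
    "c1cc2cccnc2c(N[*:1])c1",           # aminoquinoline
    "c1ccc(-n2ncc([*:1])c2)cc1",        # phenylpyrazole
    "c1ccc(Oc2ccc([*:1])cn2)cc1",       # aryloxypyridine
    "c1ccc2c(c1)CCN2[*:1]",             # indoline
    "c1ccc(CN2CCC([*:1])C2)cc1",        # benzylpyrrolidine
    "c1nc([*:1])c2cc[nH]c2n1",          # pyrrolopyrimidine
)

#: substituent alphabet (attachment marked); shared across targets
DECORATIONS: tuple[str, ...] = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]C(C)C", "[*:1]C(C)(C)C",
    "[*:1]CCCC", "[*:1]C1CC1", "[*:1]C1CCC1", "[*:1]C1CCCC1",
    "[*:1]F", "[*:1]Cl", "[*:1]Br", "[*:1]C(F)(F)F",
    "[*:1]O", "[*:1]OC", "[*:1]OCC", "[*:1]OC(C)C",
    "[*:1]N", "[*:1]NC", "[*:1]N(C)C", "[*:1]NCC",
    "[*:1]CN", "[*:1]CCN", "[*:1]CCCN", "[*:1]CN(C)C",
    "[*:1]C#N", "[*:1]C=C", "[*:1]C(=O)O", "[*:1]CC(=O)O",
    "[*:1]C(=O)N", "[*:1]C(=O)NC", "[*:1]C(=O)C",
    "[*:1]S(C)(=O)=O", "[*:1]SC", "[*:1]CO", "[*:1]CCO",
    "[*:1]c1ccccc1", "[*:1]Cc1ccccc1", "[*:1]c1ccncc1", "[*:1]c1ccco1",
)


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Recipe for one synthetic target's congeneric series."""

    target_id: str
    scaffold_smiles: str
    n_analogs: int
    decoration_alphabet: tuple[str, ...] = DECORATIONS
    activity_log_mean: float = 4.5   # ln nM; median ~90 nM
    activity_log_sd: float = 1.5
    standard_type: str = "Ki"
    target_name: str = ""

    def __post_init__(self):
        if self.n_analogs < 1:
            raise ValueError("n_analogs must be >= 1")
        if Chem.MolFromSmiles(self.scaffold_smiles) is None:
            raise ValueError(f"invalid scaffold {self.scaffold_smiles!r}")


@dataclass
class SyntheticLibrary:
    """Generated activity records plus the planted ground truth."""

    records: list[ActivityRecord]
    truth: dict[str, frozenset]  # molecule_id -> true target ids
    seed: int


def _attach(scaffold: str, decoration: str) -> str | None:
    scaf = Chem.MolFromSmiles(scaffold)
    deco = Chem.MolFromSmiles(decoration)
    if scaf is None or deco is None:
        return None
    try:
        combined = Chem.molzip(scaf, deco)
        Chem.SanitizeMol(combined)
        return Chem.MolToSmiles(combined)
    except Exception:
        return None


def _bare(scaffold: str) -> str:
    scaf = Chem.MolFromSmiles(scaffold)
    stripped = AllChem.ReplaceSubstructs(
        scaf, Chem.MolFromSmarts("[#0]"), Chem.MolFromSmiles("[H]"), replaceAll=True
    )[0]
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.RemoveHs(stripped)))
    return Chem.MolToSmiles(mol)


def generate_series(spec: SyntheticTargetSpec, seed: int) -> list[tuple[str, str]]:
    """Generate ``n_analogs`` distinct valid molecules sharing one scaffold.

    The first analog is the bare scaffold; the rest attach seeded-random
    distinct decorations.  A decoration producing an invalid molecule is
    resampled (and would exhaust into an error only if the whole alphabet
    fails).
    """
    rng = random.Random(seed)
    out: list[tuple[str, str]] = [(f"{spec.target_id}_m0", _bare(spec.scaffold_smiles))]
    pool = list(spec.decoration_alphabet)
    rng.shuffle(pool)
    seen = {out[0][1]}
    i = 1
    while len(out) < spec.n_analogs:
        if not pool:
            raise ValueError(
                f"decoration alphabet exhausted for {spec.target_id}: "
                f"only {len(out)} of {spec.n_analogs} analogs generated"
            )
        smiles = _attach(spec.scaffold_smiles, pool.pop())
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        out.append((f"{spec.target_id}_m{i}", smiles))
        i += 1
    return out


#: how to mutate a clean record so it violates exactly the named rule
_VIOLATORS = {
    "malformed": lambda r: _replace(r, standard_value=None),
    "molecule_type": lambda r: _replace(r, molecule_type="Protein"),
    "prodrug": lambda r: _replace(r, is_prodrug=True),
    "target_type": lambda r: _replace(r, target_type="ORGANISM"),
    "data_validity": lambda r: _replace(r, data_validity_comment="Potential transcription error"),
    "confidence": lambda r: _replace(r, confidence_score=5),
    "standard_type": lambda r: _replace(r, standard_type="Potency"),
    "standard_relation": lambda r: _replace(r, standard_relation=">"),
    "units": lambda r: _replace(r, standard_units="ug.mL-1"),
}


def _replace(rec: ActivityRecord, **changes) -> ActivityRecord:
    from dataclasses import replace

    return replace(rec, **changes)


def generate_activity_table(
    specs: Sequence[SyntheticTargetSpec],
    violation_counts: Mapping[str, int] | None = None,
    seed: int = 0,
    n_duplicates: int = 0,
) -> SyntheticLibrary:
    """Generate a full activity table: clean congeneric records plus exactly
    the requested number of single-rule violators.

    Clean records carry relation '=', units nM, confidence 8 and lognormal
    activity values.  ``n_duplicates`` plants extra same-(ligand, target)
    annotations with different values to exercise best-value deduplication.
    """
    if not specs:
        raise ValueError("need at least one target spec")
    violation_counts = dict(violation_counts or {})
    for rule in violation_counts:
        if rule not in _VIOLATORS:
            raise ValueError(
                f"unknown violation rule {rule!r}; known: {sorted(_VIOLATORS)}"
            )
    rng = np.random.default_rng(seed)
    records: list[ActivityRecord] = []
    truth: dict[str, set] = {}
    for k, spec in enumerate(specs):
        series = generate_series(spec, seed=seed + 7919 * k)
        values = np.exp(
            rng.normal(spec.activity_log_mean, spec.activity_log_sd, size=len(series))
        )
        for (mid, smiles), val in zip(series, values):
            records.append(
                ActivityRecord(
                    molecule_id=mid,
                    smiles=smiles,
                    target_id=spec.target_id,
                    target_name=spec.target_name or spec.target_id,
                    standard_type=spec.standard_type,
                    standard_relation="=",
                    standard_value=float(round(val, 3)),
                    standard_units="nM",
                    confidence_score=8,
                )
            )
            truth.setdefault(mid, set()).add(spec.target_id)

    clean = list(records)
    py_rng = random.Random(seed)
    for _ in range(n_duplicates):
        template = py_rng.choice(clean)
        records.append(
            _replace(template, standard_value=float(round(template.standard_value * py_rng.uniform(1.5, 10.0), 3)))
        )
    for rule in sorted(violation_counts):
        for _ in range(violation_counts[rule]):
            records.append(_VIOLATORS[rule](py_rng.choice(clean)))

    return SyntheticLibrary(
        records=records,
        truth={m: frozenset(t) for m, t in truth.items()},
        seed=seed,
    )


def default_target_specs(
    n_targets: int = 20,
    n_analogs: int = 30,
    standard_type: str = "Ki",
) -> list[SyntheticTargetSpec]:
    """One spec per bundled scaffold (cycled if ``n_targets`` exceeds them)."""
    specs = []
    for i in range(n_targets):
        specs.append(
            SyntheticTargetSpec(
                target_id=f"T{i:03d}",
                scaffold_smiles=SCAFFOLDS[i % len(SCAFFOLDS)],
                n_analogs=n_analogs,
                standard_type=standard_type,
                target_name=f"synthetic target {i}",
            )
        )
    return specs


def write_library(lib: SyntheticLibrary, activities_path, truth_path=None) -> None:
    """Write the activity table (and optionally the truth map) as TSV."""
    save_activity_table(lib.records, activities_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("molecule_id\ttarget_ids\n")
            for mid in sorted(lib.truth):
                fh.write(f"{mid}\t{','.join(sorted(lib.truth[mid]))}\n")
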
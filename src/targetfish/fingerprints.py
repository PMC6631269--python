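"""Registry-driven fingerprint panel and Tanimoto similarity.

The consensus search rests on a panel of 13 structurally complementary binary
fingerprints: circular (ECFP/FCFP-like), atom-pair, topological-torsion,
hashed linear/branched path, SMARTS-pattern and several key-based set types,
plus two path fingerprints with deliberately coarse atom invariants
(element-only with bond orders masked, and hybridization-state-only).
A :class:`Registry` freezes the panel composition and ordering; panels are
comparable only when their registry digests match.

Providers: the host toolkit (RDKit) serves the circular, atom-pair, torsion,
pattern and path types; Open Babel's FP2 serves the linear-fragment type;
MACCS comes from RDKit's 166-key implementation.  The ``pubchem``,
``klekota_roth`` and ``substructure`` specs load package-authored, reduced
SMARTS key sets (files suffixed ``_synthetic``) that emulate the flavour of
those families at a fraction of their key counts; the search algorithm is
agnostic to the exact provider, and per-fingerprint significance thresholds
are always calibrated against whatever panel is registered.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

__all__ = [
    "FingerprintSpec",
    "BitFingerprint",
    "Registry",
    "FingerprintPanel",
    "register_panel",
    "default_registry",
    "compute_fingerprint",
    "compute_panel",
    "tanimoto",
    "pack_bits",
]

FAMILIES = frozenset({"circular", "atom-pair", "torsion", "hashed-path", "smarts-keys"})


@dataclass(frozen=True)
class FingerprintSpec:
    """One fingerprint type: name, algorithmic family, length and parameters."""

    name: str
    family: str
    n_bits: int
    params: tuple = ()  # sorted (key, value) pairs; hashable

    @staticmethod
    def make(name: str, family: str, n_bits: int, **params) -> "FingerprintSpec":
        return FingerprintSpec(name, family, n_bits, tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class BitFingerprint:
    """A binary fingerprint: the set of on-bit indices under one spec."""

    spec_name: str
    bits: frozenset
    n_bits: int

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index out of range")


class Registry:
    """An immutable, ordered fingerprint panel definition.

    The digest (``registry_hash``) covers names, families, lengths and
    parameters, so two panels are comparable exactly when their registries
    were built from the same spec list.
    """

    def __init__(self, specs: Sequence[FingerprintSpec]):
        if not specs:
            raise ValueError("registry needs at least one spec")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate fingerprint names in {names}")
        for s in specs:
            if s.family not in FAMILIES:
                raise ValueError(f"unknown family {s.family!r} for {s.name}")
            if s.n_bits <= 0:
                raise ValueError(f"n_bits must be positive for {s.name}")
        self._specs = tuple(specs)
        self._index = {s.name: i for i, s in enumerate(specs)}
        payload = json.dumps(
            [[s.name, s.family, s.n_bits, list(s.params)] for s in specs]
        )
        self.registry_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def specs(self) -> tuple[FingerprintSpec, ...]:
        return self._specs

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def __len__(self) -> int:
        return len(self._specs)

    def __getitem__(self, name: str) -> FingerprintSpec:
        return self._specs[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]


def register_panel(specs: Sequence[FingerprintSpec]) -> Registry:
    """Freeze a spec list into an immutable, hashed registry."""
    return Registry(specs)


def default_registry() -> Registry:
    """The standard 13-fingerprint panel."""
    return Registry(
        [
            FingerprintSpec.make("MFP1", "circular", 2048, radius=1, features=False),
            FingerprintSpec.make("FeatMFP1", "circular", 2048, radius=1, features=True),
            FingerprintSpec.make("AP_bits", "atom-pair", 2048),
            FingerprintSpec.make("Pattern", "hashed-path", 2048, variant="pattern"),
            FingerprintSpec.make("RDKit7", "hashed-path", 2048, variant="rdkit", max_path=7),
            FingerprintSpec.make("TT_bits", "torsion", 2048),
            FingerprintSpec.make("FP2", "hashed-path", 1024, variant="fp2"),
            FingerprintSpec.make(
                "pubchem", "smarts-keys", _key_count("pubchem_synthetic.smarts"),
                key_file="pubchem_synthetic.smarts",
            ),
            FingerprintSpec.make("cdk_maccs", "smarts-keys", 166, builtin="maccs"),
            FingerprintSpec.make(
                "klekota_roth", "smarts-keys", _key_count("klekota_roth_synthetic.smarts"),
                key_file="klekota_roth_synthetic.smarts",
            ),
            FingerprintSpec.make("graph", "hashed-path", 1024, variant="graph", max_path=7),
            FingerprintSpec.make(
                "substructure", "smarts-keys", _key_count("substructure_synthetic.smarts"),
                key_file="substructure_synthetic.smarts",
            ),
            FingerprintSpec.make(
                "hybridization", "hashed-path", 1024, variant="hybridization", max_path=7
            ),
        ]
    )


# ---------------------------------------------------------------------------
# SMARTS key sets

_KEY_CACHE: dict[str, list[tuple[int, Chem.Mol, int]]] = {}


def _load_keys(key_file: str) -> list[tuple[int, Chem.Mol, int]]:
    """Parse a key-definition file: ``index<TAB>SMARTS[<TAB>min_count]``.

    A key is set when the molecule has at least ``min_count`` (default 1)
    distinct matches of the SMARTS; '#' lines are comments.
    """
    if key_file in _KEY_CACHE:
        return _KEY_CACHE[key_file]
    text = resources.files("targetfish.data.keys").joinpath(key_file).read_text()
    keys = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        idx_s, smarts = parts[0], parts[1].strip()
        min_count = int(parts[2]) if len(parts) > 2 else 1
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in {key_file}: {smarts!r}")
        keys.append((int(idx_s), patt, min_count))
    if not keys:
        raise ValueError(f"empty key file {key_file}")
    _KEY_CACHE[key_file] = keys
    return keys


def _key_count(key_file: str) -> int:
    return max(i for i, _, _ in _load_keys(key_file)) + 1


# ---------------------------------------------------------------------------
# providers

def _path_fingerprint(mol: Chem.Mol, n_bits: int, max_path: int, invariant: str) -> frozenset:
    """Hashed linear-path fingerprint with masked bond orders.

    Enumerates all simple paths of 1..max_path atoms, labels atoms with a
    single coarse invariant (element for ``graph``, hybridization state for
    ``hybridization``), takes the lexicographically smaller direction of each
    path and hashes it (CRC32) into ``n_bits`` buckets.  Formal charge, bond
    order and aromaticity never enter the invariant, so the ``graph`` variant
    is charge-blind by construction.
    """
    if invariant == "element":
        labels = [a.GetAtomicNum() for a in mol.GetAtoms()]
    elif invariant == "hybridization":
        labels = [int(a.GetHybridization()) for a in mol.GetAtoms()]
    else:  # pragma: no cover
        raise ValueError(f"unknown invariant {invariant!r}")

    adjacency = [
        [b.GetOtherAtomIdx(a.GetIdx()) for b in a.GetBonds()] for a in mol.GetAtoms()
    ]
    bits: set[int] = set()

    def emit(path: list[int]) -> None:
        fwd = tuple(labels[i] for i in path)
        canon = min(fwd, fwd[::-1])
        digest = zlib.crc32(bytes(f"{len(canon)}:{canon}", "utf8"))
        bits.add(digest % n_bits)

    def dfs(path: list[int], seen: set[int]) -> None:
        emit(path)
        if len(path) == max_path:
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in seen:
                path.append(nxt)
                seen.add(nxt)
                dfs(path, seen)
                seen.discard(nxt)
                path.pop()

    for start in range(mol.GetNumAtoms()):
        dfs([start], {start})
    return frozenset(bits)


def _fp2_fingerprint(mol: Chem.Mol, n_bits: int) -> frozenset:
    """Open Babel FP2: hashed linear fragments up to 7 atoms."""
    from openbabel import pybel

    obmol = pybel.readstring("smi", Chem.MolToSmiles(mol))
    # pybel reports 1-based bit indices over a 1024-bit vector
    return frozenset((b - 1) % n_bits for b in obmol.calcfp("FP2").bits)


def compute_fingerprint(mol: Chem.Mol, spec: FingerprintSpec) -> BitFingerprint:
    """Compute one fingerprint for an RDKit molecule under ``spec``."""
    p = spec.param_dict
    if spec.family == "circular":
        if p.get("features"):
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=p["radius"], fpSize=spec.n_bits,
                atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
            )
        else:
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=p["radius"], fpSize=spec.n_bits
            )
        bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
    elif spec.family == "atom-pair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=spec.n_bits)
        bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
    elif spec.family == "torsion":
        gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=spec.n_bits)
        bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
    elif spec.family == "hashed-path":
        variant = p.get("variant", "rdkit")
        if variant == "pattern":
            bits = frozenset(Chem.PatternFingerprint(mol, spec.n_bits).GetOnBits())
        elif variant == "rdkit":
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(
                minPath=1, maxPath=p.get("max_path", 7), fpSize=spec.n_bits
            )
            bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
        elif variant == "fp2":
            bits = _fp2_fingerprint(mol, spec.n_bits)
        elif variant == "graph":
            bits = _path_fingerprint(mol, spec.n_bits, p.get("max_path", 7), "element")
        elif variant == "hybridization":
            bits = _path_fingerprint(mol, spec.n_bits, p.get("max_path", 7), "hybridization")
        else:
            raise ValueError(f"unknown hashed-path variant {variant!r}")
    elif spec.family == "smarts-keys":
        if p.get("builtin") == "maccs":
            # RDKit's MACCS vector reserves bit 0; shift to the 166-key space.
            bits = frozenset(i - 1 for i in MACCSkeys.GenMACCSKeys(mol).GetOnBits())
        else:
            bits = frozenset(
                i
                for i, patt, min_count in _load_keys(p["key_file"])
                if (
                    mol.HasSubstructMatch(patt)
                    if min_count == 1
                    else len(mol.GetSubstructMatches(patt, maxMatches=min_count))
                    >= min_count
                )
            )
    else:  # pragma: no cover - registry validates families
        raise ValueError(f"unknown family {spec.family!r}")
    return BitFingerprint(spec.name, bits, spec.n_bits)


# ---------------------------------------------------------------------------
# panels

class FingerprintPanel:
    """Per-molecule fingerprint rows aligned to a registry's spec order."""

    def __init__(self, registry: Registry):
        self.registry = registry
        self.rows: dict[str, tuple[BitFingerprint, ...]] = {}
        self.errors: dict[str, str] = {}
        self._packed_cache: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = {}
        self._pos_cache: dict[str, int] | None = None

    @property
    def registry_hash(self) -> str:
        return self.registry.registry_hash

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.rows)

    def add(self, molecule_id: str, fps: Sequence[BitFingerprint]) -> None:
        if len(fps) != len(self.registry):
            raise ValueError("row length does not match registry")
        for fp, spec in zip(fps, self.registry.specs):
            if fp.spec_name != spec.name:
                raise ValueError("row order does not match registry order")
        self.rows[molecule_id] = tuple(fps)
        self._packed_cache.clear()
        self._pos_cache = None

    def row(self, molecule_id: str) -> tuple[BitFingerprint, ...]:
        return self.rows[molecule_id]

    def fingerprint(self, molecule_id: str, spec_name: str) -> BitFingerprint:
        return self.rows[molecule_id][self.registry.index(spec_name)]

    def packed(self, spec_name: str) -> tuple[list[str], np.ndarray, np.ndarray]:
        """All rows of one spec packed as uint64 words: (ids, matrix, popcounts)."""
        if spec_name not in self._packed_cache:
            spec = self.registry[spec_name]
            ids = list(self.rows)
            mat = np.zeros((len(ids), (spec.n_bits + 63) // 64), dtype=np.uint64)
            for r, mid in enumerate(ids):
                mat[r] = pack_bits(self.rows[mid][self.registry.index(spec_name)].bits, spec.n_bits)
            pops = np.bitwise_count(mat).sum(axis=1).astype(np.int64)
            self._packed_cache[spec_name] = (ids, mat, pops)
        return self._packed_cache[spec_name]

    def position(self) -> dict[str, int]:
        """molecule_id -> row index shared by every ``packed`` matrix."""
        if self._pos_cache is None:
            self._pos_cache = {mid: i for i, mid in enumerate(self.rows)}
        return self._pos_cache


def _smiles_of(molecule) -> tuple[str, str]:
    """(id, smiles) from a standardized/ionized structure or an (id, smiles) pair."""
    if hasattr(molecule, "source_id") and hasattr(molecule, "smiles"):
        return molecule.source_id, molecule.smiles
    mid, smiles = molecule
    return mid, smiles


def compute_panel(molecules: Iterable, registry: Registry) -> FingerprintPanel:
    """Fingerprint every molecule under every registered spec.

    Accepts standardized (neutral) or ionized structures — the two parallel
    representations of the same library — or plain ``(id, smiles)`` pairs.
    Failures are recorded per molecule in ``panel.errors``, not raised.
    """
    panel = FingerprintPanel(registry)
    for molecule in molecules:
        mid, smiles = _smiles_of(molecule)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            panel.errors[mid] = f"unparseable SMILES {smiles!r}"
            continue
        try:
            panel.add(mid, [compute_fingerprint(mol, spec) for spec in registry.specs])
        except Exception as exc:
            panel.errors[mid] = str(exc)
    return panel


# ---------------------------------------------------------------------------
# similarity

def pack_bits(bits: frozenset | set, n_bits: int) -> np.ndarray:
    """Pack a set of bit indices into uint64 words (little-endian within word)."""
    words = np.zeros((n_bits + 63) // 64, dtype=np.uint64)
    for b in bits:
        words[b >> 6] |= np.uint64(1) << np.uint64(b & 63)
    return words


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over on-bits.

    Two empty fingerprints score 0.0: absence of features is never treated
    as similarity.
    """
    if a.spec_name != b.spec_name:
        raise ValueError(f"fingerprint spec mismatch: {a.spec_name} vs {b.spec_name}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def bulk_tanimoto(query: BitFingerprint, mat: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """Tanimoto of one query fingerprint against a packed row matrix."""
    q = pack_bits(query.bits, query.n_bits)
    inter = np.bitwise_count(mat & q).sum(axis=1).astype(np.int64)
    union = pops + int(np.bitwise_count(q).sum()) - inter
    out = np.zeros(len(mat), dtype=np.float64)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out
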
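"""Per-fingerprint similarity-threshold calibration from random-pair Tc.

Different fingerprint types have wildly different background similarity:
a Tanimoto of 0.4 may be meaningless for a sparse key set and highly
significant for a dense hashed fingerprint.  The remedy is empirical: draw a
large sample of random molecule pairs from the library, compute their Tc
under every registered fingerprint, and take the m-th percentile of each
distribution as that fingerprint's significance threshold Tc_m%.  Pairs
scoring at or above the threshold are "statistically significant" matches.

Percentile convention: the threshold is the smallest observed Tc value t
such that the fraction of pairs with Tc <= t is at least m/100 (empirical
lower-value percentile, no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .fingerprints import FingerprintPanel, bulk_tanimoto, pack_bits

__all__ = [
    "PairSample",
    "ThresholdTable",
    "sample_random_pairs",
    "pair_tanimotos",
    "calibrate_thresholds",
    "calibrate_from_panel",
]


@dataclass(frozen=True)
class PairSample:
    """One random molecule pair with its Tc under every fingerprint.

    Pairs are unordered; ``id_a < id_b`` canonically.
    """

    id_a: str
    id_b: str
    tc_by_fp: Mapping[str, float] = field(default_factory=dict)


@dataclass
class ThresholdTable:
    """Calibrated Tc_m% thresholds plus the provenance needed to reproduce them."""

    thresholds: dict[str, float]
    m_percent: float
    n_pairs: int
    seed: int
    registry_hash: str = ""

    def __getitem__(self, spec_name: str) -> float:
        return self.thresholds[spec_name]

    def __len__(self) -> int:
        return len(self.thresholds)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "thresholds": {k: float(v) for k, v in self.thresholds.items()},
                    "m_percent": float(self.m_percent),
                    "n_pairs": int(self.n_pairs),
                    "seed": int(self.seed),
                    "registry_hash": self.registry_hash,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def load(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            thresholds=d["thresholds"],
            m_percent=d["m_percent"],
            n_pairs=d["n_pairs"],
            seed=d["seed"],
            registry_hash=d.get("registry_hash", ""),
        )


def sample_random_pairs(
    library: Sequence[str], n_pairs: int, seed: int
) -> list[tuple[str, str]]:
    """Draw unordered distinct molecule pairs uniformly, with replacement.

    Reproducible for a given seed; each of the C(n,2) unordered pairs is
    equally likely on every draw.
    """
    n = len(library)
    if n < 2:
        raise ValueError("need at least 2 molecules to form pairs")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_pairs)
    b = rng.integers(0, n - 1, size=n_pairs)
    b = np.where(b >= a, b + 1, b)  # resolve collisions uniformly
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return [(library[i], library[j]) for i, j in zip(lo, hi)]


def pair_tanimotos(
    panel: FingerprintPanel, pairs: Sequence[tuple[str, str]]
) -> dict[str, np.ndarray]:
    """Tc of every pair under every registered spec (vectorized popcounts)."""
    out: dict[str, np.ndarray] = {}
    pos = panel.position()
    ia = np.fromiter((pos[a] for a, _ in pairs), dtype=np.int64, count=len(pairs))
    ib = np.fromiter((pos[b] for _, b in pairs), dtype=np.int64, count=len(pairs))
    for spec in panel.registry.specs:
        ids, mat, pops = panel.packed(spec.name)
        inter = np.bitwise_count(mat[ia] & mat[ib]).sum(axis=1).astype(np.int64)
        union = pops[ia] + pops[ib] - inter
        tc = np.zeros(len(pairs))
        nz = union > 0
        tc[nz] = inter[nz] / union[nz]
        out[spec.name] = tc
    return out


def empirical_threshold(tc_values: np.ndarray, m_percent: float) -> float:
    """Smallest observed t with fraction(Tc <= t) >= m/100."""
    if len(tc_values) == 0:
        raise ValueError("cannot calibrate on an empty sample")
    if not (0 < m_percent <= 100):
        raise ValueError("m_percent must be in (0, 100]")
    srt = np.sort(np.asarray(tc_values, dtype=np.float64))
    k = int(np.ceil(m_percent / 100 * len(srt)))
    return float(srt[max(k, 1) - 1])


def calibrate_thresholds(
    pairs: Sequence[PairSample] | Mapping[str, np.ndarray],
    m_percent: float,
    *,
    n_pairs: int | None = None,
    seed: int = 0,
    registry_hash: str = "",
) -> ThresholdTable:
    """Designate per-fingerprint Tc_m% thresholds from a pair sample.

    Accepts either a list of :class:`PairSample` or a precomputed mapping of
    spec name to Tc array.  Every pair must carry a Tc for every spec.
    """
    if isinstance(pairs, Mapping):
        tc_by_fp = {k: np.asarray(v) for k, v in pairs.items()}
        n = len(next(iter(tc_by_fp.values()))) if tc_by_fp else 0
    else:
        if not pairs:
            raise ValueError("cannot calibrate on an empty pair list")
        names = set(pairs[0].tc_by_fp)
        for p in pairs:
            if set(p.tc_by_fp) != names:
                raise ValueError("every pair must carry a Tc for every spec")
        tc_by_fp = {
            name: np.array([p.tc_by_fp[name] for p in pairs]) for name in sorted(names)
        }
        n = len(pairs)
    if not tc_by_fp:
        raise ValueError("no fingerprint columns to calibrate")
    thresholds = {
        name: empirical_threshold(vals, m_percent) for name, vals in tc_by_fp.items()
    }
    return ThresholdTable(
        thresholds=thresholds,
        m_percent=m_percent,
        n_pairs=n_pairs if n_pairs is not None else n,
        seed=seed,
        registry_hash=registry_hash,
    )


def calibrate_from_panel(
    panel: FingerprintPanel, n_pairs: int, m_percent: float, seed: int
) -> ThresholdTable:
    """Sample pairs from a fingerprinted library and calibrate in one step.

    Calibration must run on the same molecular representation (neutral or
    ionized) as the database that will be searched.
    """
    pairs = sample_random_pairs(panel.molecule_ids, n_pairs, seed)
    tc_by_fp = pair_tanimotos(panel, pairs)
    return calibrate_thresholds(
        tc_by_fp, m_percent, n_pairs=n_pairs, seed=seed,
        registry_hash=panel.registry_hash,
    )
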